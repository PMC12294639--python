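# Default keyword lexicon for NLP detection of drug-use documentation
# in clinical notes. One entry per line; "#" starts a comment.
# Matching is case-insensitive; entries whose longest token is <= 4
# characters (acronyms) are matched exactly, never fuzzily.
IVDU
FENTANYL
Methadone
heroin
suboxone
IVDA
drug abuse
SUD
Substance use disorder
opioid use disorder
opioid abuse
OUD
opioid overdose
illicit drugs
addicted
addict
drug addict
injection drug use
intravenous drug use
uses fentanyl
Uses heroin
PWID
abuses drugs
injects heroin
injects drugs
injects fentanyl
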