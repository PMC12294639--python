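# Default ICD-9/ICD-10 code table for the diagnosis criterion.
# ICD-10 entries are family prefixes (dot-stripped prefix match);
# ICD-9 entries are exact codes (dot-stripped equality).
# The hepatitis-C ICD-9 family is 070.41/070.44/070.51/070.54/070.70/070.71;
# one source listing misprints the first as "0.70.41" and it is corrected here.
system,code,description
ICD10,F11,Opioid-related disorders
ICD10,F14,Cocaine-related disorder
ICD10,F15,Other stimulant-related disorders
ICD10,T400,Poisoning by opium
ICD10,T401,Poisoning by heroin
ICD10,T402,Poisoning by other opioids
ICD10,T403,Poisoning by methadone
ICD10,T404,Poisoning by synthetic narcotics
ICD10,T405,Poisoning by cocaine
ICD10,T406,Poisoning by unspecified narcotics
ICD10,T436,Poisoning by psychostimulants
ICD10,B18.2,Chronic viral hepatitis C
ICD9,070.41,Acute hepatitis C with hepatic coma
ICD9,070.44,Chronic hepatitis C with hepatic coma
ICD9,070.51,Acute hepatitis C without hepatic coma
ICD9,070.54,Chronic hepatitis C without hepatic coma
ICD9,070.70,Unspecified viral hepatitis C without hepatic coma
ICD9,070.71,Unspecified viral hepatitis C with hepatic coma
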