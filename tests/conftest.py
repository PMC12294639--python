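from functools import lru_cache

import pytest

from pwud_phenotype.text_matching import KeywordLexicon, MatcherConfig


def osa_distance_oracle(a: str, b: str) -> int:
    """Brute-force recursive optimal-string-alignment distance (memoized).

    Independent reference for the iterative DP in the package.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(rec(i - 1, j) + 1, rec(i, j - 1) + 1, rec(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, rec(i - 2, j - 2) + 1)
        return best

    return rec(len(a), len(b))


@pytest.fixture(scope="session")
def lexicon() -> KeywordLexicon:
    return KeywordLexicon.default()


@pytest.fixture
def matcher_config() -> MatcherConfig:
    return MatcherConfig()
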