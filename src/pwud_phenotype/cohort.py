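"""Cohort assembly: Venn partition of {B,D,M,N} and review sampling.

Included encounters (at least one criterion true) are partitioned into
the 15 non-empty cells of the four-set Venn diagram. Two cells anchor the
documentation-disparity analysis: the *highly documented* group (all four
criteria, cell {B,D,M,N}) and the *minimally documented* group (NLP only,
cell {N}). "X-only" always means the pure singleton cell — the criterion
present and the other three absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .types import DomainFlags

BDMN_KEY = frozenset("BDMN")
N_ONLY_KEY = frozenset("N")


def cell_label(key: frozenset[str]) -> str:
    """Canonical cell name in B,D,M,N order, e.g. 'BDN'."""
    return "".join(letter for letter in "BDMN" if letter in key)


@dataclass
class CohortPartition:
    """Disjoint assignment of included encounters to Venn cells."""

    cells: dict[frozenset[str], list[str]] = field(default_factory=dict)
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def total_included(self) -> int:
        return sum(len(ids) for ids in self.cells.values())

    def cell(self, key: Union[frozenset[str], str]) -> list[str]:
        if isinstance(key, str):
            key = frozenset(key.upper())
        return self.cells.get(key, [])

    def counts(self) -> dict[str, int]:
        return {cell_label(k): len(v) for k, v in sorted(self.cells.items(), key=cell_label)}


def build_partition(
    flags: Iterable[tuple[str, DomainFlags]],
) -> CohortPartition:
    """Partition encounters by their true-flag subset.

    Encounters with no true flag are excluded from the cohort and tracked
    separately. Duplicate encounter ids are an error.
    """
    partition = CohortPartition()
    seen: set[str] = set()
    for encounter_id, domain_flags in flags:
        if encounter_id in seen:
            raise ValueError(f"duplicate encounter_id: {encounter_id!r}")
        seen.add(encounter_id)
        key = domain_flags.as_set()
        if not key:
            partition.excluded_ids.append(encounter_id)
            continue
        partition.cells.setdefault(key, []).append(encounter_id)
    return partition


def comparison_groups(partition: CohortPartition) -> tuple[list[str], list[str]]:
    """The (highly documented, minimally documented) id lists.

    Highly documented = cell {B,D,M,N}; minimally documented = cell {N}.
    An absent cell is an empty group.
    """
    return list(partition.cell(BDMN_KEY)), list(partition.cell(N_ONLY_KEY))


@dataclass
class ReviewSample:
    """A simple random sample of one cell drawn for chart review."""

    subcohort: frozenset[str]
    sampled_ids: list[str]
    sampling_fraction: float
    seed: int


def select_review_sample(
    partition: CohortPartition,
    subcohort: Union[frozenset[str], str],
    fraction: Optional[float] = None,
    n: Optional[int] = None,
    seed: int = 0,
) -> ReviewSample:
    """Draw a without-replacement review sample from one Venn cell.

    Exactly one of ``fraction`` (0 < f <= 1; sample size = round(f * cell
    size)) or ``n`` (absolute count) must be given. Deterministic under
    ``seed``.
    """
    if isinstance(subcohort, str):
        subcohort = frozenset(subcohort.upper())
    cell_ids = partition.cell(subcohort)
    if not cell_ids:
        raise ValueError(f"subcohort {cell_label(subcohort)!r} is empty or absent")
    if (fraction is None) == (n is None):
        raise ValueError("give exactly one of fraction or n")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        n = int(round(fraction * len(cell_ids)))
        n = max(n, 1)
    assert n is not None
    if not 0 < n <= len(cell_ids):
        raise ValueError(f"sample size {n} exceeds cell size {len(cell_ids)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cell_ids), size=n, replace=False)
    sampled = [cell_ids[int(i)] for i in sorted(int(x) for x in idx)]
    return ReviewSample(
        subcohort=subcohort,
        sampled_ids=sampled,
        sampling_fraction=n / len(cell_ids),
        seed=seed,
    )
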