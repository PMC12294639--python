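"""Evaluation arithmetic for the phenotyping cohort.

Three estimators, matching standard epidemiological practice:

* **PPV** of a review sample — confirmed / reviewed, with an exact
  Clopper–Pearson 95% interval and the percent rounded half-away-from-zero
  as conventionally printed;
* **2×2 odds ratios** — cross-product OR with the Woolf (log-normal)
  confidence interval, ``SE = sqrt(1/a + 1/b + 1/c + 1/d)``, and the
  Haldane–Anscombe 0.5 correction when exactly one cell is zero;
* **adjusted odds ratios** — maximum-likelihood logistic regression
  (binomial GLM) with Wald intervals ``exp(beta ± 1.96 SE)``.

The disparity report assembles these into a descriptive comparison of the
highly documented (all four criteria, "BDMN") versus minimally documented
(NLP-only) groups: odds of BDMN membership for White/non-Hispanic versus
racially/ethnically minoritized encounters, and for the 3rd–4th versus
1st–2nd Social Vulnerability Index quartiles, unadjusted and adjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortPartition, comparison_groups
from .types import Encounter

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class PPVResult:
    reviewed: int
    confirmed: int
    ppv: float
    ppv_pct_rounded: int
    ci95: tuple[float, float]


def ppv(confirmed: int, reviewed: int) -> PPVResult:
    """Positive predictive value with exact Clopper–Pearson 95% CI.

    The rounded percent uses round-half-away-from-zero, the convention of
    printed tables (53/99 -> 54%).
    """
    if reviewed < 1:
        raise ValueError("reviewed must be >= 1")
    if not 0 <= confirmed <= reviewed:
        raise ValueError("confirmed must be in [0, reviewed]")
    p = confirmed / reviewed
    low, high = proportion_confint(confirmed, reviewed, alpha=0.05, method="beta")
    return PPVResult(
        reviewed=reviewed,
        confirmed=confirmed,
        ppv=p,
        ppv_pct_rounded=int(math.floor(p * 100.0 + 0.5)),
        ci95=(float(low), float(high)),
    )


@dataclass
class TwoByTwoTable:
    """A 2×2 count table with fixed orientation.

    Rows are exposure (level of interest first, reference second); columns
    are outcome groups (group 1 first, group 2 second)::

                       outcome group 1   outcome group 2
        exposure         a                 b
        reference        c                 d

    so the cross-product odds ratio a*d / (b*c) is the odds of group-1
    membership for the exposure level relative to the reference.
    """

    a: float
    b: float
    c: float
    d: float
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be >= 0")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def transposed_exposure(self) -> "TwoByTwoTable":
        """Swap exposure rows (reference becomes the level of interest)."""
        return TwoByTwoTable(self.c, self.d, self.a, self.b,
                             self.exposure_label, self.outcome_label)


@dataclass
class ORResult:
    or_point: float
    log_or: float
    se_log_or: float
    ci95: tuple[float, float]
    method: str = "woolf"
    continuity_corrected: bool = False


def odds_ratio_2x2(table: TwoByTwoTable) -> ORResult:
    """Cross-product odds ratio with a Woolf 95% confidence interval.

    If exactly one cell is zero, the Haldane–Anscombe correction (0.5
    added to every cell) is applied and flagged. Two zero cells in a
    diagonal/cross pattern leave the OR undefined and raise.
    """
    a, b, c, d = table.cells()
    zeros = sum(x == 0 for x in (a, b, c, d))
    corrected = False
    if zeros >= 2 and ((a == 0 and d == 0) or (b == 0 and c == 0)):
        raise ValueError("odds ratio undefined: two zero cells in a cross pattern")
    if zeros >= 1:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_point = (a * d) / (b * c)
    log_or = math.log(or_point)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))
    return ORResult(
        or_point=or_point, log_or=log_or, se_log_or=se, ci95=ci,
        method="woolf", continuity_corrected=corrected,
    )


@dataclass
class LogisticFit:
    coefficients: dict[str, float]
    se: dict[str, float]
    or_estimates: dict[str, float]
    wald_ci95: dict[str, tuple[float, float]]
    converged: bool
    n_used: int
    n_dropped_missing: int


def fit_logistic(
    outcome: Sequence[int],
    covariates: pd.DataFrame,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    Rows with any missing covariate (or outcome) are dropped and counted.
    Perfect separation (or other non-convergence) is flagged rather than
    raised; estimates are still returned with a warning.
    """
    y = pd.Series(np.asarray(outcome), name="outcome").reset_index(drop=True)
    X = covariates.reset_index(drop=True).astype(float)
    if len(y) != len(X):
        raise ValueError("outcome and covariates must have equal length")
    keep = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~keep).sum())
    y, X = y[keep], X[keep]
    if not set(pd.unique(y)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(y) < X.shape[1] + 1:
        raise ValueError("too few rows for the number of model terms")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100, tol=1e-8)
        except Exception as exc:  # non-convergence, singular matrix, ...
            warnings.warn(f"logistic fit failed to converge: {exc}")
            res = model.fit(maxiter=100, tol=1e-8, method="lbfgs")
            converged = False
        if any("separation" in str(w.message).lower() or "converge" in str(w.message).lower()
               for w in caught):
            converged = False
    params = res.params
    bse = res.bse
    # runaway coefficients are the practical signature of separation
    if np.any(np.abs(params.values) > 15) or np.any(~np.isfinite(bse.values)):
        converged = False
    if not converged:
        warnings.warn("possible perfect separation or non-convergence in logistic fit")
    coeffs = {term: float(params[term]) for term in params.index}
    ses = {term: float(bse[term]) for term in params.index}

    def _exp(x: float) -> float:  # overflow-safe under separation
        try:
            return math.exp(x)
        except OverflowError:
            return math.inf

    return LogisticFit(
        coefficients=coeffs,
        se=ses,
        or_estimates={t: _exp(v) for t, v in coeffs.items()},
        wald_ci95={
            t: (_exp(coeffs[t] - Z95 * ses[t]), _exp(coeffs[t] + Z95 * ses[t]))
            for t in coeffs
        },
        converged=converged,
        n_used=int(len(y)),
        n_dropped_missing=n_dropped,
    )


# ---------------------------------------------------------------------------
# disparity report


def _group_frame(encounters: Sequence[Encounter], bdmn: set[str], n_only: set[str]) -> pd.DataFrame:
    rows = []
    for e in encounters:
        if e.encounter_id in bdmn:
            group = "bdmn"
        elif e.encounter_id in n_only:
            group = "n_only"
        else:
            group = "other"
        rows.append(
            {
                "encounter_id": e.encounter_id,
                "group": group,
                "age": e.age,
                "sex": e.sex,
                "race_eth": e.race_eth,
                "svi_quartile": e.svi_quartile,
                "length_of_stay": e.length_of_stay,
                "primary_language": e.primary_language,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DisparityReport:
    descriptive: pd.DataFrame
    unadjusted: dict[str, ORResult]
    adjusted: dict[str, LogisticFit]
    n_missing_svi: int
    group_sizes: dict[str, int]

    def to_markdown(self) -> str:
        lines = ["# Documentation-disparity report", "", "## Descriptive", ""]
        lines.append(self.descriptive.to_markdown(index=False))
        lines.append("")
        lines.append("## Odds of highly-documented (BDMN) membership")
        lines.append("")
        for term, orr in self.unadjusted.items():
            lines.append(
                f"- {term}: unadjusted OR {orr.or_point:.2f} "
                f"(95% CI {orr.ci95[0]:.2f}, {orr.ci95[1]:.2f})"
            )
        for term, fit in self.adjusted.items():
            key = {"race": "white", "svi": "svi_34"}[term]
            lo, hi = fit.wald_ci95[key]
            lines.append(
                f"- {term}: adjusted OR {fit.or_estimates[key]:.2f} "
                f"(95% CI {lo:.2f}, {hi:.2f}); n={fit.n_used}"
            )
        lines.append(f"\nEncounters with missing SVI excluded from SVI models: "
                     f"{self.n_missing_svi}")
        return "\n".join(lines)


def disparity_report(
    partition: CohortPartition, encounters: Sequence[Encounter]
) -> DisparityReport:
    """Compare the highly- vs minimally-documented groups.

    Outcome is membership in the BDMN cell (versus NLP-only). Exposure
    references follow the descriptive-table convention: racially/
    ethnically minoritized and SVI quartiles 1–2 (most vulnerable) are the
    reference levels, so an OR > 1 means higher odds of being highly
    documented for White/non-Hispanic (resp. less-vulnerable) encounters.
    Missing SVI is excluded listwise from models that include SVI.
    """
    bdmn_ids, n_only_ids = comparison_groups(partition)
    if not bdmn_ids or not n_only_ids:
        raise ValueError("both comparison groups must be non-empty")
    included = {eid for ids in partition.cells.values() for eid in ids}
    frame = _group_frame([e for e in encounters if e.encounter_id in included],
                         set(bdmn_ids), set(n_only_ids))

    comp = frame[frame["group"].isin(["bdmn", "n_only"])].copy()
    comp["outcome"] = (comp["group"] == "bdmn").astype(int)
    comp["white"] = (comp["race_eth"] == "white_nonhispanic").astype(int)
    comp["male"] = (comp["sex"] == "male").astype(int)
    comp["svi_34"] = comp["svi_quartile"].map(
        lambda q: np.nan if pd.isna(q) else float(q in (3, 4))
    )
    comp["age_z"] = (comp["age"] - comp["age"].mean()) / comp["age"].std(ddof=0)

    # unadjusted 2x2 ORs
    def count(mask) -> int:
        return int(mask.sum())

    race_table = TwoByTwoTable(
        a=count((comp["white"] == 1) & (comp["outcome"] == 1)),
        b=count((comp["white"] == 1) & (comp["outcome"] == 0)),
        c=count((comp["white"] == 0) & (comp["outcome"] == 1)),
        d=count((comp["white"] == 0) & (comp["outcome"] == 0)),
        exposure_label="white_nonhispanic vs minoritized",
        outcome_label="bdmn vs n_only",
    )
    svi_known = comp[comp["svi_34"].notna()]
    svi_table = TwoByTwoTable(
        a=count((svi_known["svi_34"] == 1) & (svi_known["outcome"] == 1)),
        b=count((svi_known["svi_34"] == 1) & (svi_known["outcome"] == 0)),
        c=count((svi_known["svi_34"] == 0) & (svi_known["outcome"] == 1)),
        d=count((svi_known["svi_34"] == 0) & (svi_known["outcome"] == 0)),
        exposure_label="SVI 3rd-4th vs 1st-2nd quartile",
        outcome_label="bdmn vs n_only",
    )
    unadjusted = {
        "race": odds_ratio_2x2(race_table),
        "svi": odds_ratio_2x2(svi_table),
    }

    # adjusted models, one per exposure with its own adjustment set
    adjusted = {
        "race": fit_logistic(  # race OR adjusted for age, sex, SVI
            comp["outcome"], comp[["white", "age_z", "male", "svi_34"]]
        ),
        "svi": fit_logistic(  # SVI OR adjusted for age, sex, race
            comp["outcome"], comp[["svi_34", "age_z", "male", "white"]]
        ),
    }

    descriptive = _descriptive_table(frame)
    return DisparityReport(
        descriptive=descriptive,
        unadjusted=unadjusted,
        adjusted=adjusted,
        n_missing_svi=int(comp["svi_34"].isna().sum()),
        group_sizes={
            "included": len(frame),
            "bdmn": len(bdmn_ids),
            "n_only": len(n_only_ids),
        },
    )


def _descriptive_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts and percents per variable for all-included, BDMN, N-only."""
    groups = {
        "all_included": frame,
        "bdmn": frame[frame["group"] == "bdmn"],
        "n_only": frame[frame["group"] == "n_only"],
    }
    rows = []

    def add(variable: str, level: str, values: dict[str, str]) -> None:
        rows.append({"variable": variable, "level": level, **values})

    add("n", "", {g: str(len(df)) for g, df in groups.items()})
    for var, fmt in (("age", "{:.1f} ({:.1f})"), ("length_of_stay", "{:.1f} ({:.1f})")):
        add(var, "mean (SD)", {
            g: fmt.format(df[var].mean(), df[var].std(ddof=1)) if len(df) else "-"
            for g, df in groups.items()
        })
    for var, levels in (
        ("sex", ["male", "female"]),
        ("race_eth", ["minoritized", "white_nonhispanic"]),
        ("primary_language", ["english", "spanish", "other"]),
    ):
        for level in levels:
            add(var, level, {
                g: f"{(df[var] == level).sum()} "
                   f"({100 * (df[var] == level).mean():.1f}%)" if len(df) else "-"
                for g, df in groups.items()
            })
    svi34 = frame["svi_quartile"].map(lambda q: None if pd.isna(q) else q in (3, 4))
    for label, pred in (
        ("3rd-4th", lambda s: s == True),   # noqa: E712 - vectorised compare
        ("1st-2nd", lambda s: s == False),  # noqa: E712
        ("missing", lambda s: s.isna()),
    ):
        add("svi_quartile", label, {
            g: f"{int(pred(df['svi_quartile'].map(lambda q: None if pd.isna(q) else q in (3, 4))).sum())}"
            for g, df in groups.items()
        })
    return pd.DataFrame(rows)
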