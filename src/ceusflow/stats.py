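"""Group comparison statistics for the perfusion analysis.

Implements the comparison scheme applied to the exam-level perfusion
records: stratification by days on circuit (early <= 4, intermediate 5-8,
late >= 9), two-sided Mann-Whitney U tests with continuity correction
(exact enumeration for small tie-free samples), Benjamini-Hochberg
false-discovery-rate adjustment within each analysis family, paired
central-vs-peripheral region contrasts (absolute difference and ratio),
and Spearman rank correlations against cardiac covariates.

Observations are exam-level (one to three exams per animal) and treated as
independent, matching the presentation of the summary tables; no
longitudinal modelling is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "stratify",
    "mann_whitney_u",
    "bh_adjust",
    "spearman_rho",
    "summarize_table1",
    "region_contrasts",
    "PERFUSION_PARAMS",
]

logger = logging.getLogger(__name__)

PERFUSION_PARAMS = ("mfv", "transit_time", "mbf")
STRATA = ("early", "intermediate", "late")


def stratify(day_on_circuit: int) -> str:
    """Stratum of an exam by days on circuit: <=4 early, 5-8 intermediate, >=9 late."""
    day = int(day_on_circuit)
    if day < 1:
        raise InputError(f"day_on_circuit must be >= 1, got {day}")
    if day <= 4:
        return "early"
    if day <= 8:
        return "intermediate"
    return "late"


@dataclass
class GroupTestResult:
    """One two-sample Mann-Whitney comparison, before/after FDR adjustment."""

    variable: str
    region: str = ""
    stratum: str = "all"
    n1: int = 0
    n2: int = 0
    median1: float = float("nan")
    median2: float = float("nan")
    iqr1: float = float("nan")
    iqr2: float = float("nan")
    u_statistic: float = float("nan")
    z_statistic: float = float("nan")
    p_raw: float = float("nan")
    p_adjusted: float | None = None
    method: str = ""

    @property
    def significant(self) -> bool:
        return self.p_adjusted is not None and self.p_adjusted <= 0.05


def _iqr(values: np.ndarray) -> float:
    """75th minus 25th percentile, linear-interpolation quantile rule."""
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def mann_whitney_u(
    x,
    y,
    variable: str = "",
    region: str = "",
    stratum: str = "all",
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test with continuity correction.

    U is computed from midranks (so ties contribute half counts).  The
    two-sided p-value comes from the normal approximation with
    tie-corrected variance and a 0.5 continuity correction; when the
    pooled sample has at most 10 observations and no ties, the exact
    permutation distribution is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var > 0:
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    else:
        z = 0.0

    if n <= 10 and not has_ties:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        method = "exact"
    else:
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
        method = "normal-approx, continuity-corrected"

    return GroupTestResult(
        variable=variable,
        region=region,
        stratum=stratum,
        n1=n1,
        n2=n2,
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        iqr1=_iqr(x),
        iqr2=_iqr(y),
        u_statistic=float(u1),
        z_statistic=float(z),
        p_raw=p,
        method=method,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    """Spearman rank correlation between a cardiac and a perfusion variable."""

    cardiac_variable: str
    perfusion_variable: str
    region: str = ""
    group: str = ""
    n: int = 0
    rho: float = float("nan")
    p_raw: float = float("nan")
    p_adjusted: float | None = None
    undefined: bool = False


def spearman_rho(
    x,
    y,
    cardiac_variable: str = "",
    perfusion_variable: str = "",
    region: str = "",
    group: str = "",
) -> CorrelationResult:
    """Spearman's rho with the t-approximation p-value (n - 2 df).

    A constant sample leaves the rank correlation undefined; the result is
    flagged rather than coerced to zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("samples must be paired 1-D arrays")
    if x.size < 3:
        raise InputError("Spearman correlation needs n >= 3")
    base = dict(
        cardiac_variable=cardiac_variable,
        perfusion_variable=perfusion_variable,
        region=region,
        group=group,
        n=int(x.size),
    )
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(**base, undefined=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(**base, rho=float(rho), p_raw=float(p))


# --- table-level summaries ---------------------------------------------------


def _tests_to_frame(tests: list[GroupTestResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(t) for t in tests])
    if not df.empty:
        df["significant"] = [t.significant for t in tests]
    return df


def _adjust_family(tests: list[GroupTestResult]) -> None:
    valid = [t for t in tests if np.isfinite(t.p_raw)]
    if valid:
        adj = bh_adjust([t.p_raw for t in valid])
        for t, a in zip(valid, adj):
            t.p_adjusted = float(a)


def summarize_table1(
    records: pd.DataFrame,
    groups: tuple[str, str] = ("hypoxic", "normoxic"),
    stratum: str = "all",
) -> pd.DataFrame:
    """Median +/- IQR per group, region and parameter, with adjusted p.

    ``records`` is an exam-level perfusion table with columns ``group``,
    ``region`` and the perfusion parameters.  One Mann-Whitney test per
    region x parameter cell; Benjamini-Hochberg adjustment across the
    family (9 tests for three regions and three parameters).  Empty cells
    are reported as missing and skipped by the adjustment.
    """
    tests: list[GroupTestResult] = []
    for region in sorted(records["region"].unique()):
        sub = records[records["region"] == region]
        for param in PERFUSION_PARAMS:
            a = sub.loc[sub["group"] == groups[0], param].dropna().to_numpy()
            b = sub.loc[sub["group"] == groups[1], param].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                tests.append(GroupTestResult(variable=param, region=region, stratum=stratum,
                                             n1=a.size, n2=b.size, method="missing"))
                continue
            tests.append(mann_whitney_u(a, b, variable=param, region=region, stratum=stratum))
    _adjust_family(tests)
    return _tests_to_frame(tests)


def region_contrasts(
    records: pd.DataFrame,
    central: str = "central_thalamic",
    peripheral: str = "peripheral_parenchyma",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Central-minus-peripheral differences and central/peripheral ratios.

    Pairs the two small-ROI records of each exam; exams missing either
    region are skipped (count logged).  Returns the per-exam contrast table
    and the family of Mann-Whitney group comparisons (difference and ratio
    for each parameter) with BH adjustment within the family.
    """
    key = ["animal_id", "day"]
    day_col = "day" if "day" in records.columns else "day_on_circuit"
    recs = records.rename(columns={day_col: "day"})
    cen = recs[recs["region"] == central]
    per = recs[recs["region"] == peripheral]
    merged = cen.merge(per, on=key + ["group"], suffixes=("_central", "_peripheral"))
    n_exams = len(recs[recs["region"].isin([central, peripheral])].drop_duplicates(subset=key))
    skipped = n_exams - len(merged)
    if skipped > 0:
        logger.info("region_contrasts: skipped %d exams without a central/peripheral pair", skipped)

    rows = []
    for _, row in merged.iterrows():
        entry = {"animal_id": row["animal_id"], "day": row["day"], "group": row["group"]}
        for param in PERFUSION_PARAMS:
            c, p = row[f"{param}_central"], row[f"{param}_peripheral"]
            entry[f"{param}_difference"] = c - p
            entry[f"{param}_ratio"] = c / p if p > 0 else float("nan")
        rows.append(entry)
    contrasts = pd.DataFrame(rows)

    tests: list[GroupTestResult] = []
    if not contrasts.empty:
        groups = ("hypoxic", "normoxic")
        for param in PERFUSION_PARAMS:
            for measure in ("difference", "ratio"):
                col = f"{param}_{measure}"
                a = contrasts.loc[contrasts["group"] == groups[0], col].dropna().to_numpy()
                b = contrasts.loc[contrasts["group"] == groups[1], col].dropna().to_numpy()
                if a.size and b.size:
                    tests.append(mann_whitney_u(a, b, variable=col, region="central_vs_peripheral"))
        _adjust_family(tests)
    return contrasts, _tests_to_frame(tests)
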