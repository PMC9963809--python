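"""Clonogenic-assay quantification and nonparametric statistics.

The assay seeds a known number of cells per well (default 500, well area
862 mm^2) and counts the colonies formed after treatment; conditions are
compared with the Kruskal-Wallis rank test followed by Dunn's post hoc
pairwise z-tests, both implemented from the rank formulas with tie
correction.  Surviving fractions are colony means relative to a
reference condition, with delta-method SD propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneCountTable",
    "PairwiseResult",
    "TestResult",
    "surviving_fraction",
    "kruskal_wallis",
    "dunn_posthoc",
]

COUNT_COLUMNS = ["condition", "activity_MBq", "replicate", "clone_count"]


@dataclass
class CloneCountTable:
    """Replicate colony counts per (condition, activity) arm."""

    data: pd.DataFrame
    cells_seeded: int = 500
    well_area_mm2: float = 862.0

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clone count table lacks column(s): {missing}")
        if (self.data["clone_count"] < 0).any():
            raise ValueError("clone counts must be non-negative")

    def arm_label(self) -> pd.Series:
        return (
            self.data["condition"].astype(str)
            + " @ "
            + self.data["activity_MBq"].astype(float).map("{:g} MBq".format)
        )

    def groups(self) -> dict[str, np.ndarray]:
        """Counts per arm, keyed by '<condition> @ <activity> MBq'."""
        lab = self.arm_label()
        return {
            key: grp["clone_count"].to_numpy(dtype=float)
            for key, grp in self.data.groupby(lab, sort=True)
        }


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_adjusted: float
    significant_at_0_05: bool


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def surviving_fraction(
    table: CloneCountTable, reference_condition: str
) -> pd.DataFrame:
    """Mean colony count per arm relative to the reference arm.

    Returns one row per arm with ``fraction`` = arm mean / reference mean
    and ``fraction_sd`` propagated from the replicate SDs (delta method,
    treating the two means as independent).
    """
    lab = table.arm_label()
    grouped = table.data.groupby(lab, sort=True)["clone_count"]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    ns = grouped.size()
    # the reference may be a full arm label, a condition, or an activity
    if reference_condition in means.index:
        ref_keys = [reference_condition]
    else:
        ref_keys = [
            k
            for k in means.index
            if k.startswith(f"{reference_condition} @ ")
            or k.endswith(f"@ {reference_condition}")
        ]
    if not ref_keys:
        raise ValueError(f"reference condition {reference_condition!r} not found")
    m_ref = float(means[ref_keys].mean())
    if m_ref == 0:
        raise ValueError("reference condition has zero mean clone count")
    s_ref = float(sds[ref_keys].mean())
    frac = means / m_ref
    frac_sd = np.sqrt((sds / m_ref) ** 2 + (means * s_ref / m_ref**2) ** 2)
    return pd.DataFrame(
        {
            "arm": means.index,
            "mean_count": means.to_numpy(),
            "sd_count": sds.to_numpy(),
            "n": ns.to_numpy(),
            "fraction": frac.to_numpy(),
            "fraction_sd": frac_sd.to_numpy(),
        }
    ).reset_index(drop=True)


def _ranks_and_ties(groups: list[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    out, start = [], 0
    for g in groups:
        out.append(ranks[start : start + len(g)])
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return out, tie_sum, len(pooled)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test across ``groups`` of counts.

    ``H = 12/(N(N+1)) sum R_j^2/n_j - 3(N+1)``, divided by the tie
    correction ``1 - sum(t^3 - t)/(N^3 - N)``; the p-value comes from the
    chi-squared distribution with k-1 degrees of freedom.  All-identical
    observations give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    rank_groups, tie_sum, n_total = _ranks_and_ties(groups)
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        r.sum() ** 2 / len(r) for r in rank_groups
    ) - 3.0 * (n_total + 1)
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    df = len(groups) - 1
    if correction <= 0:  # every observation identical
        return TestResult(statistic=0.0, df=df, p_value=1.0)
    h /= correction
    h = max(h, 0.0)
    return TestResult(statistic=float(h), df=df, p_value=float(stats.chi2.sf(h, df)))


def dunn_posthoc(
    groups: list,
    labels: list[str] | None = None,
    adjust: str = "bonferroni",
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Dunn's post hoc pairwise rank z-tests after Kruskal-Wallis.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with tie term ``T = sum(t^3 - t)``; two-sided normal p-values, adjusted
    by Bonferroni (default) or left unadjusted.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    labels = labels or [f"group{i}" for i in range(len(groups))]
    rank_groups, tie_sum, n_total = _ranks_and_ties(groups)
    mean_ranks = [r.mean() for r in rank_groups]
    var_core = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    n_pairs = len(groups) * (len(groups) - 1) // 2
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            denom_sq = var_core * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
            if denom_sq <= 0:  # all observations identical
                z, p = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom_sq)
                p = 2.0 * stats.norm.sf(abs(z))
            if adjust == "bonferroni":
                p = min(1.0, p * n_pairs)
            results.append(
                PairwiseResult(
                    group_a=labels[i],
                    group_b=labels[j],
                    z=float(z),
                    p_adjusted=float(p),
                    significant_at_0_05=bool(p < alpha),
                )
            )
    return results
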