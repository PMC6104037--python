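"""Inter-slice reproducibility statistics.

The ladder mirrors standard practice for comparing measurement groups
within a region: Shapiro-Wilk normality per group; if every group looks
normal, one-way ANOVA with Bonferroni-corrected pairwise t-tests;
otherwise Kruskal-Wallis with Dunn's rank-based pairwise test at the
Sidak-corrected level alpha_1 = 1 - (1 - alpha)^(1/k).  A pair is
significant only for p strictly below the corrected threshold.  The
headline quantity is the fraction of significantly different pairs, a
measure of (non-)reproducibility across slices and methods.

Shapiro-Wilk, ANOVA, Kruskal-Wallis and the t-tests delegate to scipy;
Dunn's test (pairwise rank z-statistics with tie correction) is
implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "sidak_alpha",
    "choose_test",
    "dunn_test",
    "PairResult",
    "StatReport",
    "compare_regions",
    "significant_fraction",
    "region_reports",
]


def sidak_alpha(alpha: float, k: int) -> float:
    """Sidak-corrected per-comparison level alpha_1 = 1 - (1-alpha)^(1/k).

    Equals alpha at k = 1, strictly decreasing in k, and never more
    conservative than the Bonferroni level alpha/k.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / k)


def choose_test(groups: list[np.ndarray], alpha: float = 0.05) -> str:
    """"anova" iff every group passes Shapiro-Wilk at alpha, else "kruskal_wallis"."""
    if any(len(g) < 3 for g in groups):
        raise ValueError("insufficient samples for normality test (each group needs n >= 3)")
    for g in groups:
        if sps.shapiro(np.asarray(g, dtype=float)).pvalue <= alpha:
            return "kruskal_wallis"
    return "anova"


def dunn_test(groups: list[np.ndarray]) -> list[tuple[int, int, float]]:
    """Dunn's pairwise rank comparisons; returns (i, j, two-sided p).

    Pooled ranks with mid-rank ties; the z-statistic for groups i, j is
    (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) over tie groups.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(float(np.mean(ranks[start:start + n])))
        start += n

    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            out.append((i, j, 1.0))
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append((i, j, min(p, 1.0)))
    return out


@dataclass(frozen=True)
class PairResult:
    group_i: str
    group_j: str
    p: float
    significant: bool


@dataclass
class StatReport:
    """Omnibus + post-hoc comparison of measurement groups in one region."""

    region: str
    omnibus: str                    # "anova" or "kruskal_wallis"
    omnibus_p: float
    normality_p: dict[str, float]
    pairs: list[PairResult]
    alpha: float
    corrected_alpha: float
    correction: str                 # "bonferroni" or "sidak"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_significant(self) -> int:
        return sum(p.significant for p in self.pairs)

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_pairs if self.pairs else 0.0

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "omnibus": self.omnibus,
            "omnibus_p": self.omnibus_p,
            "normality_p": self.normality_p,
            "alpha": self.alpha,
            "corrected_alpha": self.corrected_alpha,
            "correction": self.correction,
            "n_pairs": self.n_pairs,
            "n_significant": self.n_significant,
            "fraction_significant": self.fraction_significant,
            "pairs": [
                {"i": p.group_i, "j": p.group_j, "p": p.p, "significant": p.significant}
                for p in self.pairs
            ],
        }

    def summary(self) -> str:
        frac, ratio = significant_fraction(self)
        lines = [
            f"Region {self.region}: {self.omnibus} omnibus p = {self.omnibus_p:.4g}",
            f"post hoc ({self.correction}, corrected alpha = {self.corrected_alpha:.4g}): "
            f"{ratio} pairs significant (fraction {frac:.3f})",
        ]
        for p in self.pairs:
            mark = "*" if p.significant else " "
            lines.append(f"  {p.group_i} vs {p.group_j}: p = {p.p:.4g} {mark}")
        return "\n".join(lines)


def compare_regions(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    region: str = "",
) -> StatReport:
    """Run the full ladder on one region's measurement groups.

    ``groups`` maps a group key — conventionally a (slice, method)
    combination — to its sample of modulus values.  The omnibus test is
    chosen by per-group normality; post hoc compares all pairs at the
    Bonferroni level alpha/k on the ANOVA path or at the Sidak level on
    the Kruskal-Wallis/Dunn path.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    test = choose_test(arrays, alpha)
    normality = {
        lab: float(sps.shapiro(arr).pvalue) for lab, arr in zip(labels, arrays)
    }
    k = len(labels) * (len(labels) - 1) // 2

    if test == "anova":
        omnibus_p = float(sps.f_oneway(*arrays).pvalue)
        corrected = alpha / k
        correction = "bonferroni"
        pairs = []
        for i, j in itertools.combinations(range(len(labels)), 2):
            p = float(sps.ttest_ind(arrays[i], arrays[j], equal_var=True).pvalue)
            pairs.append(PairResult(labels[i], labels[j], p, bool(p < corrected)))
    else:
        omnibus_p = float(sps.kruskal(*arrays).pvalue)
        corrected = sidak_alpha(alpha, k)
        correction = "sidak"
        pairs = [
            PairResult(labels[i], labels[j], p, bool(p < corrected))
            for i, j, p in dunn_test(arrays)
        ]
    return StatReport(region, test, omnibus_p, normality, pairs, alpha, corrected, correction)


def significant_fraction(report: StatReport) -> tuple[float, str]:
    """Significant-pair fraction as (float, "s/k" display string)."""
    if report.n_pairs < 1:
        raise ValueError("report has no pairs")
    return report.fraction_significant, f"{report.n_significant}/{report.n_pairs}"


def region_reports(
    moduli: pd.DataFrame,
    value: str = "E_storage_Pa",
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> list[StatReport]:
    """One StatReport per region; groups are (slice, protocol) combinations.

    Regions with fewer than two usable groups are skipped (a pairwise
    comparison needs at least two), as are groups below the Shapiro-Wilk
    minimum of ``min_group_size`` points.
    """
    if "region" not in moduli.columns:
        raise ValueError("moduli table needs a 'region' column")
    reports = []
    df = moduli[moduli["qc_pass"].astype(bool)]
    for region, rgrp in df.groupby("region"):
        groups = {}
        for (slice_id, protocol), g in rgrp.groupby(["slice_id", "protocol"]):
            vals = g[value].to_numpy()
            if vals.size >= min_group_size:
                groups[f"{slice_id}|{protocol}"] = vals
        if len(groups) >= 2:
            reports.append(compare_regions(groups, alpha=alpha, region=str(region)))
    return reports
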