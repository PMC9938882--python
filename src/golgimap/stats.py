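"""Normality-gated group comparisons for line-scan distances.

For each protein, three cell-level distance samples are compared
(TGN38–POI, cis–TGN38, cis–POI).  Per-group Shapiro–Wilk gates the family:
when every group is compatible with normality (p >= alpha) the omnibus is
one-way ANOVA with Tukey's multiple-comparisons test; otherwise
Kruskal–Wallis with Dunn's multiple-comparisons test.  Significance is
accepted at p < 0.05 and reported with the usual star codes.

The KW H statistic (with tie correction), Dunn's rank-based z tests
(Bonferroni over the three pairs) and the Tukey–Kramer studentized-range
procedure are implemented here explicitly; scipy supplies only the
reference distributions and the Shapiro–Wilk test.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """GraphPad-style significance string: ns / * / ** / *** / ****."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    for g in out:
        if g.ndim != 1 or g.size == 0:
            raise ValueError("each group must be a non-empty 1D sample")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must not contain non-finite values")
    return out


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from chi-square(k-1).

    All-identical data return (0, 1) rather than raising.
    """
    gs = _as_groups(groups)
    if sum(g.size for g in gs) < 3:
        raise ValueError("Kruskal-Wallis needs at least 3 observations in total")
    pooled = np.concatenate(gs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in gs:
        r = ranks[start:start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # every pooled value identical
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, len(gs) - 1))
    return float(h), p


@dataclass(frozen=True)
class PairResult:
    """One post-hoc pairwise comparison."""

    label_a: str
    label_b: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    stars: str


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "bonferroni",
) -> list[PairResult]:
    """Dunn's multiple-comparisons test after Kruskal–Wallis.

    Pairwise z = (mean-rank difference) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)]
    with tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p,
    Bonferroni-adjusted over the pairs and capped at 1.
    """
    gs = _as_groups(groups)
    labels = _default_labels(labels, len(gs))
    pooled = np.concatenate(gs)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in gs:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    tie = _tie_term(pooled) / (12.0 * (n - 1))
    variance_base = n * (n + 1) / 12.0 - tie

    pairs = list(itertools.combinations(range(len(gs)), 2))
    n_comparisons = len(pairs) if adjust == "bonferroni" else 1
    results = []
    for i, j in pairs:
        se2 = variance_base * (1.0 / sizes[i] + 1.0 / sizes[j])
        if se2 <= 0:  # all pooled values tied
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(se2)
            p = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, p * n_comparisons)
        results.append(PairResult(labels[i], labels[j], float(z), p, p_adj, star_code(p_adj)))
    return results


def anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> tuple[float, float, list[PairResult], bool]:
    """One-way fixed-effects ANOVA plus Tukey HSD (Tukey–Kramer for unequal n).

    Returns (F, p, pairwise results, degenerate_variance flag).  With zero
    within-group variance and unequal means the p-values take their 0 limit
    and the degenerate flag is set.
    """
    gs = _as_groups(groups)
    labels = _default_labels(labels, len(gs))
    k = len(gs)
    n = sum(g.size for g in gs)
    if n - k < 1:
        raise ValueError("ANOVA needs residual degrees of freedom")
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    dfb, dfw = k - 1, n - k
    msw = ssw / dfw
    degenerate = False
    if msw == 0:
        if ssb == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, degenerate = float("inf"), 0.0, True
    else:
        f_stat = (ssb / dfb) / msw
        p = float(sps.f.sf(f_stat, dfb, dfw))
        if ssb == 0:
            p = 1.0

    results = []
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(gs[i].mean() - gs[j].mean())
        if msw == 0:
            p_pair = 1.0 if diff == 0 else 0.0
            q = 0.0 if diff == 0 else float("inf")
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / gs[i].size + 1.0 / gs[j].size))
            q = diff / se
            p_pair = float(sps.studentized_range.sf(q, k, dfw))
        p_pair = min(1.0, max(0.0, p_pair))
        results.append(PairResult(labels[i], labels[j], q, p_pair, p_pair, star_code(p_pair)))
    return float(f_stat), float(p), results, degenerate


def _default_labels(labels: Sequence[str] | None, k: int) -> list[str]:
    if labels is None:
        return [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError(f"{len(labels)} labels for {k} groups")
    if len(set(labels)) != k:
        raise ValueError("group labels must be unique")
    return list(labels)


@dataclass
class StatReport:
    """Full record of one normality-gated three-group comparison."""

    protein_name: str
    labels: list[str]
    groups: list[np.ndarray]
    normality: list[tuple[float, float]]  # per-group (W, p); (nan, nan) if undefined
    omnibus_name: str  # "ANOVA" or "Kruskal-Wallis"
    statistic: float
    p_value: float
    posthoc: list[PairResult]
    alpha: float
    degenerate_variance: bool = False

    def significant_pairs(self) -> list[PairResult]:
        return [r for r in self.posthoc if r.p_adjusted < self.alpha]

    def to_dict(self) -> dict:
        return {
            "protein": self.protein_name,
            "alpha": self.alpha,
            "groups": {
                lab: {"n": int(g.size), "mean": float(g.mean()), "values": g.tolist()}
                for lab, g in zip(self.labels, self.groups)
            },
            "shapiro_wilk": [
                {"label": lab, "W": w, "p": p}
                for lab, (w, p) in zip(self.labels, self.normality)
            ],
            "omnibus": {
                "test": self.omnibus_name,
                "statistic": self.statistic,
                "p": self.p_value,
            },
            "posthoc": [
                {
                    "pair": f"{r.label_a} vs {r.label_b}",
                    "statistic": r.statistic,
                    "p_unadjusted": r.p_unadjusted,
                    "p_adjusted": r.p_adjusted,
                    "stars": r.stars,
                }
                for r in self.posthoc
            ],
            "degenerate_variance": self.degenerate_variance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Figure-legend style summary."""
        posthoc_name = (
            "Tukey's multiple comparisons test"
            if self.omnibus_name == "ANOVA"
            else "Dunn's multiple comparisons test"
        )
        omnibus = (
            "One-way ANOVA" if self.omnibus_name == "ANOVA" else "Kruskal-Wallis test"
        )
        lines = [f"{self.protein_name}: " + "; ".join(
            f"{lab}: n = {g.size}" for lab, g in zip(self.labels, self.groups)
        )]
        lines.append(f"{omnibus} with {posthoc_name}:")
        for r in self.posthoc:
            if r.p_adjusted < self.alpha:
                desc = f"{r.stars}p = {r.p_adjusted:.4f}" if r.p_adjusted >= 0.0001 else "****p < 0.0001"
            else:
                desc = "non-significant (ns)"
            lines.append(f"  {r.label_a} vs {r.label_b}: {desc}")
        return "\n".join(lines)


def choose_and_run(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    protein_name: str = "",
) -> StatReport:
    """Gate on per-group Shapiro–Wilk, then run the matching omnibus + post hoc.

    ANOVA + Tukey when every group's Shapiro–Wilk p >= alpha; otherwise
    Kruskal–Wallis + Dunn.  A constant group has no defined Shapiro–Wilk
    statistic and routes the comparison to the nonparametric family.
    Requires at least 3 observations per group.
    """
    gs = _as_groups(groups)
    labels = _default_labels(labels, len(gs))
    for lab, g in zip(labels, gs):
        if g.size < 3:
            raise ValueError(
                f"group {lab!r} has n={g.size} < 3; Shapiro-Wilk and the "
                "omnibus tests are undefined at useful power"
            )

    normality: list[tuple[float, float]] = []
    all_normal = True
    for g in gs:
        if np.ptp(g) == 0:
            normality.append((float("nan"), float("nan")))
            all_normal = False
            continue
        w, p = sps.shapiro(g)
        normality.append((float(w), float(p)))
        if p < alpha:
            all_normal = False

    degenerate = False
    if all_normal:
        stat, p, posthoc, degenerate = anova_tukey(gs, labels)
        name = "ANOVA"
    else:
        stat, p = kruskal_wallis(gs)
        posthoc = dunn_posthoc(gs, labels)
        name = "Kruskal-Wallis"
    return StatReport(
        protein_name=protein_name,
        labels=labels,
        groups=gs,
        normality=normality,
        omnibus_name=name,
        statistic=stat,
        p_value=p,
        posthoc=posthoc,
        alpha=alpha,
        degenerate_variance=degenerate,
    )


def compare_protein_distances(
    d_tgn_poi: Sequence[float],
    d_cis_tgn: Sequence[float],
    d_cis_poi: Sequence[float],
    protein_name: str,
    cis_marker: str = "cis",
    alpha: float = 0.05,
) -> StatReport:
    """The three-sample comparison the per-protein figures report:
    TGN38–POI vs cis–TGN38 vs cis–POI."""
    labels = [
        f"TGN38-{protein_name}",
        f"{cis_marker}-TGN38",
        f"{cis_marker}-{protein_name}",
    ]
    return choose_and_run(
        [d_tgn_poi, d_cis_tgn, d_cis_poi],
        labels=labels,
        alpha=alpha,
        protein_name=protein_name,
    )
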