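"""Three-way grouping of proteins relative to TGN38.

Each protein's cell-level TGN38→POI distances are tested against zero with
a one-sample location test (t-test when Shapiro–Wilk accepts normality,
Wilcoxon signed-rank otherwise).  A protein is *overlapping* when the test
is non-significant AND its mean offset is small relative to the
dataset-wide cis→TGN38 reference distance (the effect floor); otherwise it
is *downstream* (mean > 0) or *upstream* (mean < 0) of TGN38.  The full
decision — test used, p-value, effect floor — is recorded so every label is
re-derivable from the stored values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

GROUP_COLORS = {"upstream": "gold", "overlapping": "magenta", "downstream": "cyan"}


@dataclass
class ProteinSummary:
    """Cell-level distances, mean ± SEM and group label for one protein."""

    protein_name: str
    d_tgn_poi: np.ndarray
    mean: float
    sem: float
    group_label: str  # upstream | overlapping | downstream
    decision: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.d_tgn_poi.size)


def classify_protein(
    protein_name: str,
    d_tgn_poi: Sequence[float],
    reference_nm: float,
    alpha: float = 0.05,
    overlap_fraction: float = 0.25,
) -> ProteinSummary:
    """Assign upstream / overlapping / downstream relative to TGN38.

    Parameters
    ----------
    d_tgn_poi : sequence of float
        Cell-level signed TGN38→POI distances (nm), one per cell.
    reference_nm : float
        Dataset-wide mean cis→TGN38 distance; the overlap effect floor is
        ``overlap_fraction * reference_nm``.
    """
    d = np.asarray(d_tgn_poi, dtype=float)
    if d.size < 3:
        raise ValueError(
            f"{protein_name}: need >= 3 cells to classify, got {d.size}"
        )
    if not np.all(np.isfinite(d)):
        raise ValueError(f"{protein_name}: non-finite cell distances")
    if reference_nm <= 0:
        raise ValueError("reference_nm must be positive")

    mean = float(d.mean())
    sem = float(d.std(ddof=1) / np.sqrt(d.size))

    if np.ptp(d) == 0:
        # constant sample: no spread, Shapiro and both tests degenerate
        sw_p = float("nan")
        if mean == 0.0:
            test_name, p = "degenerate (all zero)", 1.0
        else:
            test_name, p = "degenerate (constant nonzero)", 0.0
    else:
        _, sw_p = sps.shapiro(d)
        sw_p = float(sw_p)
        if sw_p >= alpha:
            test_name = "one-sample t-test"
            p = float(sps.ttest_1samp(d, 0.0).pvalue)
        else:
            test_name = "Wilcoxon signed-rank"
            p = float(sps.wilcoxon(d).pvalue)

    floor_nm = overlap_fraction * reference_nm
    significant = p < alpha
    if (not significant) and abs(mean) < floor_nm:
        label = "overlapping"
    elif mean > 0:
        label = "downstream"
    elif mean < 0:
        label = "upstream"
    else:
        label = "overlapping"  # mean exactly 0 never leaves the TGN

    decision = {
        "shapiro_p": sw_p,
        "test": test_name,
        "p": p,
        "alpha": alpha,
        "significant": significant,
        "overlap_fraction": overlap_fraction,
        "reference_nm": reference_nm,
        "effect_floor_nm": floor_nm,
        "mean_nm": mean,
    }
    return ProteinSummary(
        protein_name=protein_name,
        d_tgn_poi=d,
        mean=mean,
        sem=sem,
        group_label=label,
        decision=decision,
    )


def overview_table(summaries: Sequence[ProteinSummary]) -> pd.DataFrame:
    """All proteins ordered by mean TGN38→POI distance (the overview figure).

    Protein names must be unique.
    """
    if not summaries:
        raise ValueError("no protein summaries")
    names = [s.protein_name for s in summaries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicated protein name(s): {dupes}")
    df = pd.DataFrame(
        [
            {
                "protein": s.protein_name,
                "n": s.n_cells,
                "mean_nm": s.mean,
                "sem_nm": s.sem,
                "group": s.group_label,
                "color": GROUP_COLORS[s.group_label],
            }
            for s in summaries
        ]
    )
    return df.sort_values("mean_nm", kind="mergesort").reset_index(drop=True)


def plot_overview(summaries: Sequence[ProteinSummary], path=None):
    """Horizontal bars of mean ± SEM per protein, colored by group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = overview_table(summaries)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    ax.barh(
        df["protein"], df["mean_nm"], xerr=df["sem_nm"], color=df["color"], edgecolor="k"
    )
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("distance from TGN38 (nm)  [negative = upstream]")
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=c, ec="k") for c in GROUP_COLORS.values()
    ]
    ax.legend(handles, list(GROUP_COLORS), loc="best", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def write_decision_records(summaries: Sequence[ProteinSummary], path) -> None:
    records = {
        s.protein_name: {"group": s.group_label, **s.decision} for s in summaries
    }
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
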