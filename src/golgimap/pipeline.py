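"""End-to-end convenience: simulate a cohort, measure it, classify and test.

This is the path the command-line interface and the reproduction script
drive; each step is the corresponding module function, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as _classify
from . import localization as loc
from . import stats as _stats
from .simulate import CohortConfig, CohortDataset, ImagingModel, ProteinSpec, render_cohort


@dataclass
class CohortResult:
    """Everything the pipeline produced for one simulated cohort."""

    dataset: CohortDataset
    measurements: list[loc.StackMeasurement]
    cells: list[loc.CellMeasurement]
    references: dict[str, float]
    summaries: list[_classify.ProteinSummary] = field(default_factory=list)
    reports: list[_stats.StatReport] = field(default_factory=list)

    def cells_frame(self) -> pd.DataFrame:
        return loc.cells_frame(self.cells)

    def measurements_frame(self) -> pd.DataFrame:
        return loc.measurements_frame(self.measurements)


def measure_dataset(
    dataset: CohortDataset,
    smooth_window: int = 5,
    thresholds: loc.QCThresholds = loc.QCThresholds(),
) -> list[loc.StackMeasurement]:
    """Measure every (image, ROI) pair of a dataset."""
    return [
        loc.measure_stack(img, roi, smooth_window=smooth_window, thresholds=thresholds)
        for img, roi in zip(dataset.images, dataset.rois)
    ]


def run_cohort(
    protein_specs: Sequence[ProteinSpec],
    model: ImagingModel | None = None,
    config: CohortConfig | None = None,
    seed: int | None = None,
    alpha: float = 0.05,
    overlap_fraction: float = 0.25,
    smooth_window: int = 5,
    thresholds: loc.QCThresholds = loc.QCThresholds(),
    run_stats: bool = True,
) -> CohortResult:
    """Simulate, measure, aggregate to cells, classify and (optionally) run
    the three-group statistics for each protein."""
    if model is None:
        model = ImagingModel()
    rng = np.random.default_rng(seed if seed is not None else model.rng_seed)
    dataset = render_cohort(protein_specs, model, config=config, rng=rng)
    measurements = measure_dataset(dataset, smooth_window=smooth_window, thresholds=thresholds)
    cells = loc.aggregate_cells(measurements)
    references = loc.reference_distance(cells)

    result = CohortResult(
        dataset=dataset,
        measurements=measurements,
        cells=cells,
        references=references,
    )
    for spec in protein_specs:
        pcells = [c for c in cells if c.protein == spec.name]
        if len(pcells) < 3:
            continue
        reference = references[pcells[0].cis_marker]
        d_tgn_poi = [c.d_tgn_poi for c in pcells]
        result.summaries.append(
            _classify.classify_protein(
                spec.name,
                d_tgn_poi,
                reference_nm=reference,
                alpha=alpha,
                overlap_fraction=overlap_fraction,
            )
        )
        if run_stats:
            result.reports.append(
                _stats.compare_protein_distances(
                    d_tgn_poi,
                    [c.d_cis_tgn for c in pcells],
                    [c.d_cis_poi for c in pcells],
                    protein_name=spec.name,
                    cis_marker=pcells[0].cis_marker,
                    alpha=alpha,
                )
            )
    return result
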