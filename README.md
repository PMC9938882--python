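# golgimap

Relative localization of Golgi proteins from line-scan intensity profiles.

## The problem

The Golgi apparatus is a stack of cisternae flanked by the trans-Golgi
network (TGN), and where a protein sits along the cis→trans axis constrains
what it can do.  In confocal images of triple-stained cells (a cis-/medial
marker such as GM130 or giantin, the TGN marker TGN38, and a protein of
interest), individual stacks appear as short parallel ridges.  Drawing a
line across a well-separated stack and plotting each channel's intensity
along it turns the question "where is protein X?" into a 1D measurement:
the distance between intensity peaks.

Because stacks are oriented arbitrarily in 3D, every in-plane distance is
compressed by cos(tilt) — absolute inter-layer distances are not measurable
from single sections.  The analysis therefore reports distances *relative*
to TGN38, signed by the cis→TGN orientation of each stack: writing s(c) for
the arc-length of channel c's peak and σ = sign(s_tgn − s_cis),

    d_ab = σ · (s(b) − s(a)),

so d_cis→tgn > 0 always, d_tgn→poi > 0 places the protein downstream of
TGN38 and d_tgn→poi < 0 upstream, regardless of the direction the line was
drawn.  Per-cell means (one data point per cell) feed a three-way
classification — upstream / overlapping / downstream of TGN38 — and a
normality-gated group comparison: Shapiro–Wilk per group, then one-way
ANOVA + Tukey when all groups are compatible with normality, otherwise
Kruskal–Wallis + Dunn (Bonferroni over the three pairs), significance at
p < 0.05.

Because no raw micrographs of this kind are publicly deposited, the package
includes a synthetic Golgi-stack renderer (anisotropic Gaussian layers,
Gaussian PSF, Poisson + read noise, random in-plane rotation and
out-of-plane tilt) that records ground truth per stack, so the entire
pipeline is testable end to end.

## Worked example

Simulate three proteins at known offsets from TGN38 (+150 nm, 0 nm,
−150 nm; 15 cells × 3 stacks each at peak SNR ≈ 10), measure every stack,
aggregate to cells, classify and test:

```python
import golgimap as gm

specs = [
    gm.ProteinSpec("AP1",   150.0, n_cells=15),
    gm.ProteinSpec("ARL1",    0.0, n_cells=15),
    gm.ProteinSpec("CASC4", -150.0, n_cells=15),
]
res = gm.run_cohort(specs, model=gm.ImagingModel(), seed=1)
print({k: round(v, 1) for k, v in res.references.items()})
for s in res.summaries:
    print(f"{s.protein_name}: {s.group_label} "
          f"(mean {s.mean:+.0f} +/- {s.sem:.0f} nm, n={s.n_cells})")
print(res.reports[0].to_text())
```

prints

```
{'GM130': 378.7}
AP1: downstream (mean +147 +/- 3 nm, n=15)
ARL1: overlapping (mean +6 +/- 4 nm, n=15)
CASC4: upstream (mean -148 +/- 3 nm, n=15)
AP1: TGN38-AP1: n = 15; GM130-TGN38: n = 15; GM130-AP1: n = 15
One-way ANOVA with Tukey's multiple comparisons test:
  TGN38-AP1 vs GM130-TGN38: ****p < 0.0001
  TGN38-AP1 vs GM130-AP1: ****p < 0.0001
  GM130-TGN38 vs GM130-AP1: ****p < 0.0001
```

The first line is the dataset-wide mean cis→TGN38 distance (the reference
against which "overlap" is judged; ≈ 400 nm truth × E[cos tilt] ≈ 0.955
under the default tilt distribution).  Each protein's cohort mean recovers
its true projected offset, and the three-group comparison reproduces the
figure-legend style report.

The same pipeline runs from the shell on TIFF + ROI inputs:

```sh
golgimap simulate --config sim.yaml --out data/ --seed 3
golgimap measure  --data data/ --out meas/
golgimap analyze  --cells meas/cells.csv --out results/ --plot
```

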