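# fibralign

Quantification of fibril alignment in 2D fluorescence images, built for
sub-epidermal collagen in larval zebrafish skin: maximum-intensity
confocal projections in which fine collagen I fibrils mature from
randomly oriented wisps into an orthogonal "plywood" cross-hatch, and in
which a stab wound refills first with wispy, poorly aligned collagen
before recovering lattice-like order.

The package provides, as importable library modules with a thin CLI on
top:

* **Fourier directionality** — the angular orientation histogram of an
  image, computed from the energy distribution of its 2D power spectrum
  (fibrils at orientation θ concentrate spectral energy perpendicular to
  θ; the 90° correction is applied internally so all reported angles are
  fibril orientations in [0°, 180°)).
* **Alignment Index (AI)** — after subtracting the orientation-
  independent background from the histogram and splitting it into the
  0–90° and 90–180° half-ranges (one per orthogonal fibril family), each
  range is summarised by

  AI = | (1/N) Σᵢ (2cos²(θᵢ − θ_th) − 1) | = | Σᵢ wᵢ cos 2(θᵢ − θ_th) | / Σᵢ wᵢ

  with θ_th the doubled-angle circular mean orientation of the range.
  AI = 1 means zero angular dispersion (perfect alignment); AI = 0 means
  entirely random orientations over the full axial range. This is the 2D
  nematic order parameter of the orientation distribution.
* **Group statistics** — mean ± SD summaries, one-way ANOVA with Tukey's
  HSD across developmental stages, and two-sided Welch t-tests for
  wounded-versus-unwounded timecourses, with the conventional
  ns/*/**/***/**** significance ladder.
* **A synthetic fibril-image generator** — fluorescence-like renderings
  (anti-aliased segments, Gaussian PSF, background, read noise) of
  scenes with exactly known orientation ground truth, including
  developmental and wound-repair presets, so the entire measurement
  chain is testable without microscopy data.

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical conventions, and known limitations.

## Worked example

Simulate the three-stage developmental series (12 synthetic fish per
stage), measure AI per image, and compare stages:

```python
from fibralign import RunConfig, run_batch

cfg = RunConfig(mode="full", preset="development",
                outdir="out/dev", seed=1, n_per_group=12)
result = run_batch(cfg)
print(result.summary.to_string(index=False))
print(result.reports.iloc[0].to_dict())
```

prints

```
    group  n     mean       sd
2dpf-like 12 0.665124 0.061166
3dpf-like 12 0.814502 0.030334
4dpf-like 12 0.933793 0.005167
{'test': 'anova', 'comparison': 'omnibus', 'statistic': 139.1521233302957,
 'p_value': 8.278025557556888e-17, 'stars': '****', 'degenerate': False}
```

The group-mean AI rises strictly with maturation — the sparse isotropic
stage sits near the analytic per-range floor for random orientations
(2/π ≈ 0.64; a 90°-wide range can never fully cancel), the tight
orthogonal lattice approaches 1 — and the omnibus ANOVA across stages is
overwhelmingly significant. The wound preset
(`preset="wound"`) reproduces the repair narrative: at the 5 dpi-like
timepoint the wound-restricted AI is far below the unwounded control
(**** by Welch t-test), while at the 16 dpi-like timepoint, when the
wound has refilled with a lattice matching its surroundings, the same
comparison is non-significant.

Each run writes `ai_results.csv` (per-image AI, per-range values, mean
orientations, masses), `group_table.csv`, `summary.csv`,
`test_reports.csv`/`.json`, a mean ± SD plot, and `run_manifest.json`
with the seed and config hash; identical configurations reproduce
byte-identical tables.

The same stages are available from the shell:

```sh
fibralign simulate --preset developmental --seed 1 --outdir out/images
fibralign directionality out/images/dev_4dpf-like.tif --out hist.csv
fibralign ai out/images/dev_4dpf-like.tif
fibralign run --preset development --seed 1 --outdir out/dev
```

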