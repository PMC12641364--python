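# shipquant

Quantification of antibody–receptor **internalization** from quencher-based
flow-cytometry assays, for people developing or screening monoclonal
antibodies (ADC candidates, blocking/depleting mAbs, antibody–oligonucleotide
conjugates) on cultured cells or primary lymphocytes.

In a SHIP-type assay the antibody carries a Cy5-labeled DNA probe; at each
timepoint the sample is split and one half receives a membrane-impermeable
complementary quencher DNA (500 nM) that silences only the probe still on
the cell surface.  With P the geometric MFI of the −quencher well, Q that of
the matched +quencher well, and a 4 °C control pair (no internalization)
giving the quenching efficiency, the package computes

    q_eff          = 1 − Q(4 °C) / P(4 °C)
    %internalized  = (1 − (P − Q) / (P · q_eff)) · 100

together with **association** (P/DOL, total cell-bound signal), **uptake**
(Q/DOL, absolute internalized signal), DOL normalization from absorbance
spectra, gel-lane densitometry for sensor-assembly QC, and the statistical
layer used in such screens (donor-wise aggregation of technical replicates,
one-/two-way ANOVA, Dunnett many-to-one comparisons against the mIgG1
isotype control, significance stars).  A receptor's internalization is only
reported when its association is significantly above the isotype background
(Dunnett-adjusted p < 0.05); ineligible entries are marked `#`.

Because such experiments ship no raw public data, the package includes a
first-class **synthetic-assay generator**: mixed lymphocyte populations with
log-normal expression and autofluorescence, paired ±quencher wells, 4 °C
controls, first-order internalization kinetics f(t) = f_max·(1 − e^(−kt)),
donor effects, isotype-level background, and 1-D gel-lane profiles — all
with known ground truth, so every pipeline stage is validated by parameter
recovery.  See `docs/methods.md` for the model and its assumptions.

## Worked example

Simulate a transferrin-receptor-like condition (f_max = 0.90, k = 0.0435/min,
so the true internalized fraction is 65.6 % at 30 min and 90.0 % at 4 h)
plus an isotype control, and run the full pipeline:

```python
from shipquant import RunConfig, run
from shipquant.panel import AntibodySpec, tfr_demo_receptor
from shipquant.simulate import ReceptorKinetics, ReceptorSpec

cfg = RunConfig(
    panel=[
        AntibodySpec(tfr_demo_receptor()),
        AntibodySpec(
            ReceptorSpec("mIgG1", {}, ReceptorKinetics(0.0, 0.0), nonspecific_gm=5.0),
            isotype=True,
        ),
    ],
    n_events=5000, n_tech=3, n_donors=3, seed=7,
)
report = run(cfg, "out/demo")
print(report.summary[["condition", "population", "timepoint_min", "q_eff",
                      "association", "internalization_pct",
                      "internalization_sd", "eligible", "marker"]].round(3))
```

```
condition population  timepoint_min  q_eff  association  internalization_pct  internalization_sd  eligible marker
      TfR          B           30.0  0.966     1918.222               65.201               0.930      True
      TfR          B          240.0  0.966     1910.313               90.303               0.242      True
      TfR       CD4T           30.0  0.966     1895.480               66.118               0.723      True
      TfR       CD4T          240.0  0.966     1915.199               89.966               1.600      True
      TfR       CD8T           30.0  0.966     1892.895               65.974               0.459      True
      TfR       CD8T          240.0  0.966     1897.557               90.759               0.416      True
    mIgG1          B           30.0  0.296        7.300                  NaN                 NaN     False      #
    ...
```

The pipeline recovers the simulated truth — q_eff ≈ 0.97, ≈66 % at 30 min
and ≈90 % at 4 h on every gated population (mean ± SD over 3 donors × 3
technical replicates) — while the isotype control is flagged ineligible
(`#`): its association sits at autofluorescence-level background, so no
internalization percentage is reported for it.  `out/demo/` also receives
the per-replicate quantification, the Dunnett statistics table, a gating
report, a ground-truth sidecar and summary plots.

The same stages are available from the shell:

```sh
shipquant validate --config run.yaml
shipquant run --config run.yaml --seed 7 --out out/demo
shipquant simulate --out out/sim      # events.csv + ground_truth.json
```

`shipquant.panel.preset_panel()` provides a ready-made 13-antibody
lymphocyte screen (CD2, CD3, CD4, CD5, CD7, CD8a, CD19, CD20, CD22, CD27,
CD38, CD44, CD45 + mIgG1) with expression magnitudes and kinetics spanning
the characteristic classes: high-association/low-internalization (CD44,
CD45), low-association/high-efficiency (CD19), and high/high (CD3, CD22).

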