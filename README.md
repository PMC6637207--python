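# smatkit

Quantification of actin turnover from fluorogenic-probe live-cell imaging.

Fluorogenic F-actin probes such as SiR-actin (SA) fluoresce only while bound
to the filament; when turnover releases the probe its fluorescence drops more
than 100-fold. The field-level probe intensity of a stained culture therefore
decays at a rate set by the cells' actin dynamics, and that decay is a
sensitive live read-out of processes that remodel the cytoskeleton — early
mesenchymal stem cell (MSC) lineage induction (adipogenic AD, osteogenic OS,
chondrogenic CH, vs basal BA), cytoskeletal drugs, serum switching, and
in-vitro aging. `smatkit` implements the complete analysis stack for this
measurement, exercised end-to-end on synthetic data with known ground truth:

* **`smatkit.kinetics`** — a ligand–receptor binding model of the probe.
  Dissociation (wash-out): `dC/dt = kf·R_T·(C0 − C) − kr·C`; association
  (uptake into unstained cells, ligand in excess): `dC/dt = kf·R_T·L_T − kr·C`.
  `kf` and the binding-site abundance `R_T` are identifiable only as the
  composite `kf_d = kf·R_T`, so the model reports `(kf_d, kr, L_T)` and the
  turnover index `kr/kf_d`. Parameters are estimated sequentially by
  deterministic multi-start least squares: rates from decay data, then `L_T`
  from uptake data with the rates held fixed.
* **`smatkit.quantify`** — the ratiometric decay pipeline ("SMAT"): mean gray
  value per frame, first-timepoint normalization per field, replicate×field
  aggregation into mean ± SEM curves, and per-timepoint condition-vs-reference
  tests (two-way ANOVA, then Bonferroni-corrected posttests across
  timepoints), including windowed analyses around a media switch.
* **`smatkit.hcia`** — dual-stain (SA + phalloidin) single-cell
  morphometrics: nuclei-seeded Otsu/watershed segmentation, a 41-feature
  panel (9 shape, 6 intensity, 26 Haralick texture), canonical linear
  discriminant analysis, Wilks' lambda (Rao's approximate F), 50%-mass
  contour ellipses, and bootstrap-forest predictor ranking.
* **`smatkit.synthetic`** — scenario presets that generate traces, rendered
  time-lapse TIFF stacks, and dual-stain cell populations with known
  parameters, so every downstream result can be checked against ground truth.
* **`smatkit.cli`** — `smatkit simulate | smat | fit | hcia | report`.

## Worked example

Simulate the lineage-induction design, quantify the decay, and fit the model:

```sh
smatkit simulate --preset lineage --seed 3 --out run --kind stacks
smatkit smat --stacks run/stacks --reference BA --out run/smat
smatkit fit  --curves run/smat/curves.csv --out run/fit
smatkit report --run run
```

which prints (seed 3):

```
[smat/curves.csv] final retained intensity:
  AD: 0.510 +/- 0.005 (n=12)
  CH: 0.252 +/- 0.002 (n=12)
  OS: 0.109 +/- 0.001 (n=12)
  BA: 0.101 +/- 0.001 (n=12)

[fit/fits.csv] kinetic parameters:
  AD: kf_d=0.009958 /min, kr=0.009643 /min, kr/kf_d=0.968
  BA: kf_d=0.003295 /min, kr=0.02949 /min, kr/kf_d=8.95
  CH: kf_d=0.006223 /min, kr=0.01829 /min, kr/kf_d=2.94
  OS: kf_d=0.003253 /min, kr=0.02665 /min, kr/kf_d=8.19
```

The retained-intensity ordering AD > CH > OS ≈ BA is the adipogenic-slowest
turnover pattern, and the fitted rates recover the scenario's generating
parameters (AD truth: `kf_d = 0.010`, `kr = 0.010`, ratio 1). A smaller
`kr/kf_d` means less dissociation pressure, i.e. slower actin turnover.

For the single-cell analysis, generate dual-stain populations and classify:

```sh
smatkit simulate --preset lineage --seed 3 --out run --kind cells
smatkit hcia --images run/hcia/24h --basal BA --seed 3 --out run/hcia_out
```

`lda_report.csv` then lists the percent of correctly classified cells for the
simultaneous 4-way analysis and for each condition-vs-basal comparison, with
Wilks' lambda and its approximate-F p-value; `ellipses.csv` holds the
50%-mass canonical contour per condition and `ranking.csv` the
bootstrap-forest feature importances.

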