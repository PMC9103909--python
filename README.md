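# sersquant

Quantitative calibration of surface-enhanced Raman scattering (SERS)
spectra for pesticide residue analysis, built around the workflow used to
quantify the fungicide carbendazim in apple extracts: multiplicative
scatter correction (MSC), a rank-stratified 2:1 calibration/prediction
split, PLS1 regression with a cross-validated latent-variable count, four
wavelength-selection algorithms — a genetic algorithm (GA), the interval
variable iterative space shrinkage approach (iVISSA), the LASSO, and
bootstrapping soft shrinkage (BOSS) — and standard-addition recovery
statistics for spiked samples.

Because no spectra are publicly deposited for this study design, the
package ships a seeded synthetic-spectrum generator that reproduces its
statistical structure: 7 concentration levels (0.1–50 mg/L) × 36
replicates = 252 spectra on a 1416-point grid over 400–2500 cm⁻¹, with
the eight carbendazim SERS bands (629, 736, 770, 1007, 1227, 1271, 1462,
1521 cm⁻¹) as Lorentzian profiles on a dominant fluorescence background
with multiplicative scatter, smooth background texture and channel noise.
Interferent spectra (five other pesticides plus a blank) and
matrix-spiked sample sets are generated the same way.

## The model in brief

For spectra **X** (n × p) and concentrations **y** (mg/L):

* MSC: each spectrum is regressed on the mean calibration spectrum,
  x ≈ a + b·m, and corrected to x′ = (x − a)/b.
* Split: samples sorted by y (high to low, seeded tie-break), one member
  of each consecutive triplet drawn into the prediction set.
* PLS1 (NIPALS with X-deflation): latent variables t = X_d w with
  w ∝ X_d′y, chosen as the smallest count whose k-fold RMSECV lies within
  2 % of the curve minimum.
* Selection: each algorithm returns a wavelength subset scored by PLS
  RMSECV; the final model is PLS1 on that subset.
* Figures of merit: R_C/RMSEC on calibration, R_P/RMSEP on prediction,
  RPD = SD(y)/RMSEP (RPD > 3 marks a good quantitative model), and for
  spiked samples recovery (%) = 100·predicted/added, per-level RSD (%),
  and relative errors (%).

See `docs/methods.md` for the full account, including the synthetic
generator's assumptions and known limitations.

## Worked example

Run the BOSS branch of the pipeline on the default synthetic experiment:

```sh
sersquant run --config pipeline.yaml --outdir out/
# pipeline.yaml:
#   methods: [boss]
#   seed: 1
```

which prints

```
boss: k=9 vars=120 R_C=1.0000 RMSEC=0.0001 R_P=1.0000 RMSEP=0.0018 RPD=9129.06
```

— BOSS kept 120 of 1416 channels, the cross-validated model uses 9 latent
variables, and the prediction set of 84 spectra is predicted with an RMSEP
of 0.0018 mg/L (the synthetic spectra are far cleaner than real ones, so
these figures sit well above the published regime; the package asserts
only the regime bounds R_P ≥ 0.98 and RPD > 3).  `out/model_report.csv`
holds this row with the selected wavelengths; `out/recovery_report.csv`
holds the spiked-sample statistics computed with the same model:

```
level_mg_L,mean,sd,recovery_min_pct,recovery_max_pct,rsd_pct,max_abs_relative_error_pct
0.1,0.0993,0.0030,93.88,105.08,3.028,6.118
0.5,0.4969,0.0023,98.53,99.95,0.460,1.466
1,0.9882,0.0059,97.61,99.56,0.599,2.386
5,4.9417,0.0274,98.22,100.04,0.555,1.778
10,9.9005,0.0495,98.36,100.05,0.500,1.640
```

Reading the first row: ten spiked samples at 0.1 mg/L were predicted at
0.0993 ± 0.0030 mg/L, i.e. standard-addition recoveries between 93.9 %
and 105.1 %, a relative standard deviation of 3.0 %, and no sample off by
more than 6.1 % — inside the benchmark bands of 86–116 % recovery,
RSD < 10 % and relative error within ±10 %.

The same objects are available as a library:

```python
from sersquant import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(methods=("boss",), seed=1))
report = result.reports[0]          # the comparison-table row
recovery = result.recovery          # per-level RecoveryReport objects
```

Other subcommands: `simulate` (write a synthetic spectra CSV),
`preprocess` (MSC), `select --method {boss,ga,lasso,ivissa}`, `train` and
`predict` (persist and apply a model bundle).

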