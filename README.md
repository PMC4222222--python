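# icvnorm

Power-proportion intracranial-volume correction for regional brain volumes.

## The problem

In volumetric MRI analysis, regional brain volumes (VOI) must be corrected
for head size before groups can be compared, and intracranial volume (ICV)
is the usual head-size measure. The traditional *proportion method* divides
each volume by ICV, implicitly assuming VOI ∝ ICV; the *ANCOVA (residual)
method* assumes a linear relation. For many structures neither assumption
holds: regional volumes scale allometrically,

```
VOI = α · ICV^β + ε,        ε ~ N(0, σ²),
```

with a region-specific exponent β that is often well below 1 (the structure
grows more slowly than the head). `icvnorm` fits this power law per region
by nonlinear least squares and applies the **power-proportion correction**

```
VOI_PPC = VOI / ICV^b,
```

where *b* is the fitted exponent. With *b* = 1 this reduces exactly to the
proportion method. The package also implements the proportion, ANCOVA
residual, quadratic-ANCOVA and log-log residual corrections, compares mean
models by leave-one-out cross-validated prediction error, and ships a
synthetic-cohort generator with known ground truth so the whole pipeline is
testable without any private data.

It is aimed at neuroimaging statisticians and imaging-core analysts who
work with per-subject volume tables (CSV/TSV) or FreeSurfer
`aseg.stats` / `aparc.stats` outputs.

## Worked example

```python
from icvnorm import (fit_all_regions, flag_nonproportional, residual_slope,
                     apply_proportion, apply_power_proportion, loocv_error)
from icvnorm.synthetic import default_spec, simulate_table

spec = default_spec(seed=42)           # 49 M + 92 F, 43 regions, known betas
table = simulate_table(spec)
fits = fit_all_regions(table)
for r in ("caudate", "putamen", "hippocampus", "precuneus"):
    f = fits[r]
    print(f"{r:12s} b={f.beta:.2f} SE={f.se_beta:.2f} "
          f"CI=({f.ci_beta[0]:.2f}, {f.ci_beta[1]:.2f}) "
          f"flag={flag_nonproportional(f)}")
```

```
caudate      b=0.78 SE=0.09 CI=(0.61, 0.96) flag=True
putamen      b=0.60 SE=0.07 CI=(0.47, 0.73) flag=True
hippocampus  b=0.63 SE=0.05 CI=(0.53, 0.74) flag=True
precuneus    b=1.02 SE=0.07 CI=(0.87, 1.17) flag=False
```

Each row is one region's fitted scaling exponent with its standard error
and 95% Wald interval; `flag=True` marks regions whose interval excludes 1,
i.e. regions for which the plain VOI/ICV ratio is a biased correction. The
correction itself, and the diagnostic that motivates it:

```python
icv, voi = table.pairs("caudate")
print(residual_slope(apply_proportion(voi, icv), icv))          # ratio method
print(residual_slope(apply_power_proportion(voi, icv, fits["caudate"].beta), icv))
```

On this cohort the proportion-corrected caudate still correlates with ICV
(r = −0.18, p = 0.03: larger heads get over-corrected), while the
power-proportion-corrected values do not (r = 0.02, p = 0.84) — the
regression line of corrected volume on ICV is flat, which is the point of
the method. `loocv_error(icv, voi, "power_law")` /
`loocv_error(icv, voi, "linear")` give the cross-validated prediction
errors used to compare mean models (19.61 vs 19.68 cc² here).

The same workflow is available from the shell:

```sh
icvnorm simulate --out cohort --seed 0
icvnorm fit      --input cohort/volumes.csv --out results
icvnorm correct  --input cohort/volumes.csv --out results --method power_proportion
icvnorm compare  --input cohort/volumes.csv --out results --plot
```

For sklearn pipelines, `PowerLawRegressor` (fit/predict on an ICV column)
and `ICVCorrector` (fit/transform on an `[ICV, region...]` matrix) are
standard estimators with `get_params`/`set_params`/`clone` support.

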