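# psfield

Spatial analysis of plant-breeding field trials with two-dimensional
P-spline mixed models.

The package fits a single-trial mixed model in which the field trend is a
2D P-spline surface decomposed ANOVA-style into three fixed linear columns
and five penalized random blocks (two main smooth trends, two
linear-by-smooth interactions, one smooth-by-smooth interaction), each with
its own smoothing parameter, alongside random row, column, and test-genotype
effects, fixed check-variety and resolvable-block effects, and an
independent (nugget) residual. Variance components are estimated by REML
through effective-dimension fixed-point updates; the fit reports per-block
effective dimensions, genotype BLUPs with prediction error variances,
ED-based and PEV-based generalized heritability, a fine-grid fitted
surface, and a nugget-residual variogram. A partially replicated (p-rep)
trial simulator with known ground truth makes every stage testable without
external data.

## Modules

| module | contents |
| --- | --- |
| `psfield.basis` | B-spline bases, difference penalties, mixed-model reparameterization, PS-ANOVA design assembly |
| `psfield.reml` | REML fitting, effective dimensions, heritability, surface prediction, variogram, restricted deviance |
| `psfield.models` | trial table, spatial / non-spatial model assembly, comparison metrics |
| `psfield.simdata` | p-rep layout and phenotype simulation (plane / smooth / AR1xAR1 trends) |
| `psfield.io_cli` | trial CSV I/O, fit outputs, command-line interface |

## Command line

```sh
# simulate a p-rep trial with a smooth field trend
psfield simulate --rows 20 --cols 10 --geno 120 --checks 2 \
    --surface smooth --amplitude 2.0 --seed 1 --out trial.csv

# fit the spatial model (and the non-spatial baseline)
psfield fit --input trial.csv --outdir fit_spats
psfield fit --input trial.csv --model nonspatial --outdir fit_ns

# effective-dimension table, variance components, heritability
psfield report fit_spats

# compare fits: heritability, residual variance, BLUP correlations
psfield compare fit_spats fit_ns --out comparison.json
```

`fit` writes `variance_components.json`, `genotype_blups.csv`,
`residuals.csv`, `surface.csv` (4x plot density by default), and
`variogram.csv` into the output directory.

Trial CSVs have the header `row,col,genotype,check,block,y`, one record per
plot, with an empty `y` cell marking a missing phenotype.

## Library use

```python
from psfield import (SimulationParams, SurfaceSpec, simulate_trial,
                     build_spats_model, fit_reml, heritability)

params = SimulationParams(n_rows=30, n_cols=12, n_geno=160, p_rep=0.3,
                          n_checks=3, sigma2_g=1.0, sigma2_e=0.4,
                          surface=SurfaceSpec(kind="smooth", amplitude=2.0,
                                              shape_seed=5),
                          seed=7)
trial, truth = simulate_trial(params)
fit = fit_reml(build_spats_model(trial))
print(fit.effective_dims, heritability(fit).h2_ed)
```

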