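# qsar3d

Grid-field 3D-QSAR in Python: CoMFA-style Lennard-Jones/Coulomb fields and
CoMSIA-style Gaussian similarity fields on a shared lattice, NIPALS partial
least squares with leave-one-out cross-validation (including a fast
covariance-matrix LOO path), and a complete external-validation statistic
battery (predictive r², through-origin regressions, penalized rm² metrics,
MAE-based rules, acceptance checklists, Pareto ranking of candidate models,
and progressive y-scrambling).

## Layout

| module | contents |
|---|---|
| `qsar3d.chem_prep` | SDF/MOL2 reading & writing (RDKit-backed), activity tables with IC50→pIC50 conversion, PEOE sigma partial charges, Kabsch rigid superposition and database alignment |
| `qsar3d.field_engine` | lattice construction, LJ/Coulomb probe energies with truncation and steric exclusion handling, five Gaussian similarity fields, StDev×Coeff contour maps, field matrix IO |
| `qsar3d.pls_engine` | minimum-sigma column filtering with equal-block-variance scaling, NIPALS PLS, LOO q² (kernel fast path ≡ explicit refits), component selection, model serialization |
| `qsar3d.validation` | r²pred, k/k′/R0² regressions, rm² battery, MAE criteria, acceptance checklists, rm²(overall), Pareto fronts, progressive scrambling |
| `qsar3d.synthetic_data` | seeded toy molecule series with known sparse generative structure; packaged 35-compound observed/predicted reference tables |
| `qsar3d.cli` | `qsar3d` command with `simulate`, `fields`, `fit`, `predict`, `validate`, `scramble`, `contour` subcommands |

## CLI quick start

```bash
# generate a seeded toy dataset (SDF + activity CSV)
qsar3d simulate --seed 1 --n-molecules 30 --noise-sd 0.1 \
    --out-structures toy.sdf --out-activities toy.csv

# fit a model (LOO component selection) and predict the test split
qsar3d fit --structures toy.sdf --activities toy.csv \
    --kinds comsia_S --min-sigma 0.05 \
    --out-model model.json --out-predictions preds.csv

# full validation battery on a prediction table (or a packaged reference table)
qsar3d validate --table preds.csv --q2 0.8 --out report.json
qsar3d validate --fixture --model comfa --q2 0.743

# robustness check and contour volumes
qsar3d scramble --structures toy.sdf --activities toy.csv \
    --kinds comsia_S --min-sigma 0.05 --seed 1 --out scramble.json
qsar3d contour --model model.json --structures toy.sdf --out-prefix maps
```

Configuration (grid margin/spacing, cutoffs, Gaussian attenuation, minimum
sigma, component limit, seed, field kinds) can be given as a YAML file via
`--config`, with individual flags overriding file values. Defaults: margin
4 Å, spacing 2 Å, energy cutoff 30 kcal/mol, attenuation 0.3 Å⁻²,
minimum sigma 2.0.

## Notes on conventions

* PEOE charges implement the sigma component only (six damped iterations by
  default); elements without published electronegativity parameters raise.
* The through-origin R0²/R′0² use the formulation that reproduces the
  shipped reference statistics; `gt_standard=True` (CLI `--gt-standard`)
  switches to the classical definitions.
* rm² metrics use the radical form rm² = R²(1 − √|R² − R0²|); sigma of
  absolute errors uses the population divisor.
* Electrostatic values at sterically buried lattice points are replaced by
  training-column means; the fills are serialized with the model so
  prediction rows are imputed consistently.
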