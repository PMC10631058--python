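# phytostress

Multi-modal prediction of plant abiotic stress type and severity from
three feature families — leaf-image texture statistics (GLCM entropy,
energy, local homogeneity), physiological/biochemical assays (RWC, CI,
CA, AC, PhC, PC) and miRNA concentrations (miR-156a, miR-166i,
miR-399g, miR-477b) — using support-vector regression with GA/PSO
kernel-parameter tuning, 5-fold cross-validation scoring (MSE, R²),
and Banzhaf cooperative-game feature importance.

A synthetic-data module emulates the underlying factorial greenhouse
experiment (4 drought levels × 4 salinity levels × 3 replicates,
5 measurement times → 48 pots, 240 records, 13 features) so the whole
pipeline is testable without lab data.

## Quick start (Python)

```python
import phytostress as ps

# synthetic feature table with the full factorial design
design = ps.generate_design(4, 4, replicates=3, time_points=5)
table = ps.generate_feature_table(design, seed=42).to_feature_table()

# evaluate one model: combined (type + severity) scenario, linear kernel
from phytostress.svm import scenario_target, KernelSpec
from phytostress.metrics import make_folds
X, y = scenario_target(table, "combined")
report = ps.evaluate(X, y, KernelSpec("linear"), make_folds(len(X), seed=0))
print(report.mse, report.r2)

# GA-tuned gamma, full grid, importance, ablation
results = ps.run_grid(table)                      # groups × scenarios × kernels × models
shares = ps.run_importance(table, group="mirna")  # Banzhaf % shares
abl = ps.run_ablation(table, ["miR-399g"], base_features=ps.FEATURE_GROUPS["mirna"])
```

## CLI

```bash
phytostress simulate --seed 1 --out data.csv --images-dir leaves/
phytostress texture leaves/*.png --out texture.csv --levels 8
phytostress grid --data data.csv --out grid.csv --seed 1
phytostress importance --data data.csv --group mirna --out shares.json
phytostress ablate --data data.csv --drop miR-399g --out ablation.json
phytostress report --grid-results grid.csv --out-dir report/
```

GA defaults: 500 iterations, population 100, crossover fraction 0.5.
PSO defaults: 100 iterations, 200 particles, inertia 1, cognitive 1.
Use `--ga-iterations/--ga-population/--pso-iterations/--pso-population`
for reduced budgets.

## Tests and acceptance report

```bash
python -m pytest -q tests/                 # full suite (~1 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` regenerates the design-level target quantities
(record count, feature count, pot count) by running the synthetic
generator with the experiment's factorial layout.

## Package layout

| module | contents |
|---|---|
| `phytostress.synth` | factorial design, feature-response model, table + leaf-image generators |
| `phytostress.texture` | grayscale conversion, leaf masking, GLCM, entropy/energy/homogeneity |
| `phytostress.metrics` | MSE, R², fold assignment, cross-validation protocol |
| `phytostress.svm` | kernel specs, target encoding, standardized ε-SVR per scenario output |
| `phytostress.optim` | real-coded GA, canonical PSO, kernel-parameter tuner |
| `phytostress.banzhaf` | exact + Monte-Carlo Banzhaf indices, CV-R² characteristic function |
| `phytostress.pipeline` | dataset loading, experiment grid, importance and ablation runs |
| `phytostress.cli` | `phytostress` command-line entry point |
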