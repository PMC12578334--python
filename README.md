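# cphmdkit

Post-processing for constant-pH molecular dynamics (CpHMD) λ-dynamics
trajectories — for computational biophysicists who run titration scans of
proteins (membrane channels in particular) and need to turn per-site λ(t)
series into protonation fractions, titration curves, pKa values, predictor
benchmarks, and net-charge-vs-pH profiles.

In λ-dynamics CpHMD each titratable site carries a continuous coordinate λ:
λ ≈ 0 means protonated, λ ≈ 1 deprotonated. Scanning pH (e.g. 1–8 in unit
steps) over several replicas and monomers yields hundreds of λ series per
residue. `cphmdkit` provides:

* **io_formats** — readers/writers for GROMACS-style xvg λ files, pKa
  tables with censored entries (`< 1`, `> 8`), residue compositions.
* **protonation** — the two standard fraction estimators (λ-threshold
  counting with 0.2/0.8 cutoffs, and simple λ averaging), hierarchical
  monomer→replica curve averaging, convergence diagnostics.
* **titration_fit** — pKa by linear interpolation at half protonation, by
  Henderson–Hasselbalch least squares

      θ(pH) = 1 / (1 + 10^(n·(pH − pKa))),   n ≡ 1,

  and by a Hill fit with n free; censor-aware classification of residues
  that stay protonated or deprotonated over the whole scan.
* **method_compare** — pairwise RMSD / Pearson-R benchmarking of pKa tables
  across prediction methods, with principled exclusion of censored
  (anomalously ionizing) residues.
* **charge_profile** — net charge Q(pH) per monomer from any pKa
  assignment, a model-pKa null model, pH 2/pH 8 normalization for overlay
  with reversal-potential data, effective Hill characterization.
* **microstate** — diagnostics for apparent negative cooperativity (Hill
  n < 1) caused by slow exchange between conformers with distinct pKa:
  HH-mixture fits, apparent-n vs pKa-separation tables, persistent
  single-state intervals, protonation/conformation trace correlation.
* **synthetic** — a seeded generator of λ-trajectories with prescribed
  titration behaviour (single-pKa sites or slowly exchanging conformer
  mixtures), plus the closed-form occupancy oracle used to validate every
  downstream stage.

## Worked example

```python
import numpy as np, pandas as pd
from cphmdkit import (TitrationModel, simulate_lambda, fraction_lambda_mean,
                      build_curve, classify_residue, fit_mixture, theta_true)

# a site titrating at pKa 3.3, sampled like a 3-monomer x 3-replica study
model = TitrationModel(conformers=((1.0, 3.3),))
rows = []
for monomer in range(3):
    for replica in range(3):
        for pH in np.arange(1.0, 9.0):
            traj = simulate_lambda(model, pH, duration=200.0,
                                   seed=1000 * monomer + 100 * replica + int(pH))
            rows.append((monomer, replica, pH, fraction_lambda_mean(traj).fraction))
curve = build_curve(pd.DataFrame(rows, columns=["monomer", "replica", "pH", "fraction"]))
call = classify_residue(curve)
print(f"classification: {call.label}")
print(f"pKa (interpolation): {call.pka_interp.value:.2f} +/- {call.pka_interp.sd:.2f}")
print(f"pKa (HH fit):        {call.pka_hh.value:.2f}")
print(f"Hill fit:            pKa {call.hill.pKa:.2f}, n = {call.hill.n:.2f}")

# a shallow titrator: slow exchange between two conformers with distinct pKa
mixture = TitrationModel(conformers=((0.5, 2.5), (0.5, 4.5)))
grid = np.arange(1.0, 9.0)
fit = fit_mixture((grid, theta_true(grid, mixture)), k=2)
print(f"mixture fit: k={fit.k}, conformers="
      + ", ".join(f"(w={w:.2f}, pKa={p:.2f})" for w, p in fit.conformers)
      + f", apparent Hill n = {fit.apparent_hill.n:.2f}")
```

prints

```
classification: titrating
pKa (interpolation): 3.33 +/- 0.00
pKa (HH fit):        3.30
Hill fit:            pKa 3.30, n = 1.00
mixture fit: k=2, conformers=(w=0.50, pKa=2.50), (w=0.50, pKa=4.50), apparent Hill n = 0.54
```

The first block recovers the true pKa (3.3) by all three estimators, with
the replica scatter as the uncertainty. The second block shows the
microstate mechanism: an equal mixture of conformers titrating at 2.5 and
4.5 is fitted exactly by the two-component model, while a plain Hill fit of
the same curve reports an *apparent* coefficient n = 0.54 — shallow
titration that looks like negative cooperativity but involves no site–site
interaction.

A command-line interface wraps the same stages for batch work:

```sh
cphmdkit simulate panel.yaml --out data/          # synthetic dataset + manifest
cphmdkit titrate data/ --out results/             # curves, pKa calls, CSV/JSON
cphmdkit compare pka_table.csv --reference CpHMD --out cmp/
cphmdkit charge pka_table.csv --composition comp.csv --out charge/
cphmdkit microstate curve.csv --out mixture.json
```

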