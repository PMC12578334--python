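# Methods

## The problem this package addresses

In constant-pH molecular dynamics with λ-dynamics, every titratable site
carries a continuous coordinate λ that interpolates between its protonated
(λ ≈ 0) and deprotonated (λ ≈ 1) forms. A simulation campaign produces one
λ(t) series per site, per monomer, per replica, per solution pH. Turning
those series into science — per-residue titration curves, pKa values,
censored calls for residues that never titrate inside the scanned window,
benchmarks against static pKa predictors, and the protein's net charge as a
function of pH — is a post-processing pipeline with many small conventions
that must be applied consistently. This package implements that pipeline
and ships a seeded generator of synthetic λ-trajectories so every stage can
be validated against closed-form expectations.

## Protonation fractions

Two estimators of a site's time-averaged protonated fraction θ:

* **threshold counting** — frames with λ < 0.2 count as protonated, λ > 0.8
  as deprotonated, frames in between are excluded from both counts;
  θ̂ = Nproto/(Nproto + Ndeproto).
* **λ averaging** (pipeline default) — θ̂ = 1 − mean(λ). λ legitimately
  overshoots [0, 1] slightly; overshoots are *kept* in the average, because
  the noise around the 0 and 1 emission levels is symmetric and cancels in
  the mean. Only the final fraction is clipped into [0, 1]. Clipping each
  frame instead would discard half of the noise distribution at the
  boundaries and bias the estimate by roughly sd·φ(0) ≈ 2 percentage points
  at extreme pH — larger than the entire observed disagreement between the
  two estimators (≲ 0.1 pp on generator output).

Curves are averaged hierarchically, mirroring a monomer × replica design:
monomer fractions are averaged within each replica first; the curve mean
and its uncertainty (sample SD) are then taken across replica means.

**Convergence** is diagnosed from the cumulative (anchored) running mean of
the protonation indicator: the convergence time is the earliest time after
which the running mean stays within ε (default 0.02) of the full-series
mean.

## pKa estimation

The protonated fraction of a monoprotic site is modelled as

    θ(pH) = 1 / (1 + 10^{ n (pH − pKa) }),

which decreases with pH and equals 1/2 at pH = pKa. (Some presentations
write the exponent with the opposite sign; this package follows the
convention in which θ is the *protonated* fraction of an acid, so θ → 1 at
low pH.) Three estimators are provided:

* **interpolation** — the pH at which θ crosses 0.5, by linear
  interpolation between the bracketing grid points. Sampling noise can make
  a curve locally non-monotone, so the curve is first regularized to be
  non-increasing by pooled adjacent violators; this guarantees a unique
  crossing. Grid points landing exactly on 0.5 resolve to that grid pH.
  Curves entirely above (below) 0.5 are *censored*: the pKa is reported as
  "> max pH" ("< min pH") and the residue classified always-protonated
  (always-deprotonated).
* **HH fit** — unweighted least squares with n ≡ 1 and pKa free,
  initialized at the interpolated value. No weighting is applied; replica
  SDs are reported but not used as weights.
* **Hill fit** — pKa and n both free, bounds n ∈ [0.05, 5] and pKa within
  5 units of the grid. n < 1 flags a shallow ("slow") titration.

On noisy sigmoidal curves the three agree closely (mean
|interpolation − HH| ≈ 0.02–0.03 pKa units at noise SD 0.02 on a unit pH
grid).

## Apparent cooperativity from microstate mixtures

A residue that exchanges slowly between conformers with distinct pKa has an
ensemble curve θ(pH) = Σ w_k θ_HH(pH; pKa_k). Such a mixture is shallower
than any single sigmoid, so a Hill fit reports n < 1 even though no
site–site interaction exists. The `microstate` module fits this mixture
directly (simplex-constrained weights, multistart from quantile crossings)
and accepts the extra component only if it reduces the residual sum of
squares by a configurable factor (default 4×) over the single-sigmoid fit —
a deliberately blunt parsimony guard, since the intended use is k = 2.

A caveat worth stating explicitly: the *apparent* Hill exponent of a
mixture is not a property of the mixture alone — it depends on the pH
window and loss used to fit it. For an equal-weight two-conformer mixture
fitted by unweighted least squares on a 7-unit window, n = 0.80, 0.54, 0.38
at pKa separations of 1, 2, 3 units; the logit-slope (Hill plot) definition
gives systematically smaller values (0.73, 0.33, 0.12). This package
reports the least-squares value, the quantity an experimenter fitting a
titration curve would obtain. Hill exponents in the 0.3–0.4 range therefore
correspond to conformer separations of roughly 2.5–3 pH units on this
window.

Persistent-interval extraction (maximal single-state runs, with
band-excluded frames not breaking a run) and trace correlation (Pearson,
e.g. protonation indicator vs a conformational observable) support the
mechanistic reading of individual shallow titrators.

## Cross-method benchmarking

pKa tables (residues × methods) admit censored cells "<x" / ">x". Pairwise
RMSD and Pearson matrices are computed after masking: residues censored in
the designated *reference* method are excluded from every statistic (they
have no usable reference value and their predictions by other methods are
dominated by the same anomaly), and each pair additionally drops residues
censored in either member. Because a pKa shift is predicted − model, the
model pKa cancels in between-method differences: shift-RMSD equals raw-pKa
RMSD for any model assignment, so benchmark RMSDs do not depend on the
model-compound values.

The bundled benchmark fixture (`tests/data/synthetic_s1_pka_table.csv`) is
a **synthetic stand-in**: its anomalous rows are real published values, but
the 31 numeric rows are constructed (see
`scripts/make_synthetic_pka_fixture.py`) so that the summary RMSDs over the
usable set equal the published benchmark statistics exactly. Tests against
it validate the comparison engine's masking and arithmetic, not the
original per-residue data.

## Net charge vs pH

Q(pH) = Σ_acids −(1 − θ_i) + Σ_bases +θ_i with θ_i from HH at the assigned
pKa. Censored residues enter as fixed charges (censored-below: permanently
deprotonated; censored-above: permanently protonated), and basic residues
without an assigned pKa default to fully protonated — appropriate for scans
of acidic windows where His/Arg/Lys never titrate. The null model assigns
every residue its model-compound pKa. For comparison with reversal-potential
titrations, curves are normalized to 1 at pH 2 and 0 at pH 8 (anchors
configurable, interpolated if between grid points). The effective Hill
characterization normalizes with the grid endpoints and fits the Hill form;
aggregates of sites with spread-out pKa give n < 1.

## The synthetic generator

`simulate_lambda` emits λ series from a two-level hidden chain:

* **conformer chain** — at each frame, with probability
  1 − exp(−dt/exchange_time), the conformer is resampled from the stationary
  weights. This "refresh" construction makes the long-run conformer
  occupancies equal the weights *exactly* (the property downstream
  estimators sense) at the cost of the mean dwell in conformer j being
  exchange_time/(1 − w_j) rather than exchange_time; a chain forced to jump
  to a different conformer could not have both.
* **protonation chain** — within the current conformer, a two-state chain
  with stationary protonated probability θ_HH(pH; pKa_conformer) and
  relaxation time proto_relax_time, realized by the same refresh
  construction (resample from the conformer's stationary Bernoulli with
  probability 1 − exp(−dt/τ) per frame) — exact stationarity, exponential
  autocorrelation.
* **emission** — λ = (0 if protonated else 1) + N(0, emission_sd), truncated
  to [−0.1, 1.1].

All draws are made upfront in a fixed order independent of the number of
conformers, so a degenerate mixture (all pKa equal) reproduces the
single-conformer trajectory bit for bit under the same seed, and identical
seeds always give identical output. Per-file seeds in generated datasets
are a stable hash of (master seed, residue, monomer, replica, pH).

Defaults (all overridable per residue): frame_interval 0.01 ns,
proto_relax_time 0.01 ns, exchange_time 50 ns, emission_sd 0.05.
The protonation relaxation default deserves a note: saved λ frames of real
constant-pH runs are nearly decorrelated at typical output strides, and a
relaxation time at the frame stride is what makes 9-trace cumulative
averages settle within ~10 ns — the convergence behaviour reported for
well-sampled sites. A relaxation time of 0.5 ns, sometimes a tempting
"physical" choice, would give the 9-trace running mean a standard error of
≈ 0.05 at 10 ns and convergence times an order of magnitude longer.
The 50 ns exchange default makes minority conformers appear as rare,
persistent excursions (tens of ns), the phenomenology the
persistent-interval tools are aimed at.

**What the generator does not emulate:** λ inertial dynamics and barrier
crossing profiles (emission is memoryless around 0/1), explicit multi-site
electrostatic coupling (coupling is representable only through
conformer-specific pKa), pH-dependent conformational weights, and force-
field or sampling artifacts of real trajectories. Passing recovery tests on
generator output therefore demonstrates the correctness of the estimators
under the stated occupancy model, not the fidelity of any MD engine.

## Error model used in validation tests

The variance of a time-averaged occupancy over a trajectory of N frames
splits into a fast within-conformer part E_k[θ_k(1−θ_k)] inflated by the
protonation autocorrelation factor (1+g_p)/(1−g_p), g_p = exp(−dt/τ_p), and
a slow between-conformer part Var_k(θ_k) inflated by the exchange factor
(1+g_c)/(1−g_c). Oracle-equivalence tests assert |θ̂ − θ_true| < 3 SE with
this formula; mixture tests shorten the exchange time (5 ns) and lengthen
the run (300 ns) so the slow component actually converges at test scale.

## Problem sizes in the shipped tests

Study-scale checks use 3 monomers × 3 replicas × 200 ns at 8 pH values
(single-site recovery, estimator agreement, convergence), which the
vectorized generator simulates in seconds; mixture and benchmark tests are
smaller. The acceptance script (`scripts/acceptance.py`) regenerates its
panels from scratch at the same sizes on every run.

## Known limitations

* No autocorrelation-aware error bars on reported pKa (replica SD only).
* No multistate reweighting across pH; each pH is analyzed independently.
* Mixture fits with k > 2 are supported but essentially untested territory;
  identifiability degrades quickly on an 8-point grid.
* Censored residues contribute fixed charges to Q(pH); no extrapolated
  titration beyond the scanned window.
* Net-charge curves are per monomer and ignore charge spatial distribution;
  they are not predictors of conductance or selectivity.
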