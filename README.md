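# trclust

Model-based clustering of antidepressant treatment-response trajectories.

Depression rating scores (HAM-D) measured repeatedly over a treatment course
do not follow a single time course: some patients improve within weeks, others
slowly or not at all. `trclust` identifies such response classes by fitting a
**finite mixture of linear regressions** to log-transformed score
trajectories, selects the number of classes with an entropy-penalized
information criterion (ICL), projects new cohorts onto a frozen model,
relates classes to clinical outcomes and baseline covariates, and predicts
response speed from baseline data with random forests. A synthetic-data
generator produces realistic cohorts (naturalistic visit schedules,
discharge-driven dropout, accidental missingness, class-informative
covariates) for end-to-end validation.

## Model

Each patient *i* contributes observations \(y_{ij} = \ln(\text{HAMD}_{ij} + 0.5)\)
at weeks \(t_{ij}\). The mixture assumes *K* latent classes; class *k* has
intercept \(I_k\), weekly slope \(S_k\), residual standard deviation
\(\sigma_k\) and weight \(\pi_k\):

\[
p(\mathbf{y}_i) \;=\; \sum_{k=1}^{K} \pi_k \prod_{j} \,
\mathcal{N}\!\left(y_{ij}\mid I_k + S_k\, t_{ij},\; \sigma_k^2\right).
\]

Parameters are estimated by EM on per-patient sufficient statistics, restarted
from many random hard partitions. For each *K* the best converged fit is
scored by

\[
\mathrm{ICL}(K) = \underbrace{-2\ell + p\ln N}_{\mathrm{BIC}} + 2\,\mathrm{ENT},
\qquad p = 3K + (K-1),
\]

where ENT is the posterior assignment entropy and *N* the number of patients;
the selected model minimizes ICL. Patients are assigned to their
maximum-posterior class, and each patient's *cluster-derived slope* is the
slope of that class — a denoised summary of response speed used as a
prediction target.

## Worked example

```python
import numpy as np
from trclust.synthetic import separated_spec, generate_cohort
from trclust.prep import regularize_cohort
from trclust.mixture import select_k, sort_components
from trclust.projection import assign_fixed, truncation_curve

spec = separated_spec(5, n_patients=400)        # 5 well-separated classes
cohort, labels = generate_cohort(spec, seed=11)
reg = regularize_cohort(cohort)                 # weekly grid, ln transform

sel = select_k(reg, range(2, 9), n_restarts=20, seed=0)
print(sel.chosen_k)                             # -> 5

model, assign = sort_components(sel.best_fit.model, sel.best_fit.assignments)
for c in model.components:
    print(f"slope={c.slope:+.3f}  intercept={c.intercept:.3f}  "
          f"sd={c.residual_sd:.3f}  weight={c.weight:.3f}")
```

Output:

```
slope=-0.297  intercept=3.295  sd=0.082  weight=0.240
slope=-0.191  intercept=3.306  sd=0.085  weight=0.205
slope=-0.110  intercept=3.303  sd=0.081  weight=0.190
slope=-0.049  intercept=3.297  sd=0.079  weight=0.193
slope=-0.005  intercept=3.303  sd=0.076  weight=0.172
```

ICL is minimized at the generating class count (−9122.6 at K = 5 versus
−9121.0 at K = 6 and −7191.9 at K = 4). Projecting the training cohort onto
its own frozen model reproduces the training labels exactly, and truncating
each trajectory to its first *m* weekly values shows how early the eventual
class is determined:

```python
proj = assign_fixed(model, reg)
print(np.mean(proj.assignments.labels == assign.labels))   # -> 1.0

curve = truncation_curve(model, reg)
print([round(c.pearson_r, 3) for c in curve if c.window_weeks in (3, 6, 9)])
# -> [0.952, 0.999, 1.0]
```

The same pipeline is available as a command-line tool:

```
trclust simulate --n-patients 400 --seed 11 --outdir sim
trclust fit --ratings sim/ratings.csv --k-range 2:8 --restarts 20 --seed 0 --outdir fit
trclust project --ratings sim/ratings.csv --model fit/model.json --outdir proj
```

## Reproduction

`scripts/acceptance.py` re-runs the pipeline end to end from a single seed
and writes the headline quantities (selected class count, parameter-recovery
errors, projection agreement, truncation correlations, covariate effect-size
calibration, random-forest adjusted R² per feature set and target) to JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical methods, defaults, and the design
of the synthetic generator.
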