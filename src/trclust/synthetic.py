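"""Synthetic cohort generator.

Emulates the statistical structure of an inpatient antidepressant-response
study: mixture-structured linear decline of ln-transformed HAM-D totals on a
design-specific visit grid (weekly to week 6 then bi-weekly to week 16, or
weekly to week 12), baseline-severity eligibility (HAM-D >= 14), discharge
censoring coupled to the response rate, accidental missingness of early
visits, and a baseline clinical-item table whose informative items carry
cluster-coupled standardized mean shifts calibrated to target one-way ANOVA
effect sizes (Cohen's f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .prep import (
    Cohort,
    DESIGN_MAX_RAW,
    DESIGN_WEEKS,
    ELIGIBILITY_MIN_BASELINE,
    RatingSeries,
    REMISSION_THRESHOLD,
)


# --------------------------------------------------------------------------
# Generating specification
# --------------------------------------------------------------------------

@dataclass
class GeneratingComponent:
    """One latent response class: a line on the ln(HAM-D + 0.5) scale."""

    weight: float
    intercept: float          # ln-scale severity at week 0
    slope: float              # ln-scale change per week
    residual_sd: float        # within-patient noise SD (ln scale)
    random_intercept_sd: float = 0.0  # between-patient intercept SD


@dataclass
class SyntheticSpec:
    """Generating conditions for a synthetic cohort."""

    n_patients: int = 1000
    components: Sequence[GeneratingComponent] = None
    design: str = "MARS"
    missing_rate: float = 0.071
    covariate_effects: Optional[Dict[str, np.ndarray]] = None
    n_noise_items: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.components is None:
            self.components = default_components()

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components], dtype=float)


def validate_spec(spec: SyntheticSpec) -> None:
    if spec.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if spec.design not in DESIGN_WEEKS:
        raise ValueError(f"design must be one of {sorted(DESIGN_WEEKS)}")
    if not (0.0 <= spec.missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    if not spec.components:
        raise ValueError("components must be non-empty")
    w = spec.weights
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("components: mixing weights must sum to 1")
    for i, c in enumerate(spec.components):
        if not (0.0 < c.weight <= 1.0):
            raise ValueError(f"components[{i}].weight must lie in (0, 1]")
        if c.residual_sd < 0:
            raise ValueError(f"components[{i}].residual_sd must be >= 0")
        if c.random_intercept_sd < 0:
            raise ValueError(f"components[{i}].random_intercept_sd must be >= 0")
    if spec.n_noise_items < 0:
        raise ValueError("n_noise_items must be >= 0")


def default_components():
    """Seven latent classes spanning fast/complete to absent response.

    Intercepts correspond to moderate-to-severe baseline severity
    (exp(3.1)-exp(3.3) ~ 22-27 raw points); the fastest class reaches the
    remission range (< 10 raw) around week 4-5 while the slowest never does
    within a 16-week window.
    """
    weights = (0.16, 0.20, 0.16, 0.08, 0.15, 0.14, 0.11)
    intercepts = (3.10, 3.15, 3.20, 3.05, 3.25, 3.20, 3.30)
    slopes = (-0.22, -0.15, -0.10, -0.06, -0.035, -0.018, -0.002)
    return [
        GeneratingComponent(w, i, s, residual_sd=0.12)
        for w, i, s in zip(weights, intercepts, slopes)
    ]


def separated_spec(k_true: int, n_patients: int = 800, design: str = "MARS",
                   missing_rate: float = 0.0) -> SyntheticSpec:
    """Equal-weight, well-separated components for simulation studies.

    Slope gaps exceed three times the residual-induced slope standard error
    even for early-discharging classes (short series), so latent classes are
    recoverable in principle.
    """
    slopes = {
        3: (-0.30, -0.13, -0.005),
        5: (-0.30, -0.19, -0.11, -0.05, -0.005),
        7: (-0.30, -0.20, -0.13, -0.08, -0.045, -0.02, 0.0),
    }
    if k_true not in slopes:
        raise ValueError("separated_spec supports k_true in {3, 5, 7}")
    ss = slopes[k_true]
    comps = [GeneratingComponent(1.0 / k_true, 3.3, s, residual_sd=0.08) for s in ss]
    # make weights sum to exactly 1
    comps[-1].weight = 1.0 - sum(c.weight for c in comps[:-1])
    return SyntheticSpec(n_patients=n_patients, components=comps, design=design,
                         missing_rate=missing_rate)


# --------------------------------------------------------------------------
# Trajectory generation
# --------------------------------------------------------------------------

def _discharge_index(raw: np.ndarray, weeks: np.ndarray) -> int:
    """Index of the discharge visit (inclusive truncation point).

    Discharge at the first scheduled week >= 2 where the raw score is below
    the remission threshold on two consecutive scheduled visits; capped at
    the design's last week.
    """
    for j in range(1, len(weeks)):
        if weeks[j] >= 2 and raw[j] < REMISSION_THRESHOLD and raw[j - 1] < REMISSION_THRESHOLD:
            return j
    return len(weeks) - 1


def generate_cohort(spec: SyntheticSpec, seed: Optional[int] = None):
    """Draw a cohort of mixture-structured trajectories.

    Returns ``(cohort, labels)`` where ``labels`` are the true component
    indices.  Patients with a baseline raw score below the eligibility
    threshold are resampled (both trajectory and label), so mixing weights
    remain interpretable.  Missingness at ``spec.missing_rate`` is applied to
    interior week 1-6 visits.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    weeks = np.array(DESIGN_WEEKS[spec.design], dtype=int)
    max_raw = DESIGN_MAX_RAW[spec.design]
    n, v = spec.n_patients, len(weeks)
    k = len(spec.components)
    intercepts = np.array([c.intercept for c in spec.components])
    slopes = np.array([c.slope for c in spec.components])
    sds = np.array([c.residual_sd for c in spec.components])
    ri_sds = np.array([c.random_intercept_sd for c in spec.components])

    labels = np.empty(n, dtype=int)
    raw = np.empty((n, v))
    pending = np.arange(n)
    while pending.size:
        m = pending.size
        lab = rng.choice(k, size=m, p=spec.weights)
        offset = rng.standard_normal(m) * ri_sds[lab]
        noise = rng.standard_normal((m, v)) * sds[lab][:, None]
        y = intercepts[lab][:, None] + offset[:, None] + slopes[lab][:, None] * weeks[None, :] + noise
        r = np.clip(np.round(np.exp(y) - 0.5), 0, max_raw)
        labels[pending] = lab
        raw[pending] = r
        pending = pending[r[:, 0] < ELIGIBILITY_MIN_BASELINE]

    series = []
    for i in range(n):
        j = _discharge_index(raw[i], weeks)
        series.append(RatingSeries(f"P{i:05d}", weeks[: j + 1].copy(), raw[i, : j + 1].copy()))
    cohort = Cohort(series, spec.design)
    if spec.missing_rate > 0:
        cohort = apply_missingness(cohort, spec.missing_rate, int(rng.integers(2**31)))
    return cohort, labels


def apply_missingness(cohort: Cohort, rate: float, seed: int) -> Cohort:
    """Mark interior week 1-6 visits missing completely at random.

    Baseline (week 0) and the final (discharge) visit are never removed.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    out = []
    for s in cohort.series:
        raw = s.raw.copy()
        candidate = (s.weeks >= 1) & (s.weeks <= 6)
        candidate[0] = False
        candidate[-1] = False
        hit = candidate & (rng.random(len(raw)) < rate)
        raw[hit] = np.nan
        out.append(RatingSeries(s.patient_id, s.weeks.copy(), raw))
    return Cohort(out, cohort.design)


# --------------------------------------------------------------------------
# Clinical baseline table
# --------------------------------------------------------------------------

# Baseline item schema: (name, type, params).  Types: N numerical (mean, sd),
# D dichotomous (prevalence), C categorical / ordinal-coded (probabilities
# over integer codes starting at 0).  Location/scale values follow typical
# inpatient-cohort descriptives.
MODEL0_SCHEMA = [
    ("age", "N", (48.3, 14.0)),
    ("sex", "D", 0.537),
    ("spouse", "D", 0.502),
    ("education", "N", (10.3, 1.5)),
    ("training_retirement", "D", 0.254),
    ("employment", "C", (0.15, 0.16, 0.69)),
    ("ICD10", "D", 0.646),
    ("age_on", "N", (36.5, 15.2)),
    ("prev_epi", "N", (2.6, 5.2)),
    ("s_history", "D", 0.195),
    ("psychot_history", "D", 0.112),
    ("fam_history", "D", 0.632),
    ("fam_F20_F25", "C", (0.93, 0.05, 0.02)),
    ("fam_F31", "C", (0.96, 0.03, 0.01)),
    ("fam_F32_F34", "C", (0.45, 0.25, 0.30)),
    ("fam_X60", "C", (0.82, 0.13, 0.05)),
    ("index_d", "N", (34.5, 58.7)),
    ("ATRQ_score", "N", (1.09, 0.90)),
    ("s_current", "D", 0.103),
    ("psychot_current", "D", 0.104),
    ("height", "N", (1.72, 0.09)),
    ("weight", "N", (75.7, 14.1)),
    ("BMI", "N", (25.3, 4.4)),
    ("HR", "N", (82.8, 13.2)),
    ("RRsys", "N", (125.8, 18.1)),
    ("RRdia", "N", (78.7, 11.1)),
    ("cort_basal", "N", (200.5, 39.6)),
    ("TSH", "N", (1.47, 1.02)),
    ("fT3", "N", (4.57, 0.93)),
    ("fT4", "N", (16.2, 9.2)),
    ("CRP", "N", (1.49, 2.92)),
    ("HbA1C", "N", (5.34, 0.34)),
    ("L_Event", "N", (29.5, 10.5)),
    ("wL_Event", "N", (82.3, 38.7)),
    ("scl_som", "N", (0.97, 0.64)),
    ("scl_comp", "N", (1.77, 0.72)),
    ("scl_uncert", "N", (1.30, 0.77)),
    ("scl_dep", "N", (2.08, 0.73)),
    ("scl_anx", "N", (1.37, 0.70)),
    ("scl_agg", "N", (0.77, 0.60)),
    ("scl_pho", "N", (0.88, 0.75)),
    ("scl_par", "N", (0.92, 0.72)),
    ("scl_psy", "N", (0.83, 0.55)),
    ("epq_neu", "N", (6.85, 2.50)),
    ("epq_psy", "N", (1.92, 1.24)),
    ("epq_ext", "N", (5.20, 2.97)),
    ("tpq_ha", "N", (20.6, 5.6)),
    ("tpq_ns", "N", (13.1, 3.8)),
    ("tpq_rd", "N", (17.8, 3.3)),
    ("tpq_rd2", "N", (4.81, 1.70)),
]
MODEL0_ITEMS = [name for name, _, _ in MODEL0_SCHEMA]
HAMD_ITEMS = [f"HAMD0_{i:02d}" for i in range(1, 22)]
EARLY_RESPONSE_ITEM = "HD_2WE"

# Cluster-profile shapes of the informative items (fast class first, resistant
# last) and their calibrated one-way-ANOVA effect-size targets (Cohen's f).
# Shapes rise from fast to slow classes for neuroticism, harm avoidance,
# episode duration, weighted life events and the anxiety-related symptom
# scores, and fall for extraversion; psychoticism is weak and non-monotone.
INFORMATIVE_PROFILES = {
    "index_d":    ((22.3, 28.5, 43.4, 17.2, 38.7, 31.0, 43.5), 0.153),
    "scl_uncert": ((1.04, 1.19, 1.41, 1.02, 1.48, 1.27, 1.53), 0.233),
    "scl_psy":    ((0.63, 0.74, 0.84, 0.67, 0.93, 0.86, 1.03), 0.234),
    "scl_pho":    ((0.64, 0.79, 0.94, 0.63, 1.02, 0.94, 1.18), 0.227),
    "epq_neu":    ((5.17, 6.59, 7.43, 5.92, 7.47, 7.00, 7.74), 0.355),
    "epq_ext":    ((6.42, 5.65, 4.95, 5.56, 4.52, 4.76, 4.26), 0.243),
    "epq_psy":    ((1.91, 1.94, 2.00, 2.35, 1.94, 2.10, 1.87), 0.081),
    "tpq_ha":     ((17.2, 19.8, 21.5, 18.2, 21.9, 21.3, 22.8), 0.341),
    "wL_Event":   ((69.8, 77.9, 87.2, 29.0, 86.5, 90.7, 95.0), 0.196),
}


def calibrate_shifts(profile: Sequence[float], f_target: float,
                     weights: np.ndarray) -> np.ndarray:
    """Rescale a cluster-profile shape to hit a Cohen's f target.

    Returns centred per-cluster standardized mean shifts mu_k such that, with
    unit within-cluster SD and mixing weights pi_k,
    sqrt(sum pi_k mu_k^2) = f_target (the population Cohen's f).  Profiles of
    a different length than ``weights`` are linearly resampled.
    """
    p = np.asarray(profile, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    k = len(w)
    if len(p) != k:
        x_old = np.linspace(0.0, 1.0, len(p))
        x_new = np.linspace(0.0, 1.0, k)
        p = np.interp(x_new, x_old, p)
    p = p - w @ p
    spread = np.sqrt(w @ p**2)
    if f_target == 0.0 or spread == 0.0:
        return np.zeros(k)
    return p * (f_target / spread)


def default_covariate_effects(weights: np.ndarray) -> Dict[str, np.ndarray]:
    """Calibrated per-cluster shifts for the default informative items."""
    return {
        name: calibrate_shifts(profile, f, weights)
        for name, (profile, f) in INFORMATIVE_PROFILES.items()
    }


@dataclass
class ClinicalTable:
    """Per-patient baseline feature table plus item-type metadata."""

    data: "pd.DataFrame"
    item_types: Dict[str, str]


def generate_clinical(labels: np.ndarray, spec: SyntheticSpec, seed: int,
                      missing_rate: float = 0.0) -> ClinicalTable:
    """Emit the baseline clinical-item table for generated patients.

    Informative items receive the per-cluster standardized mean shifts in
    ``spec.covariate_effects`` (defaults calibrated to the target Cohen's f
    values); all other items are drawn independently of the class label.
    Numerical items are Gaussian on the item's natural scale; dichotomous and
    ordinal items are sampled from their marginal category probabilities.
    Baseline HAM-D single items are uninformative integers on 0-4.
    """
    import pandas as pd

    validate_spec(spec)
    labels = np.asarray(labels, dtype=int)
    k = len(spec.components)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError("labels outside the spec's component range")
    effects = spec.covariate_effects
    if effects is None:
        effects = default_covariate_effects(spec.weights)
    known = set(MODEL0_ITEMS)
    for name, shift in effects.items():
        if name not in known:
            raise ValueError(f"unknown item name in covariate_effects: {name!r}")
        if len(np.asarray(shift)) != k:
            raise ValueError(f"covariate_effects[{name!r}] must have one shift per component")

    rng = np.random.default_rng(seed)
    n = len(labels)
    cols, types = {}, {}
    for name, typ, params in MODEL0_SCHEMA:
        types[name] = {"N": "numerical", "D": "dichotomous", "C": "categorical"}[typ]
        if typ == "N":
            mean, sd = params
            z = rng.standard_normal(n)
            if name in effects:
                z = z + np.asarray(effects[name], dtype=float)[labels]
            cols[name] = mean + sd * z
        elif typ == "D":
            cols[name] = (rng.random(n) < params).astype(float)
        else:
            probs = np.asarray(params, dtype=float)
            cols[name] = rng.choice(len(probs), size=n, p=probs / probs.sum()).astype(float)
    for name in HAMD_ITEMS:
        types[name] = "numerical"
        cols[name] = rng.integers(0, 5, size=n).astype(float)
    for j in range(spec.n_noise_items):
        name = f"noise_{j + 1:02d}"
        types[name] = "numerical"
        cols[name] = rng.standard_normal(n)

    df = pd.DataFrame(cols, index=pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id"))
    if missing_rate > 0:
        if not (0.0 <= missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        mask = rng.random(df.shape) < missing_rate
        df = df.mask(mask)
    return ClinicalTable(df, types)


def generating_truth(spec: SyntheticSpec, labels: np.ndarray, seed: int) -> dict:
    """JSON-serializable record of the generating truth for recovery tests."""
    return {
        "seed": seed,
        "design": spec.design,
        "labels": [int(v) for v in labels],
        "components": [
            {
                "weight": c.weight,
                "intercept": c.intercept,
                "slope": c.slope,
                "residual_sd": c.residual_sd,
                "random_intercept_sd": c.random_intercept_sd,
            }
            for c in spec.components
        ],
    }
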