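"""Synthetic inputs: cohorts, transition parameter sets, microsimulation.

Everything the other modules consume can be generated here without any
external data:

* :func:`generate_cohort` draws per-patient records with the marginal
  structure of the feasibility table — truncated-normal age and BMI,
  Bernoulli SINBAD components whose *total* (and hence severity) is derived
  from the sampled components, and geometric reulceration times with
  administrative censoring at 52 weeks.
* :func:`generate_transition_params` draws random monthly transition sets
  that respect the structural zeros and row sums, for property tests.
* :func:`simulate_patient_histories` runs individual-level Markov chains
  under the same transition rules as the cohort engine and reports
  per-cycle state frequencies — the engine's independent stochastic oracle.

A single integer seed controls all randomness: each generator spawns
independent child streams from ``numpy.random.SeedSequence(seed)``, so
cohorts and histories are reproducible separately and jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .model import (
    HealthState,
    N_STATES,
    TransitionParameters,
    validate_transitions,
)

__all__ = [
    "CohortGeneratorSpec",
    "generate_cohort",
    "generate_transition_params",
    "simulate_patient_histories",
    "DEFAULT_TRANSITION_BOUNDS",
]

_DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass(frozen=True)
class CohortGeneratorSpec:
    """Distributional settings for the synthetic feasibility cohort.

    Defaults mirror the published baseline summaries: age ~ N(60.8, 9.3^2)
    truncated to [18, 95] (trial eligibility starts at 18), BMI
    ~ N(32.94, 6.13^2) truncated to [15, 60], 20% female, 80% type 2
    diabetes, smoking status (current/previous/never) at the observed
    1/15, 9/15, 5/15 frequencies, and six Bernoulli SINBAD components whose
    probabilities sum to 31/15 (the observed mean total of 2.07).  The
    monthly recurrence hazard 0.0417 gives a 40% (6/15) cumulative
    reulceration probability over the 52-week (364-day) follow-up.
    """

    n: int = 15
    seed: int = 0
    age_mean: float = 60.8
    age_sd: float = 9.3
    bmi_mean: float = 32.94
    bmi_sd: float = 6.13
    p_female: float = 0.20
    p_t2dm: float = 0.80
    smoking_probs: tuple[float, float, float] = (1 / 15, 9 / 15, 5 / 15)
    employment_probs: tuple[float, float, float] = (6 / 15, 7 / 15, 2 / 15)
    sinbad_component_probs: tuple[float, ...] = (
        0.20, 0.25, 0.75, 0.15, 0.40, 0.32,
    )
    diabetes_duration_mean: float = 17.9
    diabetes_duration_sd: float = 10.1
    monthly_recurrence_hazard: float = 0.0417
    followup_days: int = 364
    study_year: int = 2021
    age_bounds: tuple[float, float] = (18.0, 95.0)
    bmi_bounds: tuple[float, float] = (15.0, 60.0)

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort size n must be >= 1")
        probs = (
            [self.p_female, self.p_t2dm, self.monthly_recurrence_hazard]
            + list(self.smoking_probs)
            + list(self.employment_probs)
            + list(self.sinbad_component_probs)
        )
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if len(self.sinbad_component_probs) != 6:
            raise ValidationError("exactly six SINBAD component probabilities")
        for tup in (self.smoking_probs, self.employment_probs):
            if abs(sum(tup) - 1.0) > 1e-9:
                raise ValidationError("categorical probabilities must sum to 1")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Redraw-on-violation truncated normal (exact truncated density)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortGeneratorSpec) -> pd.DataFrame:
    """Draw a synthetic per-patient cohort table.

    Returns the feasibility-table columns plus the six SINBAD component
    columns and two survival columns: ``time_to_event_days`` (day of
    reulceration, administratively censored at ``followup_days``) and
    ``event`` (1 = reulcerated during follow-up).  ``sinbad_score`` is the
    sum of the sampled components, never drawn independently, and
    ``reason_incomplete`` is set to ``Reulceration`` for events.
    Byte-identical output for identical specs.
    """
    ss = np.random.SeedSequence(spec.seed)
    r_demo, r_sinbad, r_recur = (np.random.default_rng(s) for s in ss.spawn(3))
    n = spec.n
    age = _truncated_normal(r_demo, spec.age_mean, spec.age_sd, *spec.age_bounds,
                            size=n)
    bmi = _truncated_normal(r_demo, spec.bmi_mean, spec.bmi_sd, *spec.bmi_bounds,
                            size=n)
    gender = np.where(r_demo.random(n) < spec.p_female, "F", "M")
    dtype_ = np.where(r_demo.random(n) < spec.p_t2dm, 2, 1)
    smoking = r_demo.choice(
        ["Current", "Previous", "Never"], size=n, p=spec.smoking_probs
    )
    employment = r_demo.choice(
        ["Retired", "Full time", "Benefits"], size=n, p=spec.employment_probs
    )
    duration = _truncated_normal(
        r_demo, spec.diabetes_duration_mean, spec.diabetes_duration_sd, 1.0, 80.0,
        size=n,
    )
    year_diagnosis = (spec.study_year - np.round(duration)).astype(int)

    comp = (
        r_sinbad.random((n, 6)) < np.asarray(spec.sinbad_component_probs)
    ).astype(int)
    sinbad_score = comp.sum(axis=1)
    neuropathy = comp[:, 2].astype(bool)
    mono_draw = r_sinbad.choice(["Both", "Right", "Left"], size=n,
                                p=[0.8, 0.1, 0.1])
    monofilament = np.where(neuropathy, mono_draw, "None")

    # day-level geometric waiting time matching the monthly hazard
    p_day = 1.0 - (1.0 - spec.monthly_recurrence_hazard) ** (1.0 / _DAYS_PER_MONTH)
    if p_day > 0:
        day = r_recur.geometric(p_day, size=n)
    else:
        day = np.full(n, np.iinfo(np.int64).max)
    event = (day <= spec.followup_days).astype(int)
    time_days = np.minimum(day, spec.followup_days)

    df = pd.DataFrame(
        {
            "study_id": [f"{i + 1:03d}" for i in range(n)],
            "gender": gender,
            "age": np.round(age).astype(int),
            "ethnicity": "English",
            "bmi": np.round(bmi, 1),
            "employment": employment,
            "smoking": smoking,
            "diabetes_type": dtype_,
            "year_diagnosis": year_diagnosis,
            "monofilament_loss": monofilament,
            "sinbad_score": sinbad_score,
            "dfu_study_visits": 1 + r_demo.poisson(3, n),
            "reason_incomplete": np.where(event == 1, "Reulceration", ""),
            "gp_visits": r_demo.poisson(1, n),
            "outpatient_visits": r_demo.poisson(1, n),
            "hospital_bed_days": r_demo.poisson(0.2, n),
            "site": comp[:, 0],
            "ischemia": comp[:, 1],
            "neuropathy": comp[:, 2],
            "bacterial_infection": comp[:, 3],
            "area": comp[:, 4],
            "depth": comp[:, 5],
            "time_to_event_days": time_days,
            "event": event,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Random transition parameter sets
# ---------------------------------------------------------------------------

#: Per-transition uniform sampling bounds for random monthly parameter sets.
DEFAULT_TRANSITION_BOUNDS: dict[tuple[HealthState, HealthState], tuple[float, float]] = {
    (HealthState.POST_DFU, HealthState.NONSEVERE_DFU): (0.003, 0.035),
    (HealthState.POST_DFU, HealthState.SEVERE_DFU): (0.001, 0.015),
    (HealthState.POST_DFU, HealthState.DEATH): (0.0005, 0.010),
    (HealthState.NONSEVERE_DFU, HealthState.POST_DFU): (0.05, 0.30),
    (HealthState.NONSEVERE_DFU, HealthState.SEVERE_DFU): (0.01, 0.10),
    (HealthState.NONSEVERE_DFU, HealthState.AMPUTATION): (0.001, 0.02),
    (HealthState.SEVERE_DFU, HealthState.POST_DFU): (0.02, 0.20),
    (HealthState.SEVERE_DFU, HealthState.AMPUTATION): (0.005, 0.05),
    (HealthState.SEVERE_DFU, HealthState.DEATH): (0.005, 0.05),
    (HealthState.AMPUTATION, HealthState.POST_AMPUTATION): (1.0, 1.0),
    (HealthState.POST_AMPUTATION, HealthState.DEATH): (0.005, 0.03),
}


def generate_transition_params(
    seed: int,
    constraints: dict[tuple[HealthState, HealthState], tuple[float, float]] | None = None,
) -> TransitionParameters:
    """Random validated transition set respecting the structural mask.

    ``constraints`` maps allowed (from, to) pairs to uniform (low, high)
    sampling bounds; unlisted pairs stay zero.  Bounds whose row could sum
    past 1 are infeasible and rejected up front.
    """
    bounds = DEFAULT_TRANSITION_BOUNDS if constraints is None else constraints
    row_max: dict[HealthState, float] = {}
    for (s, t), (lo, hi) in bounds.items():
        if not (0 <= lo <= hi <= 1):
            raise ValidationError(f"invalid bounds for {s.name}->{t.name}")
        if s != HealthState.AMPUTATION:
            row_max[s] = row_max.get(s, 0.0) + hi
    infeasible = {s.name for s, tot in row_max.items() if tot > 1}
    if infeasible:
        raise ValidationError(
            f"infeasible constraints: outflow bounds can exceed 1 for {sorted(infeasible)}"
        )
    rng = np.random.default_rng(seed)
    outflows = {
        pair: float(rng.uniform(lo, hi)) for pair, (lo, hi) in sorted(
            bounds.items(), key=lambda kv: (int(kv[0][0]), int(kv[0][1]))
        )
    }
    return validate_transitions(TransitionParameters.from_outflows(outflows))


def simulate_patient_histories(
    params: TransitionParameters,
    n: int,
    seed: int,
    n_cycles: int,
) -> np.ndarray:
    """Individual-level Markov chains from POST_DFU; per-cycle frequencies.

    Simulates ``n`` independent patients for ``n_cycles`` monthly cycles
    under the validated transition matrix and returns an
    ``(n_cycles + 1, 6)`` array of empirical state frequencies — the
    stochastic oracle for :func:`dfu_heor.model.run_cohort_trace`.
    """
    if n < 1:
        raise DomainError("need at least one simulated patient")
    if not params.validated:
        raise ValidationError("parameters must be validated")
    rng = np.random.default_rng(seed)
    P_cum = np.cumsum(params.matrix, axis=1)
    states = np.full(n, int(HealthState.POST_DFU), dtype=np.int64)
    freqs = np.empty((n_cycles + 1, N_STATES))
    freqs[0] = np.bincount(states, minlength=N_STATES) / n
    for c in range(1, n_cycles + 1):
        u = rng.random(n)
        # clip guards against cumulative rounding leaving the row sum at 1-eps
        states = np.minimum(
            (u[:, None] > P_cum[states]).sum(axis=1), N_STATES - 1
        )
        freqs[c] = np.bincount(states, minlength=N_STATES) / n
    return freqs
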