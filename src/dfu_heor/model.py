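"""Six-state Markov cohort model of recurrent diabetic foot ulcers.

The model tracks a closed hypothetical cohort of people with a recently
healed diabetic foot ulcer (DFU) through monthly cycles over the states

    POST_DFU -> NONSEVERE_DFU | SEVERE_DFU | DEATH
    NONSEVERE_DFU -> POST_DFU | SEVERE_DFU | AMPUTATION
    SEVERE_DFU -> POST_DFU | AMPUTATION | DEATH
    AMPUTATION -> POST_AMPUTATION            (tunnel, one cycle)
    POST_AMPUTATION -> DEATH
    DEATH (absorbing)

with self-transitions absorbing the residual row mass everywhere except the
amputation tunnel.  Severity is SINBAD-based: a "severe" DFU is one with a
SINBAD score >= 3.  Everyone starts in POST_DFU; the baseline cohort is
age 67, 70% male.  Each cycle accrues state utilities (QALYs, per-year
weights prorated to 1/12) and monthly state costs in GBP, both discounted at
an annual rate (3.5% base case, NICE convention).

Transition probabilities are NOT bundled as authoritative values: the
published inputs behind this model structure come from audit and literature
sources that are not reproduced here.  :func:`placeholder_transition_parameters`
ships a clearly labelled illustrative set for tests and demos only; real
analyses must supply their own parameter file.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import DomainError, StructuralViolationError, ValidationError

__all__ = [
    "HealthState",
    "N_STATES",
    "TransitionParameters",
    "EconomicParameters",
    "ModelConfig",
    "CohortTrace",
    "validate_transitions",
    "apply_intervention",
    "run_cohort_trace",
    "discount_factor",
    "discount_factors",
    "accumulate_outcomes",
    "default_structural_mask",
    "placeholder_transition_parameters",
    "base_case_economics",
    "APP_PRICES",
    "BASE_CASE_UTILITIES",
    "BASE_CASE_MONTHLY_COSTS",
]


class HealthState(enum.IntEnum):
    """The six health states of the cohort model."""

    POST_DFU = 0
    NONSEVERE_DFU = 1
    SEVERE_DFU = 2
    AMPUTATION = 3
    POST_AMPUTATION = 4
    DEATH = 5

    @classmethod
    def from_name(cls, name: str) -> "HealthState":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown health state {name!r}") from None


N_STATES = len(HealthState)

# Allowed off-diagonal moves.  Self-transitions are implicitly allowed for
# every state (they absorb residual row mass); AMPUTATION is a one-cycle
# tunnel whose full mass defaults to POST_AMPUTATION.
_ALLOWED_MOVES: dict[HealthState, frozenset[HealthState]] = {
    HealthState.POST_DFU: frozenset(
        {HealthState.NONSEVERE_DFU, HealthState.SEVERE_DFU, HealthState.DEATH}
    ),
    HealthState.NONSEVERE_DFU: frozenset(
        {HealthState.POST_DFU, HealthState.SEVERE_DFU, HealthState.AMPUTATION}
    ),
    HealthState.SEVERE_DFU: frozenset(
        {HealthState.POST_DFU, HealthState.AMPUTATION, HealthState.DEATH}
    ),
    HealthState.AMPUTATION: frozenset({HealthState.POST_AMPUTATION}),
    HealthState.POST_AMPUTATION: frozenset({HealthState.DEATH}),
    HealthState.DEATH: frozenset(),
}


def default_structural_mask(allow_amputation_death: bool = False) -> np.ndarray:
    """Boolean (6, 6) matrix of allowed off-diagonal transitions.

    ``allow_amputation_death=True`` adds AMPUTATION -> DEATH (perioperative
    mortality), departing from the printed structure; callers opting in are
    warned at parameter construction.
    """
    mask = np.zeros((N_STATES, N_STATES), dtype=bool)
    for s, targets in _ALLOWED_MOVES.items():
        for t in targets:
            mask[s, t] = True
    if allow_amputation_death:
        mask[HealthState.AMPUTATION, HealthState.DEATH] = True
    return mask


@dataclass(frozen=True)
class TransitionParameters:
    """Per-cycle (monthly) transition probabilities with a structural mask.

    ``matrix`` is a (6, 6) array; after :func:`validate_transitions` each row
    is stochastic, with the diagonal holding the residual self-transition
    mass and DEATH absorbing.
    """

    matrix: np.ndarray
    mask: np.ndarray = field(default_factory=default_structural_mask)
    validated: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValidationError(
                f"transition matrix must be {N_STATES}x{N_STATES}, got {m.shape}"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @classmethod
    def from_outflows(
        cls,
        outflows: Mapping[tuple[HealthState, HealthState], float],
        *,
        allow_amputation_death: bool = False,
    ) -> "TransitionParameters":
        """Build an (unvalidated) parameter set from off-diagonal outflows.

        Unspecified entries are zero, except the amputation tunnel: when
        AMPUTATION -> POST_AMPUTATION is *absent* it defaults to 1.0 (the
        tunnel lasts exactly one cycle).  An explicit 0.0 is honoured and the
        mass stays on the amputation self-loop instead.
        """
        mask = default_structural_mask(allow_amputation_death)
        m = np.zeros((N_STATES, N_STATES))
        for (s, t), p in outflows.items():
            s, t = HealthState(s), HealthState(t)
            if s == t:
                raise ValidationError(
                    f"self-transition {s.name}->{t.name} is implicit; "
                    "specify outflows only"
                )
            m[s, t] = p
        tunnel = (HealthState.AMPUTATION, HealthState.POST_AMPUTATION)
        if tunnel not in {(HealthState(a), HealthState(b)) for a, b in outflows}:
            m[tunnel] = 1.0
        return cls(matrix=m, mask=mask)

    def outflow(self, s: HealthState, t: HealthState) -> float:
        return float(self.matrix[HealthState(s), HealthState(t)])


def validate_transitions(params: TransitionParameters) -> TransitionParameters:
    """Complete and check a transition parameter set.

    Fills each diagonal with ``1 - sum(outflows)`` (DEATH stays absorbing),
    then enforces: probabilities in [0, 1], no mass on structurally
    forbidden pairs, and row outflow sums <= 1.

    Raises
    ------
    StructuralViolationError
        If any off-diagonal entry sits on a forbidden pair, naming it.
    ValidationError
        If an entry is negative/non-finite or a row's outflows exceed 1.
    """
    m = params.matrix.copy()
    if not np.all(np.isfinite(m)):
        raise ValidationError("transition probabilities must be finite")
    off = ~np.eye(N_STATES, dtype=bool)
    if np.any(m[off] < 0) or np.any(m[off] > 1):
        bad = np.argwhere(off & ((m < 0) | (m > 1)))[0]
        s, t = HealthState(bad[0]), HealthState(bad[1])
        raise ValidationError(
            f"probability {s.name}->{t.name} = {m[bad[0], bad[1]]} outside [0, 1]"
        )
    forbidden = off & ~params.mask & (m > 0)
    if np.any(forbidden):
        s, t = (HealthState(i) for i in np.argwhere(forbidden)[0])
        raise StructuralViolationError(
            f"transition {s.name}->{t.name} is not permitted by the model "
            "structure"
        )
    for s in HealthState:
        out = m[s, off[s]].sum()
        if out > 1 + 1e-12:
            raise ValidationError(
                f"row sum exceeds 1: outflows from {s.name} total {out:.6g}"
            )
        m[s, s] = max(0.0, 1.0 - out)
    m[HealthState.DEATH, :] = 0.0
    m[HealthState.DEATH, HealthState.DEATH] = 1.0
    return replace(params, matrix=m, validated=True)


def apply_intervention(
    params: TransitionParameters, rr: float, compliance: float
) -> TransitionParameters:
    """Scale both recurrence transitions by the compliance-adjusted risk.

    The app's effect is a relative risk ``rr`` on DFU recurrence.  With
    partial uptake a fraction ``1 - compliance`` of the cohort gets no
    effect, so the effective multiplier is

        rr_eff = compliance * rr + (1 - compliance)

    applied to POST_DFU -> NONSEVERE_DFU and POST_DFU -> SEVERE_DFU alike;
    the freed mass returns to the POST_DFU self-transition.
    """
    if not (0 < rr <= 1):
        raise DomainError(f"relative risk must be in (0, 1], got {rr}")
    if not (0 <= compliance <= 1):
        raise DomainError(f"compliance must be in [0, 1], got {compliance}")
    if not params.validated:
        params = validate_transitions(params)
    rr_eff = compliance * rr + (1.0 - compliance)
    m = params.matrix.copy()
    s = HealthState.POST_DFU
    for t in (HealthState.NONSEVERE_DFU, HealthState.SEVERE_DFU):
        m[s, t] *= rr_eff
    off = ~np.eye(N_STATES, dtype=bool)
    m[s, s] = 1.0 - m[s, off[s]].sum()
    return validate_transitions(replace(params, matrix=m, validated=False))


# ---------------------------------------------------------------------------
# Economic parameters (base-case utilities and GBP monthly costs)
# ---------------------------------------------------------------------------

BASE_CASE_UTILITIES: dict[HealthState, float] = {
    HealthState.POST_DFU: 0.64,
    HealthState.NONSEVERE_DFU: 0.61,
    HealthState.SEVERE_DFU: 0.47,
    HealthState.AMPUTATION: 0.34,
    HealthState.POST_AMPUTATION: 0.47,
    HealthState.DEATH: 0.0,
}

BASE_CASE_MONTHLY_COSTS: dict[HealthState, float] = {
    HealthState.POST_DFU: 180.70,
    HealthState.NONSEVERE_DFU: 453.83,
    HealthState.SEVERE_DFU: 972.30,
    HealthState.AMPUTATION: 1106.19,
    HealthState.POST_AMPUTATION: 311.96,
    HealthState.DEATH: 0.0,
}

#: App pricing scenarios, GBP per month.
APP_PRICES: dict[str, float] = {"free": 0.00, "monthly": 4.99, "annual": 4.17}


@dataclass(frozen=True)
class EconomicParameters:
    """State utilities, monthly costs (GBP, 2017/18 prices), app pricing.

    ``utility`` holds per-year QALY weights in [0, 1] (death fixed at 0);
    ``monthly_cost`` GBP per cycle.  ``compliance`` is the proportion of the
    cohort actually using the app.  Discount rates are annual; outcome and
    cost streams may be discounted at different rates (base case 3.5% both).
    ``wtp`` is the willingness-to-pay threshold in GBP per QALY.
    """

    utility: np.ndarray
    monthly_cost: np.ndarray
    app_price_monthly: float = APP_PRICES["monthly"]
    compliance: float = 0.90
    annual_discount_rate_costs: float = 0.035
    annual_discount_rate_outcomes: float = 0.035
    wtp: float = 20_000.0

    def __post_init__(self):
        u = np.asarray(self.utility, dtype=float)
        c = np.asarray(self.monthly_cost, dtype=float)
        if u.shape != (N_STATES,) or c.shape != (N_STATES,):
            raise ValidationError(
                f"utility and monthly_cost must have length {N_STATES}"
            )
        if np.any(u < 0) or np.any(u > 1):
            raise ValidationError("utilities must lie in [0, 1]")
        if u[HealthState.DEATH] != 0.0:
            raise ValidationError("utility of DEATH must be 0")
        if np.any(c < 0) or self.app_price_monthly < 0:
            raise ValidationError("costs must be non-negative")
        if not (0 <= self.compliance <= 1):
            raise ValidationError("compliance must lie in [0, 1]")
        for r in (self.annual_discount_rate_costs, self.annual_discount_rate_outcomes):
            if not (0 <= r < 0.5):
                raise ValidationError(f"discount rate {r} outside [0, 0.5)")
        if self.wtp < 0:
            raise ValidationError("willingness-to-pay must be non-negative")
        object.__setattr__(self, "utility", u)
        object.__setattr__(self, "monthly_cost", c)


def base_case_economics(pricing: str = "monthly", **overrides) -> EconomicParameters:
    """Base-case economic parameters under a named app-pricing scenario."""
    if pricing not in APP_PRICES:
        raise ValidationError(
            f"unknown pricing {pricing!r}; valid options: {sorted(APP_PRICES)}"
        )
    kwargs = dict(
        utility=np.array([BASE_CASE_UTILITIES[s] for s in HealthState]),
        monthly_cost=np.array([BASE_CASE_MONTHLY_COSTS[s] for s in HealthState]),
        app_price_monthly=APP_PRICES[pricing],
    )
    kwargs.update(overrides)
    return EconomicParameters(**kwargs)


# ---------------------------------------------------------------------------
# Model configuration and the cohort trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Run settings for the cohort trace.

    The cycle length is fixed at one month.  The horizon is lifetime: the
    trace runs until the cohort reaches ``max_age_years`` or the alive
    fraction drops below ``residual_alive_tolerance``.  Half-cycle
    correction (averaging start- and end-of-cycle occupancy) is on by
    default.  ``annual_step_discounting`` switches from the per-cycle factor
    (1+r)^(-c/12) to annual steps (1+r)^(-floor(c/12)).  Baseline age/sex
    describe the modelled cohort (age 67, 70% male); mortality is
    state-constant per cycle, not age-varying.
    """

    cycle_length_months: float = 1.0
    baseline_age_years: float = 67.0
    proportion_male: float = 0.70
    max_age_years: float = 100.0
    residual_alive_tolerance: float = 1e-6
    half_cycle_correction: bool = True
    annual_step_discounting: bool = False
    intervention_rr: float = 1.0

    def __post_init__(self):
        if self.cycle_length_months != 1.0:
            raise ValidationError("cycle length is fixed at 1 month")
        if self.max_age_years <= self.baseline_age_years:
            raise ValidationError("max_age_years must exceed baseline_age_years")
        if not (0 <= self.proportion_male <= 1):
            raise ValidationError("proportion_male must lie in [0, 1]")
        if not (0 < self.intervention_rr <= 1):
            raise ValidationError("intervention_rr must lie in (0, 1]")
        if self.residual_alive_tolerance < 0:
            raise ValidationError("residual_alive_tolerance must be >= 0")

    @property
    def max_cycles(self) -> int:
        return int(
            math.ceil((self.max_age_years - self.baseline_age_years) * 12.0
                      / self.cycle_length_months)
        )


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy proportions by cycle plus the settings that made them.

    ``occupancy`` has shape (n_cycles + 1, 6); row 0 is the initial
    distribution (100% POST_DFU).  Discounted totals are attached after
    :func:`accumulate_outcomes`.
    """

    occupancy: np.ndarray
    config: ModelConfig
    discounted_qalys: float | None = None
    discounted_costs: float | None = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def ages(self) -> np.ndarray:
        """Cohort age in years at the start of each recorded row."""
        return self.config.baseline_age_years + np.arange(
            self.occupancy.shape[0]
        ) / 12.0

    @property
    def alive_fraction(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, HealthState.DEATH]


def run_cohort_trace(
    params: TransitionParameters, config: ModelConfig | None = None
) -> CohortTrace:
    """Propagate the cohort through monthly cycles.

    Starts with the whole cohort in POST_DFU and iterates
    ``occupancy[c+1] = occupancy[c] @ P`` until the age cap or until the
    alive fraction falls below ``residual_alive_tolerance``.
    """
    config = config or ModelConfig()
    if not params.validated:
        raise ValidationError(
            "transition parameters must pass validate_transitions first"
        )
    n_max = config.max_cycles
    if n_max < 1:
        raise DomainError("time horizon produces zero cycles")
    P = params.matrix
    rows = np.empty((n_max + 1, N_STATES))
    v = np.zeros(N_STATES)
    v[HealthState.POST_DFU] = 1.0
    rows[0] = v
    n = 0
    for c in range(1, n_max + 1):
        v = v @ P
        rows[c] = v
        n = c
        if 1.0 - v[HealthState.DEATH] < config.residual_alive_tolerance:
            break
    return CohortTrace(occupancy=rows[: n + 1].copy(), config=config)


# ---------------------------------------------------------------------------
# Discounting and outcome accumulation
# ---------------------------------------------------------------------------


def discount_factor(
    cycle: int, annual_rate: float, *, annual_step: bool = False
) -> float:
    """Discount factor for a monthly cycle index.

    Per-cycle convention ``(1 + r)^(-c/12)``; with ``annual_step`` the
    factor steps once per completed model year, ``(1 + r)^(-floor(c/12))``.
    """
    if cycle < 0:
        raise DomainError("cycle index must be non-negative")
    if annual_rate < 0:
        raise DomainError("discount rate must be non-negative")
    exponent = (cycle // 12) if annual_step else (cycle / 12.0)
    return float((1.0 + annual_rate) ** (-exponent))


def discount_factors(
    n_cycles: int, annual_rate: float, *, annual_step: bool = False
) -> np.ndarray:
    """Vector of discount factors for cycles 0 .. n_cycles-1."""
    c = np.arange(n_cycles, dtype=float)
    exponent = np.floor(c / 12.0) if annual_step else c / 12.0
    return (1.0 + annual_rate) ** (-exponent)


def accumulate_outcomes(
    trace: CohortTrace,
    econ: EconomicParameters,
    include_app_cost: bool = False,
) -> tuple[float, float]:
    """Discounted QALYs and costs (GBP) over the trace.

    Cycle ``c`` accrues ``sum_s occ[c][s] * utility[s] / 12`` QALYs and
    ``sum_s occ[c][s] * monthly_cost[s]`` GBP, discounted by the cycle's
    factor; with half-cycle correction the occupancy used is the mean of the
    rows bounding the cycle.  The app subscription, when included, is
    charged to the alive fraction only.
    """
    if econ.utility.shape[0] != trace.occupancy.shape[1]:
        raise ValidationError("economic parameters do not match the state set")
    occ = trace.occupancy
    n = trace.n_cycles
    if trace.config.half_cycle_correction:
        eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        eff = occ[:-1]
    step = trace.config.annual_step_discounting
    d_out = discount_factors(n, econ.annual_discount_rate_outcomes, annual_step=step)
    d_cost = discount_factors(n, econ.annual_discount_rate_costs, annual_step=step)
    qalys = float(np.sum((eff @ econ.utility) / 12.0 * d_out))
    costs = float(np.sum((eff @ econ.monthly_cost) * d_cost))
    if include_app_cost:
        alive = 1.0 - eff[:, HealthState.DEATH]
        costs += float(np.sum(econ.app_price_monthly * alive * d_cost))
    return qalys, costs


# ---------------------------------------------------------------------------
# Placeholder transition values — illustrative only
# ---------------------------------------------------------------------------

#: PLACEHOLDER monthly transition probabilities for tests and demos only.
#: These are plausible orders of magnitude (monthly recurrence 0.02 split
#: 70/30 non-severe/severe), not estimates from any data source.  Real
#: analyses must load their own parameter file.
PLACEHOLDER_OUTFLOWS: dict[tuple[HealthState, HealthState], float] = {
    (HealthState.POST_DFU, HealthState.NONSEVERE_DFU): 0.014,
    (HealthState.POST_DFU, HealthState.SEVERE_DFU): 0.006,
    (HealthState.POST_DFU, HealthState.DEATH): 0.003,
    (HealthState.NONSEVERE_DFU, HealthState.POST_DFU): 0.15,
    (HealthState.NONSEVERE_DFU, HealthState.SEVERE_DFU): 0.04,
    (HealthState.NONSEVERE_DFU, HealthState.AMPUTATION): 0.005,
    (HealthState.SEVERE_DFU, HealthState.POST_DFU): 0.08,
    (HealthState.SEVERE_DFU, HealthState.AMPUTATION): 0.02,
    (HealthState.SEVERE_DFU, HealthState.DEATH): 0.010,
    (HealthState.AMPUTATION, HealthState.POST_AMPUTATION): 1.0,
    (HealthState.POST_AMPUTATION, HealthState.DEATH): 0.010,
}


def placeholder_transition_parameters() -> TransitionParameters:
    """Validated PLACEHOLDER transition set (illustrative magnitudes only)."""
    return validate_transitions(
        TransitionParameters.from_outflows(PLACEHOLDER_OUTFLOWS)
    )
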