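"""Cost-utility outputs: ICER, net monetary benefit, threshold analysis.

The comparison is always "app + standard of care" versus "standard of care"
on identical horizons: the comparator trace uses the base transition set and
no app subscription, the intervention trace applies the compliance-adjusted
relative risk to both recurrence transitions and adds the monthly app price
for the alive fraction.

Because comparative effectiveness data do not exist for this intervention,
the headline analysis is a *threshold* analysis: the smallest relative
reduction in recurrence (1 - rr) for which the ICER equals a target
willingness-to-pay, found by deterministic bisection on the net monetary
benefit at that target.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import pandas as pd

from .errors import DomainError, NoThresholdError, ValidationError
from .model import (
    APP_PRICES,
    CohortTrace,
    EconomicParameters,
    ModelConfig,
    TransitionParameters,
    accumulate_outcomes,
    apply_intervention,
    run_cohort_trace,
)

__all__ = [
    "StrategyResult",
    "IcerCategory",
    "IcerResult",
    "ThresholdStatus",
    "ThresholdResult",
    "icer",
    "nmb",
    "evaluate_strategies",
    "threshold_rr",
    "run_scenarios",
]

_ZERO_EFFECT_TOL = 1e-12


@dataclass(frozen=True)
class StrategyResult:
    """Discounted totals for one strategy arm."""

    label: str
    discounted_qalys: float
    discounted_costs: float

    def __post_init__(self):
        if self.discounted_qalys < 0 or self.discounted_costs < 0:
            raise ValidationError("strategy totals must be non-negative")


class IcerCategory(enum.Enum):
    ICER = "icer"
    DOMINANT = "dominant"        # cheaper and at least as effective
    DOMINATED = "dominated"      # costlier and less effective
    ZERO_EFFECT = "zero_effect"  # |delta QALY| below tolerance


@dataclass(frozen=True)
class IcerResult:
    """Incremental cost-effectiveness ratio with quadrant classification.

    ``southwest`` flags the less-effective-and-cheaper quadrant, where the
    ratio is a *decrement* price and must never be compared with a
    willingness-to-pay threshold silently.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    category: IcerCategory
    southwest: bool = False


def icer(intervention: StrategyResult, comparator: StrategyResult) -> IcerResult:
    """Incremental cost per QALY of ``intervention`` over ``comparator``."""
    dc = intervention.discounted_costs - comparator.discounted_costs
    dq = intervention.discounted_qalys - comparator.discounted_qalys
    if abs(dq) < _ZERO_EFFECT_TOL:
        return IcerResult(dc, dq, None, IcerCategory.ZERO_EFFECT)
    if dq > 0 and dc < 0:
        return IcerResult(dc, dq, None, IcerCategory.DOMINANT)
    if dq < 0 and dc >= 0:
        return IcerResult(dc, dq, None, IcerCategory.DOMINATED)
    southwest = dq < 0 and dc < 0
    return IcerResult(dc, dq, dc / dq, IcerCategory.ICER, southwest=southwest)


def nmb(
    intervention: StrategyResult, comparator: StrategyResult, wtp: float
) -> float:
    """Incremental net monetary benefit, ``wtp * dQALY - dCost`` (GBP)."""
    if wtp < 0:
        raise DomainError("willingness-to-pay must be non-negative")
    dq = intervention.discounted_qalys - comparator.discounted_qalys
    dc = intervention.discounted_costs - comparator.discounted_costs
    return wtp * dq - dc


def evaluate_strategies(
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig | None = None,
    rr: float = 1.0,
) -> tuple[StrategyResult, StrategyResult]:
    """Run both arms on identical horizons.

    Returns ``(intervention, comparator)``.  The early-stop residual
    tolerance is disabled here so that both traces cover exactly the same
    cycles and discounting grid.
    """
    config = config or ModelConfig()
    full = replace(config, residual_alive_tolerance=0.0)
    if not params.validated:
        raise ValidationError(
            "transition parameters must pass validate_transitions first"
        )
    soc_trace = run_cohort_trace(params, full)
    q0, c0 = accumulate_outcomes(soc_trace, econ, include_app_cost=False)
    app_params = apply_intervention(params, rr, econ.compliance)
    app_trace = run_cohort_trace(app_params, full)
    q1, c1 = accumulate_outcomes(app_trace, econ, include_app_cost=True)
    return (
        StrategyResult("app + SoC", q1, c1),
        StrategyResult("SoC", q0, c0),
    )


class ThresholdStatus(enum.Enum):
    FOUND = "found"
    DOMINANT_AT_RR1 = "dominant_at_rr1"  # app cost-saving even with no effect


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the threshold search.

    ``rr`` is the relative risk at which the ICER equals the target;
    ``relative_reduction`` is ``1 - rr`` (the quantity usually reported,
    e.g. "a 3% relative reduction in recurrence").
    """

    rr: float
    status: ThresholdStatus
    target_icer: float
    iterations: int = 0
    icer_at_rr: float | None = None

    @property
    def relative_reduction(self) -> float:
        return 1.0 - self.rr


def threshold_rr(
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig | None = None,
    target_icer: float = 20_000.0,
    *,
    rr_tol: float = 1e-6,
    max_iter: int = 200,
) -> ThresholdResult:
    """Smallest intervention effect whose ICER equals the target.

    Bisects the incremental NMB at ``wtp = target_icer``, which is zero
    exactly where the ICER crosses the target, over rr in (0, 1].  If the
    app is cost-saving even with zero effect (rr = 1), the intervention
    dominates for every rr and the boundary result is returned with status
    ``DOMINANT_AT_RR1``.

    Raises
    ------
    NoThresholdError
        If NMB at the target has no sign change on (0, 1] — e.g. with zero
        compliance the app can never change QALYs and no effect size
        reaches the target ICER.
    """
    if target_icer <= 0:
        raise DomainError("target ICER must be positive")
    config = config or ModelConfig()

    def f(rr: float) -> float:
        interv, comp = evaluate_strategies(params, econ, config, rr)
        return nmb(interv, comp, target_icer)

    hi = 1.0
    f_hi = f(hi)
    if f_hi >= 0:
        # at rr = 1 dQALY = 0, so NMB = -dCost >= 0 means the app costs
        # nothing (or saves money) with zero effect: dominant everywhere.
        return ThresholdResult(1.0, ThresholdStatus.DOMINANT_AT_RR1, target_icer)
    lo = 1e-9
    f_lo = f(lo)
    if f_lo < 0:
        raise NoThresholdError(
            "no threshold in range: net monetary benefit at the target "
            "willingness-to-pay is negative over all rr in (0, 1]",
            diagnostics={
                "nmb_at_rr_eps": f_lo,
                "nmb_at_rr_1": f_hi,
                "target_icer": target_icer,
                "compliance": econ.compliance,
                "app_price_monthly": econ.app_price_monthly,
            },
        )
    it = 0
    while hi - lo > rr_tol and it < max_iter:
        mid = 0.5 * (lo + hi)
        if f(mid) >= 0:
            lo = mid
        else:
            hi = mid
        it += 1
    rr_star = 0.5 * (lo + hi)
    res = icer(*evaluate_strategies(params, econ, config, rr_star))
    return ThresholdResult(
        rr_star, ThresholdStatus.FOUND, target_icer, iterations=it,
        icer_at_rr=res.icer,
    )


def run_scenarios(
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig | None = None,
    pricings: tuple[str, ...] = ("free", "monthly", "annual"),
    target_icer: float = 20_000.0,
) -> pd.DataFrame:
    """Threshold analysis across app-pricing scenarios.

    Returns one row per scenario with the app price, the threshold relative
    risk and relative reduction (percent), and the ICER recomputed at the
    threshold.  Unknown pricing labels are rejected listing valid options.
    """
    rows = []
    for label in pricings:
        if label not in APP_PRICES:
            raise ValidationError(
                f"unknown pricing {label!r}; valid options: {sorted(APP_PRICES)}"
            )
        econ_s = replace(econ, app_price_monthly=APP_PRICES[label])
        try:
            t = threshold_rr(params, econ_s, config, target_icer)
            status = t.status.value
            rr = t.rr
            icer_at = t.icer_at_rr
        except NoThresholdError:
            status, rr, icer_at = "no_threshold", float("nan"), None
        rows.append(
            {
                "scenario": label,
                "app_price_monthly": APP_PRICES[label],
                "target_icer": target_icer,
                "threshold_rr": rr,
                "relative_reduction_pct": 100.0 * (1.0 - rr),
                "icer_at_threshold": icer_at,
                "status": status,
            }
        )
    return pd.DataFrame(rows)
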