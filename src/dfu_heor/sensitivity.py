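"""One-way sensitivity analysis with tornado ordering.

Each parameter is pushed to the low and high end of its range while all
others stay at base, the incremental net monetary benefit (NMB) of the app
arm at a fixed relative risk and willingness-to-pay is recomputed by a full
model run at each endpoint, and the bars are sorted by descending width.

Parameter addressing uses dotted keys:

    transitions.<from_state>.to.<to_state>   e.g. transitions.post_dfu.to.severe_dfu
    utilities.<state>                        e.g. utilities.post_dfu
    costs.<state>                            e.g. costs.severe_dfu
    costs.app_monthly
    compliance
    discount_rate_outcomes / discount_rate_costs

Default ranges are conventional deterministic-sensitivity choices: +/-20% of
base for probabilities, utilities and costs (clipped to their domains) and
an absolute 1.5%-6% band for the discount rates; every range can be
overridden per parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .model import (
    EconomicParameters,
    HealthState,
    ModelConfig,
    N_STATES,
    TransitionParameters,
    validate_transitions,
)
from .economics import evaluate_strategies, nmb

__all__ = [
    "ParameterRange",
    "TornadoBar",
    "owsa",
    "default_ranges",
    "tornado_frame",
    "plot_tornado",
]


@dataclass(frozen=True)
class ParameterRange:
    """One parameter with its base value and low/high bounds."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"range for {self.name!r} must satisfy low <= base <= high "
                f"(got {self.low}, {self.base}, {self.high})"
            )


@dataclass(frozen=True)
class TornadoBar:
    """NMB at the low and high end of one parameter's range."""

    name: str
    base: float
    low: float
    high: float
    nmb_low: float
    nmb_high: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


_DISCOUNT_KEYS = {"discount_rate_outcomes", "discount_rate_costs"}


def _parse_transition_key(name: str) -> tuple[HealthState, HealthState] | None:
    parts = name.split(".")
    if len(parts) == 4 and parts[0] == "transitions" and parts[2] == "to":
        return HealthState.from_name(parts[1]), HealthState.from_name(parts[3])
    return None


def _set_parameter(
    name: str,
    value: float,
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig,
) -> tuple[TransitionParameters, EconomicParameters, ModelConfig]:
    """Return copies of the inputs with one named parameter replaced."""
    pair = _parse_transition_key(name)
    if pair is not None:
        s, t = pair
        if not (0.0 <= value <= 1.0):
            warnings.warn(
                f"{name}: value {value} clipped to [0, 1]", stacklevel=3
            )
            value = float(np.clip(value, 0.0, 1.0))
        m = params.matrix.copy()
        m[s, t] = value
        m[s, s] = 0.0  # recomputed by the validator as the residual
        return (
            validate_transitions(replace(params, matrix=m, validated=False)),
            econ,
            config,
        )
    parts = name.split(".")
    if parts[0] == "utilities" and len(parts) == 2:
        s = HealthState.from_name(parts[1])
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name}: utility {value} outside [0, 1]")
        u = econ.utility.copy()
        u[s] = value
        return params, replace(econ, utility=u), config
    if parts[0] == "costs" and len(parts) == 2:
        if parts[1] == "app_monthly":
            return params, replace(econ, app_price_monthly=value), config
        s = HealthState.from_name(parts[1])
        if value < 0:
            raise ValidationError(f"{name}: cost must be non-negative")
        c = econ.monthly_cost.copy()
        c[s] = value
        return params, replace(econ, monthly_cost=c), config
    if name == "compliance":
        return params, replace(econ, compliance=value), config
    if name == "discount_rate_outcomes":
        return params, replace(econ, annual_discount_rate_outcomes=value), config
    if name == "discount_rate_costs":
        return params, replace(econ, annual_discount_rate_costs=value), config
    raise ValidationError(f"unresolvable parameter name {name!r}")


def default_ranges(
    params: TransitionParameters,
    econ: EconomicParameters,
    *,
    proportional: float = 0.20,
    discount_band: tuple[float, float] = (0.015, 0.06),
) -> list[ParameterRange]:
    """Conventional one-way ranges for every active model parameter.

    +/-``proportional`` of base for each specified transition probability,
    non-death utility and state cost plus the app price (clipped to valid
    domains), and the absolute ``discount_band`` for both discount rates.
    """
    ranges: list[ParameterRange] = []
    off = ~np.eye(N_STATES, dtype=bool)
    for s in HealthState:
        for t in HealthState:
            p = params.matrix[s, t]
            if s == t or not off[s, t] or p <= 0 or s == HealthState.AMPUTATION:
                continue
            ranges.append(
                ParameterRange(
                    f"transitions.{s.name.lower()}.to.{t.name.lower()}",
                    p,
                    max(0.0, p * (1 - proportional)),
                    min(1.0, p * (1 + proportional)),
                )
            )
    for s in HealthState:
        if s == HealthState.DEATH:
            continue
        u = float(econ.utility[s])
        ranges.append(
            ParameterRange(
                f"utilities.{s.name.lower()}",
                u,
                max(0.0, u * (1 - proportional)),
                min(1.0, u * (1 + proportional)),
            )
        )
        c = float(econ.monthly_cost[s])
        ranges.append(
            ParameterRange(
                f"costs.{s.name.lower()}", c, c * (1 - proportional),
                c * (1 + proportional),
            )
        )
    p = econ.app_price_monthly
    ranges.append(
        ParameterRange("costs.app_monthly", p, p * (1 - proportional),
                       p * (1 + proportional))
    )
    lo, hi = discount_band
    for key, base in (
        ("discount_rate_outcomes", econ.annual_discount_rate_outcomes),
        ("discount_rate_costs", econ.annual_discount_rate_costs),
    ):
        ranges.append(ParameterRange(key, base, min(lo, base), max(hi, base)))
    return ranges


def owsa(
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig | None = None,
    ranges: Iterable[ParameterRange] | None = None,
    rr: float = 0.95,
    wtp: float = 20_000.0,
) -> list[TornadoBar]:
    """One-way sensitivity analysis of incremental NMB at fixed rr and WTP.

    Every bar endpoint is an independent full-model re-evaluation (both
    arms re-run); output is sorted by descending width, ties broken by
    name, and is invariant to the input order of ``ranges``.
    """
    config = config or ModelConfig()
    if not params.validated:
        params = validate_transitions(params)
    if ranges is None:
        ranges = default_ranges(params, econ)
    ranges = list(ranges)
    names = [r.name for r in ranges]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicated parameter entries: {sorted(dupes)}")
    for r in ranges:
        _set_parameter(r.name, r.base, params, econ, config)  # resolvability
    bars = []
    for r in ranges:
        endpoints = []
        for v in (r.low, r.high):
            p2, e2, c2 = _set_parameter(r.name, v, params, econ, config)
            interv, comp = evaluate_strategies(p2, e2, c2, rr)
            endpoints.append(nmb(interv, comp, wtp))
        bars.append(
            TornadoBar(r.name, r.base, r.low, r.high, endpoints[0], endpoints[1])
        )
    bars.sort(key=lambda b: (-b.width, b.name))
    return bars


def tornado_frame(bars: list[TornadoBar]):
    """Tornado results as a DataFrame (parameter, base, low, high, nmb_low,
    nmb_high, width), in tornado order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": b.name,
                "base": b.base,
                "low": b.low,
                "high": b.high,
                "nmb_low": b.nmb_low,
                "nmb_high": b.nmb_high,
                "width": b.width,
            }
            for b in bars
        ]
    )


def plot_tornado(bars: list[TornadoBar], path=None, nmb_base: float | None = None):
    """Horizontal-bar tornado figure; writes to ``path`` when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bars = sorted(bars, key=lambda b: b.width)  # widest on top
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(bars), 4) + 1))
    y = np.arange(len(bars))
    for i, b in enumerate(bars):
        left = min(b.nmb_low, b.nmb_high)
        ax.barh(i, abs(b.nmb_high - b.nmb_low), left=left, color="#4878a8")
    ax.set_yticks(y)
    ax.set_yticklabels([b.name for b in bars], fontsize=8)
    if nmb_base is not None:
        ax.axvline(nmb_base, color="k", lw=0.8)
    ax.set_xlabel("incremental net monetary benefit (GBP)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
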