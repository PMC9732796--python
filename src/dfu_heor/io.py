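"""Parameter-file parsing, report writing, run manifests.

Parameter files are YAML with four flat key-value sections::

    transitions:
      post_dfu.to.nonsevere_dfu: 0.014
      post_dfu.to.severe_dfu: 0.006
      ...
    utilities:
      post_dfu: 0.64
      ...
    costs:
      severe_dfu: 972.30
      app_monthly: 4.99
      compliance: 0.9
    model:
      baseline_age_years: 67
      discount_rate_outcomes: 0.035
      ...

The ``transitions`` section is mandatory and must be non-empty — the
package never silently substitutes its placeholder probabilities for a real
analysis.  Missing utility/cost keys fall back to the base-case published
values with a logged notice; unknown keys anywhere are errors.

Reports are deterministic CSVs with fixed column order, numbers at six
significant digits, and the run manifest embedded as ``#``-comment header
lines, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .model import (
    BASE_CASE_MONTHLY_COSTS,
    BASE_CASE_UTILITIES,
    CohortTrace,
    EconomicParameters,
    HealthState,
    ModelConfig,
    TransitionParameters,
    discount_factors,
    validate_transitions,
)

__all__ = [
    "load_parameters",
    "write_parameters",
    "RunManifest",
    "make_manifest",
    "write_report",
    "trace_frame",
    "write_trace_csv",
    "format_threshold_report",
]

logger = logging.getLogger("dfu_heor")

_MODEL_KEYS = {
    "cycle_length_months",
    "baseline_age_years",
    "proportion_male",
    "max_age_years",
    "residual_alive_tolerance",
    "half_cycle_correction",
    "annual_step_discounting",
    "intervention_rr",
    "discount_rate_costs",
    "discount_rate_outcomes",
    "wtp",
}

_COST_KEYS = {s.name.lower() for s in HealthState} | {"app_monthly", "compliance"}
_UTILITY_KEYS = {s.name.lower() for s in HealthState}


def _parse_transition_key(key: str) -> tuple[HealthState, HealthState]:
    parts = key.split(".")
    if len(parts) != 3 or parts[1] != "to":
        raise ValidationError(
            f"transition key {key!r} must look like 'post_dfu.to.severe_dfu'"
        )
    return HealthState.from_name(parts[0]), HealthState.from_name(parts[2])


def load_parameters(
    path,
) -> tuple[TransitionParameters, EconomicParameters, ModelConfig]:
    """Load and validate a full parameter bundle from a YAML file."""
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a mapping of sections")
    unknown = set(doc) - {"transitions", "utilities", "costs", "model"}
    if unknown:
        raise ValidationError(f"{path}: unknown sections {sorted(unknown)}")

    trans_sec = doc.get("transitions") or {}
    if not trans_sec:
        raise ValidationError(
            f"{path}: the [transitions] section is required and must be "
            "non-empty; the packaged placeholder values are never used "
            "implicitly"
        )
    outflows = {_parse_transition_key(k): float(v) for k, v in trans_sec.items()}
    params = validate_transitions(TransitionParameters.from_outflows(outflows))

    util_sec = dict(doc.get("utilities") or {})
    unknown = set(util_sec) - _UTILITY_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown utility keys {sorted(unknown)}")
    utility = []
    for s in HealthState:
        key = s.name.lower()
        if key in util_sec:
            utility.append(float(util_sec[key]))
        else:
            utility.append(BASE_CASE_UTILITIES[s])
            if s != HealthState.DEATH:
                logger.info("utilities.%s missing; base-case default %.2f used",
                            key, BASE_CASE_UTILITIES[s])

    cost_sec = dict(doc.get("costs") or {})
    unknown = set(cost_sec) - _COST_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown cost keys {sorted(unknown)}")
    monthly_cost = []
    for s in HealthState:
        key = s.name.lower()
        if key in cost_sec:
            monthly_cost.append(float(cost_sec[key]))
        else:
            monthly_cost.append(BASE_CASE_MONTHLY_COSTS[s])
            if s != HealthState.DEATH:
                logger.info("costs.%s missing; base-case default %.2f used",
                            key, BASE_CASE_MONTHLY_COSTS[s])

    model_sec = dict(doc.get("model") or {})
    unknown = set(model_sec) - _MODEL_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown model keys {sorted(unknown)}")

    econ = EconomicParameters(
        utility=utility,
        monthly_cost=monthly_cost,
        app_price_monthly=float(cost_sec.get("app_monthly", 4.99)),
        compliance=float(cost_sec.get("compliance", 0.90)),
        annual_discount_rate_costs=float(
            model_sec.get("discount_rate_costs", 0.035)
        ),
        annual_discount_rate_outcomes=float(
            model_sec.get("discount_rate_outcomes", 0.035)
        ),
        wtp=float(model_sec.get("wtp", 20_000.0)),
    )
    config_kwargs = {
        k: model_sec[k]
        for k in _MODEL_KEYS - {"discount_rate_costs", "discount_rate_outcomes", "wtp"}
        if k in model_sec
    }
    config = ModelConfig(**config_kwargs)
    return params, econ, config


def write_parameters(
    path,
    params: TransitionParameters,
    econ: EconomicParameters,
    config: ModelConfig,
) -> None:
    """Serialise a parameter bundle; round-trips through load_parameters."""
    doc = {
        "transitions": {
            f"{s.name.lower()}.to.{t.name.lower()}": float(params.matrix[s, t])
            for s in HealthState
            for t in HealthState
            if s != t and params.mask[s, t] and params.matrix[s, t] > 0
        },
        "utilities": {
            s.name.lower(): float(econ.utility[s]) for s in HealthState
        },
        "costs": {
            **{s.name.lower(): float(econ.monthly_cost[s]) for s in HealthState},
            "app_monthly": econ.app_price_monthly,
            "compliance": econ.compliance,
        },
        "model": {
            "cycle_length_months": config.cycle_length_months,
            "baseline_age_years": config.baseline_age_years,
            "proportion_male": config.proportion_male,
            "max_age_years": config.max_age_years,
            "residual_alive_tolerance": config.residual_alive_tolerance,
            "half_cycle_correction": config.half_cycle_correction,
            "annual_step_discounting": config.annual_step_discounting,
            "intervention_rr": config.intervention_rr,
            "discount_rate_costs": econ.annual_discount_rate_costs,
            "discount_rate_outcomes": econ.annual_discount_rate_outcomes,
            "wtp": econ.wtp,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Manifests and report writing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Provenance embedded in every written report."""

    package_version: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    timestamp: str | None = None


def _file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def make_manifest(
    config: ModelConfig | None = None,
    inputs: dict[str, str] | None = None,
    seed: int | None = None,
    timestamp: str | None = None,
) -> RunManifest:
    """Manifest for a run; ``timestamp`` is opt-in so that identical runs
    can produce byte-identical reports."""
    try:
        pkg_version = version("dfu-heor")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    return RunManifest(
        package_version=pkg_version,
        seed=seed,
        config=asdict(config) if config is not None else {},
        input_digests={k: _file_digest(v) for k, v in (inputs or {}).items()},
        timestamp=timestamp,
    )


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return "" if x is None else str(x)


def write_report(results: pd.DataFrame, path, manifest: RunManifest | None = None):
    """Deterministic CSV report with the manifest as a comment header.

    Numbers are formatted to six significant digits with fixed column
    order; an empty results frame yields a header-only file with a
    warning.  Identical inputs (including the manifest) give byte-identical
    output.
    """
    path = Path(path)
    lines = []
    if manifest is not None:
        lines.append("# manifest: " + json.dumps(asdict(manifest), sort_keys=True))
    lines.append(",".join(map(str, results.columns)))
    if results.empty:
        logger.warning("writing header-only report to %s: empty results", path)
    for _, row in results.iterrows():
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def trace_frame(trace: CohortTrace, econ: EconomicParameters) -> pd.DataFrame:
    """Cohort trace as a DataFrame with ages and both discount columns."""
    occ = trace.occupancy
    n_rows = occ.shape[0]
    step = trace.config.annual_step_discounting
    return pd.DataFrame(
        {
            "cycle": range(n_rows),
            "age_years": trace.ages,
            "post_dfu": occ[:, HealthState.POST_DFU],
            "nonsevere_dfu": occ[:, HealthState.NONSEVERE_DFU],
            "severe_dfu": occ[:, HealthState.SEVERE_DFU],
            "amputation": occ[:, HealthState.AMPUTATION],
            "post_amputation": occ[:, HealthState.POST_AMPUTATION],
            "death": occ[:, HealthState.DEATH],
            "discount_out": discount_factors(
                n_rows, econ.annual_discount_rate_outcomes, annual_step=step
            ),
            "discount_cost": discount_factors(
                n_rows, econ.annual_discount_rate_costs, annual_step=step
            ),
        }
    )


def write_trace_csv(trace: CohortTrace, econ: EconomicParameters, path,
                    manifest: RunManifest | None = None):
    return write_report(trace_frame(trace, econ), path, manifest)


def format_threshold_report(scenarios: pd.DataFrame) -> pd.DataFrame:
    """Scenario table with the relative reduction printed to one decimal
    percent alongside the raw relative risk."""
    out = scenarios.copy()
    out["relative_reduction_print"] = out["relative_reduction_pct"].map(
        lambda v: f"{v:.1f}%"
    )
    out["rr_print"] = out["threshold_rr"].map(lambda v: f"{v:.3f}")
    return out
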