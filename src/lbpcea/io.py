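"""Parameter-ledger configuration files and result serialization.

The ledger round-trips through a sectioned YAML document with an explicit
schema version; loading validates structure and value domains with errors
that name the offending key.  Result files are deterministic byte-for-byte
for fixed inputs: JSON with sorted keys and pre-rounded floats, CSVs with
fixed column order and float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .engine import STATE_LABELS, CohortTrace, StrategyTotals, discount_factors
from .outcomes import IncrementalResult
from .parameters import DTC, TAU, ModelParameters, round_cents
from .sensitivity import DSATable

__all__ = [
    "SCHEMA_VERSION",
    "params_to_dict",
    "params_from_dict",
    "save_parameters",
    "load_parameters",
    "default_config_path",
    "totals_record",
    "incremental_record",
    "write_results",
]

SCHEMA_VERSION = 1

_TRANSITION_KEYS = (
    "p_low_low", "p_low_high", "p_low_remission", "p_low_treat",
    "p_high_low", "p_high_high", "p_high_treat",
    "remission_share", "low_trajectory_share",
    "p_end_low", "p_end_high", "p_end_remission",
    "p_rem_stay", "p_rem_low", "p_rem_high",
)
_UNIT_COST_KEYS = (
    "app_cost", "gp_consultation", "specialist_consultation",
    "physio_session_price", "physio_sessions", "prescription_charge",
    "copay_rate", "pharmacotherapy", "diagnostics",
    "monthly_gross_wage", "working_days",
)
_RUN_KEYS = ("discount_rate", "horizon_years", "cycles_per_year",
             "cohort_size", "start_distribution")


class ConfigError(ValueError):
    """A configuration file failed schema or domain validation."""


def params_to_dict(params: ModelParameters) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "transitions": {
            **{k: getattr(params, k) for k in _TRANSITION_KEYS},
            "attrition": {s: list(params.attrition[s]) for s in (DTC, TAU)},
            "p_end_healthy": {s: params.p_end_healthy[s] for s in (DTC, TAU)},
        },
        "utilities": {s: dict(params.utilities[s]) for s in (DTC, TAU)},
        "unit_costs": {k: getattr(params, k) for k in _UNIT_COST_KEYS},
        "state_costs": {s: dict(params.state_costs[s]) for s in (DTC, TAU)},
        "absenteeism_days": dict(params.absenteeism_days),
        "run": {
            **{k: getattr(params, k) for k in _RUN_KEYS[:-1]},
            "start_distribution": list(params.start_distribution),
        },
    }


def _require(mapping: dict, keys: tuple[str, ...], section: str) -> None:
    for k in keys:
        if k not in mapping:
            raise ConfigError(f"missing key '{section}.{k}'")
    for k in mapping:
        if k not in keys:
            raise ConfigError(f"unknown key '{section}.{k}'")


def _check_prob(name: str, value: float) -> None:
    if not isinstance(value, (int, float)) or not 0.0 <= float(value) <= 1.0:
        raise ConfigError(f"'{name}' must be a probability in [0, 1], got {value!r}")


def params_from_dict(doc: dict[str, Any]) -> ModelParameters:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    top = ("schema_version", "transitions", "utilities", "unit_costs",
           "state_costs", "absenteeism_days", "run")
    _require(doc, top, "<root>")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {doc['schema_version']!r}")

    tr = dict(doc["transitions"])
    _require(tr, _TRANSITION_KEYS + ("attrition", "p_end_healthy"), "transitions")
    for k in _TRANSITION_KEYS:
        _check_prob(f"transitions.{k}", tr[k])
    attr = tr.pop("attrition")
    end_h = tr.pop("p_end_healthy")
    for s in (DTC, TAU):
        if s not in attr or len(attr[s]) != 2:
            raise ConfigError(f"transitions.attrition.{s} must list two monthly rates")
        for a in attr[s]:
            _check_prob(f"transitions.attrition.{s}", a)
        _check_prob(f"transitions.p_end_healthy.{s}", end_h[s])

    utils = doc["utilities"]
    for s in (DTC, TAU):
        _require(dict(utils[s]), STATE_LABELS, f"utilities.{s}")
        for state, u in utils[s].items():
            _check_prob(f"utilities.{s}.{state}", u)

    uc = dict(doc["unit_costs"])
    _require(uc, _UNIT_COST_KEYS, "unit_costs")
    for k, v in uc.items():
        if not isinstance(v, (int, float)) or v < 0:
            raise ConfigError(f"'unit_costs.{k}' must be a non-negative number")

    sc = doc["state_costs"]
    for s in (DTC, TAU):
        _require(dict(sc[s]), STATE_LABELS, f"state_costs.{s}")

    days = dict(doc["absenteeism_days"])
    _require(days, STATE_LABELS, "absenteeism_days")

    run = dict(doc["run"])
    _require(run, _RUN_KEYS, "run")
    _check_prob("run.discount_rate", run["discount_rate"])

    try:
        return ModelParameters(
            **{k: tr[k] for k in _TRANSITION_KEYS},
            attrition={s: tuple(attr[s]) for s in (DTC, TAU)},
            p_end_healthy={s: float(end_h[s]) for s in (DTC, TAU)},
            utilities={s: dict(utils[s]) for s in (DTC, TAU)},
            **uc,
            state_costs={s: dict(sc[s]) for s in (DTC, TAU)},
            absenteeism_days=days,
            discount_rate=run["discount_rate"],
            horizon_years=run["horizon_years"],
            cycles_per_year=run["cycles_per_year"],
            cohort_size=run["cohort_size"],
            start_distribution=tuple(run["start_distribution"]),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_parameters(params: ModelParameters, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(params_to_dict(params), sort_keys=True))
    return path


def load_parameters(path: str | Path) -> ModelParameters:
    doc = yaml.safe_load(Path(path).read_text())
    return params_from_dict(doc)


def default_config_path() -> Path:
    """The packaged base-case ledger configuration."""
    return Path(__file__).parent / "data" / "default_params.yaml"


# --- result serialization -------------------------------------------------

def totals_record(t: StrategyTotals) -> dict[str, Any]:
    return {
        "strategy": t.strategy,
        "discounted_cost": round_cents(t.discounted_cost),
        "discounted_qalys": round(t.discounted_qalys, 6),
        "undiscounted_cost": round_cents(t.undiscounted_cost),
        "undiscounted_qalys": round(t.undiscounted_qalys, 6),
        "indirect_cost": round_cents(t.indirect_cost),
        "direct_cost": round_cents(t.direct_cost),
        "healthy_count_at_horizon": t.healthy_count_at_horizon,
        "horizon_cycles": t.horizon_cycles,
        "per_state_cost": {s: round_cents(c) for s, c in zip(STATE_LABELS, t.per_state_cost)},
        "per_state_qalys": {s: round(q, 6) for s, q in zip(STATE_LABELS, t.per_state_qalys)},
    }


def incremental_record(r: IncrementalResult) -> dict[str, Any]:
    return {
        "scenario_id": r.scenario_id,
        "delta_cost": round_cents(r.delta_cost),
        "delta_qalys": round(r.delta_qalys, 6),
        "icer": None if r.icer_value is None else round(r.icer_value, 2),
        "dominance_label": r.dominance_label,
        "non_strict": r.non_strict,
    }


def trace_frame(trace: CohortTrace, annual_rate: float, cycles_per_year: int = 13,
                discount_step: str = "cycle") -> pd.DataFrame:
    """Long-format cohort trace: cycle, state, raw and corrected members."""
    df_factors = discount_factors(trace.n_cycles, annual_rate, cycles_per_year, discount_step)
    rows = []
    for t in range(trace.n_cycles):
        for s, label in enumerate(STATE_LABELS):
            rows.append({
                "cycle": t,
                "state": label,
                "raw_members": trace.raw[t, s],
                "corrected_members": trace.corrected[t, s],
                "discount_factor": df_factors[t],
            })
    return pd.DataFrame(rows)


def write_results(results: dict[str, Any], out_dir: str | Path) -> dict[str, Path]:
    """Write a result bundle; returns the paths written.

    ``results`` may contain: ``strategies`` (records), ``incrementals``
    (records), ``dsa`` (:class:`DSATable`), ``ce_plane`` (points frame),
    ``traces`` (mapping strategy -> trace frame), plus scalar metadata.
    Monetary values arrive pre-rounded; JSON key order is fixed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    for key in ("strategies", "incrementals", "metadata"):
        if key in results:
            doc[key] = results[key]
    if "dsa" in results:
        dsa: DSATable = results["dsa"]
        doc["dsa_base_icer"] = round(float(dsa.base_icer), 2)
        path = out / "tornado.csv"
        dsa.rows.to_csv(path, index=False, float_format="%.6f")
        written["tornado"] = path
    if "ce_plane" in results:
        path = out / "ce_plane.csv"
        results["ce_plane"].to_csv(path, index=False, float_format="%.6f")
        written["ce_plane"] = path
    if "traces" in results:
        for strategy, frame in results["traces"].items():
            path = out / f"trace_{strategy.lower()}.csv"
            frame.to_csv(path, index=False, float_format="%.6f")
            written[f"trace_{strategy.lower()}"] = path

    path = out / "results.json"
    path.write_text(json.dumps(doc, sort_keys=True, indent=2, allow_nan=True) + "\n")
    written["results"] = path
    return written
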