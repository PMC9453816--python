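"""Parameter data model and configuration I/O.

The model is fully specified by a single declarative parameter file (the
bundled ``data/basecase.yaml`` encodes the published base case verbatim).
Every uncertain quantity is a :class:`RangedValue` carrying its deterministic
sweep bounds and its probabilistic sampling family, so the sensitivity
machinery can enumerate the whole parameter space mechanically through
:func:`parameter_space` and perturb it through :func:`apply_override`
without touching the model code.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Iterator, Mapping, Sequence, Union

import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "LogLogisticParams",
    "HazardRatio",
    "RangedValue",
    "DosingRule",
    "HrDerivedEndpoint",
    "StrategySpec",
    "AnlotinibSpec",
    "ModelSettings",
    "ModelConfig",
    "load_model_config",
    "bundled_config_path",
    "n_cycles",
    "apply_override",
    "apply_scenario",
    "parameter_space",
    "config_to_dict",
    "dump_config_json",
]

DISTRIBUTIONS = ("beta", "gamma", "normal", "fixed")
DOSE_KINDS = ("flat", "per_kg", "per_m2", "per_cycle_pack")
PALLIATIVE_MODES = ("one_time", "per_cycle", "one_time_at_death")
END_STAGE_MODES = ("anlotinib_os", "fixed")
PD_CLOCK_MODES = ("state_entry", "model_time")


class SchemaError(ValueError):
    """A required key is missing or a file does not parse as the schema."""


class ValidationError(ValueError):
    """A parsed value violates a declared invariant."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValidationError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class LogLogisticParams:
    """Log-logistic survival parameters on the model's cycle time grid.

    ``S(t) = 1 / (1 + theta * t**kappa)`` with ``t`` in 3-week cycles;
    ``theta`` is rate-like (per cycle**kappa), ``kappa`` dimensionless.
    """

    theta: float
    kappa: float

    def __post_init__(self) -> None:
        _require_positive("theta", self.theta)
        _require_positive("kappa", self.kappa)


@dataclass(frozen=True)
class HazardRatio:
    """A hazard ratio with its 95% interval (all strictly positive)."""

    mean: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        for name in ("mean", "ci_low", "ci_high"):
            _require_positive(name, getattr(self, name))
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValidationError(
                f"hazard ratio must satisfy ci_low <= mean <= ci_high, got "
                f"{self.ci_low} <= {self.mean} <= {self.ci_high}"
            )


@dataclass(frozen=True)
class RangedValue:
    """A point estimate with sweep bounds and a sampling-distribution tag."""

    mean: float
    low: float
    high: float
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ValidationError(
                f"unknown distribution {self.distribution!r}; "
                f"expected one of {DISTRIBUTIONS}"
            )
        if not (self.low <= self.mean <= self.high):
            raise ValidationError(
                f"RangedValue requires low <= mean <= high, got "
                f"{self.low} <= {self.mean} <= {self.high}"
            )
        if self.distribution == "beta":
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValidationError(
                    f"beta-distributed value must lie in [0, 1], got "
                    f"[{self.low}, {self.high}]"
                )
        if self.distribution == "gamma" and self.low < 0:
            raise ValidationError(
                f"gamma-distributed value must be >= 0, got low={self.low}"
            )

    @staticmethod
    def fixed(value: float) -> "RangedValue":
        return RangedValue(value, value, value, "fixed")


@dataclass(frozen=True)
class DosingRule:
    """Drug acquisition rule with vial-wastage rounding.

    The administered dose (``flat`` mg, ``per_kg`` mg/kg, ``per_m2`` mg/m2,
    or a fixed ``per_cycle_pack``) is rounded up to an integral number of
    pricing units of ``unit_size`` mg, except for ``per_cycle_pack`` which is
    billed as exactly one unit per administration.
    """

    unit_price: RangedValue
    unit_size: float
    dose_kind: str
    dose_value: float
    administrations_per_cycle: float

    def __post_init__(self) -> None:
        if self.dose_kind not in DOSE_KINDS:
            raise ValidationError(
                f"dose_kind must be one of {DOSE_KINDS}, got {self.dose_kind!r}"
            )
        _require_positive("unit_price.mean", self.unit_price.mean)
        _require_positive("unit_size", self.unit_size)
        _require_positive("dose_value", self.dose_value)
        _require_positive(
            "administrations_per_cycle", self.administrations_per_cycle
        )


@dataclass(frozen=True)
class HrDerivedEndpoint:
    """A survival endpoint defined as hazard-ratio shift of a reference arm."""

    reference: str
    endpoint: str  # "os" | "pfs"
    hr: HazardRatio

    def __post_init__(self) -> None:
        if self.endpoint not in ("os", "pfs"):
            raise ValidationError(
                f"endpoint must be 'os' or 'pfs', got {self.endpoint!r}"
            )


Endpoint = Union[LogLogisticParams, HrDerivedEndpoint]


@dataclass(frozen=True)
class StrategySpec:
    """Everything that defines one comparator arm."""

    name: str
    os: Endpoint
    pfs: Endpoint
    discontinuation_prob_per_cycle: RangedValue
    dosing: DosingRule
    ae_cost: RangedValue
    ae_disutility: RangedValue
    subsequent_therapy_proportion: RangedValue

    def __post_init__(self) -> None:
        for fname in ("discontinuation_prob_per_cycle", "subsequent_therapy_proportion"):
            rv = getattr(self, fname)
            if not (0.0 <= rv.mean <= 1.0):
                raise ValidationError(
                    f"{self.name}.{fname}.mean must lie in [0, 1], got {rv.mean}"
                )


@dataclass(frozen=True)
class AnlotinibSpec:
    """Third-/further-line therapy driving post-progression transitions."""

    os: LogLogisticParams
    pfs: LogLogisticParams
    dosing: DosingRule


@dataclass(frozen=True)
class ModelSettings:
    cycle_length_days: float
    horizon_years: float
    discount_rate_annual: RangedValue
    wtp_per_qaly: float
    body_weight_kg: RangedValue
    body_surface_m2: RangedValue
    utilities: Mapping[str, RangedValue]
    care_costs: Mapping[str, RangedValue]
    anlotinib: AnlotinibSpec
    half_cycle_correction: bool = False
    end_stage_mortality_mode: str = "anlotinib_os"
    end_stage_fixed_prob: float | None = None
    palliative_cost_mode: str = "one_time"
    pd_clock_mode: str = "state_entry"

    def __post_init__(self) -> None:
        _require_positive("cycle_length_days", self.cycle_length_days)
        _require_positive("horizon_years", self.horizon_years)
        r = self.discount_rate_annual
        if not (0.0 <= r.mean <= 0.08):
            raise ValidationError(
                f"discount_rate_annual.mean must lie in [0, 0.08], got {r.mean}"
            )
        for key in ("pfs", "pd", "end_stage"):
            if key not in self.utilities:
                raise SchemaError(f"missing required key utilities.{key}")
            u = self.utilities[key]
            if not (0.0 <= u.mean <= 1.0):
                raise ValidationError(
                    f"utilities.{key}.mean must lie in [0, 1], got {u.mean}"
                )
        for key in ("followup", "bsc", "palliative"):
            if key not in self.care_costs:
                raise SchemaError(f"missing required key care_costs.{key}")
        if self.end_stage_mortality_mode not in END_STAGE_MODES:
            raise ValidationError(
                f"end_stage_mortality_mode must be one of {END_STAGE_MODES}"
            )
        if self.end_stage_mortality_mode == "fixed":
            p = self.end_stage_fixed_prob
            if p is None or not (0.0 < p <= 1.0):
                raise ValidationError(
                    "end_stage_fixed_prob must lie in (0, 1] when "
                    "end_stage_mortality_mode='fixed' (end-stage must be transient)"
                )
        if self.palliative_cost_mode not in PALLIATIVE_MODES:
            raise ValidationError(
                f"palliative_cost_mode must be one of {PALLIATIVE_MODES}"
            )
        if self.pd_clock_mode not in PD_CLOCK_MODES:
            raise ValidationError(f"pd_clock_mode must be one of {PD_CLOCK_MODES}")


@dataclass(frozen=True)
class ModelConfig:
    """Settings plus comparator arms; unpacks as ``settings, strategies``."""

    settings: ModelSettings
    strategies: tuple[StrategySpec, ...]
    scenarios: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Any]:
        return iter((self.settings, self.strategies))

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(
            f"unknown strategy {name!r}; have {[s.name for s in self.strategies]}"
        )


# ---------------------------------------------------------------------------
# parsing


def _get(mapping: Mapping[str, Any], key: str, ctx: str) -> Any:
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"{ctx} must be a mapping, got {type(mapping).__name__}")
    if key not in mapping:
        raise SchemaError(f"missing required key {ctx}.{key}" if ctx else
                          f"missing required key {key}")
    return mapping[key]


def _parse_ranged(node: Any, ctx: str) -> RangedValue:
    if isinstance(node, (int, float)):
        return RangedValue.fixed(float(node))
    try:
        return RangedValue(
            mean=float(_get(node, "mean", ctx)),
            low=float(_get(node, "low", ctx)),
            high=float(_get(node, "high", ctx)),
            distribution=str(node.get("distribution", "fixed")),
        )
    except ValidationError as exc:
        raise ValidationError(f"{ctx}: {exc}") from exc


def _parse_loglogistic(node: Any, ctx: str) -> LogLogisticParams:
    return LogLogisticParams(
        theta=float(_get(node, "theta", ctx)), kappa=float(_get(node, "kappa", ctx))
    )


def _parse_hr(node: Any, ctx: str) -> HazardRatio:
    return HazardRatio(
        mean=float(_get(node, "mean", ctx)),
        ci_low=float(_get(node, "ci_low", ctx)),
        ci_high=float(_get(node, "ci_high", ctx)),
    )


def _parse_endpoint(node: Any, ctx: str) -> Endpoint:
    if isinstance(node, Mapping) and "reference" in node:
        return HrDerivedEndpoint(
            reference=str(_get(node, "reference", ctx)),
            endpoint=str(_get(node, "endpoint", ctx)),
            hr=_parse_hr(_get(node, "hr", ctx), f"{ctx}.hr"),
        )
    return _parse_loglogistic(node, ctx)


def _parse_dosing(node: Any, ctx: str) -> DosingRule:
    return DosingRule(
        unit_price=_parse_ranged(_get(node, "unit_price", ctx), f"{ctx}.unit_price"),
        unit_size=float(_get(node, "unit_size", ctx)),
        dose_kind=str(_get(node, "dose_kind", ctx)),
        dose_value=float(_get(node, "dose_value", ctx)),
        administrations_per_cycle=float(
            _get(node, "administrations_per_cycle", ctx)
        ),
    )


def _parse_strategy(node: Any) -> StrategySpec:
    name = str(_get(node, "name", "strategies[]"))
    ctx = f"strategies.{name}"
    return StrategySpec(
        name=name,
        os=_parse_endpoint(_get(node, "os", ctx), f"{ctx}.os"),
        pfs=_parse_endpoint(_get(node, "pfs", ctx), f"{ctx}.pfs"),
        discontinuation_prob_per_cycle=_parse_ranged(
            _get(node, "discontinuation_prob_per_cycle", ctx),
            f"{ctx}.discontinuation_prob_per_cycle",
        ),
        dosing=_parse_dosing(_get(node, "dosing", ctx), f"{ctx}.dosing"),
        ae_cost=_parse_ranged(_get(node, "ae_cost", ctx), f"{ctx}.ae_cost"),
        ae_disutility=_parse_ranged(
            _get(node, "ae_disutility", ctx), f"{ctx}.ae_disutility"
        ),
        subsequent_therapy_proportion=_parse_ranged(
            _get(node, "subsequent_therapy_proportion", ctx),
            f"{ctx}.subsequent_therapy_proportion",
        ),
    )


def _parse_settings(node: Any) -> ModelSettings:
    ctx = "settings"
    anl = _get(node, "anlotinib", ctx)
    return ModelSettings(
        cycle_length_days=float(_get(node, "cycle_length_days", ctx)),
        horizon_years=float(_get(node, "horizon_years", ctx)),
        discount_rate_annual=_parse_ranged(
            _get(node, "discount_rate_annual", ctx), f"{ctx}.discount_rate_annual"
        ),
        wtp_per_qaly=float(_get(node, "wtp_per_qaly", ctx)),
        body_weight_kg=_parse_ranged(
            _get(node, "body_weight_kg", ctx), f"{ctx}.body_weight_kg"
        ),
        body_surface_m2=_parse_ranged(
            _get(node, "body_surface_m2", ctx), f"{ctx}.body_surface_m2"
        ),
        utilities={
            k: _parse_ranged(v, f"{ctx}.utilities.{k}")
            for k, v in _get(node, "utilities", ctx).items()
        },
        care_costs={
            k: _parse_ranged(v, f"{ctx}.care_costs.{k}")
            for k, v in _get(node, "care_costs", ctx).items()
        },
        anlotinib=AnlotinibSpec(
            os=_parse_loglogistic(_get(anl, "os", f"{ctx}.anlotinib"), f"{ctx}.anlotinib.os"),
            pfs=_parse_loglogistic(_get(anl, "pfs", f"{ctx}.anlotinib"), f"{ctx}.anlotinib.pfs"),
            dosing=_parse_dosing(_get(anl, "dosing", f"{ctx}.anlotinib"), f"{ctx}.anlotinib.dosing"),
        ),
        half_cycle_correction=bool(node.get("half_cycle_correction", False)),
        end_stage_mortality_mode=str(
            node.get("end_stage_mortality_mode", "anlotinib_os")
        ),
        end_stage_fixed_prob=(
            None
            if node.get("end_stage_fixed_prob") is None
            else float(node["end_stage_fixed_prob"])
        ),
        palliative_cost_mode=str(node.get("palliative_cost_mode", "one_time")),
        pd_clock_mode=str(node.get("pd_clock_mode", "state_entry")),
    )


def config_from_dict(raw: Mapping[str, Any]) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a plain nested dict."""
    settings = _parse_settings(_get(raw, "settings", ""))
    strat_nodes = _get(raw, "strategies", "")
    if not isinstance(strat_nodes, Sequence) or not strat_nodes:
        raise SchemaError("strategies must be a non-empty list")
    strategies = tuple(_parse_strategy(n) for n in strat_nodes)
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate strategy names in {names}")
    scenarios = {
        str(k): dict(v) for k, v in (raw.get("scenarios") or {}).items()
    }
    return ModelConfig(settings=settings, strategies=strategies, scenarios=scenarios)


def bundled_config_path() -> str:
    """Filesystem path of the bundled base-case parameter file."""
    return str(resources.files("nsclc_cea").joinpath("data/basecase.yaml"))


def load_model_config(path: str | None = None) -> ModelConfig:
    """Read and validate a model-config file (the bundled base case if None)."""
    if path is None:
        path = bundled_config_path()
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path} does not contain a mapping at top level")
    return config_from_dict(raw)


def n_cycles(settings: ModelSettings) -> int:
    """Number of whole model cycles in the horizon (365.25-day years)."""
    return int(math.floor(settings.horizon_years * 365.25 / settings.cycle_length_days))


# ---------------------------------------------------------------------------
# serialization


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    """Normalized plain-dict form of a config (parses back via round-trip)."""
    return _to_plain(config)


def dump_config_json(config: ModelConfig, indent: int = 2) -> str:
    return json.dumps(config_to_dict(config), indent=indent, sort_keys=True)


# ---------------------------------------------------------------------------
# parameter registry, overrides, scenarios


@dataclass(frozen=True)
class ParamRef:
    """A named handle on one uncertain parameter inside a config."""

    name: str
    path: tuple[Any, ...]  # attribute / key tokens from the config root
    kind: str  # "ranged" | "hazard_ratio"

    def get(self, config: ModelConfig) -> RangedValue | HazardRatio:
        obj: Any = config
        for tok in self.path:
            if isinstance(obj, tuple):  # strategies tuple, token = index
                obj = obj[tok]
            elif isinstance(obj, Mapping):
                obj = obj[tok]
            else:
                obj = getattr(obj, tok)
        return obj


def _set_path(obj: Any, path: tuple[Any, ...], value: Any) -> Any:
    if not path:
        return value
    tok, rest = path[0], path[1:]
    if isinstance(obj, tuple):
        items = list(obj)
        items[tok] = _set_path(items[tok], rest, value)
        return tuple(items)
    if isinstance(obj, Mapping):
        out = dict(obj)
        out[tok] = _set_path(out[tok], rest, value)
        return out
    return replace(obj, **{tok: _set_path(getattr(obj, tok), rest, value)})


def parameter_space(config: ModelConfig) -> dict[str, ParamRef]:
    """All named uncertain parameters of a config, in a stable order.

    Sweepable/sampleable parameters are the RangedValue leaves plus the
    hazard ratios of HR-derived endpoints. Survival shape parameters
    (theta/kappa) are point inputs and deliberately absent.
    """
    refs: list[ParamRef] = []

    def add(name: str, *path: Any, kind: str = "ranged") -> None:
        refs.append(ParamRef(name=name, path=tuple(path), kind=kind))

    add("discount_rate", "settings", "discount_rate_annual")
    add("body_weight", "settings", "body_weight_kg")
    add("body_surface_area", "settings", "body_surface_m2")
    for key in config.settings.utilities:
        add(f"utility.{key}", "settings", "utilities", key)
    for key in config.settings.care_costs:
        add(f"cost.{key}", "settings", "care_costs", key)
    add("cost.anlotinib_unit_price", "settings", "anlotinib", "dosing", "unit_price")
    for i, strat in enumerate(config.strategies):
        s = strat.name
        add(f"{s}.discontinuation_prob", "strategies", i,
            "discontinuation_prob_per_cycle")
        add(f"{s}.unit_price", "strategies", i, "dosing", "unit_price")
        add(f"{s}.ae_cost", "strategies", i, "ae_cost")
        add(f"{s}.ae_disutility", "strategies", i, "ae_disutility")
        add(f"{s}.subsequent_therapy_proportion", "strategies", i,
            "subsequent_therapy_proportion")
        for ep in ("os", "pfs"):
            if isinstance(getattr(strat, ep), HrDerivedEndpoint):
                add(f"{s}.hr_{ep}", "strategies", i, ep, "hr", kind="hazard_ratio")
    return {r.name: r for r in refs}


def apply_override(
    config: ModelConfig, name: str, value: float | Mapping[str, float]
) -> ModelConfig:
    """Return a new config differing only in the named parameter.

    A scalar ``value`` replaces the parameter's point estimate (mean),
    widening the stored bounds if needed so invariants keep holding; a
    mapping replaces the whole RangedValue / HazardRatio field-by-field.
    """
    space = parameter_space(config)
    if name not in space:
        raise KeyError(
            f"unknown parameter {name!r}; valid names: {sorted(space)}"
        )
    ref = space[name]
    current = ref.get(config)
    if isinstance(value, Mapping):
        if ref.kind == "hazard_ratio":
            new: Any = HazardRatio(**{**_to_plain(current), **value})
        else:
            new = RangedValue(**{**_to_plain(current), **value})
    else:
        v = float(value)
        if ref.kind == "hazard_ratio":
            assert isinstance(current, HazardRatio)
            new = HazardRatio(
                mean=v, ci_low=min(current.ci_low, v), ci_high=max(current.ci_high, v)
            )
        else:
            assert isinstance(current, RangedValue)
            new = RangedValue(
                mean=v,
                low=min(current.low, v),
                high=max(current.high, v),
                distribution=current.distribution,
            )
    return _set_path(config, ref.path, new)


def apply_scenario(config: ModelConfig, scenario: str) -> ModelConfig:
    """Apply one of the config's named override sets (e.g. a sex subgroup)."""
    if scenario not in config.scenarios:
        raise KeyError(
            f"unknown scenario {scenario!r}; valid names: {sorted(config.scenarios)}"
        )
    out = config
    for pname, value in config.scenarios[scenario].items():
        out = apply_override(out, pname, value)
    return out
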