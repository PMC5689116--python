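"""Pattern configuration: every detector threshold, with defaults.

The default values reproduce the published default pattern definitions
verbatim (e.g. hypoglycemia "< 70 mg/dL", SD "> 70 mg/dL", hypoglycemic
trend "> 1 event/day on 3 consecutive days").  Every comparison carries an
explicit strictness flag: thresholds printed as ">" or "<" never trigger
at equality.

Configs serialize to/from JSON (unknown keys rejected), support dotted-key
overrides (``variability.sd.value``), and ship with named presets:

* ``default`` — the consensus defaults.
* ``trend_relaxed`` — the revised trend definitions discussed as more
  clinically relevant: hypoglycemic trend ">=1"/3 days, hyperglycemic
  trend ">=2"/4 days.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

__all__ = [
    "Comparison",
    "VariabilityConfig",
    "TrendConfig",
    "OvercorrectionConfig",
    "TimeBlockPatternConfig",
    "CartridgeConfig",
    "MissedBolusConfig",
    "UsageConfig",
    "AdherenceConfig",
    "PatternConfig",
    "ConfigError",
    "PRESETS",
    "default_config",
    "preset_config",
    "load_config",
]


class ConfigError(ValueError):
    """Configuration file or override violates the schema."""


_OPS = {
    "gt": lambda x, v: x > v,
    "ge": lambda x, v: x >= v,
    "lt": lambda x, v: x < v,
    "le": lambda x, v: x <= v,
}
_OP_SYMBOL = {"gt": ">", "ge": ">=", "lt": "<", "le": "<="}


@dataclass(frozen=True)
class Comparison:
    """A threshold with an explicit comparator (gt / ge / lt / le)."""

    value: float
    op: str = "gt"

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigError(f"unknown comparator {self.op!r}")

    def check(self, x: float) -> bool:
        return _OPS[self.op](x, self.value)

    def __str__(self) -> str:
        return f"{_OP_SYMBOL[self.op]}{self.value:g}"


def C(value: float, op: str) -> Comparison:  # terse constructor for defaults
    return Comparison(value, op)


@dataclass(frozen=True)
class VariabilityConfig:
    sd: Comparison = C(70.0, "gt")            # mg/dL
    cv: Comparison = C(36.0, "gt")            # %, optional pattern
    cv_enabled: bool = False
    lbgi_edges: tuple[float, ...] = (1.1, 2.5, 5.0)
    hbgi_edges: tuple[float, ...] = (4.5, 9.0)


@dataclass(frozen=True)
class TrendConfig:
    per_day: Comparison = C(1.0, "gt")        # events per day
    run_days: int = 3                          # consecutive days


@dataclass(frozen=True)
class OvercorrectionConfig:
    fraction: Comparison = C(0.25, "gt")      # share of primary events
    lookback_min: float = 180.0                # "within <3 h" (strict)
    primary_threshold: Optional[Comparison] = None  # hyper side: >200 mg/dL


@dataclass(frozen=True)
class TimeBlockPatternConfig:
    window_days: int = 7
    count: Comparison = C(3.0, "gt")          # events/readings per block
    pre_threshold: Comparison = C(150.0, "gt")   # preprandial hyper, mg/dL
    post_threshold: Comparison = C(180.0, "gt")  # postprandial hyper, mg/dL


@dataclass(frozen=True)
class CartridgeConfig:
    expected_interval_days: float = 7.0
    assoc_window_h: float = 6.0                # hypo-after-change window
    hypo_fraction: Comparison = C(0.80, "gt")  # share of changes with hypo
    delay_days: Comparison = C(1.0, "gt")      # delay qualifying a cycle
    delay_hyper_fraction: Comparison = C(0.50, "gt")  # readings hyper in delay
    delayed_fraction: Comparison = C(0.30, "gt")      # share of delayed cycles


@dataclass(frozen=True)
class MissedBolusConfig:
    window_days: int = 28
    count: Comparison = C(3.0, "gt")
    carb_grams: Comparison = C(20.0, "gt")
    bolus_lookback_min: float = 120.0
    rescue_window_min: float = 60.0  # carbs this soon after a hypo are rescue


@dataclass(frozen=True)
class UsageConfig:
    marks_per_day: Comparison = C(3.0, "lt")
    marks_day_share: Comparison = C(0.50, "gt")
    records_per_day: Comparison = C(3.0, "lt")
    records_day_share: Comparison = C(0.50, "gt")
    stops_per_day: Comparison = C(2.0, "gt")
    stops_day_share: Comparison = C(0.50, "gt")


@dataclass(frozen=True)
class AdherenceConfig:
    bg_per_day: Comparison = C(4.0, "lt")
    bg_day_share: Comparison = C(0.80, "ge")
    before_bolus_fraction: Comparison = C(0.25, "gt")
    before_bolus_lookback_min: float = 30.0
    calculator_fraction: Comparison = C(0.25, "gt")  # share without calculator
    bolus_patterns_csii_only: bool = True


@dataclass(frozen=True)
class PatternConfig:
    """Complete dashboard configuration (all thresholds addressable)."""

    hypo_threshold: Comparison = C(70.0, "lt")    # mg/dL, strict
    hyper_threshold: Comparison = C(160.0, "gt")  # mg/dL, strict
    merge_gap_min: float = 60.0  # readings closer than this form one event
    variability: VariabilityConfig = field(default_factory=VariabilityConfig)
    hypo_trend: TrendConfig = field(default_factory=TrendConfig)
    hyper_trend: TrendConfig = field(
        default_factory=lambda: TrendConfig(per_day=C(2.0, "gt"), run_days=7))
    hypo_overcorrection: OvercorrectionConfig = field(
        default_factory=OvercorrectionConfig)
    hyper_overcorrection: OvercorrectionConfig = field(
        default_factory=lambda: OvercorrectionConfig(
            primary_threshold=C(200.0, "gt")))
    time_block: TimeBlockPatternConfig = field(
        default_factory=TimeBlockPatternConfig)
    cartridge: CartridgeConfig = field(default_factory=CartridgeConfig)
    missed_bolus: MissedBolusConfig = field(default_factory=MissedBolusConfig)
    usage: UsageConfig = field(default_factory=UsageConfig)
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _to_plain(self)

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "PatternConfig":
        return _from_plain(cls, data, path="")

    def with_overrides(self, overrides: dict[str, Any]) -> "PatternConfig":
        """Apply dotted-key overrides, e.g. ``{"variability.sd.value": 75}``."""
        plain = self.to_dict()
        for dotted, value in overrides.items():
            node = plain
            *parents, leaf = dotted.split(".")
            for key in parents:
                if not isinstance(node, dict) or key not in node:
                    raise ConfigError(f"unknown config key {dotted!r}")
                node = node[key]
            if not isinstance(node, dict) or leaf not in node:
                raise ConfigError(f"unknown config key {dotted!r}")
            node[leaf] = value
        return PatternConfig.from_dict(plain)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    return obj


def _from_plain(cls, data: Any, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"expected an object at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = path or "top level"
        raise ConfigError(f"unknown key(s) at {where}: {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        sub = f"{path}.{name}" if path else name
        kwargs[name] = _coerce(f.type, value, sub)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path or 'top level'}: {exc}") from exc


_NESTED = {
    "Comparison": Comparison,
    "VariabilityConfig": VariabilityConfig,
    "TrendConfig": TrendConfig,
    "OvercorrectionConfig": OvercorrectionConfig,
    "TimeBlockPatternConfig": TimeBlockPatternConfig,
    "CartridgeConfig": CartridgeConfig,
    "MissedBolusConfig": MissedBolusConfig,
    "UsageConfig": UsageConfig,
    "AdherenceConfig": AdherenceConfig,
}


def _coerce(annotation: Any, value: Any, path: str):
    name = annotation if isinstance(annotation, str) else getattr(annotation, "__name__", "")
    if name.startswith("Optional[") and name.endswith("]"):
        if value is None:
            return None
        name = name[len("Optional["):-1]
    for marker, cls in _NESTED.items():
        if marker in name:
            if value is None:
                return None
            return _from_plain(cls, value, path)
    if "tuple" in name and isinstance(value, list):
        return tuple(value)
    return value


# ---------------------------------------------------------------------------
# Presets and loading

def default_config() -> PatternConfig:
    return PatternConfig()


def _trend_relaxed() -> PatternConfig:
    return dataclasses.replace(
        default_config(),
        hypo_trend=TrendConfig(per_day=C(1.0, "ge"), run_days=3),
        hyper_trend=TrendConfig(per_day=C(2.0, "ge"), run_days=4),
    )


PRESETS = {
    "default": default_config,
    "trend_relaxed": _trend_relaxed,
}


def preset_config(name: str) -> PatternConfig:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def load_config(
    path: Optional[Union[str, Path]] = None,
    preset: str = "default",
    overrides: Optional[dict[str, Any]] = None,
) -> PatternConfig:
    """Load a config: preset defaults, then file contents, then overrides.

    The file holds a partial JSON object; only the keys it names change.
    Unknown keys anywhere raise :class:`ConfigError` naming the key.
    """
    config = preset_config(preset)
    if path is not None:
        try:
            data = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        merged = _deep_merge(config.to_dict(), data, path="")
        config = PatternConfig.from_dict(merged)
    if overrides:
        config = config.with_overrides(overrides)
    return config


def _deep_merge(base: dict, incoming: Any, path: str) -> dict:
    if not isinstance(incoming, dict):
        raise ConfigError(f"expected an object at {path or 'top level'}")
    out = dict(base)
    for key, value in incoming.items():
        sub = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown key at {sub}")
        if isinstance(base[key], dict):
            out[key] = _deep_merge(base[key], value, sub)
        else:
            out[key] = value
    return out
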