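"""Model inputs for the post-metastasectomy surveillance cost-utility model.

Every quantity the model consumes lives in a :class:`ModelConfig`: unit costs
(2021 Canadian dollars, public-payer perspective), health-state utilities,
per-modality test operating characteristics, clinical probabilities, the
summary statistics of the source cohort (257 stage IV colorectal cancer
patients followed after curative-intent metastasectomy), and analysis
settings.  Configs are immutable; derived configs (probabilistic-sensitivity
draws, scenario analyses) are built with :func:`set_param`.

Configs round-trip through YAML (JSON is a YAML subset and is accepted).
An override file only needs the fields it changes; everything else is filled
from the packaged base case.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, fields, is_dataclass, replace
from typing import Any, Mapping

import yaml

SCHEMA_VERSION = 1

#: Accepted chemotherapy charging conventions.  "once_per_episode" charges the
#: chemotherapy figure a single time on entry into a treated phase (the
#: reading consistent with the published 10-year totals of CAD 7,707-19,890);
#: "monthly" charges it every cycle spent in the phase.
CHEMO_CHARGING_MODES = ("once_per_episode", "monthly")


class ConfigError(ValueError):
    """Raised for schema problems (unknown/missing fields, bad types)."""


class ValidationError(ConfigError):
    """Raised when a field value is outside its admissible range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class Uncertain:
    """A point value with an optional uncertainty range (lo, hi)."""

    value: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.lo is not None and self.hi is not None:
            _check(self.lo <= self.hi, f"Uncertain: lo {self.lo} > hi {self.hi}")
        if self.lo is not None:
            _check(self.lo <= self.value, f"Uncertain: value {self.value} below lo {self.lo}")
        if self.hi is not None:
            _check(self.value <= self.hi, f"Uncertain: value {self.value} above hi {self.hi}")


def _check_prob(name: str, u: Uncertain | float) -> None:
    vals = [u.value, u.lo, u.hi] if isinstance(u, Uncertain) else [u]
    for v in vals:
        if v is not None:
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in 2021 CAD.

    ``palliative_chemo_month`` / ``curative_chemo_month`` hold the cost of one
    month of systemic therapy; whether that figure is charged per cycle or
    once per treatment episode is governed by
    ``AnalysisSettings.chemo_charging``.  No published cost exists for the
    six-month perioperative (curative-intent) regimen, so the palliative
    figure is used as its proxy by default; both are user-overridable.
    """

    cea_test: float = 60.62
    clinic_visit: float = 25.94
    colonoscopy: float = 1059.35
    ct_scan: float = 300.15
    hepatic_metastasectomy: float = 4086.72
    post_anesthesia_recovery: float = 84.58
    palliative_chemo_month: float = 6409.77
    curative_chemo_month: float = 6409.77

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _check(v >= 0, f"costs.{f.name} must be >= 0, got {v}")


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities (0 = dead, 1 = perfect health).

    Four published utilities cover six states: undetected recurrence and
    curative-intent treatment both carry the generic "recurrence" utility;
    the asymptomatic/symptomatic utilities belong to the detected palliative
    states.
    """

    ned: float = 0.78
    undetected_recurrence: float = 0.74
    curative_treatment: float = 0.74
    palliative_asymptomatic: float = 0.68
    palliative_symptomatic: float = 0.50

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_prob(f"utilities.{f.name}", getattr(self, f.name))


@dataclass(frozen=True)
class TestModality:
    """Operating characteristics of one surveillance test."""

    sensitivity: Uncertain
    specificity: Uncertain

    def __post_init__(self) -> None:
        _check_prob("sensitivity", self.sensitivity)
        _check_prob("specificity", self.specificity)


def _default_tests() -> dict[str, TestModality]:
    return {
        "clinic_visit": TestModality(Uncertain(0.42, 0.27, 0.57), Uncertain(0.95, 0.70, 1.00)),
        "cea_test": TestModality(Uncertain(0.64, 0.49, 0.79), Uncertain(0.90, 0.75, 1.00)),
        "ct": TestModality(Uncertain(0.83, 0.68, 0.98), Uncertain(0.93, 0.78, 1.00)),
        "colonoscopy": TestModality(Uncertain(0.95, 0.80, 1.00), Uncertain(1.00, 0.85, 1.00)),
    }


@dataclass(frozen=True)
class TestPerformance:
    """Sensitivity/specificity of the surveillance panel, per modality."""

    clinic_visit: TestModality = field(default_factory=lambda: _default_tests()["clinic_visit"])
    cea_test: TestModality = field(default_factory=lambda: _default_tests()["cea_test"])
    ct: TestModality = field(default_factory=lambda: _default_tests()["ct"])
    colonoscopy: TestModality = field(default_factory=lambda: _default_tests()["colonoscopy"])

    @property
    def panel(self) -> tuple[TestModality, TestModality, TestModality]:
        """The three tests performed at every scheduled visit."""
        return (self.clinic_visit, self.cea_test, self.ct)


@dataclass(frozen=True)
class ClinicalInputs:
    """Clinical probabilities and durations."""

    metastasectomy_mortality: Uncertain = field(
        default_factory=lambda: Uncertain(0.010, 0.003, 0.015))
    mean_months_undetected_to_symptomatic: Uncertain = field(
        default_factory=lambda: Uncertain(4.0, 1.0, 28.0))
    asymptomatic_metastasectomy_rate: float = 0.23
    symptomatic_metastasectomy_rate: float = 0.05
    curative_treatment_duration: int = 6  # cycles of perioperative chemotherapy

    def __post_init__(self) -> None:
        _check_prob("clinical.metastasectomy_mortality", self.metastasectomy_mortality)
        _check_prob("clinical.asymptomatic_metastasectomy_rate",
                    self.asymptomatic_metastasectomy_rate)
        _check_prob("clinical.symptomatic_metastasectomy_rate",
                    self.symptomatic_metastasectomy_rate)
        m = self.mean_months_undetected_to_symptomatic
        _check(m.value >= 1, f"mean_months_undetected_to_symptomatic must be >= 1, got {m.value}")
        _check(self.curative_treatment_duration >= 1,
               "curative_treatment_duration must be >= 1")


@dataclass(frozen=True)
class CohortSummary:
    """Printed outcome summaries of the source cohort (n = 257).

    ``recurrence_fraction`` is the cumulative recurrence by the median
    follow-up time.  Survival of the recurred stratum is measured from
    recurrence; survival of the non-recurred stratum from cohort entry.
    """

    recurrence_fraction: float = 0.751
    median_followup_months: float = 76.4
    os5_recurred: float = 0.254
    os10_recurred: float = 0.031
    os10_nonrecurred: float = 0.815

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "median_followup_months":
                _check_prob(f"cohort.{f.name}", getattr(self, f.name))
        _check(self.median_followup_months > 0, "median_followup_months must be > 0")
        _check(self.os10_recurred <= self.os5_recurred,
               "cohort.os10_recurred must not exceed os5_recurred")


@dataclass(frozen=True)
class AnalysisSettings:
    """Run-level settings: horizon, discounting, sample sizes, seeds."""

    cycle_length_months: float = 1.0
    horizon_cycles: int = 120
    n_patients: int = 10_000
    n_psa_draws: int = 10_000
    n_patients_per_psa_draw: int = 1_000
    annual_discount_rate: float = 0.015
    wtp_grid: tuple[float, ...] = (
        0.0, 25_000.0, 50_000.0, 75_000.0, 100_000.0, 150_000.0, 200_000.0,
        300_000.0, 400_000.0, 425_000.0, 500_000.0, 750_000.0, 1_000_000.0)
    rng_seed: int = 17
    false_positive_workup: bool = True
    chemo_charging: str = "once_per_episode"

    def __post_init__(self) -> None:
        _check(self.annual_discount_rate >= 0, "annual_discount_rate must be >= 0")
        _check(self.horizon_cycles >= 1, "horizon_cycles must be >= 1")
        _check(self.cycle_length_months > 0, "cycle_length_months must be > 0")
        _check(self.n_patients >= 1, "n_patients must be >= 1")
        _check(50_000.0 in self.wtp_grid, "wtp_grid must include 50,000 CAD/QALY")
        _check(self.chemo_charging in CHEMO_CHARGING_MODES,
               f"chemo_charging must be one of {CHEMO_CHARGING_MODES}")


@dataclass(frozen=True)
class PsaDistribution:
    """Distribution assigned to one parameter in the probabilistic SA.

    family is one of gamma | beta | fixed; mean/sd are the matched moments
    (ranges in the source table are read as 95 % intervals, sd = width/3.92).
    A gamma/beta entry with sd = 0 is a point mass and passes through.
    """

    family: str
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        _check(self.family in ("gamma", "beta", "fixed"),
               f"PSA family must be gamma|beta|fixed, got {self.family!r}")


def _r95(lo: float, hi: float) -> float:
    """Standard deviation implied by reading (lo, hi) as a 95% interval."""
    return (hi - lo) / 3.92


def default_psa_distributions() -> dict[str, PsaDistribution]:
    g, b, fx = "gamma", "beta", "fixed"
    return {
        "costs.cea_test": PsaDistribution(fx),
        "costs.clinic_visit": PsaDistribution(g, 25.94, _r95(10.37, 41.60)),
        "costs.colonoscopy": PsaDistribution(g, 1059.35, _r95(618.06, 14_833.48)),
        "costs.ct_scan": PsaDistribution(g, 300.15, 0.0),
        "costs.hepatic_metastasectomy": PsaDistribution(g, 4086.72, 741.75),
        "costs.post_anesthesia_recovery": PsaDistribution(g, 84.58, 31.43),
        "costs.palliative_chemo_month": PsaDistribution(g, 6409.77, 0.0),
        "costs.curative_chemo_month": PsaDistribution(fx),
        "utilities.ned": PsaDistribution(fx),
        "utilities.undetected_recurrence": PsaDistribution(fx),
        "utilities.curative_treatment": PsaDistribution(fx),
        "utilities.palliative_asymptomatic": PsaDistribution(fx),
        "utilities.palliative_symptomatic": PsaDistribution(fx),
        "tests.clinic_visit.sensitivity": PsaDistribution(b, 0.42, _r95(0.27, 0.57)),
        "tests.cea_test.sensitivity": PsaDistribution(b, 0.64, _r95(0.49, 0.79)),
        "tests.ct.sensitivity": PsaDistribution(b, 0.83, _r95(0.68, 0.98)),
        "tests.colonoscopy.sensitivity": PsaDistribution(b, 0.95, _r95(0.80, 1.00)),
        "tests.clinic_visit.specificity": PsaDistribution(b, 0.95, _r95(0.70, 1.00)),
        "tests.cea_test.specificity": PsaDistribution(b, 0.90, _r95(0.75, 1.00)),
        "tests.ct.specificity": PsaDistribution(b, 0.93, _r95(0.78, 1.00)),
        "tests.colonoscopy.specificity": PsaDistribution(b, 1.00, _r95(0.85, 1.00)),
        "clinical.metastasectomy_mortality": PsaDistribution(b, 0.010, _r95(0.003, 0.015)),
        "clinical.mean_months_undetected_to_symptomatic": PsaDistribution(g, 4.0, _r95(1.0, 28.0)),
        "clinical.asymptomatic_metastasectomy_rate": PsaDistribution(fx),
        "clinical.symptomatic_metastasectomy_rate": PsaDistribution(fx),
    }


@dataclass(frozen=True)
class ModelConfig:
    """The complete, validated input set for one model run."""

    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    tests: TestPerformance = field(default_factory=TestPerformance)
    clinical: ClinicalInputs = field(default_factory=ClinicalInputs)
    cohort: CohortSummary = field(default_factory=CohortSummary)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    psa_distributions: dict[str, PsaDistribution] = field(
        default_factory=default_psa_distributions)
    schema_version: int = SCHEMA_VERSION

    def digest(self) -> str:
        """Stable SHA-256 over the canonical YAML serialization."""
        doc = yaml.safe_dump(to_dict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()


def default_config() -> ModelConfig:
    """The packaged base case, exactly as published."""
    return ModelConfig()


# ---------------------------------------------------------------------------
# serialization

def _to_plain(obj: Any) -> Any:
    if isinstance(obj, Uncertain):
        d = {"value": obj.value}
        if obj.lo is not None:
            d["lo"] = obj.lo
        if obj.hi is not None:
            d["hi"] = obj.hi
        return d
    if is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def to_dict(config: ModelConfig) -> dict:
    """Plain-dict (YAML-ready) form of a config."""
    return _to_plain(config)


def _build(cls: type, data: Any, path: str) -> Any:
    """Reconstruct dataclass `cls` from plain data, naming bad fields."""
    if cls is Uncertain:
        if isinstance(data, Mapping):
            unknown = set(data) - {"value", "lo", "hi"}
            if unknown:
                raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
            if "value" not in data:
                raise ConfigError(f"{path}: missing required field 'value'")
            return Uncertain(float(data["value"]),
                             None if data.get("lo") is None else float(data["lo"]),
                             None if data.get("hi") is None else float(data["hi"]))
        return Uncertain(float(data))
    if is_dataclass(cls):
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")
        kwargs = {}
        for name, f in known.items():
            if name not in data:
                continue  # packaged default applies
            sub = data[name]
            subpath = f"{path}.{name}" if path else name
            if name == "psa_distributions":
                kwargs[name] = {k: _build(PsaDistribution, v, f"{subpath}.{k}")
                                for k, v in sub.items()}
            elif name == "wtp_grid":
                kwargs[name] = tuple(float(x) for x in sub)
            elif f.type in ("Uncertain", "Uncertain | float"):
                kwargs[name] = _build(Uncertain, sub, subpath)
            elif f.type == "TestModality":
                kwargs[name] = _build(TestModality, sub, subpath)
            elif is_dataclass(_FIELD_TYPES.get((cls, name), type(None))):
                kwargs[name] = _build(_FIELD_TYPES[(cls, name)], sub, subpath)
            else:
                kwargs[name] = sub
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
    return data


# Nested dataclass field types (string annotations make this explicit).
_FIELD_TYPES: dict[tuple[type, str], type] = {
    (ModelConfig, "costs"): CostInputs,
    (ModelConfig, "utilities"): UtilityInputs,
    (ModelConfig, "tests"): TestPerformance,
    (ModelConfig, "clinical"): ClinicalInputs,
    (ModelConfig, "cohort"): CohortSummary,
    (ModelConfig, "settings"): AnalysisSettings,
    (TestPerformance, "clinic_visit"): TestModality,
    (TestPerformance, "cea_test"): TestModality,
    (TestPerformance, "ct"): TestModality,
    (TestPerformance, "colonoscopy"): TestModality,
}


def from_dict(data: Mapping | None) -> ModelConfig:
    """Build a config from a (possibly partial) plain mapping."""
    if data is None:
        data = {}
    if "schema_version" in data and int(data["schema_version"]) != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {data['schema_version']} (expected {SCHEMA_VERSION})")
    return _build(ModelConfig, data, "")


def load_config(path: str) -> ModelConfig:
    """Load a YAML/JSON config file; unspecified fields take base-case defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


def save_config(config: ModelConfig, path: str) -> None:
    """Write a config as YAML (round-trips through :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# parameter paths (used by sensitivity analyses)

def get_param(config: ModelConfig, path: str) -> Any:
    """Fetch a parameter by dotted path; Uncertain leaves yield their value."""
    obj: Any = config
    for part in path.split("."):
        if not hasattr(obj, part):
            raise ConfigError(_unknown_path_msg(config, path))
        obj = getattr(obj, part)
    if isinstance(obj, Uncertain):
        return obj.value
    return obj


def set_param(config: ModelConfig, path: str, value: Any) -> ModelConfig:
    """Return a new config with the parameter at `path` replaced by `value`.

    If the leaf is an :class:`Uncertain`, its point value is replaced and the
    range widened if needed so the result still validates.
    """
    parts = path.split(".")
    chain = [config]
    for part in parts[:-1]:
        cur = chain[-1]
        if not hasattr(cur, part):
            raise ConfigError(_unknown_path_msg(config, path))
        chain.append(getattr(cur, part))
    parent, leaf = chain[-1], parts[-1]
    if not hasattr(parent, leaf):
        raise ConfigError(_unknown_path_msg(config, path))
    old = getattr(parent, leaf)
    if isinstance(old, Uncertain) and not isinstance(value, Uncertain):
        v = float(value)
        value = Uncertain(v,
                          None if old.lo is None else min(old.lo, v),
                          None if old.hi is None else max(old.hi, v))
    new = replace(parent, **{leaf: value})
    for part, obj in zip(reversed(parts[:-1]), reversed(chain[:-1])):
        new = replace(obj, **{part: new})
    return new


def known_param_paths(config: ModelConfig) -> list[str]:
    """All dotted paths that :func:`set_param` accepts (numeric leaves)."""
    paths: list[str] = []

    def walk(obj: Any, prefix: str) -> None:
        for f in fields(obj):
            sub = getattr(obj, f.name)
            p = f"{prefix}.{f.name}" if prefix else f.name
            if isinstance(sub, Uncertain) or isinstance(sub, (int, float)):
                paths.append(p)
            elif is_dataclass(sub) and not isinstance(sub, PsaDistribution):
                walk(sub, p)

    for section in ("costs", "utilities", "tests", "clinical", "cohort", "settings"):
        walk(getattr(default_config(), section), section)
    return paths


def _unknown_path_msg(config: ModelConfig, path: str) -> str:
    return (f"unknown parameter path {path!r}; known paths include: "
            + ", ".join(known_param_paths(config)[:12]) + ", ...")
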