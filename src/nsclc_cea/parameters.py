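"""Parameter sets for the decision model: types, validation, serialization.

Everything downstream (survival extrapolation, cohort simulation, costing,
sensitivity analysis) consumes a :class:`Scenario`, the single validated
bundle of inputs for one two-arm comparison.  Three scenarios ship with the
package — the PD-L1 ≥50%, ≥1% and <1% strata of the first-line comparison of
nivolumab plus ipilimumab against platinum-doublet chemotherapy in advanced
non-small-cell lung cancer — with every numeric input (Weibull survival
parameters per arm and endpoint, health-state utilities, per-cycle drug and
resource prices, grade ≥3 adverse-event risks and unit costs, subsequent
therapy mixes, plausible ranges and distribution families for sensitivity
analysis) stored in plain YAML under ``nsclc_cea/data``.

Prices are US dollars.  Survival time is measured in 6-week model cycles:
a Weibull ``scale`` of 0.1 means S(t) = exp(-0.1 * t**shape) with t counted
in cycles (see :mod:`nsclc_cea.survival` for unit converters).
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "WeibullParams",
    "UtilityInputs",
    "AEItem",
    "TherapyMixItem",
    "ScheduleEntry",
    "ArmSpec",
    "ModelSettings",
    "SARange",
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "write_scenario",
    "builtin_scenarios",
    "builtin_scenario",
    "parameter_table",
    "resolve_path",
    "get_path",
    "set_path",
]

BUILTIN_POPULATIONS = ("pdl1_ge50", "pdl1_ge1", "pdl1_lt1")


class ScenarioError(ValueError):
    """A scenario file failed to parse or violated an invariant."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class WeibullParams(_Model):
    """Weibull survival parameters S(t) = exp(-scale * t**shape).

    ``shape`` is the dimensionless γ; ``scale`` is λ in units of
    cycles**(-shape), time measured in 6-week model cycles.
    """

    shape: float = Field(gt=0)
    scale: float = Field(gt=0)


class UtilityInputs(_Model):
    """Health-state utilities on the 0 (death) .. 1 (perfect health) scale."""

    u_pfs_intervention: float = Field(ge=0, le=1)
    u_pfs_comparator: float = Field(ge=0, le=1)
    u_pd: float = Field(ge=0, le=1)


class AEItem(_Model):
    """One grade ≥3 adverse event: per-patient incidence and unit cost.

    ``unit_cost`` is derived from the scenario-level ``ae_costs`` table on
    :meth:`Scenario.refresh` and excluded from serialization.
    """

    name: str
    risk: float = Field(ge=0, le=1)
    unit_cost: float = Field(default=0.0, ge=0, exclude=True)


class TherapyMixItem(_Model):
    """One post-progression therapy: uptake proportion and how it accrues.

    ``per_cycle`` items bill ``cost_per_cycle`` for every cycle spent in the
    progressive-disease state; ``one_time`` items (radiotherapy, priced as a
    course) bill once at progression.  ``cost_per_cycle`` is resolved from
    the scenario drug-price table via ``price_key``.
    """

    name: str
    proportion: float = Field(ge=0, le=1)
    price_key: str
    accrual: Literal["per_cycle", "one_time"] = "per_cycle"
    cost_per_cycle: float = Field(default=0.0, ge=0, exclude=True)


class ScheduleEntry(_Model):
    """Active-treatment drug cost over a half-open cycle range [start, end)."""

    name: str
    start: int = Field(ge=0)
    end: Optional[int] = None  # None = until leaving PFS
    cost_per_cycle: float = Field(ge=0)


class ArmSpec(_Model):
    """One treatment arm: survival endpoints, regimen, AE and PD-therapy mix."""

    name: str
    regimen: Literal["nivo_ipi", "platinum_doublet"]
    os: WeibullParams
    pfs: WeibullParams
    ae_profile: List[AEItem] = Field(default_factory=list)
    subsequent_mix: List[TherapyMixItem] = Field(default_factory=list)
    #: Trial-reported proportion discontinuing active treatment.  Stored for
    #: audit; only applied to drug costs when
    #: ``ModelSettings.apply_discontinuation`` is set.
    discontinuation: Optional[float] = Field(default=None, ge=0, le=1)
    #: Derived on refresh; never read from a scenario file.
    active_treatment_schedule: List[ScheduleEntry] = Field(
        default_factory=list, exclude=True
    )

    @model_validator(mode="after")
    def _mix_proportions(self) -> "ArmSpec":
        total = sum(m.proportion for m in self.subsequent_mix)
        if total > 1 + 1e-9:
            raise ValueError(
                f"arm {self.name!r}: subsequent-therapy proportions sum to "
                f"{total:.3f} > 1"
            )
        return self


class ModelSettings(_Model):
    """Global model settings shared by both arms."""

    cycle_length_days: float = Field(default=42.0, gt=0)
    horizon_years: float = Field(default=20.0, gt=0)
    annual_discount_rate: float = Field(default=0.03, ge=0)
    half_cycle_correction: bool = False
    wtp: float = Field(default=150_000.0, gt=0)
    #: Optional cap (in cycles) on active-treatment drug/administration cost
    #: accrual in the intervention arm; None = treat to progression.
    treatment_cap_cycles: Optional[int] = Field(default=None, ge=1)
    #: Optional cap (in cycles of PD residence, measured in model cycles
    #: since entry is not tracked individually: applied as a cap on the
    #: number of cycles any per-cycle subsequent therapy is billed).
    subsequent_cap_cycles: Optional[int] = Field(default=None, ge=1)
    apply_discontinuation: bool = False
    #: Range → SD convention for probabilistic draws: sd = (max-min)/divisor.
    range_sd_divisor: float = Field(default=3.92, gt=0)

    @model_validator(mode="after")
    def _at_least_one_cycle(self) -> "ModelSettings":
        if self.horizon_years * 365.25 / self.cycle_length_days < 1:
            raise ValueError("horizon shorter than one cycle")
        return self

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / 365.25

    @property
    def n_cycles(self) -> int:
        """Number of cycle starts simulated (indices 0 .. n_cycles-1)."""
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_length_days)) + 1


class SARange(_Model):
    """Plausible range and distribution family for one numeric parameter."""

    min: float
    max: float
    family: Optional[Literal["beta", "gamma"]] = None

    @model_validator(mode="after")
    def _ordered(self) -> "SARange":
        if self.min > self.max:
            raise ValueError("range min exceeds max")
        return self


class Scenario(_Model):
    """Complete parameter bundle for one population comparison."""

    population: str
    settings: ModelSettings = Field(default_factory=ModelSettings)
    utilities: UtilityInputs
    #: Histology split of the chemotherapy arm (non-squamous share).
    histology_nonsquamous: float = Field(ge=0, le=1)
    #: Share of platinum use that is carboplatin (vs cisplatin); the source
    #: trial does not report the split, default 50/50.
    platinum_carboplatin_share: float = Field(default=0.5, ge=0, le=1)
    #: Acquisition cost per 6-week model cycle (one-course price for
    #: radiotherapy), USD.
    drug_prices: Dict[str, float]
    #: Management cost per grade ≥3 event, USD.
    ae_costs: Dict[str, float]
    admin_cost_per_cycle: float = Field(ge=0)
    ct_cost_per_cycle: float = Field(ge=0)
    lab_cost_per_cycle: float = Field(ge=0)
    intervention: ArmSpec
    comparator: ArmSpec
    sa_ranges: Dict[str, SARange] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _refresh_and_check(self) -> "Scenario":
        self.refresh()
        return self

    # -- derived fields -------------------------------------------------

    def refresh(self) -> "Scenario":
        """Recompute derived fields from the raw price/risk tables.

        Must be called after mutating any raw field (the sensitivity module
        does this after every ``set_path``).  Raises :class:`ScenarioError`
        on dangling price or AE-cost references.
        """
        for price in self.drug_prices.values():
            if price < 0:
                raise ScenarioError("negative drug price")
        for cost in self.ae_costs.values():
            if cost < 0:
                raise ScenarioError("negative AE cost")
        for arm in (self.intervention, self.comparator):
            for item in arm.ae_profile:
                if item.name not in self.ae_costs:
                    raise ScenarioError(
                        f"arm {arm.name!r}: AE item {item.name!r} has no entry "
                        "in ae_costs"
                    )
                item.unit_cost = self.ae_costs[item.name]
            for mix in arm.subsequent_mix:
                if mix.price_key not in self.drug_prices:
                    raise ScenarioError(
                        f"arm {arm.name!r}: subsequent therapy {mix.name!r} "
                        f"references unknown price {mix.price_key!r}"
                    )
                mix.cost_per_cycle = self.drug_prices[mix.price_key]
            arm.active_treatment_schedule = self._build_schedule(arm)
        for path in self.sa_ranges:
            value = get_path(self, path)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ScenarioError(f"sa_ranges path {path!r} is not numeric")
        return self

    def _build_schedule(self, arm: ArmSpec) -> List[ScheduleEntry]:
        p = self.drug_prices
        if arm.regimen == "nivo_ipi":
            cap = self.settings.treatment_cap_cycles
            return [
                ScheduleEntry(name="nivolumab", start=0, end=cap,
                              cost_per_cycle=p["nivolumab"]),
                ScheduleEntry(name="ipilimumab", start=0, end=cap,
                              cost_per_cycle=p["ipilimumab"]),
            ]
        # Platinum doublet: two 3-week administrations per model cycle for
        # the first two model cycles (= four chemotherapy cycles), histology
        # weighted; then pemetrexed maintenance for the non-squamous share
        # while progression free.
        nsq = self.histology_nonsquamous
        plat = (self.platinum_carboplatin_share * p["carboplatin"]
                + (1 - self.platinum_carboplatin_share) * p["cisplatin"])
        doublet = 2 * (nsq * (p["pemetrexed"] + plat)
                       + (1 - nsq) * (p["gemcitabine"] + plat))
        maintenance = nsq * p["pemetrexed"]
        return [
            ScheduleEntry(name="platinum_doublet", start=0, end=2,
                          cost_per_cycle=doublet),
            ScheduleEntry(name="pemetrexed_maintenance", start=2, end=None,
                          cost_per_cycle=maintenance),
        ]

    def arm(self, role: str) -> ArmSpec:
        if role == "intervention":
            return self.intervention
        if role == "comparator":
            return self.comparator
        raise ValueError(f"unknown arm role {role!r}")


# ---------------------------------------------------------------------------
# dotted-path access ("utilities.u_pd", "comparator.ae_profile[anemia].risk")
# ---------------------------------------------------------------------------

def _split_path(path: str) -> List[Union[str, Tuple[str, str]]]:
    parts: List[Union[str, Tuple[str, str]]] = []
    for token in path.split("."):
        if "[" in token:
            if not token.endswith("]"):
                raise KeyError(f"malformed path segment {token!r}")
            field, _, key = token[:-1].partition("[")
            parts.append((field, key))
        else:
            parts.append(token)
    return parts


def _step(obj, part):
    if isinstance(part, tuple):
        field, key = part
        seq = _step(obj, field)
        for item in seq:
            if getattr(item, "name", None) == key:
                return item
        raise KeyError(f"no item named {key!r} in {field!r}")
    if isinstance(obj, dict):
        if part not in obj:
            raise KeyError(f"no key {part!r}")
        return obj[part]
    if not hasattr(obj, part):
        raise KeyError(f"no field {part!r} on {type(obj).__name__}")
    return getattr(obj, part)


def resolve_path(scenario: Scenario, path: str):
    """Return ``(parent, leaf)`` for a dotted parameter path."""
    parts = _split_path(path)
    obj = scenario
    for part in parts[:-1]:
        obj = _step(obj, part)
    leaf = parts[-1]
    _step(obj, leaf)  # raises if missing
    return obj, leaf


def get_path(scenario: Scenario, path: str):
    parent, leaf = resolve_path(scenario, path)
    return _step(parent, leaf)


def set_path(scenario: Scenario, path: str, value: float) -> None:
    """Set a numeric field by path and refresh derived quantities."""
    parent, leaf = resolve_path(scenario, path)
    if isinstance(leaf, tuple):
        raise KeyError(f"path {path!r} addresses an object, not a number")
    if isinstance(parent, dict):
        parent[leaf] = value
    else:
        setattr(parent, leaf, value)
    scenario.refresh()


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def load_scenario(source: Union[str, Path, dict]) -> Scenario:
    """Load and validate a scenario from a YAML/JSON file or a mapping.

    Unknown keys are rejected; invariant violations raise
    :class:`ScenarioError` naming the offending field.
    """
    if isinstance(source, dict):
        raw = source
        where = "<mapping>"
    else:
        path = Path(source)
        if not path.exists():
            raise ScenarioError(f"scenario file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ScenarioError(f"cannot parse {path}: {exc}") from exc
        where = str(path)
    if not isinstance(raw, dict):
        raise ScenarioError(f"{where}: scenario file must contain a mapping")
    try:
        return Scenario.model_validate(raw)
    except ScenarioError:
        raise
    except Exception as exc:  # pydantic ValidationError
        raise ScenarioError(f"{where}: {exc}") from exc


def write_scenario(scenario: Scenario, path: Union[str, Path]) -> Path:
    """Serialize a scenario to YAML (derived fields omitted); returns path."""
    path = Path(path)
    payload = scenario.model_dump(mode="json", exclude_none=True)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def builtin_scenario(population: str) -> Scenario:
    """Load one bundled scenario: ``pdl1_ge50``, ``pdl1_ge1`` or ``pdl1_lt1``."""
    if population not in BUILTIN_POPULATIONS:
        raise ScenarioError(
            f"unknown bundled population {population!r}; "
            f"choose from {BUILTIN_POPULATIONS}"
        )
    ref = resources.files("nsclc_cea.data").joinpath(f"{population}.yaml")
    raw = yaml.safe_load(ref.read_text())
    return Scenario.model_validate(raw)


def builtin_scenarios() -> Dict[str, Scenario]:
    """All three bundled PD-L1 strata, keyed by population label."""
    return {pop: builtin_scenario(pop) for pop in BUILTIN_POPULATIONS}


def parameter_table(scenario: Scenario):
    """Flat audit listing of every numeric input as a pandas DataFrame."""
    import pandas as pd

    rows = []

    def add(path, value, note=""):
        rows.append({"path": path, "value": value, "note": note})

    for arm in ("intervention", "comparator"):
        spec = scenario.arm(arm)
        for ep in ("os", "pfs"):
            wb = getattr(spec, ep)
            add(f"{arm}.{ep}.shape", wb.shape)
            add(f"{arm}.{ep}.scale", wb.scale, "per cycle^shape")
        for item in spec.ae_profile:
            add(f"{arm}.ae_profile[{item.name}].risk", item.risk)
        for mix in spec.subsequent_mix:
            add(f"{arm}.subsequent_mix[{mix.name}].proportion", mix.proportion,
                f"{mix.accrual}, priced as {mix.price_key}")
        if spec.discontinuation is not None:
            add(f"{arm}.discontinuation", spec.discontinuation,
                "stored; unused unless apply_discontinuation")
    for key, value in scenario.drug_prices.items():
        add(f"drug_prices.{key}", value, "USD per cycle")
    for key, value in scenario.ae_costs.items():
        add(f"ae_costs.{key}", value, "USD per event")
    add("admin_cost_per_cycle", scenario.admin_cost_per_cycle)
    add("ct_cost_per_cycle", scenario.ct_cost_per_cycle)
    add("lab_cost_per_cycle", scenario.lab_cost_per_cycle)
    for field in ("u_pfs_intervention", "u_pfs_comparator", "u_pd"):
        add(f"utilities.{field}", getattr(scenario.utilities, field))
    add("histology_nonsquamous", scenario.histology_nonsquamous)
    add("platinum_carboplatin_share", scenario.platinum_carboplatin_share)
    add("settings.annual_discount_rate", scenario.settings.annual_discount_rate)
    add("settings.cycle_length_days", scenario.settings.cycle_length_days)
    add("settings.horizon_years", scenario.settings.horizon_years)
    return pd.DataFrame(rows)
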