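"""Scenario schema: growth medium, polymerase allocation, promoters, reporter.

A :class:`Scenario` fully specifies one simulated plate-reader experiment:
the carbon sources and their Monod parameters, how RNA polymerase is
partitioned between rRNA synthesis and the rest of the genome as a function
of growth rate, the promoter fusions carried by the (virtual) strains, the
destabilized luciferase reporter, and the measurement layer (sampling grid,
multiplicative noise, optical-density background).

Scenarios are plain frozen dataclasses, loadable from YAML/JSON mappings.
Unknown keys are rejected so that typos in configuration files fail loudly
instead of silently running with defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .errors import ConfigurationError

__all__ = [
    "Substrate",
    "MediumSpec",
    "RnapParams",
    "PromoterSpec",
    "ReporterSpec",
    "Spo0AParams",
    "GtpDip",
    "ProgramStep",
    "Scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
    "save_scenario",
    "bundled_scenario",
    "list_bundled_scenarios",
]

LN2 = 0.6931471805599453

PROMOTER_CLASSES = ("constitutive", "rrn_like", "repressed", "activated")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class Substrate:
    """One carbon source: initial concentration plus Monod growth parameters.

    Units: ``conc`` mg/ml, ``mu_max`` 1/h, ``K_s`` mg/ml, ``yield_od``
    OD units of biomass produced per mg/ml of substrate consumed.
    """

    name: str
    conc: float
    mu_max: float
    K_s: float
    yield_od: float

    def __post_init__(self) -> None:
        _require(self.conc >= 0, f"substrate {self.name}: conc must be >= 0")
        _require(self.mu_max >= 0, f"substrate {self.name}: mu_max must be >= 0")
        _require(self.K_s > 0, f"substrate {self.name}: K_s must be > 0")
        _require(self.yield_od > 0, f"substrate {self.name}: yield_od must be > 0")


@dataclass(frozen=True)
class MediumSpec:
    """Mixture of substrates with a catabolite-repression preference order.

    ``repression_order`` ranks the substrates from most to least preferred;
    a substrate is only consumed once every more-preferred one is exhausted,
    with a first-order induction lag (``induction_rate``) that gives the
    diauxic pause its finite width.  ``lysis_rate`` is an optional first-order
    biomass decay applied once every substrate is gone (mild stationary-phase
    lysis); it defaults to zero so that strict mass balance holds.
    """

    substrates: tuple[Substrate, ...]
    repression_order: tuple[str, ...]
    induction_rate: float = 20.0
    decay_rate: float = 0.0
    lysis_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "repression_order", tuple(self.repression_order))
        names = [s.name for s in self.substrates]
        _require(len(set(names)) == len(names), "duplicate substrate names")
        _require(
            sorted(self.repression_order) == sorted(names),
            "repression_order must be a permutation of substrate names",
        )
        _require(self.induction_rate >= 0, "induction_rate must be >= 0")
        _require(self.decay_rate >= 0, "decay_rate must be >= 0")
        _require(self.lysis_rate >= 0, "lysis_rate must be >= 0")

    def preference_rank(self, name: str) -> int:
        return self.repression_order.index(name)


@dataclass(frozen=True)
class RnapParams:
    """RNA-polymerase allocation between rRNA genes and the rest.

    The committed fraction is ``f_rrn(mu) = f_max * mu / (mu + K_mu)`` so a
    fast-growing cell devotes up to ``f_max`` of its polymerase pool to
    stable-RNA synthesis, and a growth arrest releases it all.
    """

    f_max: float
    K_mu: float
    R_total: float = 1.0

    def __post_init__(self) -> None:
        _require(0 < self.f_max < 1, "f_max must lie in (0, 1)")
        _require(self.K_mu > 0, "K_mu must be > 0")
        _require(self.R_total > 0, "R_total must be > 0")


@dataclass(frozen=True)
class PromoterSpec:
    """One promoter fusion and how it responds to polymerase and Spo0A~P.

    ``kind`` selects the response law:

    - ``constitutive``: Michaelis form in free polymerase,
      ``strength * R_free / (R_free + K_R)`` -- the passively regulated class
      that bursts when growth pauses release polymerase.
    - ``rrn_like``: proportional to the rRNA-committed fraction,
      ``strength * f_rrn`` -- tracks the growth rate.
    - ``repressed``: constitutive form multiplied by a repressive Hill factor
      in Spo0A~P (abrB-like).
    - ``activated``: activating Hill factor in Spo0A~P (spoIIG/comK-like).

    A ``G``-initiating promoter is additionally scaled by the GTP-pool
    factor (normalized to 1 at a full pool); ``A``-initiating promoters
    ignore the pool.
    """

    name: str
    kind: str
    strength: float
    K_R: float = 0.5
    initiating_nucleotide: str = "A"
    intp_K: float = 0.5
    regulator_K: float | None = None
    hill_n: float | None = None

    def __post_init__(self) -> None:
        _require(self.kind in PROMOTER_CLASSES,
                 f"promoter {self.name}: unknown class {self.kind!r}; "
                 f"expected one of {PROMOTER_CLASSES}")
        _require(self.strength >= 0, f"promoter {self.name}: strength must be >= 0")
        _require(self.K_R > 0, f"promoter {self.name}: K_R must be > 0")
        _require(self.initiating_nucleotide in ("A", "G"),
                 f"promoter {self.name}: initiating_nucleotide must be 'A' or 'G'")
        _require(self.intp_K > 0, f"promoter {self.name}: intp_K must be > 0")
        if self.kind in ("repressed", "activated"):
            _require(self.regulator_K is not None and self.regulator_K > 0,
                     f"promoter {self.name}: {self.kind} class requires regulator_K > 0")
            _require(self.hill_n is not None and self.hill_n >= 1,
                     f"promoter {self.name}: {self.kind} class requires hill_n >= 1")


@dataclass(frozen=True)
class ReporterSpec:
    """The destabilized luciferase reporter.

    ``half_life`` is in hours (default 0.1 h = 6 min), so the degradation
    rate is ``delta = ln 2 / half_life ~= 6.93 / h``: fast enough that the
    emitted light tracks the instantaneous transcription rate rather than
    the accumulated protein.  ``light_coeff`` converts per-cell reporter
    units to instrument RLU per OD unit of biomass; its absolute value is
    arbitrary, as on a real luminometer.
    """

    half_life: float = 0.1
    light_coeff: float = 1.0e5
    maturation_delay: float = 0.0

    def __post_init__(self) -> None:
        _require(self.half_life > 0, "reporter half_life must be > 0")
        _require(self.light_coeff > 0, "light_coeff must be > 0")
        _require(self.maturation_delay >= 0, "maturation_delay must be >= 0")

    @property
    def delta(self) -> float:
        """First-order degradation rate, 1/h."""
        return LN2 / self.half_life


@dataclass(frozen=True)
class Spo0AParams:
    """Synthesis/phosphorylation kinetics of the master regulator.

    Protein: ``dP/dt = A_spo0A(t) - gamma_P * P``; phosphoform:
    ``dSp/dt = k_phos * P * kappa(t) - k_deph * Sp`` with ``kappa`` a
    kinase-availability profile (constant 1 by default).
    """

    gamma_P: float = 1.0
    k_phos: float = 2.0
    k_deph: float = 2.0

    def __post_init__(self) -> None:
        _require(self.gamma_P >= 0, "gamma_P must be >= 0")
        _require(self.k_phos >= 0, "k_phos must be >= 0")
        _require(self.k_deph >= 0, "k_deph must be >= 0")


@dataclass(frozen=True)
class GtpDip:
    """A scripted depression of the GTP pool: ``depth`` in [0, 1]."""

    start: float
    end: float
    depth: float

    def __post_init__(self) -> None:
        _require(self.end > self.start, "GTP dip must have end > start")
        _require(0 <= self.depth <= 1, "GTP dip depth must lie in [0, 1]")


@dataclass(frozen=True)
class ProgramStep:
    """A scripted additive activity step (units/h) on one promoter.

    Steps may be negative; a +step followed by a smaller -step produces the
    stationary-phase waves of activity seen after growth ends.
    """

    promoter: str
    time: float
    step: float

    def __post_init__(self) -> None:
        _require(self.time >= 0, "program step time must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """A complete simulated experiment."""

    name: str
    medium: MediumSpec
    rnap: RnapParams
    promoters: tuple[PromoterSpec, ...]
    reporter: ReporterSpec = field(default_factory=ReporterSpec)
    spo0a: Spo0AParams = field(default_factory=Spo0AParams)
    spo0a_promoter: str | None = None
    gtp_dip_schedule: tuple[GtpDip, ...] = ()
    stationary_program: tuple[ProgramStep, ...] = ()
    sampling_interval: float = 0.025
    duration: float = 8.0
    initial_biomass: float = 0.05
    noise_cv: float = 0.02
    od_background: float = 0.04

    def __post_init__(self) -> None:
        object.__setattr__(self, "promoters", tuple(self.promoters))
        object.__setattr__(self, "gtp_dip_schedule", tuple(self.gtp_dip_schedule))
        object.__setattr__(self, "stationary_program", tuple(self.stationary_program))
        _require(self.sampling_interval > 0, "sampling_interval must be > 0")
        _require(self.duration > 0, "duration must be > 0")
        _require(self.initial_biomass > 0, "initial_biomass must be > 0")
        _require(self.noise_cv >= 0, "noise_cv must be >= 0")
        _require(self.od_background >= 0, "od_background must be >= 0")
        names = [p.name for p in self.promoters]
        _require(len(set(names)) == len(names), "duplicate promoter names")
        if self.spo0a_promoter is not None:
            _require(self.spo0a_promoter in names,
                     f"spo0a_promoter {self.spo0a_promoter!r} is not a promoter")
        for step in self.stationary_program:
            _require(step.promoter in names,
                     f"stationary_program references unknown promoter {step.promoter!r}")
        needs_sp = any(p.kind in ("repressed", "activated") for p in self.promoters)
        if needs_sp:
            _require(self.spo0a_promoter is not None,
                     "repressed/activated promoters require a spo0a_promoter "
                     "to drive the Spo0A~P series")

    def promoter(self, name: str) -> PromoterSpec:
        for p in self.promoters:
            if p.name == name:
                return p
        raise ConfigurationError(f"no promoter named {name!r}")

    def with_(self, **kwargs: Any) -> "Scenario":
        """Return a copy with the given top-level fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# (De)serialization


def _build(cls, data: Mapping[str, Any], context: str):
    """Construct a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


def scenario_from_dict(data: Mapping[str, Any]) -> Scenario:
    """Build a :class:`Scenario` from a nested plain mapping (YAML/JSON)."""
    if not isinstance(data, Mapping):
        raise ConfigurationError("scenario: expected a mapping at top level")
    allowed = {f.name for f in fields(Scenario)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"scenario: unknown keys {sorted(unknown)}")
    d = dict(data)
    med = dict(d.get("medium", {}))
    subs = tuple(_build(Substrate, s, "medium.substrates") for s in med.pop("substrates", ()))
    medium = _build(MediumSpec, {**med, "substrates": subs}, "medium")
    d["medium"] = medium
    d["rnap"] = _build(RnapParams, d.get("rnap", {}), "rnap")
    d["promoters"] = tuple(_build(PromoterSpec, p, "promoters") for p in d.get("promoters", ()))
    if "reporter" in d:
        d["reporter"] = _build(ReporterSpec, d["reporter"], "reporter")
    if "spo0a" in d:
        d["spo0a"] = _build(Spo0AParams, d["spo0a"], "spo0a")
    if "gtp_dip_schedule" in d:
        d["gtp_dip_schedule"] = tuple(
            _build(GtpDip, g, "gtp_dip_schedule") for g in d["gtp_dip_schedule"])
    if "stationary_program" in d:
        d["stationary_program"] = tuple(
            _build(ProgramStep, s, "stationary_program") for s in d["stationary_program"])
    return Scenario(**d)


def _asdict(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {f.name: _asdict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_asdict(x) for x in obj]
    return obj


def scenario_to_dict(scenario: Scenario) -> dict:
    return _asdict(scenario)


def load_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return scenario_from_dict(data)
    except ConfigurationError as err:
        raise ConfigurationError(f"{path}: {err}") from err


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario_to_dict(scenario)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def list_bundled_scenarios() -> list[str]:
    pkg = resources.files("luxpulse") / "data"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def bundled_scenario(name: str) -> Scenario:
    """Load a scenario shipped with the package (e.g. ``"dsm"``)."""
    pkg = resources.files("luxpulse") / "data" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise ConfigurationError(
            f"no bundled scenario {name!r}; available: {list_bundled_scenarios()}")
    return scenario_from_dict(yaml.safe_load(text))
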