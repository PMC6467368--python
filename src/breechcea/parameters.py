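"""Model inputs for the breech-screening cost-effectiveness model.

Every input of the decision-analytic model lives here as a typed, validated
parameter: binary-event probabilities as (events, non-events) count pairs
driving beta distributions, mode-of-delivery (MOD) distributions as per-category
counts driving Dirichlet distributions, fixed unit costs (GBP, 2017 price
level), neonatal-mortality risks by presentation and mode, and the economic
settings (lifetime QALY constant, discount rate, national birth count,
willingness-to-pay thresholds, PSA size).

The defaults are the published inputs of the model: probabilities estimated
from a prospective cohort of 3,879 nulliparous women scanned at 36 weeks of
gestational age, delivery costs from NHS reference costs, and an ECV cost from
the literature.  Each probability and MOD parameter carries the chance-node
code of the decision tree it feeds (A1, A2, B1-B4, C1-C11); those codes are
also the keys of the YAML/JSON configuration format so a configuration file
can be audited line-by-line against the published input table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "MOD_CATEGORIES",
    "ENDPOINT_CLASSES",
    "EventCount",
    "ModCounts",
    "CostSchedule",
    "MortalitySchedule",
    "EconSettings",
    "ModelParameters",
    "ParameterDraw",
    "PROBABILITY_FIELDS",
    "MOD_FIELDS",
    "NODE_CODES",
    "default_parameters",
    "point_estimate",
    "sample_probability",
    "sample_mod",
    "validate",
    "point_draw",
    "sample_draw",
    "save_parameters",
    "load_parameters",
    "params_to_dict",
    "params_from_dict",
]

#: Mode-of-delivery categories, in the column order of the published input table.
MOD_CATEGORIES = ("cephalic_vaginal", "elcs", "emcs", "vaginal_breech")

#: Terminal endpoint classes of the decision tree: presentation at delivery
#: crossed with mode of delivery (cephalic EMCS/ELCS vs breech EMCS/ELCS are
#: distinct because mortality risks differ by presentation).
ENDPOINT_CLASSES = (
    "cephalic_vaginal",
    "cephalic_elcs",
    "cephalic_emcs",
    "vaginal_breech",
    "breech_elcs",
    "breech_emcs",
)


@dataclass(frozen=True)
class EventCount:
    """A binary-outcome parameter as (events, non-events) counts.

    The counts are used directly as the alpha/beta shape parameters of the
    beta distribution in the PSA (no prior increment), and their ratio is the
    deterministic point estimate.
    """

    events: float
    non_events: float

    @property
    def total(self) -> float:
        return self.events + self.non_events

    @property
    def point(self) -> float:
        """events / (events + non-events); raises on an empty count pair."""
        if self.total <= 0:
            raise ValueError("EventCount with zero total has no point estimate")
        return self.events / self.total

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from Beta(events, non-events); zero counts are degenerate."""
        if self.events == 0:
            return np.zeros(size) if size is not None else 0.0
        if self.non_events == 0:
            return np.ones(size) if size is not None else 1.0
        return rng.beta(self.events, self.non_events, size=size)


@dataclass(frozen=True)
class ModCounts:
    """A mode-of-delivery distribution as per-category counts.

    ``counts`` follow :data:`MOD_CATEGORIES` order. Positive counts are
    Dirichlet concentration parameters; zero counts are structural zeros --
    the category is excluded from sampling and receives probability exactly 0
    in every draw (the published table prints 0 for impossible modes, e.g.
    vaginal breech in a cephalic node).

    ``context`` records whether the distribution applies to women who are
    cephalic or breech at delivery, which decides which endpoint classes the
    ELCS/EMCS categories map to.
    """

    counts: tuple
    context: str  # "cephalic" | "breech"

    @property
    def mean(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Dirichlet draw over positive-count categories, structural zeros kept.

        Implemented as normalised gamma variates so that a batch of draws can
        be taken in one call (shape ``(size, 4)``).
        """
        counts = np.asarray(self.counts, dtype=float)
        positive = counts > 0
        shape = () if size is None else (int(size),)
        out = np.zeros(shape + (len(counts),))
        g = rng.gamma(counts[positive], 1.0, size=shape + (int(positive.sum()),))
        out[..., positive] = g / g.sum(axis=-1, keepdims=True)
        return out


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in GBP at the 2017 price level, per unit or episode.

    ``neonatal_death`` is not part of the published input table; the default
    is recovered from the published per-patient mortality-cost expectation
    (see docs/methods.md) and is configurable.
    """

    scan: float = 20.7
    ecv: float = 297.4
    cephalic_vaginal: float = 2297.3
    elcs: float = 3438.1
    emcs: float = 4553.4
    vaginal_breech: float = 3999.7
    neonatal_death: float = 1620.0

    def endpoint_unit_costs(self) -> np.ndarray:
        """Delivery unit cost per endpoint class (ENDPOINT_CLASSES order)."""
        return np.array(
            [
                self.cephalic_vaginal,
                self.elcs,
                self.emcs,
                self.vaginal_breech,
                self.elcs,
                self.emcs,
            ]
        )


@dataclass(frozen=True)
class MortalitySchedule:
    """Neonatal mortality risk by presentation at delivery and mode.

    Cephalic deliveries carry one risk regardless of mode (vaginal and ELCS
    assumed identical, EMCS assumed equal to ELCS); breech cesareans (elective
    or emergency) carry one risk; vaginal breech delivery carries another.
    """

    cephalic_any_mode: float = 0.001
    breech_cesarean: float = 0.0005
    breech_vaginal: float = 0.002

    def endpoint_risks(self) -> np.ndarray:
        return np.array(
            [
                self.cephalic_any_mode,
                self.cephalic_any_mode,
                self.cephalic_any_mode,
                self.breech_vaginal,
                self.breech_cesarean,
                self.breech_cesarean,
            ]
        )


@dataclass(frozen=True)
class EconSettings:
    """Economic evaluation settings.

    ``qaly_per_surviving_birth`` is the net present value of average lifetime
    QALYs at birth (discounted at ``discount_rate``); ``population_size`` is
    the annual number of deliveries the per-patient results are scaled to.
    """

    qaly_per_surviving_birth: float = 24.3
    discount_rate: float = 0.035
    population_size: int = 585_489
    wtp_thresholds: tuple = (20_000.0, 30_000.0)
    psa_iterations: int = 100_000
    random_seed: int | None = None


#: Draw order of the seven probability parameters (fixed for reproducibility).
PROBABILITY_FIELDS = (
    "p_breech",
    "p_detect",
    "p_ecv_attempt",
    "p_ecv_success",
    "p_src_no_ecv",
    "p_srb_after_ecv",
    "p_src_failed_ecv",
)

#: Draw order of the six MOD distributions (fixed for reproducibility).
MOD_FIELDS = (
    "mod_no_breech",
    "mod_ceph_after_ecv",
    "mod_ceph_spontaneous",
    "mod_breech_no_ecv",
    "mod_breech_failed_ecv",
    "mod_breech_undetected",
)

#: Chance-node codes of the decision tree, mapped to parameter fields.
NODE_CODES = {
    "A1": "p_breech",
    "B1": "p_breech",
    "B3": "p_detect",
    "C1": "p_ecv_attempt",
    "C2": "p_ecv_success",
    "C3": "p_src_no_ecv",
    "C4": "p_srb_after_ecv",
    "C5": "p_src_failed_ecv",
    "A2": "mod_no_breech",
    "B2": "mod_no_breech",
    "C8": "mod_ceph_after_ecv",
    "C6": "mod_ceph_spontaneous",
    "C10": "mod_ceph_spontaneous",
    "C7": "mod_breech_no_ecv",
    "C11": "mod_breech_failed_ecv",
    "C9": "mod_breech_undetected",
    "B4": "mod_breech_undetected",
}


@dataclass(frozen=True)
class ModelParameters:
    """The complete input set of the model: all probabilities, MOD
    distributions, unit costs, mortality risks and economic settings."""

    # probabilities (chance nodes)
    p_breech: EventCount = EventCount(179, 3700)            # A1 / B1
    p_detect: EventCount = EventCount(79, 96)               # B3
    p_ecv_attempt: EventCount = EventCount(84, 93)          # C1
    p_ecv_success: EventCount = EventCount(12, 72)          # C2
    p_src_no_ecv: EventCount = EventCount(21, 72)           # C3
    p_srb_after_ecv: EventCount = EventCount(1, 11)         # C4
    p_src_failed_ecv: EventCount = EventCount(3, 127)       # C5
    # mode-of-delivery distributions (CV, ELCS, EMCS, VB)
    mod_no_breech: ModCounts = ModCounts((2813, 141, 735, 0), "cephalic")       # A2 / B2
    mod_ceph_after_ecv: ModCounts = ModCounts((8, 0, 3, 0), "cephalic")         # C8
    mod_ceph_spontaneous: ModCounts = ModCounts((11, 1, 9, 0), "cephalic")      # C6 / C10
    mod_breech_no_ecv: ModCounts = ModCounts((0, 52, 20, 0), "breech")          # C7
    mod_breech_failed_ecv: ModCounts = ModCounts((0, 54, 18, 0), "breech")      # C11
    mod_breech_undetected: ModCounts = ModCounts((0, 0, 15, 11), "breech")      # C9 / B4
    costs: CostSchedule = CostSchedule()
    mortality: MortalitySchedule = MortalitySchedule()
    econ: EconSettings = EconSettings()


@dataclass(frozen=True)
class ParameterDraw:
    """One complete realisation of the model's uncertain parameters.

    Probability fields are floats (or equal-length arrays for a batch of
    draws); MOD fields are length-4 vectors (or ``(n, 4)`` arrays) summing to
    1 with structural zeros preserved.  Costs and mortality risks are carried
    along unchanged -- they are fixed, not sampled.
    """

    p_breech: float
    p_detect: float
    p_ecv_attempt: float
    p_ecv_success: float
    p_src_no_ecv: float
    p_srb_after_ecv: float
    p_src_failed_ecv: float
    mod_no_breech: np.ndarray
    mod_ceph_after_ecv: np.ndarray
    mod_ceph_spontaneous: np.ndarray
    mod_breech_no_ecv: np.ndarray
    mod_breech_failed_ecv: np.ndarray
    mod_breech_undetected: np.ndarray
    costs: CostSchedule
    mortality: MortalitySchedule


def default_parameters() -> ModelParameters:
    """The published input set with default economic settings."""
    return ModelParameters()


def point_estimate(p: EventCount) -> float:
    """Deterministic point estimate events / (events + non-events)."""
    return p.point


def sample_probability(p: EventCount, rng: np.random.Generator, size=None):
    """One (or ``size``) draws from Beta(events, non-events)."""
    return p.sample(rng, size=size)


def sample_mod(m: ModCounts, rng: np.random.Generator, size=None) -> np.ndarray:
    """One (or ``size``) Dirichlet draws respecting structural zeros."""
    return m.sample(rng, size=size)


def validate(params: ModelParameters) -> list[str]:
    """Check every type invariant; returns a (possibly empty) list of
    violations, each naming the offending parameter and rule."""
    violations: list[str] = []
    for name in PROBABILITY_FIELDS:
        ec: EventCount = getattr(params, name)
        if ec.events < 0:
            violations.append(f"{name}: events must be non-negative")
        if ec.non_events < 0:
            violations.append(f"{name}: non_events must be non-negative")
        if ec.events + ec.non_events <= 0:
            violations.append(f"{name}: events + non_events must be > 0")
    for name in MOD_FIELDS:
        mc: ModCounts = getattr(params, name)
        counts = np.asarray(mc.counts, dtype=float)
        if counts.shape != (4,):
            violations.append(f"{name}: must have one count per MOD category")
            continue
        if (counts < 0).any():
            violations.append(f"{name}: counts must be non-negative")
        if counts.sum() <= 0:
            violations.append(f"{name}: at least one category count must be > 0")
        if mc.context not in ("cephalic", "breech"):
            violations.append(f"{name}: context must be 'cephalic' or 'breech'")
    for f in fields(params.costs):
        if getattr(params.costs, f.name) < 0:
            violations.append(f"CostSchedule.{f.name}: must be non-negative")
    for f in fields(params.mortality):
        risk = getattr(params.mortality, f.name)
        if not 0 <= risk <= 1:
            violations.append(f"MortalitySchedule.{f.name}: must be in [0, 1]")
    econ = params.econ
    if econ.qaly_per_surviving_birth <= 0:
        violations.append("EconSettings.qaly_per_surviving_birth: must be > 0")
    if econ.population_size <= 0:
        violations.append("EconSettings.population_size: must be > 0")
    if econ.psa_iterations < 1:
        violations.append("EconSettings.psa_iterations: must be >= 1")
    if econ.discount_rate < 0:
        violations.append("EconSettings.discount_rate: must be non-negative")
    return violations


def point_draw(params: ModelParameters) -> ParameterDraw:
    """The deterministic draw: every probability at its point estimate,
    every MOD vector at its Dirichlet mean."""
    kwargs = {name: getattr(params, name).point for name in PROBABILITY_FIELDS}
    kwargs.update({name: getattr(params, name).mean for name in MOD_FIELDS})
    return ParameterDraw(costs=params.costs, mortality=params.mortality, **kwargs)


def sample_draw(
    params: ModelParameters, rng: np.random.Generator, size=None
) -> ParameterDraw:
    """A random realisation (or a batch of ``size`` realisations).

    Parameters are drawn in a fixed, documented order -- the seven
    probabilities in :data:`PROBABILITY_FIELDS` order, then the six MOD
    distributions in :data:`MOD_FIELDS` order -- so a seeded run is
    bit-reproducible.
    """
    kwargs = {name: getattr(params, name).sample(rng, size=size) for name in PROBABILITY_FIELDS}
    kwargs.update({name: getattr(params, name).sample(rng, size=size) for name in MOD_FIELDS})
    return ParameterDraw(costs=params.costs, mortality=params.mortality, **kwargs)


# --------------------------------------------------------------------------
# Configuration-file round trip.  Keys mirror the chance-node codes so a file
# can be checked cell-by-cell against the published input table.

_PROB_KEYS = {
    "p_breech": "A1_breech_prevalence",
    "p_detect": "B3_detection_without_ultrasound",
    "p_ecv_attempt": "C1_ecv_attempted",
    "p_ecv_success": "C2_ecv_success",
    "p_src_no_ecv": "C3_spontaneous_version_no_ecv",
    "p_srb_after_ecv": "C4_reversion_after_ecv",
    "p_src_failed_ecv": "C5_spontaneous_version_failed_ecv",
}
_MOD_KEYS = {
    "mod_no_breech": "A2_no_breech",
    "mod_ceph_after_ecv": "C8_cephalic_after_ecv",
    "mod_ceph_spontaneous": "C6_C10_cephalic_spontaneous",
    "mod_breech_no_ecv": "C7_breech_no_ecv",
    "mod_breech_failed_ecv": "C11_breech_failed_ecv",
    "mod_breech_undetected": "B4_C9_undetected_breech",
}


def params_to_dict(params: ModelParameters) -> dict:
    d: dict = {"probabilities": {}, "mod": {}, "costs": {}, "mortality": {}, "econ": {}}
    for name, key in _PROB_KEYS.items():
        ec: EventCount = getattr(params, name)
        d["probabilities"][key] = {"events": ec.events, "non_events": ec.non_events}
    for name, key in _MOD_KEYS.items():
        mc: ModCounts = getattr(params, name)
        entry = dict(
            zip(
                MOD_CATEGORIES,
                [int(c) if float(c).is_integer() else float(c) for c in mc.counts],
            )
        )
        entry["context"] = mc.context
        d["mod"][key] = entry
    d["costs"] = dataclasses.asdict(params.costs)
    d["mortality"] = dataclasses.asdict(params.mortality)
    econ = dataclasses.asdict(params.econ)
    econ["wtp_thresholds"] = list(econ["wtp_thresholds"])
    d["econ"] = econ
    return d


def params_from_dict(d: dict) -> ModelParameters:
    kwargs: dict = {}
    for name, key in _PROB_KEYS.items():
        if key in d.get("probabilities", {}):
            entry = d["probabilities"][key]
            kwargs[name] = EventCount(entry["events"], entry["non_events"])
    for name, key in _MOD_KEYS.items():
        if key in d.get("mod", {}):
            entry = dict(d["mod"][key])
            context = entry.pop("context")
            kwargs[name] = ModCounts(tuple(entry[c] for c in MOD_CATEGORIES), context)
    if "costs" in d:
        kwargs["costs"] = CostSchedule(**d["costs"])
    if "mortality" in d:
        kwargs["mortality"] = MortalitySchedule(**d["mortality"])
    if "econ" in d:
        econ = dict(d["econ"])
        if "wtp_thresholds" in econ:
            econ["wtp_thresholds"] = tuple(econ["wtp_thresholds"])
        kwargs["econ"] = EconSettings(**econ)
    return ModelParameters(**kwargs)


def save_parameters(path, params: ModelParameters) -> None:
    """Write parameters to YAML (default) or JSON, by file suffix."""
    path = Path(path)
    d = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_parameters(path) -> ModelParameters:
    """Read parameters from a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return params_from_dict(d)
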