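"""Food-web data model for benthic carbon-flow inverse modelling.

A food web is described by compartments (living and non-living carbon
stocks), directed flows between them, a site environment (temperature and
the field-measured bounds on community respiration and particulate carbon
deposition), and a set of physiological rate rules. All stocks are in
mmol C m^-2 and all flows in mmol C m^-2 d^-1.

Compartments are either *internal* (their carbon budget is balanced at
steady state) or *external* (unbounded sources/sinks such as the water
column or mobile predators). The standard benthic web distinguishes
detritus (Det), dissolved organic carbon (DOC), heterotrophic and
chemosynthetic bacteria (Bac, ChBac), four macrofaunal feeding guilds
(MacES, MacDF, MacSF, MacPS) and two megafaunal guilds (MegDF, MegSF),
plus the externals Det_w, DOC_w, DIC, Det_s and Predation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .errors import ModelValidationError

INTERNAL = "internal"
EXTERNAL = "external"

TAXON_CLASSES = frozenset({"detritus", "dissolved", "bacteria", "macrofauna", "megafauna"})
FEEDING_MODES = frozenset(
    {"deposit", "suspension", "predation", "symbiont_fixation", "heterotrophy", "chemoautotrophy"}
)

#: External compartment that carries community respiration (flows into it are
#: respiratory losses); external sources/sinks recognised by the default
#: topology rules.
DIC_ID = "DIC"
WATER_DETRITUS_ID = "Det_w"
BURIAL_ID = "Det_s"
WATER_DOC_ID = "DOC_w"
PREDATION_ID = "Predation"


@dataclass(frozen=True)
class Compartment:
    """One carbon stock.

    ``biomass`` is required for internal bacteria, macrofauna and megafauna
    (it feeds the biomass-dependent physiological constraints) and must be
    absent for externals. ``d13c_mean``/``d13c_sd`` are per-mil vs VPDB and
    optional; compartments without isotope data simply contribute no diet
    constraints.
    """

    id: str
    name: str
    locality: str = INTERNAL
    taxon_class: str = "detritus"
    biomass: float | None = None
    d13c_mean: float | None = None
    d13c_sd: float | None = None
    feeding_modes: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.locality not in (INTERNAL, EXTERNAL):
            raise ModelValidationError(
                f"compartment {self.id!r}: locality must be internal or external, got {self.locality!r}"
            )
        if self.taxon_class not in TAXON_CLASSES:
            raise ModelValidationError(
                f"compartment {self.id!r}: unknown taxon_class {self.taxon_class!r}"
            )
        unknown = set(self.feeding_modes) - FEEDING_MODES
        if unknown:
            raise ModelValidationError(
                f"compartment {self.id!r}: unknown feeding modes {sorted(unknown)}"
            )
        if self.locality == EXTERNAL and self.biomass is not None:
            raise ModelValidationError(
                f"external compartment {self.id!r} must not carry biomass"
            )
        if (
            self.locality == INTERNAL
            and self.taxon_class in ("bacteria", "macrofauna", "megafauna")
            and self.biomass is not None
            and self.biomass <= 0
        ):
            raise ModelValidationError(
                f"compartment {self.id!r}: biomass must be > 0, got {self.biomass}"
            )

    @property
    def is_internal(self) -> bool:
        return self.locality == INTERNAL

    @property
    def is_fauna(self) -> bool:
        return self.taxon_class in ("macrofauna", "megafauna")

    @property
    def is_symbiont_bearer(self) -> bool:
        """True for fauna fed exclusively by endosymbiont carbon fixation."""
        return self.is_fauna and self.feeding_modes == frozenset({"symbiont_fixation"})


@dataclass
class SiteEnvironment:
    """Site-level measurements used as model bounds.

    ``scoc_range`` bounds total community respiration (sediment community
    oxygen consumption in carbon units); ``poc_range`` bounds direct
    particulate organic-carbon deposition. ``substrate_conc`` (chemical name
    to umol/l) is carried as metadata only.
    """

    site_id: str
    depth: float
    temperature: float
    scoc_range: tuple[float, float] | None = None
    poc_range: tuple[float, float] | None = None
    advection: float | None = None
    substrate_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not -2.0 <= self.temperature <= 100.0:
            raise ModelValidationError(
                f"site {self.site_id!r}: temperature {self.temperature} outside [-2, 100] degC"
            )
        for label, rng in (("scoc_range", self.scoc_range), ("poc_range", self.poc_range)):
            if rng is not None:
                lo, hi = rng
                if lo > hi:
                    raise ModelValidationError(f"site {self.site_id!r}: {label} has lo > hi")


def _check_range(name: str, rng: tuple[float, float], hi_cap: float = 10.0) -> None:
    lo, hi = rng
    if not (lo <= hi and 0.0 <= lo and hi <= hi_cap):
        raise ModelValidationError(f"rule {name!r}: range {rng} invalid (need 0 <= lo <= hi <= {hi_cap})")


@dataclass(frozen=True)
class TaxonClassRules:
    """Biomass-scaled physiology for one faunal class.

    All efficiencies are dimensionless fractions; ``growth_coeff_range``
    bounds secondary production per unit biomass per day (before temperature
    scaling); ``maintenance_coeff`` is the minimum respiration per unit
    biomass per day; ``biomass_specific_respiration`` (d^-1) anchors the
    respiration window ``respiration_multiplier_range``.
    """

    growth_coeff_range: tuple[float, float]
    nge_range: tuple[float, float]
    ae_range: tuple[float, float]
    faecal_range: tuple[float, float]
    maintenance_coeff: float
    respiration_multiplier_range: tuple[float, float]
    biomass_specific_respiration: float

    def __post_init__(self):
        _check_range("growth_coeff_range", self.growth_coeff_range)
        _check_range("nge_range", self.nge_range)
        _check_range("ae_range", self.ae_range)
        _check_range("faecal_range", self.faecal_range)
        _check_range("respiration_multiplier_range", self.respiration_multiplier_range)
        if self.maintenance_coeff < 0 or self.biomass_specific_respiration <= 0:
            raise ModelValidationError("maintenance/biomass-specific respiration must be positive")


@dataclass(frozen=True)
class PhysiologyRules:
    """Rate rules applied when compiling physiological constraints.

    Defaults are the conventional deep-sea ranges: bacterial growth
    efficiency 0.05-0.45, viral lysis returning 30-80% of bacterial
    production to detritus, chemosynthetic fixation efficiency 0.10-0.50,
    burial of 1-3% of gross organic-matter input, DOC efflux of at most 10%
    of community respiration, and a Q10 of 2 for temperature scaling.
    """

    q10: float = 2.0
    bge_range: tuple[float, float] = (0.05, 0.45)
    viral_lysis_range: tuple[float, float] = (0.30, 0.80)
    chemo_efficiency_range: tuple[float, float] = (0.10, 0.50)
    burial_efficiency_range: tuple[float, float] = (0.01, 0.03)
    doc_efflux_range: tuple[float, float] = (0.0, 0.1)
    macrofauna: TaxonClassRules = TaxonClassRules(
        growth_coeff_range=(0.01, 0.05),
        nge_range=(0.30, 0.70),
        ae_range=(0.20, 0.75),
        faecal_range=(0.25, 0.80),
        maintenance_coeff=0.01,
        respiration_multiplier_range=(0.5, 1.5),
        biomass_specific_respiration=0.01,
    )
    megafauna: TaxonClassRules = TaxonClassRules(
        growth_coeff_range=(0.0027, 0.014),
        nge_range=(0.50, 0.70),
        ae_range=(0.20, 0.75),
        faecal_range=(0.25, 0.80),
        maintenance_coeff=0.001,
        respiration_multiplier_range=(0.5, 1.5),
        biomass_specific_respiration=0.01,
    )

    def __post_init__(self):
        if self.q10 <= 0:
            raise ModelValidationError(f"q10 must be > 0, got {self.q10}")
        for name in ("bge_range", "viral_lysis_range", "chemo_efficiency_range",
                     "burial_efficiency_range", "doc_efflux_range"):
            _check_range(name, getattr(self, name))

    def for_class(self, taxon_class: str) -> TaxonClassRules:
        if taxon_class == "macrofauna":
            return self.macrofauna
        if taxon_class == "megafauna":
            return self.megafauna
        raise KeyError(taxon_class)


def temperature_limitation(q10: float, temperature_c: float, mode: str = "exact") -> float:
    """Temperature scaling factor Tlim = q10 ** ((T - 20) / 10).

    Equals 1 at 20 degC for every q10 and is strictly increasing in T for
    q10 > 1. ``mode="rounded"`` rounds to one decimal, reproducing the
    coarse constants (0.2 at -1 degC, 1.3 at 24 degC, 7.0 at 48 degC for
    q10 = 2) sometimes used in tabulated model set-ups.
    """
    if q10 <= 0:
        raise ValueError(f"q10 must be > 0, got {q10}")
    tlim = q10 ** ((temperature_c - 20.0) / 10.0)
    if mode == "rounded":
        return round(tlim, 1)
    if mode != "exact":
        raise ValueError(f"unknown Tlim mode {mode!r}")
    return tlim


@dataclass(frozen=True)
class Flow:
    """A directed carbon flow; ``index`` is its position in the flow vector."""

    index: int
    source: str
    sink: str

    @property
    def label(self) -> str:
        return f"{self.source}->{self.sink}"


# Linear constraint contributed through a model file's CONSTRAINTS section:
# (coefficients keyed by flow label, operator '=', '>' or '<', right-hand side).
ExtraConstraint = tuple[dict[str, float], str, float]


@dataclass
class FoodWebModel:
    """A validated food-web model ready for constraint compilation."""

    compartments: list[Compartment]
    flows: list[Flow]
    environment: SiteEnvironment | None = None
    rules: PhysiologyRules = field(default_factory=PhysiologyRules)
    extra_constraints: list[ExtraConstraint] = field(default_factory=list)

    def __post_init__(self):
        self._by_id = {c.id: c for c in self.compartments}
        if len(self._by_id) != len(self.compartments):
            dupes = [c for c, n in _counts(c.id for c in self.compartments).items() if n > 1]
            raise ModelValidationError(f"duplicate compartment ids: {dupes}")
        self._validate()

    # -- lookups ---------------------------------------------------------

    def compartment(self, comp_id: str) -> Compartment:
        return self._by_id[comp_id]

    def has_compartment(self, comp_id: str) -> bool:
        return comp_id in self._by_id

    @property
    def internal(self) -> list[Compartment]:
        return [c for c in self.compartments if c.is_internal]

    @property
    def flow_labels(self) -> list[str]:
        return [f.label for f in self.flows]

    @property
    def n_flows(self) -> int:
        return len(self.flows)

    def flow_index(self, label: str) -> int:
        try:
            return self._label_index[label]
        except AttributeError:
            self._label_index = {f.label: f.index for f in self.flows}
            return self._label_index[label]

    def has_flow(self, label: str) -> bool:
        try:
            self.flow_index(label)
            return True
        except KeyError:
            return False

    def flows_into(self, comp_id: str) -> list[Flow]:
        return [f for f in self.flows if f.sink == comp_id]

    def flows_out_of(self, comp_id: str) -> list[Flow]:
        return [f for f in self.flows if f.source == comp_id]

    def feeding_inflows(self, comp_id: str) -> list[Flow]:
        """Inflows that represent feeding (everything except DIC fixation)."""
        return [f for f in self.flows_into(comp_id) if f.source != DIC_ID]

    def respiration_flow(self, comp_id: str) -> Flow | None:
        for f in self.flows_out_of(comp_id):
            if f.sink == DIC_ID:
                return f
        return None

    def production_outflows(self, comp_id: str) -> list[Flow]:
        """Flows carrying secondary production: to consumers or external predators."""
        out = []
        for f in self.flows_out_of(comp_id):
            if f.sink == PREDATION_ID:
                out.append(f)
            elif self.has_compartment(f.sink) and self.compartment(f.sink).is_fauna:
                out.append(f)
        return out

    def tlim(self, mode: str = "exact") -> float:
        if self.environment is None:
            raise ModelValidationError("model has no site environment")
        return temperature_limitation(self.rules.q10, self.environment.temperature, mode)

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        labels = set()
        for f in self.flows:
            if f.source == f.sink:
                raise ModelValidationError(f"flow {f.label!r} is a self-loop")
            for end in (f.source, f.sink):
                if end not in self._by_id:
                    raise ModelValidationError(
                        f"flow {f.label!r} references undeclared compartment {end!r}"
                    )
            if not (self._by_id[f.source].is_internal or self._by_id[f.sink].is_internal):
                raise ModelValidationError(
                    f"flow {f.label!r} connects two external compartments"
                )
            if f.label in labels:
                raise ModelValidationError(f"duplicate flow {f.label!r}")
            labels.add(f.label)
        for c in self.internal:
            if not any(f.sink == c.id for f in self.flows):
                raise ModelValidationError(f"internal compartment {c.id!r} has no inflow")
            if not any(f.source == c.id for f in self.flows):
                raise ModelValidationError(f"internal compartment {c.id!r} has no outflow")

    def with_environment(self, environment: SiteEnvironment) -> "FoodWebModel":
        return replace(self, environment=environment)


def _counts(items) -> dict:
    out: dict = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


# ----------------------------------------------------------------------
# Default topology rules
# ----------------------------------------------------------------------

# Edge recipe used when no explicit flow list is supplied. Keyed on the
# standard compartment ids; each edge is emitted only when both endpoints
# are present. Water-column detritus feeds the sediment pool and suspension
# feeders; sediment detritus feeds microbes, the DOC pool, burial and
# deposit feeders; bacterial carbon is grazed by macrofaunal deposit feeders
# and predators; every living internal respires to DIC and sheds detritus;
# non-predatory macrofauna are eaten by macrofaunal predators; all fauna
# except symbiont-bearers are exposed to external (megafaunal/fish) predation.
_DEFAULT_EDGES: list[tuple[str, str]] = [
    ("Det_w", "Det"), ("Det_w", "MacSF"), ("Det_w", "MegSF"),
    ("Det", "Bac"), ("Det", "DOC"), ("Det", "Det_s"), ("Det", "MacDF"), ("Det", "MegDF"),
    ("DOC", "Bac"), ("DOC", "DOC_w"),
    ("DIC", "ChBac"), ("DIC", "MacES"),
    ("Bac", "DIC"), ("Bac", "Det"), ("Bac", "MacDF"), ("Bac", "MacPS"),
    ("ChBac", "DIC"), ("ChBac", "Det"), ("ChBac", "MacDF"),
    ("MacES", "DIC"), ("MacES", "Det"), ("MacES", "MacPS"),
    ("MacDF", "DIC"), ("MacDF", "Det"), ("MacDF", "MacPS"), ("MacDF", "Predation"),
    ("MacSF", "DIC"), ("MacSF", "Det"), ("MacSF", "MacPS"), ("MacSF", "Predation"),
    ("MacPS", "DIC"), ("MacPS", "Det"), ("MacPS", "Predation"),
    ("MegDF", "DIC"), ("MegDF", "Det"), ("MegDF", "Predation"),
    ("MegSF", "DIC"), ("MegSF", "Det"), ("MegSF", "Predation"),
]


def default_flow_list(compartment_ids: set[str]) -> list[tuple[str, str]]:
    """Default edges restricted to the compartments actually present."""
    return [(s, t) for s, t in _DEFAULT_EDGES if s in compartment_ids and t in compartment_ids]


def build_topology(
    compartments: list[Compartment],
    site_absences: set[str] | frozenset[str] = frozenset(),
    flow_list: list[tuple[str, str]] | None = None,
    environment: SiteEnvironment | None = None,
    rules: PhysiologyRules | None = None,
    extra_constraints: list[ExtraConstraint] | None = None,
) -> FoodWebModel:
    """Assemble and validate a :class:`FoodWebModel`.

    ``site_absences`` removes compartments (and every flow touching them)
    before validation, mirroring guilds missing from a given site. When
    ``flow_list`` is omitted the default edge recipe is applied; that
    recipe is written in terms of the standard compartment ids, so models
    with non-standard ids must pass an explicit ``flow_list``.
    """
    if not compartments:
        raise ModelValidationError("compartment list is empty")
    present = [c for c in compartments if c.id not in site_absences]
    present_ids = {c.id for c in present}
    if flow_list is None:
        flow_list = default_flow_list(present_ids)
        if not flow_list:
            raise ModelValidationError(
                "no default edges apply to these compartment ids; pass an explicit flow_list"
            )
    else:
        flow_list = [(s, t) for s, t in flow_list if s not in site_absences and t not in site_absences]
    flows = [Flow(i, s, t) for i, (s, t) in enumerate(flow_list)]
    return FoodWebModel(
        compartments=present,
        flows=flows,
        environment=environment,
        rules=rules if rules is not None else PhysiologyRules(),
        extra_constraints=list(extra_constraints or []),
    )
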