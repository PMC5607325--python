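"""Compile a food-web model into a linear constraint system.

The unknown is the flow vector x (one coordinate per directed flow, in
mmol C m^-2 d^-1). Compilation emits equality rows ``E x = f`` (steady-state
mass balance of every internal compartment) and inequality rows
``G x >= h`` (physiological rate windows, isotope diet bounds, site-level
bounds, nonnegativity). Every row carries a provenance tag so infeasibility
certificates and provenance-diff tests can name the rule behind a row.

Notation used for a faunal compartment c:
    I  = total feeding ingestion (all inflows except DIC fixation)
    Fe = flow c->Det (egesta plus other detritus production)
    R  = flow c->DIC (respiration)
    P  = flows to consumers and to external predation (secondary production)
with assimilation A = I - Fe; at steady state I = Fe + R + P.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CompileError, ModelValidationError
from .model import (
    DIC_ID,
    WATER_DETRITUS_ID,
    BURIAL_ID,
    WATER_DOC_ID,
    FoodWebModel,
)

_ZERO_TOL = 1e-12


@dataclass
class ConstraintSystem:
    """Equalities ``E x = f`` and inequalities ``G x >= h`` over labelled flows."""

    E: np.ndarray
    f: np.ndarray
    G: np.ndarray
    h: np.ndarray
    flow_labels: list[str]
    eq_provenance: list[str] = field(default_factory=list)
    ineq_provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.flow_labels)
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float)).reshape(-1, n) if np.size(self.E) else np.zeros((0, n))
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float)).reshape(-1, n) if np.size(self.G) else np.zeros((0, n))
        self.f = np.asarray(self.f, dtype=float).ravel()
        self.h = np.asarray(self.h, dtype=float).ravel()
        if self.E.shape[0] != self.f.size or self.G.shape[0] != self.h.size:
            raise CompileError("row/rhs dimension mismatch")
        if len(self.eq_provenance) != self.E.shape[0] or len(self.ineq_provenance) != self.G.shape[0]:
            raise CompileError("provenance length mismatch")
        for M, which in ((self.E, "equality"), (self.G, "inequality")):
            if M.shape[0] and np.any(np.abs(M).max(axis=1) <= _ZERO_TOL):
                raise CompileError(f"{which} row with all-zero coefficients")

    @property
    def n_flows(self) -> int:
        return len(self.flow_labels)

    @property
    def row_provenance(self) -> list[str]:
        return list(self.eq_provenance) + list(self.ineq_provenance)

    def residuals(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(equality residuals E x - f, inequality slacks G x - h)."""
        x = np.asarray(x, dtype=float)
        return self.E @ x.T - (self.f[:, None] if x.ndim > 1 else self.f), \
               self.G @ x.T - (self.h[:, None] if x.ndim > 1 else self.h)

    def satisfied_by(self, x: np.ndarray, tol: float = 1e-8) -> bool:
        eq, ineq = self.residuals(x)
        ok = True
        if eq.size:
            ok &= bool(np.max(np.abs(eq)) <= tol)
        if ineq.size:
            ok &= bool(np.min(ineq) >= -tol)
        return ok


@dataclass
class Row:
    """One linear row under construction: ``coeffs . x (op) rhs``."""

    coeffs: dict[str, float]
    rhs: float
    tag: str


def _expr(*terms: tuple[float, str | None]) -> dict[str, float]:
    """Sum coefficient/label terms into a sparse expression; None labels are skipped."""
    out: dict[str, float] = {}
    for coef, label in terms:
        if label is None or coef == 0.0:
            continue
        out[label] = out.get(label, 0.0) + coef
    return out


def _sum_labels(labels: list[str], coef: float = 1.0) -> dict[str, float]:
    out: dict[str, float] = {}
    for lab in labels:
        out[lab] = out.get(lab, 0.0) + coef
    return out


def _combine(*exprs_scaled: tuple[float, dict[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for scale, expr in exprs_scaled:
        for lab, coef in expr.items():
            out[lab] = out.get(lab, 0.0) + scale * coef
    return out


def _range_rows(expr: dict[str, float], lo_expr: dict[str, float] | float,
                hi_expr: dict[str, float] | float, tag: str) -> list[Row]:
    """Rows for ``lo <= expr <= hi`` where the bounds may themselves be linear."""
    rows = []
    if isinstance(lo_expr, dict):
        rows.append(Row(_combine((1.0, expr), (-1.0, lo_expr)), 0.0, tag))
    else:
        rows.append(Row(dict(expr), float(lo_expr), tag))
    if isinstance(hi_expr, dict):
        rows.append(Row(_combine((1.0, hi_expr), (-1.0, expr)), 0.0, tag))
    else:
        rows.append(Row({k: -v for k, v in expr.items()}, -float(hi_expr), tag))
    return rows


def _filter_rows(rows: list[Row]) -> list[Row]:
    """Drop rows whose coefficients cancelled to zero; reject impossible ones."""
    kept = []
    for r in rows:
        coeffs = {k: v for k, v in r.coeffs.items() if abs(v) > _ZERO_TOL}
        if not coeffs:
            if r.rhs > _ZERO_TOL:
                raise CompileError(
                    f"row {r.tag!r} requires 0 >= {r.rhs}; the model topology is missing a flow "
                    "this rule needs"
                )
            continue
        kept.append(Row(coeffs, r.rhs, r.tag))
    return kept


# ----------------------------------------------------------------------
# Sub-compilers
# ----------------------------------------------------------------------

def compile_mass_balance(model: FoodWebModel) -> list[Row]:
    """One steady-state row per internal compartment: inflows - outflows = 0."""
    internals = model.internal
    if not internals:
        raise CompileError("model has no internal compartments")
    rows = []
    for c in internals:
        coeffs = _combine(
            (1.0, _sum_labels([fl.label for fl in model.flows_into(c.id)])),
            (-1.0, _sum_labels([fl.label for fl in model.flows_out_of(c.id)])),
        )
        rows.append(Row(coeffs, 0.0, f"mass_balance:{c.id}"))
    return rows


def compile_physiological_constraints(model: FoodWebModel, tlim_mode: str = "exact") -> list[Row]:
    """Rate-window rows for every living internal compartment.

    Fauna get assimilation-efficiency, faecal, net-growth-efficiency,
    growth, maintenance and respiration-window rows (symbiont-bearers get a
    chemosynthetic fixation-efficiency row instead of the ingestion-based
    ones). Heterotrophic bacteria get growth-efficiency and viral-lysis
    rows; chemoautotrophic bacteria get fixation-efficiency and lysis rows.
    Bacterial respiration carries no biomass-dependent bounds.
    """
    tlim = model.tlim(tlim_mode)
    if tlim <= 0:
        raise CompileError(f"temperature limitation factor is {tlim}; must be > 0")
    rules = model.rules
    rows: list[Row] = []

    for c in model.internal:
        if c.taxon_class == "bacteria":
            r_flow = model.respiration_flow(c.id)
            if r_flow is None:
                raise CompileError(f"bacterial compartment {c.id!r} has no respiration flow")
            R = _expr((1.0, r_flow.label))
            uptake = _sum_labels([fl.label for fl in model.feeding_inflows(c.id)])
            fixation = _sum_labels(
                [fl.label for fl in model.flows_into(c.id) if fl.source == DIC_ID]
            )
            if "chemoautotrophy" in c.feeding_modes or (fixation and not uptake):
                lo, hi = rules.chemo_efficiency_range
                prod = _combine((1.0, fixation), (-1.0, R))
                rows += _range_rows(
                    prod,
                    _combine((lo, fixation)),
                    _combine((hi, fixation)),
                    f"physiology:chemo_efficiency:{c.id}",
                )
            else:
                lo, hi = rules.bge_range
                prod = _combine((1.0, uptake), (-1.0, R))
                rows += _range_rows(
                    prod,
                    _combine((lo, uptake)),
                    _combine((hi, uptake)),
                    f"physiology:bge:{c.id}",
                )
            lys_lo, lys_hi = rules.viral_lysis_range
            lysis = _sum_labels(
                [fl.label for fl in model.flows_out_of(c.id) if fl.sink == "Det"]
            )
            if lysis:
                rows += _range_rows(
                    lysis,
                    _combine((lys_lo, prod)),
                    _combine((lys_hi, prod)),
                    f"physiology:viral_lysis:{c.id}",
                )
            continue

        if not c.is_fauna:
            continue

        if c.biomass is None:
            raise CompileError(f"faunal compartment {c.id!r} has no biomass")
        cls = rules.for_class(c.taxon_class)
        B = c.biomass
        r_flow = model.respiration_flow(c.id)
        if r_flow is None:
            raise CompileError(f"faunal compartment {c.id!r} has no respiration flow")
        R = _expr((1.0, r_flow.label))
        P = _sum_labels([fl.label for fl in model.production_outflows(c.id)])

        if c.is_symbiont_bearer:
            fixation = _sum_labels(
                [fl.label for fl in model.flows_into(c.id) if fl.source == DIC_ID]
            )
            if not fixation:
                raise CompileError(f"symbiont-bearing {c.id!r} has no DIC fixation inflow")
            lo, hi = rules.chemo_efficiency_range
            fixed_om = _combine((1.0, fixation), (-1.0, R))
            rows += _range_rows(
                fixed_om,
                _combine((lo, fixation)),
                _combine((hi, fixation)),
                f"physiology:chemo_efficiency:{c.id}",
            )
        else:
            ingest = _sum_labels([fl.label for fl in model.feeding_inflows(c.id)])
            faeces = _sum_labels(
                [fl.label for fl in model.flows_out_of(c.id) if fl.sink == "Det"]
            )
            assim = _combine((1.0, ingest), (-1.0, faeces))
            ae_lo, ae_hi = cls.ae_range
            rows += _range_rows(
                assim, _combine((ae_lo, ingest)), _combine((ae_hi, ingest)),
                f"physiology:assimilation_efficiency:{c.id}",
            )
            f_lo, f_hi = cls.faecal_range
            rows += _range_rows(
                faeces, _combine((f_lo, ingest)), _combine((f_hi, ingest)),
                f"physiology:faecal_production:{c.id}",
            )
            nge_lo, nge_hi = cls.nge_range
            rows += _range_rows(
                P, _combine((nge_lo, assim)), _combine((nge_hi, assim)),
                f"physiology:nge:{c.id}",
            )

        g_lo, g_hi = cls.growth_coeff_range
        rows += _range_rows(P, g_lo * tlim * B, g_hi * tlim * B, f"physiology:growth:{c.id} [Tlim]")
        rows.append(Row(dict(R), cls.maintenance_coeff * tlim * B,
                        f"physiology:maintenance_respiration:{c.id} [Tlim]"))
        m_lo, m_hi = cls.respiration_multiplier_range
        bsr = cls.biomass_specific_respiration
        rows += _range_rows(R, m_lo * B * bsr * tlim, m_hi * B * bsr * tlim,
                            f"physiology:respiration_window:{c.id} [Tlim]")

    return _filter_rows(rows)


def compile_isotope_constraints(
    model: FoodWebModel, discrimination: float = 1.0, tolerance_sd: float = 2.0
) -> list[Row]:
    """Linear diet-mixing rows from carbon stable-isotope signatures.

    For a consumer j with tissue signature delta_j +/- sd_j and food sources
    i with signatures delta_i, the flow-weighted mixture of source
    signatures plus one trophic discrimination step Delta must reproduce the
    consumer signature within k standard deviations:

        | sum_i f_ij (delta_i + Delta - delta_j) | <= k * sd_j * sum_i f_ij

    which is linear in the flows. Consumers without isotope data, or with a
    food source lacking a mean signature, contribute no rows. Compartments
    fed only by symbiont fixation are not diet consumers.
    """
    rows: list[Row] = []
    k = tolerance_sd
    for c in model.internal:
        if c.taxon_class not in ("bacteria", "macrofauna", "megafauna"):
            continue
        if c.is_symbiont_bearer or "chemoautotrophy" in c.feeding_modes:
            continue
        if c.d13c_mean is None or c.d13c_sd is None:
            continue
        inflows = model.feeding_inflows(c.id)
        if not inflows:
            raise CompileError(
                f"consumer {c.id!r} has isotope data but no potential food flows"
            )
        source_means = {}
        for fl in inflows:
            src = model.compartment(fl.source)
            if src.d13c_mean is None:
                source_means = None
                break
            source_means[fl.label] = src.d13c_mean
        if source_means is None:
            continue
        lower = {}
        upper = {}
        for fl in inflows:
            mis = source_means[fl.label] + discrimination - c.d13c_mean
            lower[fl.label] = mis + k * c.d13c_sd
            upper[fl.label] = -(mis - k * c.d13c_sd)
        rows.append(Row(lower, 0.0, f"isotope:{c.id}"))
        rows.append(Row(upper, 0.0, f"isotope:{c.id}"))
    return _filter_rows(rows)


def compile_site_constraints(model: FoodWebModel) -> list[Row]:
    """Site-level rows: POC deposition, SCOC, relative DOC efflux and burial.

    Total respiration (the sum of every flow into DIC from an internal
    compartment) is bounded by the measured sediment community oxygen
    consumption range; direct deposition Det_w->Det by the POC flux range;
    DOC export to the water column by a fraction of total respiration; and
    burial Det->Det_s by a small fraction of gross organic-matter input
    (deposition + gross suspension feeding + gross chemosynthetic fixation).
    """
    env = model.environment
    if env is None:
        raise CompileError("model has no site environment")
    if env.scoc_range is None:
        raise CompileError(f"site {env.site_id!r}: scoc_range is required")
    if env.poc_range is None:
        raise CompileError(f"site {env.site_id!r}: poc_range is required")

    rows: list[Row] = []
    internal_ids = {c.id for c in model.internal}

    poc_label = f"{WATER_DETRITUS_ID}->Det"
    if not model.has_flow(poc_label):
        raise CompileError(f"site constraints need the deposition flow {poc_label!r}")
    rows += _range_rows(_expr((1.0, poc_label)), env.poc_range[0], env.poc_range[1], "poc")

    respiration = _sum_labels(
        [fl.label for fl in model.flows if fl.sink == DIC_ID and fl.source in internal_ids]
    )
    if not respiration:
        raise CompileError("no respiration flows (x->DIC) to bound by SCOC")
    rows += _range_rows(respiration, env.scoc_range[0], env.scoc_range[1], "scoc")

    efflux_label = f"DOC->{WATER_DOC_ID}"
    if model.has_flow(efflux_label):
        lo, hi = model.rules.doc_efflux_range
        rows += _range_rows(
            _expr((1.0, efflux_label)),
            _combine((lo, respiration)),
            _combine((hi, respiration)),
            "doc_efflux",
        )

    burial_label = f"Det->{BURIAL_ID}"
    if model.has_flow(burial_label):
        gross = _sum_labels(
            [fl.label for fl in model.flows
             if fl.source in (WATER_DETRITUS_ID, DIC_ID) and fl.sink in internal_ids]
        )
        b_lo, b_hi = model.rules.burial_efficiency_range
        rows += _range_rows(
            _expr((1.0, burial_label)),
            _combine((b_lo, gross)),
            _combine((b_hi, gross)),
            "burial",
        )
    return _filter_rows(rows)


def _extra_rows(model: FoodWebModel) -> tuple[list[Row], list[Row]]:
    eq, ineq = [], []
    for i, (coeffs, op, rhs) in enumerate(model.extra_constraints):
        for lab in coeffs:
            if not model.has_flow(lab):
                raise CompileError(f"custom constraint references unknown flow {lab!r}")
        tag = f"custom:{i}"
        if op == "=":
            eq.append(Row(dict(coeffs), rhs, tag))
        elif op == ">":
            ineq.append(Row(dict(coeffs), rhs, tag))
        elif op == "<":
            ineq.append(Row({k: -v for k, v in coeffs.items()}, -rhs, tag))
        else:
            raise CompileError(f"custom constraint operator {op!r} not one of = < >")
    return eq, ineq


@dataclass(frozen=True)
class IsotopeOptions:
    """Trophic discrimination Delta (per mil) and tolerance in consumer SDs."""

    discrimination: float = 1.0
    tolerance_sd: float = 2.0
    enabled: bool = True


def compile(
    model: FoodWebModel,
    isotope_options: IsotopeOptions | None = None,
    tlim_mode: str = "exact",
    include_physiology: bool = True,
    include_site: bool = True,
) -> ConstraintSystem:
    """Compile the full constraint system for a model.

    Deterministic: the same model always yields the identical system. The
    ``include_*`` switches exist so callers can build reduced systems (for
    example a biomass-free polytope for synthetic-data generation).
    """
    iso = isotope_options or IsotopeOptions()
    eq_rows = compile_mass_balance(model)
    ineq_rows: list[Row] = []
    if include_physiology:
        ineq_rows += compile_physiological_constraints(model, tlim_mode=tlim_mode)
    if iso.enabled:
        ineq_rows += compile_isotope_constraints(model, iso.discrimination, iso.tolerance_sd)
    if include_site:
        ineq_rows += compile_site_constraints(model)
    extra_eq, extra_ineq = _extra_rows(model)
    eq_rows += extra_eq
    ineq_rows += extra_ineq
    for lab in model.flow_labels:
        ineq_rows.append(Row({lab: 1.0}, 0.0, f"nonnegativity:{lab}"))
    return rows_to_system(model.flow_labels, eq_rows, ineq_rows)


def rows_to_system(flow_labels: list[str], eq_rows: list[Row], ineq_rows: list[Row]) -> ConstraintSystem:
    """Assemble row lists into dense arrays, checking label validity."""
    index = {lab: i for i, lab in enumerate(flow_labels)}
    n = len(flow_labels)

    def densify(rows: list[Row]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        M = np.zeros((len(rows), n))
        rhs = np.zeros(len(rows))
        tags = []
        for i, r in enumerate(rows):
            for lab, coef in r.coeffs.items():
                try:
                    M[i, index[lab]] = coef
                except KeyError:
                    raise CompileError(f"row {r.tag!r} references undeclared flow {lab!r}")
            rhs[i] = r.rhs
            tags.append(r.tag)
        return M, rhs, tags

    E, f, eq_tags = densify(eq_rows)
    G, h, ineq_tags = densify(ineq_rows)
    return ConstraintSystem(E, f, G, h, list(flow_labels), eq_tags, ineq_tags)
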