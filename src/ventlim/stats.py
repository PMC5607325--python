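"""Reduce flow ensembles to reported quantities.

Covers per-flow mean/SD/coefficient-of-variation summaries, the
fraction-of-solutions significance procedure (two ensembles are compared by
the fraction of cross pairs in which one exceeds the other; >95% is
significant, >98% highly significant), percentage diet compositions, and
the organic-matter budget partition (gross and net inputs, respiration by
compartment class, detritus production, burial, DOC efflux and external
predation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import VentlimError
from .model import DIC_ID, PREDATION_ID, WATER_DETRITUS_ID, BURIAL_ID, WATER_DOC_ID, FoodWebModel
from .sample import FlowEnsemble

SIGNIFICANT = 0.95
HIGHLY_SIGNIFICANT = 0.98


@dataclass
class EnsembleSummary:
    flow_labels: list[str]
    mean: np.ndarray
    sd: np.ndarray
    cov: np.ndarray          # nan where undefined (mean == 0)
    cov_undefined: np.ndarray
    n_cov_ge_1: int
    n_cov_lt_05: int
    n_cov_lt_02: int


def ensemble_summary(ensemble: FlowEnsemble) -> EnsembleSummary:
    """Per-flow sample mean, sample SD (n-1) and CoV = SD / |mean|.

    A flow whose ensemble mean is zero has no defined CoV; it is flagged
    rather than reported as infinite, and excluded from the CoV bins.
    """
    X = ensemble.samples
    if X.shape[0] < 2:
        raise VentlimError("ensemble_summary needs at least 2 solutions")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    undefined = np.abs(mean) <= 1e-12
    cov = np.full(mean.shape, np.nan)
    cov[~undefined] = sd[~undefined] / np.abs(mean[~undefined])
    defined = cov[~undefined]
    return EnsembleSummary(
        flow_labels=list(ensemble.flow_labels),
        mean=mean,
        sd=sd,
        cov=cov,
        cov_undefined=undefined,
        n_cov_ge_1=int((defined >= 1.0).sum()),
        n_cov_lt_05=int((defined < 0.5).sum()),
        n_cov_lt_02=int((defined < 0.2).sum()),
    )


@dataclass
class ComparisonResult:
    label: str
    fraction_greater: float
    verdict: str  # none | significant | highly_significant


def fraction_greater(
    values_a: np.ndarray,
    values_b: np.ndarray,
    label: str = "",
    seed: int = 0,
    max_pairs: int = 10_000_000,
) -> ComparisonResult:
    """Fraction of cross pairs (a, b) with a strictly greater than b.

    Exhaustive over all |A| x |B| pairs when that product is small enough,
    otherwise seeded Monte-Carlo pairing. Ties count as not greater.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise VentlimError("fraction_greater needs non-empty ensembles")
    if a.size * b.size <= max_pairs:
        b_sorted = np.sort(b)
        greater = np.searchsorted(b_sorted, a, side="left").sum()
        frac = float(greater) / (a.size * b.size)
    else:
        rng = np.random.default_rng(seed)
        n = max_pairs
        ia = rng.integers(0, a.size, n)
        ib = rng.integers(0, b.size, n)
        frac = float((a[ia] > b[ib]).mean())
    if frac > HIGHLY_SIGNIFICANT:
        verdict = "highly_significant"
    elif frac > SIGNIFICANT:
        verdict = "significant"
    else:
        verdict = "none"
    return ComparisonResult(label, frac, verdict)


@dataclass
class DietComposition:
    consumer: str
    sources: list[str]
    percentages: np.ndarray  # mean percentage per source, sums to 100
    n_zero_intake: int       # solutions excluded for zero total intake


def diet_composition(model: FoodWebModel, ensemble: FlowEnsemble, consumer: str) -> DietComposition:
    """Mean percentage contribution of each feeding inflow to a consumer's intake.

    Computed per solution (each solution's inflows divided by its total
    intake), then averaged. Carbon fixation by endosymbionts is not
    feeding, so symbiont-only compartments have no diet.
    """
    inflows = model.feeding_inflows(consumer)
    if not inflows:
        raise VentlimError(
            f"{consumer!r} has no feeding inflows (symbiont fixation is not a diet)"
        )
    cols = np.array([fl.index for fl in inflows])
    F = ensemble.samples[:, cols]
    totals = F.sum(axis=1)
    ok = totals > 1e-12
    n_zero = int((~ok).sum())
    if not ok.any():
        raise VentlimError(f"every solution has zero intake for {consumer!r}")
    props = F[ok] / totals[ok, None]
    return DietComposition(
        consumer=consumer,
        sources=[fl.source for fl in inflows],
        percentages=100.0 * props.mean(axis=0),
        n_zero_intake=n_zero,
    )


@dataclass
class BudgetReport:
    """Organic-matter budget in mmol C m^-2 d^-1, mean and sample SD per line.

    "Net" input routes subtract the respiration of the mediating
    compartments (suspension feeders for suspension feeding; chemosynthetic
    bacteria and symbiont-bearing fauna for chemosynthesis); their egesta
    stay in-system as detritus and are tracked separately.
    """

    lines: dict[str, tuple[float, float]]
    input_shares_pct: dict[str, tuple[float, float]]
    missing_routes: list[str] = field(default_factory=list)
    max_conservation_residual: float = 0.0


def _sum_columns(model: FoodWebModel, X: np.ndarray, labels: list[str]) -> np.ndarray:
    if not labels:
        return np.zeros(X.shape[0])
    cols = [model.flow_index(lab) for lab in labels]
    return X[:, cols].sum(axis=1)


def om_budget(model: FoodWebModel, ensemble: FlowEnsemble) -> BudgetReport:
    """Partition the carbon budget of every solution, then average."""
    X = ensemble.samples
    missing: list[str] = []

    def flows_where(pred) -> list[str]:
        return [fl.label for fl in model.flows if pred(fl)]

    internal_ids = {c.id for c in model.internal}
    suspension = {
        c.id for c in model.internal if c.is_fauna and "suspension" in c.feeding_modes
    }
    chemo = {
        c.id for c in model.internal
        if ("chemoautotrophy" in c.feeding_modes) or c.is_symbiont_bearer
    }
    living = {
        c.id for c in model.internal if c.taxon_class in ("bacteria", "macrofauna", "megafauna")
    }

    poc_label = f"{WATER_DETRITUS_ID}->Det"
    if model.has_flow(poc_label):
        poc = X[:, model.flow_index(poc_label)]
    else:
        poc = np.zeros(X.shape[0])
        missing.append("poc_deposition")

    gross_susp = _sum_columns(model, X, flows_where(
        lambda fl: fl.source == WATER_DETRITUS_ID and fl.sink in suspension))
    gross_chemo = _sum_columns(model, X, flows_where(
        lambda fl: fl.source == DIC_ID and fl.sink in internal_ids))
    if not suspension:
        missing.append("suspension_feeding")
    if not chemo:
        missing.append("chemosynthesis")

    resp_by = {
        cid: _sum_columns(model, X, flows_where(
            lambda fl, cid=cid: fl.source == cid and fl.sink == DIC_ID))
        for cid in internal_ids
    }
    total_resp = sum(resp_by.values())
    resp_susp = sum((resp_by[c] for c in suspension), np.zeros(X.shape[0]))
    resp_chemo = sum((resp_by[c] for c in chemo), np.zeros(X.shape[0]))
    resp_bacteria = sum((resp_by[c.id] for c in model.internal if c.taxon_class == "bacteria"),
                        np.zeros(X.shape[0]))
    resp_macro = sum((resp_by[c.id] for c in model.internal if c.taxon_class == "macrofauna"),
                     np.zeros(X.shape[0]))
    resp_mega = sum((resp_by[c.id] for c in model.internal if c.taxon_class == "megafauna"),
                    np.zeros(X.shape[0]))

    net_susp = gross_susp - resp_susp
    net_chemo = gross_chemo - resp_chemo
    net_total = poc + net_susp + net_chemo
    gross_total = poc + gross_susp + gross_chemo

    detritus_production = _sum_columns(model, X, flows_where(
        lambda fl: fl.source in living and fl.sink == "Det"))
    burial = _sum_columns(model, X, flows_where(
        lambda fl: fl.sink == BURIAL_ID))
    doc_efflux = _sum_columns(model, X, flows_where(
        lambda fl: fl.sink == WATER_DOC_ID))
    predation = _sum_columns(model, X, flows_where(
        lambda fl: fl.sink == PREDATION_ID))

    residual = gross_total - total_resp - burial - doc_efflux - predation

    def ms(v: np.ndarray) -> tuple[float, float]:
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    lines = {
        "poc_deposition": ms(poc),
        "gross_suspension_feeding": ms(gross_susp),
        "net_suspension_feeding": ms(net_susp),
        "gross_chemosynthesis": ms(gross_chemo),
        "net_chemosynthesis": ms(net_chemo),
        "net_total_om_input": ms(net_total),
        "gross_total_om_input": ms(gross_total),
        "detritus_production": ms(detritus_production),
        "total_respiration": ms(total_resp),
        "bacterial_respiration": ms(resp_bacteria),
        "macrofaunal_respiration": ms(resp_macro),
        "megafaunal_respiration": ms(resp_mega),
        "burial": ms(burial),
        "doc_efflux": ms(doc_efflux),
        "external_predation": ms(predation),
    }
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(net_total > 1e-12, net_total, np.nan)
        shares = {
            "poc_deposition": 100.0 * poc / denom,
            "net_suspension_feeding": 100.0 * net_susp / denom,
            "net_chemosynthesis": 100.0 * net_chemo / denom,
        }
    input_shares = {}
    for k, v in shares.items():
        v = v[np.isfinite(v)]
        input_shares[k] = (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0) \
            if v.size else (0.0, 0.0)
    return BudgetReport(
        lines=lines,
        input_shares_pct=input_shares,
        missing_routes=missing,
        max_conservation_residual=float(np.abs(residual).max()) if residual.size else 0.0,
    )
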