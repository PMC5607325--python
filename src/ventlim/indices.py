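"""Ecological network analysis of a flow solution.

Bridges a flow vector to the classic whole-network indices: total system
throughflow (TST), the Finn cycling index (FCI, fraction of throughflow
that is recycled, from the inverse of the output-fraction matrix), average
mutual information (AMI, bits of constraint the topology places on where a
unit of carbon goes next), and a compartmentalisation index (mean pairwise
overlap of interaction neighbourhoods).

The bridge object is a :class:`FlowMatrix`: internal-to-internal transfers
in a square matrix plus import, export and respiration vectors. Flows out
of external sources (water-column detritus, DIC fixation) are imports;
flows into DIC are respiration; flows to the remaining externals (burial,
water-column DOC, mobile predators) are exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import VentlimError
from .model import DIC_ID, FoodWebModel
from .sample import FlowEnsemble

_BAL_TOL = 1e-8


@dataclass
class FlowMatrix:
    labels: list[str]
    T: np.ndarray            # (n, n) internal transfers, zero diagonal
    imports: np.ndarray      # (n,)
    exports: np.ndarray      # (n,)
    respiration: np.ndarray  # (n,)

    def __post_init__(self):
        n = len(self.labels)
        self.T = np.asarray(self.T, dtype=float)
        for name in ("imports", "exports", "respiration"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).ravel())
        if self.T.shape != (n, n):
            raise VentlimError("flow matrix must be square over the labels")
        if min(self.T.min(initial=0.0), self.imports.min(initial=0.0),
               self.exports.min(initial=0.0), self.respiration.min(initial=0.0)) < 0:
            raise VentlimError("flow matrix entries must be nonnegative")
        if np.any(np.diag(self.T) != 0):
            raise VentlimError("flow matrix diagonal must be zero")

    @property
    def inflow(self) -> np.ndarray:
        """Per-compartment total inputs (internal transfers + imports)."""
        return self.T.sum(axis=0) + self.imports

    @property
    def outflow(self) -> np.ndarray:
        return self.T.sum(axis=1) + self.exports + self.respiration

    def max_imbalance(self) -> float:
        return float(np.abs(self.inflow - self.outflow).max()) if self.labels else 0.0


def to_flow_matrix(model: FoodWebModel, flow_vector: np.ndarray) -> FlowMatrix:
    """Arrange a flow vector into internal transfers + boundary vectors."""
    x = np.asarray(flow_vector, dtype=float).ravel()
    if x.size != model.n_flows:
        raise VentlimError(f"flow vector length {x.size} != model flow count {model.n_flows}")
    if x.min(initial=0.0) < 0:
        raise VentlimError("flow vector has negative entries")
    labels = [c.id for c in model.internal]
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    T = np.zeros((n, n))
    imports = np.zeros(n)
    exports = np.zeros(n)
    respiration = np.zeros(n)
    for fl in model.flows:
        v = x[fl.index]
        src_in = fl.source in idx
        snk_in = fl.sink in idx
        if src_in and snk_in:
            T[idx[fl.source], idx[fl.sink]] += v
        elif snk_in:
            imports[idx[fl.sink]] += v
        elif src_in:
            if fl.sink == DIC_ID:
                respiration[idx[fl.source]] += v
            else:
                exports[idx[fl.source]] += v
    return FlowMatrix(labels, T, imports, exports, respiration)


def total_system_throughflow(fm: FlowMatrix) -> float:
    """Sum over compartments of their (input) throughflow."""
    return float(fm.inflow.sum())


def n_links(fm: FlowMatrix, tol: float = 0.0) -> int:
    """Number of realised flows (internal transfers plus boundary flows)."""
    return int(
        (fm.T > tol).sum()
        + (fm.imports > tol).sum()
        + (fm.exports > tol).sum()
        + (fm.respiration > tol).sum()
    )


def finn_cycling_index(fm: FlowMatrix, corrected: bool = False) -> float:
    """Fraction of total throughflow that is recycled.

    With throughflows T_i and output fractions G_ij = T_ij / T_i, the
    matrix N = (I - G)^-1 gives the expected number of visits n_ii a unit
    of carbon entering i makes to i; the cycled throughflow is
    Tc = sum_i ((n_ii - 1) / n_ii) T_i. The plain index is Tc / TST; the
    corrected variant removes the cycled fraction from the denominator,
    Tc / (TST - Tc). Throughflows are input throughflows; on a balanced
    matrix these equal the output throughflows.
    """
    thru = fm.inflow
    tst = thru.sum()
    if tst <= 0:
        raise VentlimError("total system throughflow is zero")
    active = thru > 0
    Ta = thru[active]
    Gm = fm.T[np.ix_(active, active)] / Ta[:, None]
    I = np.eye(Gm.shape[0])
    try:
        Nmat = np.linalg.inv(I - Gm)
    except np.linalg.LinAlgError as exc:
        raise VentlimError(
            "I - G is singular: a fully cyclic component retains carbon forever"
        ) from exc
    nii = np.diag(Nmat)
    tc = float((((nii - 1.0) / nii) * Ta).sum())
    if corrected:
        straight = tst - tc
        return tc / straight if straight > 0 else np.inf
    return tc / float(tst)


def average_mutual_information(fm: FlowMatrix) -> float:
    """AMI in bits over the extended matrix (import row, export/respiration columns)."""
    n = len(fm.labels)
    ext = np.zeros((n + 1, n + 2))
    ext[:n, :n] = fm.T
    ext[n, :n] = fm.imports
    ext[:n, n] = fm.exports
    ext[:n, n + 1] = fm.respiration
    total = ext.sum()
    if total <= 0:
        raise VentlimError("cannot compute AMI of an empty network")
    p = ext / total
    row = p.sum(axis=1, keepdims=True)
    col = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (row @ col))
    return float(np.nansum(terms))


def compartmentalisation(fm: FlowMatrix, tol: float = 0.0) -> float:
    """Mean pairwise Jaccard overlap of interaction neighbourhoods.

    Neighbourhoods are taken on the undirected internal interaction graph
    and include the focal compartment itself, so a complete graph scores 1
    and an edgeless one scores 0.
    """
    n = len(fm.labels)
    if n < 2:
        raise VentlimError("compartmentalisation needs at least 2 compartments")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    sym = fm.T + fm.T.T
    for i in range(n):
        for j in range(i + 1, n):
            if sym[i, j] > tol:
                g.add_edge(i, j)
    hoods = [set(g[i]) | {i} for i in range(n)]
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            union = hoods[i] | hoods[j]
            total += (len(hoods[i] & hoods[j]) / len(union)) if union else 0.0
            n_pairs += 1
    return total / n_pairs


@dataclass
class NetworkIndexReport:
    tst: float
    n_links: int
    fci: float
    cfci: float
    ami: float
    compartmentalisation: float

    def as_dict(self) -> dict[str, float]:
        return {
            "tst": self.tst,
            "n_links": self.n_links,
            "fci": self.fci,
            "cfci": self.cfci,
            "ami": self.ami,
            "compartmentalisation": self.compartmentalisation,
        }


def network_indices(model: FoodWebModel, flow_vector: np.ndarray) -> NetworkIndexReport:
    fm = to_flow_matrix(model, flow_vector)
    return NetworkIndexReport(
        tst=total_system_throughflow(fm),
        n_links=n_links(fm, tol=1e-10),
        fci=finn_cycling_index(fm, corrected=False),
        cfci=finn_cycling_index(fm, corrected=True),
        ami=average_mutual_information(fm),
        compartmentalisation=compartmentalisation(fm, tol=1e-10),
    )


def ensemble_indices(
    model: FoodWebModel, ensemble: FlowEnsemble, stride: int = 1
) -> dict[str, tuple[float, float]]:
    """Each index per solution, then mean and sample SD over the ensemble.

    ``stride`` subsamples rows (every stride-th solution) when per-row
    evaluation over very large ensembles is unnecessary.
    """
    rows = ensemble.samples[::stride]
    if rows.shape[0] == 0:
        raise VentlimError("ensemble is empty")
    values: dict[str, list[float]] = {}
    for x in rows:
        rep = network_indices(model, x).as_dict()
        for k, v in rep.items():
            values.setdefault(k, []).append(float(v))
    out = {}
    for k, vals in values.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[k] = (float(arr.mean()), sd)
    return out
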