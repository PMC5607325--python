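"""Deterministic treatment of a compiled constraint system.

Feasibility is decided by a phase-1 linear program (HiGHS). The
*parsimonious* solution is the unique minimum-Euclidean-norm flow vector
satisfying all constraints, obtained by eliminating the equalities through
an orthonormal null-space basis and solving the remaining least-distance
problem with the Lawson-Hanson LDP-to-NNLS reduction. Per-flow attainable
ranges come from a pair of linear programs per coordinate.

The parsimonious point is plumbing (a start point for the sampler and a
quick sanity check), never an estimate in its own right: the method's
output is always the sampled ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .compile import ConstraintSystem
from .errors import InfeasibleError

#: Constraint-satisfaction tolerance used throughout (flows are O(0.01-10)).
TOL = 1e-8


@dataclass
class FeasibilityResult:
    feasible: bool
    certificate: list[str]

    def __bool__(self) -> bool:
        return self.feasible


@dataclass
class SolveReport:
    feasible: bool
    parsimonious_x: np.ndarray | None
    flow_ranges: np.ndarray | None  # (n, 2) min/max, +-inf where unbounded
    unbounded: np.ndarray | None    # boolean per flow
    diagnostics: list[str]
    flow_labels: list[str]


def _linprog(system: ConstraintSystem, c: np.ndarray):
    return scipy.optimize.linprog(
        c,
        A_ub=-system.G if system.G.size else None,
        b_ub=-system.h if system.G.size else None,
        A_eq=system.E if system.E.size else None,
        b_eq=system.f if system.E.size else None,
        bounds=[(None, None)] * system.n_flows,
        method="highs",
    )


def check_feasibility(system: ConstraintSystem, find_certificate: bool = True) -> FeasibilityResult:
    """Phase-1 LP verdict; on infeasibility, isolate an irreducible row set.

    The certificate is computed by a deletion filter: rows are dropped one
    at a time and kept only if their removal restores feasibility, leaving
    a small mutually inconsistent core named by provenance tags.
    """
    res = _linprog(system, np.zeros(system.n_flows))
    if res.status == 0 or res.status == 3:  # optimal or unbounded objective==0
        return FeasibilityResult(True, [])
    if not find_certificate:
        return FeasibilityResult(False, [])
    return FeasibilityResult(False, _deletion_filter(system))


def _subsystem(system: ConstraintSystem, eq_keep: np.ndarray, ineq_keep: np.ndarray) -> ConstraintSystem:
    sub = ConstraintSystem.__new__(ConstraintSystem)
    sub.E = system.E[eq_keep]
    sub.f = system.f[eq_keep]
    sub.G = system.G[ineq_keep]
    sub.h = system.h[ineq_keep]
    sub.flow_labels = system.flow_labels
    sub.eq_provenance = [t for t, k in zip(system.eq_provenance, eq_keep) if k]
    sub.ineq_provenance = [t for t, k in zip(system.ineq_provenance, ineq_keep) if k]
    return sub


def _deletion_filter(system: ConstraintSystem, max_rows: int = 400) -> list[str]:
    n_eq, n_ineq = system.E.shape[0], system.G.shape[0]
    if n_eq + n_ineq > max_rows:
        return sorted(set(system.row_provenance))
    eq_keep = np.ones(n_eq, dtype=bool)
    ineq_keep = np.ones(n_ineq, dtype=bool)
    for which, i in [("eq", i) for i in range(n_eq)] + [("ineq", i) for i in range(n_ineq)]:
        keep = eq_keep if which == "eq" else ineq_keep
        keep[i] = False
        res = _linprog(_subsystem(system, eq_keep, ineq_keep), np.zeros(system.n_flows))
        if res.status == 0 or res.status == 3:
            keep[i] = True  # removal restored feasibility: row is part of the conflict
    tags = [t for t, k in zip(system.eq_provenance, eq_keep) if k]
    tags += [t for t, k in zip(system.ineq_provenance, ineq_keep) if k]
    return sorted(set(tags))


def nullspace_parameterisation(system: ConstraintSystem, tol: float = TOL):
    """Reduce ``E x = f`` to ``x = x0 + N z`` with orthonormal ``N``.

    Returns (x0, N, A, b) where the inequalities become ``A z >= b``.
    Raises :class:`InfeasibleError` if the equalities are inconsistent.
    """
    n = system.n_flows
    if system.E.shape[0]:
        x0, *_ = np.linalg.lstsq(system.E, system.f, rcond=None)
        if np.linalg.norm(system.E @ x0 - system.f) > tol * max(1.0, np.linalg.norm(system.f)):
            raise InfeasibleError("equality constraints are inconsistent",
                                  sorted(set(system.eq_provenance)))
        N = scipy.linalg.null_space(system.E)
    else:
        x0 = np.zeros(n)
        N = np.eye(n)
    A = system.G @ N if system.G.size else np.zeros((0, N.shape[1]))
    b = system.h - system.G @ x0 if system.G.size else np.zeros(0)
    return x0, N, A, b


def _ldp(A: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    """Least-distance program: min ||z|| s.t. A z >= b (Lawson & Hanson).

    Reduced to nonnegative least squares on the stacked matrix [A b]^T;
    returns None when the inequalities are inconsistent.
    """
    m, k = A.shape
    if m == 0:
        return np.zeros(k)
    Emat = np.vstack([A.T, b[None, :]])          # (k+1, m)
    fvec = np.zeros(k + 1)
    fvec[-1] = 1.0
    u, _ = scipy.optimize.nnls(Emat, fvec)
    r = Emat @ u - fvec
    if np.linalg.norm(r) <= 1e-12:
        return None
    return -r[:k] / r[k]


def parsimonious_solution(system: ConstraintSystem, tol: float = TOL) -> np.ndarray:
    """Minimum-norm flow vector satisfying all constraints."""
    x0, N, A, b = nullspace_parameterisation(system, tol)
    z = _ldp(A, b)
    if z is None:
        feas = check_feasibility(system)
        raise InfeasibleError("system is infeasible", feas.certificate)
    x = x0 + N @ z
    if not system.satisfied_by(x, tol=max(tol, 1e-7)):
        # LDP is numerically exact on well-scaled systems; a failure here
        # means genuine infeasibility or severe ill-conditioning.
        feas = check_feasibility(system)
        if not feas.feasible:
            raise InfeasibleError("system is infeasible", feas.certificate)
        raise InfeasibleError("parsimonious solve failed to meet tolerance")
    return x


def flow_ranges(system: ConstraintSystem) -> tuple[np.ndarray, np.ndarray]:
    """Per-flow [min, max] over the polytope (two LPs per flow).

    Unbounded coordinates are flagged, not raised: the returned ranges hold
    ``-inf``/``+inf`` there and the boolean mask marks them.
    """
    n = system.n_flows
    ranges = np.zeros((n, 2))
    unbounded = np.zeros(n, dtype=bool)
    c = np.zeros(n)
    for j in range(n):
        for sign, col in ((1.0, 0), (-1.0, 1)):
            c[:] = 0.0
            c[j] = sign
            res = _linprog(system, c)
            if res.status == 3:
                ranges[j, col] = -np.inf if sign > 0 else np.inf
                unbounded[j] = True
            elif res.status == 0:
                ranges[j, col] = sign * res.fun
            else:
                feas = check_feasibility(system)
                raise InfeasibleError("flow_ranges on infeasible system", feas.certificate)
    return ranges, unbounded


def solve(system: ConstraintSystem) -> SolveReport:
    """Feasibility + parsimonious solution + per-flow ranges in one report."""
    feas = check_feasibility(system)
    if not feas.feasible:
        return SolveReport(False, None, None, None, feas.certificate, system.flow_labels)
    x = parsimonious_solution(system)
    ranges, unbounded = flow_ranges(system)
    return SolveReport(True, x, ranges, unbounded, [], system.flow_labels)
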