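"""Uniform sampling of the feasible flow polytope.

The constraint system is reduced to the null space of its equalities,
``x = x0 + N z`` with orthonormal ``N``, where the inequalities become
half-spaces ``A z >= b``. A mirror (reflective) random walk is run in z:
each step proposes a Gaussian displacement and reflects the trajectory off
every violated half-space until the end point is interior. A symmetric
proposal with specular reflection leaves the uniform distribution on the
polytope invariant, so the chain samples the polytope uniformly; this is
the established sampler for linear inverse food-web models.

Food-web polytopes are strongly anisotropic (tightly constrained
respiration flows next to loosely bounded deposition), so a short ladder
of pilot runs first estimates the polytope covariance and the main chain
runs in the whitened (Cholesky) frame, where a few reflections per step
suffice and mixing is fast. The chain starts at the max-slack
(Chebyshev-type) interior point unless a start is supplied, discards a
burn-in, and then retains every iterate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import scipy.optimize

from .compile import ConstraintSystem
from .errors import InfeasibleError, UnboundedError, VentlimError
from .solve import TOL, flow_ranges, nullspace_parameterisation

DEFAULT_BURN_IN = 1000
#: Default proposal scale: this fraction of the mean whitened axis width.
JUMP_RANGE_FRACTION = 0.3


@dataclass
class FlowEnsemble:
    """A matrix of sampled flow vectors (rows) with sampler metadata."""

    samples: np.ndarray  # (n_samples, n_flows)
    flow_labels: list[str]
    seed: int
    n_burn_in: int
    jump_length: float
    n_iterations_requested: int

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.samples[:, self.flow_labels.index(label)]


@dataclass
class ConvergenceReport:
    """Relative deviation of prefix-chain moments from the longest run."""

    tracked_flows: list[str]
    run_lengths: list[int]
    dev_mean: np.ndarray  # (n_run_lengths, n_tracked)
    dev_sd: np.ndarray
    min_iterations: int
    tolerance: float


def _reduced_geometry(system: ConstraintSystem, tol: float = TOL):
    """Null-space geometry with unit-normalised inequality rows.

    Rows whose normal vanishes in the null space (constraints fixed by the
    equalities) are dropped after checking they are not violated outright.
    """
    x0, N, A, b = nullspace_parameterisation(system, tol)
    m = A.shape[0]
    norms = np.linalg.norm(A, axis=1) if m else np.zeros(0)
    degenerate = norms <= 1e-12
    if np.any(degenerate & (b > tol)):
        bad = [t for t, d, bi in zip(system.ineq_provenance, degenerate, b) if d and bi > tol]
        raise InfeasibleError("constraints violated for every point of the equality subspace",
                              sorted(set(bad)))
    keep = ~degenerate
    A = A[keep] / norms[keep][:, None] if m else A
    b = (b[keep] / norms[keep]) if m else b
    return x0, N, A, b


def _interior_point(A: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Max-slack point: argmax_t { t : A z - t >= b } (rows are unit norm).

    Returns the point and its slack radius (the inscribed-ball radius).
    """
    if A.shape[0] == 0:
        return np.zeros(k), 1.0
    c = np.zeros(k + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-A, np.ones((A.shape[0], 1))])
    res = scipy.optimize.linprog(
        c, A_ub=A_ub, b_ub=-b, bounds=[(None, None)] * k + [(None, 1e6)], method="highs"
    )
    if res.status != 0:
        raise InfeasibleError("no interior point found; system is infeasible or degenerate")
    t = res.x[-1]
    if t <= 0:
        raise VentlimError(
            "feasible region has empty interior in the null space "
            "(an inequality holds with equality everywhere); sampling is not defined"
        )
    return res.x[:-1], float(t)


@numba.njit(cache=True)
def _mirror_kernel(z, A, b, steps, out, max_reflections, eps):  # pragma: no cover - jitted
    """Reflective-walk inner loop (compiled): advance one chunk of steps.

    ``steps`` holds the pre-drawn Gaussian displacements, so the caller owns
    all randomness and the kernel is bit-deterministic.
    """
    n_steps, k = steps.shape
    m = A.shape[0]
    z1 = np.empty(k)
    z2 = np.empty(k)
    for step in range(n_steps):
        for j in range(k):
            z1[j] = z[j]
            z2[j] = z[j] + steps[step, j]
        ok = m == 0
        refl = 0
        while not ok and refl < max_reflections:
            refl += 1
            # most violated-first crossing along the segment z1 -> z2
            best_alpha = np.inf
            best_row = -1
            inside = True
            for i in range(m):
                ri = -b[i]
                for j in range(k):
                    ri += A[i, j] * z2[j]
                if ri < -eps:
                    inside = False
                    num = b[i]
                    ad = 0.0
                    for j in range(k):
                        num -= A[i, j] * z1[j]
                        ad += A[i, j] * (z2[j] - z1[j])
                    if ad < -1e-15:
                        alpha = num / ad
                        if alpha < best_alpha:
                            best_alpha = alpha
                            best_row = i
            if inside:
                ok = True
                break
            if best_row < 0:
                break
            if best_alpha < 0.0:
                best_alpha = 0.0
            elif best_alpha > 1.0:
                best_alpha = 1.0
            # advance to the crossing point, then reflect the end point
            r2 = -b[best_row]
            for j in range(k):
                r2 += A[best_row, j] * z2[j]
            for j in range(k):
                z1[j] = z1[j] + best_alpha * (z2[j] - z1[j])
                z2[j] = z2[j] - 2.0 * r2 * A[best_row, j]
        if ok:
            for j in range(k):
                z[j] = z2[j]
        # else: reject the move, stay put (rare; keeps the chain valid)
        for j in range(k):
            out[step, j] = z[j]
    return z


def _mirror_chain(z0, A, b, sigma, n_steps, rng, max_reflections=2000, eps=1e-11,
                  chunk=20_000):
    """Run the reflective walk; returns the (n_steps, k) trajectory in z."""
    k = z0.size
    out = np.empty((n_steps, k))
    z = z0.astype(float).copy()
    A = np.ascontiguousarray(A, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    done = 0
    while done < n_steps:
        n = min(chunk, n_steps - done)
        steps = rng.normal(0.0, sigma, (n, k))
        z = _mirror_kernel(z, A, b, steps, out[done:done + n], max_reflections, eps)
        done += n
    return out


def _whitened(A: np.ndarray, b: np.ndarray, mu: np.ndarray, L: np.ndarray):
    """Constraints in the frame z = mu + L w, rows re-normalised."""
    if A.shape[0] == 0:
        return A, b
    Aw = A @ L
    bw = b - A @ mu
    norms = np.linalg.norm(Aw, axis=1)
    norms[norms <= 1e-300] = 1.0
    return Aw / norms[:, None], bw / norms

# Adaptation schedule: pilot lengths and proposal SDs (in whitened units).
_ADAPT_STAGES = ((3_000, 5.0), (5_000, 1.0), (8_000, 1.0))


def _adaptive_frame(A, b, z0, radius, k, rng):
    """Estimate an affine frame (mu, L) in which the polytope is round.

    The polytope directions can span orders of magnitude (well-constrained
    respiration flows next to loosely bounded deposition), which cripples
    any isotropic walker. A short ladder of pilot mirror runs estimates the
    sample covariance, whitens, and repeats; the final frame makes the main
    chain mix in a handful of steps. The frame is fixed before the retained
    run, so uniform invariance is untouched.
    """
    mu = z0.astype(float).copy()
    L = np.eye(k) * max(radius, 1e-12)
    for n_pilot, sigma in _ADAPT_STAGES:
        Aw, bw = _whitened(A, b, mu, L)
        W = _mirror_chain(np.zeros(k), Aw, bw, sigma, n_pilot, rng)
        Z = W @ L.T + mu
        mu = Z.mean(axis=0)
        S = np.atleast_2d(np.cov(Z.T))
        # eigenvalue floor keeps genuinely thin directions from collapsing
        evals, evecs = np.linalg.eigh(S)
        floor = max(evals.max(), 1e-300) * 1e-10
        evals = np.maximum(evals, floor)
        L = evecs * np.sqrt(evals)
    return mu, L


def assert_bounded(system: ConstraintSystem) -> None:
    """Raise :class:`UnboundedError` naming flows with unbounded ranges."""
    ranges, unbounded = flow_ranges(system)
    if unbounded.any():
        bad = [lab for lab, u in zip(system.flow_labels, unbounded) if u]
        raise UnboundedError("cannot sample an unbounded polytope", bad)


def sample_polytope(
    system: ConstraintSystem,
    n_iterations: int,
    seed: int,
    jump_length: float | None = None,
    start: np.ndarray | None = None,
    burn_in: int = DEFAULT_BURN_IN,
    check_tol: float = TOL,
    check_bounded: bool = True,
) -> FlowEnsemble:
    """Draw ``n_iterations`` uniform samples of the feasible polytope.

    ``jump_length`` is the proposal SD in the whitened frame the adaptive
    pilots establish; the default, ``0.3 * sqrt(12)``, is 0.3 of the mean
    per-axis width of the whitened polytope (a uniform axis of width W has
    SD W / sqrt(12)). Identical arguments give a bit-identical ensemble.
    Every retained row is checked against the full system at ``check_tol``;
    a violation is a bug and raises rather than returning a corrupt
    ensemble.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if jump_length is None:
        jump_length = JUMP_RANGE_FRACTION * np.sqrt(12.0)
    if check_bounded:
        assert_bounded(system)
    x0, N, A, b = _reduced_geometry(system)
    k = N.shape[1]
    rng = np.random.default_rng(seed)
    if k == 0:
        X = np.tile(x0, (n_iterations, 1))
        _assert_valid(system, X, check_tol)
        return FlowEnsemble(X, list(system.flow_labels), seed, burn_in,
                            float(jump_length), n_iterations)
    if start is not None:
        start = np.asarray(start, dtype=float)
        if not system.satisfied_by(start, tol=check_tol):
            raise ValueError("supplied start point violates the constraint system")
        z0 = N.T @ (start - x0)
        _, radius = _interior_point(A, b, k)
    else:
        z0, radius = _interior_point(A, b, k)
    mu, L = _adaptive_frame(A, b, z0, radius, k, rng)
    Aw, bw = _whitened(A, b, mu, L)
    traj = _mirror_chain(np.zeros(k), Aw, bw, jump_length, burn_in + n_iterations, rng)
    zs = traj[burn_in:] @ L.T + mu
    X = zs @ N.T + x0
    _assert_valid(system, X, check_tol)
    return FlowEnsemble(
        samples=X,
        flow_labels=list(system.flow_labels),
        seed=seed,
        n_burn_in=burn_in,
        jump_length=float(jump_length),
        n_iterations_requested=n_iterations,
    )


def _assert_valid(system: ConstraintSystem, X: np.ndarray, tol: float) -> None:
    if system.E.size:
        eq = system.E @ X.T - system.f[:, None]
        worst = float(np.abs(eq).max())
        if worst > tol:
            raise VentlimError(f"sampled point violates an equality by {worst:.2e}")
    if system.G.size:
        slack = system.G @ X.T - system.h[:, None]
        worst = float(slack.min())
        if worst < -tol:
            raise VentlimError(f"sampled point violates an inequality by {-worst:.2e}")


def convergence_diagnostic(
    system: ConstraintSystem,
    tracked_flows: list[str] | None = None,
    run_lengths: tuple[int, ...] = (300, 3_000, 30_000, 200_000),
    seed: int = 0,
    tolerance: float = 0.02,
    jump_length: float | None = None,
) -> ConvergenceReport:
    """Decide how many iterations the ensemble needs.

    All runs share the same start point and random stream, so the shorter
    runs are exact prefixes of the longest; per tracked flow the relative
    deviation of prefix mean and SD from the longest run is reported, and
    ``min_iterations`` is the smallest run length at which every tracked
    deviation is within ``tolerance`` (flows pinned to a constant by the
    equalities count as converged immediately).
    """
    run_lengths = tuple(int(r) for r in run_lengths)
    if len(run_lengths) < 2 or any(b <= a for a, b in zip(run_lengths, run_lengths[1:])):
        raise ValueError("run_lengths must be >= 2 strictly increasing values")
    ens = sample_polytope(system, max(run_lengths), seed=seed,
                          jump_length=jump_length, burn_in=0)
    labels = ens.flow_labels
    if tracked_flows is None:
        tracked_flows = _default_tracked(ens)
    missing = [t for t in tracked_flows if t not in labels]
    if missing:
        raise ValueError(f"tracked flows not in system: {missing}")
    cols = np.array([labels.index(t) for t in tracked_flows])
    X = ens.samples[:, cols]
    final_mean = X.mean(axis=0)
    final_sd = X.std(axis=0, ddof=1)
    dev_mean = np.zeros((len(run_lengths), len(cols)))
    dev_sd = np.zeros_like(dev_mean)
    constant = final_sd <= 1e-12  # pinned by the equalities: converged by definition
    for i, L in enumerate(run_lengths):
        pm = X[:L].mean(axis=0)
        ps = X[:L].std(axis=0, ddof=1) if L > 1 else np.zeros(len(cols))
        dev_mean[i] = np.where(constant, 0.0, _rel_dev(pm, final_mean))
        dev_sd[i] = np.where(constant, 0.0, _rel_dev(ps, final_sd))
    ok = (dev_mean <= tolerance).all(axis=1) & (dev_sd <= tolerance).all(axis=1)
    min_iterations = run_lengths[int(np.argmax(ok))] if ok.any() else run_lengths[-1]
    return ConvergenceReport(list(tracked_flows), list(run_lengths),
                             dev_mean, dev_sd, int(min_iterations), tolerance)


def _rel_dev(value: np.ndarray, ref: np.ndarray, tiny: float = 1e-12) -> np.ndarray:
    out = np.zeros_like(ref)
    fixed = np.abs(ref) <= tiny
    out[fixed] = np.where(np.abs(value[fixed]) <= 1e-9, 0.0, np.inf)
    out[~fixed] = np.abs(value[~fixed] - ref[~fixed]) / np.abs(ref[~fixed])
    return out


def _default_tracked(ens: FlowEnsemble, n: int = 5) -> list[str]:
    """Five non-constant flows spanning the magnitude range of the solution."""
    means = np.abs(ens.samples.mean(axis=0))
    sds = ens.samples.std(axis=0)
    candidates = np.flatnonzero(sds > 1e-12)
    if candidates.size == 0:
        return list(ens.flow_labels[: min(n, len(ens.flow_labels))])
    order = candidates[np.argsort(means[candidates])]
    picks = order[np.unique(np.linspace(0, order.size - 1, min(n, order.size)).astype(int))]
    return [ens.flow_labels[i] for i in picks]
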