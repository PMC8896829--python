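"""Energy minimization under vitelline confinement and the K_b schedule.

The model is quasi-static: for each value of the basal stiffness Kb an
energy-minimizing vertex configuration is found, starting from the
previous equilibrium.  Kb decreases adiabatically (2^10 down to 2^0,
halving at each step), producing the sequence of intermediate furrow
states.  Perturbation experiments continue the schedule from an
intermediate state under modified parameters.

Confinement by the vitelline membrane is a hard inequality |x_v| <= R
imposed by projection (radial clamp) inside the minimizer's line
search; the shell never contributes energy.  The minimizer is a
limited-memory quasi-Newton method (projected L-BFGS) with analytic
gradients and a monotone Armijo backtracking line search, so the energy
is non-increasing along every accepted iterate sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .geometry import EmbryoGeometry, TissueAnnotation, mirror_vertices
from .mechanics import Configuration, ModelParams, energy_and_gradient, energy_hessian

__all__ = [
    "EquilibriumState",
    "Trajectory",
    "default_schedule",
    "minimize_energy",
    "run_schedule",
    "continue_schedule",
]

#: Default adiabatic basal-stiffness schedule: 2^10, 2^9, ..., 2^0.
DEFAULT_SCHEDULE = tuple(float(2**k) for k in range(10, -1, -1))


def default_schedule() -> list[float]:
    return list(DEFAULT_SCHEDULE)


@dataclass
class EquilibriumState:
    """An energy-minimized configuration at one Kb value."""

    vertices: np.ndarray  # (2n, 2)
    Kb: float
    energy: float
    grad_norm: float      # infinity-norm of the projected gradient
    n_iter: int
    converged: bool
    energy_history: np.ndarray | None = None

    @property
    def configuration(self) -> Configuration:
        return Configuration(self.vertices)


@dataclass
class Trajectory:
    """Ordered equilibrium states along a (possibly continued) schedule."""

    states: list[EquilibriumState]
    schedule: list[float]
    params: ModelParams
    geometry: EmbryoGeometry
    annotation: TissueAnnotation
    perturbation: dict | None = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.schedule):
            raise ValueError("states and schedule must align 1:1")
        sched = np.asarray(self.schedule, float)
        if sched.size > 1 and not np.all(np.diff(sched) < 0):
            raise ValueError("Kb schedule must be strictly decreasing")

    @property
    def final(self) -> EquilibriumState:
        return self.states[-1]

    @property
    def n_states(self) -> int:
        return len(self.states)


def _project(x: np.ndarray, radius: float) -> np.ndarray:
    """Radially clamp every vertex onto or inside the vitelline circle."""
    r = np.linalg.norm(x, axis=1)
    scale = np.minimum(1.0, radius / np.maximum(r, 1e-300))
    return x * scale[:, None]


def _projected_gradient(x: np.ndarray, g: np.ndarray, radius: float) -> np.ndarray:
    """Gradient with infeasible (outward) components removed at the shell.

    For a vertex on the shell whose steepest-descent direction points
    outward, the radial component is inactive: only tangential motion
    (or inward motion) is admissible.
    """
    r = np.linalg.norm(x, axis=1)
    on_shell = r >= radius * (1.0 - 1e-12)
    if not np.any(on_shell):
        return g
    pg = g.copy()
    u = x[on_shell] / r[on_shell, None]
    g_rad = np.sum(pg[on_shell] * u, axis=1)
    blocked = g_rad < 0.0  # energy decreases by moving outward: not allowed
    idx = np.flatnonzero(on_shell)[blocked]
    pg[idx] -= g_rad[blocked, None] * (x[idx] / np.linalg.norm(x[idx], axis=1)[:, None])
    return pg


def _default_gtol(geom: EmbryoGeometry, p: ModelParams) -> float:
    """Gradient tolerance scaled to the dominant force in the problem."""
    a0 = float(np.mean(geom.rest_apical))
    force_scale = max(p.mu0, 1000.0) * a0
    return 1e-6 * force_scale


def _minimize_newton(
    x: np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
    gtol: float,
    max_iter: int,
    record_energy: bool,
    symmetric: bool = False,
    max_step: float = 1.0,
) -> EquilibriumState:
    """Projected Newton with active-set shell contact.

    Vertices pressed against the vitelline shell are clamped to it and
    parametrized by their polar angle (one tangential degree of
    freedom); interior vertices keep both Cartesian degrees of freedom.
    The Newton system uses the dense analytic Hessian reduced to this
    basis, with Levenberg damping escalated whenever the factorization
    fails or the step is not a descent direction, and a monotone Armijo
    backtracking line search on radially clamped trial points.

    With ``symmetric=True`` the search is restricted to the
    mirror-symmetric subspace: iterates and gradients are averaged with
    their mirror images, so the solver follows the symmetric solution
    branch even where the unconstrained problem would buckle sideways.
    """
    R = geom.vitelline_radius
    n_cells = geom.n_cells

    def _sym(arr: np.ndarray) -> np.ndarray:
        return 0.5 * (arr + mirror_vertices(arr, n_cells))

    x = _project(np.asarray(x, float).copy(), R)
    if symmetric:
        x = _project(_sym(x), R)
    m = x.shape[0]
    f, g = energy_and_gradient(x, geom, ann, p)
    if symmetric:
        g = _sym(g)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite energy at the starting configuration")
    energies = [f] if record_energy else None
    c1 = 1e-4
    tau = 0.0
    converged = False
    n_iter = 0
    # trust-region-like cap on the per-iteration displacement: base value
    # keeps the descent path local (no hopping between basins); the cap
    # relaxes up to 3x during long monotone downhill stretches
    tr_cap = max_step
    tr_max = 3.0 * max_step

    for n_iter in range(1, max_iter + 1):
        r = np.linalg.norm(x, axis=1)
        on_shell = r >= R * (1.0 - 1e-12)
        xhat = x / np.maximum(r, 1e-300)[:, None]
        g_rad = np.sum(g * xhat, axis=1)
        # clamped: on the shell and pushed outward (outward motion infeasible)
        active = on_shell & (g_rad <= 0.0)

        pg = g.copy()
        pg[active] -= g_rad[active, None] * xhat[active]
        pg_inf = float(np.max(np.abs(pg)))
        if pg_inf <= gtol:
            converged = True
            n_iter -= 1
            break

        H = energy_hessian(x, geom, ann, p)

        # reduced basis: free vertices contribute (x, y); active vertices
        # contribute the unit tangent of the shell circle
        free_idx = np.flatnonzero(~active)
        act_idx = np.flatnonzero(active)
        n_free2 = 2 * free_idx.size
        n_red = n_free2 + act_idx.size
        free_dof = np.stack([2 * free_idx, 2 * free_idx + 1], axis=1).reshape(-1)
        tangents = np.stack([-xhat[act_idx, 1], xhat[act_idx, 0]], axis=1)
        act_dof = np.stack([2 * act_idx, 2 * act_idx + 1], axis=1)  # (na, 2)

        gf = g.reshape(-1)
        g_red = np.empty(n_red)
        g_red[:n_free2] = gf[free_dof]
        g_red[n_free2:] = np.sum(g[act_idx] * tangents, axis=1)

        H_red = np.empty((n_red, n_red))
        H_ff = H[np.ix_(free_dof, free_dof)]
        H_fa = (
            H[np.ix_(free_dof, act_dof[:, 0])] * tangents[None, :, 0]
            + H[np.ix_(free_dof, act_dof[:, 1])] * tangents[None, :, 1]
        ) if act_idx.size else np.empty((n_free2, 0))
        if act_idx.size:
            Haa_blocks = H[np.ix_(act_dof.reshape(-1), act_dof.reshape(-1))]
            na = act_idx.size
            Hb = Haa_blocks.reshape(na, 2, na, 2)
            H_aa = np.einsum("ia,iajb,jb->ij", tangents, Hb, tangents, optimize=True)
        else:
            H_aa = np.empty((0, 0))
        H_red[:n_free2, :n_free2] = H_ff
        H_red[:n_free2, n_free2:] = H_fa
        H_red[n_free2:, :n_free2] = H_fa.T
        H_red[n_free2:, n_free2:] = H_aa
        # arc-length parametrization x(s) = R e(theta0 + s/R) has
        # d2x/ds2 = -x/R^2, which adds -g.x/R^2 to the tangential
        # curvature of each clamped vertex
        if act_idx.size:
            diag = np.arange(2 * free_idx.size, n_red)
            H_red[diag, diag] -= np.sum(g[act_idx] * x[act_idx], axis=1) / R**2

        diag_scale = max(float(np.mean(np.abs(np.diag(H_red)))), 1e-12)
        accepted = False
        for _attempt in range(25):
            try:
                cf = cho_factor(H_red + tau * diag_scale * np.eye(n_red), lower=True)
                d_red = cho_solve(cf, -g_red)
            except LinAlgError:
                tau = max(tau * 10.0, 1e-8)
                continue
            slope = float(g_red @ d_red)
            if not np.isfinite(slope) or slope >= 0.0:
                tau = max(tau * 10.0, 1e-8)
                continue
            step_flat = np.zeros(2 * m)
            step_flat[free_dof] = d_red[:n_free2]
            if act_idx.size:
                step_flat[act_dof[:, 0]] += d_red[n_free2:] * tangents[:, 0]
                step_flat[act_dof[:, 1]] += d_red[n_free2:] * tangents[:, 1]
            step = step_flat.reshape(m, 2)
            # keep the descent path local: quasi-static relaxation should
            # track the basin it starts in, not hop over ridges on large
            # quasi-Newton steps
            step_inf = float(np.max(np.abs(step)))
            alpha0 = 1.0 if step_inf <= tr_cap else tr_cap / step_inf
            alpha = alpha0
            for _ in range(60):
                xn = _project(x + alpha * step, R)
                if symmetric:
                    xn = _project(_sym(xn), R)
                fn, gn = energy_and_gradient(xn, geom, ann, p)
                if symmetric:
                    gn = _sym(gn)
                if np.isfinite(fn) and fn <= f + c1 * alpha * slope:
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                break
            tau = max(tau * 10.0, 1e-8)
        if not accepted:
            break  # no feasible descent; report current residual

        x, f, g = xn, fn, gn
        tau = max(tau / 3.0, 0.0) if tau > 1e-10 else 0.0
        if alpha == alpha0 and step_inf > tr_cap:
            tr_cap = min(tr_cap * 1.6, tr_max)   # cap-limited full step accepted
        elif alpha < alpha0:
            tr_cap = max(max_step, tr_cap * 0.5)
        if energies is not None:
            energies.append(f)

    if not converged:
        r = np.linalg.norm(x, axis=1)
        xhat = x / np.maximum(r, 1e-300)[:, None]
        g_rad = np.sum(g * xhat, axis=1)
        active = (r >= R * (1.0 - 1e-12)) & (g_rad <= 0.0)
        pg = g.copy()
        pg[active] -= g_rad[active, None] * xhat[active]
        pg_inf = float(np.max(np.abs(pg)))
        converged = pg_inf <= gtol
    if not converged:
        warnings.warn(
            f"Newton minimization did not converge: |pg|_inf={pg_inf:.3g} > gtol={gtol:.3g} "
            f"after {n_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return EquilibriumState(
        vertices=x,
        Kb=p.Kb,
        energy=f,
        grad_norm=pg_inf,
        n_iter=n_iter,
        converged=converged,
        energy_history=np.asarray(energies) if energies is not None else None,
    )


def minimize_energy(
    start: Configuration | np.ndarray,
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
    gtol: float | None = None,
    max_iter: int | None = None,
    method: str = "newton",
    memory: int = 12,
    record_energy: bool = False,
    symmetric: bool = False,
    max_step: float = 1.0,
) -> EquilibriumState:
    """Minimize the total energy subject to vitelline confinement.

    Two solvers share the same convergence measure (infinity-norm of
    the projected gradient, i.e. with infeasible outward components at
    the shell removed):

    * ``method='newton'`` (default): projected Newton with the dense
      analytic Hessian, an active-set parametrization of shell-contact
      vertices and Levenberg damping.  Typically converges in tens of
      iterations.
    * ``method='lbfgs'``: projected L-BFGS with radial clamping inside
      a monotone Armijo line search; first-order, slow but independent
      of the Hessian code, kept as a cross-check.

    The default ``gtol`` scales with the peak contractile force
    (1e-6 * mu0 * a0).  Non-convergence returns a state flagged
    ``converged=False`` with a warning; a non-finite energy raises.
    """
    x = start.vertices if isinstance(start, Configuration) else np.asarray(start, float)
    if gtol is None:
        gtol = _default_gtol(geom, p)
    if method == "newton":
        return _minimize_newton(x, geom, ann, p, gtol, max_iter or 20_000, record_energy,
                                symmetric=symmetric, max_step=max_step)
    if method != "lbfgs":
        raise ValueError(f"unknown minimization method {method!r}")
    if symmetric:
        raise ValueError("symmetric-subspace minimization requires method='newton'")
    max_iter = max_iter or 20_000
    x = _project(x.copy(), geom.vitelline_radius)

    f, g = energy_and_gradient(x, geom, ann, p)
    if not np.isfinite(f):
        raise FloatingPointError("non-finite energy at the starting configuration")

    history: list[tuple[np.ndarray, np.ndarray, float]] = []
    energies = [f] if record_energy else None
    c1 = 1e-4
    n_iter = 0
    converged = False
    pg = _projected_gradient(x, g, geom.vitelline_radius)
    pg_inf = float(np.max(np.abs(pg)))

    for n_iter in range(1, max_iter + 1):
        if pg_inf <= gtol:
            converged = True
            n_iter -= 1
            break

        # two-loop recursion on the raw gradient
        q = g.reshape(-1).copy()
        alphas = []
        for s, y, rho in reversed(history):
            a_i = rho * float(s @ q)
            alphas.append(a_i)
            q -= a_i * y
        if history:
            s, y, rho = history[-1]
            gamma = float(s @ y) / float(y @ y)
        else:
            gamma = 1.0 / max(pg_inf, 1.0)
        q *= gamma
        for (s, y, rho), a_i in zip(history, reversed(alphas)):
            q += (a_i - rho * float(y @ q)) * s
        d = -q.reshape(x.shape)

        def try_direction(direction: np.ndarray, alpha0: float):
            alpha = alpha0
            for _ in range(50):
                xn = _project(x + alpha * direction, geom.vitelline_radius)
                step = xn - x
                slope = float(np.sum(g * step))
                if slope < 0.0:
                    fn, gn = energy_and_gradient(xn, geom, ann, p)
                    if np.isfinite(fn) and fn <= f + c1 * slope:
                        return xn, fn, gn
                alpha *= 0.5
            return None

        result = try_direction(d, 1.0)
        if result is None:
            # quasi-Newton direction failed: restart from steepest descent
            history.clear()
            sd = -pg
            result = try_direction(sd, 1.0 / max(pg_inf, 1.0))
        if result is None:
            break  # stalled: no feasible descent found

        xn, fn, gn = result
        s_vec = (xn - x).reshape(-1)
        y_vec = (gn - g).reshape(-1)
        sy = float(s_vec @ y_vec)
        if sy > 1e-10 * np.linalg.norm(s_vec) * np.linalg.norm(y_vec):
            history.append((s_vec, y_vec, 1.0 / sy))
            if len(history) > memory:
                history.pop(0)
        x, f, g = xn, fn, gn
        if energies is not None:
            energies.append(f)
        pg = _projected_gradient(x, g, geom.vitelline_radius)
        pg_inf = float(np.max(np.abs(pg)))

    if pg_inf <= gtol:
        converged = True
    if not converged:
        warnings.warn(
            f"energy minimization did not converge: |pg|_inf={pg_inf:.3g} > gtol={gtol:.3g} "
            f"after {n_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return EquilibriumState(
        vertices=x,
        Kb=p.Kb,
        energy=f,
        grad_norm=pg_inf,
        n_iter=n_iter,
        converged=converged,
        energy_history=np.asarray(energies) if energies is not None else None,
    )


def run_schedule(
    geom: EmbryoGeometry,
    ann: TissueAnnotation,
    p: ModelParams,
    schedule: Sequence[float] | None = None,
    gtol: float | None = None,
    max_iter: int | None = None,
    symmetrize: bool = True,
) -> Trajectory:
    """Equilibrate through the adiabatic Kb schedule from the rest geometry.

    State k is the minimizer initialized from state k-1; state 0 starts
    from the rest configuration.  With ``symmetrize`` (default) the
    minimizer is restricted to the mirror-symmetric subspace, which
    keeps the furrow on the midline instead of letting round-off noise
    seed a sideways buckling mode.
    """
    if schedule is None:
        schedule = default_schedule()
    schedule = [float(k) for k in schedule]
    if any(k <= 0 for k in schedule):
        raise ValueError("Kb schedule must be positive")

    states: list[EquilibriumState] = []
    x = geom.vertices
    for kb in schedule:
        pk = p.with_kb(kb)
        st = minimize_energy(x, geom, ann, pk, gtol=gtol, max_iter=max_iter,
                             symmetric=symmetrize)
        states.append(st)
        x = st.vertices
    return Trajectory(states=states, schedule=schedule, params=p,
                      geometry=geom, annotation=ann)


def continue_schedule(
    traj: Trajectory,
    from_index: int,
    p_override: ModelParams,
    gtol: float | None = None,
    max_iter: int | None = None,
    symmetrize: bool = True,
    perturbation: dict | None = None,
) -> Trajectory:
    """Re-run the schedule tail from an intermediate state under new parameters.

    Starting from ``traj.states[from_index]``, every remaining schedule
    entry (from ``from_index`` inclusive, so the final state is always
    re-equilibrated at the last Kb) is re-minimized under
    ``p_override``.  States before ``from_index`` are carried over
    unchanged.  Used for in-silico perturbations: e.g. zeroing
    contractility at a defined intermediate equilibrium state.
    """
    if not 0 <= from_index < traj.n_states:
        raise IndexError(f"from_index {from_index} outside trajectory of {traj.n_states} states")
    geom, ann = traj.geometry, traj.annotation
    states = list(traj.states[:from_index])
    x = traj.states[from_index].vertices
    for kb in traj.schedule[from_index:]:
        pk = p_override.with_kb(kb)
        st = minimize_energy(x, geom, ann, pk, gtol=gtol, max_iter=max_iter,
                             symmetric=symmetrize)
        states.append(st)
        x = st.vertices
    record = dict(perturbation or {})
    record.setdefault("from_index", from_index)
    return Trajectory(states=states, schedule=list(traj.schedule), params=p_override,
                      geometry=geom, annotation=ann, perturbation=record)
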