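"""Transition and emission probabilities for the total-branch-length state.

The joint law of the ancestral process and its accumulated tree length
``L(t) = int_0^t v(state) ds`` solves a linear transport system

    dF/dt + dF/dx * V = F * Q(t)

where ``V`` holds the per-state accumulation velocities (the number of
active lineages at the locus, zero once its MRCA is reached) and ``Q(t)``
is the process rate matrix.  Velocities are nonnegative integers, so on a
uniform grid with ``dt == dx`` the advection part is an exact integer cell
shift; the source coupling is applied by matrix exponentials in a Strang
splitting (half source, exact shift, half source), second order in ``dt``
with no numerical diffusion along characteristics.  The initial condition
``F(0, x) = P[state] for x >= 0`` makes the solution automatically equal
the plain process distribution ``g(t)`` wherever ``x >= n t``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .demography import DemographicModel, Discretization
from .tmrca_probs import (EmissionSet, RhoProcessSpec, ThetaProcessSpec,
                          TransitionSet, _emission_cdf_rows,
                          _finalize_transitions, absorption_matrix,
                          enumerate_rho_states, enumerate_theta_states,
                          solve_theta_ode, _far_horizon)

DEFAULT_NX_1D = 2000
DEFAULT_NX_2D = 500


def velocity(state, locus: str = "a") -> int:
    """Branch-length accumulation speed of a process state.

    For a two-locus state ``(k_ab, k_a, k_b, kappa)`` and locus tag ``a``
    or ``b`` this is ``(k_ab + k_l) * 1{k_ab + k_l > 1}``; for a one-locus
    mutation state ``(k, k_star)`` it is ``k`` (zero once k == 1).
    """
    if len(state) == 4:
        k_ab, k_a, k_b, _ = state
        k = k_ab + (k_a if locus == "a" else k_b)
    elif len(state) == 2:
        k = state[0]
    else:
        raise ValueError(f"unrecognized state {state!r}")
    return int(k) if k > 1 else 0


def _epoch_exponentials(Q_coal, Q_other, model, dt):
    """Cache of ``expm(Q^T * dt)`` keyed by demographic epoch."""
    cache = {}

    def get(t_mid: float) -> np.ndarray:
        k = int(model.epoch_index(t_mid))
        if k not in cache:
            Q = model.coal_rate(model.epoch_starts[k]) * Q_coal + Q_other
            cache[k] = expm(Q.T * dt)
        return cache[k]

    return get


class LengthGrid:
    """Solution slices of a length PDE at requested times.

    ``values[t_index]`` is an array ``(n_states, nx+1[, nx+1])`` of joint
    probabilities ``P[state, L <= x (, L_b <= y)]`` on the uniform length
    grid ``x_axis``; slices are linear interpolations between the two
    nearest solver steps.
    """

    def __init__(self, states, x_axis, times, values):
        self.states = states
        self.x_axis = np.asarray(x_axis)
        self.times = np.asarray(times)
        self.values = values

    def _interp_x(self, arr, x):
        x = min(max(float(x), self.x_axis[0]), self.x_axis[-1])
        j = min(int(np.searchsorted(self.x_axis, x, side="right")) - 1,
                len(self.x_axis) - 2)
        w = (x - self.x_axis[j]) / (self.x_axis[j + 1] - self.x_axis[j])
        return (1 - w) * arr[..., j] + w * arr[..., j + 1]

    def at(self, t_index: int, x: float, y: float | None = None) -> np.ndarray:
        """Per-state probabilities at the stored time, interpolated in space."""
        arr = self.values[t_index]
        if y is not None:
            arr = self._interp_x(arr, y)
        return self._interp_x(arr, x)


def _advect(F, shifts):
    """Exact integer-cell shift along the trailing axes; zero inflow."""
    for s, (vx, vy) in enumerate(shifts):
        if vx:
            F[s, vx:] = F[s, :-vx].copy()
            F[s, :vx] = 0.0
        if vy:
            F[s, :, vy:] = F[s, :, :-vy].copy()
            F[s, :, :vy] = 0.0
    return F


def _solve_length_pde(Q_coal, Q_other, model, init_index, velocities,
                      x_max, nx, record_times, two_d=False):
    """March the transport system to ``max(record_times)``.

    Returns a LengthGrid with slices at ``record_times`` (sorted).
    """
    record_times = np.sort(np.asarray(record_times, dtype=float))
    dx = x_max / nx
    dt = dx
    m = Q_coal.shape[0]
    shape = (m, nx + 1, nx + 1) if two_d else (m, nx + 1)
    F = np.zeros(shape)
    F[init_index] = 1.0
    shifts = list(velocities) if two_d else [(v, 0) for v in velocities]

    exp_half = _epoch_exponentials(Q_coal, Q_other, model, dt / 2.0)
    n_steps = int(np.ceil(record_times[-1] / dt - 1e-12))
    slices = [None] * len(record_times)
    prev = np.empty_like(F)

    def capture(t_prev, t_new, before, after):
        for i, tr in enumerate(record_times):
            if slices[i] is None and t_prev <= tr <= t_new + 1e-12:
                w = 0.0 if t_new == t_prev else (tr - t_prev) / (t_new - t_prev)
                slices[i] = (1 - w) * before + w * after

    capture(-1.0, 0.0, F, F)
    t = 0.0
    for _ in range(n_steps):
        prev[...] = F
        E = exp_half(t + dt / 2.0)
        F = (E @ F.reshape(m, -1)).reshape(shape)
        F = _advect(F, shifts)
        F = (E @ F.reshape(m, -1)).reshape(shape)
        capture(t, t + dt, prev, F)
        t += dt
    if any(s is None for s in slices):
        raise RuntimeError("internal: a requested time slice was not captured")
    return LengthGrid(None, np.linspace(0.0, x_max, nx + 1), record_times,
                      slices)


def solve_marginal_length_pde(spec: RhoProcessSpec, model: DemographicModel,
                              x_max: float, record_times, nx: int = DEFAULT_NX_1D,
                              locus: str = "a") -> LengthGrid:
    """Joint law of the two-locus process and one locus' accumulated length."""
    velocities = [velocity(s, locus) for s in spec.states]
    grid = _solve_length_pde(spec.Q_coal, spec.rho * spec.Q_recomb, model,
                             spec.index[spec.initial_state], velocities,
                             x_max, nx, record_times)
    grid.states = spec.states
    return grid


def solve_joint_length_pde(spec: RhoProcessSpec, model: DemographicModel,
                           x_max: float, record_times,
                           nx: int = DEFAULT_NX_2D) -> LengthGrid:
    """Joint law of the process and both loci's accumulated lengths."""
    velocities = [(velocity(s, "a"), velocity(s, "b")) for s in spec.states]
    grid = _solve_length_pde(spec.Q_coal, spec.rho * spec.Q_recomb, model,
                             spec.index[spec.initial_state], velocities,
                             x_max, nx, record_times, two_d=True)
    grid.states = spec.states
    return grid


def solve_theta_length_pde(spec: ThetaProcessSpec, model: DemographicModel,
                           x_max: float, record_times,
                           nx: int = DEFAULT_NX_1D) -> LengthGrid:
    """Joint law of the mutation process and its accumulated tree length."""
    velocities = [velocity(s) for s in spec.states]
    grid = _solve_length_pde(spec.Q_coal, spec.theta * spec.Q_mut, model,
                             spec.index[spec.initial_state], velocities,
                             x_max, nx, record_times)
    grid.states = spec.states
    return grid


def joint_length_cdf(spec: RhoProcessSpec, grid: LengthGrid, t_index: int,
                     x: float, y: float) -> float:
    """``P[L_a <= x, L_b <= y]`` from a joint solution slice.

    Valid for any recorded time ``t >= max(x, y) / 2``: beyond that point
    no further length can accumulate below the thresholds, because a locus
    still short of its MRCA adds at least two units per unit time, so the
    absorbing-state mass below ``(x, y)`` is already settled.
    """
    vals = grid.at(t_index, x, y)
    total = vals[spec.index[(1, 0, 0, 0)]]
    if (1, 0, 0, 1) in spec.index:
        total += vals[spec.index[(1, 0, 0, 1)]]
    return float(total)


def build_transition_length(model: DemographicModel, n: int,
                            disc: Discretization, rho: float | None = None,
                            nx: int = DEFAULT_NX_2D,
                            nx_marginal: int | None = None) -> TransitionSet:
    """HMM transition matrix with total branch length as hidden state.

    The marginal (infinite-boundary) column is evaluated on the same grid
    resolution as the joint solve so the two discretization errors cancel
    in the probability-mass differencing.
    """
    if rho is None:
        rho = model.rho
    spec = enumerate_rho_states(n, rho)
    bounds = disc.boundaries
    finite = disc.finite_boundaries
    S = disc.S
    x_max = finite[-1]
    dx = x_max / nx
    # one common evaluation time past every front: every entry of the CDF
    # matrix is settled for t >= max(x, y)/2, and reading all entries from
    # a single slice keeps the differencing internally consistent (the
    # zero-recombination limit then collapses to the identity exactly)
    t_star = x_max / 2.0 + 10.0 * dx
    # snap boundaries to grid nodes so joint and marginal reads coincide
    ix = np.clip(np.rint(finite / dx).astype(int), 1, nx)

    joint = solve_joint_length_pde(spec, model, x_max, [t_star], nx=nx)
    marg = solve_marginal_length_pde(spec, model, x_max, [t_star],
                                     nx=nx_marginal or nx)
    scale = (nx_marginal or nx) / nx
    ix_marg = np.clip(np.rint(ix * scale).astype(int), 1, nx_marginal or nx)
    a_done = [spec.index[s] for s in spec.states if velocity(s, "a") == 0]
    absorbed = [spec.index[(1, 0, 0, 0)]]
    if (1, 0, 0, 1) in spec.index:
        absorbed.append(spec.index[(1, 0, 0, 1)])

    F = joint.values[0]
    A_CDF = np.zeros((S + 1, S + 1))
    A_CDF[1:S, 1:S] = F[absorbed][:, ix][:, :, ix].sum(axis=0)
    A_CDF[1:S, S] = A_CDF[S, 1:S] = (
        marg.values[0][a_done][:, ix_marg].sum(axis=0))
    A_CDF[S, S] = 1.0
    return _finalize_transitions(np.clip(A_CDF, 0.0, 1.0), bounds, tol=1e-4)


def build_emission_length(model: DemographicModel, n: int,
                          disc: Discretization, theta: float | None = None,
                          nx: int = DEFAULT_NX_1D) -> EmissionSet:
    """HMM emission matrix with total branch length as hidden state."""
    if theta is None:
        theta = model.theta
    spec = enumerate_theta_states(n, theta)
    bounds = disc.boundaries
    finite = disc.finite_boundaries
    S = disc.S
    x_max = finite[-1]

    grid = solve_theta_length_pde(spec, model, x_max, finite / 2.0, nx=nx)
    B_CDF = np.zeros((S + 1, n))
    for i in range(1, S):
        vals = grid.at(i - 1, bounds[i])
        B_CDF[i] = _emission_cdf_rows(spec, vals[None, :])[0]
    # the infinite boundary carries the overall derived-allele distribution,
    # obtained from the eventual absorption of the mutation process
    t_far = max(_far_horizon(model), finite[-1])
    g_far = solve_theta_ode(spec, model, [t_far])[0]
    g_inf = g_far @ absorption_matrix(spec.rate_matrix(model, t_far))
    B_CDF[S] = _emission_cdf_rows(spec, g_inf[None, :])[0]

    B_PMF = B_CDF[1:] - B_CDF[:-1]
    if B_PMF.min() < -1e-5:
        raise RuntimeError(f"emission CDF differencing produced mass "
                           f"{B_PMF.min():.2e} < -1e-5")
    B_PMF = np.clip(B_PMF, 0.0, None)
    row_sums = B_PMF.sum(axis=1)
    if np.any(row_sums < 1e-12):
        raise RuntimeError("degenerate discretization: a hidden state has "
                           "vanishing marginal probability")
    B = B_PMF / row_sums[:, None]
    return EmissionSet(B_CDF, B_PMF, B, bounds.copy())
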