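"""Transition and emission probabilities for the tree-height hidden state.

Two augmented ancestral processes drive the computation:

* ``A_rho`` follows the lineages of n samples at two neighbouring loci
  backwards in time, permitting at most one recombination event between
  them.  States are tuples ``(k_ab, k_a, k_b, kappa)``: coupled lineages,
  lineages ancestral only to locus a, only to locus b, and the number of
  recombinations so far.  Its absorbing-state probabilities give the joint
  CDF of the two tree heights and hence the HMM transition matrix.
* ``A_theta`` follows one locus and permits at most one mutation.  States
  are ``(k, k_star)``: active lineages and the number of lineages at the
  time of the mutation (-1 before any mutation).  Its absorbing states give
  the joint CDF of tree height and emitted derived-allele count.

Both are continuous-time Markov chains with piecewise-constant-in-time rate
matrices ``Q(t) = lambda(t) * Q_coal + Q_other``; their distributions are
integrated with an explicit Dormand-Prince 8(5,3) Runge-Kutta scheme,
restarted at every rate change point.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.integrate import solve_ivp

from .demography import DemographicModel, Discretization

ODE_RTOL = 1e-9
ODE_ATOL = 1e-12


# ---------------------------------------------------------------------------
# state-space enumeration
# ---------------------------------------------------------------------------

@dataclass
class RhoProcessSpec:
    """Enumerated state space of the two-locus ancestral process."""

    n: int
    rho: float
    states: list
    index: dict
    absorbing: set
    Q_coal: np.ndarray   # multiply by lambda(t)
    Q_recomb: np.ndarray  # multiply by rho (already includes the 1/2)

    @property
    def initial_state(self):
        return (self.n, 0, 0, 0)

    def rate_matrix(self, model: DemographicModel, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be nonnegative")
        return model.coal_rate(t) * self.Q_coal + self.rho * self.Q_recomb


@dataclass
class ThetaProcessSpec:
    """Enumerated state space of the single-locus process with mutation."""

    n: int
    theta: float
    states: list
    index: dict
    absorbing: set
    Q_coal: np.ndarray  # multiply by lambda(t)
    Q_mut: np.ndarray   # multiply by theta (already includes the 1/2)

    @property
    def initial_state(self):
        return (self.n, -1)

    def rate_matrix(self, model: DemographicModel, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("time must be nonnegative")
        return model.coal_rate(t) * self.Q_coal + self.theta * self.Q_mut


def _rho_transitions(state, n):
    """Outgoing (target, coal_coeff, recomb_coeff) moves of one state."""
    k_ab, k_a, k_b, kappa = state
    out = []
    if k_ab >= 2:
        out.append(((k_ab - 1, k_a, k_b, kappa), comb(k_ab, 2), 0.0))
    if k_a >= 1:
        out.append(((k_ab, k_a - 1, k_b, kappa), comb(k_a, 2) + k_a * k_ab, 0.0))
    if k_b >= 1:
        out.append(((k_ab, k_a, k_b - 1, kappa), comb(k_b, 2) + k_b * k_ab, 0.0))
    if kappa == 0 and k_ab >= 2:
        # recombination decouples one shared lineage; at most one event is
        # tracked, and the fully-coalesced state (1,0,0,0) is absorbing so
        # it emits no formal recombination move
        out.append(((k_ab - 1, k_a + 1, k_b + 1, 1), 0.0, k_ab / 2.0))
    return out


def enumerate_rho_states(n: int, rho: float = 0.0) -> RhoProcessSpec:
    """Breadth-first closure of {(n,0,0,0)} under the two-locus moves."""
    if n < 2:
        raise ValueError("need at least two samples")
    absorbing = {(1, 0, 0, 0), (1, 0, 0, 1)}
    seen = {(n, 0, 0, 0)}
    frontier = [(n, 0, 0, 0)]
    while frontier:
        state = frontier.pop()
        if state in absorbing:
            continue
        for target, _, _ in _rho_transitions(state, n):
            if target not in seen:
                seen.add(target)
                frontier.append(target)
    states = sorted(seen)
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    Qc = np.zeros((m, m))
    Qr = np.zeros((m, m))
    for s in states:
        if s in absorbing:
            continue
        i = index[s]
        for target, c_coeff, r_coeff in _rho_transitions(s, n):
            j = index[target]
            Qc[i, j] += c_coeff
            Qr[i, j] += r_coeff
        Qc[i, i] = -Qc[i].sum()
        Qr[i, i] = -Qr[i].sum()
    return RhoProcessSpec(n, rho, states, index, absorbing & seen, Qc, Qr)


def enumerate_theta_states(n: int, theta: float = 0.0) -> ThetaProcessSpec:
    """Breadth-first closure of {(n,-1)} under coalescence and one mutation."""
    if n < 2:
        raise ValueError("need at least two samples")
    seen = {(n, -1)}
    frontier = [(n, -1)]
    moves = []
    while frontier:
        k, k_star = frontier.pop()
        out = []
        if k >= 2:
            out.append(((k - 1, k_star), comb(k, 2), 0.0))
            if k_star == -1:
                # a mutation may strike any of the k lineages; no second
                # mutation is permitted and k = 1 is already absorbed
                out.append(((k, k), 0.0, k / 2.0))
        moves.append(((k, k_star), out))
        for target, _, _ in out:
            if target not in seen:
                seen.add(target)
                frontier.append(target)
    states = sorted(seen)
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    Qc = np.zeros((m, m))
    Qm = np.zeros((m, m))
    for s, out in moves:
        i = index[s]
        for target, c_coeff, m_coeff in out:
            Qc[i, index[target]] += c_coeff
            Qm[i, index[target]] += m_coeff
        Qc[i, i] = -Qc[i].sum()
        Qm[i, i] = -Qm[i].sum()
    absorbing = {s for s in states if s[0] == 1}
    return ThetaProcessSpec(n, theta, states, index, absorbing, Qc, Qm)


def rho_rate_matrix(spec: RhoProcessSpec, model: DemographicModel,
                    t: float) -> np.ndarray:
    return spec.rate_matrix(model, t)


def theta_rate_matrix(spec: ThetaProcessSpec, model: DemographicModel,
                      t: float) -> np.ndarray:
    return spec.rate_matrix(model, t)


# ---------------------------------------------------------------------------
# ODE solution
# ---------------------------------------------------------------------------

def _solve_forward(Q_coal, Q_other, model: DemographicModel, g0,
                   eval_times) -> np.ndarray:
    """Integrate ``dg/dt = g (lambda(t) Q_coal + Q_other)`` at sorted times.

    The integration is restarted at every rate change point so the solver
    never steps across a coefficient discontinuity.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(np.diff(eval_times) < 0) or np.any(eval_times < 0):
        raise ValueError("eval_times must be nonnegative and nondecreasing")
    out = np.empty((len(eval_times), len(g0)))
    g = np.asarray(g0, dtype=float)
    t_now = 0.0
    pos = 0
    while pos < len(eval_times) and eval_times[pos] <= t_now:
        out[pos] = g
        pos += 1
    if pos == len(eval_times):
        return out
    t_end = eval_times[-1]
    segments = np.concatenate([
        model.change_points[(model.change_points > 0)
                            & (model.change_points < t_end)],
        [t_end],
    ])
    for seg_end in segments:
        if seg_end <= t_now:
            continue
        lam = model.coal_rate(0.5 * (t_now + min(seg_end, t_end)))
        Q = lam * Q_coal + Q_other
        inside = eval_times[(eval_times > t_now) & (eval_times <= seg_end)]
        t_eval = np.unique(np.concatenate([inside, [seg_end]]))
        sol = solve_ivp(lambda t, y: y @ Q, (t_now, seg_end), g,
                        method="DOP853", t_eval=t_eval,
                        rtol=ODE_RTOL, atol=ODE_ATOL)
        if not sol.success:
            raise RuntimeError(f"ODE solver failed near t={sol.t[-1]:g}: "
                               f"{sol.message}")
        for k, t in enumerate(sol.t):
            while pos < len(eval_times) and np.isclose(eval_times[pos], t):
                out[pos] = sol.y[:, k]
                pos += 1
        g = sol.y[:, -1]
        t_now = seg_end
    if pos != len(eval_times):
        raise RuntimeError("internal: not all evaluation times were filled")
    return np.clip(out, 0.0, None)


def solve_rho_ode(spec: RhoProcessSpec, model: DemographicModel,
                  eval_times) -> np.ndarray:
    """Distribution of ``A_rho`` at the requested times (rows)."""
    g0 = np.zeros(len(spec.states))
    g0[spec.index[spec.initial_state]] = 1.0
    return _solve_forward(spec.Q_coal, spec.rho * spec.Q_recomb, model, g0,
                          eval_times)


def solve_theta_ode(spec: ThetaProcessSpec, model: DemographicModel,
                    eval_times) -> np.ndarray:
    """Distribution of ``A_theta`` at the requested times (rows)."""
    g0 = np.zeros(len(spec.states))
    g0[spec.index[spec.initial_state]] = 1.0
    return _solve_forward(spec.Q_coal, spec.theta * spec.Q_mut, model, g0,
                          eval_times)


def absorption_matrix(Q: np.ndarray) -> np.ndarray:
    """Eventual absorbing-state distribution of a homogeneous chain.

    Row i gives the distribution over states at t = infinity, started from
    state i, for the constant rate matrix ``Q`` (absorbing rows are zero).
    Used to evaluate CDFs at the infinite discretization boundary.
    """
    m = Q.shape[0]
    absorbing = np.where(np.all(Q == 0.0, axis=1))[0]
    transient = np.setdiff1d(np.arange(m), absorbing)
    P = np.zeros((m, m))
    P[absorbing, absorbing] = 1.0
    if len(transient):
        Qtt = Q[np.ix_(transient, transient)]
        Qta = Q[np.ix_(transient, absorbing)]
        P[np.ix_(transient, absorbing)] = np.linalg.solve(-Qtt, Qta)
    return P


# ---------------------------------------------------------------------------
# joint tree-height CDF and the HMM matrices
# ---------------------------------------------------------------------------

def _rho_cdf_from_g(spec: RhoProcessSpec, model: DemographicModel,
                    g_min: np.ndarray, tau_min: float, tau_max: float) -> float:
    """P[T_first <= tau_min ; T_second <= tau_max] given g at tau_min.

    The locus with the smaller threshold must have coalesced by
    ``tau_min``; if only it has (one pending lineage pair remains after a
    recombination), the other locus coalesces in (tau_min, tau_max] with
    the pairwise-coalescence probability.
    """
    idx = spec.index
    val = g_min[idx[(1, 0, 0, 0)]]
    if (1, 0, 0, 1) in idx:
        val += g_min[idx[(1, 0, 0, 1)]]
    if (1, 0, 1, 1) in idx and tau_max > tau_min:
        integral = model.integrated_rate(tau_min, tau_max)
        val += g_min[idx[(1, 0, 1, 1)]] * -np.expm1(-integral)
    return float(val)


def joint_tmrca_cdf(spec: RhoProcessSpec, model: DemographicModel,
                    tau_a: float, tau_b: float) -> float:
    """Joint CDF ``P[T_a <= tau_a ; T_b <= tau_b]`` of the two tree heights.

    The two loci are exchangeable, so the smaller argument plays the role
    of the first-coalesced locus.
    """
    if tau_a < 0 or tau_b < 0:
        raise ValueError("thresholds must be nonnegative")
    lo, hi = min(tau_a, tau_b), max(tau_a, tau_b)
    if lo == 0.0:
        return 0.0
    if np.isinf(lo):
        lo = hi = _far_horizon(model, spec=None)
        g = solve_rho_ode(spec, model, [lo])[0]
        Q = spec.rate_matrix(model, lo)
        g = g @ absorption_matrix(Q)
        return _rho_cdf_from_g(spec, model, g, np.inf, np.inf)
    g = solve_rho_ode(spec, model, [lo])[0]
    return _rho_cdf_from_g(spec, model, g, lo, hi)


def _far_horizon(model: DemographicModel, spec=None) -> float:
    """A finite time by which residual transient mass is negligible."""
    last = model.change_points[-1] if len(model.change_points) else 0.0
    return last + 60.0 / float(np.exp(model.log_rates[-1]))


@dataclass
class TransitionSet:
    """Joint CDF/PMF of neighbouring-locus hidden states and the HMM rows.

    ``A_CDF`` is (S+1)x(S+1) on the boundary grid, ``A_PMF`` the SxS joint
    interval masses, ``A`` the row-normalized transition matrix, and ``Pi``
    the marginal state distribution (row sums of ``A_PMF``).
    """

    A_CDF: np.ndarray
    A_PMF: np.ndarray
    A: np.ndarray
    Pi: np.ndarray
    boundaries: np.ndarray


@dataclass
class EmissionSet:
    """Joint CDF/PMF of hidden state and derived-allele count, and ``B``."""

    B_CDF: np.ndarray
    B_PMF: np.ndarray
    B: np.ndarray
    boundaries: np.ndarray


def _difference_2d(cdf: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    pmf = (cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1])
    if pmf.min() < -tol:
        raise RuntimeError(f"joint CDF differencing produced mass "
                           f"{pmf.min():.2e} < -{tol:g}")
    return np.clip(pmf, 0.0, None)


def _finalize_transitions(A_CDF: np.ndarray, boundaries,
                          tol: float = 1e-6) -> TransitionSet:
    A_PMF = _difference_2d(A_CDF, tol)
    row_sums = A_PMF.sum(axis=1)
    if np.any(row_sums < 1e-12):
        raise RuntimeError("degenerate discretization: a hidden state has "
                           "vanishing marginal probability")
    A = A_PMF / row_sums[:, None]
    Pi = row_sums / row_sums.sum()
    return TransitionSet(A_CDF, A_PMF, A, Pi, np.asarray(boundaries))


def build_transition_tmrca(model: DemographicModel, n: int,
                           disc: Discretization,
                           rho: float | None = None) -> TransitionSet:
    """HMM transition matrix with tree height as hidden state.

    ``rho`` is the scaled recombination rate between two neighbouring
    bases, ``4 N0 r``, defaulting to the model's value.
    """
    if rho is None:
        rho = model.rho
    spec = enumerate_rho_states(n, rho)
    finite = disc.finite_boundaries
    t_far = max(_far_horizon(model), finite[-1])
    g = solve_rho_ode(spec, model, np.concatenate([finite, [t_far]]))
    g_inf = g[-1] @ absorption_matrix(spec.rate_matrix(model, t_far))

    S = disc.S
    A_CDF = np.zeros((S + 1, S + 1))
    bounds = disc.boundaries
    idx = spec.index
    has_pending = (1, 0, 1, 1) in idx
    for i in range(1, S + 1):
        for j in range(i, S + 1):
            if i == S and j == S:
                val = _rho_cdf_from_g(spec, model, g_inf, np.inf, np.inf)
            elif j == S:
                gi = g[i - 1]
                val = gi[idx[(1, 0, 0, 0)]]
                if (1, 0, 0, 1) in idx:
                    val += gi[idx[(1, 0, 0, 1)]]
                if has_pending:
                    val += gi[idx[(1, 0, 1, 1)]]
            else:
                val = _rho_cdf_from_g(spec, model, g[i - 1],
                                      bounds[i], bounds[j])
            A_CDF[i, j] = A_CDF[j, i] = val
    return _finalize_transitions(A_CDF, bounds)


def derived_allele_prob(n: int, k_star: int, d: int) -> float:
    """P[d derived alleles | the single mutation struck one of k_star lineages].

    Equals ``C(n-d-1, k_star-2) / C(n-1, k_star-1)``; zero when d is too
    large for the given k_star.
    """
    if not 2 <= k_star <= n:
        raise ValueError("k_star must be in 2..n")
    if not 1 <= d <= n - 1:
        raise ValueError("d must be in 1..n-1 (d = 0 is the no-mutation branch)")
    if n - d - 1 < k_star - 2:
        return 0.0
    return comb(n - d - 1, k_star - 2) / comb(n - 1, k_star - 1)


def _emission_cdf_rows(spec: ThetaProcessSpec, g_rows: np.ndarray) -> np.ndarray:
    """Map process distributions to joint (T <= t ; d) CDF rows."""
    n = spec.n
    out = np.zeros((g_rows.shape[0], n))
    out[:, 0] = g_rows[:, spec.index[(1, -1)]]
    for k_star in range(2, n + 1):
        col = g_rows[:, spec.index[(1, k_star)]]
        for d in range(1, n):
            p = derived_allele_prob(n, k_star, d)
            if p:
                out[:, d] += col * p
    return out


def build_emission_tmrca(model: DemographicModel, n: int,
                         disc: Discretization,
                         theta: float | None = None) -> EmissionSet:
    """HMM emission matrix with tree height as hidden state.

    ``theta`` is the scaled per-site mutation rate ``4 N0 mu``, defaulting
    to the model's value.
    """
    if theta is None:
        theta = model.theta
    spec = enumerate_theta_states(n, theta)
    finite = disc.finite_boundaries
    t_far = max(_far_horizon(model), finite[-1])
    g = solve_theta_ode(spec, model, np.concatenate([finite, [t_far]]))
    g_inf = g[-1] @ absorption_matrix(spec.rate_matrix(model, t_far))

    S = disc.S
    B_CDF = np.zeros((S + 1, n))
    B_CDF[1:S] = _emission_cdf_rows(spec, g[:-1])
    B_CDF[S] = _emission_cdf_rows(spec, g_inf[None, :])[0]
    B_PMF = B_CDF[1:] - B_CDF[:-1]
    if B_PMF.min() < -1e-6:
        raise RuntimeError(f"emission CDF differencing produced mass "
                           f"{B_PMF.min():.2e} < -1e-6")
    B_PMF = np.clip(B_PMF, 0.0, None)
    row_sums = B_PMF.sum(axis=1)
    if np.any(row_sums < 1e-12):
        raise RuntimeError("degenerate discretization: a hidden state has "
                           "vanishing marginal probability")
    B = B_PMF / row_sums[:, None]
    return EmissionSet(B_CDF, B_PMF, B, disc.boundaries.copy())
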