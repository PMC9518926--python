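"""EM inference of piecewise-constant population size histories.

The E-step runs the forward-backward algorithm over a composite-likelihood
collection of haplotype subsets (possibly of several sizes, possibly
overlapping) and aggregates expected transition/emission/initial counts
per subset size.  The M-step maximizes the expected complete-data
log-likelihood

    Q(lambda) = sum_i E[s1 = i] log Pi_i(lambda)
              + sum_ij E[#(i->j)] log A_ij(lambda)
              + sum_id E[#(i emits d)] log B_id(lambda)

summed across subset sizes, by Nelder-Mead search in the space of log
coalescent rates.  Summing sufficient statistics within a size class and
summing Q across classes is algebraically identical to summing per-subset
Q functions.  Optionally a smoothness penalty ``c12 * sum (delta adjacent
log-rates)^2`` regularizes the history.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import hypergeom

from . import length_probs, tmrca_probs
from .demography import (DemographicModel, Discretization,
                         length_discretization, tmrca_discretization,
                         watterson_init)
from .hmm_core import ObservationSequence, SufficientStats, \
    forward_backward_skipping
from .tmrca_probs import EmissionSet

DEFAULT_MAX_ITERS = {"tmrca": 25, "length": 15}


@dataclass
class SubsetScheme:
    """Haplotype subsets multiplied into the composite likelihood."""

    subsets: list
    mode: str = "by-sizes"
    sizes: list | None = None
    seed: int = 0

    def __post_init__(self):
        self.subsets = [tuple(int(i) for i in s) for s in self.subsets]
        for s in self.subsets:
            if len(s) < 2:
                raise ValueError("every subset needs at least two haplotypes")

    @property
    def distinct_sizes(self) -> list:
        return sorted({len(s) for s in self.subsets})

    def of_size(self, k: int) -> list:
        return [s for s in self.subsets if len(s) == k]

    @classmethod
    def all_pairs(cls, n: int) -> "SubsetScheme":
        """All overlapping pairs, the MSMC2-style scheme."""
        return cls(list(itertools.combinations(range(n), 2)),
                   mode="explicit")

    @classmethod
    def from_file(cls, path) -> "SubsetScheme":
        subsets = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    subsets.append(tuple(int(x) for x in line.split()))
        return cls(subsets, mode="explicit")


def build_subsets(n: int, sizes=None, seed: int = 0,
                  subsets=None) -> SubsetScheme:
    """Random non-overlapping partition per size, or explicit subsets.

    In by-sizes mode, for each requested size the sample is shuffled with
    the seeded RNG and chunked; a remainder smaller than the size is
    discarded.  Explicit subsets may overlap.
    """
    if subsets is not None:
        return SubsetScheme([tuple(s) for s in subsets], mode="explicit")
    if not sizes:
        raise ValueError("provide subset sizes or explicit subsets")
    rng = np.random.default_rng(seed)
    out = []
    for size in sizes:
        size = int(size)
        if size < 2:
            raise ValueError("subset size must be >= 2")
        if size > n:
            raise ValueError(f"subset size {size} exceeds sample size {n}")
        perm = rng.permutation(n)
        for k in range(n // size):
            out.append(tuple(sorted(perm[k * size:(k + 1) * size])))
    return SubsetScheme(out, mode="by-sizes", sizes=list(sizes), seed=seed)


@dataclass
class EMConfig:
    """Tunable knobs of the EM loop and its Nelder-Mead M-step."""

    max_iters: int | None = None     # default 25 (tree height) / 15 (length)
    nm_xtol: float = 1e-3            # simplex convergence in log-rate units
    nm_ftol: float = 1e-3
    nm_maxfev: int | None = None
    simplex_init_offset: float = 0.3   # absolute, used for < 5 parameters
    simplex_init_fraction: float = 0.05  # relative, used for >= 5 parameters
    regularization_c12: float = 0.0
    convergence_tol: float = 1e-6    # relative composite log-likelihood change
    seed: int = 0
    discretization_size: int = 16
    length_nx_2d: int = 300
    length_nx_1d: int = 1500

    def __post_init__(self):
        if self.max_iters is not None and self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        for name in ("nm_xtol", "nm_ftol", "convergence_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pseudo_haploid_emission(B_2n: EmissionSet, n: int) -> EmissionSet:
    """Down-sample a 2n-haplotype emission layer to n pseudo-haploids.

    The observable count for n pseudo-haploids is a hypergeometric draw of
    n alleles without replacement from the 2n underlying haplotypes.  Mass
    on the all-derived pseudo-haploid outcome (d = n), unobservable under
    the convention that monomorphic sites are recorded as d = 0, is folded
    back by row renormalization.
    """
    two_n = B_2n.B.shape[1]
    if two_n != 2 * n:
        raise ValueError("emission layer must be built for sample size 2n")
    H = np.zeros((two_n, n))
    for d_prime in range(two_n):
        H[d_prime] = hypergeom.pmf(np.arange(n), two_n, d_prime, n)
    B_PMF = B_2n.B_PMF @ H
    row_sums = B_PMF.sum(axis=1)
    return EmissionSet(B_2n.B_CDF @ H, B_PMF, B_PMF / row_sums[:, None],
                       B_2n.boundaries.copy())


def build_matrices(model: DemographicModel, n_s: int, disc: Discretization,
                   hidden_state: str = "tmrca", pseudo_haploid: bool = False,
                   rho_multiplier: float = 1.0, config: EMConfig | None = None):
    """(A, B, Pi) for one subset size under the given rate function."""
    rho = model.rho * rho_multiplier
    if pseudo_haploid:
        if hidden_state != "tmrca":
            raise ValueError("pseudo-haploid mode uses the tree-height state")
        n_build = 2 * n_s
    else:
        n_build = n_s
    if hidden_state == "tmrca":
        ts = tmrca_probs.build_transition_tmrca(model, n_build, disc, rho=rho)
        es = tmrca_probs.build_emission_tmrca(model, n_build, disc)
    elif hidden_state == "length":
        cfg = config or EMConfig()
        ts = length_probs.build_transition_length(model, n_build, disc,
                                                  rho=rho, nx=cfg.length_nx_2d)
        es = length_probs.build_emission_length(model, n_build, disc,
                                                nx=cfg.length_nx_1d)
    else:
        raise ValueError(f"unknown hidden state {hidden_state!r}")
    if pseudo_haploid:
        es = pseudo_haploid_emission(es, n_s)
    return ts.A, es.B, ts.Pi


def q_function(log_rates, stats_by_size: dict, base_model: DemographicModel,
               discs: dict, hidden_state: str = "tmrca",
               pseudo_haploid: bool = False, c12: float = 0.0,
               config: EMConfig | None = None) -> float:
    """Expected complete-data log-likelihood of a candidate rate vector."""
    model = base_model.with_log_rates(log_rates)
    total = 0.0
    for n_s, stats in stats_by_size.items():
        try:
            A, B, Pi = build_matrices(model, n_s, discs[n_s], hidden_state,
                                      pseudo_haploid, config=config)
        except (RuntimeError, FloatingPointError):
            return -np.inf
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))
                and np.all(np.isfinite(Pi))):
            return -np.inf
        for mat, counts in ((Pi, stats.expected_initial),
                            (A, stats.expected_transitions),
                            (B, stats.expected_emissions)):
            logm = np.log(np.clip(mat, 1e-300, None))
            total += float(np.sum(np.where(counts > 0, counts * logm, 0.0)))
    if c12 > 0 and len(log_rates) > 1:
        total -= c12 * float(np.sum(np.diff(np.asarray(log_rates)) ** 2))
    return total


def _initial_simplex(x0: np.ndarray, config: EMConfig) -> np.ndarray:
    """Simplex seeding: fixed +/- offsets along axes for few parameters,
    relative coordinate perturbations otherwise."""
    p = len(x0)
    simplex = np.tile(x0, (p + 1, 1))
    if p < 5:
        for i in range(p):
            sign = 1.0 if i % 2 == 0 else -1.0
            simplex[i + 1, i] += sign * config.simplex_init_offset
    else:
        for i in range(p):
            step = config.simplex_init_fraction * x0[i]
            if step == 0.0:
                step = config.simplex_init_fraction
            simplex[i + 1, i] += step
    return simplex


def m_step(stats_by_size: dict, current_params, config: EMConfig,
           base_model: DemographicModel, discs: dict,
           hidden_state: str = "tmrca",
           pseudo_haploid: bool = False) -> np.ndarray:
    """Nelder-Mead maximization of the Q function in log-rate space."""
    x0 = np.asarray(current_params, dtype=float)
    cache = {}

    def neg_q(x):
        key = tuple(np.round(x, 12))
        if key not in cache:
            cache[key] = -q_function(x, stats_by_size, base_model, discs,
                                     hidden_state, pseudo_haploid,
                                     config.regularization_c12, config)
        return cache[key]

    res = minimize(neg_q, x0, method="Nelder-Mead",
                   options={
                       "initial_simplex": _initial_simplex(x0, config),
                       "xatol": config.nm_xtol,
                       "fatol": config.nm_ftol,
                       "maxfev": config.nm_maxfev or 200 * len(x0),
                   })
    # never move to a point worse than the current one
    if neg_q(res.x) <= neg_q(x0):
        return np.asarray(res.x, dtype=float)
    return x0


class _ObservationCache:
    """Subset observations extracted once per (chromosome, subset)."""

    def __init__(self, data):
        self.data = list(data)
        self._cache = {}

    def get(self, chrom_idx: int, subset) -> ObservationSequence:
        key = (chrom_idx, subset)
        if key not in self._cache:
            self._cache[key] = self.data[chrom_idx].observations(subset)
        return self._cache[key]


def run_em(data, scheme: SubsetScheme, model0: DemographicModel,
           hidden_state: str = "tmrca", config: EMConfig | None = None,
           pseudo_haploid: bool = False, verbose: bool = False):
    """Full EM loop over one or more chromosomes.

    Parameters
    ----------
    data : sequence
        One entry per chromosome; each must provide
        ``observations(subset) -> ObservationSequence`` for a tuple of
        haplotype indices (see :class:`popsizehmm.simdata.SiteData`).
    scheme : SubsetScheme
        Composite-likelihood subsets (indices into the haplotype panel;
        in pseudo-haploid mode, into the pseudo-haploid panel).
    model0 : DemographicModel
        Initial model; its change points define the parameterization and
        stay fixed, only the per-epoch log rates are optimized.

    Returns
    -------
    (DemographicModel, list of per-iteration dict records)
    """
    config = config or EMConfig()
    max_iters = config.max_iters or DEFAULT_MAX_ITERS[hidden_state]
    S = config.discretization_size
    disc_fn = (tmrca_discretization if hidden_state == "tmrca"
               else length_discretization)
    discs = {}
    for n_s in scheme.distinct_sizes:
        n_build = 2 * n_s if pseudo_haploid else n_s
        discs[n_s] = disc_fn(S, n_build, model0)

    cache = _ObservationCache(data)
    model = model0
    history = []
    prev_ll = -np.inf
    for iteration in range(max_iters):
        stats_by_size = {}
        comp_ll = 0.0
        for n_s in scheme.distinct_sizes:
            A, B, Pi = build_matrices(model, n_s, discs[n_s], hidden_state,
                                      pseudo_haploid, config=config)
            agg = SufficientStats.zeros(len(Pi), n_s)
            for subset in scheme.of_size(n_s):
                for ci in range(len(cache.data)):
                    agg += forward_backward_skipping(
                        cache.get(ci, subset), A, B, Pi)
            stats_by_size[n_s] = agg
            comp_ll += agg.log_likelihood
        history.append({"iteration": iteration,
                        "composite_log_likelihood": float(comp_ll),
                        "log_rates": model.log_rates.tolist()})
        if verbose:
            print(f"  EM iter {iteration}: composite ll = {comp_ll:.3f}")
        if np.isfinite(prev_ll) and abs(comp_ll - prev_ll) \
                <= config.convergence_tol * abs(prev_ll):
            break
        prev_ll = comp_ll
        new_rates = m_step(stats_by_size, model.log_rates, config, model,
                           discs, hidden_state, pseudo_haploid)
        model = model.with_log_rates(new_rates)
    return model, history


def initial_model_from_data(data, n: int, mu: float, r: float,
                            change_points=None) -> DemographicModel:
    """Watterson initialization from segregating-site counts."""
    seg = 0
    loci = 0
    full = tuple(range(n))
    for chrom in data:
        obs = chrom.observations(full)
        seg += obs.num_segregating
        loci += obs.total_loci
    base = watterson_init(seg, n, loci, mu, r)
    if change_points is None:
        return base
    change_points = np.asarray(change_points, dtype=float)
    return DemographicModel(change_points,
                            np.zeros(len(change_points) + 1), base.N0, mu, r)
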