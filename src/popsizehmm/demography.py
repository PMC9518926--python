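"""Piecewise-constant demographic models and hidden-state discretizations.

Time is measured internally in coalescent units of ``2 * N0`` generations.
A demographic history is represented by the coalescent rate function
``lambda(t) = 1 / eta(t)``, where ``eta(t) = N(2 * N0 * t) / N0`` is the
population size relative to the reference diploid size ``N0``.  The rate is
piecewise constant and right-continuous: the epoch beginning at a change
point owns the value at that point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def harmonic_number(n: int) -> float:
    """Return ``a_n = sum_{i=1}^{n} 1/i`` (0 for n <= 0)."""
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


@dataclass
class DemographicModel:
    """Piecewise-constant coalescent rate history.

    Parameters
    ----------
    change_points : array-like
        Strictly increasing epoch start times in coalescent units; the first
        epoch starts at 0 implicitly and is not listed.
    log_rates : array-like
        One log coalescent rate per epoch (``len(change_points) + 1``
        values).  Working in log space keeps rates positive by construction.
    N0 : float
        Reference diploid population size (individuals).
    mu : float
        Per-generation per-site mutation probability.
    r : float
        Per-generation per-site recombination probability.
    """

    change_points: np.ndarray
    log_rates: np.ndarray
    N0: float
    mu: float = 1.25e-8
    r: float = 1.25e-8

    def __post_init__(self) -> None:
        self.change_points = np.asarray(self.change_points, dtype=float)
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        if self.change_points.ndim != 1 or self.log_rates.ndim != 1:
            raise ValueError("change_points and log_rates must be 1-D")
        if len(self.log_rates) != len(self.change_points) + 1:
            raise ValueError(
                "need exactly one log rate per epoch "
                f"({len(self.change_points) + 1} epochs, "
                f"{len(self.log_rates)} rates given)"
            )
        if len(self.change_points) and (
            np.any(np.diff(self.change_points) <= 0) or self.change_points[0] <= 0
        ):
            raise ValueError("change_points must be strictly increasing and > 0")

    # -- constructors -----------------------------------------------------

    @classmethod
    def constant(cls, N0: float, mu: float = 1.25e-8, r: float = 1.25e-8,
                 rate: float = 1.0) -> "DemographicModel":
        """Constant-size model: ``eta(t) = 1/rate`` for all t."""
        return cls(np.array([]), np.array([np.log(rate)]), N0, mu, r)

    @classmethod
    def from_sizes(cls, change_points_gen, sizes, N0: float | None = None,
                   mu: float = 1.25e-8, r: float = 1.25e-8) -> "DemographicModel":
        """Build from epoch start times in generations and diploid sizes.

        ``sizes[0]`` is the size of the epoch starting at the present; if
        ``N0`` is omitted it defaults to ``sizes[0]``.
        """
        sizes = np.asarray(sizes, dtype=float)
        change_points_gen = np.asarray(change_points_gen, dtype=float)
        if np.any(sizes <= 0):
            raise ValueError("population sizes must be positive")
        if N0 is None:
            N0 = float(sizes[0])
        cps = change_points_gen / (2.0 * N0)
        log_rates = np.log(N0 / sizes)
        return cls(cps, log_rates, N0, mu, r)

    # -- derived accessors ------------------------------------------------

    @property
    def rates(self) -> np.ndarray:
        return np.exp(self.log_rates)

    @property
    def theta(self) -> float:
        """Population-scaled per-site mutation rate ``4 * N0 * mu``."""
        return 4.0 * self.N0 * self.mu

    @property
    def rho(self) -> float:
        """Population-scaled per-base recombination rate ``4 * N0 * r``."""
        return 4.0 * self.N0 * self.r

    @property
    def epoch_starts(self) -> np.ndarray:
        return np.concatenate([[0.0], self.change_points])

    def epoch_index(self, t) -> np.ndarray:
        """Epoch owning time ``t`` (right-continuous at change points)."""
        return np.searchsorted(self.change_points, np.asarray(t, dtype=float),
                               side="right")

    def coal_rate(self, t):
        """Coalescent rate ``lambda(t)``; piecewise constant in t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        out = np.exp(self.log_rates[self.epoch_index(t)])
        return float(out) if out.ndim == 0 else out

    def integrated_rate(self, t_lo: float, t_hi: float) -> float:
        """Exact integral of ``lambda`` over ``[t_lo, t_hi]``.

        ``t_hi`` may be ``inf``; the result is then ``inf`` provided the
        terminal rate is positive (rates are positive by construction).
        """
        if t_lo < 0 or t_lo > t_hi:
            raise ValueError("need 0 <= t_lo <= t_hi")
        if t_lo == t_hi:
            return 0.0
        if np.isinf(t_hi):
            return np.inf
        starts = self.epoch_starts
        ends = np.concatenate([self.change_points, [np.inf]])
        lo = np.clip(starts, t_lo, t_hi)
        hi = np.clip(ends, t_lo, t_hi)
        return float(np.sum(np.exp(self.log_rates) * np.maximum(hi - lo, 0.0)))

    def inverse_integrated_rate(self, t_lo: float, target: float) -> float:
        """Smallest ``t`` with ``integrated_rate(t_lo, t) == target``.

        Used to draw coalescence times by inversion sampling.
        """
        if target < 0:
            raise ValueError("target must be nonnegative")
        if target == 0:
            return t_lo
        t = t_lo
        remaining = target
        k = int(self.epoch_index(t_lo))
        bounds = np.concatenate([self.change_points, [np.inf]])
        while True:
            rate = float(np.exp(self.log_rates[k]))
            span = bounds[k] - t
            if rate * span >= remaining:
                return t + remaining / rate
            remaining -= rate * span
            t = bounds[k]
            k += 1

    # -- user-facing conversion -------------------------------------------

    def size_at(self, k_generations):
        """Diploid population size ``N(k) = N0 / lambda(k / (2 N0))``."""
        t = np.asarray(k_generations, dtype=float) / (2.0 * self.N0)
        out = self.N0 / self.coal_rate(t)
        return float(out) if np.ndim(out) == 0 else out

    def size_history_table(self) -> pd.DataFrame:
        """Size history as (generation_start, generation_end, N_diploid)."""
        starts_gen = self.epoch_starts * 2.0 * self.N0
        ends_gen = np.concatenate([self.change_points * 2.0 * self.N0, [np.inf]])
        return pd.DataFrame({
            "generation_start": starts_gen,
            "generation_end": ends_gen,
            "N_diploid": self.N0 / np.exp(self.log_rates),
        })

    def with_log_rates(self, log_rates) -> "DemographicModel":
        return DemographicModel(self.change_points.copy(),
                                np.asarray(log_rates, dtype=float),
                                self.N0, self.mu, self.r)


def log_spaced_change_points(min_gen: float, max_gen: float, n_points: int,
                             N0: float) -> np.ndarray:
    """``n_points`` change points log-equidistant between two times (inclusive),
    given in generations, returned in coalescent units."""
    if not (0 < min_gen < max_gen):
        raise ValueError("need 0 < min_gen < max_gen")
    gens = np.exp(np.linspace(np.log(min_gen), np.log(max_gen), n_points))
    return gens / (2.0 * N0)


@dataclass
class Discretization:
    """Partition of ``[0, inf)`` into S hidden-state intervals.

    ``boundaries`` holds ``S + 1`` strictly increasing values with
    ``boundaries[0] == 0`` and ``boundaries[-1] == inf``.  Interval ``i``
    (0-based) is ``[boundaries[i], boundaries[i+1])``.
    """

    boundaries: np.ndarray
    S: int = field(init=False)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        b = self.boundaries
        if b[0] != 0.0 or not np.isinf(b[-1]) or np.any(np.isinf(b[:-1])):
            raise ValueError("boundaries must run from 0 to a single inf")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        self.S = len(b) - 1

    @property
    def finite_boundaries(self) -> np.ndarray:
        return self.boundaries[1:-1]

    def index(self, v) -> np.ndarray:
        """Interval index of value(s) ``v``: the unique i with
        ``boundaries[i] <= v < boundaries[i+1]``."""
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise ValueError("values must be nonnegative")
        idx = np.searchsorted(self.boundaries, v, side="right") - 1
        return int(idx) if idx.ndim == 0 else idx


def _mean_rate(model: DemographicModel) -> float:
    """Harmonic mean of the epoch rates (i.e. inverse mean relative size)."""
    return float(1.0 / np.mean(1.0 / np.exp(model.log_rates)))


def watterson_init(seg_sites: int, n: int, seq_len: int, mu: float,
                   r: float = 1.25e-8) -> DemographicModel:
    """Constant-size model initialized from Watterson's estimator.

    ``theta_hat = seg_sites / (seq_len * a_{n-1})`` per site, with
    ``a_{n-1} = sum_{i=1}^{n-1} 1/i``, and ``N0 = theta_hat / (4 mu)``.
    """
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if seq_len <= 0:
        raise ValueError("sequence length must be positive")
    if seg_sites == 0:
        raise ValueError(
            "no segregating sites: Watterson initialization is undefined; "
            "supply an initial demographic model explicitly"
        )
    theta_hat = seg_sites / (seq_len * harmonic_number(n - 1))
    return DemographicModel.constant(N0=theta_hat / (4.0 * mu), mu=mu, r=r)


def tmrca_cdf(x, n: int, rate: float = 1.0):
    """CDF of the tree height under a constant coalescent rate.

    ``T = sum_{k=2}^{n} T_k`` with ``T_k ~ Exp(rate * k(k-1)/2)`` — a
    hypoexponential with distinct rates.
    """
    rates = rate * np.arange(2, n + 1) * (np.arange(2, n + 1) - 1) / 2.0
    return _hypoexp_cdf(x, rates)


def tmrca_discretization(S: int, n: int, model: DemographicModel,
                         t_min: float | None = None,
                         t_max: float | None = None) -> Discretization:
    """Exponential-scale discretization for the tree-height hidden state.

    Interior boundaries are log-equidistant between ``t_min`` and
    ``t_max``, which default to the 0.5% and 99.5% quantiles of the tree
    height under a constant model at the harmonic-mean rate.  Anchoring
    the range at quantiles keeps every hidden state at appreciable
    marginal probability for any sample size (the height of an n-tree
    concentrates well away from zero once n is large).  Both ends can be
    overridden.
    """
    from scipy.optimize import brentq

    if S < 2:
        raise ValueError("need at least two hidden states")
    lbar = _mean_rate(model)
    upper = 60.0 / lbar
    if t_min is None:
        t_min = brentq(lambda x: float(tmrca_cdf(x, n, lbar)) - 0.005,
                       1e-12, upper)
    if t_max is None:
        t_max = brentq(lambda x: float(tmrca_cdf(x, n, lbar)) - 0.995,
                       1e-12, upper)
    if S == 2:
        interior = np.array([np.sqrt(t_min * t_max)])
    else:
        interior = np.exp(np.linspace(np.log(t_min), np.log(t_max), S - 1))
    return Discretization(np.concatenate([[0.0], interior, [np.inf]]))


def _hypoexp_cdf(x, rates: np.ndarray):
    """CDF of a sum of independent exponentials with distinct rates."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) == 1:
        return 1.0 - np.exp(-rates[0] * np.asarray(x, dtype=float))
    diff = rates[None, :] - rates[:, None]
    np.fill_diagonal(diff, 1.0)
    # w_k = prod_{j != k} a_j / (a_j - a_k)
    ratio = rates[None, :] / diff
    np.fill_diagonal(ratio, 1.0)
    w = np.prod(ratio, axis=1)
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.sum(w * (1.0 - np.exp(-np.outer(x, rates))), axis=-1)
    return float(out[0]) if scalar else out


def total_length_cdf(x, n: int, rate: float = 1.0):
    """CDF of the total branch length of a constant-rate coalescent tree.

    ``L = sum_{k=2}^{n} k * T_k`` with ``T_k ~ Exp(rate * k(k-1)/2)``, so
    ``k * T_k ~ Exp(rate * (k-1)/2)`` — a hypoexponential with distinct
    rates ``rate * (k-1)/2`` for k = 2..n.
    """
    rates = rate * (np.arange(2, n + 1) - 1) / 2.0
    return _hypoexp_cdf(x, rates)


def length_discretization(S: int, n: int, model: DemographicModel) -> Discretization:
    """Quantile discretization for the total-branch-length hidden state.

    Boundaries are the i/S quantiles (i = 1..S-1) of the total tree length
    under a constant-size model at the harmonic-mean rate, making the
    marginal state distribution approximately uniform.
    """
    from scipy.optimize import brentq

    if S < 2:
        raise ValueError("need at least two hidden states")
    lbar = _mean_rate(model)
    # generous upper bracket: mean + many sds of L
    upper = (2.0 * harmonic_number(n - 1) / lbar) * 50.0 + 50.0 / lbar
    interior = [
        brentq(lambda x, q=i / S: float(total_length_cdf(x, n, lbar)) - q,
               1e-12, upper)
        for i in range(1, S)
    ]
    return Discretization(np.concatenate([[0.0], interior, [np.inf]]))
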