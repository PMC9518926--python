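"""Scaled forward-backward machinery over run-length-encoded sequences.

Genomic observation sequences are dominated by long invariant stretches
(derived-allele count 0).  Sequences are therefore stored run-length
encoded, and the forward-backward recursions can either be unrolled locus
by locus (:func:`forward_backward`, the reference implementation) or
advanced across each homogeneous run in one step through powers of
``M_d = A @ diag(B[:, d])`` (:func:`forward_backward_skipping`).  Within a
run the expected transition and occupancy counts are accumulated exactly
using the spectral decomposition of ``M_d``; if the eigenbasis is too
ill-conditioned the code falls back to the per-locus recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EIG_COND_MAX = 1e8


@dataclass
class ObservationSequence:
    """Run-length-encoded derived-allele counts along one chromosome."""

    n: int
    d_values: np.ndarray
    run_lengths: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.d_values = np.asarray(self.d_values, dtype=np.int64)
        self.run_lengths = np.asarray(self.run_lengths, dtype=np.int64)
        if len(self.d_values) != len(self.run_lengths):
            raise ValueError("d_values and run_lengths must align")
        if len(self.d_values) == 0:
            raise ValueError("empty observation sequence")
        if np.any(self.run_lengths < 1):
            raise ValueError("run lengths must be >= 1")
        if np.any(self.d_values < 0) or np.any(self.d_values > self.n - 1):
            raise ValueError("derived counts must lie in 0..n-1")

    @property
    def total_loci(self) -> int:
        return int(self.run_lengths.sum())

    @classmethod
    def from_values(cls, values, n: int, chrom: str = "1") -> "ObservationSequence":
        """Compress a per-locus vector of derived-allele counts."""
        values = np.asarray(values, dtype=np.int64)
        if len(values) == 0:
            raise ValueError("empty observation sequence")
        edges = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(values)]])
        return cls(n, values[starts], ends - starts, chrom)

    @classmethod
    def from_site_counts(cls, positions, counts, n: int,
                         seq_len: int | None = None,
                         chrom: str = "1") -> "ObservationSequence":
        """Build from sparse SNP positions (0-based) and their counts.

        Loci between SNPs become invariant (d = 0) runs.  With ``seq_len``
        the sequence covers ``[0, seq_len)``; otherwise it covers the span
        from the first to the last polymorphic site.
        """
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if np.any(np.diff(positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        keep = counts != 0
        positions, counts = positions[keep], counts[keep]
        if seq_len is None:
            if len(positions) == 0:
                raise ValueError("no polymorphic sites and no sequence length")
            offset, end = positions[0], positions[-1] + 1
        else:
            offset, end = 0, int(seq_len)
            if len(positions) and positions[-1] >= end:
                raise ValueError("SNP position beyond sequence length")
        d_vals, lens = [], []
        cursor = offset
        for pos, c in zip(positions, counts):
            if pos > cursor:
                d_vals.append(0)
                lens.append(pos - cursor)
            d_vals.append(int(c))
            lens.append(1)
            cursor = pos + 1
        if end > cursor:
            d_vals.append(0)
            lens.append(end - cursor)
        if not d_vals:
            d_vals, lens = [0], [end - offset]
        return cls(n, np.array(d_vals), np.array(lens), chrom)

    def to_values(self) -> np.ndarray:
        return np.repeat(self.d_values, self.run_lengths)

    @property
    def num_segregating(self) -> int:
        return int(self.run_lengths[self.d_values > 0].sum())


@dataclass
class SufficientStats:
    """Expected HMM counts from one or more sequences at subset size n_s."""

    expected_transitions: np.ndarray
    expected_emissions: np.ndarray
    expected_initial: np.ndarray
    log_likelihood: float
    n_s: int
    n_sequences: int = 1

    def __iadd__(self, other: "SufficientStats") -> "SufficientStats":
        if other.n_s != self.n_s:
            raise ValueError("cannot aggregate stats across subset sizes")
        if other.expected_transitions.shape != self.expected_transitions.shape:
            raise ValueError("cannot aggregate stats across discretizations")
        self.expected_transitions += other.expected_transitions
        self.expected_emissions += other.expected_emissions
        self.expected_initial += other.expected_initial
        self.log_likelihood += other.log_likelihood
        self.n_sequences += other.n_sequences
        return self

    @classmethod
    def zeros(cls, S: int, n_s: int) -> "SufficientStats":
        return cls(np.zeros((S, S)), np.zeros((S, n_s)), np.zeros(S), 0.0,
                   n_s, n_sequences=0)


def _validate(obs: ObservationSequence, A, B, Pi):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    S = A.shape[0]
    if A.shape != (S, S) or B.shape[0] != S or Pi.shape != (S,):
        raise ValueError("inconsistent matrix shapes")
    if B.shape[1] != obs.n:
        raise ValueError(f"emission alphabet {B.shape[1]} does not match "
                         f"sample size {obs.n}")
    if not (np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
            and np.allclose(B.sum(axis=1), 1.0, atol=1e-6)
            and np.isclose(Pi.sum(), 1.0, atol=1e-6)):
        raise ValueError("A, B rows and Pi must be stochastic")
    return A, B, Pi


def forward_backward(obs: ObservationSequence, A, B, Pi,
                     return_posterior: bool = False):
    """Reference scaled forward-backward, unrolled locus by locus."""
    A, B, Pi = _validate(obs, A, B, Pi)
    d = obs.to_values()
    L = len(d)
    S = A.shape[0]
    alpha = np.empty((L, S))
    scale = np.empty(L)
    v = Pi * B[:, d[0]]
    scale[0] = v.sum()
    if scale[0] <= 0:
        raise ZeroDivisionError("locus 0 has zero emission probability")
    alpha[0] = v / scale[0]
    for l in range(1, L):
        v = (alpha[l - 1] @ A) * B[:, d[l]]
        scale[l] = v.sum()
        if scale[l] <= 0:
            raise ZeroDivisionError(f"locus {l} has zero emission probability")
        alpha[l] = v / scale[l]

    beta = np.empty((L, S))
    beta[-1] = 1.0
    trans = np.zeros((S, S))
    emit = np.zeros((S, obs.n))
    for l in range(L - 2, -1, -1):
        w = B[:, d[l + 1]] * beta[l + 1]
        trans += np.outer(alpha[l], w / scale[l + 1]) * A
        beta[l] = (A @ w) / scale[l + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    for sym in np.unique(d):
        emit[:, sym] = gamma[d == sym].sum(axis=0)
    stats = SufficientStats(trans, emit, gamma[0].copy(),
                            float(np.log(scale).sum()), obs.n)
    if return_posterior:
        return stats, gamma
    return stats


class _RunOperator:
    """Spectral helper for powers of ``M = A @ diag(B[:, d])``."""

    def __init__(self, A, B_col):
        self.M = A * B_col[None, :]
        lam, U = np.linalg.eig(self.M)
        self.ok = np.linalg.cond(U) < _EIG_COND_MAX
        if self.ok:
            self.lam = lam
            self.U = U
            self.V = np.linalg.inv(U)
            self.smax = max(np.abs(lam).max(), 1e-300)
            self.mu = lam / self.smax

    def propagate(self, vec, m: int, transpose: bool = False):
        """``vec @ M^m`` (or ``M^m @ vec``), returned normalized with the
        log of the dropped factor."""
        if m == 0:
            return vec, 0.0
        if not self.ok:
            logn = 0.0
            for _ in range(m):
                vec = (self.M.T @ vec) if transpose else (vec @ self.M)
                s = np.abs(vec).sum()
                vec = vec / s
                logn += np.log(s)
            return vec, logn
        mu_m = self.mu ** m
        if transpose:
            out = (self.U @ (mu_m * (self.V @ vec))).real
        else:
            out = ((vec @ self.U) * mu_m @ self.V).real
        s = np.abs(out).sum()
        if s <= 0:
            raise ZeroDivisionError("run propagation annihilated the state "
                                    "distribution")
        return out / s, np.log(s) + m * np.log(self.smax)

    def _pair_power_sum(self, m: int) -> np.ndarray:
        """``W[r, s] = sum_{p=0}^{m-1} mu_r^p mu_s^{m-1-p}`` (scale-free)."""
        mu = self.mu
        num = mu[:, None] ** m - mu[None, :] ** m
        den = mu[:, None] - mu[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            W = num / den
        close = np.abs(den) < 1e-9
        if np.any(close):
            avg = 0.5 * (mu[:, None] + mu[None, :])
            W = np.where(close, m * avg ** max(m - 1, 0), W)
        return W

    def pair_sums(self, a, b, m: int) -> np.ndarray:
        """``G[i, j] = sum_{p=0}^{m-1} (a M^p)_i (M^{m-1-p} b)_j`` divided
        by ``smax^{m-1}`` (the caller cancels the factor against Z)."""
        c = a @ self.U
        e = self.V @ b
        W = self._pair_power_sum(m)
        G = (self.V.T * c[None, :]) @ (W * e[None, :]) @ self.U.T
        return G.real

    def z_scaled(self, a, b, m: int) -> float:
        """``a M^m b / smax^m`` (scale-free bridge normalizer)."""
        c = a @ self.U
        e = self.V @ b
        return float((c * self.mu ** m @ e).real)


def forward_backward_skipping(obs: ObservationSequence, A, B, Pi,
                              return_posterior: bool = False):
    """Forward-backward advancing each homogeneous run in one step.

    Produces the same log-likelihood and expected counts as
    :func:`forward_backward` (up to numerical tolerance) at cost
    proportional to the number of runs rather than the number of loci.
    """
    A, B, Pi = _validate(obs, A, B, Pi)
    S = A.shape[0]
    d = obs.d_values
    lens = obs.run_lengths
    R = len(d)
    ops = {sym: _RunOperator(A, B[:, sym]) for sym in np.unique(d)}

    # forward: alpha at the first and last locus of every run
    a_start = np.empty((R, S))
    a_end = np.empty((R, S))
    loglik = 0.0
    v = Pi * B[:, d[0]]
    s = v.sum()
    if s <= 0:
        raise ZeroDivisionError("locus 0 has zero emission probability")
    loglik += np.log(s)
    a_start[0] = v / s
    for r in range(R):
        if r > 0:
            v = a_end[r - 1] @ ops[d[r]].M
            s = v.sum()
            if s <= 0:
                raise ZeroDivisionError(
                    f"run {r} (symbol {d[r]}) has zero emission probability")
            loglik += np.log(s)
            a_start[r] = v / s
        vec, logn = ops[d[r]].propagate(a_start[r], int(lens[r]) - 1)
        a_end[r] = vec
        loglik += logn

    # backward: beta at the last and first locus of every run
    b_end = np.empty((R, S))
    b_start = np.empty((R, S))
    b_end[-1] = 1.0 / S
    for r in range(R - 1, -1, -1):
        vec, _ = ops[d[r]].propagate(b_end[r], int(lens[r]) - 1,
                                     transpose=True)
        b_start[r] = vec
        if r > 0:
            w = ops[d[r]].M @ b_start[r]
            b_end[r - 1] = w / np.abs(w).sum()

    trans = np.zeros((S, S))
    emit = np.zeros((S, obs.n))
    for r in range(R):
        op = ops[d[r]]
        m = int(lens[r])
        a, b = a_start[r], b_end[r]
        if op.ok:
            # scale-free ratios: pair_sums(m) carries smax^(m-1), and
            # z_scaled(m-1) carries smax^-(m-1), so occupancy needs no
            # correction while the transition sum is one power short
            Zs = op.z_scaled(a, b, m - 1)
            occ = np.diag(op.pair_sums(a, b, m)) / Zs
            if m > 1:
                G = op.pair_sums(a, b, m - 1)
                trans += (A * B[:, d[r]][None, :] * G) / (Zs * op.smax)
        else:
            occ = np.zeros(S)
            alpha_l = a.copy()
            # exact per-locus recursion within the run
            fwd = [alpha_l]
            for _ in range(m - 1):
                v = fwd[-1] @ op.M
                fwd.append(v / v.sum())
            beta_l = b.copy()
            bwd = [beta_l]
            for _ in range(m - 1):
                w = op.M @ bwd[-1]
                bwd.append(w / np.abs(w).sum())
            bwd = bwd[::-1]
            for p in range(m):
                g = fwd[p] * bwd[p]
                occ += g / g.sum()
            for p in range(m - 1):
                xi = np.outer(fwd[p], B[:, d[r]] * bwd[p + 1]) * A
                trans += xi / xi.sum()
        emit[:, d[r]] += occ
        if r < R - 1:
            xi = np.outer(a_end[r], B[:, d[r + 1]] * b_start[r + 1]) * A
            trans += xi / xi.sum()

    init = a_start[0] * b_start[0]
    init /= init.sum()
    stats = SufficientStats(trans, emit, init, float(loglik), obs.n)
    if return_posterior:
        post = a_start * b_start
        post /= post.sum(axis=1, keepdims=True)
        return stats, post
    return stats


@dataclass
class MetaObservation:
    """Windowed (meta-locus) compression of an observation sequence.

    Each window of ``w`` loci is assumed to share one hidden state; its
    emission probability is the product of the per-site emissions of the
    SNP counts it contains plus the remaining invariant sites.  Adjacent
    windows are linked by a transition matrix built at the rescaled
    recombination distance ``w * rho``.
    """

    n: int
    window: int
    snp_counts: list            # per window: array of nonzero d values
    invariant_counts: np.ndarray  # per window: number of d = 0 loci
    rho_multiplier: int = field(init=False)

    def __post_init__(self):
        self.rho_multiplier = self.window


def meta_locus_compress(obs: ObservationSequence, w: int) -> MetaObservation:
    """Partition a sequence into meta-loci of ``w`` sites."""
    if w < 1:
        raise ValueError("window size must be >= 1")
    values = obs.to_values()
    L = len(values)
    starts = np.arange(0, L, w)
    snp_counts = []
    invariant = np.empty(len(starts), dtype=np.int64)
    for k, s in enumerate(starts):
        chunk = values[s:s + w]
        nz = chunk[chunk > 0]
        snp_counts.append(nz.copy())
        invariant[k] = len(chunk) - len(nz)
    return MetaObservation(obs.n, w, snp_counts, invariant)


def forward_backward_meta(meta: MetaObservation, A_meta, B, Pi):
    """Forward-backward over meta-loci with product emissions.

    ``A_meta`` must be built with the recombination rate scaled by the
    window size (``meta.rho_multiplier``).
    """
    B = np.asarray(B, dtype=float)
    A_meta = np.asarray(A_meta, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    S = A_meta.shape[0]
    T = len(meta.snp_counts)
    logB = np.log(np.clip(B, 1e-300, None))
    log_e = np.empty((T, S))
    for t in range(T):
        vec = meta.invariant_counts[t] * logB[:, 0]
        for dv in meta.snp_counts[t]:
            vec = vec + logB[:, dv]
        log_e[t] = vec
    # scale each window emission to avoid underflow
    offsets = log_e.max(axis=1)
    E = np.exp(log_e - offsets[:, None])

    alpha = np.empty((T, S))
    scale = np.empty(T)
    v = Pi * E[0]
    scale[0] = v.sum()
    alpha[0] = v / scale[0]
    for t in range(1, T):
        v = (alpha[t - 1] @ A_meta) * E[t]
        scale[t] = v.sum()
        if scale[t] <= 0:
            raise ZeroDivisionError(f"meta-locus {t} has zero emission "
                                    "probability")
        alpha[t] = v / scale[t]
    beta = np.empty((T, S))
    beta[-1] = 1.0
    trans = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        w_vec = E[t + 1] * beta[t + 1]
        trans += np.outer(alpha[t], w_vec / scale[t + 1]) * A_meta
        beta[t] = (A_meta @ w_vec) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    emit = np.zeros((S, meta.n))
    for t in range(T):
        emit[:, 0] += gamma[t] * meta.invariant_counts[t]
        for dv in meta.snp_counts[t]:
            emit[:, dv] += gamma[t]
    loglik = float(np.log(scale).sum() + offsets.sum())
    return SufficientStats(trans, emit, gamma[0].copy(), loglik, meta.n)
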