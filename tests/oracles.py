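"""Independent Monte-Carlo oracles for the ancestral processes.

These simulators implement the two-locus recombination process and the
single-locus mutation process directly from their transition-rate tables,
sharing no code with the ODE/PDE machinery they are used to validate.
Constant coalescent rate only.
"""

import numpy as np


def simulate_two_locus(n, rho, lam=1.0, reps=100_000, seed=0):
    """Jump-chain simulation of the two-locus ancestral process.

    Returns dict with arrays ``Ta``, ``Tb`` (per-locus coalescence times)
    and ``La``, ``Lb`` (accumulated branch lengths).
    """
    rng = np.random.default_rng(seed)
    kab = np.full(reps, n, dtype=np.int64)
    ka = np.zeros(reps, dtype=np.int64)
    kb = np.zeros(reps, dtype=np.int64)
    kappa = np.zeros(reps, dtype=np.int64)
    t = np.zeros(reps)
    Ta = np.full(reps, np.nan)
    Tb = np.full(reps, np.nan)
    La = np.zeros(reps)
    Lb = np.zeros(reps)
    while True:
        active = ~((kab == 1) & (ka == 0) & (kb == 0))
        if not active.any():
            break
        idx = np.flatnonzero(active)
        c_ab = kab[idx] * (kab[idx] - 1) / 2.0
        c_a = ka[idx] * (ka[idx] - 1) / 2.0 + ka[idx] * kab[idx]
        c_b = kb[idx] * (kb[idx] - 1) / 2.0 + kb[idx] * kab[idx]
        rec = np.where(kappa[idx] == 0, kab[idx] * rho / 2.0, 0.0)
        rates = np.stack([lam * c_ab, lam * c_a, lam * c_b, rec], axis=1)
        total = rates.sum(axis=1)
        dt = rng.exponential(1.0 / total)
        va = np.where(kab[idx] + ka[idx] > 1, kab[idx] + ka[idx], 0)
        vb = np.where(kab[idx] + kb[idx] > 1, kab[idx] + kb[idx], 0)
        La[idx] += va * dt
        Lb[idx] += vb * dt
        t[idx] += dt
        u = rng.random(len(idx)) * total
        cum = np.cumsum(rates, axis=1)
        move = (u[:, None] >= cum).sum(axis=1)
        m0, m1, m2, m3 = (move == 0), (move == 1), (move == 2), (move == 3)
        kab[idx[m0]] -= 1
        ka[idx[m1]] -= 1
        kb[idx[m2]] -= 1
        kab[idx[m3]] -= 1
        ka[idx[m3]] += 1
        kb[idx[m3]] += 1
        kappa[idx[m3]] += 1
        done_a = (kab[idx] + ka[idx] == 1) & np.isnan(Ta[idx])
        Ta[idx[done_a]] = t[idx[done_a]]
        done_b = (kab[idx] + kb[idx] == 1) & np.isnan(Tb[idx])
        Tb[idx[done_b]] = t[idx[done_b]]
    return {"Ta": Ta, "Tb": Tb, "La": La, "Lb": Lb}


def simulate_mutation_process(n, theta, lam=1.0, reps=100_000, seed=0):
    """Jump-chain simulation of the single-locus process with one mutation.

    Returns dict with ``T`` (tree height), ``L`` (total branch length) and
    ``k_star`` (lineage count at the mutation; -1 if none).
    """
    rng = np.random.default_rng(seed)
    k = np.full(reps, n, dtype=np.int64)
    k_star = np.full(reps, -1, dtype=np.int64)
    t = np.zeros(reps)
    L = np.zeros(reps)
    while True:
        idx = np.flatnonzero(k > 1)
        if len(idx) == 0:
            break
        coal = lam * k[idx] * (k[idx] - 1) / 2.0
        mut = np.where(k_star[idx] == -1, k[idx] * theta / 2.0, 0.0)
        total = coal + mut
        dt = rng.exponential(1.0 / total)
        t[idx] += dt
        L[idx] += k[idx] * dt
        is_mut = rng.random(len(idx)) * total < mut
        k_star[idx[is_mut]] = k[idx[is_mut]]
        k[idx[~is_mut]] -= 1
    return {"T": t, "L": L, "k_star": k_star}


def empirical_joint_cdf(xs, ys, x_grid, y_grid):
    """Empirical P[X <= x, Y <= y] and its binomial standard error."""
    p = np.empty((len(x_grid), len(y_grid)))
    m = len(xs)
    for i, x in enumerate(x_grid):
        for j, y in enumerate(y_grid):
            p[i, j] = np.mean((xs <= x) & (ys <= y))
    se = np.sqrt(np.clip(p * (1 - p), 1e-12, None) / m)
    return p, se
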