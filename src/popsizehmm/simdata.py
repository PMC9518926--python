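"""Synthetic data generation and accuracy metrics.

Two fidelities of test input are provided:

* :func:`sample_from_chmm` draws observation sequences directly from given
  HMM matrices — a model-exact source for mismatch-free EM recovery tests.
* :func:`simulate_sequence` runs a sequential (Markovian) coalescent along
  a chromosome: the first genealogy is drawn from the time-varying
  coalescent; moving along the sequence, recombination events detach the
  lineage above a uniformly chosen tree point, which then re-coalesces at
  rate ``lambda(t)`` into the remaining branches.  Mutations are laid on
  branches as a Poisson process under the infinite-sites idealization (at
  most one mutation per base; collisions are redrawn) and written out as
  derived-allele genotypes, optionally in VCF form.

The inference-accuracy metrics are the mean absolute log-size error
``Delta(k)`` across replicates at generation k, and its integral ``phi``
against ``log k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import DemographicModel
from .hmm_core import ObservationSequence


@dataclass
class SimulationScenario:
    """A replicate-generating configuration."""

    truth: DemographicModel
    n: int
    seq_len: int
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.seq_len < 1 or self.replicates < 1:
            raise ValueError("seq_len and replicates must be >= 1")


@dataclass
class SiteData:
    """Polymorphic sites of one simulated or parsed chromosome.

    ``genotypes`` is a 0/1 matrix (haplotypes x SNPs) with 1 marking the
    derived allele; ``positions`` are 0-based and strictly increasing.
    """

    chrom: str
    seq_len: int
    positions: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or \
                self.genotypes.shape[1] != len(self.positions):
            raise ValueError("genotypes must be (haplotypes, n_sites)")
        if len(self.positions) and (
                np.any(np.diff(self.positions) <= 0)
                or self.positions[0] < 0
                or self.positions[-1] >= self.seq_len):
            raise ValueError("positions must be increasing within [0, seq_len)")

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[0]

    def observations(self, subset) -> ObservationSequence:
        """Derived-allele counts over a haplotype subset, RLE-compressed.

        Sites where every subset member carries the derived allele are
        recorded as invariant (d = 0), matching the convention that only
        within-subset polymorphism is informative.
        """
        subset = tuple(subset)
        sub = self.genotypes[list(subset)]
        # a site with a missing call (-1) in the subset is treated invariant
        missing = (sub < 0).any(axis=0)
        counts = np.where(missing, 0,
                          np.clip(sub, 0, None).sum(axis=0)).astype(np.int64)
        counts[counts == len(subset)] = 0
        return ObservationSequence.from_site_counts(
            self.positions, counts, n=len(subset), seq_len=self.seq_len,
            chrom=self.chrom)

    def pseudo_haploidize(self, rng) -> "SiteData":
        """One uniformly chosen allele per diploid individual per site."""
        n = self.n_haplotypes
        if n % 2:
            raise ValueError("need an even number of haplotypes to form "
                             "diploid individuals")
        picks = rng.integers(0, 2, size=(n // 2, len(self.positions)))
        rows = 2 * np.arange(n // 2)[:, None] + picks
        geno = self.genotypes[rows, np.arange(len(self.positions))[None, :]]
        return SiteData(self.chrom, self.seq_len, self.positions.copy(),
                        geno)


# ---------------------------------------------------------------------------
# model-exact sampling
# ---------------------------------------------------------------------------

def sample_from_chmm(A, B, Pi, n_loci: int, seed: int = 0,
                     chrom: str = "1") -> ObservationSequence:
    """Draw an observation sequence from explicit HMM matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    S, n = B.shape
    rng = np.random.default_rng(seed)
    cumA = np.cumsum(A, axis=1)
    states = np.empty(n_loci, dtype=np.int64)
    us = rng.random(n_loci)
    s = int(np.searchsorted(np.cumsum(Pi), us[0], side="right"))
    states[0] = min(s, S - 1)
    for l in range(1, n_loci):
        s = int(np.searchsorted(cumA[s], us[l], side="right"))
        s = min(s, S - 1)
        states[l] = s
    emissions = np.empty(n_loci, dtype=np.int64)
    ue = rng.random(n_loci)
    cumB = np.cumsum(B, axis=1)
    for st in range(S):
        mask = states == st
        emissions[mask] = np.minimum(
            np.searchsorted(cumB[st], ue[mask], side="right"), n - 1)
    return ObservationSequence.from_values(emissions, n=n, chrom=chrom)


# ---------------------------------------------------------------------------
# sequential coalescent simulator
# ---------------------------------------------------------------------------

class _Tree:
    """Mutable rooted binary tree over n leaves with node times."""

    def __init__(self, n):
        self.n = n
        cap = 2 * n
        self.time = np.zeros(cap)
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.children = {i: [] for i in range(cap)}
        self.free = []
        self.root = -1

    def sample_initial(self, model: DemographicModel, rng):
        active = list(range(self.n))
        next_id = self.n
        t = 0.0
        while len(active) > 1:
            k = len(active)
            target = rng.exponential() / (k * (k - 1) / 2.0)
            t = model.inverse_integrated_rate(t, target)
            i, j = rng.choice(len(active), size=2, replace=False)
            a, b = active[i], active[j]
            node = next_id
            next_id += 1
            self.time[node] = t
            self.parent[a] = self.parent[b] = node
            self.children[node] = [a, b]
            active = [x for x in active if x not in (a, b)] + [node]
        self.root = active[0]

    def edges(self):
        """(child, parent) pairs; every node but the root has one."""
        return [(c, p) for c, p in enumerate(self.parent)
                if p >= 0]

    def branch_lengths(self):
        es = self.edges()
        return es, np.array([self.time[p] - self.time[c] for c, p in es])

    def total_length(self) -> float:
        _, lens = self.branch_lengths()
        return float(lens.sum())

    def tmrca(self) -> float:
        return float(self.time[self.root])

    def leaves_under(self, node) -> list:
        stack, out = [node], []
        while stack:
            x = stack.pop()
            if x < self.n:
                out.append(x)
            else:
                stack.extend(self.children[x])
        return out

    def spr_recombination(self, model: DemographicModel, rng):
        """One sequential-coalescent update: cut above a uniform tree point
        and re-coalesce the detached lineage."""
        es, lens = self.branch_lengths()
        probs = lens / lens.sum()
        e_idx = rng.choice(len(es), p=probs)
        child, old_parent = es[e_idx]
        u = self.time[child] + rng.random() * lens[e_idx]

        # splice out old_parent: sibling inherits its slot in the tree
        sib = [c for c in self.children[old_parent] if c != child][0]
        grand = self.parent[old_parent]
        self.parent[sib] = grand
        if grand >= 0:
            self.children[grand] = [sib if c == old_parent else c
                                    for c in self.children[grand]]
        else:
            self.root = sib
        self.parent[child] = -1
        self.parent[old_parent] = -1
        self.children[old_parent] = []
        self.free.append(old_parent)

        # nodes of the detached subtree are excluded from crossing counts
        detached = set()
        stack = [child]
        while stack:
            x = stack.pop()
            detached.add(x)
            stack.extend(self.children[x])
        events = sorted({self.time[x] for x in range(2 * self.n)
                         if (x == self.root or self.parent[x] >= 0)
                         and x not in detached and self.time[x] > u}
                        | {u})
        E = rng.exponential()
        new_time = None
        for idx in range(len(events)):
            seg_lo = events[idx]
            seg_hi = events[idx + 1] if idx + 1 < len(events) else np.inf
            k = self._crossing_count(seg_lo, detached)
            if k == 0:
                k = 1  # above the remaining root a single lineage persists
            cand = model.inverse_integrated_rate(seg_lo, E / k)
            if cand < seg_hi:
                new_time = cand
                break
            E -= k * model.integrated_rate(seg_lo, seg_hi)
        assert new_time is not None
        targets = [x for x in range(2 * self.n)
                   if x not in detached and (self.parent[x] >= 0
                                             or x == self.root)
                   and self.time[x] <= new_time
                   and (self.parent[x] < 0
                        or self.time[self.parent[x]] > new_time)]
        target = targets[rng.integers(len(targets))]
        node = self.free.pop()
        self.time[node] = new_time
        tp = self.parent[target]
        self.parent[target] = node
        self.parent[child] = node
        self.children[node] = [target, child]
        self.parent[node] = tp
        if tp >= 0:
            self.children[tp] = [node if c == target else c
                                 for c in self.children[tp]]
        else:
            self.root = node

    def _crossing_count(self, t: float, detached) -> int:
        """Lineages of the remaining tree spanning time ``t`` (the lineage
        above the remaining root extends to infinity)."""
        k = 0
        for x in range(2 * self.n):
            if x in detached:
                continue
            p = self.parent[x]
            if p >= 0:
                if self.time[x] <= t < self.time[p]:
                    k += 1
            elif x == self.root and self.time[x] <= t:
                k += 1
        return k


def simulate_sequence(scenario: SimulationScenario, replicate: int = 0,
                      chrom: str | None = None):
    """Simulate one chromosome; returns (SiteData, truth-track DataFrame).

    The truth track records, per constant-genealogy segment, the start and
    end base, the tree height and the total branch length (coalescent
    units).
    """
    import pandas as pd

    model = scenario.truth
    n = scenario.n
    L = scenario.seq_len
    rng = np.random.default_rng((scenario.seed, replicate))
    theta, rho = model.theta, model.rho

    tree = _Tree(n)
    tree.sample_initial(model, rng)

    positions, columns = [], []
    track = []
    used = set()
    pos = 0.0
    while pos < L:
        tlen = tree.total_length()
        gap = rng.exponential(1.0 / (0.5 * rho * tlen)) if rho > 0 else np.inf
        seg_end = min(pos + gap, float(L))
        seg_len = seg_end - pos
        # mutations on this constant-genealogy segment
        es, lens = tree.branch_lengths()
        n_mut = rng.poisson(0.5 * theta * tlen * seg_len)
        if n_mut:
            branch_idx = rng.choice(len(es), size=n_mut, p=lens / lens.sum())
            sites = np.floor(pos + rng.random(n_mut) * seg_len).astype(np.int64)
            for b_i, site in zip(branch_idx, sites):
                for _ in range(10):
                    if site not in used and site < L:
                        break
                    site = int(np.floor(pos + rng.random() * seg_len))
                else:
                    continue
                if site in used or site >= L:
                    continue
                carriers = tree.leaves_under(es[b_i][0])
                if 0 < len(carriers) < n:
                    used.add(site)
                    col = np.zeros(n, dtype=np.int8)
                    col[carriers] = 1
                    positions.append(site)
                    columns.append(col)
        track.append((int(pos), int(np.ceil(seg_end)), tree.tmrca(),
                      tlen))
        pos = seg_end
        if pos < L:
            tree.spr_recombination(model, rng)

    if positions:
        order = np.argsort(positions)
        positions = np.asarray(positions, dtype=np.int64)[order]
        geno = np.stack([columns[i] for i in order], axis=1)
    else:
        positions = np.empty(0, dtype=np.int64)
        geno = np.empty((n, 0), dtype=np.int8)
    data = SiteData(chrom or str(replicate + 1), L, positions, geno)
    truth = pd.DataFrame(track, columns=["start", "end", "tmrca",
                                         "total_length"])
    return data, truth


def write_vcf(data: SiteData, path, diploid: bool = True,
              sample_prefix: str = "sample"):
    """Write the polymorphic sites as a minimal VCF (REF = ancestral).

    With ``diploid=True`` haplotypes 2i and 2i+1 form individual i; the
    ancestral allele is repeated in the AA info tag.
    """
    n = data.n_haplotypes
    if diploid and n % 2:
        raise ValueError("need an even number of haplotypes for diploid "
                         "output")
    n_samples = n // 2 if diploid else n
    names = [f"{sample_prefix}{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={data.chrom},length={data.seq_len}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                 'Description="Ancestral Allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        for j, p in enumerate(data.positions):
            col = data.genotypes[:, j]
            if diploid:
                gts = [f"{col[2*i]}|{col[2*i+1]}" for i in range(n_samples)]
            else:
                gts = [str(col[i]) for i in range(n_samples)]
            fh.write(f"{data.chrom}\t{p + 1}\t.\tA\tT\t.\tPASS\tAA=A\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

def _size_at(estimate, k):
    if hasattr(estimate, "size_at"):
        return estimate.size_at(k)
    return estimate(k)


def mean_signed_error(estimates, truth, k_grid):
    """``Delta(k) = mean_j |log(N_hat_j(k) / N_true(k))|`` over replicates.

    ``estimates`` is a sequence of fitted models (or callables ``N(k)``),
    ``truth`` the true model, ``k_grid`` the generations at which to
    evaluate.  Returns the Delta curve on the grid.
    """
    k_grid = np.asarray(k_grid, dtype=float)
    if np.any(k_grid <= 0):
        raise ValueError("generations must be positive")
    true_sizes = np.asarray([_size_at(truth, k) for k in k_grid])
    if np.any(true_sizes <= 0):
        raise ValueError("population sizes must be positive")
    delta = np.zeros(len(k_grid))
    for est in estimates:
        sizes = np.asarray([_size_at(est, k) for k in k_grid])
        if np.any(sizes <= 0):
            raise ValueError("population sizes must be positive")
        delta += np.abs(np.log(sizes / true_sizes))
    return delta / len(estimates)


def integrated_error(delta, k_grid) -> float:
    """``phi = int Delta(k) d log k`` by the trapezoid rule."""
    k_grid = np.asarray(k_grid, dtype=float)
    return float(np.trapezoid(delta, np.log(k_grid)))


def metric_grid(change_points_gen, n_points: int = 200) -> np.ndarray:
    """Log-spaced evaluation grid spanning the inference discretization,
    extended by one logarithmic step on either side."""
    cps = np.asarray(change_points_gen, dtype=float)
    if len(cps) < 2:
        raise ValueError("need at least two change points")
    step = np.log(cps[-1] / cps[0]) / (len(cps) - 1)
    lo = np.log(cps[0]) - step
    hi = np.log(cps[-1]) + step
    return np.exp(np.linspace(lo, hi, n_points))
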