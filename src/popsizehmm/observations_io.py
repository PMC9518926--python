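"""VCF input handling: derived-allele counts, masks, pseudo-haploids.

Only biallelic SNPs with genotype calls are used; phase separators are
ignored by construction since only allele counts are read.  Polarization
is either taken from the ancestral-allele ``AA`` INFO tag (sites lacking
it are treated as invariant) or the reference allele is assumed
ancestral.  Sites where every haplotype in a subset carries the derived
allele are recorded as invariant (d = 0), and inter-SNP gaps become
invariant runs of length (gap - 1).  Internal coordinates are 0-based
half-open; VCF positions are converted on read.
"""

from __future__ import annotations

import numpy as np

from .hmm_core import ObservationSequence
from .simdata import SiteData


def read_vcf(path, samples=None, polarization: str = "AA"):
    """Parse a VCF into one :class:`SiteData` per chromosome.

    Parameters
    ----------
    path : str
        Plain or bgzipped VCF with GT fields (haploid or diploid).
    samples : list of str, optional
        Sample names to keep, in this order; default all.
    polarization : {"AA", "ref-ancestral"}
        How to identify the derived allele.

    Returns
    -------
    (list of SiteData, list of haplotype labels)
    """
    from cyvcf2 import VCF

    if polarization not in ("AA", "ref-ancestral"):
        raise ValueError("polarization must be 'AA' or 'ref-ancestral'")
    vcf = VCF(str(path), gts012=False)
    if samples is not None:
        missing = set(samples) - set(vcf.samples)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")
        vcf.set_samples(list(samples))
    names = list(vcf.samples)
    contig_len = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            fields = dict(f.split("=", 1) for f in
                          line[len("##contig=<"):].rstrip(">").split(",")
                          if "=" in f)
            if "ID" in fields and "length" in fields:
                contig_len[fields["ID"]] = int(fields["length"])

    per_chrom: dict[str, list] = {}
    ploidy = None
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue  # multiallelic and indel records are treated invariant
        gts = np.array(var.genotypes, dtype=np.int64)  # (samples, ploidy+1)
        alleles = gts[:, :-1]
        if ploidy is None:
            ploidy = alleles.shape[1]
        if polarization == "AA":
            aa = var.INFO.get("AA")
            if aa is None:
                continue  # unpolarizable, treated invariant
            aa = str(aa).upper()
            if aa == var.REF.upper():
                derived = alleles.copy()
            elif aa == var.ALT[0].upper():
                derived = np.where(alleles >= 0, 1 - alleles, alleles)
            else:
                continue
        else:
            derived = alleles.copy()
        per_chrom.setdefault(var.CHROM, []).append(
            (var.POS - 1, derived.reshape(-1)))

    haplotype_labels = []
    for name in names:
        if (ploidy or 1) == 1:
            haplotype_labels.append(name)
        else:
            haplotype_labels.extend(f"{name}.{k}" for k in range(ploidy))

    out = []
    for chrom in sorted(per_chrom):
        records = per_chrom[chrom]
        positions = np.array([p for p, _ in records], dtype=np.int64)
        geno = np.stack([g for _, g in records], axis=1).astype(np.int8)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        geno = geno[:, order]
        keep = np.concatenate([[True], np.diff(positions) > 0])
        seq_len = contig_len.get(chrom, int(positions[-1]) + 1)
        out.append(SiteData(chrom, seq_len, positions[keep], geno[:, keep]))
    if not out:
        raise ValueError(f"no usable biallelic SNPs found in {path}")
    return out, haplotype_labels


def vcf_to_observations(path, subset=None, polarization: str = "AA",
                        mask=None, samples=None):
    """Observation sequences (one per chromosome) from a VCF.

    ``subset`` selects haplotype indices (columns of the expanded
    genotype matrix); default all.  ``mask`` is an optional iterable of
    (chrom, start, end) 0-based half-open intervals excised from the
    sequences.
    """
    site_data, labels = read_vcf(path, samples=samples,
                                 polarization=polarization)
    out = []
    for data in site_data:
        idx = tuple(subset) if subset is not None \
            else tuple(range(data.n_haplotypes))
        obs = data.observations(idx)
        if mask is not None:
            intervals = [(s, e) for c, s, e in mask if c == data.chrom]
            if intervals:
                obs = mask_observation(obs, intervals)
        out.append(obs)
    return out, labels


def read_bed_mask(path):
    """(chrom, start, end) triples from a BED file (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out


def mask_observation(obs: ObservationSequence,
                     intervals) -> ObservationSequence:
    """Excise masked loci from a run-length-encoded sequence.

    Runs overlapping a masked interval are split and the excised loci
    contribute nothing; adjacent same-symbol runs are re-merged.
    """
    starts = np.concatenate([[0], np.cumsum(obs.run_lengths)[:-1]])
    ends = starts + obs.run_lengths
    total = obs.total_loci
    # clip and merge overlapping mask intervals
    clipped = []
    for s, e in sorted((max(0, int(s)), min(total, int(e)))
                       for s, e in intervals):
        if e <= s:
            continue
        if clipped and s <= clipped[-1][1]:
            clipped[-1] = (clipped[-1][0], max(clipped[-1][1], e))
        else:
            clipped.append((s, e))
    if not clipped:
        return obs
    d_out, len_out = [], []

    def push(d, ln):
        if ln <= 0:
            return
        if d_out and d_out[-1] == d:
            len_out[-1] += ln
        else:
            d_out.append(d)
            len_out.append(ln)

    for d, s, e in zip(obs.d_values, starts, ends):
        cursor = s
        for ms, me in clipped:
            if me <= cursor or ms >= e:
                continue
            push(int(d), min(ms, e) - cursor)
            cursor = max(cursor, me)
        push(int(d), e - cursor)
    if not d_out:
        raise ValueError("mask removed the entire sequence")
    return ObservationSequence(obs.n, np.array(d_out), np.array(len_out),
                               obs.chrom)


def pseudo_haploidize(path_or_data, seed: int = 0, samples=None,
                      polarization: str = "AA"):
    """Pseudo-haploid panel: one random allele per individual per site.

    Accepts a VCF path (diploid genotypes required) or a SiteData with an
    even number of haplotypes; homozygous sites are unaffected by the
    random draw.
    """
    rng = np.random.default_rng(seed)
    if isinstance(path_or_data, SiteData):
        return path_or_data.pseudo_haploidize(rng)
    site_data, _ = read_vcf(path_or_data, samples=samples,
                            polarization=polarization)
    return [d.pseudo_haploidize(rng) for d in site_data]
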