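"""Genotype I/O and core per-locus statistics.

The central container is :class:`GenotypeMatrix`: an individuals x loci
matrix of alternate-allele counts (0/1/2, ``-1`` missing) with sample,
deme and locus metadata.  On top of it sit the classic population-genetic
summaries every downstream stage consumes: per-deme allele frequencies,
observed heterozygosity, the Weir & Cockerham (1984) FST estimator
(per-locus theta and the multi-locus ratio-of-sums form, matching the
VCFtools convention), and sliding-window LD pruning.

VCF positions are 1-based (as in the format); all in-memory arrays are
0-based indexed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosage matrix with metadata.

    Attributes
    ----------
    G:
        ``(n_samples, n_loci)`` int8 array of {0, 1, 2}; ``-1`` = missing.
    samples:
        Ordered sample labels.
    demes:
        Deme (population) label per sample, aligned with ``samples``.
    chrom, pos:
        Locus coordinates; ``pos`` is 1-based and strictly increasing
        within each chromosome.
    """

    G: np.ndarray
    samples: list[str]
    demes: list[str]
    chrom: list[str]
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.G.shape
        if len(self.samples) != n or len(self.demes) != n:
            raise ValueError("sample metadata length does not match G rows")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("locus metadata length does not match G columns")
        for c in set(self.chrom):
            p = self.pos[np.asarray(self.chrom) == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_loci(self) -> int:
        return self.G.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def deme_labels(self) -> list[str]:
        """Unique deme labels in order of first appearance."""
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d)
        return list(seen)

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.G[:, idx], list(self.samples), list(self.demes),
            [self.chrom[i] for i in idx], self.pos[idx])

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.G[idx, :], [self.samples[i] for i in idx],
            [self.demes[i] for i in idx], list(self.chrom), self.pos.copy())

    def deme_allele_freq(self) -> tuple[np.ndarray, list[str]]:
        """Per-deme alternate-allele frequency, shape (n_demes, n_loci)."""
        labels = self.deme_labels()
        demes = np.asarray(self.demes)
        out = np.full((len(labels), self.n_loci), np.nan)
        for i, lab in enumerate(labels):
            sub = self.G[demes == lab]
            valid = sub != MISSING
            cnt = np.where(valid, sub, 0).sum(axis=0)
            denom = 2 * valid.sum(axis=0)
            with np.errstate(invalid="ignore"):
                out[i] = np.where(denom > 0, cnt / np.maximum(denom, 1), np.nan)
        return out, labels


# ---------------------------------------------------------------------------
# VCF I/O (minimal GT-only 4.2 dialect)

def read_vcf(path, demes: dict[str, str] | list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are skipped (count logged).  Missing genotypes
    (``./.``) become the missing code.  ``demes`` maps sample label to
    deme label; by default every sample gets deme ``"pop0"``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        g = np.array([a + b if a >= 0 and b >= 0 else MISSING
                      for a, b, *_ in var.genotypes], dtype=np.int8)
        rows.append(g)
        chrom.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic record(s)", n_skipped)
    G = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    if demes is None:
        deme_list = ["pop0"] * len(samples)
    elif isinstance(demes, dict):
        deme_list = [demes[s] for s in samples]
    else:
        deme_list = list(demes)
    gm = GenotypeMatrix(G, samples, deme_list, chrom, np.array(pos, dtype=np.int64))
    gm.n_multiallelic_skipped = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT field only; REF=A, ALT=T placeholders)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        seen: dict[str, None] = {}
        for c in gm.chrom:
            seen.setdefault(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j in range(gm.n_loci):
            gts = "\t".join(code[int(g)] for g in gm.G[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Per-sample / per-group statistics

def heterozygosity(gm: GenotypeMatrix, grouping: list[str] | None = None):
    """Mean proportion of heterozygous sites per group.

    For each sample, the proportion of its non-missing loci with genotype 1;
    the group value is the mean over its samples.  Samples with all loci
    missing are excluded with a warning.
    """
    groups = np.asarray(grouping if grouping is not None else gm.demes)
    out: dict[str, float] = {}
    for lab in dict.fromkeys(groups):
        sub = gm.G[groups == lab]
        if sub.shape[0] == 0:
            raise ValueError(f"group {lab!r} has no samples")
        valid = sub != MISSING
        n_valid = valid.sum(axis=1)
        usable = n_valid > 0
        if not usable.all():
            logger.warning("heterozygosity: excluding %d all-missing sample(s) in %s",
                           int((~usable).sum()), lab)
        het = (sub == 1).sum(axis=1)
        out[lab] = float(np.mean(het[usable] / n_valid[usable]))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) FST

def _wc_components(gm: GenotypeMatrix, groups: list[str]):
    """Per-locus Weir-Cockerham variance components a, b, c.

    Returns (a, b, c, usable) arrays over loci; ``usable`` is False where
    fewer than two groups have >= 2 non-missing samples or the locus is
    monomorphic across the used samples.
    """
    demes = np.asarray(gm.demes)
    mats = [gm.G[demes == g] for g in groups]
    m = gm.n_loci
    r_eff = np.zeros(m)
    n_list, p_list, h_list = [], [], []
    for sub in mats:
        valid = sub != MISSING
        n_i = valid.sum(axis=0).astype(float)            # diploid counts
        alt = np.where(valid, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), np.nan)
            h_i = np.where(n_i > 0,
                           np.where(valid, sub == 1, False).sum(axis=0)
                           / np.maximum(n_i, 1), np.nan)
        n_list.append(n_i)
        p_list.append(p_i)
        h_list.append(h_i)
    n_arr = np.array(n_list)        # (r, m)
    p_arr = np.array(p_list)
    h_arr = np.array(h_list)

    use = n_arr >= 2                # group usable at locus
    r_eff = use.sum(axis=0).astype(float)
    usable = r_eff >= 2

    n_use = np.where(use, n_arr, 0.0)
    nbar = n_use.sum(axis=0) / np.maximum(r_eff, 1)
    nc = np.where(
        r_eff > 1,
        (n_use.sum(axis=0) - (n_use ** 2).sum(axis=0) / np.maximum(n_use.sum(axis=0), 1))
        / np.maximum(r_eff - 1, 1),
        np.nan)
    with np.errstate(invalid="ignore"):
        pbar = (n_use * np.nan_to_num(p_arr)).sum(axis=0) / np.maximum(n_use.sum(axis=0), 1)
        s2 = (n_use * (np.nan_to_num(p_arr) - pbar) ** 2).sum(axis=0) \
            / np.maximum((r_eff - 1) * nbar, 1e-12)
        hbar = (n_use * np.nan_to_num(h_arr)).sum(axis=0) / np.maximum(n_use.sum(axis=0), 1)

        a = (nbar / np.maximum(nc, 1e-12)) * (
            s2 - (1.0 / np.maximum(nbar - 1, 1e-12))
            * (pbar * (1 - pbar) - s2 * (r_eff - 1) / np.maximum(r_eff, 1) - hbar / 4.0))
        b = (nbar / np.maximum(nbar - 1, 1e-12)) * (
            pbar * (1 - pbar) - s2 * (r_eff - 1) / np.maximum(r_eff, 1)
            - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0

    mono = (pbar <= 0) | (pbar >= 1)
    usable = usable & ~mono
    return a, b, c, usable


def wc_fst(gm: GenotypeMatrix, groups: list[str] | None = None):
    """Weir-Cockerham FST: per-locus theta and multi-locus ratio of sums.

    Per-locus theta = a / (a + b + c); negative estimates are reported
    as-is.  Loci monomorphic over the used samples, or with fewer than
    two groups having >= 2 non-missing samples, get NaN and are excluded
    from the multi-locus sum.
    """
    if groups is None:
        groups = gm.deme_labels()
    if len(groups) < 2:
        raise ValueError("wc_fst requires at least two groups")
    a, b, c, usable = _wc_components(gm, list(groups))
    if not usable.any():
        raise ValueError("no usable polymorphic loci for FST")
    denom = a + b + c
    per_locus = np.full(gm.n_loci, np.nan)
    ok = usable & (np.abs(denom) > 1e-300)
    per_locus[ok] = a[ok] / denom[ok]
    multi = float(a[usable].sum() / denom[usable].sum())
    return per_locus, multi


# ---------------------------------------------------------------------------
# LD pruning

def ld_prune(gm: GenotypeMatrix, window: int = 50, step: int = 5,
             r2_max: float = 0.2) -> np.ndarray:
    """Greedy sliding-window LD pruning on genotype correlation.

    Within each window, for any retained pair with squared Pearson
    correlation of dosages above ``r2_max``, the locus with the larger
    position (later input order) is dropped.  Deterministic given input
    order.  Returns indices of retained loci.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    m = gm.n_loci
    keep = np.ones(m, dtype=bool)
    G = gm.G.astype(float)
    G[gm.G == MISSING] = np.nan
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if keep[j]]
        for ai in range(len(idx)):
            j1 = idx[ai]
            if not keep[j1]:
                continue
            for bi in range(ai + 1, len(idx)):
                j2 = idx[bi]
                if not keep[j2]:
                    continue
                x, y = G[:, j1], G[:, j2]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                sx, sy = xs.std(), ys.std()
                if sx == 0 or sy == 0:
                    continue
                r = float(np.corrcoef(xs, ys)[0, 1])
                if r * r > r2_max:
                    keep[j2] = False     # drop the later locus
        if start + window >= m:
            break
        start += step
    return np.flatnonzero(keep)
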