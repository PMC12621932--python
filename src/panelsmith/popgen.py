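"""Core population-genetic statistics.

Windowed nucleotide diversity (pi), Tajima's D, Malecot's inbreeding
coefficient f, genotype-correlation r^2 with windowed LD pruning, and
method-of-moments IBD (Z0/Z1/Z2, PI_HAT).  All statistics are phase-free
and work from allele counts; multiallelic sites contribute to pi through
the full allele-pair sum and are collapsed to a major-vs-rest biallelic
encoding for D, f and r^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "windowed_pi", "site_pairwise_diff", "tajimas_d", "tajima_constants",
    "malecot_f", "genotype_r2", "ld_prune", "ibd_pi_hat", "kinship_table",
    "KinshipEstimate", "SelectionStats",
]


@dataclass
class SelectionStats:
    """Per-subpopulation selection/inbreeding summary for one region."""
    region_id: str
    tajimas_d: dict      # subpop -> float or None
    malecot_f: dict      # subpop -> float or None
    n_haplotypes: dict   # subpop -> int


@dataclass
class KinshipEstimate:
    sample_a: str
    sample_b: str
    z0: float
    z1: float
    z2: float
    pi_hat: float
    n_sites: int


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pairwise_diff(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean pairwise difference per site from allele counts.

    For allele counts c_k with n = sum c_k, the probability two distinct
    sampled chromosomes differ is sum_{i<j} 2 c_i c_j / (n (n-1))
    = (n^2 - sum c_k^2) / (n (n-1)).  Sites with n < 2 contribute 0 and
    are reported via the skipped mask.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    skipped = n < 2
    denom = np.where(skipped, 1.0, n * (n - 1))
    diff = (n ** 2 - (counts ** 2).sum(axis=1)) / denom
    diff[skipped] = 0.0
    return diff, skipped


def windowed_pi(matrix: GenotypeMatrix, window_bp: int = 50,
                contig_lengths: dict | None = None,
                sample_index=None) -> pd.DataFrame:
    """Tile each contig with non-overlapping windows and compute pi per window.

    Window pi is the sum of per-site mean pairwise differences divided by
    the full window length (monomorphic and missing positions included in
    the denominator).  Returns a DataFrame with columns contig, start, end,
    pi, s (segregating sites), mean_dp, n_skipped.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if contig_lengths is None:
        contig_lengths = {
            c: int(matrix.positions[matrix.contigs == c].max()) + 1
            for c in pd.unique(matrix.contigs)
        }
    counts = matrix.allele_counts(sample_index=sample_index)
    diffs, skipped = site_pairwise_diff(counts)
    seg = (counts > 0).sum(axis=1) >= 2
    dp = matrix.dp if sample_index is None else matrix.dp[:, sample_index]
    site_dp = dp.mean(axis=1) if dp.size else np.zeros(matrix.n_variants)

    frames = []
    for contig, length in contig_lengths.items():
        n_win = int(np.ceil(length / window_bp))
        idx = np.flatnonzero(matrix.contigs == contig)
        w_pi = np.zeros(n_win)
        w_s = np.zeros(n_win, dtype=int)
        w_skip = np.zeros(n_win, dtype=int)
        w_dp_sum = np.zeros(n_win)
        w_nvar = np.zeros(n_win, dtype=int)
        if idx.size:
            win = matrix.positions[idx] // window_bp
            np.add.at(w_pi, win, diffs[idx])
            np.add.at(w_s, win, seg[idx].astype(int))
            np.add.at(w_skip, win, skipped[idx].astype(int))
            np.add.at(w_dp_sum, win, site_dp[idx])
            np.add.at(w_nvar, win, 1)
        starts = np.arange(n_win) * window_bp
        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts,
            "end": np.minimum(starts + window_bp, length),
            "pi": w_pi / window_bp,
            "s": w_s,
            "mean_dp": np.where(w_nvar > 0, w_dp_sum / np.maximum(w_nvar, 1), 0.0),
            "n_skipped": w_skip,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """Standard normalizing constants for a sample of n chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _major_vs_rest(counts: np.ndarray) -> np.ndarray:
    """Collapse per-site allele counts to a (major, rest) biallelic pair."""
    counts = np.asarray(counts, dtype=float)
    major = counts.max(axis=1)
    total = counts.sum(axis=1)
    return np.stack([major, total - major], axis=1)


def tajimas_d(matrix: GenotypeMatrix, region=None, sample_index=None,
              n_haplotypes: int | None = None):
    """Tajima's D over a region: (k - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    k is the mean pairwise difference count summed over sites (not per bp)
    and S the segregating-site count, both after major-vs-rest collapsing.
    The constants use n = 2 x (number of samples) unless overridden.
    Returns None when S = 0 or n < 4.
    """
    sub = _region_subset(matrix, region)
    if sample_index is not None:
        sub = sub.take_samples(sample_index)
    n = n_haplotypes if n_haplotypes is not None else 2 * sub.n_samples
    if n < 4:
        return None
    counts = _major_vs_rest(sub.allele_counts())
    seg = (counts > 0).all(axis=1)
    s = int(seg.sum())
    if s == 0:
        return None
    diffs, _ = site_pairwise_diff(counts)
    k = float(diffs[seg].sum())
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return (k - s / c["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Malecot's f
# ---------------------------------------------------------------------------

def malecot_f(matrix: GenotypeMatrix, region=None, sample_index=None):
    """Inbreeding coefficient as a ratio of sums over polymorphic sites.

    f = 1 - sum(observed het counts) / sum(2 p (1-p) n_geno), with p the
    major-allele frequency after biallelic collapsing; clamped to [-1, 1].
    Returns None when no polymorphic site has >= 2 genotyped diploids.
    """
    sub = _region_subset(matrix, region)
    if sample_index is not None:
        sub = sub.take_samples(sample_index)
    hobs_total = 0.0
    hexp_total = 0.0
    for v in range(sub.n_variants):
        calls = sub.calls[v]
        ok = (calls != MISSING).all(axis=1)
        n_geno = int(ok.sum())
        if n_geno < 2:
            continue
        alleles = calls[ok].ravel()
        vals, cnts = np.unique(alleles, return_counts=True)
        if len(vals) < 2:
            continue
        major = vals[np.argmax(cnts)]
        p = cnts.max() / cnts.sum()
        is_major = calls[ok] == major
        hobs = int((is_major.sum(axis=1) == 1).sum())
        hobs_total += hobs
        hexp_total += 2.0 * p * (1.0 - p) * n_geno
    if hexp_total == 0.0:
        return None
    return float(np.clip(1.0 - hobs_total / hexp_total, -1.0, 1.0))


def _region_subset(matrix: GenotypeMatrix, region):
    if region is None:
        return matrix
    contig, start, end = region
    return matrix.take_variants(matrix.region_index(contig, start, end))


# ---------------------------------------------------------------------------
# LD: r^2 and windowed pruning
# ---------------------------------------------------------------------------

def genotype_r2(x, y):
    """Squared Pearson correlation of genotype dosages (composite r^2).

    Computed over pairwise-complete samples; returns None when either
    vector has zero variance or fewer than 2 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return None
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def ld_prune(matrix_or_dosage, r2_max: float = 0.01, window_snps: int = 500,
             step_snps: int = 250) -> np.ndarray:
    """Windowed LD pruning of coordinate-sorted variants.

    Within each window of ``window_snps`` variants (advancing by
    ``step_snps``), variants are scanned left to right and removed when
    their r^2 with any retained earlier variant in the window exceeds
    ``r2_max``; removal is global.  Returns retained variant indices.
    """
    if isinstance(matrix_or_dosage, GenotypeMatrix):
        dosage = matrix_or_dosage.dosage()
    else:
        dosage = np.asarray(matrix_or_dosage, dtype=float)
    n = dosage.shape[0]
    removed = np.zeros(n, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_snps, n)
        for j in range(start, stop):
            if removed[j]:
                continue
            for i in range(start, j):
                if removed[i]:
                    continue
                r2 = genotype_r2(dosage[i], dosage[j])
                if r2 is not None and r2 > r2_max:
                    removed[j] = True
                    break
        if stop >= n:
            break
        start += step_snps
    return np.flatnonzero(~removed)


# ---------------------------------------------------------------------------
# Method-of-moments IBD
# ---------------------------------------------------------------------------

def ibd_pi_hat(matrix: GenotypeMatrix, sample_a, sample_b,
               allele_freqs=None, min_sites: int = 200):
    """Method-of-moments IBD sharing for one sample pair.

    Observed identity-by-state counts at biallelic SNPs are compared with
    their expectations given the population allele frequencies:
    P(IBS0|IBD0) = 2 p^2 q^2, P(IBS1|IBD0) = 4 p q (p^2 + q^2),
    P(IBS1|IBD1) = 2 p q, P(IBS0|IBD1) = P(IBS<2|IBD2) = 0.  Z0 and Z1
    follow by moment matching, Z2 = 1 - Z0 - Z1; the Zs are clamped to
    [0, 1] and renormalized.  PI_HAT = Z2 + Z1/2.  Frequencies default to
    estimates from all samples in the matrix.  Returns None when fewer
    than ``min_sites`` informative sites remain.
    """
    ia = matrix.samples.index(sample_a) if isinstance(sample_a, str) else sample_a
    ib = matrix.samples.index(sample_b) if isinstance(sample_b, str) else sample_b
    biallelic = np.array([len(a) == 1 for a in matrix.alt]) & matrix.is_snp()
    dosage = matrix.dosage()
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            allele_freqs = np.nanmean(dosage, axis=1) / 2.0
    p = np.asarray(allele_freqs, dtype=float)
    da, db = dosage[:, ia], dosage[:, ib]
    ok = biallelic & ~np.isnan(da) & ~np.isnan(db) & (p > 0) & (p < 1)
    if ok.sum() < min_sites:
        return None
    da, db, p = da[ok], db[ok], p[ok]
    q = 1.0 - p
    ibs = 2 - np.abs(da - db)
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    e0 = float(np.sum(2 * p ** 2 * q ** 2))
    e1_ibd0 = float(np.sum(4 * p * q * (p ** 2 + q ** 2)))
    e1_ibd1 = float(np.sum(2 * p * q))
    z0 = n0 / e0 if e0 > 0 else 0.0
    z1 = (n1 - z0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    z2 = 1.0 - z0 - z1
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    z = z / z.sum() if z.sum() > 0 else np.array([1.0, 0.0, 0.0])
    name_a = matrix.samples[ia]
    name_b = matrix.samples[ib]
    return KinshipEstimate(name_a, name_b, float(z[0]), float(z[1]),
                           float(z[2]), float(z[2] + z[1] / 2), int(ok.sum()))


def kinship_table(matrix: GenotypeMatrix, min_sites: int = 200) -> pd.DataFrame:
    """PI_HAT for every sample pair; null pairs carry NaN and are counted."""
    rows = []
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(matrix.dosage(), axis=1) / 2.0
    for ia, ib in itertools.combinations(range(matrix.n_samples), 2):
        est = ibd_pi_hat(matrix, ia, ib, allele_freqs=freqs, min_sites=min_sites)
        if est is None:
            rows.append((matrix.samples[ia], matrix.samples[ib],
                         np.nan, np.nan, np.nan, np.nan, 0))
        else:
            rows.append((est.sample_a, est.sample_b, est.z0, est.z1,
                         est.z2, est.pi_hat, est.n_sites))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "Z0", "Z1",
                                       "Z2", "PI_HAT", "n_sites"])
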