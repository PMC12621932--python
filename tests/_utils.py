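"""Shared builders and independent brute-force oracles for the test suite.

The oracles deliberately re-derive each statistic from first principles
(pair enumeration, exhaustive scanning) so they share no code path with
the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from panelsmith.dna import revcomp
from panelsmith.genotypes import GenotypeMatrix


# ---------------------------------------------------------------------------
# Matrix builder
# ---------------------------------------------------------------------------

def make_matrix(gts, positions=None, contig="c1", dp=None, gq=None,
                ref=None, alt=None, subpops=None, info=None):
    """Build a GenotypeMatrix from compact genotype strings.

    ``gts`` is a list (variants) of lists (samples) of strings like
    "0/1", "1|0" or "./.".
    """
    n_var = len(gts)
    n_samp = len(gts[0]) if n_var else 0
    calls = np.full((n_var, n_samp, 2), -1, dtype=np.int8)
    phased = np.zeros((n_var, n_samp), dtype=bool)
    for v, row in enumerate(gts):
        for s, g in enumerate(row):
            sep = "|" if "|" in g else "/"
            a0, a1 = g.split(sep)
            if a0 != ".":
                calls[v, s, 0] = int(a0)
            if a1 != ".":
                calls[v, s, 1] = int(a1)
            phased[v, s] = sep == "|"
    if positions is None:
        positions = np.arange(n_var, dtype=np.int64)
    if dp is None:
        dp = np.full((n_var, n_samp), 100, dtype=np.int32)
    if gq is None:
        gq = np.full((n_var, n_samp), 99, dtype=np.int32)
    n_alt = max(int(calls.max()), 1) if calls.size else 1
    return GenotypeMatrix(
        contigs=np.array([contig] * n_var, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.array(ref if ref is not None else ["A"] * n_var, dtype=object),
        alt=alt if alt is not None else [tuple("TGC"[:n_alt])] * n_var,
        calls=calls,
        dp=np.asarray(dp, dtype=np.int32),
        gq=np.asarray(gq, dtype=np.int32),
        phased=phased,
        samples=[f"s{i}" for i in range(n_samp)],
        info=dict(info or {}),
        subpops=None if subpops is None else np.array(subpops, dtype=object),
    )


# ---------------------------------------------------------------------------
# pi oracle: average per-bp Hamming distance over haplotype pairs
# ---------------------------------------------------------------------------

def pi_windows_oracle(haplotypes, positions, window_bp, contig_length):
    """haplotypes: (n_hap, n_var) allele matrix, fully observed."""
    haplotypes = np.asarray(haplotypes)
    n_hap = haplotypes.shape[0]
    n_win = int(np.ceil(contig_length / window_bp))
    out = np.zeros(n_win)
    pairs = list(itertools.combinations(range(n_hap), 2))
    for w in range(n_win):
        lo, hi = w * window_bp, (w + 1) * window_bp
        cols = [i for i, p in enumerate(positions) if lo <= p < hi]
        if not cols:
            continue
        total = 0
        for a, b in pairs:
            total += int(np.sum(haplotypes[a, cols] != haplotypes[b, cols]))
        out[w] = total / len(pairs) / window_bp
    return out


# ---------------------------------------------------------------------------
# Tajima's D oracle from the published constant formulas
# ---------------------------------------------------------------------------

def tajimas_d_oracle(haplotypes):
    """D from a fully observed haplotype matrix, by direct pair counting."""
    haplotypes = np.asarray(haplotypes)
    n, n_var = haplotypes.shape
    seg_cols = [j for j in range(n_var)
                if len(set(haplotypes[:, j].tolist())) > 1]
    s = len(seg_cols)
    if s == 0 or n < 4:
        return None
    pairs = list(itertools.combinations(range(n), 2))
    k = sum(int(np.sum(haplotypes[a, seg_cols] != haplotypes[b, seg_cols]))
            for a, b in pairs) / len(pairs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def haplotypes_to_matrix(haplotypes, positions=None, contig="c1"):
    """Pair consecutive haplotypes into diploids and build a matrix."""
    haplotypes = np.asarray(haplotypes)
    n_hap, n_var = haplotypes.shape
    assert n_hap % 2 == 0
    gts = []
    for v in range(n_var):
        row = []
        for d in range(n_hap // 2):
            row.append(f"{haplotypes[2 * d, v]}|{haplotypes[2 * d + 1, v]}")
        gts.append(row)
    return make_matrix(gts, positions=positions, contig=contig)


# ---------------------------------------------------------------------------
# LD pruning oracle
# ---------------------------------------------------------------------------

def ld_prune_oracle(dosage, r2_max, window_snps, step_snps):
    """Exhaustive re-implementation of the windowed left-to-right scan."""
    n = dosage.shape[0]
    removed = [False] * n
    start = 0
    while True:
        stop = min(start + window_snps, n)
        for j in range(start, stop):
            if removed[j]:
                continue
            for i in range(start, j):
                if removed[i]:
                    continue
                x, y = dosage[i], dosage[j]
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                if xs.std() == 0 or ys.std() == 0:
                    continue
                r = np.corrcoef(xs, ys)[0, 1]
                if r * r > r2_max:
                    removed[j] = True
                    break
        if stop >= n:
            break
        start += step_snps
    return [i for i in range(n) if not removed[i]]


# ---------------------------------------------------------------------------
# In-silico PCR oracle
# ---------------------------------------------------------------------------

def ispcr_hits_oracle(primer, seq, mismatch_fraction):
    """Position-by-position mismatch counting at every offset and strand."""
    max_mm = int(np.floor(mismatch_fraction * len(primer)))
    hits = []
    for strand, query in (("+", primer), ("-", revcomp(primer))):
        for o in range(len(seq) - len(primer) + 1):
            mm = sum(1 for a, b in zip(seq[o:o + len(query)], query) if a != b)
            if mm <= max_mm:
                hits.append((o, o + len(primer), strand, mm))
    return sorted(hits)


def ispcr_products_oracle(fwd_hits, rev_hits, max_product):
    """All convergent pairings (both primer orderings) within the span."""
    products = set()
    for plus, minus in ((fwd_hits, rev_hits), (rev_hits, fwd_hits)):
        for hs, he, st, _ in plus:
            if st != "+":
                continue
            for ms, me, mt, _ in minus:
                if mt != "-":
                    continue
                span = me - hs
                if hs <= ms and (he - hs) + (me - ms) <= span <= max_product:
                    products.add((hs, me))
    return sorted(products)
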