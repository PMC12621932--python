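"""Evaluation of a sequenced amplicon panel.

Read-to-locus assignment with multi-mapper exclusion, coverage-uniformity
summaries, per-primer balancing factors, rarefaction of read counts
(proportion of amplicons genotyped at >= 10 reads as a function of
sequencing depth), SNPs per amplicon, amplicon/library size statistics,
and microhaplotype extraction from phased genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadAssignment:
    table: pd.DataFrame        # input rows + assigned locus_id (or reason)
    counts: pd.Series          # unique-read count per locus (multimap excluded)
    tallies: dict              # assigned / off_panel / multimap_excluded / rejected


def assign_reads(alignments: pd.DataFrame, panel) -> ReadAssignment:
    """Assign aligned reads to panel loci by majority overlap.

    A read is assigned to a locus when at least 50% of the read interval
    overlaps the locus interval.  Multimap-flagged reads are recorded but
    never counted; malformed rows (end <= start) are rejected and counted.
    Reads are conserved: assigned + off-panel + multimap + rejected equals
    the input row count.
    """
    loci = list(panel)
    by_contig: dict = {}
    for l in loci:
        by_contig.setdefault(l.contig, []).append(l)

    assigned_to = []
    tallies = {"assigned": 0, "off_panel": 0, "multimap_excluded": 0,
               "rejected": 0}
    counts = {l.locus_id: 0 for l in loci}
    for row in alignments.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if end <= start:
            tallies["rejected"] += 1
            assigned_to.append("__rejected__")
            continue
        hit = None
        for l in by_contig.get(row.contig, ()):
            overlap = min(end, l.end) - max(start, l.start)
            if overlap * 2 >= (end - start):
                hit = l.locus_id
                break
        if hit is None:
            tallies["off_panel"] += 1
            assigned_to.append("__off_panel__")
        elif int(row.multimap):
            tallies["multimap_excluded"] += 1
            assigned_to.append("__multimap__")
        else:
            tallies["assigned"] += 1
            counts[hit] += 1
            assigned_to.append(hit)

    table = alignments.copy()
    table["assigned"] = assigned_to
    return ReadAssignment(table=table,
                          counts=pd.Series(counts, name="reads"),
                          tallies=tallies)


# ---------------------------------------------------------------------------
# Coverage uniformity and balancing
# ---------------------------------------------------------------------------

def coverage_uniformity(counts) -> dict:
    """Share vector, top-locus share, and Gini coefficient of read counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero counts")
    shares = counts / total
    x = np.sort(shares)
    n = len(x)
    gini = float(np.sum((2 * np.arange(1, n + 1) - n - 1) * x) / (n * np.sum(x)))
    return {"shares": shares, "top_share": float(shares.max()), "gini": gini}


def balancing_factors(counts, target_share: float | None = None,
                      clamp=(0.1, 2.0)) -> np.ndarray:
    """Per-primer dilution multipliers equalizing read share.

    factor_i = clamp(target_share / observed_share_i); zero-count loci get
    the upper clamp (they need the most primer) with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    if target_share is None:
        target_share = 1.0 / n
    total = counts.sum()
    factors = np.full(n, clamp[1], dtype=float)
    nz = counts > 0
    if not nz.all():
        log.warning("%d zero-count loci set to the upper clamp", int((~nz).sum()))
    if total > 0:
        factors[nz] = np.clip(target_share / (counts[nz] / total), *clamp)
    return factors


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    depths: np.ndarray
    mean: np.ndarray            # mean proportion of genotyped amplicons
    sd: np.ndarray
    replicates: int
    seed: int
    threshold: int
    observed_proportion: float  # at full observed depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth": self.depths, "mean_proportion": self.mean,
                             "sd": self.sd})


def rarefaction(counts, depths, threshold: int = 10, replicates: int = 100,
                seed: int = 0) -> RarefactionCurve:
    """Subsample a fixed read pool and track amplicon genotypability.

    At each depth, ``replicates`` multivariate-hypergeometric subsamples
    (without replacement) are drawn from the per-locus counts and the
    proportion of loci reaching ``threshold`` reads is averaged.  A depth
    equal to the observed total reproduces the observed proportion exactly
    (sd 0); depths beyond it are not extrapolated and raise.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    n_loci = len(counts)
    observed = float((counts >= threshold).sum() / n_loci)
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for depth in depths:
        depth = int(depth)
        if depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        if depth > total:
            raise ValueError(
                f"depth {depth} exceeds the {total} observed reads; "
                "extrapolation is not supported")
        if depth == total:
            means.append(observed)
            sds.append(0.0)
            continue
        props = np.empty(replicates)
        for r in range(replicates):
            sub = rng.multivariate_hypergeometric(counts, depth)
            props[r] = (sub >= threshold).sum() / n_loci
        means.append(float(props.mean()))
        sds.append(float(props.std()))
    return RarefactionCurve(np.asarray(list(depths)), np.asarray(means),
                            np.asarray(sds), replicates, seed, threshold,
                            observed)


# ---------------------------------------------------------------------------
# SNPs per amplicon
# ---------------------------------------------------------------------------

def snps_per_amplicon(matrix: GenotypeMatrix, panel) -> dict:
    """Count variants falling in each locus interval (half-open)."""
    per_locus = {}
    in_any = np.zeros(matrix.n_variants, dtype=bool)
    for l in panel:
        idx = matrix.region_index(l.contig, l.start, l.end)
        per_locus[l.locus_id] = int(idx.size)
        in_any[idx] = True
    counts = pd.Series(per_locus, name="n_snps")
    return {
        "per_locus": counts,
        "off_panel_variants": int((~in_any).sum()),
        "median": float(counts.median()) if len(counts) else None,
    }


# ---------------------------------------------------------------------------
# Amplicon and library sizes
# ---------------------------------------------------------------------------

def amplicon_size_stats(panel, index_fwd_extra: str = "",
                        index_rev_extra: str = "") -> dict:
    """Amplicon length distribution and predicted final library sizes.

    The sequencing construct adds the two PCR1 adapter tails plus whatever
    the second-round index primers append beyond those tails
    (``index_*_extra``); the overhead is computed from the sequences, not
    assumed.
    """
    lengths, overheads = [], []
    missing = [l.locus_id for l in panel
               if l.end is None or l.start is None or l.end <= l.start]
    if missing:
        raise ValueError(f"loci lacking a predicted length: {missing}")
    for l in panel:
        lengths.append(l.amplicon_length)
        overheads.append(len(l.fwd_tail) + len(l.rev_tail)
                         + len(index_fwd_extra) + len(index_rev_extra))
    lengths = np.asarray(lengths)
    lib = lengths + np.asarray(overheads)
    return {
        "amplicon_min": int(lengths.min()),
        "amplicon_median": float(np.median(lengths)),
        "amplicon_max": int(lengths.max()),
        "total_targeted_bp": int(lengths.sum()),
        "library_min": int(lib.min()),
        "library_median": float(np.median(lib)),
        "library_max": int(lib.max()),
    }


# ---------------------------------------------------------------------------
# Microhaplotypes
# ---------------------------------------------------------------------------

def extract_microhaplotypes(matrix: GenotypeMatrix, panel) -> pd.DataFrame:
    """Phased multi-SNP alleles per sample per locus.

    Each sample contributes two haplotype strings (allele indices in
    variant-position order) per locus.  A missing call anywhere in the
    locus, or an unphased heterozygous call, yields a null pair with the
    reason recorded.  Homozygous calls are phase-unambiguous.
    """
    rows = []
    for l in panel:
        idx = matrix.region_index(l.contig, l.start, l.end)
        for s, sample in enumerate(matrix.samples):
            hap1, hap2, reason = [], [], None
            for v in idx:
                a0, a1 = matrix.calls[v, s]
                if a0 == MISSING or a1 == MISSING:
                    reason = "missing call"
                    break
                if a0 != a1 and not matrix.phased[v, s]:
                    reason = "unphased heterozygote"
                    break
                hap1.append(str(a0))
                hap2.append(str(a1))
            if reason is None:
                rows.append((sample, l.locus_id, "".join(hap1), "".join(hap2), None))
            else:
                rows.append((sample, l.locus_id, None, None, reason))
    return pd.DataFrame(rows, columns=["sample", "locus_id", "hap1", "hap2",
                                       "reason"])
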