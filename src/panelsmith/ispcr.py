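"""In-silico PCR: mismatch-tolerant primer mapping and product prediction.

Primers are matched ungapped (substitutions only) on both strands with a
mismatch budget of floor(mismatch_fraction x primer length) — 5% allows a
single mismatch for typical 17-26 bp primers.  Convergent hit pairs
within a maximum outer span form predicted products; a primer pair with
more than one product in the genome (the intended target included) is
flagged as having putative off-target loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dna import revcomp

__all__ = ["PrimerHit", "AmpliconProduct", "find_primer_hits",
           "predict_products", "flag_off_targets"]


@dataclass(frozen=True)
class PrimerHit:
    contig: str
    start: int          # 0-based half-open
    end: int
    strand: str         # "+" or "-"
    mismatches: int
    primer_id: str


@dataclass(frozen=True)
class AmpliconProduct:
    forward_hit: PrimerHit    # the plus-strand hit (upstream)
    reverse_hit: PrimerHit    # the minus-strand hit (downstream)
    contig: str
    start: int                # outer product interval
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan(genome_arr: np.ndarray, primer: str, max_mm: int):
    """Offsets and mismatch counts of all ungapped matches of primer."""
    p = _encode(primer)
    L = len(p)
    G = len(genome_arr)
    if G < L:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    n_off = G - L + 1
    mm = np.zeros(n_off, dtype=np.int16)
    for i in range(L):
        mm += genome_arr[i:i + n_off] != p[i]
    keep = np.flatnonzero(mm <= max_mm)
    return keep, mm[keep].astype(int)


def find_primer_hits(primer: str, genome: dict, mismatch_fraction: float = 0.05,
                     primer_id: str = "primer") -> list:
    """All ungapped hits of a primer (both strands) within the mismatch budget.

    An N in the genome counts as a mismatch.  Primers shorter than 10 bp
    are rejected as uninformative.
    """
    if len(primer) < 10:
        raise ValueError(f"primer {primer_id!r} shorter than 10 bp")
    if set(primer) - set("ACGT"):
        raise ValueError(f"primer {primer_id!r} contains non-ACGT characters")
    max_mm = int(np.floor(mismatch_fraction * len(primer)))
    hits = []
    for name in sorted(genome):
        arr = _encode(genome[name].seq)
        for strand, query in (("+", primer), ("-", revcomp(primer))):
            offs, mms = _scan(arr, query, max_mm)
            for o, m in zip(offs, mms):
                hits.append(PrimerHit(name, int(o), int(o) + len(primer),
                                      strand, int(m), primer_id))
    return hits


def predict_products(fwd_hits, rev_hits, max_product: int = 300) -> list:
    """Convergent pairings of two primers' hits with outer span <= max_product.

    Both primer orderings are tried: either primer may supply the
    plus-strand (upstream) hit, the other the minus-strand (downstream)
    hit.  Divergent pairs and overlapping pairs shorter than the two
    primer footprints yield no product.
    """
    products = set()
    for plus_pool, minus_pool in ((fwd_hits, rev_hits), (rev_hits, fwd_hits)):
        for hp in plus_pool:
            if hp.strand != "+":
                continue
            for hm in minus_pool:
                if hm.strand != "-" or hm.contig != hp.contig:
                    continue
                span = hm.end - hp.start
                min_len = (hp.end - hp.start) + (hm.end - hm.start)
                if hp.start <= hm.start and min_len <= span <= max_product:
                    products.add(AmpliconProduct(hp, hm, hp.contig,
                                                 hp.start, hm.end))
    return sorted(products, key=lambda p: (p.contig, p.start, p.end))


def flag_off_targets(panel, genome: dict, mismatch_fraction: float = 0.05,
                     max_product: int = 300) -> pd.DataFrame:
    """Per-locus product census: >1 product means putative off-target loci.

    The count includes the intended target; a pair with zero products is
    flagged separately as target-not-found.  Returns a DataFrame with
    columns locus_id, n_products, off_target, target_not_found and the
    per-locus product list.
    """
    rows = []
    for locus in panel:
        fwd = find_primer_hits(locus.fwd_seq, genome, mismatch_fraction,
                               primer_id=f"{locus.locus_id}/F")
        rev = find_primer_hits(locus.rev_seq, genome, mismatch_fraction,
                               primer_id=f"{locus.locus_id}/R")
        prods = predict_products(fwd, rev, max_product=max_product)
        rows.append({
            "locus_id": locus.locus_id,
            "n_products": len(prods),
            "off_target": len(prods) > 1,
            "target_not_found": len(prods) == 0,
            "products": prods,
        })
    return pd.DataFrame(rows)
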