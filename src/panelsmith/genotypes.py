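"""In-memory genotype matrix shared by all statistics and filters.

Diploid calls are stored as a (variants x samples x 2) array of allele
indices with -1 for missing alleles.  Per-call read depth (DP) and phred
genotype quality (GQ) ride alongside, as do the per-site INFO annotations
the hard-filter cascade consumes (QD, FS, ReadPosRankSum).  Positions are
0-based; conversion from the 1-based VCF convention happens in the reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    contigs: np.ndarray            # (n_var,) object/str
    positions: np.ndarray          # (n_var,) int64, 0-based
    ref: np.ndarray                # (n_var,) object/str
    alt: list                      # (n_var,) list of tuples of alt alleles
    calls: np.ndarray              # (n_var, n_samp, 2) int8, MISSING = -1
    dp: np.ndarray                 # (n_var, n_samp) int32
    gq: np.ndarray                 # (n_var, n_samp) int32
    phased: np.ndarray             # (n_var, n_samp) bool
    samples: list
    info: dict = field(default_factory=dict)   # name -> float array, NaN = undefined
    subpops: np.ndarray | None = None          # (n_samp,) labels, optional

    def __post_init__(self):
        n_var, n_samp = self.calls.shape[:2]
        if self.dp.shape != (n_var, n_samp) or self.gq.shape != (n_var, n_samp):
            raise ValueError("DP/GQ shape does not match calls")
        if len(self.samples) != n_samp:
            raise ValueError("sample id count does not match calls")
        for v in range(n_var):
            n_alleles = 1 + len(self.alt[v])
            a = self.calls[v]
            if np.any(a[a != MISSING] >= n_alleles):
                raise ValueError(f"allele index out of range at variant {v}")

    # -- shape -----------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    # -- subsetting ------------------------------------------------------
    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            contigs=self.contigs[index],
            positions=self.positions[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            calls=self.calls[index],
            dp=self.dp[index],
            gq=self.gq[index],
            phased=self.phased[index],
            info={k: v[index] for k, v in self.info.items()},
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            calls=self.calls[:, index],
            dp=self.dp[:, index],
            gq=self.gq[:, index],
            phased=self.phased[:, index],
            samples=[self.samples[i] for i in index],
            subpops=None if self.subpops is None else self.subpops[index],
        )

    def region_index(self, contig: str, start: int, end: int) -> np.ndarray:
        """Variant indices with position in [start, end) on contig."""
        m = (self.contigs == contig) & (self.positions >= start) & (self.positions < end)
        return np.flatnonzero(m)

    def subpop_sample_index(self, label) -> np.ndarray:
        if self.subpops is None:
            raise ValueError("matrix carries no subpopulation labels")
        return np.flatnonzero(self.subpops == label)

    # -- derived views ---------------------------------------------------
    def is_snp(self) -> np.ndarray:
        """True for variants whose ref and every alt allele have length 1."""
        out = np.empty(self.n_variants, dtype=bool)
        for v in range(self.n_variants):
            out[v] = len(self.ref[v]) == 1 and all(len(a) == 1 for a in self.alt[v])
        return out

    def allele_counts(self, sample_index=None, max_allele: int | None = None) -> np.ndarray:
        """(n_var, n_alleles) counts of each allele index over non-missing calls."""
        calls = self.calls if sample_index is None else self.calls[:, sample_index]
        if max_allele is None:
            max_allele = max((len(a) for a in self.alt), default=0)
        n_alleles = 1 + max_allele
        flat = calls.reshape(self.n_variants, -1)
        out = np.zeros((self.n_variants, n_alleles), dtype=np.int64)
        for k in range(n_alleles):
            out[:, k] = (flat == k).sum(axis=1)
        return out

    def dosage(self, sample_index=None) -> np.ndarray:
        """Reference-vs-rest dosage (count of non-reference alleles, 0/1/2).

        Multiallelic sites are collapsed to ref-vs-any-alt; missing calls
        yield NaN.
        """
        calls = self.calls if sample_index is None else self.calls[:, sample_index]
        missing = (calls == MISSING).any(axis=2)
        dos = (calls > 0).sum(axis=2).astype(float)
        dos[missing] = np.nan
        return dos

    def missing_mask(self) -> np.ndarray:
        """(n_var, n_samp) True where the genotype is missing."""
        return (self.calls == MISSING).any(axis=2)
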