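"""Readers and writers for the external formats the pipeline touches.

One coordinate convention everywhere: intervals are 0-based, half-open.
VCF positions (1-based in the file) and genetic-map anchors (bp as printed)
are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_DNA = set("ACGTN")
_PRIMER_RE = re.compile(r"^[ACGT]+$")

PRIMER_COLUMNS = {
    "locus_id": "locus_id",
    "fwd_seq": "fwd_seq",
    "rev_seq": "rev_seq",
    "fwd_tail": "fwd_tail",
    "rev_tail": "rev_tail",
    "balancing_factor": "balancing_factor",
    "contig": "contig",
    "start": "start",
    "end": "end",
}


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """One reference contig: uppercase DNA plus soft-mask intervals.

    Lowercase runs in the source FASTA (the common carrier of repeat
    annotation) are recorded as half-open intervals and the sequence is
    uppercased, so downstream string matching never sees case.
    """

    name: str
    seq: str
    softmask: list = field(default_factory=list)  # [(start, end), ...]

    def __len__(self) -> int:
        return len(self.seq)


def _lowercase_runs(seq: str):
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def read_fasta(path) -> dict:
    """Load a FASTA file into {contig id: GenomeSequence}.

    Raises on duplicate contig ids and on any character outside
    {A,C,G,T,N} (case-insensitive), naming the offending position.
    """
    genome: dict = {}
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate contig id {rec.id!r}")
            raw = str(rec.seq)
            for i, c in enumerate(raw):
                if c.upper() not in _DNA:
                    raise ValueError(
                        f"invalid DNA character {c!r} at {rec.id}:{i + 1}"
                    )
            genome[rec.id] = GenomeSequence(
                name=rec.id, seq=raw.upper(), softmask=_lowercase_runs(raw)
            )
    if not genome:
        log.warning("FASTA %s contained no records", path)
    return genome


def write_fasta(genome: dict, path, width: int = 70) -> None:
    """Write GenomeSequences, re-lowercasing soft-masked intervals."""
    with _open(path, "wt") as fh:
        for contig in genome.values():
            seq = list(contig.seq)
            for s, e in contig.softmask:
                for i in range(s, e):
                    seq[i] = seq[i].lower()
            fh.write(f">{contig.name}\n")
            s = "".join(seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, required_fields=("GT",)) -> GenotypeMatrix:
    """Read a VCF v4.x into a GenotypeMatrix.

    Only GT, DP, GQ (FORMAT) and QD, FS, ReadPosRankSum (INFO) are
    interpreted; everything else passes through the reader untouched.
    Positions are converted to 0-based.  Absent INFO values are stored as
    NaN ("undefined"), never as 0.  Records must be coordinate-sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for fld in required_fields:
        if fld == "GT":
            continue
        try:
            vcf.get_header_type(fld)
        except KeyError:
            raise ValueError(f"required field {fld!r} absent from VCF header")

    samples = list(vcf.samples)
    contigs, positions, refs, alts = [], [], [], []
    calls, dps, gqs, phases = [], [], [], []
    info_keys = ("QD", "FS", "ReadPosRankSum")
    info = {k: [] for k in info_keys}

    last: dict = {}
    seen_contigs: list = []
    for var in vcf:
        if var.CHROM not in last:
            if seen_contigs and var.CHROM in seen_contigs:
                raise ValueError(f"unsorted VCF: contig {var.CHROM} interleaved")
            seen_contigs.append(var.CHROM)
            last[var.CHROM] = -1
        if var.POS < last[var.CHROM]:
            raise ValueError(
                f"unsorted VCF: {var.CHROM}:{var.POS} after {last[var.CHROM]}"
            )
        last[var.CHROM] = var.POS

        contigs.append(var.CHROM)
        positions.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(tuple(var.ALT))
        row_calls = np.full((len(samples), 2), MISSING, dtype=np.int8)
        row_phase = np.zeros(len(samples), dtype=bool)
        for s, g in enumerate(var.genotypes):
            a0, a1 = g[0], g[1]
            if a0 >= 0:
                row_calls[s, 0] = a0
            if a1 >= 0:
                row_calls[s, 1] = a1
            row_phase[s] = bool(g[2])
        calls.append(row_calls)
        phases.append(row_phase)

        dp = var.format("DP")
        gq = var.format("GQ")
        dps.append(_format_column(dp, len(samples)))
        gqs.append(_format_column(gq, len(samples)))
        for k in info_keys:
            v = var.INFO.get(k)
            info[k].append(np.nan if v is None else float(v))

    n = len(positions)
    return GenotypeMatrix(
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        calls=(np.stack(calls) if n else np.empty((0, len(samples), 2), np.int8)),
        dp=(np.stack(dps) if n else np.empty((0, len(samples)), np.int32)),
        gq=(np.stack(gqs) if n else np.empty((0, len(samples)), np.int32)),
        phased=(np.stack(phases) if n else np.empty((0, len(samples)), bool)),
        samples=samples,
        info={k: np.array(v, dtype=float) for k, v in info.items()},
    )


def _format_column(arr, n_samples) -> np.ndarray:
    if arr is None:
        return np.zeros(n_samples, dtype=np.int32)
    col = np.asarray(arr).reshape(n_samples, -1)[:, 0].astype(np.int64)
    col[col < 0] = 0  # cyvcf2 missing sentinel
    return col.astype(np.int32)


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: dict | None = None,
              extra_header_lines=()) -> None:
    """Write a GenotypeMatrix as VCF v4.2 text (GT:DP:GQ, known INFO keys)."""
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in extra_header_lines:
            fh.write(line.rstrip("\n") + "\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">\n')
        fh.write('##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,'
                 'Description="Read position rank-sum">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for v in range(matrix.n_variants):
            parts = []
            for k in ("QD", "FS", "ReadPosRankSum"):
                if k in matrix.info and not np.isnan(matrix.info[k][v]):
                    parts.append(f"{k}={matrix.info[k][v]:.4f}")
            info_s = ";".join(parts) if parts else "."
            alt_s = ",".join(matrix.alt[v]) if matrix.alt[v] else "."
            cols = [
                str(matrix.contigs[v]), str(matrix.positions[v] + 1), ".",
                str(matrix.ref[v]), alt_s, ".", ".", info_s, "GT:DP:GQ",
            ]
            for s in range(matrix.n_samples):
                a0, a1 = matrix.calls[v, s]
                sep = "|" if matrix.phased[v, s] else "/"
                gt = (f"{a0}{sep}{a1}" if a0 != MISSING and a1 != MISSING
                      else f".{sep}.")
                cols.append(f"{gt}:{matrix.dp[v, s]}:{matrix.gq[v, s]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Per-contig (bp, cM) anchors with linear interpolation between them.

    Queries beyond the terminal anchors clamp to the terminal cM values.
    """

    def __init__(self, anchors: dict):
        self.anchors = {}
        for contig, pairs in anchors.items():
            pairs = sorted(pairs)
            bp = np.array([p for p, _ in pairs], dtype=float)
            cm = np.array([c for _, c in pairs], dtype=float)
            if len(bp) < 2:
                raise ValueError(f"contig {contig}: need >=2 anchors, got {len(bp)}")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"contig {contig}: bp positions not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"contig {contig}: cM decreases with bp")
            self.anchors[contig] = (bp, cm)

    def interpolate(self, contig: str, bp) -> np.ndarray | float:
        if contig not in self.anchors:
            raise KeyError(f"no genetic map for contig {contig!r}")
        xs, cs = self.anchors[contig]
        out = np.interp(np.asarray(bp, dtype=float), xs, cs)
        return float(out) if np.isscalar(bp) else out

    def cm_range(self, contig: str):
        _, cs = self.anchors[contig]
        return float(cs[0]), float(cs[-1])

    @property
    def contigs(self):
        return list(self.anchors)


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    need = {"contig", "bp", "cM"}
    if not need.issubset(df.columns):
        raise ValueError(f"genetic map must have columns {sorted(need)}")
    anchors = {
        c: list(zip(g["bp"].astype(float), g["cM"].astype(float)))
        for c, g in df.groupby("contig", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    rows = []
    for contig, (bp, cm) in gmap.anchors.items():
        for b, c in zip(bp, cm):
            rows.append((contig, int(b), c))
    pd.DataFrame(rows, columns=["contig", "bp", "cM"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Primer table
# ---------------------------------------------------------------------------

def read_primer_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a primer panel table (TSV).

    The canonical column set is locus_id, fwd_seq, rev_seq, fwd_tail,
    rev_tail, balancing_factor and optional contig/start/end target
    coordinates; ``column_map`` renames file columns onto that set, so any
    supplementary-table layout can be adapted.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str})
    if column_map:
        df = df.rename(columns=column_map)
    return validate_primer_table(df)


def validate_primer_table(df: pd.DataFrame) -> pd.DataFrame:
    need = ["locus_id", "fwd_seq", "rev_seq", "balancing_factor"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"primer table missing columns: {missing}")
    if df["locus_id"].duplicated().any():
        dup = df.loc[df["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValueError(f"duplicate locus id {dup!r}")
    for col in ("fwd_seq", "rev_seq"):
        for locus, seq in zip(df["locus_id"], df[col]):
            if not _PRIMER_RE.match(str(seq)):
                raise ValueError(
                    f"locus {locus!r}: {col} contains non-ACGT characters"
                )
    if (df["balancing_factor"] <= 0).any():
        bad = df.loc[df["balancing_factor"] <= 0, "locus_id"].iloc[0]
        raise ValueError(f"locus {bad!r}: balancing factor must be > 0")
    for col in ("fwd_tail", "rev_tail"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    df["fwd_len"] = df["fwd_seq"].str.len()
    df["rev_len"] = df["rev_seq"].str.len()
    df["fwd_tail_len"] = df["fwd_tail"].str.len()
    df["rev_tail_len"] = df["rev_tail"].str.len()
    return df.reset_index(drop=True)


def write_primer_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in PRIMER_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and read-alignment tables
# ---------------------------------------------------------------------------

def read_bed(path) -> list:
    """Read a BED-3 file into [(contig, start, end)], 0-based half-open."""
    out = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals, path, names=None, scores=None) -> None:
    with _open(path, "wt") as fh:
        for i, (contig, start, end) in enumerate(intervals):
            cols = [contig, str(start), str(end)]
            if names is not None:
                cols.append(str(names[i]))
            if scores is not None:
                if names is None:
                    cols.append(".")
                cols.append(f"{scores[i]:.6g}")
            fh.write("\t".join(cols) + "\n")


def read_alignment_table(path) -> pd.DataFrame:
    """Read-to-reference intervals: read_id, contig, start, end, multimap."""
    df = pd.read_csv(path, sep="\t")
    need = {"read_id", "contig", "start", "end", "multimap"}
    if not need.issubset(df.columns):
        raise ValueError(f"alignment table must have columns {sorted(need)}")
    df["multimap"] = df["multimap"].astype(int)
    return df
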