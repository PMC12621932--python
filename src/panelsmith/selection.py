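"""Gap-filling marker selection over a genetic map, dimer screening, and
final panel choice.

The selector repeatedly finds the widest remaining centimorgan gap across
all chromosomes and drops a marker into it, scoring candidates by how
centrally they sit in the gap and how many SNPs they carry, with a seeded
epsilon-random choice among near-best candidates ("pseudo-random"
gap filling).  Several independently seeded sets are drawn; the final
panel is the set with the smallest maximum cM gap, greedily truncated to
the target size and purged of loci excluded after wet-lab validation.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dna import revcomp
from .io import GeneticMap

log = logging.getLogger(__name__)

# Default PCR1 adapter tails (Illumina-compatible): 31 bp forward, 34 bp
# reverse, appended 5' of each locus-specific sequence.
DEFAULT_FWD_TAIL = "TCGTCGGCAGCGTCAGATGTGTATAAGAGAC"
DEFAULT_REV_TAIL = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"


@dataclass
class PanelLocus:
    locus_id: str
    contig: str
    start: int                 # amplicon interval, 0-based half-open
    end: int
    core_start: int
    core_end: int
    cm: float | None
    snp_count: int
    fwd_seq: str = ""
    rev_seq: str = ""
    fwd_tail: str = DEFAULT_FWD_TAIL
    rev_tail: str = DEFAULT_REV_TAIL
    balancing_factor: float = 1.0

    @property
    def amplicon_length(self) -> int:
        return self.end - self.start


@dataclass
class Panel:
    loci: list = field(default_factory=list)

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def ids(self):
        return [l.locus_id for l in self.loci]

    def get(self, locus_id: str) -> PanelLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def intervals(self):
        return [(l.contig, l.start, l.end) for l in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "locus_id": l.locus_id, "fwd_seq": l.fwd_seq, "rev_seq": l.rev_seq,
            "fwd_tail": l.fwd_tail, "rev_tail": l.rev_tail,
            "balancing_factor": l.balancing_factor, "contig": l.contig,
            "start": l.start, "end": l.end,
        } for l in self.loci])


@dataclass
class SelectionRun:
    seed: int
    m: int
    n_sets: int
    sets: list            # list of list of locus ids
    summaries: list       # per set: dict(max_gap, median_gap, total_snps)


# ---------------------------------------------------------------------------
# Gap-filling selection
# ---------------------------------------------------------------------------

def gap_fill_select(candidates, gmap: GeneticMap, m: int = 350,
                    n_sets: int = 10, seed: int = 0, w_gap: float = 0.7,
                    w_snp: float = 0.3, eps: float = 0.05) -> SelectionRun:
    """Draw ``n_sets`` pseudo-random gap-filling marker sets of size ``m``.

    Each set starts from chromosome-end sentinels (the terminal cM values
    of the map) and repeatedly fills the widest current gap, choosing
    uniformly at random among candidates within ``eps`` of the best
    combined centrality/SNP score.  Set i uses seed ``seed + i``.
    """
    cands = [c for c in candidates]
    if not cands:
        raise ValueError("no candidates to select from")
    for c in cands:
        if c.cm is None:
            raise ValueError(f"candidate {_cid(c)} has no cM position")
        if c.contig not in gmap.anchors:
            raise KeyError(f"no genetic map for contig {c.contig!r}")
    if len(cands) < m:
        log.warning("only %d candidates for m=%d; selecting all", len(cands), m)

    max_snp = max(_snp(c) for c in cands) or 1
    sets, summaries = [], []
    for set_i in range(n_sets):
        rng = np.random.default_rng(seed + set_i)
        chosen = _fill_one_set(cands, gmap, min(m, len(cands)), rng,
                               w_gap, w_snp, eps, max_snp)
        ids = [_cid(c) for c in chosen]
        sets.append(ids)
        summaries.append(_summarize(chosen))
    return SelectionRun(seed=seed, m=m, n_sets=n_sets, sets=sets,
                        summaries=summaries)


def _cid(c) -> str:
    return getattr(c, "locus_id", None) or c.region_id


def _snp(c) -> int:
    return c.snp_count


def _cm_mid(c) -> float:
    return c.cm


def _fill_one_set(cands, gmap, m, rng, w_gap, w_snp, eps, max_snp):
    positions = {}   # contig -> sorted chosen cMs incl. sentinels
    contigs = sorted({c.contig for c in cands})
    for contig in contigs:
        lo, hi = gmap.cm_range(contig)
        positions[contig] = [lo, hi]
    available = list(range(len(cands)))
    chosen = []
    while len(chosen) < m and available:
        gaps = []
        for contig in contigs:
            pos = positions[contig]
            for a, b in zip(pos, pos[1:]):
                gaps.append((b - a, contig, a, b))
        gaps.sort(key=lambda g: (-g[0], g[1], g[2]))
        picked = None
        for gap_len, contig, lo, hi in gaps:
            inside = [k for k in available
                      if cands[k].contig == contig and lo <= _cm_mid(cands[k]) <= hi]
            if not inside:
                continue
            half = (hi - lo) / 2.0
            mid = (lo + hi) / 2.0
            scores = {}
            for k in inside:
                central = 1.0 if half == 0 else 1.0 - abs(_cm_mid(cands[k]) - mid) / half
                scores[k] = w_gap * central + w_snp * (_snp(cands[k]) / max_snp)
            best = max(scores.values())
            eligible = sorted(k for k, s in scores.items() if s >= best - eps)
            picked = eligible[int(rng.integers(0, len(eligible)))]
            break
        if picked is None:
            break
        available.remove(picked)
        chosen.append(cands[picked])
        bisect.insort(positions[cands[picked].contig], _cm_mid(cands[picked]))
    return chosen


def _summarize(chosen) -> dict:
    stats = spacing_stats([(c.contig, _cm_mid(c)) for c in chosen])
    return {
        "max_gap": stats["max_gap"],
        "median_gap": stats["median_gap"],
        "total_snps": int(sum(_snp(c) for c in chosen)),
    }


# ---------------------------------------------------------------------------
# Spacing statistics
# ---------------------------------------------------------------------------

def spacing_stats(loci) -> dict:
    """cM gaps between consecutive markers, pooled across contigs.

    ``loci`` is an iterable of (contig, cM) pairs or PanelLocus objects.
    Contig ends contribute no gap; a contig with a single locus
    contributes none either.
    """
    pairs = [(l.contig, l.cm) if isinstance(l, PanelLocus) else l for l in loci]
    by_contig: dict = {}
    for contig, cm in pairs:
        by_contig.setdefault(contig, []).append(cm)
    gaps = []
    for cms in by_contig.values():
        cms.sort()
        gaps.extend(b - a for a, b in zip(cms, cms[1:]))
    return {
        "gaps": gaps,
        "min_gap": min(gaps) if gaps else None,
        "median_gap": float(np.median(gaps)) if gaps else None,
        "max_gap": max(gaps) if gaps else None,
        "loci_per_contig": {c: len(v) for c, v in by_contig.items()},
    }


# ---------------------------------------------------------------------------
# Dimer screening
# ---------------------------------------------------------------------------

def dimer_screen(primers, t3: int = 5, ti: int = 8) -> list:
    """Flag primer pairs able to form dimers, by complementarity heuristic.

    ``primers`` is an iterable of (id, sequence).  A pair (A, B) is
    flagged when the 3'-terminal ``t3`` bases of A reverse-complement-match
    a subsequence of B (extension-competent 3' duplex) or when any perfect
    reverse-complement run of >= ``ti`` bases exists anywhere between the
    two.  The flag set is symmetric; self-dimers are screened too.
    """
    primers = list(primers)
    flagged = {}
    for id_a, seq_a in primers:
        tail_rc = revcomp(seq_a[-t3:])
        kmers_a = {revcomp(seq_a[i:i + ti]) for i in range(len(seq_a) - ti + 1)}
        for id_b, seq_b in primers:
            key = tuple(sorted((id_a, id_b)))
            if key in flagged:
                continue
            if tail_rc in seq_b:
                flagged[key] = "3'-anchored complement"
                continue
            for i in range(len(seq_b) - ti + 1):
                if seq_b[i:i + ti] in kmers_a:
                    flagged[key] = f"internal complement run >= {ti}"
                    break
    return [(a, b, why) for (a, b), why in sorted(flagged.items())]


# ---------------------------------------------------------------------------
# Final set choice
# ---------------------------------------------------------------------------

def choose_final_set(run: SelectionRun, candidates, final_m: int = 300,
                     exclusion=()) -> Panel:
    """Pick the best set from a selection run and trim it to the final panel.

    The set minimizing the maximum cM gap wins (ties: smaller median gap,
    then lower seed).  It is truncated to ``final_m`` by iteratively
    removing the locus whose removal least increases the maximum gap, then
    loci on the exclusion list are dropped without replacement.
    """
    if not run.sets:
        raise ValueError("empty selection run")
    by_id = {_cid(c): c for c in candidates}
    order = sorted(
        range(len(run.sets)),
        key=lambda i: (run.summaries[i]["max_gap"] if run.summaries[i]["max_gap"]
                       is not None else np.inf,
                       run.summaries[i]["median_gap"] if run.summaries[i]["median_gap"]
                       is not None else np.inf,
                       i),
    )
    chosen = [by_id[i] for i in run.sets[order[0]]]

    while len(chosen) > final_m:
        best_idx, best_max = None, None
        for k in range(len(chosen)):
            trial = chosen[:k] + chosen[k + 1:]
            mg = spacing_stats([(c.contig, _cm_mid(c)) for c in trial])["max_gap"]
            mg = -np.inf if mg is None else mg
            if best_max is None or mg < best_max:
                best_idx, best_max = k, mg
        chosen.pop(best_idx)

    excl = set(exclusion)
    unknown = excl - {_cid(c) for c in chosen}
    for u in sorted(unknown):
        log.warning("exclusion id %r not in the chosen set; ignored", u)
    chosen = [c for c in chosen if _cid(c) not in excl]
    return Panel([_as_locus(c) for c in chosen])


def _as_locus(c) -> PanelLocus:
    if isinstance(c, PanelLocus):
        return c
    return PanelLocus(
        locus_id=c.region_id, contig=c.contig,
        start=c.flank_left[0], end=c.flank_right[1],
        core_start=c.core_start, core_end=c.core_end,
        cm=c.cm, snp_count=c.snp_count,
    )


# ---------------------------------------------------------------------------
# Primer attachment (flank-derived locus-specific sequences)
# ---------------------------------------------------------------------------

def attach_primers(panel: Panel, genome: dict, seed: int = 0,
                   primer_len_range=(17, 26)) -> Panel:
    """Derive locus-specific primers from the conserved flanks of each locus.

    The forward primer is the flank sequence immediately 5' of the core;
    the reverse primer is the reverse complement of the sequence
    immediately 3' of it.  Lengths are drawn per primer from
    ``primer_len_range`` (inclusive).  The amplicon interval is reset to
    the outer primer coordinates.
    """
    rng = np.random.default_rng(seed)
    out = []
    for locus in panel:
        seq = genome[locus.contig].seq
        lf = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
        lr = int(rng.integers(primer_len_range[0], primer_len_range[1] + 1))
        start = locus.core_start - lf
        end = locus.core_end + lr
        if start < 0 or end > len(seq):
            raise ValueError(f"locus {locus.locus_id}: primer footprint off contig")
        fwd = seq[start:locus.core_start]
        rev = revcomp(seq[locus.core_end:end])
        out.append(replace(locus, start=start, end=end, fwd_seq=fwd, rev_seq=rev))
    return Panel(out)
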