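"""Candidate target-region detection and filtering.

A candidate is a short high-diversity core (by default 50-150 bp with
window pi > 0.005) flanked on both sides by low-diversity sequence
(pi < 0.0001), the configuration that admits conserved PCR primer sites
around a maximally informative amplicon.  Candidates then pass through a
repeat mask, a copy-number-suspicion filter (inflated depth, diversity or
SNP count betray collapsed duplications), and a selection/inbreeding
filter (per-subpopulation Tajima's D and Malecot's f), leaving regions
suitable for neutral population genotyping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .popgen import SelectionStats, malecot_f, tajimas_d

FLAG_NAMES = ("te", "cnv", "selection", "depth")


@dataclass
class DesignConfig:
    """Thresholds of the region-design filter cascade."""
    pi_core_min: float = 0.005       # window pi above this joins a core run
    pi_flank_max: float = 0.0001     # flank windows must stay below this
    min_core: int = 50               # core length bounds, bp
    max_core: int = 150
    min_flank: int = 30              # required clean flank per side, bp
    depth_ceiling: float = 20_000.0  # CNV-suspect when all samples exceed
    pi_ceiling: float = 0.02         # CNV-suspect when core pi exceeds
    snp_ceiling: int = 25            # CNV-suspect when core SNP count exceeds
    depth_floor: float = 5_000.0     # samples below are dropped per region
    tajima_low: float = -2.0
    tajima_high: float = 2.0
    f_ceiling: float = 0.25
    fail_on_null_d: bool = True      # a subpop with S=0 fails the region


@dataclass
class CandidateRegion:
    region_id: str
    contig: str
    core_start: int
    core_end: int
    flank_left: tuple
    flank_right: tuple
    core_pi: float
    flank_pi: tuple
    snp_count: int
    selection: SelectionStats | None = None
    mean_depth: dict = field(default_factory=dict)   # sample -> core mean DP
    dropped_low_depth: int = 0
    flags: dict = field(default_factory=lambda: {k: False for k in FLAG_NAMES})
    reasons: list = field(default_factory=list)
    cm: float | None = None

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start

    @property
    def passes(self) -> bool:
        return not any(self.flags.values())

    @property
    def span(self) -> tuple:
        return (self.flank_left[0], self.flank_right[1])


# ---------------------------------------------------------------------------
# Core scan
# ---------------------------------------------------------------------------

def scan_candidates(pi_track: pd.DataFrame, config: DesignConfig | None = None
                    ) -> list:
    """Find flanked high-diversity cores in a tiled window-pi track.

    Maximal runs of consecutive windows with pi > pi_core_min whose total
    length lies within the core bounds become cores; each core must be
    bordered on both sides by enough sub-threshold windows to cover
    ``min_flank`` bp.  Cores at contig ends (missing a full flank) are
    rejected.
    """
    config = config or DesignConfig()
    candidates = []
    for contig, grp in pi_track.groupby("contig", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        window_bp = int((grp["end"] - grp["start"]).iloc[0])
        n_flank_win = math.ceil(config.min_flank / window_bp)
        hot = (grp["pi"] > config.pi_core_min).to_numpy()
        pis = grp["pi"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        svals = grp["s"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            if not hot[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            core_start, core_end = int(starts[i]), int(ends[j])
            length = core_end - core_start
            if config.min_core <= length <= config.max_core:
                left = range(i - n_flank_win, i)
                right = range(j + 1, j + 1 + n_flank_win)
                has_left = i - n_flank_win >= 0
                has_right = j + n_flank_win < n
                if has_left and has_right:
                    left_ok = all(pis[k] < config.pi_flank_max for k in left)
                    right_ok = all(pis[k] < config.pi_flank_max for k in right)
                    if left_ok and right_ok:
                        fl = (int(starts[i - n_flank_win]), core_start)
                        fr = (core_end, int(ends[j + n_flank_win]))
                        core_len_windows = ends[i:j + 1] - starts[i:j + 1]
                        core_pi = float(
                            np.sum(pis[i:j + 1] * core_len_windows) / length
                        )
                        candidates.append(CandidateRegion(
                            region_id=f"{contig}:{core_start}-{core_end}",
                            contig=contig,
                            core_start=core_start,
                            core_end=core_end,
                            flank_left=fl,
                            flank_right=fr,
                            core_pi=core_pi,
                            flank_pi=(
                                float(np.mean(pis[list(left)])),
                                float(np.mean(pis[list(right)])),
                            ),
                            snp_count=int(svals[i:j + 1].sum()),
                        ))
            i = j + 1
    return candidates


# ---------------------------------------------------------------------------
# Filters (each sets flags on the unfiltered candidate list)
# ---------------------------------------------------------------------------

def apply_repeat_mask(candidates, mask_intervals) -> list:
    """Flag candidates whose core or either flank overlaps a masked interval.

    Intervals are half-open; an interval ending exactly where the candidate
    span begins does not overlap.
    """
    by_contig: dict = {}
    for contig, s, e in mask_intervals:
        by_contig.setdefault(contig, []).append((s, e))
    for ivs in by_contig.values():
        ivs.sort()
    for cand in candidates:
        span_s, span_e = cand.span
        for s, e in by_contig.get(cand.contig, ()):
            if s < span_e and e > span_s:
                cand.flags["te"] = True
                cand.reasons.append("repeat-mask overlap")
                break
    return candidates


def cnv_depth_filter(candidates, matrix: GenotypeMatrix,
                     config: DesignConfig | None = None) -> list:
    """Flag copy-number-suspect and depth-failed candidates.

    Per region, samples with mean core depth below the floor are dropped
    from that region's statistics and counted.  A region is CNV-suspect
    when depth exceeds the ceiling in *all* remaining samples, or core pi
    exceeds its ceiling, or the core SNP count exceeds its ceiling.
    """
    config = config or DesignConfig()
    for cand in candidates:
        idx = matrix.region_index(cand.contig, cand.core_start, cand.core_end)
        if idx.size == 0:
            depth = np.zeros(matrix.n_samples)
        else:
            depth = matrix.dp[idx].mean(axis=0)
        cand.mean_depth = dict(zip(matrix.samples, depth.tolist()))
        keep = depth >= config.depth_floor
        cand.dropped_low_depth = int((~keep).sum())
        if not keep.any():
            cand.flags["depth"] = True
            cand.reasons.append("no sample meets the depth floor")
            continue
        if np.all(depth[keep] > config.depth_ceiling):
            cand.flags["cnv"] = True
            cand.reasons.append("depth above ceiling in all samples")
        if cand.core_pi > config.pi_ceiling:
            cand.flags["cnv"] = True
            cand.reasons.append("core pi above ceiling")
        if cand.snp_count > config.snp_ceiling:
            cand.flags["cnv"] = True
            cand.reasons.append("core SNP count above ceiling")
    return candidates


def selection_filter(candidates, matrix: GenotypeMatrix, subpops=None,
                     config: DesignConfig | None = None) -> list:
    """Flag candidates under apparent selection or inbreeding.

    A region passes only if, in every subpopulation, Tajima's D lies
    strictly inside (tajima_low, tajima_high) and Malecot's f is below the
    ceiling.  A null D (no segregating sites in a subpopulation) fails the
    region when ``fail_on_null_d`` is set.
    """
    config = config or DesignConfig()
    if subpops is None:
        if matrix.subpops is None:
            raise ValueError("matrix carries no subpopulation labels")
        subpops = sorted(set(matrix.subpops))
    if len(subpops) < 2:
        raise ValueError("selection filter needs >= 2 subpopulations")
    for cand in candidates:
        region = (cand.contig, cand.core_start, cand.core_end)
        d_by, f_by, n_by = {}, {}, {}
        for pop in subpops:
            sidx = matrix.subpop_sample_index(pop)
            n_by[pop] = 2 * len(sidx)
            if len(sidx) * 2 < 4:
                d_by[pop] = None
                f_by[pop] = None
                cand.flags["selection"] = True
                cand.reasons.append(f"subpop {pop}: <4 haplotypes")
                continue
            d = tajimas_d(matrix, region=region, sample_index=sidx)
            f = malecot_f(matrix, region=region, sample_index=sidx)
            d_by[pop], f_by[pop] = d, f
            if d is None:
                if config.fail_on_null_d:
                    cand.flags["selection"] = True
                    cand.reasons.append(f"subpop {pop}: D undefined (S=0)")
            elif not (config.tajima_low < d < config.tajima_high):
                cand.flags["selection"] = True
                cand.reasons.append(f"subpop {pop}: D={d:.2f} outside bounds")
            if f is not None and f >= config.f_ceiling:
                cand.flags["selection"] = True
                cand.reasons.append(f"subpop {pop}: f={f:.2f} above ceiling")
        cand.selection = SelectionStats(cand.region_id, d_by, f_by, n_by)
    return candidates


# ---------------------------------------------------------------------------
# Composite pipeline and export
# ---------------------------------------------------------------------------

def find_regions(matrix: GenotypeMatrix, contig_lengths: dict,
                 config: DesignConfig | None = None, repeat_mask=None,
                 subpops=None, gmap=None, window_bp: int = 50) -> list:
    """Window-pi scan plus the full filter cascade; returns all candidates.

    Flags are each computed from the unfiltered candidate, so filter order
    does not matter; the pass set is exactly the zero-flag candidates.
    """
    from .popgen import windowed_pi

    config = config or DesignConfig()
    track = windowed_pi(matrix, window_bp=window_bp, contig_lengths=contig_lengths)
    cands = scan_candidates(track, config)
    if repeat_mask:
        apply_repeat_mask(cands, repeat_mask)
    cnv_depth_filter(cands, matrix, config)
    if subpops is not None or matrix.subpops is not None:
        selection_filter(cands, matrix, subpops=subpops, config=config)
    if gmap is not None:
        for cand in cands:
            mid = (cand.core_start + cand.core_end) / 2.0
            cand.cm = gmap.interpolate(cand.contig, mid)
    return cands


def regions_to_frame(candidates) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "region_id": c.region_id, "contig": c.contig,
            "core_start": c.core_start, "core_end": c.core_end,
            "core_pi": c.core_pi, "snp_count": c.snp_count,
            "flank_pi_left": c.flank_pi[0], "flank_pi_right": c.flank_pi[1],
            "flag_te": c.flags["te"], "flag_cnv": c.flags["cnv"],
            "flag_selection": c.flags["selection"], "flag_depth": c.flags["depth"],
            "passes": c.passes, "cm": c.cm,
            "dropped_low_depth": c.dropped_low_depth,
            "reasons": "; ".join(c.reasons),
        })
    return pd.DataFrame(rows)
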