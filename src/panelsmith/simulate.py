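"""Synthetic genomes, populations and read tables for end-to-end testing.

The generator plants the exact structure the design pipeline looks for:
short high-diversity cores (two segregating sites per 50-bp window, minor
allele frequencies from a neutral-spectrum-like 1/x density) on an almost
invariant background, tandem-repeat tracts standing in for transposable
elements, and collapsed-duplication decoys — cores whose surrounding
sequence is copied verbatim elsewhere and whose variant records carry
doubled depth, excess heterozygosity and an inflated SNP count, the
signature of a paralog collapse.  Two subpopulations with correlated
allele frequencies plus admixed individuals provide the population
structure the selection filters and kinship estimator need.

Everything is deterministic under the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dna import random_dna
from .genotypes import GenotypeMatrix
from .io import write_vcf


@dataclass
class SimulationConfig:
    seed: int
    contig_lengths: dict = field(default_factory=lambda: {"chr1": 120_000,
                                                          "chr2": 120_000})
    n_cores: int = 50
    core_length_choices: tuple = (50, 100, 150)   # aligned to the window grid
    window_bp: int = 50
    # per core window: one intermediate-frequency anchor site plus rare
    # sites; the mix puts the mean per-site heterozygosity near the
    # neutral-spectrum expectation 1/a1 so Tajima's D centres on zero
    anchor_maf_range: tuple = (0.2, 0.45)
    rare_maf_range: tuple = (0.02, 0.12)
    rare_sites_per_window: int = 2
    background_site_spacing: int = 2_000          # ~1 site per this many bp
    background_maf: float = 0.05
    flank_guard: int = 150                        # background-free margin, bp
    n_te: int = 10
    te_length_range: tuple = (300, 600)
    te_motif_len: int = 10
    n_decoys: int = 5
    decoy_sites: int = 30                         # pushes S past the CNV ceiling
    decoy_het_prob: float = 0.9
    decoy_zone: int = 10_000                      # reserved per contig for copies
    decoy_flank_copy: int = 100                   # bp copied around a decoy core
    subpop_sizes: tuple = (25, 25)
    subpop_labels: tuple = ("A", "B")
    n_admixed: int = 5
    admixture_proportion: float = 0.5
    subpop_freq_logit_sd: float = 0.3             # between-subpop drift, logit scale
    mean_depth: float = 9_000.0                   # per-call Poisson mean, cores
    decoy_depth_factor: float = 2.0
    gq_range: tuple = (60, 100)
    missing_rate: float = 0.01
    spike_qd: float = 0.03                        # hard-filter violation fractions
    spike_fs: float = 0.03
    spike_rprs: float = 0.03
    bias_log_sd: float = 0.5                      # per-primer amplification bias
    read_total: int = 200_000
    multimap_prob: float = 0.9                    # for reads on decoy loci
    read_length: int = 150


@dataclass
class ReferenceTruth:
    cores: list          # [(contig, start, end)] planted cores, incl. decoys
    decoy_index: list    # indices into cores that are duplication decoys
    tes: list            # [(contig, start, end)]
    decoy_copies: list   # [(contig, start, end, source_core_index)]

    @property
    def true_cores(self) -> list:
        """Planted cores that are not duplication decoys."""
        return [c for i, c in enumerate(self.cores) if i not in set(self.decoy_index)]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def simulate_reference(config: SimulationConfig):
    """Random genome with planted cores, TE tracts and duplication decoys.

    Returns (genome, truth).  Cores are laid out in per-contig slots, each
    far enough from its neighbours and from contig ends that flanks stay
    clean; each decoy copies its core plus ``decoy_flank_copy`` bp of
    flank verbatim into a reserved zone at the contig end.
    """
    from .io import GenomeSequence

    rng = np.random.default_rng(config.seed)
    contigs = list(config.contig_lengths)
    seqs = {c: list(random_dna(rng, L)) for c, L in config.contig_lengths.items()}

    # distribute cores across contigs
    per_contig = _split_evenly(config.n_cores, len(contigs))
    n_te_per = _split_evenly(config.n_te, len(contigs))
    cores, tes = [], []
    w = config.window_bp
    for ci, contig in enumerate(contigs):
        length = config.contig_lengths[contig]
        usable = length - (config.decoy_zone if config.n_decoys else 0)
        n_slots = per_contig[ci]
        if n_slots == 0:
            continue
        slot_w = usable // n_slots
        if slot_w < 3_000:
            raise ValueError("planted features exceed genome length")
        te_slots = set(np.linspace(0, n_slots - 1, n_te_per[ci], dtype=int)
                       ) if n_te_per[ci] else set()
        for s in range(n_slots):
            base = s * slot_w
            core_len = int(rng.choice(config.core_length_choices))
            offset = w * int(rng.integers(1_000 // w, 2_000 // w))
            start = base + offset
            cores.append((contig, start, start + core_len))
            if s in te_slots:
                te_len = int(rng.integers(*config.te_length_range))
                te_start = base + slot_w // 2 + 500
                motif = random_dna(rng, config.te_motif_len)
                tract = (motif * (te_len // len(motif) + 1))[:te_len]
                seqs[contig][te_start:te_start + te_len] = list(tract)
                tes.append((contig, te_start, te_start + te_len))

    decoy_index = sorted(
        rng.choice(len(cores), size=config.n_decoys, replace=False).tolist()
    ) if config.n_decoys else []
    decoy_copies = []
    zone_cursor = {c: config.contig_lengths[c] - config.decoy_zone + 500
                   for c in contigs}
    for k, idx in enumerate(decoy_index):
        contig, cs, ce = cores[idx]
        span_s = cs - config.decoy_flank_copy
        span_e = ce + config.decoy_flank_copy
        src = seqs[contig][span_s:span_e]
        dest_contig = contigs[k % len(contigs)]
        dest = zone_cursor[dest_contig]
        if dest + len(src) > config.contig_lengths[dest_contig]:
            raise ValueError("planted features exceed genome length")
        seqs[dest_contig][dest:dest + len(src)] = src
        decoy_copies.append((dest_contig, dest, dest + len(src), idx))
        zone_cursor[dest_contig] = dest + len(src) + 500

    genome = {c: GenomeSequence(c, "".join(seqs[c])) for c in contigs}
    return genome, ReferenceTruth(cores, decoy_index, tes, decoy_copies)


def _split_evenly(n: int, k: int) -> list:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Population genotypes
# ---------------------------------------------------------------------------

def simulate_population(config: SimulationConfig, truth: ReferenceTruth,
                        genome: dict) -> GenotypeMatrix:
    """Genotypes for two subpopulations plus admixed individuals.

    Segregating sites sit only inside planted cores (two per 50-bp window)
    and sparsely on the background; subpopulation allele frequencies are
    the shared base frequency plus independent jitter; admixed samples
    draw each allele from a subpopulation chosen by the ancestry
    proportion.  Decoy cores get ``decoy_sites`` sites with excess
    heterozygosity and doubled depth.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_a, n_b = config.subpop_sizes
    n_samp = n_a + n_b + config.n_admixed
    labels = ([config.subpop_labels[0]] * n_a + [config.subpop_labels[1]] * n_b
              + ["ADM"] * config.n_admixed)
    samples = [f"s{i:03d}" for i in range(n_samp)]

    decoy_set = set(truth.decoy_index)
    site_rows = []   # (contig, pos, p_base, kind) kind: core|decoy|background
    w = config.window_bp
    n_per_window = 1 + config.rare_sites_per_window
    for i, (contig, cs, ce) in enumerate(truth.cores):
        if i in decoy_set:
            pos = cs + np.sort(rng.choice(ce - cs, size=min(config.decoy_sites,
                                                            ce - cs), replace=False))
            for p_ in pos:
                site_rows.append((contig, int(p_), 0.5, "decoy"))
        else:
            for ws in range(cs, ce, w):
                offs = np.sort(rng.choice(w, size=n_per_window, replace=False))
                mafs = [float(rng.uniform(*config.anchor_maf_range))]
                mafs += [float(rng.uniform(*config.rare_maf_range))
                         for _ in range(config.rare_sites_per_window)]
                for o, maf in zip(offs, mafs):
                    p = maf if rng.random() < 0.5 else 1.0 - maf
                    site_rows.append((contig, int(ws + o), p, "core"))

    # sparse background sites away from core flanks and the decoy zone
    guard = []
    for contig, cs, ce in truth.cores:
        guard.append((contig, cs - config.flank_guard, ce + config.flank_guard))
    for contig, length in config.contig_lengths.items():
        n_bg = length // config.background_site_spacing
        zone_start = length - (config.decoy_zone if config.n_decoys else 0)
        placed = 0
        while placed < n_bg:
            p_ = int(rng.integers(0, zone_start))
            if any(c == contig and s <= p_ < e for c, s, e in guard):
                continue
            site_rows.append((contig, p_, config.background_maf, "background"))
            placed += 1

    site_rows.sort(key=lambda r: (r[0], r[1]))
    n_var = len(site_rows)

    calls = np.empty((n_var, n_samp, 2), dtype=np.int8)
    dp = np.empty((n_var, n_samp), dtype=np.int32)
    gq = np.empty((n_var, n_samp), dtype=np.int32)
    bases = np.array(list("ACGT"))
    contigs_arr, positions, refs, alts = [], [], [], []
    alpha = config.admixture_proportion
    def _logit_jitter(p: float) -> float:
        z = np.log(p / (1 - p)) + rng.normal(0.0, config.subpop_freq_logit_sd)
        return float(1.0 / (1.0 + np.exp(-z)))

    for v, (contig, pos, p, kind) in enumerate(site_rows):
        p_a = _logit_jitter(p)
        p_b = _logit_jitter(p)
        if kind == "decoy":
            # collapsed paralog: reads from two loci pile up on one
            het = rng.random(n_samp) < config.decoy_het_prob
            hom_alt = rng.random(n_samp) < 0.5
            g = np.where(het[:, None], np.array([[0, 1]]),
                         np.where(hom_alt[:, None], 1, 0))
            calls[v] = g
        else:
            probs = np.empty((n_samp, 2))
            probs[:n_a] = p_a
            probs[n_a:n_a + n_b] = p_b
            anc = rng.random((config.n_admixed, 2)) < alpha
            probs[n_a + n_b:] = np.where(anc, p_a, p_b)
            calls[v] = (rng.random((n_samp, 2)) < probs).astype(np.int8)
        mean_dp = config.mean_depth * (config.decoy_depth_factor
                                       if kind == "decoy" else 1.0)
        dp[v] = rng.poisson(mean_dp, size=n_samp)
        gq[v] = rng.integers(*config.gq_range, size=n_samp)
        ref = genome[contig].seq[pos]
        alt = str(rng.choice(bases[bases != ref]))
        contigs_arr.append(contig)
        positions.append(pos)
        refs.append(ref)
        alts.append((alt,))

    missing = rng.random((n_var, n_samp)) < config.missing_rate
    calls[missing] = -1

    return GenotypeMatrix(
        contigs=np.array(contigs_arr, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        calls=calls,
        dp=dp,
        gq=gq,
        phased=np.ones((n_var, n_samp), dtype=bool),
        samples=samples,
        info={},
        subpops=np.array(labels, dtype=object),
    )


# ---------------------------------------------------------------------------
# Annotated VCF with spiked hard-filter violations
# ---------------------------------------------------------------------------

def simulate_annotated_vcf(matrix: GenotypeMatrix, config: SimulationConfig,
                           path) -> pd.DataFrame:
    """Attach QD/FS/ReadPosRankSum annotations, spike violations, write VCF.

    A disjoint random fraction of records is spiked to violate each hard
    filter (QD <= 5, FS >= 60, ReadPosRankSum <= -8).  Returns the truth
    table (one row per record, boolean violation columns) so the site
    filter can be checked for confusion-free behaviour.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = matrix.n_variants
    qd = rng.uniform(8.0, 25.0, size=n)
    fs = rng.uniform(0.0, 20.0, size=n)
    rprs = rng.normal(0.0, 1.0, size=n).clip(-6.0, 6.0)

    order = rng.permutation(n)
    n_qd = int(round(config.spike_qd * n))
    n_fs = int(round(config.spike_fs * n))
    n_rprs = int(round(config.spike_rprs * n))
    qd_idx = order[:n_qd]
    fs_idx = order[n_qd:n_qd + n_fs]
    rprs_idx = order[n_qd + n_fs:n_qd + n_fs + n_rprs]
    qd[qd_idx] = rng.uniform(0.5, 4.9, size=n_qd)
    fs[fs_idx] = rng.uniform(61.0, 120.0, size=n_fs)
    rprs[rprs_idx] = rng.uniform(-12.0, -8.5, size=n_rprs)

    matrix.info["QD"] = qd
    matrix.info["FS"] = fs
    matrix.info["ReadPosRankSum"] = rprs
    write_vcf(matrix, path, contig_lengths=config.contig_lengths)

    truth = pd.DataFrame({
        "contig": matrix.contigs, "position": matrix.positions,
        "violates_qd": np.zeros(n, dtype=bool),
        "violates_fs": np.zeros(n, dtype=bool),
        "violates_rprs": np.zeros(n, dtype=bool),
    })
    truth.loc[qd_idx, "violates_qd"] = True
    truth.loc[fs_idx, "violates_fs"] = True
    truth.loc[rprs_idx, "violates_rprs"] = True
    return truth


# ---------------------------------------------------------------------------
# Read tables
# ---------------------------------------------------------------------------

def simulate_read_table(panel, config: SimulationConfig,
                        decoy_locus_ids=(), bias=None, rng_seed=None):
    """Reads multinomially distributed over panel loci with primer biases.

    Per-locus expected share is proportional to balancing factor times a
    log-normal amplification bias.  Reads on decoy-duplicated loci are
    flagged multimap with probability ``multimap_prob``.  A fixed ``bias``
    vector may be supplied to emulate repeated sequencing runs of the same
    primer pool.  Returns (alignment DataFrame, per-locus counted reads,
    true per-locus totals).
    """
    rng = np.random.default_rng(config.seed + 3 if rng_seed is None else rng_seed)
    loci = list(panel)
    factors = np.array([l.balancing_factor for l in loci], dtype=float)
    if bias is None:
        bias = np.exp(rng.normal(0.0, config.bias_log_sd, size=len(loci)))
    shares = factors * bias
    shares = shares / shares.sum()
    totals = rng.multinomial(config.read_total, shares)

    decoy_set = set(decoy_locus_ids)
    rows = []
    counted = {}
    rid = 0
    for l, n_reads in zip(loci, totals):
        is_decoy = l.locus_id in decoy_set
        mm = (rng.random(n_reads) < config.multimap_prob) if is_decoy \
            else np.zeros(n_reads, dtype=bool)
        end = min(l.start + config.read_length, l.end)
        for j in range(n_reads):
            rows.append((f"r{rid:07d}", l.contig, l.start, end, int(mm[j])))
            rid += 1
        counted[l.locus_id] = int(n_reads - mm.sum())
    table = pd.DataFrame(rows, columns=["read_id", "contig", "start", "end",
                                        "multimap"])
    return table, pd.Series(counted, name="reads"), pd.Series(
        dict(zip([l.locus_id for l in loci], totals.tolist())), name="total_reads")


# ---------------------------------------------------------------------------
# Genetic map for the synthetic genome
# ---------------------------------------------------------------------------

def simulate_genetic_map(config: SimulationConfig, cm_per_mb: float = 50.0):
    """Linear genetic map over the synthetic contigs (anchors every 20 kb)."""
    from .io import GeneticMap

    anchors = {}
    for contig, length in config.contig_lengths.items():
        bps = list(range(0, length + 1, 20_000))
        if bps[-1] != length:
            bps.append(length)
        anchors[contig] = [(bp, bp / 1e6 * cm_per_mb) for bp in bps]
    return GeneticMap(anchors)
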