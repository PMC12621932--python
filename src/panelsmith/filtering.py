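"""Post-calling variant and sample filters.

Two profiles mirror the two data regimes the panel serves: deep amplicon
sequencing (GQ >= 30, DP >= 10, 10% sample-missingness ceiling) and
heterogeneous-depth WGS (GQ > 20, DP >= 5, 50% sample ceiling, plus
kinship-based pruning of near-duplicate samples).  Site-level hard
filters (QD > 5, FS < 60, ReadPosRankSum > -8) and the 10% variant
missingness ceiling are shared.  An absent site annotation never fails a
record (pass-by-absence): the annotation source leaves e.g.
ReadPosRankSum undefined at sites without heterozygous calls, and those
are valid sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix
from .popgen import kinship_table


@dataclass
class FilterProfile:
    mode: str = "amplicon"            # "amplicon" | "wgs"
    qd_floor: float = 5.0
    fs_ceiling: float = 60.0
    rprs_floor: float = -8.0
    gq_floor: float = 30.0
    gq_inclusive: bool = True         # amplicon: GQ >= 30; wgs: GQ > 20
    dp_floor: float = 10.0
    variant_missing_ceiling: float = 0.10
    sample_missing_ceiling: float = 0.10
    pi_hat_ceiling: float = 0.75

    @classmethod
    def amplicon(cls) -> "FilterProfile":
        return cls(mode="amplicon", gq_floor=30.0, gq_inclusive=True,
                   dp_floor=10.0, sample_missing_ceiling=0.10)

    @classmethod
    def wgs(cls) -> "FilterProfile":
        return cls(mode="wgs", gq_floor=20.0, gq_inclusive=False,
                   dp_floor=5.0, sample_missing_ceiling=0.50)


@dataclass
class FilterReport:
    stages: list = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_kept: int, removed_reasons: dict,
            notes: dict | None = None):
        if n_in != n_kept + sum(removed_reasons.values()):
            raise ValueError(f"stage {stage}: counts do not telescope")
        self.stages.append({
            "stage": stage, "input": n_in, "retained": n_kept,
            "removed": dict(removed_reasons), "notes": dict(notes or {}),
        })

    def stage(self, name: str) -> dict:
        for s in self.stages:
            if s["stage"] == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Site-level hard filter
# ---------------------------------------------------------------------------

def site_hard_filter(matrix: GenotypeMatrix, profile: FilterProfile | None = None,
                     report: FilterReport | None = None):
    """Keep SNP records with QD > 5, FS < 60 and ReadPosRankSum > -8.

    Non-SNP records (any allele longer than 1 bp) are removed.  A record
    whose annotation is absent passes that rule (pass-by-absence) and is
    counted in the report notes.
    """
    profile = profile or FilterProfile.amplicon()
    report = report if report is not None else FilterReport()
    n = matrix.n_variants
    is_snp = matrix.is_snp()
    qd = matrix.info.get("QD", np.full(n, np.nan))
    fs = matrix.info.get("FS", np.full(n, np.nan))
    rprs = matrix.info.get("ReadPosRankSum", np.full(n, np.nan))

    fail_qd = ~np.isnan(qd) & ~(qd > profile.qd_floor)
    fail_fs = ~np.isnan(fs) & ~(fs < profile.fs_ceiling)
    fail_rprs = ~np.isnan(rprs) & ~(rprs > profile.rprs_floor)
    keep = is_snp & ~fail_qd & ~fail_fs & ~fail_rprs

    removed = {
        "not_snp": int((~is_snp).sum()),
        "qd": int((fail_qd & is_snp).sum()),
        "fs": int((fail_fs & is_snp & ~fail_qd).sum()),
        "read_pos_rank_sum": int((fail_rprs & is_snp & ~fail_qd & ~fail_fs).sum()),
    }
    pass_by_absence = int((keep & (np.isnan(qd) | np.isnan(fs) | np.isnan(rprs))).sum())
    report.add("site_hard_filter", n, int(keep.sum()), removed,
               notes={"pass_by_absence": pass_by_absence})
    return matrix.take_variants(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Genotype-level mask
# ---------------------------------------------------------------------------

def genotype_mask(matrix: GenotypeMatrix, profile: FilterProfile | None = None,
                  report: FilterReport | None = None):
    """Set sub-threshold genotype calls to missing; records are never removed.

    Amplicon mode masks GQ < 30 or DP < 10 (inclusive floors as printed);
    WGS mode masks GQ <= 20 or DP < 5 (the GQ bound is strict there).
    """
    profile = profile or FilterProfile.amplicon()
    report = report if report is not None else FilterReport()
    if profile.gq_inclusive:
        bad_gq = matrix.gq < profile.gq_floor
    else:
        bad_gq = matrix.gq <= profile.gq_floor
    bad = bad_gq | (matrix.dp < profile.dp_floor)
    already = matrix.missing_mask()
    to_mask = bad & ~already

    calls = matrix.calls.copy()
    calls[to_mask] = MISSING
    out = GenotypeMatrix(
        contigs=matrix.contigs, positions=matrix.positions, ref=matrix.ref,
        alt=matrix.alt, calls=calls, dp=matrix.dp, gq=matrix.gq,
        phased=matrix.phased, samples=matrix.samples, info=matrix.info,
        subpops=matrix.subpops,
    )
    n_calls = matrix.n_variants * matrix.n_samples
    report.add("genotype_mask", n_calls,
               n_calls - int(to_mask.sum()),
               {"low_gq_or_dp": int(to_mask.sum())},
               notes={"already_missing": int(already.sum())})
    return out, report


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def missingness_filter(matrix: GenotypeMatrix, profile: FilterProfile | None = None,
                       report: FilterReport | None = None):
    """Drop high-missingness variants, then high-missingness samples.

    Single pass: variant missingness is computed over all samples, samples
    are then judged on the retained variants only.  No iteration.
    """
    profile = profile or FilterProfile.amplicon()
    report = report if report is not None else FilterReport()
    miss = matrix.missing_mask()
    n_var, n_samp = miss.shape

    var_frac = miss.mean(axis=1) if n_samp else np.zeros(n_var)
    keep_var = var_frac <= profile.variant_missing_ceiling
    out = matrix.take_variants(np.flatnonzero(keep_var))
    report.add("variant_missingness", n_var, int(keep_var.sum()),
               {"missingness": int((~keep_var).sum())})

    miss2 = out.missing_mask()
    samp_frac = miss2.mean(axis=0) if out.n_variants else np.zeros(n_samp)
    keep_samp = samp_frac <= profile.sample_missing_ceiling
    out = out.take_samples(np.flatnonzero(keep_samp))
    report.add("sample_missingness", n_samp, int(keep_samp.sum()),
               {"missingness": int((~keep_samp).sum())})
    return out, report


# ---------------------------------------------------------------------------
# Kinship pruning
# ---------------------------------------------------------------------------

def kinship_prune(matrix: GenotypeMatrix, pi_hat_ceiling: float = 0.75,
                  min_sites: int = 200, keep_related: bool = False,
                  report: FilterReport | None = None):
    """Greedy pruning of sample pairs sharing too much of the genome IBD.

    Pairs with PI_HAT above the ceiling form graph edges; the
    highest-degree sample is removed repeatedly until no edge remains
    (ties: more missing data first, then the lexicographically later id).
    ``keep_related`` inverts the rule and retains only flagged samples.
    Pairs with too few informative sites contribute no edge and are
    counted in the report.
    """
    report = report if report is not None else FilterReport()
    table = kinship_table(matrix, min_sites=min_sites)
    null_pairs = int(table["PI_HAT"].isna().sum())
    edges = set()
    for _, row in table.iterrows():
        if not np.isnan(row["PI_HAT"]) and row["PI_HAT"] > pi_hat_ceiling:
            edges.add((row["sample_a"], row["sample_b"]))

    miss = matrix.missing_mask().mean(axis=0)
    missing_by = dict(zip(matrix.samples, miss))
    removed = []
    active = set(edges)
    while active:
        degree: dict = {}
        for a, b in active:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        victim = max(degree,
                     key=lambda s: (degree[s], missing_by.get(s, 0.0), s))
        removed.append(victim)
        active = {e for e in active if victim not in e}

    if keep_related:
        related = {s for e in edges for s in e}
        retained = [s for s in matrix.samples if s in related]
        dropped = {"unrelated": matrix.n_samples - len(retained)}
    else:
        retained = [s for s in matrix.samples if s not in removed]
        dropped = {"kinship": len(removed)}
    report.add("kinship_prune", matrix.n_samples, len(retained), dropped,
               notes={"null_pairs": null_pairs,
                      "edges": len(edges)})
    return retained, report


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(matrix: GenotypeMatrix, profile: FilterProfile | None = None,
                prune_kin: bool = False):
    """Site filter -> genotype mask -> missingness (-> kinship in WGS use).

    Returns (filtered matrix, report).  The report notes whether the
    output is a missingness fixed point (re-running would change nothing).
    """
    profile = profile or FilterProfile.amplicon()
    report = FilterReport()
    out, _ = site_hard_filter(matrix, profile, report)
    out, _ = genotype_mask(out, profile, report)
    out, _ = missingness_filter(out, profile, report)
    if prune_kin and out.n_samples >= 2:
        retained, _ = kinship_prune(out, profile.pi_hat_ceiling, report=report)
        idx = [out.samples.index(s) for s in retained]
        out = out.take_samples(np.array(idx, dtype=int))

    if out.n_variants and out.n_samples:
        miss = out.missing_mask()
        fixed = (miss.mean(axis=1) <= profile.variant_missing_ceiling).all() and \
                (miss.mean(axis=0) <= profile.sample_missing_ceiling).all()
    else:
        fixed = True
    report.stages.append({"stage": "fixed_point", "input": out.n_variants,
                          "retained": out.n_variants, "removed": {},
                          "notes": {"at_fixed_point": bool(fixed)}})
    return out, report
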