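"""Run the post-calling filter cascade on an annotated synthetic VCF.

The simulator spikes a known fraction of records with hard-filter
violations (QD <= 5, FS >= 60, ReadPosRankSum <= -8); the cascade should
remove exactly those, then mask low-quality genotypes and drop
high-missingness variants and samples.
"""

import tempfile
from pathlib import Path

from panelsmith import filtering, io, simulate

cfg = simulate.SimulationConfig(seed=1)
genome, truth = simulate.simulate_reference(cfg)
matrix = simulate.simulate_population(cfg, truth, genome)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "annotated.vcf"
    spike_truth = simulate.simulate_annotated_vcf(matrix, cfg, vcf)
    loaded = io.read_vcf(vcf)

n_spiked = int((spike_truth[["violates_qd", "violates_fs",
                             "violates_rprs"]].any(axis=1)).sum())
print(f"{loaded.n_variants} records, {n_spiked} spiked with hard-filter "
      "violations")

filtered, report = filtering.run_cascade(loaded,
                                         filtering.FilterProfile.amplicon())
for stage in report.stages:
    print(f"  {stage['stage']:20s} in={stage['input']:<6d} "
          f"kept={stage['retained']:<6d} removed={stage['removed']}")
print(f"final matrix: {filtered.n_variants} variants x "
      f"{filtered.n_samples} samples")
# The site stage should remove exactly the spiked records; the genotype
# and missingness stages remove nothing here because the simulator draws
# high-quality deep genotypes by default.
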