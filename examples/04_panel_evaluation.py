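"""Evaluate a sequenced panel: balance, rarefaction, microhaplotypes.

Simulates a read table with primer-specific amplification biases,
measures coverage uniformity, derives balancing factors, and asks how
deep one must sequence for amplicons to be genotyped at >= 10 reads.
"""

from panelsmith import evaluate, regions, selection, simulate

cfg = simulate.SimulationConfig(seed=1)
genome, truth = simulate.simulate_reference(cfg)
matrix = simulate.simulate_population(cfg, truth, genome)
gmap = simulate.simulate_genetic_map(cfg)
passing = [c for c in regions.find_regions(matrix, cfg.contig_lengths,
                                           repeat_mask=truth.tes,
                                           subpops=cfg.subpop_labels,
                                           gmap=gmap) if c.passes]
panel = selection.attach_primers(selection.choose_final_set(
    selection.gap_fill_select(passing, gmap, m=30, n_sets=10, seed=1),
    passing, final_m=25), genome, seed=1)

table, counted, totals = simulate.simulate_read_table(panel, cfg)
assignment = evaluate.assign_reads(table, panel)
unif = evaluate.coverage_uniformity(assignment.counts.to_numpy())
print(f"{assignment.tallies['assigned']} reads assigned; most abundant "
      f"amplicon holds {100 * unif['top_share']:.1f}% of reads "
      f"(Gini {unif['gini']:.2f})")

factors = evaluate.balancing_factors(totals.to_numpy())
print(f"balancing factors span {factors.min():.2f}-{factors.max():.2f}; "
      "diluting each primer by its factor flattens the pool")

total = int(assignment.counts.sum())
curve = evaluate.rarefaction(assignment.counts.to_numpy(),
                             depths=[250, 500, 2000, total],
                             threshold=10, replicates=100, seed=1)
for d, m in zip(curve.depths, curve.mean):
    print(f"  at {d:>7d} reads: {100 * m:5.1f}% of amplicons genotyped "
          "(>=10 reads)")

haps = evaluate.extract_microhaplotypes(matrix, panel)
ok = haps["hap1"].notna()
print(f"microhaplotypes extracted for {ok.mean() * 100:.1f}% of "
      "sample-locus pairs (phased, fully called loci)")
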