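"""Design an amplicon panel on a synthetic genome, end to end.

Simulates a two-chromosome genome with planted high-diversity cores,
scans windowed nucleotide diversity for flanked candidate regions, runs
the repeat/CNV/selection filter cascade, and picks a gap-filled panel
over the genetic map.
"""

from panelsmith import evaluate, regions, selection, simulate

cfg = simulate.SimulationConfig(seed=1)
genome, truth = simulate.simulate_reference(cfg)
matrix = simulate.simulate_population(cfg, truth, genome)
gmap = simulate.simulate_genetic_map(cfg)

candidates = regions.find_regions(matrix, cfg.contig_lengths,
                                  repeat_mask=truth.tes,
                                  subpops=cfg.subpop_labels, gmap=gmap)
passing = [c for c in candidates if c.passes]
print(f"{len(candidates)} candidate regions scanned, "
      f"{len(passing)} pass all filters "
      f"({len(truth.true_cores)} neutral cores were planted)")

run = selection.gap_fill_select(passing, gmap, m=30, n_sets=10, seed=1)
panel = selection.choose_final_set(run, passing, final_m=25)
panel = selection.attach_primers(panel, genome, seed=1)

spacing = selection.spacing_stats(panel.loci)
sizes = evaluate.amplicon_size_stats(panel)
print(f"final panel: {len(panel)} loci, median marker gap "
      f"{spacing['median_gap']:.2f} cM (max {spacing['max_gap']:.2f} cM)")
print(f"amplicons {sizes['amplicon_min']}-{sizes['amplicon_max']} bp "
      f"(median {sizes['amplicon_median']:.0f}), "
      f"{sizes['total_targeted_bp']} bp targeted in total; "
      f"expected library {sizes['library_min']}-{sizes['library_max']} bp "
      "after adapter tails")
# A small median gap means markers sit evenly along the genetic map; the
# library range is what a fragment analyzer should show after indexing.
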