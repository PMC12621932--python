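"""Check primer specificity by in-silico PCR and screen for dimers.

Duplicated-decoy loci planted by the simulator should each yield two
predicted products (the off-target signature); all other loci exactly
one.
"""

from panelsmith import ispcr, selection, simulate

cfg = simulate.SimulationConfig(seed=1)
genome, truth = simulate.simulate_reference(cfg)

decoys = [truth.cores[i] for i in truth.decoy_index]
panel = selection.attach_primers(selection.Panel(
    [selection.PanelLocus(locus_id=f"decoy{i}", contig=c, start=s, end=e,
                          core_start=s, core_end=e, cm=None, snp_count=0)
     for i, (c, s, e) in enumerate(decoys)]
    + [selection.PanelLocus(locus_id=f"unique{i}", contig=c, start=s, end=e,
                            core_start=s, core_end=e, cm=None, snp_count=0)
       for i, (c, s, e) in enumerate(truth.true_cores[:10])]),
    genome, seed=1)

census = ispcr.flag_off_targets(panel, genome, mismatch_fraction=0.05,
                                max_product=300)
print(census.drop(columns="products").to_string(index=False))
n_off = int(census["off_target"].sum())
print(f"\n{n_off} of {len(census)} primer pairs map to more than one locus "
      "at 5% mismatch within 300 bp — these would be flagged as putative "
      "off-target loci and their multi-mapping reads excluded downstream.")

pool = [(f"{l.locus_id}/F", l.fwd_seq) for l in panel] + \
       [(f"{l.locus_id}/R", l.rev_seq) for l in panel]
dimers = selection.dimer_screen(pool)
print(f"dimer screen: {len(dimers)} primer pairs flagged by the "
      "3'-complementarity heuristic")
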