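import numpy as np
import pytest

from panelsmith import regions, selection, simulate


@pytest.fixture(scope="session")
def sim_bundle():
    """Default synthetic study conditions: genome, truth and genotypes."""
    cfg = simulate.SimulationConfig(seed=1)
    genome, truth = simulate.simulate_reference(cfg)
    matrix = simulate.simulate_population(cfg, truth, genome)
    return cfg, genome, truth, matrix


@pytest.fixture(scope="session")
def sim_candidates(sim_bundle):
    cfg, genome, truth, matrix = sim_bundle
    gmap = simulate.simulate_genetic_map(cfg)
    cands = regions.find_regions(matrix, cfg.contig_lengths,
                                 repeat_mask=truth.tes,
                                 subpops=cfg.subpop_labels, gmap=gmap)
    return cands


@pytest.fixture(scope="session")
def sim_panel(sim_bundle, sim_candidates):
    """A primer panel built from the passing candidates of the default sim."""
    cfg, genome, truth, matrix = sim_bundle
    passing = [c for c in sim_candidates if c.passes]
    panel = selection.Panel([selection.PanelLocus(
        locus_id=c.region_id, contig=c.contig, start=c.flank_left[0],
        end=c.flank_right[1], core_start=c.core_start, core_end=c.core_end,
        cm=c.cm, snp_count=c.snp_count,
    ) for c in passing])
    return selection.attach_primers(panel, genome, seed=cfg.seed)


def overlaps(cand, key) -> bool:
    contig, start, end = key
    return (cand.contig == contig and cand.core_start < end
            and cand.core_end > start)
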