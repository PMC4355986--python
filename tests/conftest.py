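import numpy as np
import pytest

import methclust as mc
from methclust import dmr as dmr_mod


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition synthetic study (20 tumor / 10 normal,
    200 windows, 30 planted 3x hyper regions), reads included."""
    return mc.simulate_cohort(mc.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_tracks(default_cohort):
    cohort = default_cohort
    return {
        sid: mc.quantify_sample(reads, cohort.annotation.chrom_lengths, sample_id=sid)
        for sid, reads in cohort.reads.items()
    }


@pytest.fixture(scope="session")
def default_dmr_records(default_cohort, default_tracks):
    cohort, tracks = default_cohort, default_tracks
    tumor = [tracks[s.sample_id] for s in cohort.samples if s.group == "tumor"]
    normal = [tracks[s.sample_id] for s in cohort.samples if s.group == "normal"]
    regions = dmr_mod.classify_regions(cohort.annotation.genes, cohort.annotation.cgis)
    records = dmr_mod.call_dmrs(regions, tumor, normal, cohort.annotation.chrom_lengths)
    return regions, records


@pytest.fixture
def tiny_sim_config():
    """A minimal, fast cohort for pipeline and file round-trip tests."""
    return dict(
        seed=11, n_genes=12, n_clusters=2, genes_per_cluster=4,
        n_intragenic_cgis=4, n_intergenic_cgis=4, background_slots=10,
        n_tumor=8, n_normal=4, baseline_bin_rate=0.5,
    )
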