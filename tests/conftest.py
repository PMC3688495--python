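import numpy as np
import pytest

from bgckit.genome_model import GeneModel, GenomeAnnotation
from bgckit.simulate import SimConfig, demo_dataset, simulate_counts, simulate_scenario


@pytest.fixture(scope="session")
def demo():
    """Reference-layout genome with simulated counts (42-gene locus +
    background scaffold)."""
    ann, cm, truth, cfg = demo_dataset(seed=11)
    return ann, cm, truth, cfg


@pytest.fixture(scope="session")
def study():
    """Default synthetic study with all four comparator scenarios."""
    cfg = SimConfig(seed=5)
    s = simulate_scenario(
        cfg, ["lineage_specific", "conserved_cluster", "inversion", "hgt_candidate"]
    )
    return cfg, s


@pytest.fixture(scope="session")
def study_counts(study):
    cfg, s = study
    cm, samples = simulate_counts(cfg, s.focal, s.truth)
    return cm


@pytest.fixture
def toy_annotation():
    """Five genes on one scaffold plus one on another, hand-placed."""
    genes = [
        GeneModel("g1", "sc1", 100, 200, "+", "housekeeping"),
        GeneModel("g2", "sc1", 300, 400, "-", "tailoring"),
        GeneModel("g3", "sc1", 500, 900, "+", "backbone_nrps"),
        GeneModel("g4", "sc1", 1000, 1200, "+", "racemase"),
        GeneModel("g5", "sc1", 1500, 1600, "+", "housekeeping"),
        GeneModel("h1", "sc2", 50, 80, "+", "housekeeping"),
    ]
    return GenomeAnnotation(genome_id="toy", genes=genes)
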