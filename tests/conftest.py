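import pytest

from licapc.classify import ClassifiedRead, Slice, classify_reads, default_exclusion
from licapc.sim3c import SimConfig, simulate_library
from licapc.toydata import toy_locus


@pytest.fixture(scope="session")
def locus():
    """Shared sparse two-chromosome locus: (genome, fragment map, viewpoint id)."""
    return toy_locus(cis_bp=200_000, trans_bp=100_000, vp_fragment_bp=2000, seed=11)


@pytest.fixture(scope="session")
def sim_library(locus):
    """Simulated library on the shared locus with duplicates and wobble."""
    genome, fmap, vp = locus
    config = SimConfig(
        viewpoint_ids=(vp,),
        trans_fraction=0.2,
        n_molecules=3000,
        dup_rate=1.0,
        wobble_prob=0.1,
        seed=7,
    )
    reads, truth = simulate_library(config, fmap, genome)
    return config, reads, truth


@pytest.fixture(scope="session")
def classified_library(locus, sim_library):
    """Classified reads of the shared simulated library."""
    genome, fmap, vp = locus
    config, reads, truth = sim_library
    targets = {"vp": {vp}}
    exclusion = default_exclusion(fmap, targets, config.exclusion_bp)
    classified, n_dropped = classify_reads(reads, targets, exclusion, fmap)
    assert n_dropped == 0
    return classified


def make_read(read_id, slices, viewpoint="vp", reporters=None, status="informative"):
    """Minimal informative ClassifiedRead for dedup/profile unit tests."""
    sl = [Slice(c, s, e, "+", fid) for (c, s, e, fid) in slices]
    if reporters is None:
        reporters = tuple(s.fragment_id for s in sl[1:])
    return ClassifiedRead(
        read_id=read_id,
        slices=sl,
        viewpoint=viewpoint,
        n_capture=1,
        reporter_ids=tuple(reporters),
        n_excluded=0,
        status=status,
        capture_ids=(sl[0].fragment_id,),
    )
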