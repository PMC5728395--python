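"""Simulator: interaction distribution, breakpoint models, PCR duplication,
library-level invariants."""

import numpy as np
import pandas as pd
import pytest

from licapc.restriction_map import digest_reference
from licapc.sim3c import (
    SimConfig,
    apply_pcr_duplication,
    build_interaction_distribution,
    sample_breakpoints,
    simulate_library,
)
from licapc.sim3c import _Molecule
from licapc.toydata import toy_locus


def two_cis_fragment_map():
    """chr1 with fragments at controlled spacing: viewpoint plus cis
    fragments at distances d and 2d from the viewpoint midpoint."""
    # fragments of 100 bp each: GATC every 100 bp
    seq = ("GATC" + "A" * 96) * 8
    return digest_reference({"chr1": seq})


class TestInteractionDistribution:
    def test_trans_zero_when_t_zero(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(viewpoint_ids=(vp,), trans_fraction=0.0, seed=0)
        probs = build_interaction_distribution(fmap, config)
        trans_ids = fmap.fragment_ids("chr2")
        assert np.all(probs[trans_ids] == 0)
        assert probs.sum() == pytest.approx(1.0)

    def test_small_alpha_limit_is_uniform(self):
        fmap = two_cis_fragment_map()
        config = SimConfig(
            viewpoint_ids=(0,), alpha=1e-9, trans_fraction=0.0, exclusion_bp=0, seed=0
        )
        probs = build_interaction_distribution(fmap, config)
        allowed = probs[probs > 0]
        assert np.allclose(allowed, allowed[0])

    def test_inverse_distance_ratio(self):
        # fragments at distance d and 2d, alpha=1 -> probabilities 2:1
        fmap = two_cis_fragment_map()
        config = SimConfig(
            viewpoint_ids=(0,), alpha=1.0, trans_fraction=0.0, exclusion_bp=0, seed=0
        )
        probs = build_interaction_distribution(fmap, config)
        # fragment 1 is 100 bp from the viewpoint midpoint, fragment 2 is 200
        assert probs[1] / probs[2] == pytest.approx(2.0)

    def test_viewpoint_and_exclusion_zone_zeroed(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(viewpoint_ids=(vp,), exclusion_bp=1000, seed=0)
        probs = build_interaction_distribution(fmap, config)
        assert probs[vp] == 0
        vp_frag = fmap.fragment(vp)
        for f in fmap.fragments(vp_frag.chrom):
            if f.start < vp_frag.end + 1000 and f.end > vp_frag.start - 1000:
                assert probs[f.id] == 0

    def test_peak_weights_multiply(self):
        fmap = two_cis_fragment_map()
        base = SimConfig(
            viewpoint_ids=(0,), alpha=1.0, trans_fraction=0.0, exclusion_bp=0, seed=0
        )
        peaked = SimConfig(
            viewpoint_ids=(0,),
            peaks=((3, 9.0),),
            alpha=1.0,
            trans_fraction=0.0,
            exclusion_bp=0,
            seed=0,
        )
        p0 = build_interaction_distribution(fmap, base)
        p1 = build_interaction_distribution(fmap, peaked)
        # unnormalized weight at fragment 3 multiplied by (1 + 9) = 10
        assert (p1[3] / p1[1]) / (p0[3] / p0[1]) == pytest.approx(10.0)

    def test_all_trans_error_without_trans_fragments(self):
        fmap = two_cis_fragment_map()
        config = SimConfig(
            viewpoint_ids=(0,), trans_fraction=1.0, exclusion_bp=0, seed=0
        )
        with pytest.raises(ValueError):
            build_interaction_distribution(fmap, config)


class TestSampleBreakpoints:
    def test_sonication_uniform(self):
        rng = np.random.default_rng(0)
        seq = "ACGT" * 25
        draws = np.array(
            [sample_breakpoints(seq, "sonication", 1.0, rng) for _ in range(20000)]
        )
        freqs = np.bincount(draws, minlength=len(seq))[1:] / len(draws)
        expected = 1.0 / (len(seq) - 1)
        se = np.sqrt(expected * (1 - expected) / len(draws))
        assert np.all(np.abs(freqs - expected) < 4 * se)

    def test_all_gc_sequence_any_weight_is_uniform(self):
        rng = np.random.default_rng(1)
        seq = "G" * 40
        draws = np.array(
            [sample_breakpoints(seq, "tagmentation", 7.0, rng) for _ in range(20000)]
        )
        freqs = np.bincount(draws, minlength=len(seq))[1:] / len(draws)
        expected = 1.0 / (len(seq) - 1)
        se = np.sqrt(expected * (1 - expected) / len(draws))
        assert np.all(np.abs(freqs - expected) < 4 * se)

    def test_tagmentation_matches_closed_form_weights(self):
        rng = np.random.default_rng(2)
        seq = "ATGC" * 10
        w = 3.0
        n = 100_000
        draws = np.array(
            [sample_breakpoints(seq, "tagmentation", w, rng) for _ in range(n)]
        )
        weights = np.array([w if seq[p] in "GC" else 1.0 for p in range(1, len(seq))])
        expected = weights / weights.sum()
        freqs = np.bincount(draws, minlength=len(seq))[1:] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            sample_breakpoints("A", "sonication", 1.0, np.random.default_rng(0))


def _mols(n, spread=1000):
    return [
        _Molecule(
            molecule_id=i,
            slices=[("chr1", 100 + i * spread, 250 + i * spread, "+"),
                    ("chr1", 5000 + i * spread, 5100 + i * spread, "+")],
            reporter_fragment=7,
            is_cis=True,
            umi=("chr1", 100 + i * spread, "chr1", 5100 + i * spread),
        )
        for i in range(n)
    ]


class TestPcrDuplication:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        reads = apply_pcr_duplication(_mols(10), 0.0, 0.5, rng)
        assert len(reads) == 10
        assert not any(r["is_duplicate"] for r in reads)
        assert not any(r["was_wobbled"] for r in reads)

    def test_forced_wobble_shifts_one_umi_by_1_or_2(self):
        rng = np.random.default_rng(3)
        n_checked = 0
        while n_checked < 50:
            reads = apply_pcr_duplication(_mols(1), 2.0, 1.0, rng)
            if len(reads) < 2:
                continue
            orig, dup = reads[0], reads[1]
            assert not orig["was_wobbled"] and dup["was_wobbled"]
            dl = abs(dup["slices"][0][1] - orig["slices"][0][1])
            dr = abs(dup["slices"][-1][2] - orig["slices"][-1][2])
            assert (dl, dr) in {(1, 0), (2, 0), (0, 1), (0, 2)}
            n_checked += 1

    def test_geometric_mean_duplication(self):
        rng = np.random.default_rng(4)
        rho = 1.5
        reads = apply_pcr_duplication(_mols(10_000), rho, 0.0, rng)
        mean = len(reads) / 10_000
        # reads per molecule = 1 + G, mean 1 + rho, var rho(1+rho)
        se = np.sqrt(rho * (1 + rho) / 10_000)
        assert abs(mean - (1 + rho)) < 3 * se


class TestSimulateLibrary:
    def test_no_duplication_yields_n_reads(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(
            viewpoint_ids=(vp,), n_molecules=500, dup_rate=0.0, wobble_prob=0.0, seed=5
        )
        reads, truth = simulate_library(config, fmap, genome)
        assert len(truth) + truth.attrs["n_skipped"] == 500
        assert not truth["is_duplicate"].any()
        assert not truth["was_wobbled"].any()

    def test_no_wobble_means_identical_umis_within_molecule(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(
            viewpoint_ids=(vp,), n_molecules=300, dup_rate=2.0, wobble_prob=0.0, seed=6
        )
        reads, truth = simulate_library(config, fmap, genome)
        firsts = reads[reads.slice_index == 0].set_index("read_id")
        lasts = reads[reads.slice_index == 1].set_index("read_id")
        observed = pd.DataFrame(
            {"l": firsts["start"], "r": lasts["end"], "mol": truth.set_index("read_id")["molecule_id"]}
        )
        assert (observed.groupby("mol")[["l", "r"]].nunique() == 1).all().all()

    def test_determinism(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(viewpoint_ids=(vp,), n_molecules=400, dup_rate=1.0, seed=9)
        r1, t1 = simulate_library(config, fmap, genome)
        r2, t2 = simulate_library(config, fmap, genome)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_truth_and_read_records_conserved(self, sim_library):
        config, reads, truth = sim_library
        assert set(reads["read_id"]) == set(truth["read_id"])
        assert len(truth) == reads["read_id"].nunique()

    def test_reporter_frequencies_match_distribution(self):
        """Empirical reporter frequencies vs the true distribution: total
        variation distance < 0.02 at n = 5e4 on a ~100-fragment locus, and
        indistinguishable from an independent multinomial draw at the same
        n (the TVD floor is multinomial sampling noise)."""
        n = 50_000
        genome, fmap, vp = toy_locus(
            cis_bp=20_000, trans_bp=6_000, vp_fragment_bp=1500, seed=11
        )
        config = SimConfig(
            viewpoint_ids=(vp,), trans_fraction=0.1, n_molecules=n, seed=12
        )
        reads, truth = simulate_library(config, fmap, genome)
        probs = build_interaction_distribution(fmap, config)
        emp = np.bincount(truth["reporter_fragment"], minlength=fmap.n_fragments)
        emp = emp / emp.sum()
        tvd = 0.5 * np.abs(emp - probs).sum()
        assert tvd < 0.02
        oracle = np.random.default_rng(99)
        oracle_tvd = np.mean(
            [
                0.5 * np.abs(oracle.multinomial(n, probs) / n - probs).sum()
                for _ in range(5)
            ]
        )
        assert tvd < 2 * oracle_tvd

    def test_cis_fraction_of_molecules_converges(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(
            viewpoint_ids=(vp,), trans_fraction=0.3, n_molecules=20_000, seed=13
        )
        reads, truth = simulate_library(config, fmap, genome)
        mols = truth.drop_duplicates("molecule_id")
        assert mols["is_cis"].mean() == pytest.approx(0.7, abs=3 * np.sqrt(0.21 / len(mols)))

    def test_tagmentation_requires_genome(self, locus):
        genome, fmap, vp = locus
        config = SimConfig(
            viewpoint_ids=(vp,), breakpoint_model="tagmentation", gc_weight=5.0, seed=1
        )
        with pytest.raises(ValueError):
            simulate_library(config, fmap, None)


class TestSimConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"trans_fraction": 1.5},
            {"n_molecules": 0},
            {"dup_rate": -1.0},
            {"wobble_prob": 2.0},
            {"breakpoint_model": "laser"},
            {"gc_weight": 0.5},
            {"peaks": ((1, -2.0),)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(viewpoint_ids=(0,), **kwargs)
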