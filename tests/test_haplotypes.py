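from __future__ import annotations

import numpy as np
import pytest

from pedassoc.datasets import BLOCK1_HAPLOTYPE_FREQUENCIES, BLOCK1_MARKERS
from pedassoc.genotypes import GenotypeTable, Marker
from pedassoc.haplotypes import (
    POOLED_LABEL,
    HaplotypeError,
    HaplotypeFrequencySet,
    assign_diplotypes,
    em_haplotype_frequencies,
    find_blocks,
    pairwise_ld,
    pool_rare_haplotypes,
)
from pedassoc.simulate import simulate_dataset

from .oracles import em_grid_oracle


def two_marker_table(calls: list[list[int]]) -> GenotypeTable:
    markers = [Marker("m1", "A", "a"), Marker("m2", "B", "b")]
    return GenotypeTable(
        [f"i{k}" for k in range(len(calls))], markers, np.array(calls, dtype=np.int8)
    )


def freq_set(fmap: dict[tuple[int, ...], float], k: int = 2) -> HaplotypeFrequencySet:
    markers = [Marker(f"m{j+1}", "ABCD"[j], "abcd"[j]) for j in range(k)]
    haps = list(fmap)
    return HaplotypeFrequencySet(
        [m.marker_id for m in markers], markers, haps,
        np.array([fmap[h] for h in haps]), 0.0, 0, 100,
    )


class TestEM:
    def test_unambiguous_data_equals_direct_counting(self):
        # all doubly homozygous: no phase ambiguity, convergence in 1 sweep
        gt = two_marker_table([[0, 0], [0, 0], [2, 2], [0, 2]])
        fs = em_haplotype_frequencies(gt, ["m1", "m2"])
        assert fs.n_iterations == 1
        f = dict(zip(fs.haplotypes, fs.frequencies))
        assert f[(0, 0)] == pytest.approx(4 / 8)
        assert f[(1, 1)] == pytest.approx(2 / 8)
        assert f[(0, 1)] == pytest.approx(2 / 8)

    def test_matches_exhaustive_grid_oracle(self):
        # 2 x AABB, 1 x AaBb, 1 x aabb
        gt = two_marker_table([[0, 0], [0, 0], [1, 1], [2, 2]])
        fs = em_haplotype_frequencies(gt, ["m1", "m2"])
        oracle = em_grid_oracle({(0, 0): 2, (1, 1): 1, (2, 2): 1})
        f = dict(zip(fs.haplotypes, fs.frequencies))
        est = [f.get(h, 0.0) for h in [(0, 0), (0, 1), (1, 0), (1, 1)]]
        assert np.allclose(est, oracle, atol=2e-3)

    def test_recovers_block1_generating_frequencies(self, unrelated_config):
        """EM on 500 unrelated individuals recovers the generating block-1
        haplotype frequencies within 3 binomial standard errors."""
        ds = simulate_dataset(unrelated_config(500, seed=21))
        fs = em_haplotype_frequencies(ds.genotypes, BLOCK1_MARKERS)
        est = dict(zip(fs.labels, fs.frequencies))
        for hap, truth in BLOCK1_HAPLOTYPE_FREQUENCIES.items():
            se = np.sqrt(truth * (1 - truth) / (2 * fs.n_individuals))
            assert abs(est.get(hap, 0.0) - truth) <= 3 * se, hap

    def test_estimates_consistent_as_n_grows(self, unrelated_config):
        errs = []
        for n, seed in [(100, 1), (500, 2), (2000, 3)]:
            ds = simulate_dataset(unrelated_config(n, seed=seed))
            fs = em_haplotype_frequencies(ds.genotypes, BLOCK1_MARKERS)
            est = dict(zip(fs.labels, fs.frequencies))
            errs.append(
                sum(
                    abs(est.get(h, 0.0) - t)
                    for h, t in BLOCK1_HAPLOTYPE_FREQUENCIES.items()
                )
            )
        assert errs[-1] < errs[0]

    def test_window_size_guard(self, default_dataset):
        with pytest.raises(HaplotypeError):
            em_haplotype_frequencies(default_dataset.genotypes, ["c.-724 A>G"])

    def test_frequencies_sum_to_one(self, default_dataset):
        fs = em_haplotype_frequencies(default_dataset.genotypes, BLOCK1_MARKERS)
        assert fs.frequencies.sum() == pytest.approx(1.0)
        assert (fs.frequencies >= 0).all()


class TestPairwiseLD:
    def test_complete_ld(self):
        ld = pairwise_ld(freq_set({(0, 0): 0.5, (1, 1): 0.5}))
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_independent_markers(self):
        f = {(0, 0): 0.35, (0, 1): 0.35, (1, 0): 0.15, (1, 1): 0.15}
        ld = pairwise_ld(freq_set(f))
        assert ld.D == pytest.approx(0.0, abs=1e-12)
        assert ld.Dprime == pytest.approx(0.0, abs=1e-9)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_equals_dprime_squared_at_balanced_freqs(self):
        f = {(0, 0): 0.35, (0, 1): 0.15, (1, 0): 0.15, (1, 1): 0.35}
        ld = pairwise_ld(freq_set(f))
        assert ld.r2 == pytest.approx(ld.Dprime**2)

    def test_invariant_to_marker_order(self, default_dataset):
        gt = default_dataset.genotypes
        a = pairwise_ld(em_haplotype_frequencies(gt, ["c.-2012 T>C", "c.-2005 A>G"]))
        b = pairwise_ld(em_haplotype_frequencies(gt, ["c.-2005 A>G", "c.-2012 T>C"]))
        assert a.Dprime == pytest.approx(b.Dprime, abs=1e-9)
        assert a.r2 == pytest.approx(b.r2, abs=1e-9)

    def test_monomorphic_flagged(self):
        with pytest.raises(HaplotypeError, match="monomorphic"):
            pairwise_ld(freq_set({(0, 0): 0.6, (0, 1): 0.4}))


class TestPooling:
    def test_published_pooled_mass(self):
        fs = freq_set(
            {(0, 0, 0, 0): 0.348, (0, 0, 0, 1): 0.319, (0, 0, 1, 0): 0.257,
             (0, 0, 1, 1): 0.040, (0, 1, 0, 0): 0.024, (0, 1, 0, 1): 0.012},
            k=4,
        )
        pooled = pool_rare_haplotypes(fs, threshold=0.05)
        assert pooled.frequency_of(POOLED_LABEL) == pytest.approx(0.076)
        assert pooled.frequencies.sum() == pytest.approx(1.0)
        assert len(pooled.pooled_members[POOLED_LABEL]) == 3

    def test_identity_when_nothing_rare(self):
        fs = freq_set({(0, 0): 0.6, (1, 1): 0.4})
        pooled = pool_rare_haplotypes(fs, threshold=0.05)
        assert pooled.labels == fs.labels
        np.testing.assert_allclose(pooled.frequencies, fs.frequencies)

    def test_zero_threshold_is_identity(self):
        fs = freq_set({(0, 0): 0.97, (1, 1): 0.03})
        pooled = pool_rare_haplotypes(fs, threshold=0.0)
        assert POOLED_LABEL not in pooled.labels


class TestDiplotypes:
    def test_unambiguous_individuals_have_posterior_one(self):
        gt = two_marker_table([[0, 0], [1, 0], [2, 2]])
        fs = em_haplotype_frequencies(gt, ["m1", "m2"])
        d = assign_diplotypes(gt, fs)
        assert np.allclose(d.posteriors, 1.0)
        assert d.pairs[0] == ("AB", "AB")
        assert d.pairs[1] == ("AB", "aB")

    def test_double_heterozygote_posterior(self):
        fs = freq_set({(0, 0): 0.7, (1, 1): 0.2, (0, 1): 0.05, (1, 0): 0.05})
        gt = two_marker_table([[1, 1]])
        d = assign_diplotypes(gt, fs)
        assert d.pairs[0] == ("AB", "ab")
        expected = (2 * 0.7 * 0.2) / (2 * 0.7 * 0.2 + 2 * 0.05 * 0.05)
        assert d.posteriors[0] == pytest.approx(expected)  # ~0.9825
        assert not d.flagged[0]

    def test_incompatible_individual_flagged_uniform(self):
        fs = freq_set({(0, 0): 0.6, (1, 1): 0.4})  # no Ab / aB haplotypes
        gt = two_marker_table([[0, 2]])  # AAbb needs (0,1) twice
        d = assign_diplotypes(gt, fs)
        assert d.flagged[0]
        assert d.posteriors[0] == pytest.approx(1.0)  # single compatible pair

    def test_pooled_labels_used(self):
        fs = freq_set({(0, 0): 0.5, (1, 1): 0.46, (0, 1): 0.04})
        pooled = pool_rare_haplotypes(fs, 0.05)
        gt = two_marker_table([[0, 1]])  # AABb -> (AB, Ab): Ab is rare
        d = assign_diplotypes(gt, fs, pooled)
        assert d.pairs[0] == ("AB", POOLED_LABEL)


class TestBlocks:
    def test_complete_ld_pair_forms_block(self, unrelated_config):
        cfg = unrelated_config(500, seed=5)
        ds = simulate_dataset(cfg)
        blocks = find_blocks(ds.genotypes, ["c.-1376 G>A", "c.-724 A>G"])
        assert len(blocks) == 1 and len(blocks[0]) == 2

    def test_independent_markers_no_block(self, unrelated_config):
        # markers from different blocks are generated independently
        ds = simulate_dataset(unrelated_config(500, seed=6))
        blocks = find_blocks(ds.genotypes, ["c.-1621 T>G", "c.-1376 G>A"])
        assert blocks == []

    def test_default_panel_splits_into_two_blocks(self, default_dataset):
        blocks = find_blocks(default_dataset.genotypes)
        assert [list(b.markers) for b in blocks] == [
            ["c.-2012 T>C", "c.-2005 A>G", "c.-1762 T>C", "c.-1621 T>G"],
            ["c.-1376 G>A", "c.-724 A>G"],
        ]
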