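from __future__ import annotations

import json

import numpy as np
import pytest
import yaml

from pedassoc.datasets import BLOCK1_HAPLOTYPE_FREQUENCIES, BLOCK1_MARKERS
from pedassoc.genotypes import read_genotypes
from pedassoc.haplotypes import em_haplotype_frequencies, pairwise_ld
from pedassoc.pedigree import build_a_matrix, read_pedigree
from pedassoc.phenotypes import read_phenotypes
from pedassoc.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    write_dataset,
)


class TestPedigreeGeneration:
    def test_default_daughter_design_structure(self, default_dataset):
        ped = default_dataset.pedigree
        daughters = [r for r in ped.records if r.sire != "" and r.dam != ""]
        assert len(daughters) == 506
        assert len({r.sire for r in daughters}) == 8
        dams = [r.dam for r in daughters]
        assert len(set(dams)) == len(dams)  # every dam unique

    def test_single_sire_half_sib_relationship(self):
        cfg = SimulationConfig(n_sires=1, n_daughters=12)
        A = build_a_matrix(simulate_pedigree(cfg))
        cows = [a for a in A.ids if a.startswith("C")]
        sub = A.submatrix(cows)
        off_diag = sub[~np.eye(len(cows), dtype=bool)]
        assert np.allclose(off_diag, 0.25)  # paternal half sibs

    def test_deep_pedigree_adds_grandsires(self):
        cfg = SimulationConfig(n_daughters=40, deep_pedigree=True)
        ped = simulate_pedigree(cfg)
        sires = [r for r in ped.records if r.animal.startswith("S")]
        assert all(s.sire.startswith("G") for s in sires)

    def test_determinism_same_seed_same_pedigree(self):
        p1 = simulate_pedigree(SimulationConfig(seed=9))
        p2 = simulate_pedigree(SimulationConfig(seed=9))
        assert [(r.animal, r.sire, r.dam) for r in p1.records] == [
            (r.animal, r.sire, r.dam) for r in p2.records
        ]


class TestGenotypeGeneration:
    def test_full_determinism_contract(self):
        d1 = simulate_dataset(seed=33)
        d2 = simulate_dataset(seed=33)
        assert np.array_equal(d1.genotypes.calls, d2.genotypes.calls)
        for t in d1.traits:
            np.testing.assert_array_equal(d1.traits[t].ebv, d2.traits[t].ebv)
        assert d1.truth["config_digest"] == d2.truth["config_digest"]

    def test_within_block_haplotypes_come_from_founder_table(self, default_dataset):
        cols = [default_dataset.genotypes.marker_ids.index(m) for m in BLOCK1_MARKERS]
        table = set(BLOCK1_HAPLOTYPE_FREQUENCIES)
        for haps in list(default_dataset.truth["phased_haplotypes"].values())[:50]:
            for h in haps:
                assert "".join(h[c] for c in cols) in table

    def test_monomorphic_configuration_all_calls_identical(self):
        cfg = SimulationConfig(
            n_sires=2,
            n_daughters=20,
            blocks=[(["c.-2012 T>C", "c.-2005 A>G"], {"TA": 1.0}),
                    (["c.-1762 T>C", "c.-1621 T>G", "c.-1376 G>A", "c.-724 A>G"],
                     {"TTGA": 1.0})],
            missing_rate=0.0,
            seed=5,
        )
        ped = simulate_pedigree(cfg)
        gt, _ = simulate_genotypes(cfg, ped)
        assert np.all(gt.calls == 0)

    def test_allele_frequency_unbiased_over_replicates(self):
        """Mean realized T frequency at the first marker tracks the generating
        0.64 over replicates (the daughter design adds sire-drift variance far
        beyond binomial, so the check is on the replicate mean)."""
        freqs = []
        for seed in range(20):
            ds = simulate_dataset(seed=100 + seed)
            col = ds.genotypes.column("c.-2012 T>C")
            ok = col >= 0
            freqs.append(1.0 - col[ok].sum() / (2.0 * ok.sum()))
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.64) <= 3 * se + 0.01

    def test_within_block_ld_exceeds_between_block_ld(self):
        within, between = [], []
        for seed in range(10):
            ds = simulate_dataset(seed=300 + seed)
            gt = ds.genotypes
            w = pairwise_ld(em_haplotype_frequencies(gt, ["c.-2005 A>G", "c.-1621 T>G"]))
            b = pairwise_ld(em_haplotype_frequencies(gt, ["c.-1621 T>G", "c.-724 A>G"]))
            within.append(w.Dprime)
            between.append(b.Dprime)
        assert np.mean(within) > np.mean(between)


class TestPhenotypeGeneration:
    def test_noiseless_limit_exact_class_values(self):
        base = SimulationConfig().to_dict()
        cfg = SimulationConfig.from_dict(
            {**base,
             "sigma2_a": {t: 0.0 for t in base["sigma2_a"]},
             "sigma2_e": {t: 0.0 for t in base["sigma2_e"]},
             "n_daughters": 60, "daughters_per_sire": None,
             "missing_rate": 0.0, "seed": 4}
        )
        ds = simulate_dataset(cfg)
        tv = ds.traits["PY"]
        labels = ds.genotypes.genotype_labels("c.-724 A>G")
        cv = ds.truth["class_values"]["PY"]
        expected = np.array([cfg.mu["PY"] + cv[labels[a]] for a in tv.animals])
        np.testing.assert_allclose(tv.ebv, expected, atol=1e-12)

    def test_variance_partition_consistent_with_configuration(self):
        """Across replicates, Var(u)/Var(y - class effects) matches
        sigma_a^2 / (sigma_a^2 + sigma_e^2 E[1/rel]) up to the small
        family-covariance correction."""
        lo, hi = SimulationConfig().rel_range
        e_inv_rel = np.log(hi / lo) / (hi - lo)
        s2a = SimulationConfig().sigma2_a["MY"]
        s2e = SimulationConfig().sigma2_e["MY"]
        theory = s2a / (s2a + s2e * e_inv_rel)
        ratios = []
        for seed in range(12):
            ds = simulate_dataset(seed=500 + seed)
            tv = ds.traits["MY"]
            u = np.array([ds.truth["polygenic"]["MY"][a] for a in tv.animals])
            labels = ds.genotypes.genotype_labels("c.-724 A>G")
            cv = ds.truth["class_values"]["MY"]
            g = np.array([cv.get(labels[a], 0.0) for a in tv.animals])
            resid = tv.ebv - g
            ratios.append(np.var(u) / np.var(resid - resid.mean()))
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - theory) <= 3 * se + 0.03


class TestRoundTrip:
    def test_written_files_reproduce_dataset(self, default_dataset, dataset_dir):
        ped = read_pedigree(dataset_dir / "pedigree.csv")
        assert [(r.animal, r.sire, r.dam) for r in ped.records] == [
            (r.animal, r.sire, r.dam) for r in default_dataset.pedigree.records
        ]
        gt = read_genotypes(dataset_dir / "genotypes.csv",
                            markers=default_dataset.genotypes.markers)
        assert np.array_equal(gt.calls, default_dataset.genotypes.calls)
        traits = read_phenotypes(dataset_dir / "phenotypes.csv")
        for t, tv in default_dataset.traits.items():
            np.testing.assert_allclose(traits[t].ebv, tv.ebv)
            np.testing.assert_allclose(traits[t].rel, tv.rel)

    def test_truth_json_has_seed_and_digest(self, default_dataset, dataset_dir):
        truth = json.loads((dataset_dir / "truth.json").read_text())
        assert truth["seed"] == default_dataset.config.seed
        assert truth["config_digest"] == default_dataset.config.digest()

    def test_vcf_consistent_with_csv(self, dataset_dir, default_dataset):
        gt_vcf = read_genotypes(dataset_dir / "genotypes.vcf", format="vcf")
        assert np.array_equal(gt_vcf.calls, default_dataset.genotypes.calls)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_daughters=50, n_sires=5, seed=77)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        cfg2 = SimulationConfig.from_yaml(path)
        assert cfg2.to_dict() == cfg.to_dict()
        assert cfg2.digest() == cfg.digest()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(blocks=[(["c.-2012 T>C", "c.-2005 A>G"], {"TA": 0.9})])
        with pytest.raises(ValueError, match="sum to n_daughters"):
            SimulationConfig(n_daughters=10, daughters_per_sire=[3, 3])
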