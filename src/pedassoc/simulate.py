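"""Synthetic daughter-design datasets with block LD and weighted EBV noise.

The generator emulates the study design the animal model assumes: ~8 paternal
half-sib families of ~506 daughters, founder haplotypes drawn from published
block frequency tables (two blocks, independent by default), Mendelian gene
dropping of whole block haplotypes, and EBV phenotypes built as

    y_i = mu + g(genotype class at the effect locus) + u_i + e_i,
    u ~ N(0, A sigma_a^2),   e_i ~ N(0, sigma_e^2 / rel_i)

so that every pipeline stage (kinship, QC, LD, association, effects) can be
exercised against known truth.  Genotype class values are parameterised as
(+a, d, -a) for (alphabetically first homozygote, heterozygote, other
homozygote), so the configured additive and dominance effects are exactly
what the downstream decomposition should recover.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import datasets
from .genotypes import GenotypeTable, Marker, write_genotypes_csv, write_genotypes_vcf
from .pedigree import Pedigree, PedigreeRecord, RelationshipMatrix, build_a_matrix, write_pedigree
from .phenotypes import TRAITS, TraitVector, write_phenotypes

# Per-trait generator defaults.  Effects (a, d) are the published additive /
# dominance estimates at the default effect locus c.-724 A>G; grand means are
# EBV-scale round numbers; variance components give ratio sigma_a^2/sigma_e^2
# = 1 at field-realistic per-trait EBV spreads.
DEFAULT_EFFECTS: dict[str, tuple[float, float]] = {
    "MY": (255.51, -9.42),
    "FY": (1.90, 2.37),
    "FP": (-0.021, 0.017),
    "PY": (8.03, 1.12),
    "PP": (-0.002, 0.010),
}
DEFAULT_MU: dict[str, float] = {"MY": 300.0, "FY": 6.0, "FP": -0.04, "PY": 11.0, "PP": 0.004}
_SD: dict[str, float] = {"MY": 500.0, "FY": 18.0, "FP": 0.15, "PY": 15.0, "PP": 0.05}
DEFAULT_SIGMA2_A: dict[str, float] = {t: _SD[t] ** 2 / 2.0 for t in TRAITS}
DEFAULT_SIGMA2_E: dict[str, float] = {t: _SD[t] ** 2 / 2.0 for t in TRAITS}


def _default_blocks() -> list[tuple[list[str], dict[str, float]]]:
    return [
        (list(datasets.BLOCK1_MARKERS), dict(datasets.BLOCK1_HAPLOTYPE_FREQUENCIES)),
        (list(datasets.BLOCK2_MARKERS), dict(datasets.BLOCK2_HAPLOTYPE_FREQUENCIES)),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the daughter-design generator (defaults = study design)."""

    n_sires: int = 8
    n_daughters: int = 506
    daughters_per_sire: list[int] | None = None
    markers: list[Marker] = field(default_factory=lambda: list(datasets.PDE9A_MARKERS))
    blocks: list[tuple[list[str], dict[str, float]]] = field(default_factory=_default_blocks)
    inter_block_recombination: float = 0.5
    effect_marker: str = "c.-724 A>G"
    effects: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    mu: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    sigma2_a: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA2_A))
    sigma2_e: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA2_E))
    rel_range: tuple[float, float] = (0.3, 0.9)
    missing_rate: float = 0.01
    deep_pedigree: bool = False
    n_grandsires: int = 4
    seed: int = 1

    def __post_init__(self) -> None:
        if self.daughters_per_sire is None:
            base, extra = divmod(self.n_daughters, self.n_sires)
            self.daughters_per_sire = [
                base + (1 if i < extra else 0) for i in range(self.n_sires)
            ]
        if sum(self.daughters_per_sire) != self.n_daughters:
            raise ValueError("daughters_per_sire must sum to n_daughters")
        for mids, freqs in self.blocks:
            if not np.isclose(sum(freqs.values()), 1.0, atol=1e-9):
                raise ValueError(f"haplotype frequencies of block {mids} must sum to 1")
        for t in self.effects:
            if self.sigma2_a.get(t, 0.0) < 0 or self.sigma2_e.get(t, 0.0) < 0:
                raise ValueError("variance components must be >= 0")

    # -- (de)serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_sires": self.n_sires,
            "n_daughters": self.n_daughters,
            "daughters_per_sire": list(self.daughters_per_sire or []),
            "markers": [
                {"marker_id": m.marker_id, "allele_first": m.allele_first,
                 "allele_second": m.allele_second, "external_id": m.external_id}
                for m in self.markers
            ],
            "blocks": [{"markers": mids, "frequencies": freqs} for mids, freqs in self.blocks],
            "inter_block_recombination": self.inter_block_recombination,
            "effect_marker": self.effect_marker,
            "effects": {t: list(ad) for t, ad in self.effects.items()},
            "mu": dict(self.mu),
            "sigma2_a": dict(self.sigma2_a),
            "sigma2_e": dict(self.sigma2_e),
            "rel_range": list(self.rel_range),
            "missing_rate": self.missing_rate,
            "deep_pedigree": self.deep_pedigree,
            "n_grandsires": self.n_grandsires,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "markers" in d:
            d["markers"] = [Marker(**m) for m in d["markers"]]
        if "blocks" in d:
            d["blocks"] = [(list(b["markers"]), dict(b["frequencies"])) for b in d["blocks"]]
        if "effects" in d:
            d["effects"] = {t: tuple(ad) for t, ad in d["effects"].items()}
        if "rel_range" in d:
            d["rel_range"] = tuple(d["rel_range"])
        if d.get("daughters_per_sire") == []:
            d["daughters_per_sire"] = None
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeTable
    traits: dict[str, TraitVector]
    truth: dict

    @property
    def daughters(self) -> list[str]:
        return self.genotypes.individuals


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stage,)))


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Paternal half-sib families: founder sires, unique founder dams.

    With ``deep_pedigree`` a grandsire layer is added above sires and dams so
    the pedigree spans three generations.
    """
    rng = _rng(cfg, 0)
    sires = [f"S{i + 1:03d}" for i in range(cfg.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(cfg.n_daughters)]
    records: list[PedigreeRecord] = []
    if cfg.deep_pedigree:
        gsires = [f"G{i + 1:03d}" for i in range(cfg.n_grandsires)]
        records += [PedigreeRecord(g) for g in gsires]
        records += [PedigreeRecord(s, rng.choice(gsires), "") for s in sires]
        records += [PedigreeRecord(d, rng.choice(gsires), "") for d in dams]
    else:
        records += [PedigreeRecord(s) for s in sires]
        records += [PedigreeRecord(d) for d in dams]
    k = 0
    for sire, n_d in zip(sires, cfg.daughters_per_sire or []):
        for _ in range(n_d):
            records.append(PedigreeRecord(f"C{k + 1:04d}", sire, dams[k]))
            k += 1
    return Pedigree(records, generation_depth=3)


def _hap_tables(cfg: SimulationConfig) -> list[tuple[list[int], np.ndarray, np.ndarray]]:
    """Per block: marker indices, haplotype allele-index matrix, frequencies."""
    midx = {m.marker_id: j for j, m in enumerate(cfg.markers)}
    out = []
    for mids, freqs in cfg.blocks:
        cols = [midx[mid] for mid in mids]
        labels = sorted(freqs)
        haps = np.array(
            [
                [cfg.markers[c].alleles.index(lbl[k]) for k, c in enumerate(cols)]
                for lbl in labels
            ],
            dtype=np.int8,
        )
        out.append((cols, haps, np.array([freqs[l] for l in labels])))
    return out


def simulate_genotypes(cfg: SimulationConfig, ped: Pedigree) -> tuple[GenotypeTable, dict]:
    """Gene-drop block haplotypes down the pedigree.

    Founders draw each block haplotype i.i.d. from the block frequency table;
    offspring inherit one gamete per parent, with the block-2 haplotype taken
    from the same parental chromosome as block 1 with probability
    ``1 - inter_block_recombination``.  Returns the daughters' genotype table
    plus the hidden phased haplotypes of every animal.
    """
    rng = _rng(cfg, 1)
    tables = _hap_tables(cfg)
    n_mark = len(cfg.markers)
    phased: dict[str, np.ndarray] = {}  # animal -> (2, n_markers) allele indices
    block_choice: dict[str, np.ndarray] = {}  # which founder hap idx per chrom/block

    def founder_gametes() -> np.ndarray:
        chroms = np.zeros((2, n_mark), dtype=np.int8)
        for cols, haps, freqs in tables:
            for c in range(2):
                chroms[c, cols] = haps[rng.choice(len(haps), p=freqs)]
        return chroms

    def gamete(parent: str) -> np.ndarray:
        chroms = phased[parent]
        g = np.zeros(n_mark, dtype=np.int8)
        current = int(rng.integers(2))
        for b, (cols, _, _) in enumerate(tables):
            if b > 0 and rng.random() < cfg.inter_block_recombination:
                current = 1 - current
            g[cols] = chroms[current, cols]
        return g

    for animal in ped.topological_order():
        sire, dam = ped.parents(animal)
        chroms = np.zeros((2, n_mark), dtype=np.int8)
        if sire == "" and dam == "":
            chroms = founder_gametes()
        else:
            chroms[0] = gamete(sire) if sire else founder_gametes()[0]
            chroms[1] = gamete(dam) if dam else founder_gametes()[1]
        phased[animal] = chroms

    daughters = [r.animal for r in ped.records if r.sire != "" and r.dam != ""]
    if cfg.deep_pedigree:  # sires/dams then also have parents; keep cows only
        daughters = [a for a in daughters if a.startswith("C")]
    calls = np.zeros((len(daughters), n_mark), dtype=np.int8)
    for i, a in enumerate(daughters):
        calls[i] = phased[a].sum(axis=0)  # 0/1/2 copies of the second allele
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = -1
    gt = GenotypeTable(daughters, list(cfg.markers), calls)
    truth_haps = {
        a: ["".join(cfg.markers[j].alleles[x] for j, x in enumerate(ch)) for ch in phased[a]]
        for a in phased
    }
    return gt, {"phased_haplotypes": truth_haps}


def simulate_phenotypes(
    cfg: SimulationConfig, ped: Pedigree, gt: GenotypeTable, A: RelationshipMatrix | None = None
) -> tuple[dict[str, TraitVector], dict]:
    """EBV phenotypes for the daughters under the weighted animal model."""
    rng = _rng(cfg, 2)
    if A is None:
        A = build_a_matrix(ped)
    daughters = gt.individuals
    n = len(daughters)
    labels = gt.genotype_labels(cfg.effect_marker)
    m = gt.marker(cfg.effect_marker)
    hom1, het, hom2 = sorted([m.genotype_label(0), m.genotype_label(1), m.genotype_label(2)])
    rel = rng.uniform(*cfg.rel_range, size=n)

    A_full = A.values
    try:
        L = np.linalg.cholesky(A_full)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(A_full)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    didx = [A.ids.index(a) for a in daughters]

    traits: dict[str, TraitVector] = {}
    truth: dict = {
        "rel": dict(zip(daughters, rel.round(6).tolist())),
        "effect_marker": cfg.effect_marker,
        "class_values": {},
        "polygenic": {},
    }
    for t, (a_eff, d_eff) in cfg.effects.items():
        g_of = {hom1: a_eff, het: d_eff, hom2: -a_eff, "": 0.0}
        g = np.array([g_of[labels[a]] for a in daughters])
        u_all = L @ rng.standard_normal(A_full.shape[0]) * np.sqrt(cfg.sigma2_a[t])
        u = u_all[didx]
        e = rng.standard_normal(n) * np.sqrt(cfg.sigma2_e[t] / rel)
        y = cfg.mu[t] + g + u + e
        traits[t] = TraitVector(t, list(daughters), y, rel)
        truth["class_values"][t] = {hom1: a_eff, het: d_eff, hom2: -a_eff}
        truth["polygenic"][t] = dict(zip(daughters, u.round(6).tolist()))
    return traits, truth


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Full generator run: pedigree, genotypes, phenotypes, hidden truth."""
    if cfg is None:
        cfg = SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "seed": seed})
    ped = simulate_pedigree(cfg)
    A = build_a_matrix(ped)
    gt, gt_truth = simulate_genotypes(cfg, ped)
    traits, ph_truth = simulate_phenotypes(cfg, ped, gt, A)
    truth = {
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        **gt_truth,
        **ph_truth,
    }
    return SimulatedDataset(cfg, ped, gt, traits, truth)


def write_dataset(ds: SimulatedDataset, out_dir, vcf: bool = False) -> dict[str, Path]:
    """Write pedigree/genotype/phenotype CSVs, config YAML and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "genotypes": out / "genotypes.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    write_pedigree(ds.pedigree, paths["pedigree"])
    write_genotypes_csv(ds.genotypes, paths["genotypes"])
    write_phenotypes(ds.traits, paths["phenotypes"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    ds.config.to_yaml(paths["config"])
    if vcf:
        paths["vcf"] = out / "genotypes.vcf"
        write_genotypes_vcf(ds.genotypes, paths["vcf"])
    return paths
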