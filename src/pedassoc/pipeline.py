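"""End-to-end candidate-gene analysis: QC -> HWE -> LD/blocks -> association.

``run_pipeline`` chains the module operations on pedigree / genotype /
phenotype files and writes tab-separated reports (frequency + HWE table,
LD table, block list, per-SNP and per-block association tables, genetic
effects) plus a machine-readable JSON summary.  Every number in the reports
comes from the module functions themselves; nothing is computed report-side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AssociationResult,
    MultipleTestingReport,
    associate_block,
    associate_marker,
    association_table,
)
from .effects import EffectEstimates, effect_tests, effects_table
from .genotypes import GenotypeTable, frequencies, frequency_table, hwe_table, read_genotypes
from .haplotypes import (
    POOLED_LABEL,
    assign_diplotypes,
    em_haplotype_frequencies,
    find_blocks,
    ld_table,
    pool_rare_haplotypes,
)
from .mixed_model import ModelError
from .pedigree import build_a_matrix, read_pedigree
from .phenotypes import read_phenotypes

log = logging.getLogger("pedassoc")


@dataclass
class RunConfig:
    pedigree_path: str
    genotype_path: str
    phenotype_path: str
    out_dir: str
    genotype_format: str = "csv"
    markers: list[str] | None = None      # None = all markers in the file
    traits: list[str] | None = None       # None = all traits in the file
    blocks: list[list[str]] | str = "auto"
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    bonferroni_m: int | None = None       # None = number of markers tested
    generation_depth: int = 3
    pool_threshold: float = 0.05
    reuse_variance_components: bool = False
    seed: int = 1

    def __post_init__(self) -> None:
        for p in (self.pedigree_path, self.genotype_path, self.phenotype_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the JSON-ready summary dict.

    On a stage failure, partial outputs are kept and a MANIFEST file marks
    which stage aborted before the exception propagates.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    stages_done: list[str] = []
    summary: dict = {"version": __version__, "seed": cfg.seed, "stages": stages_done}
    stage = "setup"
    try:
        stage = "read_inputs"
        ped = read_pedigree(cfg.pedigree_path, generation_depth=cfg.generation_depth)
        gt = read_genotypes(cfg.genotype_path, format=cfg.genotype_format)
        traits = read_phenotypes(cfg.phenotype_path)
        marker_ids = cfg.markers or gt.marker_ids
        trait_names = cfg.traits or list(traits)
        log.info(
            "inputs: %d pedigree records, %d genotyped animals x %d markers, "
            "%d traits", len(ped), len(gt.individuals), len(gt.markers), len(trait_names),
        )
        stages_done.append(stage)

        stage = "kinship"
        phenotyped = sorted({a for t in trait_names for a in traits[t].animals})
        ped_trim = ped.trim_to_generations(phenotyped, cfg.generation_depth)
        A = build_a_matrix(ped_trim)
        log.info("kinship: A is %d x %d (trimmed to %d generations)",
                 len(A.ids), len(A.ids), cfg.generation_depth)
        summary["n_animals_in_A"] = len(A.ids)
        stages_done.append(stage)

        stage = "qc"
        freq = frequency_table(gt)
        hwe = hwe_table(gt)
        qc = freq.merge(hwe[["marker_id", "chi2", "p", "df"]], on="marker_id")
        _write(qc, out / "frequencies_hwe.tsv")
        summary["markers"] = marker_ids
        summary["hwe_p"] = dict(zip(hwe["marker_id"], hwe["p"]))
        stages_done.append(stage)

        stage = "ld"
        ld = ld_table(gt, marker_ids)
        _write(ld, out / "ld_pairs.tsv")
        if cfg.blocks == "auto":
            blocks = find_blocks(gt, marker_ids)
            block_windows = [list(b.markers) for b in blocks]
        else:
            block_windows = [list(b) for b in cfg.blocks]
        _write(
            pd.DataFrame(
                [{"block": i + 1, "n_markers": len(w), "markers": ";".join(w)}
                 for i, w in enumerate(block_windows)]
            ),
            out / "blocks.tsv",
        )
        summary["n_blocks"] = len(block_windows)
        summary["blocks"] = block_windows
        log.info("ld: %d blocks %s", len(block_windows), block_windows)
        stages_done.append(stage)

        stage = "snp_association"
        m_tests = cfg.bonferroni_m or len(marker_ids)
        mt = MultipleTestingReport(m_tests)
        summary["bonferroni"] = {
            "m": m_tests,
            "threshold_05": mt.threshold_05,
            "threshold_01": mt.threshold_01,
        }
        snp_results: list[AssociationResult] = []
        effect_rows: list[EffectEstimates] = []
        snp_p: dict[str, dict[str, float]] = {}
        lambda_by_trait: dict[str, float] = {}
        for trait_name in trait_names:
            tv = traits[trait_name]
            snp_p[trait_name] = {}
            for mid in marker_ids:
                fixed = lambda_by_trait.get(trait_name) if cfg.reuse_variance_components else None
                try:
                    res, fit = associate_marker(gt, mid, tv, A, m_tests=m_tests, fixed_lambda=fixed)
                except ModelError as exc:
                    log.warning("skipping %s/%s: %s", mid, trait_name, exc)
                    continue
                if cfg.reuse_variance_components and trait_name not in lambda_by_trait:
                    lambda_by_trait[trait_name] = fit.lam
                snp_results.append(res)
                snp_p[trait_name][mid] = res.p_value
                log.info("assoc %s / %s: n=%d F=%.3f p=%.4g", mid, trait_name,
                         res.n_used, res.f_stat, res.p_value)
                if len(fit.model.levels) == 3:
                    f = frequencies(gt, mid)
                    effect_rows.append(
                        effect_tests(fit, f["freq_allele_first"], f["freq_allele_second"],
                                     marker_id=mid, trait=trait_name)
                    )
        _write(association_table(snp_results), out / "association_snps.tsv")
        summary["snp_p_values"] = snp_p
        stages_done.append(stage)

        stage = "effects"
        _write(effects_table(effect_rows), out / "effects.tsv")
        stages_done.append(stage)

        stage = "block_association"
        hap_rows = []
        block_results: list[AssociationResult] = []
        block_p: dict[str, dict[str, float]] = {t: {} for t in trait_names}
        for b, window in enumerate(block_windows, start=1):
            freqs = em_haplotype_frequencies(gt, window, seed=cfg.seed)
            pooled = pool_rare_haplotypes(freqs, cfg.pool_threshold)
            for lbl, fr in zip(pooled.labels, pooled.frequencies):
                hap_rows.append(
                    {"block": b, "haplotype": lbl, "frequency_pct": 100.0 * fr,
                     "members": ";".join(pooled.pooled_members.get(lbl, []) or [lbl])}
                )
            diplo = assign_diplotypes(gt, freqs, pooled)
            label = f"block{b}[{window[0]}..{window[-1]}]"
            for trait_name in trait_names:
                try:
                    res, _ = associate_block(
                        gt, diplo, traits[trait_name], A, block_label=label, m_tests=m_tests
                    )
                except ModelError as exc:
                    log.warning("skipping %s/%s: %s", label, trait_name, exc)
                    continue
                block_results.append(res)
                block_p[trait_name][label] = res.p_value
                log.info("assoc %s / %s: n=%d F=%.3f p=%.4g", label, trait_name,
                         res.n_used, res.f_stat, res.p_value)
        _write(pd.DataFrame(hap_rows), out / "haplotypes.tsv")
        _write(association_table(block_results), out / "association_blocks.tsv")
        summary["block_p_values"] = block_p
        stages_done.append(stage)

        with open(out / "summary.json", "w") as f:
            json.dump(summary, f, indent=1, sort_keys=True, default=float)
        (out / "MANIFEST").write_text(
            "status: complete\nstages: " + ", ".join(stages_done) + "\n"
        )
        return summary
    except Exception as exc:
        (out / "MANIFEST").write_text(
            f"status: INCOMPLETE\nfailed_stage: {stage}\nerror: {exc}\n"
            "stages_completed: " + ", ".join(stages_done) + "\n"
        )
        log.error("pipeline aborted in stage %s: %s", stage, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
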