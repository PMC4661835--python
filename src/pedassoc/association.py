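"""Single-marker and diplotype association with compact letter displays.

Each analysis fits the reliability-weighted animal model with the genotype
(or pooled-diplotype) class as the fixed factor, reports per-class
least-squares means, a Wald F-test of class equality, pairwise letter
groupings at the 0.05 (lowercase) and 0.01 (uppercase) levels, and the
Bonferroni verdict for the panel-wide number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable
from .haplotypes import DiplotypeAssignment
from .mixed_model import MixedAnimalModel, MixedAnimalModelResults, ModelError
from .pedigree import RelationshipMatrix
from .phenotypes import TraitVector


def bonferroni(nominal: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold: nominal / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return nominal / m


@dataclass
class MultipleTestingReport:
    m: int
    threshold_05: float = field(init=False)
    threshold_01: float = field(init=False)

    def __post_init__(self) -> None:
        self.threshold_05 = bonferroni(0.05, self.m)
        self.threshold_01 = bonferroni(0.01, self.m)


def compact_letter_display(levels: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds the pairs whose means differ; classes sharing a
    letter are not significantly different.
    """
    groups: list[set[str]] = [set(levels)]
    for pair in sorted(significant, key=sorted):
        a, b = sorted(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend((g - {a}, g - {b}))
            else:
                new_groups.append(g)
        # absorb: drop duplicates and subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    letters = {lvl: "" for lvl in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lvl in g:
            letters[lvl] += letter
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def pairwise_letters(
    results: MixedAnimalModelResults, alpha_levels: tuple[float, float] = (0.05, 0.01)
) -> dict[float, dict[str, str]]:
    """Letter groupings from all pairwise LSM t-tests at each alpha."""
    pw = results.pairwise_pvalues()
    levels = results.model.levels
    out: dict[float, dict[str, str]] = {}
    for alpha in alpha_levels:
        sig = {
            frozenset((r["class_a"], r["class_b"]))
            for _, r in pw.iterrows()
            if r["p"] < alpha
        }
        out[alpha] = compact_letter_display(levels, sig)
    return out


@dataclass
class AssociationResult:
    """Per-class LSMs, overall test, letters, and Bonferroni verdicts."""

    factor: str                  # marker id or block label
    trait: str
    classes: pd.DataFrame        # class, n, lsmean, se, letters_05, letters_01
    f_stat: float
    num_df: int
    den_df: int
    p_value: float
    sigma2_a: float
    sigma2_e: float
    n_used: int
    m_tests: int = 1

    @property
    def significant_bonferroni_05(self) -> bool:
        return self.p_value < bonferroni(0.05, self.m_tests)

    @property
    def significant_bonferroni_01(self) -> bool:
        return self.p_value < bonferroni(0.01, self.m_tests)

    def to_row(self) -> dict:
        return {
            "factor": self.factor,
            "trait": self.trait,
            "F": self.f_stat,
            "num_df": self.num_df,
            "den_df": self.den_df,
            "p": self.p_value,
            "n": self.n_used,
            "sigma2_a": self.sigma2_a,
            "sigma2_e": self.sigma2_e,
            "bonferroni_05": self.significant_bonferroni_05,
            "bonferroni_01": self.significant_bonferroni_01,
        }


def _associate_classes(
    factor: str,
    class_series: pd.Series,
    trait: TraitVector,
    A: RelationshipMatrix,
    m_tests: int = 1,
    fixed_lambda: float | None = None,
) -> tuple[AssociationResult, MixedAnimalModelResults]:
    """Shared association pipeline for any per-animal class labelling."""
    pheno = trait.to_frame().set_index("animal")
    common = [a for a in class_series.index if a in pheno.index and a in A.ids]
    classes = class_series.loc[common]
    keep = classes != ""
    classes = classes[keep]
    if classes.empty or classes.nunique() < 2:
        raise ModelError(f"{factor}/{trait.trait}: no contrast among usable animals")
    animals = list(classes.index)
    model = MixedAnimalModel(
        pheno.loc[animals, "ebv"].to_numpy(float),
        classes.tolist(),
        A,
        pheno.loc[animals, "rel"].to_numpy(float),
        ids=animals,
    )
    res = model.fit(fixed_lambda=fixed_lambda)
    f, q, dd, p = res.anova()
    letters = pairwise_letters(res)
    table = res.lsmeans()
    table["letters_05"] = [letters[0.05][c] for c in table["class"]]
    table["letters_01"] = [letters[0.01][c].upper() for c in table["class"]]
    result = AssociationResult(
        factor=factor,
        trait=trait.trait,
        classes=table,
        f_stat=f,
        num_df=q,
        den_df=dd,
        p_value=p,
        sigma2_a=res.sigma2_a,
        sigma2_e=res.sigma2_e,
        n_used=model.nobs,
        m_tests=m_tests,
    )
    return result, res


def associate_marker(
    gt: GenotypeTable,
    marker_id: str,
    trait: TraitVector,
    A: RelationshipMatrix,
    m_tests: int = 1,
    fixed_lambda: float | None = None,
) -> tuple[AssociationResult, MixedAnimalModelResults]:
    """Animal-model association of one SNP with one trait.

    Animals missing the genotype, the phenotype, or the pedigree are dropped
    listwise.  Returns the report plus the full model results (the latter
    feeds the genetic-effect decomposition).
    """
    labels = gt.genotype_labels(marker_id)
    return _associate_classes(marker_id, labels, trait, A, m_tests, fixed_lambda)


def associate_block(
    gt: GenotypeTable,
    diplotypes: DiplotypeAssignment,
    trait: TraitVector,
    A: RelationshipMatrix,
    block_label: str = "block",
    m_tests: int = 1,
    fixed_lambda: float | None = None,
) -> tuple[AssociationResult, MixedAnimalModelResults]:
    """Animal-model association of pooled diplotype classes with one trait."""
    labels = diplotypes.labels()
    return _associate_classes(block_label, labels, trait, A, m_tests, fixed_lambda)


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-form report: one row per factor x trait x class."""
    rows = []
    for r in results:
        thr = MultipleTestingReport(r.m_tests)
        for _, c in r.classes.iterrows():
            rows.append(
                {
                    "factor": r.factor,
                    "trait": r.trait,
                    "class": c["class"],
                    "n": c["n"],
                    "lsmean": c["lsmean"],
                    "se": c["se"],
                    "letters_05": c["letters_05"],
                    "letters_01": c["letters_01"],
                    "p_overall": r.p_value,
                    "bonferroni_threshold_05": thr.threshold_05,
                    "bonferroni_threshold_01": thr.threshold_01,
                    "significant_bonferroni_05": r.significant_bonferroni_05,
                    "significant_bonferroni_01": r.significant_bonferroni_01,
                }
            )
    return pd.DataFrame(rows)
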