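"""Additive / dominance / allele-substitution decomposition of genotype means.

With genotype-class least-squares means for the two homozygotes and the
heterozygote, the classical single-locus decomposition is

    a     = (LSM_hom1 - LSM_hom2) / 2
    d     = LSM_het - (LSM_hom1 + LSM_hom2) / 2
    alpha = a + d * (p - q)

Orientation convention: hom1 is the **alphabetically first** homozygote
genotype (AA before GG, CC before TT), i.e. the order genotype classes sort
in; and the frequency difference multiplying d is f(major) - f(minor).
The sign of ``a`` (and of the a-part of alpha) therefore refers to
substituting the alphabetically first allele; d is orientation-free.

Standard errors treat the allele frequencies as known constants, so each
effect is a fixed linear contrast of the class LSMs and inherits its SE from
the fixed-effect covariance of the fitted animal model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import MixedAnimalModelResults, ModelError


class EffectError(ValueError):
    pass


@dataclass
class EffectEstimates:
    """Single-locus genetic effects for one trait, with optional tests."""

    marker_id: str
    trait: str
    a_add: float
    d_dom: float | None
    alpha_sub: float | None
    p_major: float
    q_minor: float
    se_a: float | None = None
    se_d: float | None = None
    se_alpha: float | None = None
    p_a: float | None = None
    p_d: float | None = None
    p_alpha: float | None = None

    def stars(self, p: float | None) -> str:
        if p is None:
            return ""
        return "**" if p < 0.01 else ("*" if p < 0.05 else "")

    def to_rows(self) -> list[dict]:
        return [
            {"marker_id": self.marker_id, "trait": self.trait, "effect": name,
             "estimate": est, "se": se, "p": p,
             "significance": self.stars(p)}
            for name, est, se, p in [
                ("additive", self.a_add, self.se_a, self.p_a),
                ("dominance", self.d_dom, self.se_d, self.p_d),
                ("allele_substitution", self.alpha_sub, self.se_alpha, self.p_alpha),
            ]
        ]


def decompose_effects(
    lsm_hom1: float,
    lsm_het: float | None,
    lsm_hom2: float,
    freq_allele1: float,
    freq_allele2: float,
    marker_id: str = "",
    trait: str = "",
) -> EffectEstimates:
    """Decompose three genotype LSMs into (a, d, alpha).

    ``lsm_hom1`` must be the alphabetically first homozygote class and
    ``freq_allele1`` its allele's frequency.  A missing heterozygote class
    (``lsm_het=None``) still yields ``a``; d and alpha are unavailable.
    """
    if not np.isclose(freq_allele1 + freq_allele2, 1.0, atol=1e-6):
        raise EffectError("allele frequencies must sum to 1")
    a = (lsm_hom1 - lsm_hom2) / 2.0
    if lsm_het is None:
        return EffectEstimates(marker_id, trait, a, None, None,
                               max(freq_allele1, freq_allele2),
                               min(freq_allele1, freq_allele2))
    d = lsm_het - (lsm_hom1 + lsm_hom2) / 2.0
    f_major = max(freq_allele1, freq_allele2)
    f_minor = min(freq_allele1, freq_allele2)
    alpha = a + d * (f_major - f_minor)
    return EffectEstimates(marker_id, trait, a, d, alpha, f_major, f_minor)


def effect_tests(
    results: MixedAnimalModelResults,
    freq_allele1: float,
    freq_allele2: float,
    marker_id: str = "",
    trait: str = "",
) -> EffectEstimates:
    """Effects with SEs and t-tests from a fitted three-class genotype model.

    The model's class levels must be the three genotype strings, which sort
    as (hom1, het, hom2); a, d and alpha are then linear contrasts of the
    class LSMs, tested with df = n - rank(X).
    """
    levels = results.model.levels
    if len(levels) != 3:
        raise EffectError(
            f"need the three genotype classes, got {levels}; "
            "use decompose_effects for partial data"
        )
    _, L = results._lsm_rows()
    c_a = (L[0] - L[2]) / 2.0
    c_d = L[1] - (L[0] + L[2]) / 2.0
    f_major = max(freq_allele1, freq_allele2)
    f_minor = min(freq_allele1, freq_allele2)
    c_alpha = c_a + (f_major - f_minor) * c_d
    try:
        est_a, se_a, _, p_a = results.contrast(c_a)
        est_d, se_d, _, p_d = results.contrast(c_d)
        est_al, se_al, _, p_al = results.contrast(c_alpha)
    except ModelError as exc:
        raise EffectError(f"singular effect contrast: {exc}") from exc
    return EffectEstimates(
        marker_id, trait, est_a, est_d, est_al, f_major, f_minor,
        se_a, se_d, se_al, p_a, p_d, p_al,
    )


def effects_table(estimates: list[EffectEstimates]) -> pd.DataFrame:
    rows: list[dict] = []
    for e in estimates:
        rows.extend(e.to_rows())
    return pd.DataFrame(rows)
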