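"""Per-animal EBV phenotypes with reliabilities.

Traits follow the usual dairy panel: milk yield (MY, kg), fat yield (FY, kg),
fat percentage (FP, percentage points), protein yield (PY, kg) and protein
percentage (PP, percentage points).  The EBV is the response of the animal
model and its reliability scales the residual weight (w_i = 1/REL_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAITS = ["MY", "FY", "FP", "PY", "PP"]


class PhenotypeError(ValueError):
    pass


@dataclass
class TraitVector:
    """EBVs and reliabilities for one trait."""

    trait: str
    animals: list[str]
    ebv: np.ndarray
    rel: np.ndarray

    def __post_init__(self) -> None:
        self.ebv = np.asarray(self.ebv, dtype=float)
        self.rel = np.asarray(self.rel, dtype=float)
        if not (len(self.animals) == len(self.ebv) == len(self.rel)):
            raise PhenotypeError("animals, ebv and rel must align")
        if np.any(~np.isfinite(self.ebv)):
            raise PhenotypeError("EBVs must be finite")
        if np.any(self.rel <= 0) or np.any(self.rel > 1):
            raise PhenotypeError("reliabilities must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animals, "trait": self.trait, "ebv": self.ebv, "rel": self.rel}
        )

    def __len__(self) -> int:
        return len(self.animals)


def read_phenotypes(path) -> dict[str, TraitVector]:
    """Read EBV phenotypes from CSV, long or wide form.

    Long form (canonical): columns ``animal,trait,ebv,rel``.  Wide form:
    ``animal`` plus ``<TRAIT>`` and ``<TRAIT>_rel`` column pairs.
    """
    df = pd.read_csv(path)
    if {"animal", "trait", "ebv", "rel"}.issubset(df.columns):
        out = {}
        for trait, sub in df.groupby("trait", sort=False):
            out[str(trait)] = TraitVector(
                str(trait), sub["animal"].astype(str).tolist(),
                sub["ebv"].to_numpy(float), sub["rel"].to_numpy(float),
            )
        return out
    if "animal" in df.columns:
        traits = [c for c in df.columns if f"{c}_rel" in df.columns]
        if traits:
            out = {}
            for t in traits:
                sub = df[["animal", t, f"{t}_rel"]].dropna()
                out[t] = TraitVector(
                    t, sub["animal"].astype(str).tolist(),
                    sub[t].to_numpy(float), sub[f"{t}_rel"].to_numpy(float),
                )
            return out
    raise PhenotypeError(
        "phenotype CSV must be long form (animal,trait,ebv,rel) or wide form "
        "(animal + TRAIT/TRAIT_rel pairs)"
    )


def write_phenotypes(traits: dict[str, TraitVector], path) -> None:
    pd.concat([tv.to_frame() for tv in traits.values()], ignore_index=True).to_csv(
        path, index=False
    )
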