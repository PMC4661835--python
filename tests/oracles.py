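"""Independent oracles used to validate the implementation.

These deliberately share no code path with the package: gene dropping checks
the tabular relationship matrix, an exhaustive likelihood grid checks the
haplotype EM, and closed-form ANOVA/GLS formulas check the mixed model.
"""

from __future__ import annotations

import numpy as np

from pedassoc.pedigree import Pedigree


def gene_drop_relationship(ped: Pedigree, n_drops: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of the numerator relationship matrix.

    Every founder gamete gets a unique allele label; alleles are dropped down
    the pedigree ``n_drops`` times.  A_ij is estimated as 4x the probability
    that a random allele from i is identical by descent with a random allele
    from j, which equals 2*kinship(i,j) (and 1+F on the diagonal).
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    idx = {a: i for i, a in enumerate(order)}
    n = len(order)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    next_label = 0
    for a in order:
        i = idx[a]
        sire, dam = ped.parents(a)
        for slot, parent in enumerate((sire, dam)):
            if parent == "":
                alleles[i, slot] = next_label  # one founder allele per gamete slot
                next_label += 1
            else:
                p = idx[parent]
                pick = rng.integers(2, size=n_drops)
                alleles[i, slot] = alleles[p, pick, np.arange(n_drops)]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ibd = sum(
                np.mean(alleles[i, s] == alleles[j, t]) for s in (0, 1) for t in (0, 1)
            )
            A[i, j] = A[j, i] = ibd / 2.0  # 2 * kinship
    return A, order


def em_grid_oracle(
    genotype_counts: dict[tuple[int, int], int], coarse: float = 0.01, fine: float = 0.001
) -> np.ndarray:
    """Exhaustive-grid MLE of two-marker haplotype frequencies.

    ``genotype_counts`` maps (g1, g2) second-allele dosages to counts.
    Haplotype order: (0,0), (0,1), (1,0), (1,1).  Coarse grid over the
    3-simplex then local refinement to ``fine`` resolution.
    """

    def loglik(f: np.ndarray) -> np.ndarray:
        f = np.clip(f, 1e-12, None)
        f1, f2, f3, f4 = f[..., 0], f[..., 1], f[..., 2], f[..., 3]
        probs = {
            (0, 0): f1**2, (0, 1): 2 * f1 * f2, (0, 2): f2**2,
            (1, 0): 2 * f1 * f3, (1, 1): 2 * (f1 * f4 + f2 * f3), (1, 2): 2 * f2 * f4,
            (2, 0): f3**2, (2, 1): 2 * f3 * f4, (2, 2): f4**2,
        }
        ll = 0.0
        for g, c in genotype_counts.items():
            ll = ll + c * np.log(np.clip(probs[g], 1e-300, None))
        return ll

    def grid(lo: np.ndarray, hi: np.ndarray, step: float) -> np.ndarray:
        axes = [np.arange(l, h + step / 2, step) for l, h in zip(lo, hi)]
        g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        s = g.sum(axis=1)
        g = g[s <= 1.0 + 1e-9]
        return np.column_stack([g, 1.0 - g.sum(axis=1)])

    pts = grid(np.zeros(3), np.ones(3), coarse)
    best = pts[np.argmax(loglik(pts))]
    lo = np.clip(best[:3] - 1.5 * coarse, 0, 1)
    hi = np.clip(best[:3] + 1.5 * coarse, 0, 1)
    pts = grid(lo, hi, fine)
    return pts[np.argmax(loglik(pts))]


def gls_solution(X: np.ndarray, V: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Textbook GLS estimator (X' V^-1 X)^-1 X' V^-1 y."""
    Vi = np.linalg.inv(V)
    return np.linalg.inv(X.T @ Vi @ X) @ (X.T @ Vi @ y)
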