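"""Haplotype frequency estimation, linkage disequilibrium, and blocks.

Haplotype frequencies over a short marker window are estimated from unphased
genotypes with the classical EM algorithm: under Hardy-Weinberg random
pairing of haplotypes, each multi-site genotype is a mixture over the
haplotype pairs compatible with it, and EM alternates posterior phase
assignment (E) with frequency re-estimation (M).  The log-likelihood is
non-decreasing across iterations, which is asserted on every run.

Pairwise LD is summarised by D, D' = |D| / Dmax and r^2.  Blocks are found
with the confidence-interval criterion on D' (Gabriel-style): a pair is in
"strong LD" when a likelihood-based 90% CI for |D'| has lower bound >= 0.70
and upper bound >= 0.98, shows "strong recombination" when the upper bound
is < 0.90, and a block is a maximal marker run whose bounding pair is strong
and in which >= 95% of informative pairs are strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable, Marker

POOLED_LABEL = "POOLED"

# Haploview-default CI thresholds for the D' block criterion
CI_LOWER_STRONG = 0.70
CI_UPPER_STRONG = 0.98
CI_UPPER_RECOMB = 0.90
STRONG_FRACTION = 0.95
_CI_MASS = 0.05  # each tail of the two-sided 90% interval


class HaplotypeError(ValueError):
    pass


@dataclass
class HaplotypeFrequencySet:
    """EM-estimated haplotype frequencies over a marker window."""

    window: list[str]                 # marker ids, in panel order
    markers: list[Marker]
    haplotypes: list[tuple[int, ...]]  # 0 = first allele, 1 = second allele
    frequencies: np.ndarray
    loglik: float
    n_iterations: int
    n_individuals: int
    pooled_members: dict[str, list[str]] = field(default_factory=dict)

    def label(self, hap: tuple[int, ...] | str) -> str:
        if isinstance(hap, str):
            return hap
        return "".join(m.alleles[a] for m, a in zip(self.markers, hap))

    @property
    def labels(self) -> list[str]:
        return [self.label(h) for h in self.haplotypes]

    def frequency_of(self, label: str) -> float:
        return float(self.frequencies[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"haplotype": self.labels, "frequency": self.frequencies}
        ).sort_values("frequency", ascending=False, ignore_index=True)


def _window_genotypes(gt: GenotypeTable, window: Sequence[str]) -> tuple[list[str], np.ndarray]:
    """Individuals with complete calls in the window, and their 0/1/2 codes."""
    cols = np.column_stack([gt.column(mid) for mid in window])
    keep = ~np.any(cols == MISSING, axis=1)
    ids = [a for a, k in zip(gt.individuals, keep) if k]
    return ids, cols[keep]


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with an unphased genotype."""
    het = [i for i, g in enumerate(geno) if g == 1]
    base = [g // 2 for g in geno]  # 0->allele0, 2->allele1; het slots filled below
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    # fix the first het site to break the h1/h2 symmetry: 2^(k-1) pairs
    for combo in product((0, 1), repeat=len(het) - 1):
        h1, h2 = list(base), list(base)
        h1[het[0]], h2[het[0]] = 0, 1
        for pos, a in zip(het[1:], combo):
            h1[pos], h2[pos] = a, 1 - a
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_frequencies(
    gt: GenotypeTable,
    window: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    n_restarts: int = 0,
) -> HaplotypeFrequencySet:
    """EM haplotype frequencies for a 2-8 marker window.

    Individuals with any missing call in the window are excluded.  The EM is
    initialised at the product of observed allele frequencies (deterministic);
    ``seed`` only matters when ``n_restarts`` > 0, which adds random
    Dirichlet restarts and keeps the best likelihood.
    """
    window = list(window)
    if not 2 <= len(window) <= 8:
        raise HaplotypeError("window must span 2-8 markers")
    markers = [gt.marker(mid) for mid in window]
    ids, codes = _window_genotypes(gt, window)
    if not ids:
        raise HaplotypeError("no individual has complete calls in the window")

    genos, counts = np.unique(codes, axis=0, return_counts=True)
    hap_index: dict[tuple[int, ...], int] = {}
    geno_pairs: list[list[tuple[int, int, float]]] = []  # (i1, i2, multiplicity)
    for g in map(tuple, genos):
        entries = []
        for h1, h2 in _compatible_pairs(g):
            i1 = hap_index.setdefault(h1, len(hap_index))
            i2 = hap_index.setdefault(h2, len(hap_index))
            entries.append((i1, i2, 2.0 if h1 != h2 else 1.0))
        geno_pairs.append(entries)
    haplotypes = [h for h, _ in sorted(hap_index.items(), key=lambda kv: kv[1])]
    H = len(haplotypes)

    if all(len(entries) == 1 for entries in geno_pairs):
        # phase-unambiguous data: EM fixed point is direct gamete counting
        f = np.zeros(H)
        for (i1, i2, _), c in zip((e[0] for e in geno_pairs), counts):
            f[i1] += c
            f[i2] += c
        f /= f.sum()
        ll = float(
            sum(
                c * np.log(max((2.0 if i1 != i2 else 1.0) * f[i1] * f[i2], np.finfo(float).tiny))
                for (i1, i2, _), c in zip((e[0] for e in geno_pairs), counts)
            )
        )
        order = np.argsort(-f)
        return HaplotypeFrequencySet(
            window=window,
            markers=markers,
            haplotypes=[haplotypes[i] for i in order],
            frequencies=f[order],
            loglik=ll,
            n_iterations=1,
            n_individuals=len(ids),
        )

    allele1_freq = (genos * counts[:, None]).sum(axis=0) / (2.0 * counts.sum())
    init = np.array(
        [np.prod([allele1_freq[j] if a else 1 - allele1_freq[j] for j, a in enumerate(h)])
         for h in haplotypes]
    )
    inits = [init / init.sum()]
    if n_restarts:
        rng = np.random.default_rng(seed)
        inits += [rng.dirichlet(np.ones(H)) for _ in range(n_restarts)]

    def run(f0: np.ndarray) -> tuple[np.ndarray, float, int]:
        f = f0.copy()
        prev = -np.inf
        for it in range(1, max_iter + 1):
            expected = np.zeros(H)
            ll = 0.0
            for entries, c in zip(geno_pairs, counts):
                probs = np.array([mult * f[i1] * f[i2] for i1, i2, mult in entries])
                tot = probs.sum()
                if tot <= 0:
                    tot = np.finfo(float).tiny
                    probs = np.full(len(entries), tot / len(entries))
                ll += c * np.log(tot)
                post = probs / tot
                for (i1, i2, _), w in zip(entries, post):
                    expected[i1] += c * w
                    expected[i2] += c * w
            f = expected / expected.sum()
            if ll + 1e-12 < prev:
                raise AssertionError("EM log-likelihood decreased")
            if ll - prev < tol:
                return f, ll, it
            prev = ll
        return f, prev, max_iter

    best = max((run(f0) for f0 in inits), key=lambda r: r[1])
    f, ll, iters = best
    order = np.argsort([-fi for fi in f])
    return HaplotypeFrequencySet(
        window=window,
        markers=markers,
        haplotypes=[haplotypes[i] for i in order],
        frequencies=f[order],
        loglik=ll,
        n_iterations=iters,
        n_individuals=len(ids),
    )


@dataclass(frozen=True)
class LDStats:
    marker_a: str
    marker_b: str
    D: float
    Dprime: float
    r2: float


def pairwise_ld(freqs: HaplotypeFrequencySet) -> LDStats:
    """D, D' and r^2 from a two-marker haplotype frequency set."""
    if len(freqs.window) != 2:
        raise HaplotypeError("pairwise LD needs exactly two markers")
    f = {h: float(fr) for h, fr in zip(freqs.haplotypes, freqs.frequencies)}
    f00 = f.get((0, 0), 0.0)
    p1 = f00 + f.get((0, 1), 0.0)   # first allele at marker 1
    p2 = f00 + f.get((1, 0), 0.0)   # first allele at marker 2
    q1, q2 = 1.0 - p1, 1.0 - p2
    if min(p1, q1, p2, q2) <= 0:
        raise HaplotypeError("monomorphic marker: LD undefined")
    D = f00 - p1 * p2
    dmax = min(p1 * q2, q1 * p2) if D > 0 else min(p1 * p2, q1 * q2)
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (p1 * q1 * p2 * q2)
    return LDStats(freqs.window[0], freqs.window[1], D, min(dprime, 1.0), min(r2, 1.0))


def ld_table(gt: GenotypeTable, markers: Sequence[str] | None = None) -> pd.DataFrame:
    """All pairwise D/D'/r^2 over a marker list (EM per pair)."""
    mids = list(markers) if markers is not None else gt.marker_ids
    rows = []
    for i in range(len(mids)):
        for j in range(i + 1, len(mids)):
            try:
                ld = pairwise_ld(em_haplotype_frequencies(gt, [mids[i], mids[j]]))
                rows.append(
                    {"marker_a": ld.marker_a, "marker_b": ld.marker_b,
                     "D": ld.D, "Dprime": ld.Dprime, "r2": ld.r2}
                )
            except HaplotypeError:
                rows.append({"marker_a": mids[i], "marker_b": mids[j],
                             "D": np.nan, "Dprime": np.nan, "r2": np.nan})
    return pd.DataFrame(rows)


def dprime_confidence_interval(
    gt: GenotypeTable, marker_a: str, marker_b: str, resolution: float = 0.001
) -> tuple[float, float]:
    """Likelihood-based two-sided 90% CI for |D'| between two markers.

    Allele frequencies are fixed at their sample values; the two-locus
    genotype likelihood is profiled over |D'| on a grid and the normalised
    likelihood mass gives the interval (flat prior over the grid).
    """
    cols = np.column_stack([gt.column(marker_a), gt.column(marker_b)])
    cols = cols[~np.any(cols == MISSING, axis=1)]
    if len(cols) == 0:
        raise HaplotypeError("no complete two-locus genotypes")
    g1, g2 = cols[:, 0], cols[:, 1]
    n = len(cols)
    pA = 1.0 - g1.sum() / (2.0 * n)   # first allele, marker a
    pB = 1.0 - g2.sum() / (2.0 * n)
    qA, qB = 1.0 - pA, 1.0 - pB
    if min(pA, qA, pB, qB) <= 0:
        raise HaplotypeError("monomorphic marker: D' undefined")
    counts = np.zeros((3, 3))
    np.add.at(counts, (g1, g2), 1)

    def loglik(D: float) -> float:
        fAB = pA * pB + D
        fAb = pA * qB - D
        faB = qA * pB - D
        fab = qA * qB + D
        f = np.clip(np.array([fAB, fAb, faB, fab]), 1e-12, None)
        fAB, fAb, faB, fab = f
        # genotype-class probabilities (rows marker a: 0/1/2 second-allele count)
        P = np.array([
            [fAB**2, 2 * fAB * fAb, fAb**2],
            [2 * fAB * faB, 2 * (fAB * fab + fAb * faB), 2 * fAb * fab],
            [faB**2, 2 * faB * fab, fab**2],
        ])
        return float(np.sum(counts * np.log(np.clip(P, 1e-300, None))))

    d_pos = min(pA * qB, qA * pB)
    d_neg = min(pA * pB, qA * qB)
    grid = np.arange(0.0, 1.0 + resolution / 2, resolution)
    ll = np.array([max(loglik(dp * d_pos), loglik(-dp * d_neg)) for dp in grid])
    like = np.exp(ll - ll.max())
    cum = np.cumsum(like) / like.sum()
    lower = grid[int(np.searchsorted(cum, _CI_MASS))]
    upper = grid[int(np.searchsorted(cum, 1.0 - _CI_MASS))]
    return float(lower), float(upper)


@dataclass(frozen=True)
class Block:
    start: int                 # index into the marker list
    stop: int                  # inclusive
    markers: tuple[str, ...]

    def __len__(self) -> int:
        return self.stop - self.start + 1


def find_blocks(
    gt: GenotypeTable, markers: Sequence[str] | None = None, method: str = "gabriel_ci"
) -> list[Block]:
    """Partition an ordered marker list into D'-CI haplotype blocks."""
    if method != "gabriel_ci":
        raise ValueError(f"unknown block method {method!r}")
    mids = list(markers) if markers is not None else gt.marker_ids
    if len(mids) < 2:
        raise HaplotypeError("block finding needs at least two markers")
    m = len(mids)
    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                low, up = dprime_confidence_interval(gt, mids[i], mids[j])
            except HaplotypeError:
                continue
            is_strong = low >= CI_LOWER_STRONG and up >= CI_UPPER_STRONG
            is_recomb = up < CI_UPPER_RECOMB
            strong[i, j] = is_strong
            informative[i, j] = is_strong or is_recomb

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong[i, j]:
                continue
            idx = [(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
            n_inf = sum(informative[a, b] for a, b in idx)
            n_str = sum(strong[a, b] for a, b in idx)
            if n_inf and n_str / n_inf >= STRONG_FRACTION:
                candidates.append((i, j))
    candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for i, j in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(Block(i, j, tuple(mids[i : j + 1])))
    return sorted(blocks, key=lambda b: b.start)


def pool_rare_haplotypes(
    freqs: HaplotypeFrequencySet, threshold: float = 0.05
) -> HaplotypeFrequencySet:
    """Merge haplotypes below ``threshold`` into a single POOLED class."""
    keep = freqs.frequencies >= threshold
    if keep.all() or threshold <= 0:
        return replace(freqs, pooled_members=dict(freqs.pooled_members))
    rare_labels = [freqs.label(h) for h, k in zip(freqs.haplotypes, keep) if not k]
    pooled_freq = float(freqs.frequencies[~keep].sum())
    new_haps: list = [h for h, k in zip(freqs.haplotypes, keep) if k]
    new_freqs = list(freqs.frequencies[keep])
    new_haps.append(POOLED_LABEL)
    new_freqs.append(pooled_freq)
    out = replace(
        freqs,
        haplotypes=new_haps,
        frequencies=np.array(new_freqs),
        pooled_members={POOLED_LABEL: rare_labels},
    )
    return out


@dataclass
class DiplotypeAssignment:
    """Most probable haplotype pair per individual, with its posterior."""

    individuals: list[str]
    pairs: list[tuple[str, str]]       # pooled-class labels, sorted within pair
    posteriors: np.ndarray
    flagged: list[bool]                # True when no positive-frequency pair existed

    def labels(self) -> pd.Series:
        """Diplotype class label ('H1/H2') per individual."""
        return pd.Series(
            ["/".join(p) for p in self.pairs], index=self.individuals, name="diplotype"
        )


def assign_diplotypes(
    gt: GenotypeTable,
    freqs: HaplotypeFrequencySet,
    pooled: HaplotypeFrequencySet | None = None,
) -> DiplotypeAssignment:
    """Assign each fully genotyped individual its most probable haplotype pair.

    The pair maximises f(h1) f(h2) (x2 when h1 != h2) over pairs compatible
    with the observed genotype; the posterior is that term over the sum
    across compatible pairs.  When ``pooled`` is given, reported pair labels
    use the pooled classes (rare haplotypes collapse to POOLED) while the
    maximisation itself uses the full frequency set.  Ties break
    lexicographically on the label pair.
    """
    ids, codes = _window_genotypes(gt, freqs.window)
    fmap = {h: float(f) for h, f in zip(freqs.haplotypes, freqs.frequencies)}
    pool_of: dict[str, str] = {}
    if pooled is not None:
        for lbl in pooled.pooled_members.get(POOLED_LABEL, []):
            pool_of[lbl] = POOLED_LABEL

    pairs_out: list[tuple[str, str]] = []
    post_out: list[float] = []
    flags: list[bool] = []
    for g in map(tuple, codes):
        cand = _compatible_pairs(g)
        weights = np.array(
            [(2.0 if h1 != h2 else 1.0) * fmap.get(h1, 0.0) * fmap.get(h2, 0.0)
             for h1, h2 in cand]
        )
        total = weights.sum()
        if total > 0:
            flagged = False
        else:  # genotype incompatible with every positive-frequency haplotype
            weights = np.ones(len(cand))
            total = weights.sum()
            flagged = True
        labelled = sorted(
            (tuple(sorted((freqs.label(h1), freqs.label(h2)))), w)
            for (h1, h2), w in zip(cand, weights)
        )
        # deterministic tie-break: highest weight, then lexicographically first
        best_w = max(w for _, w in labelled)
        best_pair = next(lbl for lbl, w in labelled if w == best_w)
        pairs_out.append(tuple(sorted(pool_of.get(l, l) for l in best_pair)))
        post_out.append(float(best_w / total))
        flags.append(flagged)
    return DiplotypeAssignment(ids, pairs_out, np.array(post_out), flags)
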