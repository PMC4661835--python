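"""Genotype tables, allele/genotype frequencies, and Hardy-Weinberg tests.

Genotypes are unphased biallelic calls stored as small integers per
individual x marker: 0 = homozygous for the marker's first allele,
1 = heterozygous, 2 = homozygous for the second allele, -1 = missing.
Missing calls are excluded marker-wise, so per-marker sample sizes may
differ (as they do in real SNaPshot panels with imperfect call rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
_MISSING_CELLS = {"", "./.", ".|.", ".", "NA", "na", "-/-"}


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with an ordered allele pair.

    ``marker_id`` is the panel label (e.g. ``"c.-724 A>G"``); ``external_id``
    an optional dbSNP-style accession.
    """

    marker_id: str
    allele_first: str
    allele_second: str
    external_id: str | None = None

    def __post_init__(self) -> None:
        if self.allele_first == self.allele_second:
            raise GenotypeError(f"marker {self.marker_id!r}: alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_first, self.allele_second)

    def genotype_label(self, code: int) -> str:
        """Human genotype string for a call code, alleles sorted ('AG' not 'GA')."""
        a, b = self.allele_first, self.allele_second
        pair = {0: (a, a), 1: tuple(sorted((a, b))), 2: (b, b)}[code]
        return "".join(pair)


@dataclass
class GenotypeTable:
    individuals: list[str]
    markers: list[Marker]
    calls: np.ndarray  # (n_individuals, n_markers) int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise GenotypeError("calls shape inconsistent with individuals/markers")
        if len(set(self.individuals)) != len(self.individuals):
            raise GenotypeError("duplicate individual ids")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise GenotypeError("duplicate marker ids")
        self._mindex = {m.marker_id: j for j, m in enumerate(self.markers)}
        self._iindex = {a: i for i, a in enumerate(self.individuals)}

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def marker(self, marker_id: str) -> Marker:
        return self.markers[self._mindex[marker_id]]

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self._mindex[marker_id]]

    def genotype_labels(self, marker_id: str) -> pd.Series:
        """Per-individual genotype strings ('' for missing) at one marker."""
        m = self.marker(marker_id)
        col = self.column(marker_id)
        lab = np.array(["", m.genotype_label(0), m.genotype_label(1), m.genotype_label(2)])
        return pd.Series(lab[col + 1], index=self.individuals, name=marker_id)

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        idx = [self._iindex[a] for a in individuals]
        return GenotypeTable(list(individuals), self.markers, self.calls[idx])


def _parse_cell(cell: str, marker_id: str, animal: str, alleles: set[str]) -> tuple[str, str] | None:
    cell = cell.strip()
    if cell in _MISSING_CELLS:
        return None
    sep = "/" if "/" in cell else ("|" if "|" in cell else None)
    parts = cell.split(sep) if sep else list(cell)
    if len(parts) != 2:
        raise GenotypeError(f"cannot parse genotype {cell!r} at {marker_id} for {animal}")
    a, b = parts[0].strip(), parts[1].strip()
    alleles.update((a, b))
    if len(alleles) > 2:
        raise GenotypeError(
            f"marker {marker_id!r} is not biallelic: cell {cell!r} of {animal} "
            f"brings alleles to {sorted(alleles)}"
        )
    return a, b


def read_genotypes(path, format: str = "csv", markers: Sequence[Marker] | None = None) -> GenotypeTable:
    """Read genotypes from CSV (``animal`` column + one column per marker,
    cells like ``A/G``) or from a biallelic-SNP VCF (phase is discarded).

    If ``markers`` is given, allele order follows the panel; otherwise
    alleles are inferred from the data and ordered alphabetically.
    """
    if format == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "animal" not in df.columns:
        raise GenotypeError("genotype CSV must have an 'animal' column")
    individuals = [a.strip() for a in df["animal"]]
    if len(set(individuals)) != len(individuals):
        dup = pd.Series(individuals)
        raise GenotypeError(
            f"duplicate individual id {dup[dup.duplicated()].iloc[0]!r} in genotype file"
        )
    panel = {m.marker_id: m for m in markers} if markers else {}
    marker_cols = [c for c in df.columns if c != "animal"]
    out_markers: list[Marker] = []
    calls = np.full((len(individuals), len(marker_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(marker_cols):
        known = panel.get(col)
        alleles: set[str] = set(known.alleles) if known else set()
        pairs: list[tuple[str, str] | None] = []
        for animal, cell in zip(individuals, df[col]):
            pairs.append(_parse_cell(cell, col, animal, alleles))
        if known is None:
            obs = sorted(alleles)
            if len(obs) == 0:
                raise GenotypeError(f"marker {col!r}: all calls missing")
            if len(obs) == 1:  # monomorphic in file; invent a placeholder 2nd allele
                obs.append("*")
            known = Marker(col, obs[0], obs[1])
        code = {
            frozenset((known.allele_first,)): 0,
            frozenset((known.allele_first, known.allele_second)): 1,
            frozenset((known.allele_second,)): 2,
        }
        for i, pair in enumerate(pairs):
            if pair is not None:
                calls[i, j] = code[frozenset(pair)]
        out_markers.append(known)
    return GenotypeTable(individuals, out_markers, calls)


def _read_vcf(path) -> GenotypeTable:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        individuals = list(vf.header.samples)
        markers: list[Marker] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            if len(rec.alts or ()) != 1:
                raise GenotypeError(
                    f"VCF record {rec.chrom}:{rec.pos} is not biallelic"
                )
            mid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
            markers.append(Marker(mid, rec.ref, rec.alts[0]))
            col = np.full(len(individuals), MISSING, dtype=np.int8)
            for i, sample in enumerate(individuals):
                gt = rec.samples[sample]["GT"]
                if gt is None or any(a is None for a in gt):
                    continue
                col[i] = sum(gt)  # de-phased: count of ALT alleles
            rows.append(col)
    return GenotypeTable(individuals, markers, np.column_stack(rows))


def write_genotypes_csv(gt: GenotypeTable, path) -> None:
    data = {"animal": gt.individuals}
    for m in gt.markers:
        col = gt.column(m.marker_id)
        cells = np.array(
            [
                "",
                f"{m.allele_first}/{m.allele_first}",
                f"{m.allele_first}/{m.allele_second}",
                f"{m.allele_second}/{m.allele_second}",
            ]
        )
        data[m.marker_id] = cells[col + 1]
    pd.DataFrame(data).to_csv(path, index=False)


def write_genotypes_vcf(gt: GenotypeTable, path) -> None:
    """Emit the table as an uncompressed VCF (one synthetic contig, unit-spaced)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##contig=<ID=panel,length=1000000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in gt.individuals:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, m in enumerate(gt.markers):
            rec = vf.new_record(
                contig="panel", start=j, stop=j + 1, id=m.marker_id.replace(" ", "_"),
                alleles=(m.allele_first, m.allele_second),
            )
            for i, s in enumerate(gt.individuals):
                c = gt.calls[i, j]
                rec.samples[s]["GT"] = (
                    (None, None) if c == MISSING else {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(c)]
                )
            vf.write(rec)


def frequencies(gt: GenotypeTable, marker_id: str) -> pd.Series:
    """Genotype counts/frequencies and allele frequencies at one marker.

    Frequencies are over non-missing calls, at full precision; rounding is a
    reporting concern.
    """
    m = gt.marker(marker_id)
    col = gt.column(marker_id)
    n0 = int(np.sum(col == 0))
    n1 = int(np.sum(col == 1))
    n2 = int(np.sum(col == 2))
    n = n0 + n1 + n2
    if n == 0:
        raise GenotypeError(f"marker {marker_id!r}: all calls missing")
    p_first = (n0 + 0.5 * n1) / n
    return pd.Series(
        {
            "marker_id": marker_id,
            "allele_first": m.allele_first,
            "allele_second": m.allele_second,
            "n": n,
            "n_hom_first": n0,
            "n_het": n1,
            "n_hom_second": n2,
            "freq_hom_first": n0 / n,
            "freq_het": n1 / n,
            "freq_hom_second": n2 / n,
            "freq_allele_first": p_first,
            "freq_allele_second": 1.0 - p_first,
        }
    )


def allele_frequency_from_genotype_freqs(f_hom: float, f_het: float) -> float:
    """Allele frequency implied by its homozygote and heterozygote frequencies."""
    return f_hom + 0.5 * f_het


def frequency_table(gt: GenotypeTable) -> pd.DataFrame:
    return pd.DataFrame([frequencies(gt, mid) for mid in gt.marker_ids])


def hwe_chisq(counts: Sequence[int]) -> tuple[float, float, int]:
    """Chi-square test of Hardy-Weinberg proportions from genotype counts.

    ``counts`` = (n_hom_first, n_het, n_hom_second).  Expected counts come
    from the observed allele frequencies; 1 degree of freedom (3 classes -
    1 - 1 estimated allele frequency), no continuity correction.
    Returns ``(chi2, p, df)``.  A monomorphic marker yields (0, 1) with a
    warning since HWE is untestable there.
    """
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    if n < 1:
        raise GenotypeError("HWE test needs at least one genotyped individual")
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        warnings.warn("monomorphic marker: HWE chi-square undefined, returning 0", stacklevel=2)
        return 0.0, 1.0, 1
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval, 1


def hwe_table(gt: GenotypeTable) -> pd.DataFrame:
    """Per-marker HWE chi-square results for a whole panel."""
    rows = []
    for mid in gt.marker_ids:
        f = frequencies(gt, mid)
        chi2, p, df = hwe_chisq((f["n_hom_first"], f["n_het"], f["n_hom_second"]))
        rows.append({"marker_id": mid, "n": f["n"], "chi2": chi2, "p": p, "df": df})
    return pd.DataFrame(rows)
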