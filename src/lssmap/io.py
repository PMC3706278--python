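"""Readers and writers for haplotype matrices, trait tables and scan results.

Haplotype TSV dialect: a ``#positions`` header line listing 1-based bp
coordinates, then one row per haplotype — label ``<individual>_1`` /
``<individual>_2`` followed by one 0/1 column per SNP.  Rows ``2i`` and
``2i+1`` (0-based) belong to diploid individual ``i``.  Phased VCF is
accepted as an equivalent encoding (two haplotype rows per sample, in sample
order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("lssmap")

__all__ = [
    "HaplotypeMatrix",
    "TraitTable",
    "read_haplotypes",
    "write_haplotypes",
    "read_traits",
    "write_traits",
    "write_scan_results",
    "read_scan_results",
]


@dataclass
class HaplotypeMatrix:
    """Phased biallelic SNP data: ``n_hap x S`` 0/1 matrix plus bp positions.

    Columns are guaranteed polymorphic (monomorphic columns are dropped with
    a warning on construction); positions are strictly increasing 1-based bp
    coordinates.
    """

    alleles: np.ndarray
    positions: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n_hap, n_snp = self.alleles.shape
        if n_hap % 2 != 0:
            raise ValueError(f"number of haplotypes must be even, got {n_hap}")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        if self.positions.shape != (n_snp,):
            raise ValueError("positions length must match SNP count")
        poly = (self.alleles.min(axis=0) == 0) & (self.alleles.max(axis=0) == 1)
        if not poly.all():
            dropped = self.positions[~poly]
            logger.warning(
                "dropping %d monomorphic column(s) at position(s) %s",
                len(dropped), ", ".join(map(str, dropped)),
            )
            self.alleles = self.alleles[:, poly]
            self.positions = self.positions[poly]
        if self.positions.size and (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")
        if self.positions.size and self.positions[0] < 1:
            raise ValueError("positions must be >= 1 (1-based bp)")
        if not self.labels:
            self.labels = [f"ind{i // 2}_{i % 2 + 1}" for i in range(n_hap)]

    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.n_hap // 2

    @property
    def hap_to_individual(self) -> np.ndarray:
        return np.arange(self.n_hap) // 2

    def minor_allele_frequencies(self) -> np.ndarray:
        freq = self.alleles.mean(axis=0)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class TraitTable:
    """One quantitative trait value per diploid individual."""

    identifiers: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.identifiers) != len(self.values):
            raise ValueError("identifiers and values differ in length")
        if len(self.identifiers) != len(set(self.identifiers)):
            raise ValueError("duplicate individual identifiers")
        if len(self.values) == 0:
            raise ValueError("no individuals")
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def tip_values(self) -> np.ndarray:
        """Trait vector at haplotype tips (each value duplicated on both copies)."""
        return np.repeat(self.values, 2)


def read_haplotypes(path, format: str = "tsv") -> HaplotypeMatrix:
    """Read phased haplotypes from TSV (dialect above) or phased VCF."""
    if format == "tsv":
        return _read_haplotypes_tsv(path)
    if format == "vcf":
        return _read_haplotypes_vcf(path)
    raise ValueError(f"unknown haplotype format {format!r}")


def _read_haplotypes_tsv(path) -> HaplotypeMatrix:
    positions = None
    labels: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#positions":
                positions = [int(x) for x in fields[1:]]
                continue
            if line.startswith("#"):
                continue
            labels.append(fields[0])
            row = []
            for col, tok in enumerate(fields[1:], start=1):
                if tok not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary allele code {tok!r} at line {lineno}, column {col}"
                    )
                row.append(int(tok))
            rows.append(row)
    if positions is None:
        raise ValueError(f"{path}: missing '#positions' header line")
    if not rows:
        raise ValueError(f"{path}: no haplotype rows")
    return HaplotypeMatrix(np.array(rows, dtype=np.int8), np.array(positions), labels)


def _read_haplotypes_vcf(path) -> HaplotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{variant.CHROM}:{variant.POS}: not biallelic (ALT={variant.ALT})"
            )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(variant.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at {variant.CHROM}:{variant.POS}"
                )
            if a not in (0, 1) or b not in (0, 1):
                raise ValueError(
                    f"non-binary allele for sample {samples[i]} at {variant.CHROM}:{variant.POS}"
                )
            col[2 * i], col[2 * i + 1] = a, b
        positions.append(variant.POS)
        columns.append(col)
    if not columns:
        raise ValueError(f"{path}: no variant records")
    labels = [f"{s}_{j}" for s in samples for j in (1, 2)]
    return HaplotypeMatrix(np.array(columns, dtype=np.int8).T, np.array(positions), labels)


def write_haplotypes(matrix: HaplotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#positions\t" + "\t".join(map(str, matrix.positions)) + "\n")
        for label, row in zip(matrix.labels, matrix.alleles):
            fh.write(label + "\t" + "\t".join(map(str, row)) + "\n")


def read_traits(path) -> TraitTable:
    """Read a two-column (identifier, value) TSV of per-individual traits."""
    ids: list[str] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            try:
                value = float(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric trait value {fields[1]!r} at line {lineno}"
                ) from None
            ids.append(fields[0])
            values.append(value)
    if not ids:
        raise ValueError(f"{path}: no individuals")
    return TraitTable(ids, np.array(values))


def write_traits(traits: TraitTable, path) -> None:
    with open(path, "w") as fh:
        for ident, value in zip(traits.identifiers, traits.values):
            fh.write(f"{ident}\t{value:.12g}\n")


def write_scan_results(scan, path) -> None:
    """Write a per-SNP scan table; chromosome-level summary in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# chromosome_pvalue\t{scan.chromosome_pvalue:.12g}\n")
        fh.write(f"# max_snp_position\t{scan.max_snp_position}\n")
        fh.write(f"# n_permutations\t{scan.n_permutations}\n")
        fh.write(f"# seed\t{scan.seed}\n")
        fh.write("position\tlss\tbest_k\tlocus_pvalue\n")
        for pos, score, k, p in zip(scan.positions, scan.lss, scan.best_k, scan.locus_pvalues):
            fh.write(f"{pos}\t{score:.12g}\t{k}\t{p:.12g}\n")


def read_scan_results(path):
    """Round-trip reader for :func:`write_scan_results` output."""
    from .significance import ScanResult

    header: dict[str, str] = {}
    positions: list[int] = []
    lss: list[float] = []
    best_k: list[int] = []
    pvals: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition("\t")
                header[key] = value
            elif line and not line.startswith("position"):
                pos, score, k, p = line.split("\t")
                positions.append(int(pos))
                lss.append(float(score))
                best_k.append(int(k))
                pvals.append(float(p))
    return ScanResult(
        positions=np.array(positions, dtype=np.int64),
        lss=np.array(lss),
        best_k=np.array(best_k, dtype=np.int64),
        locus_pvalues=np.array(pvals),
        chromosome_pvalue=float(header["chromosome_pvalue"]),
        max_snp_position=int(header["max_snp_position"]),
        n_permutations=int(header["n_permutations"]),
        seed=int(header["seed"]),
    )
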