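"""SNP genotype handling: QC filters, genomic relationships, genetic distances.

Genotypes are held as line x marker dosage matrices with codes 0/1/2 counting
copies of a designated "counted" allele (ALT when read from VCF, the
column-coded allele when read from a dosage matrix). Missing calls are NaN.
All allele frequencies are computed on the line subset actually present in
the matrix, never inherited from a larger panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "filter_snps",
    "vanraden_grm",
    "rogers_distance",
    "read_dosage_matrix",
    "read_vcf",
    "write_vcf",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix.

    Parameters
    ----------
    line_ids : list of str
        One identifier per line (row).
    marker_ids : list of str
        One identifier per marker (column).
    dosages : ndarray, shape (n_lines, n_markers)
        Counted-allele dosage in {0, 1, 2}; missing calls are ``nan``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D lines x markers array")
        n, p = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise ValueError("line/marker id lengths do not match dosage shape")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be coded 0/1/2 or missing (nan)")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per marker over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def to_dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    def write_dosage_matrix(self, path: str | Path) -> None:
        """Tab-separated matrix: header of marker IDs, first column line IDs."""
        df = self.to_dosage_frame()
        df.index.name = "line"
        df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class RelationshipMatrix:
    """Symmetric line x line relationship (genomic) or distance matrix."""

    line_ids: list[str]
    values: np.ndarray
    kind: str = "genomic"  # "genomic" | "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match line_ids")
        if self.kind not in ("genomic", "distance"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def ridged(self, ridge: float = 1e-6) -> np.ndarray:
        """Values with a small ridge on the diagonal (stabilises inversion;
        duplicated lines otherwise make a genomic matrix exactly singular)."""
        return self.values + ridge * np.eye(self.n_lines)

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)
        df.index.name = "line"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind=kind)


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.05, callrate_min: float = 0.0
) -> GenotypeMatrix:
    """Remove markers with low minor allele frequency or low call rate.

    MAF is computed on non-missing calls of the present line subset. The line
    set and the order of retained markers are unchanged. Filtering is
    idempotent: applying the same thresholds twice retains the same markers.

    Raises
    ------
    ValueError
        If thresholds are out of range or every marker is removed.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= callrate_min <= 1.0:
        raise ValueError("callrate_min must be in [0, 1]")
    maf = geno.minor_allele_frequencies()
    callrate = geno.call_rates()
    with np.errstate(invalid="ignore"):
        keep = (callrate >= callrate_min) & ~np.isnan(maf) & (maf >= maf_min)
    if not keep.any():
        raise ValueError("empty panel: all markers removed by QC thresholds")
    return GenotypeMatrix(
        line_ids=list(geno.line_ids),
        marker_ids=[m for m, k in zip(geno.marker_ids, keep) if k],
        dosages=geno.dosages[:, keep],
    )


def vanraden_grm(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix G = ZZ' / (2 sum p_j (1 - p_j)).

    Z is the dosage matrix centred by twice the observed allele frequency of
    each marker (computed from the lines in `geno`). Missing dosages are
    mean-imputed (to 2 p_j) before centring, i.e. they contribute zero.
    """
    if geno.n_lines < 2:
        raise ValueError("need at least 2 lines for a relationship matrix")
    p = geno.allele_frequencies()
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if not poly.any() or denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    Z = geno.dosages - 2.0 * p  # nan where missing
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean-imputed dosages centre to zero
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(geno.line_ids), G, kind="genomic")


def rogers_distance(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Rogers' genetic distance between every pair of lines.

    Per biallelic locus, with individual allele frequencies p = dosage/2,
    d = sqrt(((p1 - p2)^2 + ((1-p1) - (1-p2))^2) / 2) = |p1 - p2|,
    averaged over pairwise-complete loci. Values are in [0, 1] with zero
    diagonal; a pair with no shared called locus gets ``nan`` with a warning.
    """
    n = geno.n_lines
    P = geno.dosages / 2.0
    obs = ~np.isnan(P)
    P0 = np.where(obs, P, 0.0)
    O = obs.astype(float)
    # sum over shared loci of |p_i - p_j|; dosages give p in {0, .5, 1}, for
    # which |p_i - p_j| and sqrt(mean squared allele-freq difference) agree
    # per locus, so accumulate via the three-level decomposition below.
    shared = O @ O.T
    D = np.zeros((n, n))
    # |p_i - p_j| is not a bilinear form; loop over lines (n is small relative
    # to markers and this path is exercised on panels, not inner loops).
    for i in range(n):
        both = obs[i] & obs  # (n, p) pairwise-complete mask against line i
        D[i] = np.where(both, np.abs(P0[i] - P0), 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(shared > 0, D / shared, np.nan)
    if np.isnan(D).any():
        warnings.warn("some line pairs share no called loci; distance set to nan")
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return RelationshipMatrix(list(geno.line_ids), D, kind="distance")


# ---------------------------------------------------------------------------
# I/O


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a tab-separated dosage matrix (marker-ID header, line-ID column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        line_ids=list(df.index.astype(str)),
        marker_ids=list(df.columns.astype(str)),
        dosages=df.to_numpy(float),
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT calls from a VCF; the counted allele is ALT (dosage = #ALT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        marker_ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((len(line_ids), 0))
    return GenotypeMatrix(line_ids, marker_ids, dosages)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal single-chromosome VCF with GT fields only."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.line_ids)
            + "\n"
        )
        for j, mid in enumerate(geno.marker_ids):
            calls = [
                "./." if np.isnan(d) else gt_code[d] for d in geno.dosages[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")
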