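"""SNP genotype containers and input/output.

Genotypes are held as a lines x markers matrix coded ``{-1, 0, 1}``:
``1`` is homozygous for the major allele, ``-1`` homozygous for the minor
allele, and ``0`` a heterozygous (uncertain) call.  Missing calls are
``NaN`` until :func:`impute_missing` runs.  Major/minor orientation is
always determined from sample allele frequencies, with ties broken toward
the alphabetically first allele.

The module also provides the two derived quantities every downstream stage
needs: a VanRaden genomic relationship (kinship) matrix and principal
component covariates for population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "read_hapmap",
    "read_vcf",
    "write_hapmap",
    "write_vcf",
    "impute_missing",
    "filter_maf",
    "compute_kinship",
    "pca_covariates",
]

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


@dataclass
class GenotypeMatrix:
    """Lines x SNPs genotype codes with a marker map.

    Parameters
    ----------
    line_ids : list of str
        One identifier per row of `codes`.
    markers : pandas.DataFrame
        One row per SNP with at least columns ``id``, ``chrom``, ``pos``
        (1-based bp).  Optional columns: ``cm`` (genetic position),
        ``allele_major`` / ``allele_minor`` (nucleotide letters used by the
        HapMap/VCF writers).
    codes : numpy.ndarray
        Float array, values in {-1, 0, 1} or NaN for missing.
    """

    line_ids: list = field(default_factory=list)
    markers: pd.DataFrame = None
    codes: np.ndarray = None

    def __post_init__(self):
        self.line_ids = list(self.line_ids)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (lines x markers)")
        if self.codes.shape[0] != len(self.line_ids):
            raise ValueError(
                f"{len(self.line_ids)} line ids but {self.codes.shape[0]} code rows"
            )
        if self.codes.shape[1] != len(self.markers):
            raise ValueError(
                f"{len(self.markers)} markers but {self.codes.shape[1]} code columns"
            )
        self.markers = self.markers.reset_index(drop=True)
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if sub["pos"].duplicated().any():
                raise ValueError(f"duplicated marker positions on chromosome {chrom}")
        valid = np.isnan(self.codes) | np.isin(self.codes, (-1.0, 0.0, 1.0))
        if not valid.all():
            raise ValueError("genotype codes must be -1, 0, 1 or NaN")

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def subset_lines(self, index) -> "GenotypeMatrix":
        """Row subset by positional index array."""
        index = np.asarray(index)
        ids = [self.line_ids[i] for i in index]
        return GenotypeMatrix(ids, self.markers.copy(), self.codes[index])

    def subset_markers(self, mask) -> "GenotypeMatrix":
        """Column subset by boolean mask or positional index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            list(self.line_ids), self.markers.iloc[idx].copy(), self.codes[:, idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.codes, index=self.line_ids, columns=self.markers["id"].tolist()
        )

    def major_allele_freq(self) -> np.ndarray:
        """Per-SNP major-allele frequency; a heterozygote contributes one
        copy of each allele."""
        return _allele_freq(self.codes)


def _allele_freq(codes: np.ndarray) -> np.ndarray:
    n_obs = np.sum(~np.isnan(codes), axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        # dosage of the major allele per line is (code + 1); total 2 per line
        dose = np.nansum(codes + 1.0, axis=0)
        return np.where(n_obs > 0, dose / (2.0 * n_obs), np.nan)


@dataclass
class KinshipMatrix:
    """Symmetric PSD lines x lines genomic relationship matrix."""

    line_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids),) * 2:
            raise ValueError("kinship dimensions do not match line ids")


# ---------------------------------------------------------------------------
# readers / writers


def _orient(alleles: list, counts: list):
    """Return (major, minor) with ties broken alphabetically."""
    order = sorted(zip(alleles, counts), key=lambda ac: (-ac[1], ac[0]))
    return order[0][0], order[1][0]


def read_hapmap(path) -> GenotypeMatrix:
    """Read a tab-delimited HapMap genotype file.

    Heterozygous or ambiguous calls become 0; ``N``/``NN`` stays missing.
    Markers with more than two observed alleles are skipped with a warning.
    """
    with open(path, "r", newline="") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if len(header) < 12:
            raise ValueError("HapMap header must have 11 metadata columns plus samples")
        samples = header[11:]
        rows = []
        meta = []
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\r\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != 11 + len(samples):
                raise ValueError(f"malformed HapMap row at line {lineno}")
            try:
                pos = int(parts[3])
            except ValueError as exc:
                raise ValueError(f"bad position at line {lineno}") from exc
            calls = parts[11:]
            allele_counts: dict = {}
            for call in calls:
                for a in call:
                    if a in "ACGT":
                        allele_counts[a] = allele_counts.get(a, 0) + 1
            # single-letter homozygous convention: count the call twice
            for call in calls:
                if len(call) == 1 and call in "ACGT":
                    allele_counts[call] += 1
            alleles = sorted(allele_counts)
            if len(alleles) > 2:
                warnings.warn(
                    f"skipping multi-allelic marker {parts[0]} at line {lineno}"
                )
                continue
            if len(alleles) == 0:
                warnings.warn(f"skipping all-missing marker {parts[0]}")
                continue
            if len(alleles) == 1:
                major, minor = alleles[0], None
            else:
                major, minor = _orient(alleles, [allele_counts[a] for a in alleles])
            row = np.full(len(samples), np.nan)
            for j, call in enumerate(calls):
                obs = [a for a in call if a in "ACGT"]
                if len(obs) == 1:
                    obs = obs * 2
                if len(obs) != 2:
                    continue  # missing
                if obs[0] != obs[1]:
                    row[j] = 0.0
                elif obs[0] == major:
                    row[j] = 1.0
                else:
                    row[j] = -1.0
            rows.append(row)
            meta.append(
                {
                    "id": parts[0],
                    "chrom": str(parts[2]),
                    "pos": pos,
                    "allele_major": major,
                    "allele_minor": minor if minor is not None else major,
                }
            )
    markers = pd.DataFrame(meta)
    codes = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, markers, codes)


def write_hapmap(g: GenotypeMatrix, path) -> None:
    majors, minors = _allele_letters(g)
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_META + list(map(str, g.line_ids))) + "\n")
        for j in range(g.n_markers):
            m = g.markers.iloc[j]
            a, b = majors[j], minors[j]
            calls = []
            for code in g.codes[:, j]:
                if np.isnan(code):
                    calls.append("NN")
                elif code == 1:
                    calls.append(a + a)
                elif code == -1:
                    calls.append(b + b)
                else:
                    calls.append("".join(sorted((a, b))))
            fields = [
                str(m["id"]), f"{a}/{b}", str(m["chrom"]), str(int(m["pos"])),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            fh.write("\t".join(fields + calls) + "\n")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT fields; REF is the major allele."""
    majors, minors = _allele_letters(g)
    order = np.lexsort((g.markers["pos"].to_numpy(), g.markers["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.markers["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.line_ids))
            + "\n"
        )
        for j in order:
            m = g.markers.iloc[j]
            gts = []
            for code in g.codes[:, j]:
                if np.isnan(code):
                    gts.append("./.")
                elif code == 1:
                    gts.append("0/0")
                elif code == -1:
                    gts.append("1/1")
                else:
                    gts.append("0/1")
            fh.write(
                "\t".join(
                    [
                        str(m["chrom"]), str(int(m["pos"])), str(m["id"]),
                        majors[j], minors[j], ".", "PASS", ".", "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic VCF via cyvcf2; orientation from sample frequencies."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            warnings.warn(f"skipping multi-allelic marker {v.ID} at {v.CHROM}:{v.POS}")
            continue
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        ref_copies = 2 * np.sum(gt == 0) + np.sum(gt == 1)
        alt_copies = 2 * np.sum(gt == 3) + np.sum(gt == 1)
        if ref_copies + alt_copies == 0:
            warnings.warn(f"skipping all-missing marker {v.ID}")
            continue
        major, minor = _orient([v.REF, v.ALT[0]], [ref_copies, alt_copies])
        ref_is_major = major == v.REF
        row = np.full(len(samples), np.nan)
        row[gt == 1] = 0.0
        row[gt == 0] = 1.0 if ref_is_major else -1.0
        row[gt == 3] = -1.0 if ref_is_major else 1.0
        rows.append(row)
        meta.append(
            {
                "id": v.ID if v.ID not in (None, ".") else f"S{v.CHROM}_{v.POS}",
                "chrom": str(v.CHROM),
                "pos": int(v.POS),
                "allele_major": major,
                "allele_minor": minor,
            }
        )
    markers = pd.DataFrame(meta)
    codes = np.vstack(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, markers, codes)


def _allele_letters(g: GenotypeMatrix):
    if "allele_major" in g.markers.columns:
        return (
            g.markers["allele_major"].tolist(),
            g.markers["allele_minor"].tolist(),
        )
    return ["A"] * g.n_markers, ["G"] * g.n_markers


# ---------------------------------------------------------------------------
# processing


def impute_missing(g: GenotypeMatrix, mode: str = "major", seed: int | None = None) -> GenotypeMatrix:
    """Fill missing codes locus by locus.

    mode "major" fills the most frequent allele's homozygote (ties toward
    code 1); mode "draw" samples from the per-SNP empirical code
    distribution with the given seed.  A SNP with no observed calls raises.
    """
    if mode not in ("major", "draw"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    codes = g.codes.copy()
    missing = np.isnan(codes)
    if not missing.any():
        return GenotypeMatrix(list(g.line_ids), g.markers.copy(), codes)
    all_missing = missing.all(axis=0)
    if all_missing.any():
        snp = g.markers["id"].iloc[int(np.flatnonzero(all_missing)[0])]
        raise ValueError(f"SNP {snp} is 100% missing and cannot be imputed")
    rng = np.random.default_rng(seed)
    for j in np.flatnonzero(missing.any(axis=0)):
        col = codes[:, j]
        obs = col[~np.isnan(col)]
        if mode == "major":
            p = (np.sum(obs == 1) * 2 + np.sum(obs == 0)) / (2.0 * obs.size)
            fill = 1.0 if p >= 0.5 else -1.0
            col[np.isnan(col)] = fill
        else:
            vals, counts = np.unique(obs, return_counts=True)
            n_miss = int(np.isnan(col).sum())
            col[np.isnan(col)] = rng.choice(vals, size=n_miss, p=counts / counts.sum())
    return GenotypeMatrix(list(g.line_ids), g.markers.copy(), codes)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Drop SNPs with minor-allele frequency below `threshold`.

    A heterozygote contributes one copy of each allele.  The boundary is
    kept: MAF exactly equal to the threshold survives.
    """
    if g.has_missing:
        raise ValueError("run impute_missing before filter_maf")
    n = g.n_lines
    n_major = np.sum(g.codes == 1, axis=0)
    n_het = np.sum(g.codes == 0, axis=0)
    major_copies = 2 * n_major + n_het
    minor_copies = 2 * n - major_copies
    min_copies = np.minimum(major_copies, minor_copies)
    keep = min_copies + 1e-9 >= threshold * 2 * n
    if not keep.any():
        raise ValueError(
            f"no SNP passes MAF >= {threshold}; review the threshold"
        )
    return g.subset_markers(keep)


def compute_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix.

    K = W W' / c with W the column-centered code matrix and
    c = sum_k 2 p_k (1 - p_k), p_k the major-allele frequency.
    """
    if g.has_missing:
        raise ValueError("impute before computing kinship")
    p = g.major_allele_freq()
    var_terms = 2.0 * p * (1.0 - p)
    zero_var = var_terms <= 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance SNPs excluded from the kinship scale"
        )
    c = float(var_terms[~zero_var].sum())
    if c <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    W = g.codes - g.codes.mean(axis=0)
    K = W @ W.T / c
    return KinshipMatrix(list(g.line_ids), K)


def pca_covariates(g: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Coordinates of lines on the top-k principal axes of the centered
    code matrix; each axis's largest-magnitude loading is made positive."""
    if k >= g.n_lines:
        raise ValueError(f"k={k} must be smaller than the number of lines ({g.n_lines})")
    if g.has_missing:
        raise ValueError("impute before PCA")
    W = g.codes - g.codes.mean(axis=0)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    scores = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            scores[:, j] = -scores[:, j]
    return scores
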