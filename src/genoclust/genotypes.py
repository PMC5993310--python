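"""Genotype container and readers/writers for co-dominant marker formats.

The central object is :class:`GenotypeMatrix`, which stores allele *counts*
per individual per locus (an individual carries ``ploidy`` allele copies at
each typed locus).  Internally counts live in a dense ``(N, P)`` integer
array where the ``P = sum_j A_j`` columns concatenate the allele universes of
the ``J`` loci; this layout keeps every likelihood computation a single
matrix product.  Missing genotypes are all-zero blocks flagged in
``missing_mask``.

Supported exchange formats: Genepop, STRUCTURE text (one- or two-row),
a plain CSV allele-count matrix, and biallelic VCF.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "GenotypeFormatError",
    "read_genepop",
    "read_structure",
    "write_structure",
    "read_counts_csv",
    "write_counts_csv",
    "read_vcf_biallelic",
]


class GenotypeFormatError(ValueError):
    """Raised when an input file violates its declared format."""


def from_dosage(
    dosage: np.ndarray,
    ploidy: int = 2,
    locus_names: Sequence[str] | None = None,
    individual_ids: Sequence[str] | None = None,
    allow_monomorphic: bool = True,
) -> "GenotypeMatrix":
    """Build a biallelic GenotypeMatrix from an (N, J) dosage array.

    ``dosage[i, j]`` is the copy number of the reference allele (0..ploidy);
    negative entries mark missing genotypes.  This is the bridge from plain
    numpy arrays (e.g. inside sklearn pipelines) to the genotype container.
    """
    dosage = np.asarray(dosage)
    if dosage.ndim != 2:
        raise ValueError("dosage must be a 2-D (individuals x loci) array")
    if not np.issubdtype(dosage.dtype, np.integer):
        rounded = np.rint(dosage)
        if not np.allclose(dosage[dosage >= 0], rounded[dosage >= 0]):
            raise ValueError("dosage entries must be integer allele copy numbers")
        dosage = rounded.astype(np.int64)
    N, J = dosage.shape
    missing = dosage < 0
    if np.any(dosage > ploidy):
        raise ValueError("dosage exceeds ploidy")
    ref = np.where(missing, 0, dosage)
    alt = np.where(missing, 0, ploidy - dosage)
    counts = np.empty((N, 2 * J), dtype=np.int64)
    counts[:, 0::2] = ref
    counts[:, 1::2] = alt
    return GenotypeMatrix(
        counts=counts,
        ploidy=ploidy,
        locus_names=list(locus_names) if locus_names else [f"L{j+1}" for j in range(J)],
        allele_labels=[["1", "2"] for _ in range(J)],
        individual_ids=(
            list(individual_ids) if individual_ids else [f"ind{i+1}" for i in range(N)]
        ),
        missing_mask=missing,
        allow_monomorphic=allow_monomorphic,
    )


@dataclass
class GenotypeMatrix:
    """Allele counts for N individuals at J co-dominant loci.

    Parameters
    ----------
    counts : ndarray of shape (N, P), integer
        Allele copy counts; columns are the concatenated per-locus allele
        universes (locus j occupies columns ``offsets[j]:offsets[j+1]``).
    ploidy : int
        Allele copies per individual per locus (2 for diploids).
    locus_names : list of str
    allele_labels : list of list of str
        Per-locus allele labels, lexicographically sorted.
    individual_ids : list of str
    missing_mask : ndarray of shape (N, J), bool
        True where the genotype is missing; the corresponding count block is
        all zeros.
    allow_monomorphic : bool
        Permit loci with a single observed allele (otherwise an error).
    """

    counts: np.ndarray
    ploidy: int
    locus_names: list[str]
    allele_labels: list[list[str]]
    individual_ids: list[str]
    missing_mask: np.ndarray
    allow_monomorphic: bool = False
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n_alleles = np.array([len(a) for a in self.allele_labels], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(n_alleles)])
        self.validate()

    # -- basic dimensions -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_alleles_per_locus(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def total_alleles(self) -> int:
        """P, the total allele count across loci."""
        return int(self.offsets[-1])

    def locus_slice(self, j: int) -> slice:
        return slice(int(self.offsets[j]), int(self.offsets[j + 1]))

    def validate(self) -> None:
        N, P = self.counts.shape
        if P != self.offsets[-1]:
            raise ValueError(
                f"counts has {P} columns but allele labels imply {self.offsets[-1]}"
            )
        if len(self.locus_names) != len(self.allele_labels):
            raise ValueError("locus_names and allele_labels length mismatch")
        if len(self.individual_ids) != N:
            raise ValueError("individual_ids length mismatch")
        if self.missing_mask.shape != (N, self.n_loci):
            raise ValueError("missing_mask must be (N, J)")
        if self.ploidy < 1:
            raise ValueError("ploidy must be a positive integer")
        if np.any(self.counts < 0):
            raise ValueError("negative allele counts")
        # per-locus row sums: ploidy where typed, 0 where missing
        sums = np.add.reduceat(self.counts, self.offsets[:-1], axis=1)
        expected = np.where(self.missing_mask, 0, self.ploidy)
        bad = np.argwhere(sums != expected)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"allele counts for individual {i + 1} at locus {j + 1} sum to "
                f"{sums[i, j]}, expected {expected[i, j]}"
            )
        if not self.allow_monomorphic and np.any(self.n_alleles_per_locus < 2):
            j = int(np.argmax(self.n_alleles_per_locus < 2))
            raise ValueError(
                f"locus {j + 1} ({self.locus_names[j]}) is monomorphic; pass "
                "allow_monomorphic=True to accept it"
            )

    # -- derived views ----------------------------------------------------
    def frequency_profiles(self, impute: bool = True) -> np.ndarray:
        """Per-individual allele frequency profiles, counts/ploidy.

        Missing loci are mean-imputed per allele column when ``impute`` so
        the result is usable as a Euclidean embedding for Ward/K-means/PCA.
        """
        prof = self.counts.astype(float) / self.ploidy
        if impute and self.missing_mask.any():
            col_missing = np.repeat(self.missing_mask, self.n_alleles_per_locus, axis=1)
            with np.errstate(invalid="ignore"):
                col_mean = np.where(
                    (~col_missing).sum(axis=0) > 0,
                    np.where(col_missing, 0.0, prof).sum(axis=0)
                    / np.maximum((~col_missing).sum(axis=0), 1),
                    0.0,
                )
            prof = np.where(col_missing, col_mean[None, :], prof)
        return prof

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ploidy == other.ploidy
            and self.locus_names == other.locus_names
            and self.allele_labels == other.allele_labels
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.missing_mask, other.missing_mask)
        )


def _build_matrix(
    genotypes: list[list[tuple[str, ...] | None]],
    ploidy: int,
    locus_names: list[str],
    individual_ids: list[str],
    allow_monomorphic: bool = False,
    fixed_allele_labels: list[list[str]] | None = None,
) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from per-(individual, locus) allele tuples.

    ``None`` marks a missing genotype.  The allele universe of each locus is
    the set of labels observed anywhere, sorted lexicographically, so the
    result is independent of file ordering; ``fixed_allele_labels`` overrides
    it for formats that declare the universe (e.g. VCF REF/ALT).
    """
    J = len(locus_names)
    if fixed_allele_labels is not None:
        allele_labels = fixed_allele_labels
    else:
        allele_labels = []
        for j in range(J):
            seen = set()
            for row in genotypes:
                if row[j] is not None:
                    seen.update(row[j])
            allele_labels.append(sorted(seen))
    index = [{a: k for k, a in enumerate(labels)} for labels in allele_labels]
    offsets = np.concatenate([[0], np.cumsum([len(a) for a in allele_labels])])
    N = len(genotypes)
    counts = np.zeros((N, int(offsets[-1])), dtype=np.int64)
    missing = np.zeros((N, J), dtype=bool)
    for i, row in enumerate(genotypes):
        for j, alleles in enumerate(row):
            if alleles is None:
                missing[i, j] = True
                continue
            base = int(offsets[j])
            for a in alleles:
                counts[i, base + index[j][a]] += 1
    return GenotypeMatrix(
        counts=counts,
        ploidy=ploidy,
        locus_names=locus_names,
        allele_labels=allele_labels,
        individual_ids=individual_ids,
        missing_mask=missing,
        allow_monomorphic=allow_monomorphic,
    )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def read_genepop(
    path: str | Path, ploidy: int = 2, allow_monomorphic: bool = False
) -> tuple[GenotypeMatrix, list[int]]:
    """Read a Genepop file.

    Returns the genotype matrix and, separately, the POP-block index of each
    individual (0-based).  Block membership is informational only; the
    clustering never uses it.

    Allele codes are fixed-width 2- or 3-digit strings; the all-zero code
    denotes a missing genotype.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeFormatError(f"{path}: too short to be a Genepop file")
    # line 1: title. Locus names: either comma-separated on one line, or one
    # per line until the first POP.
    idx = 1
    locus_names: list[str] = []
    while idx < len(lines) and lines[idx].strip().lower() != "pop":
        chunk = lines[idx].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        idx += 1
    if idx == len(lines):
        raise GenotypeFormatError(f"{path}: no POP block found")
    J = len(locus_names)
    genotypes: list[list[tuple[str, ...] | None]] = []
    ids: list[str] = []
    pop_labels: list[int] = []
    pop = -1
    width: int | None = None
    for lineno, raw in enumerate(lines[idx:], start=idx + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop += 1
            continue
        if "," not in line:
            raise GenotypeFormatError(
                f"{path}:{lineno}: expected 'id , genotypes' (missing comma)"
            )
        ind_id, _, geno_part = line.partition(",")
        fields = geno_part.split()
        if len(fields) != J:
            raise GenotypeFormatError(
                f"{path}:{lineno}: {len(fields)} genotype fields, expected {J}"
            )
        row: list[tuple[str, ...] | None] = []
        for f_ in fields:
            if not re.fullmatch(r"\d+", f_):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: non-numeric genotype field {f_!r}"
                )
            if len(f_) % ploidy != 0:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: genotype {f_!r} not divisible into "
                    f"{ploidy} allele codes"
                )
            w = len(f_) // ploidy
            if w not in (2, 3):
                raise GenotypeFormatError(
                    f"{path}:{lineno}: allele code width {w} (expected 2 or 3)"
                )
            if width is None:
                width = w
            elif w != width:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: inconsistent allele-code width "
                    f"({w} vs {width})"
                )
            alleles = tuple(f_[k * w : (k + 1) * w] for k in range(ploidy))
            if all(int(a) == 0 for a in alleles):
                row.append(None)
            else:
                row.append(alleles)
        genotypes.append(row)
        ids.append(ind_id.strip())
        pop_labels.append(max(pop, 0))
    return (
        _build_matrix(genotypes, ploidy, locus_names, ids, allow_monomorphic),
        pop_labels,
    )


def write_genepop(g: GenotypeMatrix, path: str | Path, title: str = "genoclust export") -> None:
    """Write a Genepop file (single POP block, 3-digit allele codes)."""
    path = Path(path)
    label_code = [
        {a: f"{k + 1:03d}" for k, a in enumerate(labels)} for labels in g.allele_labels
    ]
    out = [title, ",".join(g.locus_names), "pop"]
    for i in range(g.n_individuals):
        fields = []
        for j in range(g.n_loci):
            if g.missing_mask[i, j]:
                fields.append("000" * g.ploidy)
                continue
            block = g.counts[i, g.locus_slice(j)]
            codes = []
            for k, c in enumerate(block):
                codes.extend([label_code[j][g.allele_labels[j][k]]] * int(c))
            fields.append("".join(codes))
        out.append(f"{g.individual_ids[i]} , " + " ".join(fields))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE text
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    ploidy: int = 2,
    one_row_per_individual: bool = False,
    missing_code: str = "-9",
    has_header: bool = True,
    allow_monomorphic: bool = False,
) -> GenotypeMatrix:
    """Read a whitespace-delimited STRUCTURE table.

    Two dialects: two-row (``ploidy`` consecutive rows per individual, one
    allele per locus per row) or one-row (``ploidy`` consecutive columns per
    locus).  A genotype is missing if any of its allele entries equals
    ``missing_code``.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise GenotypeFormatError(f"{path}: empty file")
    header: list[str] | None = None
    data_rows = [ln.split() for ln in lines]
    if has_header:
        header = data_rows[0]
        data_rows = data_rows[1:]
    if not data_rows:
        raise GenotypeFormatError(f"{path}: no data rows")
    if one_row_per_individual:
        n_cols = len(data_rows[0]) - 1
        if n_cols % ploidy != 0:
            raise GenotypeFormatError(
                f"{path}: {n_cols} genotype columns not divisible by ploidy {ploidy}"
            )
        J = n_cols // ploidy
        locus_names = header[:J] if header and len(header) >= J else [
            f"L{j + 1}" for j in range(J)
        ]
        genotypes, ids = [], []
        for row in data_rows:
            ids.append(row[0])
            vals = row[1:]
            geno_row: list[tuple[str, ...] | None] = []
            for j in range(J):
                alleles = tuple(vals[j * ploidy : (j + 1) * ploidy])
                geno_row.append(None if missing_code in alleles else alleles)
            genotypes.append(geno_row)
    else:
        if len(data_rows) % ploidy != 0:
            raise GenotypeFormatError(
                f"{path}: {len(data_rows)} data rows not divisible by ploidy {ploidy}"
            )
        J = len(data_rows[0]) - 1
        locus_names = header if header and len(header) == J else [
            f"L{j + 1}" for j in range(J)
        ]
        genotypes, ids = [], []
        for i in range(0, len(data_rows), ploidy):
            block = data_rows[i : i + ploidy]
            ids.append(block[0][0])
            geno_row = []
            for j in range(J):
                alleles = tuple(block[c][j + 1] for c in range(ploidy))
                geno_row.append(None if missing_code in alleles else alleles)
            genotypes.append(geno_row)
    return _build_matrix(genotypes, ploidy, locus_names, ids, allow_monomorphic)


def write_structure(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the two-row STRUCTURE dialect with a locus-name header."""
    path = Path(path)
    out = ["\t".join(g.locus_names)]
    for i in range(g.n_individuals):
        rows = [[g.individual_ids[i]] for _ in range(g.ploidy)]
        for j in range(g.n_loci):
            if g.missing_mask[i, j]:
                for r in rows:
                    r.append("-9")
                continue
            block = g.counts[i, g.locus_slice(j)]
            alleles: list[str] = []
            for k, c in enumerate(block):
                alleles.extend([g.allele_labels[j][k]] * int(c))
            for c, r in enumerate(rows):
                r.append(alleles[c])
        out.extend("\t".join(r) for r in rows)
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV allele-count matrix
# ---------------------------------------------------------------------------

def write_counts_csv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the documented CSV dialect: header ``id,<locus>.<allele>,...``,
    one integer cell per allele column, empty cells for missing genotypes."""
    path = Path(path)
    cols = [
        f"{g.locus_names[j]}.{a}"
        for j in range(g.n_loci)
        for a in g.allele_labels[j]
    ]
    lines = ["id," + ",".join(cols)]
    col_locus = np.repeat(np.arange(g.n_loci), g.n_alleles_per_locus)
    for i in range(g.n_individuals):
        cells = [
            "" if g.missing_mask[i, col_locus[p]] else str(int(g.counts[i, p]))
            for p in range(g.total_alleles)
        ]
        lines.append(f"{g.individual_ids[i]}," + ",".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_counts_csv(
    path: str | Path, ploidy: int = 2, allow_monomorphic: bool = False
) -> GenotypeMatrix:
    """Read the CSV allele-count dialect written by :func:`write_counts_csv`."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    header = lines[0].split(",")
    if header[0] != "id":
        raise GenotypeFormatError(f"{path}: header must start with 'id'")
    locus_names: list[str] = []
    allele_labels: list[list[str]] = []
    for col in header[1:]:
        locus, dot, allele = col.rpartition(".")
        if not dot:
            raise GenotypeFormatError(f"{path}: column {col!r} lacks '<locus>.<allele>'")
        if not locus_names or locus_names[-1] != locus:
            locus_names.append(locus)
            allele_labels.append([])
        allele_labels[-1].append(allele)
    offsets = np.concatenate([[0], np.cumsum([len(a) for a in allele_labels])])
    J, P = len(locus_names), int(offsets[-1])
    ids, count_rows, miss_rows = [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != P + 1:
            raise GenotypeFormatError(
                f"{path}:{lineno}: {len(cells) - 1} cells, expected {P}"
            )
        ids.append(cells[0])
        row = np.zeros(P, dtype=np.int64)
        miss = np.zeros(J, dtype=bool)
        for j in range(J):
            block = cells[1 + offsets[j] : 1 + offsets[j + 1]]
            if all(c == "" for c in block):
                miss[j] = True
                continue
            try:
                vals = [int(c) for c in block]
            except ValueError as e:
                raise GenotypeFormatError(f"{path}:{lineno}: non-integer cell") from e
            if sum(vals) != ploidy:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: individual {len(ids)} locus {j + 1} counts "
                    f"sum to {sum(vals)}, expected ploidy {ploidy}"
                )
            row[offsets[j] : offsets[j + 1]] = vals
        count_rows.append(row)
        miss_rows.append(miss)
    return GenotypeMatrix(
        counts=np.array(count_rows),
        ploidy=ploidy,
        locus_names=locus_names,
        allele_labels=allele_labels,
        individual_ids=ids,
        missing_mask=np.array(miss_rows),
        allow_monomorphic=allow_monomorphic,
    )


# ---------------------------------------------------------------------------
# VCF (biallelic sites)
# ---------------------------------------------------------------------------

def read_vcf_biallelic(path: str | Path, allow_monomorphic: bool = False) -> GenotypeMatrix:
    """Read GT fields from a VCF, keeping only biallelic sites.

    Non-biallelic sites are skipped (count logged).  ``./.`` (or any GT with
    a missing allele) becomes a missing genotype.  Ploidy is taken from the
    first parsed GT.  The allele universe of every site is the declared
    REF/ALT pair (labels "0" and "1"), even if one allele is unobserved.
    """
    path = Path(path)
    sample_ids: list[str] = []
    site_names: list[str] = []
    rows: list[list[tuple[str, ...] | None]] = []
    n_skipped = 0
    ploidy: int | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                if not sample_ids:
                    raise GenotypeFormatError(f"{path}: no sample columns")
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise GenotypeFormatError(f"{path}: record with no genotypes")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or alt in (".", "") or len(ref.split(",")) != 1:
                n_skipped += 1
                continue
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                n_skipped += 1
                continue
            name = vid if vid not in (".", "") else f"{chrom}:{pos}"
            site_row: list[tuple[str, ...] | None] = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx]
                alleles = re.split(r"[/|]", gt)
                if ploidy is None:
                    ploidy = len(alleles)
                if "." in alleles:
                    site_row.append(None)
                else:
                    site_row.append(tuple(alleles))
            site_names.append(name)
            rows.append(site_row)
    if not rows:
        raise GenotypeFormatError(f"{path}: no biallelic sites with GT found")
    if n_skipped:
        logger.info("%s: skipped %d non-biallelic site(s)", path, n_skipped)
    assert ploidy is not None
    # transpose site-major -> individual-major
    genotypes = [[rows[j][i] for j in range(len(rows))] for i in range(len(sample_ids))]
    g = _build_matrix(
        genotypes, ploidy, site_names, list(sample_ids), allow_monomorphic,
        fixed_allele_labels=[["0", "1"] for _ in rows],
    )
    g.n_sites_skipped = n_skipped  # type: ignore[attr-defined]
    return g
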