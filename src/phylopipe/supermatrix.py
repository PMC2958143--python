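"""Supermatrix construction and descriptive statistics.

Gene alignments are concatenated end-to-end into a partitioned character
matrix. Five partitioning schemes are materialized: by gene, exon vs intron,
codon positions plus intron, a fixed number of equal-length blocks, and a
single partition. Statistics follow the conventions of classic supermatrix
studies: variable / parsimony-informative site counts, per-taxon base
composition with a chi-square homogeneity test, pooled transition:transversion
ratio, and p / Kimura two-parameter distances with pairwise deletion of
missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from Bio import SeqIO

__all__ = [
    "GeneAlignment",
    "ConcatenatedMatrix",
    "DistanceMatrix",
    "concatenate",
    "site_classes",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "base_composition",
    "chi_square_homogeneity",
    "ti_tv_ratio",
    "per_gene_report",
    "equal_blocks",
]

# character codes: ACGT = 0..3; 4 '-', 5 '?', 6 'N' all treated as missing
CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "?": 5, "N": 6}
DECODE = np.array(list("ACGT-?N"))
MISSING_THRESHOLD = 4  # code >= 4 => not an unambiguous base

# site-annotation codes
CODON1, CODON2, CODON3, INTRON = 0, 1, 2, 3
ANNOT_NAMES = {CODON1: "codon1", CODON2: "codon2", CODON3: "codon3", INTRON: "intron"}

_PURINES = frozenset((0, 2))  # A, G


def encode_rows(rows: Sequence[str]) -> np.ndarray:
    table = np.full(256, 255, dtype=np.uint8)
    for ch, code in CODES.items():
        table[ord(ch)] = code
        table[ord(ch.lower())] = code
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    out = table[arr]
    if np.any(out == 255):
        bad = chr(arr[out == 255][0])
        raise ValueError(f"unsupported character {bad!r} in alignment")
    return out.reshape(len(rows), -1)


def decode_rows(data: np.ndarray) -> list[str]:
    return ["".join(DECODE[row]) for row in data]


@dataclass
class GeneAlignment:
    """One aligned locus: nucleotide rows plus exon/intron site annotation."""

    gene_id: str
    taxa: list[str]
    rows: list[str]
    site_annotation: np.ndarray  # int8, codes CODON1..INTRON per column

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in gene alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows of unequal length")
        self.site_annotation = np.asarray(self.site_annotation, dtype=np.int8)
        if self.site_annotation.shape != (self.length,):
            raise ValueError("annotation length != alignment length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def exon_fraction(self) -> float:
        if self.length == 0:
            return 0.0
        return float(np.mean(self.site_annotation != INTRON))

    def encoded(self) -> np.ndarray:
        return encode_rows(self.rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, r in zip(self.taxa, self.rows):
                fh.write(f">{t}\n{r}\n")

    @classmethod
    def from_fasta(cls, path, gene_id: Optional[str] = None,
                   site_annotation: Optional[np.ndarray] = None) -> "GeneAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"empty FASTA {path}")
        taxa = [r.id for r in recs]
        rows = [str(r.seq).upper() for r in recs]
        if site_annotation is None:
            site_annotation = _default_annotation(len(rows[0]), 1.0)
        return cls(gene_id or Path(str(path)).stem, taxa, rows, site_annotation)


def _default_annotation(length: int, exon_fraction: float) -> np.ndarray:
    """Leading exon block (codon positions cycling 1,2,3) then intron."""
    n_exon = int(round(length * exon_fraction))
    ann = np.full(length, INTRON, dtype=np.int8)
    ann[:n_exon] = np.arange(n_exon) % 3
    return ann


def equal_blocks(total: int, k: int) -> list[np.ndarray]:
    """Balanced partition of range(total) into k contiguous blocks whose
    sizes differ by at most 1."""
    if k < 1 or total < k:
        raise ValueError("need total >= k >= 1")
    bounds = np.linspace(0, total, k + 1).round().astype(int)
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(k)]


@dataclass
class ConcatenatedMatrix:
    """Supermatrix with partition map and missing-data mask."""

    taxa: list[str]
    data: np.ndarray                 # uint8 (n_taxa, length) of CODES
    site_annotation: np.ndarray      # int8 per column
    gene_spans: list[tuple[str, int, int]]  # (gene_id, start, end)
    schemes: dict = field(default_factory=dict)  # name -> {part: index array}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("row count != taxa count")
        if not self.schemes:
            self.schemes = self._build_schemes()
        self._validate_schemes()

    @property
    def length(self) -> int:
        return self.data.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data >= MISSING_THRESHOLD

    def rows(self) -> list[str]:
        return decode_rows(self.data)

    def _build_schemes(self) -> dict:
        L = self.length
        ann = self.site_annotation
        by_gene = {g: np.arange(s, e) for g, s, e in self.gene_spans}
        exon_intron = {
            "exon": np.flatnonzero(ann != INTRON),
            "intron": np.flatnonzero(ann == INTRON),
        }
        codon_intron = {
            "codon1": np.flatnonzero(ann == CODON1),
            "codon2": np.flatnonzero(ann == CODON2),
            "codon3": np.flatnonzero(ann == CODON3),
            "intron": np.flatnonzero(ann == INTRON),
        }
        n_blocks = min(7, L)
        equal7 = {f"block{i+1}": idx for i, idx in enumerate(equal_blocks(L, n_blocks))}
        single = {"all": np.arange(L)}
        schemes = {
            "by_gene": by_gene,
            "exon_intron": {k: v for k, v in exon_intron.items() if v.size},
            "codon_intron": {k: v for k, v in codon_intron.items() if v.size},
            "equal7": equal7,
            "single": single,
        }
        return schemes

    def _validate_schemes(self):
        L = self.length
        for name, parts in self.schemes.items():
            seen = np.zeros(L, dtype=bool)
            for idx in parts.values():
                if np.any(seen[idx]):
                    raise ValueError(f"scheme {name}: overlapping site sets")
                seen[idx] = True
            if not seen.all():
                raise ValueError(f"scheme {name}: site sets do not cover matrix")

    # ------------------------------------------------------------------
    def subset(self, columns: np.ndarray) -> "ConcatenatedMatrix":
        cols = np.asarray(columns)
        return ConcatenatedMatrix(
            taxa=list(self.taxa),
            data=self.data[:, cols],
            site_annotation=self.site_annotation[cols],
            gene_spans=[("subset", 0, cols.size)],
            schemes={"single": {"all": np.arange(cols.size)}},
        )

    def write_nexus(self, path, include_sets: bool = True) -> None:
        rows = self.rows()
        pad = max(len(t) for t in self.taxa) + 2
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={self.n_taxa} NCHAR={self.length};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            for t, r in zip(self.taxa, rows):
                safe = t.replace(" ", "_")
                fh.write(f"    {safe:<{pad}}{r}\n")
            fh.write("  ;\nEND;\n")
            if include_sets:
                fh.write("\nBEGIN SETS;\n")
                for scheme, parts in self.schemes.items():
                    for part, idx in parts.items():
                        ranges = _index_ranges(idx)
                        spec = " ".join(
                            f"{a+1}-{b+1}" if b > a else f"{a+1}" for a, b in ranges
                        )
                        fh.write(f"  CHARSET {scheme}_{part} = {spec};\n")
                fh.write("END;\n")


def _index_ranges(idx: np.ndarray) -> list[tuple[int, int]]:
    if idx.size == 0:
        return []
    idx = np.sort(idx)
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


# ----------------------------------------------------------------------
def concatenate(genes: Sequence[GeneAlignment],
                taxa: Optional[Sequence[str]] = None) -> ConcatenatedMatrix:
    """Concatenate gene alignments in input order.

    Taxa absent from a gene get all-'?' rows for that gene's columns.
    """
    if not genes:
        raise ValueError("empty gene list")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    if taxa is None:
        taxa = []
        for g in genes:
            for t in g.taxa:
                if t not in taxa:
                    taxa.append(t)
    taxa = list(taxa)
    for g in genes:
        extra = set(g.taxa) - set(taxa)
        if extra:
            raise ValueError(f"gene {g.gene_id} has taxa outside master list: {extra}")
    total = sum(g.length for g in genes)
    data = np.full((len(taxa), total), CODES["?"], dtype=np.uint8)
    ann = np.empty(total, dtype=np.int8)
    spans = []
    offset = 0
    tindex = {t: i for i, t in enumerate(taxa)}
    for g in genes:
        enc = g.encoded()
        for row_i, t in enumerate(g.taxa):
            data[tindex[t], offset:offset + g.length] = enc[row_i]
        ann[offset:offset + g.length] = g.site_annotation
        spans.append((g.gene_id, offset, offset + g.length))
        offset += g.length
    return ConcatenatedMatrix(taxa=taxa, data=data, site_annotation=ann,
                              gene_spans=spans)


# ----------------------------------------------------------------------
# site classification
# ----------------------------------------------------------------------
def site_classes(data: np.ndarray) -> dict:
    """Classify columns as constant / variable / parsimony-informative.

    Missing characters and gaps are ignored. A column is variable when >= 2
    distinct unambiguous states occur; parsimony-informative when >= 2 states
    each occur in >= 2 rows. Percentages use total columns as denominator.
    """
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a matrix with >= 2 rows")
    if data.shape[1] == 0:
        raise ValueError("zero-length matrix")
    n_taxa, L = data.shape
    counts = np.zeros((4, L), dtype=np.int32)
    for b in range(4):
        counts[b] = (data == b).sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    n_ge2 = (counts >= 2).sum(axis=0)
    variable = n_states >= 2
    informative = n_ge2 >= 2
    classes = np.where(informative, 2, np.where(variable, 1, 0)).astype(np.int8)
    return {
        "classes": classes,  # 0 constant, 1 variable-only, 2 informative
        "n_variable": int(variable.sum()),
        "n_informative": int(informative.sum()),
        "n_total": int(L),
        "pct_variable": 100.0 * variable.sum() / L,
        "pct_informative": 100.0 * informative.sum() / L,
    }


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------
def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(n comparable sites, transitions, transversions) with pairwise deletion."""
    ok = (a < MISSING_THRESHOLD) & (b < MISSING_THRESHOLD)
    a, b = a[ok], b[ok]
    diff = a != b
    if not diff.any():
        return a.size, 0, 0
    da, db = a[diff], b[diff]
    ti = ((da == 0) & (db == 2)) | ((da == 2) & (db == 0)) \
        | ((da == 1) & (db == 3)) | ((da == 3) & (db == 1))
    n_ti = int(ti.sum())
    return a.size, n_ti, int(diff.sum()) - n_ti


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    n, ti, tv = _pair_counts(a, b)
    if n == 0:
        raise ValueError("no comparable sites")
    return (ti + tv) / n


def k2p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Kimura two-parameter distance; returns inf when saturated
    (logarithm argument <= 0)."""
    n, ti, tv = _pair_counts(a, b)
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ti / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    estimator: str  # "p" | "k2p"

    def __post_init__(self):
        v = self.values
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("nonzero diagonal")
        finite = np.isfinite(v)
        if not np.array_equal(v[finite], v.T[finite.T]):
            raise ValueError("asymmetric distance matrix")

    @property
    def saturated(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def distance_matrix(matrix: ConcatenatedMatrix, estimator: str = "k2p") -> DistanceMatrix:
    fn = {"p": p_distance, "k2p": k2p_distance}[estimator]
    n = matrix.n_taxa
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(matrix.data[i], matrix.data[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(matrix.taxa), out, estimator)


# ----------------------------------------------------------------------
# composition
# ----------------------------------------------------------------------
def base_counts(data: np.ndarray) -> np.ndarray:
    """(n_taxa, 4) counts of unambiguous A, C, G, T per row."""
    return np.stack([(data == b).sum(axis=1) for b in range(4)], axis=1)


def base_composition(matrix: ConcatenatedMatrix, per_taxon: bool = True) -> pd.DataFrame:
    counts = base_counts(matrix.data)
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        bad = matrix.taxa[int(np.argmin(totals))]
        raise ValueError(f"taxon {bad} has zero unambiguous sites")
    freqs = counts / totals
    df = pd.DataFrame(freqs, index=matrix.taxa, columns=list("ACGT"))
    overall = counts.sum(axis=0) / counts.sum()
    df.loc["overall"] = overall
    return df if per_taxon else df.loc[["overall"]]


def chi_square_homogeneity(matrix: ConcatenatedMatrix,
                           columns: Optional[np.ndarray] = None) -> tuple[float, int, float]:
    """Chi-square test of base-composition homogeneity across taxa.

    Expected counts derive from the pooled composition; df = (n_taxa-1) * 3.
    Cells whose expected count is zero contribute nothing.
    """
    data = matrix.data if columns is None else matrix.data[:, columns]
    counts = base_counts(data).astype(float)
    row_tot = counts.sum(axis=1)
    keep = row_tot > 0
    counts, row_tot = counts[keep], row_tot[keep]
    n_taxa = counts.shape[0]
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa with unambiguous sites")
    pooled = counts.sum(axis=0) / counts.sum()
    expected = row_tot[:, None] * pooled[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(cells.sum())
    df = (n_taxa - 1) * 3
    p = float(chi2.sf(stat, df))
    return stat, df, p


def ti_tv_ratio(matrix: ConcatenatedMatrix) -> float:
    """Pooled transitions / transversions over all taxon pairs; NaN when the
    transversion count is zero (undefined, not infinity)."""
    n = matrix.n_taxa
    if n < 2:
        raise ValueError("need >= 2 rows")
    ti_tot = tv_tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            _, ti, tv = _pair_counts(matrix.data[i], matrix.data[j])
            ti_tot += ti
            tv_tot += tv
    if tv_tot == 0:
        return math.nan
    return ti_tot / tv_tot


# ----------------------------------------------------------------------
def per_gene_report(genes: Sequence[GeneAlignment]) -> pd.DataFrame:
    """Per-locus statistics table plus an aggregate row for the concatenation."""
    if not genes:
        raise ValueError("need >= 1 gene")
    rows = []
    for g in genes:
        data = g.encoded()
        sc = site_classes(data) if data.shape[0] >= 2 else {
            "n_variable": 0, "n_informative": 0}
        pd_vals = []
        for i in range(data.shape[0]):
            for j in range(i + 1, data.shape[0]):
                ok = (data[i] < MISSING_THRESHOLD) & (data[j] < MISSING_THRESHOLD)
                if ok.any():
                    pd_vals.append(float(np.mean(data[i][ok] != data[j][ok])))
        counts = base_counts(data).sum(axis=0)
        comp = counts / counts.sum() if counts.sum() else np.full(4, np.nan)
        rows.append({
            "gene": g.gene_id,
            "length": g.length,
            "pct_exon": 100.0 * g.exon_fraction,
            "n_variable": sc["n_variable"],
            "n_informative": sc["n_informative"],
            "mean_p_distance": float(np.mean(pd_vals)) if pd_vals else 0.0,
            "freq_A": comp[0], "freq_C": comp[1],
            "freq_G": comp[2], "freq_T": comp[3],
        })
    cat = concatenate(list(genes))
    sc = site_classes(cat.data)
    counts = base_counts(cat.data).sum(axis=0)
    comp = counts / counts.sum()
    pd_all = []
    for i in range(cat.n_taxa):
        for j in range(i + 1, cat.n_taxa):
            try:
                pd_all.append(p_distance(cat.data[i], cat.data[j]))
            except ValueError:
                pass
    rows.append({
        "gene": "concatenated",
        "length": cat.length,
        "pct_exon": 100.0 * float(np.mean(cat.site_annotation != INTRON)),
        "n_variable": sc["n_variable"],
        "n_informative": sc["n_informative"],
        "mean_p_distance": float(np.mean(pd_all)) if pd_all else 0.0,
        "freq_A": comp[0], "freq_C": comp[1],
        "freq_G": comp[2], "freq_T": comp[3],
    })
    return pd.DataFrame(rows)
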