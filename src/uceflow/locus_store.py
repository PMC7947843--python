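"""Per-locus alignment storage, completeness filtering, and supermatrices.

A *locus* is one UCE-style alignment: an (taxa x sites) character matrix
over ``A C G T``, gaps and IUPAC ambiguity codes.  Loci are read and
written one per file (FASTA or NEXUS, via dendropy), can be filtered by
taxon-completeness thresholds (the 75p / 90p style matrices), and can be
concatenated into a supermatrix with 1-based inclusive charset ranges in
the NEXUS convention.  Internally all site coordinates are 0-based
half-open; only emitted charsets use the 1-based inclusive dialect.
"""

from __future__ import annotations

import io
import json
import pathlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "LocusAlignment", "Supermatrix", "LocusFormatError",
    "COMPLETENESS_75P", "COMPLETENESS_90P",
    "read_locus", "read_loci", "write_locus_fasta", "write_locus_nexus",
    "filter_by_completeness", "concatenate", "write_supermatrix_nexus",
    "write_raxml_partitions", "coverage_table",
]

#: Named completeness presets from the 75p / 90p matrix convention.
COMPLETENESS_75P = 0.75
COMPLETENESS_90P = 0.90

# IUPAC nucleotide codes -> 4-bit mask over (A, C, G, T)
IUPAC_MASKS: dict[str, int] = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111, "?": 0b1111,
    "X": 0b1111,
}

UNAMBIGUOUS = frozenset("ACGT")


class LocusFormatError(ValueError):
    """Raised when an alignment file cannot be interpreted."""


@dataclass
class LocusAlignment:
    """One locus: an aligned character matrix with a stable taxon order.

    ``matrix`` has dtype ``'U1'`` and shape ``(n_taxa, n_sites)``; states
    are uppercase IUPAC codes, ``-`` for gaps.
    """

    locus_id: str
    taxa: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise LocusFormatError(
                f"locus {self.locus_id}: matrix must be 2-D")
        if len(self.taxa) != self.matrix.shape[0]:
            raise LocusFormatError(
                f"locus {self.locus_id}: {len(self.taxa)} labels for "
                f"{self.matrix.shape[0]} rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise LocusFormatError(
                f"locus {self.locus_id}: duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def slice_sites(self, left: int, right: int,
                    locus_id: str | None = None) -> "LocusAlignment":
        """Sub-alignment of columns ``[left, right)``."""
        return LocusAlignment(locus_id or self.locus_id, self.taxa,
                              self.matrix[:, left:right])

    def subset_taxa(self, keep: list[str]) -> "LocusAlignment":
        idx = [self.taxa.index(t) for t in keep]
        return LocusAlignment(self.locus_id, tuple(keep), self.matrix[idx])

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])


@dataclass
class Supermatrix:
    """Concatenation of loci with a charset table.

    ``charsets`` maps a partition name to a 1-based inclusive site range
    ``(start, end)``; ranges are contiguous, non-overlapping and cover
    every column.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    charsets: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def as_alignment(self, locus_id: str = "supermatrix") -> LocusAlignment:
        return LocusAlignment(locus_id, self.taxa, self.matrix)


# --------------------------------------------------------------------- input

def _normalize_label(label: str) -> str:
    return " ".join(label.split())


def _from_char_matrix(cm: dendropy.DnaCharacterMatrix, locus_id: str,
                      source: str) -> LocusAlignment:
    taxa, rows = [], []
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        taxa.append(_normalize_label(taxon.label))
        rows.append(list(str(seq.symbols_as_string()).upper()))
    if not rows:
        raise LocusFormatError(f"{source}: no sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        bad = [t for t, r in zip(taxa, rows) if len(r) != len(rows[0])]
        raise LocusFormatError(
            f"{source}: ragged alignment (rows {bad} differ in length)")
    return LocusAlignment(locus_id, tuple(taxa), np.array(rows, dtype="U1"))


def read_locus(path, format: str = "fasta",
               locus_id: str | None = None) -> LocusAlignment:
    """Read a single locus alignment from ``path``.

    ``format`` is ``"fasta"`` or ``"nexus"``.  Taxon-label whitespace is
    normalized and states uppercased.  Errors name the offending file.
    """
    path = pathlib.Path(path)
    if format not in ("fasta", "nexus"):
        raise ValueError(f"unknown format {format!r}")
    if locus_id is None:
        locus_id = path.stem
    text = path.read_text()
    if not text.strip():
        raise LocusFormatError(f"{path}: empty file")
    kwargs = {"preserve_underscores": True} if format == "nexus" else {}
    try:
        cm = dendropy.DnaCharacterMatrix.get(data=text, schema=format,
                                             **kwargs)
    except Exception as exc:  # dendropy raises a zoo of parse errors
        raise LocusFormatError(f"{path}: {exc}") from exc
    return _from_char_matrix(cm, locus_id, str(path))


def read_loci(paths, format: str = "fasta") -> list[LocusAlignment]:
    """Read one :class:`LocusAlignment` per file."""
    return [read_locus(p, format=format) for p in paths]


# -------------------------------------------------------------------- output

def write_locus_fasta(locus: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for i, taxon in enumerate(locus.taxa):
            fh.write(f">{taxon}\n")
            fh.write("".join(locus.matrix[i]) + "\n")


def write_locus_nexus(locus: LocusAlignment, path) -> None:
    d = {t: "".join(locus.matrix[i]) for i, t in enumerate(locus.taxa)}
    cm = dendropy.DnaCharacterMatrix.from_dict(d)
    cm.write(path=str(path), schema="nexus")


# ----------------------------------------------------------------- filtering

def filter_by_completeness(loci, total_taxa: int,
                           threshold: float) -> list[LocusAlignment]:
    """Retain loci with at least ``threshold`` of ``total_taxa`` sampled.

    The comparison is inclusive (>=): a locus with exactly 75% of the
    taxa survives the 75p filter.  Order is preserved; the operation is
    idempotent.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if total_taxa < max((l.n_taxa for l in loci), default=0):
        raise ValueError("total_taxa smaller than a locus's taxon count")
    return [l for l in loci if l.n_taxa / total_taxa >= threshold]


# ------------------------------------------------------------- concatenation

def concatenate(loci, scheme: dict | None = None) -> Supermatrix:
    """Concatenate loci into a supermatrix.

    Taxa missing from a locus get all-gap rows for that block.  With no
    ``scheme``, one charset per locus is emitted; with a ``scheme``
    mapping locus id -> :class:`~uceflow.swsc_partitioner.PartitionScheme`,
    each partitioned locus contributes ``_Lflank``/``_core``/``_Rflank``
    charsets instead.
    """
    if not loci:
        raise ValueError("need at least one locus")
    taxa: list[str] = []
    seen_fold: dict[str, str] = {}
    for locus in loci:
        for t in locus.taxa:
            if t not in taxa:
                if t.casefold() in seen_fold and seen_fold[t.casefold()] != t:
                    raise ValueError(
                        f"taxon labels differ only by case: "
                        f"{seen_fold[t.casefold()]!r} vs {t!r}")
                seen_fold[t.casefold()] = t
                taxa.append(t)
    total = sum(l.n_sites for l in loci)
    matrix = np.full((len(taxa), total), "-", dtype="U1")
    index = {t: i for i, t in enumerate(taxa)}
    charsets: list[tuple[str, int, int]] = []
    offset = 0
    for locus in loci:
        rows = [index[t] for t in locus.taxa]
        matrix[rows, offset:offset + locus.n_sites] = locus.matrix
        if scheme is not None and scheme.get(locus.locus_id) is not None:
            ps = scheme[locus.locus_id]
            segs = [("Lflank", 0, ps.left), ("core", ps.left, ps.right),
                    ("Rflank", ps.right, locus.n_sites)]
            for name, a, b in segs:
                charsets.append((f"{locus.locus_id}_{name}",
                                 offset + a + 1, offset + b))
        else:
            charsets.append((locus.locus_id, offset + 1,
                             offset + locus.n_sites))
        offset += locus.n_sites
    return Supermatrix(tuple(taxa), matrix, charsets)


def write_supermatrix_nexus(sm: Supermatrix, path) -> None:
    """NEXUS with a ``sets`` block holding the charsets."""
    d = {t: "".join(sm.matrix[i]) for i, t in enumerate(sm.taxa)}
    cm = dendropy.DnaCharacterMatrix.from_dict(d)
    buf = io.StringIO()
    cm.write(file=buf, schema="nexus")
    lines = [buf.getvalue().rstrip(), "", "BEGIN SETS;"]
    for name, start, end in sm.charsets:
        lines.append(f"    charset {name} = {start}-{end};")
    lines.append("END;")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def write_raxml_partitions(sm: Supermatrix, path, model: str = "DNA") -> None:
    with open(path, "w") as fh:
        for name, start, end in sm.charsets:
            fh.write(f"{model}, {name} = {start}-{end}\n")


# ----------------------------------------------------------------- distances

def pairwise_p_distances(locus: LocusAlignment) -> np.ndarray:
    """Uncorrected p-distance matrix with pairwise deletion.

    Gaps and ambiguity codes are treated as missing.  Pairs with no
    overlapping unambiguous sites get ``nan``.
    """
    n = locus.n_taxa
    valid = np.isin(locus.matrix, list(UNAMBIGUOUS))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                D[i, j] = D[j, i] = np.nan
            else:
                diff = (locus.matrix[i, both] != locus.matrix[j, both]).sum()
                D[i, j] = D[j, i] = diff / m
    return D


# ------------------------------------------------------------------- reports

def coverage_table(loci, total_taxa: int):
    """Per-locus taxon coverage as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "locus": [l.locus_id for l in loci],
        "n_taxa": [l.n_taxa for l in loci],
        "n_sites": [l.n_sites for l in loci],
        "coverage": [l.n_taxa / total_taxa for l in loci],
    })


def write_manifest(path, **fields) -> None:
    pathlib.Path(path).write_text(json.dumps(fields, indent=2) + "\n")
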