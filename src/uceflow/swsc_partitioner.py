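"""Entropy-based core/flank partitioning of UCE loci.

Each locus is split into left flank / core / right flank by choosing the
two breakpoints that minimize the summed within-segment sum of squared
errors (SSE) of per-site Shannon entropy about the segment means — a
sliding-window site-characteristics criterion with entropy as the sole
site statistic.  The search is exhaustive over all admissible breakpoint
pairs (O(L^2) with prefix sums), so the reported optimum is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus_store import LocusAlignment

__all__ = [
    "PartitionScheme", "UnpartitionableLocusError", "site_entropy",
    "entropy_profile", "best_breakpoints", "partition_locus",
    "partition_loci", "charsets_for", "DEFAULT_MIN_LEN",
]

#: Minimum segment length in sites; segments must be able to support a
#: substitution-model fit.
DEFAULT_MIN_LEN = 50


class UnpartitionableLocusError(ValueError):
    """Locus too short for three segments of the minimum length."""


@dataclass
class PartitionScheme:
    """Breakpoints (0-based half-open): [0,left), [left,right), [right,L)."""

    locus_id: str
    left: int
    right: int
    length: int
    objective: float

    def __post_init__(self):
        if not (0 < self.left < self.right < self.length):
            raise ValueError("breakpoints out of order")
        if self.objective < -1e-9:
            raise ValueError("negative SSE objective")

    def segment_ranges(self):
        return [(0, self.left), (self.left, self.right),
                (self.right, self.length)]


def site_entropy(column) -> float:
    """Shannon entropy (bits) of base frequencies in one column.

    Gaps/ambiguities are excluded; an all-missing column has entropy 0.
    """
    column = np.asarray(column, dtype="U1")
    counts = np.array([(column == b).sum() for b in "ACGT"], float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_profile(locus: LocusAlignment) -> np.ndarray:
    """Per-site entropy vector; length equals the site count."""
    M = locus.matrix
    counts = np.stack([(M == b).sum(axis=0) for b in "ACGT"]).astype(float)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / np.where(total > 0, total, 1), 0.0)
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=0)


def best_breakpoints(profile: np.ndarray, min_len: int = DEFAULT_MIN_LEN,
                     locus_id: str = "") -> PartitionScheme:
    """Exhaustive minimum-SSE breakpoint pair.

    Ties resolve to the smallest left, then smallest right, breakpoint.
    Raises :class:`UnpartitionableLocusError` when L < 3*min_len.
    """
    H = np.asarray(profile, float)
    L = H.size
    if L < 3 * min_len:
        raise UnpartitionableLocusError(
            f"locus {locus_id or '?'}: {L} sites < 3 x min_len {min_len}")
    S1 = np.concatenate([[0.0], np.cumsum(H)])
    S2 = np.concatenate([[0.0], np.cumsum(H * H)])

    def sse(a, b):
        n = b - a
        s = S1[b] - S1[a]
        return np.maximum((S2[b] - S2[a]) - s * s / n, 0.0)

    best = (np.inf, -1, -1)
    r_max = L - min_len
    for l in range(min_len, L - 2 * min_len + 1):
        r = np.arange(l + min_len, r_max + 1)
        total = sse(0, l) + sse(l, r) + sse(r, L)
        j = int(np.argmin(total))
        if total[j] < best[0]:
            best = (float(total[j]), l, int(r[j]))
    obj, l, r = best
    return PartitionScheme(locus_id, l, r, L, obj)


def partition_locus(locus: LocusAlignment, scheme: PartitionScheme):
    """Split a locus into (left flank, core, right flank) sub-alignments."""
    if scheme.length != locus.n_sites:
        raise ValueError(
            f"scheme length {scheme.length} != locus sites {locus.n_sites}")
    names = ("Lflank", "core", "Rflank")
    return tuple(
        locus.slice_sites(a, b, locus_id=f"{locus.locus_id}_{name}")
        for name, (a, b) in zip(names, scheme.segment_ranges()))


def partition_loci(loci, min_len: int = DEFAULT_MIN_LEN) -> dict:
    """Schemes for a collection; unpartitionable loci map to None."""
    out = {}
    for locus in loci:
        try:
            out[locus.locus_id] = best_breakpoints(
                entropy_profile(locus), min_len, locus.locus_id)
        except UnpartitionableLocusError:
            out[locus.locus_id] = None
    return out


def charsets_for(scheme: PartitionScheme):
    """1-based inclusive charset ranges (NEXUS convention)."""
    names = ("Lflank", "core", "Rflank")
    return [(f"{scheme.locus_id}_{name}", a + 1, b)
            for name, (a, b) in zip(names, scheme.segment_ranges())]


def write_breakpoint_table(schemes: dict, path) -> None:
    import pandas as pd

    rows = []
    for locus_id, s in schemes.items():
        if s is None:
            rows.append({"locus": locus_id, "left": -1, "right": -1,
                         "objective": np.nan, "partitionable": False})
        else:
            rows.append({"locus": locus_id, "left": s.left, "right": s.right,
                         "objective": s.objective, "partitionable": True})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
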