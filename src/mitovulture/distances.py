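"""Pairwise genetic distances over per-gene alignments and concatenations.

The default statistic is the uncorrected p-distance with pairwise deletion,
reported as a percentage: columns where either sequence of a pair carries a
gap or ambiguity are excluded for that pair, and the distance is
100 x mismatches / used sites.  A Poisson-corrected variant
(-100 x ln(1 - p)) and complete deletion (drop a column if *any* taxon has a
gap there) are available, covering the common settings of distance tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AlignmentBlock

__all__ = ["MISSING_CHARS", "DistanceMatrix", "p_distance", "distance_matrix", "group_range"]

#: Characters excluded by deletion rules (gap and ambiguity codes).
MISSING_CHARS = frozenset("-.?*XBZJ")


@dataclass
class DistanceMatrix:
    """Symmetric percentage distances with per-pair used-site counts."""

    taxa: list[str]
    values: np.ndarray  # percentages, zero diagonal
    used_sites: np.ndarray

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.taxa):
            for j in range(i + 1, len(self.taxa)):
                rows.append(
                    {
                        "taxon_a": a,
                        "taxon_b": self.taxa[j],
                        "distance": float(self.values[i, j]),
                        "used_sites": int(self.used_sites[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "distance", "used_sites"])


def p_distance(row_a: str, row_b: str, method: str = "p") -> tuple[float, int]:
    """Distance between two equal-length gapped rows, as a percentage.

    Pairwise deletion: a column counts only when neither row has a gap or
    ambiguity character there.  ``method='poisson'`` applies the Poisson
    multiple-hit correction -ln(1 - p).  Raises when no usable column
    remains.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length; align first")
    used = 0
    diff = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x in MISSING_CHARS or y in MISSING_CHARS:
            continue
        used += 1
        if x != y:
            diff += 1
    if used == 0:
        raise ValueError("no usable sites after pairwise deletion")
    p = diff / used
    if method == "poisson":
        if p >= 1.0:
            raise ValueError("Poisson correction undefined at p = 1")
        return 100.0 * -math.log(1.0 - p), used
    if method != "p":
        raise ValueError(f"unknown distance method {method!r}")
    return 100.0 * p, used


def _complete_deletion(rows: dict[str, str]) -> dict[str, str]:
    seqs = list(rows.values())
    keep = [
        i
        for i in range(len(seqs[0]))
        if all(s[i].upper() not in MISSING_CHARS for s in seqs)
    ]
    return {t: "".join(s[i] for i in keep) for t, s in rows.items()}


def _concatenate(blocks: list[AlignmentBlock]) -> AlignmentBlock:
    taxa = set(blocks[0].taxa)
    for b in blocks[1:]:
        if set(b.taxa) != taxa:
            raise ValueError(
                f"taxon sets differ between blocks ({blocks[0].gene!r} vs {b.gene!r}); "
                "cannot concatenate"
            )
    order = blocks[0].taxa
    rows = {t: "".join(b.rows[t] for b in blocks) for t in order}
    return AlignmentBlock(gene="concatenated", rows=rows)


def _matrix_of(block: AlignmentBlock, method: str, deletion: str) -> DistanceMatrix:
    rows = dict(block.rows)
    if deletion == "complete":
        rows = _complete_deletion(rows)
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    taxa = list(rows)
    n = len(taxa)
    values = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    for i in range(n):
        used[i, i] = len(rows[taxa[i]])
        for j in range(i + 1, n):
            d, u = p_distance(rows[taxa[i]], rows[taxa[j]], method=method)
            values[i, j] = values[j, i] = d
            used[i, j] = used[j, i] = u
    return DistanceMatrix(taxa=taxa, values=values, used_sites=used)


def distance_matrix(
    blocks: list[AlignmentBlock] | AlignmentBlock,
    concatenate: bool = True,
    method: str = "p",
    deletion: str = "pairwise",
) -> DistanceMatrix | dict[str, DistanceMatrix]:
    """Distance matrix over one block, a concatenation, or per gene.

    With ``concatenate=True`` (default) the blocks are joined end to end —
    all blocks must then share one taxon set.  With ``concatenate=False`` a
    mapping gene -> matrix is returned.  Under pairwise deletion the
    concatenated p-distance equals the used-site-weighted mean of the
    per-gene p-distances.
    """
    if isinstance(blocks, AlignmentBlock):
        blocks = [blocks]
    if not blocks:
        raise ValueError("no alignment blocks given")
    if concatenate:
        return _matrix_of(_concatenate(blocks), method, deletion)
    return {b.gene: _matrix_of(b, method, deletion) for b in blocks}


def group_range(
    matrix: DistanceMatrix, focal: str, members: list[str]
) -> tuple[float, float]:
    """(min, max) distance from a focal taxon to a set of other taxa,
    rounded to 2 decimals — the "X vs group ranged from a% to b%" summary."""
    ds = [matrix.get(focal, m) for m in members if m != focal]
    if not ds:
        raise ValueError("no comparison taxa supplied")
    return round(min(ds), 2), round(max(ds), 2)
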