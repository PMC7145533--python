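"""Gap-padded supermatrix assembly and matrix statistics.

Per-gene alignments are expanded so every gene carries the full taxon
list (missing taxa get all-gap rows), concatenated in a declared gene
order with half-open column partitions, and thinned to taxa carrying a
minimum number of data positions. Completeness and the distinct
alignment-pattern count summarise the phylogenetic workload of the
result.

"Data" cells are non-gap, non-N characters: N carries no phylogenetic
signal, while partial IUPAC ambiguity still does and counts as data.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .model import Supermatrix

__all__ = [
    "pad_missing_taxa",
    "concatenate",
    "filter_taxa",
    "completeness",
    "distinct_patterns",
    "is_data",
]

_NON_DATA = {"-", "N", "?"}


def is_data(char: str) -> bool:
    """True for characters that carry signal (not gap, N, or ?)."""
    return char.upper() not in _NON_DATA


def pad_missing_taxa(
    alignments: Mapping[str, Mapping[str, str]],
    taxa: Sequence[str],
) -> dict[str, dict[str, str]]:
    """Expand each gene alignment to the full ordered taxon list.

    Absent taxa receive all-gap rows of the gene's aligned length; within
    a gene all present rows must already be equal length (ragged
    alignments are rejected).
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("empty taxa list")
    out: dict[str, dict[str, str]] = {}
    for gene, rows in alignments.items():
        if not rows:
            raise ValueError(f"{gene}: empty alignment")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{gene}: ragged alignment (lengths {sorted(lengths)})")
        L = lengths.pop()
        unknown = set(rows) - set(taxa)
        if unknown:
            raise ValueError(f"{gene}: taxa not in the master list: {sorted(unknown)}")
        out[gene] = {t: rows.get(t, "-" * L) for t in taxa}
    return out


def concatenate(
    completed: Mapping[str, Mapping[str, str]],
    gene_order: Optional[Sequence[str]] = None,
) -> Supermatrix:
    """Concatenate completed per-gene alignments into one supermatrix.

    Columns are laid out in ``gene_order`` (default: mapping order), and
    each gene's half-open column range is recorded as a partition. All
    genes must share the identical taxon list.
    """
    genes = list(gene_order) if gene_order is not None else list(completed)
    if not genes:
        raise ValueError("no genes to concatenate")
    taxa = list(completed[genes[0]])
    for g in genes:
        if list(completed[g]) != taxa:
            raise ValueError(f"{g}: taxon set or order differs across genes")
    partitions = []
    offset = 0
    blocks = []
    for g in genes:
        rows = completed[g]
        L = len(next(iter(rows.values())))
        partitions.append((g, offset, offset + L))
        offset += L
        blocks.append(np.array([list(rows[t]) for t in taxa], dtype="<U1"))
    return Supermatrix(taxa=taxa, partitions=partitions, cells=np.hstack(blocks))


def filter_taxa(matrix: Supermatrix, min_positions: int) -> Supermatrix:
    """Drop taxa with fewer than ``min_positions`` data (non-gap, non-N) cells."""
    if min_positions < 0:
        raise ValueError("min_positions must be >= 0")
    data = _data_mask(matrix.cells)
    keep = data.sum(axis=1) >= min_positions
    return Supermatrix(
        taxa=[t for t, k in zip(matrix.taxa, keep) if k],
        partitions=list(matrix.partitions),
        cells=matrix.cells[keep],
    )


def completeness(matrix: Supermatrix) -> float:
    """Percentage of cells that are data (non-gap, non-N)."""
    if matrix.cells.size == 0:
        raise ValueError("empty supermatrix")
    return 100.0 * float(_data_mask(matrix.cells).mean())


def distinct_patterns(matrix: Supermatrix) -> int:
    """Number of unique columns (case-insensitive; gap and N are states)."""
    if matrix.cells.size == 0:
        raise ValueError("empty supermatrix")
    upper = np.char.upper(matrix.cells)
    cols = {tuple(upper[:, j]) for j in range(upper.shape[1])}
    return len(cols)


def _data_mask(cells: np.ndarray) -> np.ndarray:
    upper = np.char.upper(cells)
    mask = np.ones(upper.shape, dtype=bool)
    for ch in _NON_DATA:
        mask &= upper != ch
    return mask
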