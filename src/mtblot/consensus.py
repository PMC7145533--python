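"""Reference-free consensus calling and reading-frame checks.

The consensus is a per-column plurality call over base counts: depth-0
columns yield N, ties yield the IUPAC ambiguity code over the tied bases
(substitution-only model; indels are out of scope on the exon-concatenated
coordinate system). A consensus is *accepted* only when its gene-wide mean
depth reaches the configured floor. Intactness of the reading frame — the
first-tier criterion — requires a start codon, a single terminal stop under
the universal genetic code, and a low ambiguous-base fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable, IUPACData

from .model import ClassifierConfig, PileupColumn

__all__ = [
    "ConsensusResult",
    "cigar_match_length",
    "cigar_filter",
    "call_consensus",
    "orf_intact",
    "consensus_quality_filter",
]

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_MATCH_OPS = frozenset("M=X")

#: stop codons of the universal genetic code (plant mitochondria use it)
STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)

# frozenset of tied bases -> IUPAC ambiguity code
_IUPAC_BY_BASES = {
    frozenset(bases): code
    for code, bases in IUPACData.ambiguous_dna_values.items()
    if len(bases) > 1 and set(bases) <= set("ACGT")
}

_BASES = np.array(list("ACGT"))


@dataclass
class ConsensusResult:
    """A called consensus with its acceptance evidence."""

    gene_id: str
    sequence: str
    mean_depth: float
    accepted: bool
    readset_id: Optional[str] = None
    orf_intact: Optional[bool] = None
    orf_diagnostics: list[str] = field(default_factory=list)

    @property
    def n_fraction(self) -> float:
        """Fraction of ambiguous characters (anything outside ACGT)."""
        if not self.sequence:
            return 1.0
        plain = sum(1 for c in self.sequence.upper() if c in "ACGT")
        return 1.0 - plain / len(self.sequence)


def cigar_match_length(cigar: str, mode: str = "total") -> int:
    """Aligned-match length of a CIGAR string.

    ``total`` sums all M/=/X bases; ``longest_run`` takes the longest
    contiguous stretch of match operations (adjacent M/=/X merge).
    Malformed strings raise ValueError.
    """
    if not cigar or cigar == "*":
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    if mode == "total":
        return sum(int(n) for n, op in ops if op in _MATCH_OPS)
    if mode == "longest_run":
        best = run = 0
        for n, op in ops:
            if op in _MATCH_OPS:
                run += int(n)
                best = max(best, run)
            else:
                run = 0
        return best
    raise ValueError(f"unknown cigar mode: {mode!r}")


def cigar_filter(records: Iterable, min_match: int = 25, mode: str = "total") -> list:
    """Keep alignment records whose matched length is ≥ ``min_match``.

    Records may be pysam AlignedSegments or anything exposing a
    ``cigarstring`` attribute; plain CIGAR strings are also accepted.
    Records with malformed CIGARs are dropped with a logged warning.
    Order-preserving and idempotent.
    """
    kept = []
    for rec in records:
        cigar = rec if isinstance(rec, str) else getattr(rec, "cigarstring", None)
        try:
            if cigar is None:
                raise ValueError("record has no CIGAR")
            if cigar_match_length(cigar, mode=mode) >= min_match:
                kept.append(rec)
        except ValueError as exc:
            log.warning("dropping record with unusable CIGAR: %s", exc)
    return kept


def call_consensus(
    columns: Sequence[PileupColumn],
    cfg: ClassifierConfig = ClassifierConfig(),
    length: Optional[int] = None,
    readset_id: Optional[str] = None,
    gene_id: Optional[str] = None,
) -> ConsensusResult:
    """Plurality consensus over pileup columns.

    Columns must be position-sorted and unique; positions not supplied are
    treated as zero-count columns (depth 0 → N). ``length`` fixes the gene
    length; by default it is inferred from the last column. The result is
    flagged accepted only when the gene-wide mean depth reaches
    ``cfg.consensus_min_avg_depth``; rejected consensuses are still
    returned, just marked.
    """
    if columns:
        positions = [c.position for c in columns]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("pileup columns must be sorted and free of duplicates")
        gene_ids = {c.gene_id for c in columns}
        if len(gene_ids) > 1:
            raise ValueError(f"pileup columns span several genes: {sorted(gene_ids)}")
        col_gene = gene_ids.pop()
        if gene_id is not None and col_gene != gene_id:
            raise ValueError(
                f"pileup columns for {col_gene!r} passed as gene {gene_id!r}"
            )
        gene_id = col_gene
        inferred = positions[-1] + 1
    else:
        gene_id, inferred = gene_id or "", 0
    L = inferred if length is None else int(length)
    if L < 1:
        raise ValueError("cannot call a consensus over zero positions")
    if columns and columns[-1].position >= L:
        raise ValueError("pileup column beyond declared gene length")

    counts = np.zeros((L, 4), dtype=np.int64)
    for c in columns:
        counts[c.position] = [c.counts[b] for b in "ACGT"]
    depths = counts.sum(axis=1)
    mean_depth = float(depths.mean())

    top = counts.max(axis=1)
    chars = []
    for i in range(L):
        if depths[i] == 0:
            chars.append("N")
            continue
        winners = _BASES[counts[i] == top[i]]
        if len(winners) == 1:
            chars.append(winners[0])
        else:
            chars.append(_IUPAC_BY_BASES[frozenset(winners)])
    return ConsensusResult(
        gene_id=gene_id,
        sequence="".join(chars),
        mean_depth=mean_depth,
        accepted=mean_depth >= cfg.consensus_min_avg_depth,
        readset_id=readset_id,
    )


def orf_intact(seq: str, cfg: ClassifierConfig = ClassifierConfig()) -> tuple[bool, list[str]]:
    """Is this sequence an intact reading frame?

    Requires: length ≥ 3 and a multiple of 3; first codon in the allowed
    start set; exactly one stop codon, at the terminal position; ambiguous
    (non-ACGT) fraction within the configured cap. Codons containing
    ambiguity are never counted as stops. Returns (flag, diagnostics).
    """
    diagnostics: list[str] = []
    seq = seq.upper()
    if not seq:
        return False, ["empty sequence"]
    if len(seq) < 3 or len(seq) % 3 != 0:
        diagnostics.append(f"length {len(seq)} is not a positive multiple of 3")
    ambiguous = sum(1 for c in seq if c not in "ACGT")
    frac = ambiguous / len(seq)
    if frac > cfg.orf_max_ambiguous_frac:
        diagnostics.append(
            f"ambiguous fraction {frac:.3f} exceeds cap {cfg.orf_max_ambiguous_frac}"
        )
    codons = [seq[i:i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if not codons or codons[0] not in cfg.orf_start_codons:
        diagnostics.append(
            f"first codon {codons[0] if codons else '∅'} not in start set "
            f"{tuple(cfg.orf_start_codons)}"
        )
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    if len(stops) != 1 or (stops and stops[0] != len(codons) - 1):
        if any(i < len(codons) - 1 for i in stops):
            diagnostics.append("internal stop codon")
        if not stops or stops[-1] != len(codons) - 1:
            diagnostics.append("no terminal stop codon")
    return (not diagnostics), diagnostics


def consensus_quality_filter(
    results: Iterable[ConsensusResult],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[ConsensusResult]:
    """High-quality, high-coverage subset: mean depth and N-fraction gates."""
    return [
        r for r in results
        if r.mean_depth >= cfg.consensus_min_avg_depth
        and r.n_fraction <= cfg.consensus_max_n_frac
    ]
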