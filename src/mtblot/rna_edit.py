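"""Tallying candidate C-to-U RNA-edit sites from variant calls.

Plant mitochondrial transcripts are edited C→U at hundreds of sites;
against a DNA reference these show up as C→T variants in RNA read
mappings. Two mapping contexts are tallied separately:

* coding — variants called against extracted CDS reference sequences
  (sense strand), where only C→T qualifies;
* noncoding — variants on the genomic reference outside every CDS
  interval, where either C→T or T→C qualifies (the genomic strand of a
  noncoding position is arbitrary).

Only biallelic SNVs at or above a minimum alternate-allele frequency are
counted. This module tallies observed variant evidence; edit *prediction*
from protein conservation is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import ClassifierConfig, EditSite, GeneModel

__all__ = ["VariantRecord", "read_vcf", "tally_edits", "codon_positions", "EditSummary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantRecord:
    """A minimal biallelic SNV: chromosome, 0-based position, alleles, AF."""

    seq_id: str
    position: int
    ref: str
    alts: tuple[str, ...]
    frequency: Optional[float]


@dataclass
class EditSummary:
    """Counts of qualifying edit candidates by context."""

    coding: int = 0
    noncoding: int = 0
    skipped_multiallelic: int = 0

    @property
    def total(self) -> int:
        return self.coding + self.noncoding


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read SNV records from a VCF via pysam; AF taken from INFO."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            af = rec.info.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, (tuple, list)) else af)
            records.append(
                VariantRecord(
                    seq_id=rec.chrom,
                    position=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    frequency=af,
                )
            )
    return records


def tally_edits(
    variants: Iterable[VariantRecord],
    cds_models: Sequence[GeneModel],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[EditSite], EditSummary]:
    """Tally C-to-U candidates across the coding and noncoding partitions.

    A variant whose seq_id names a CDS model is in the coding context and
    its position is the CDS 5′ offset; any other variant is genomic, and
    positions inside a CDS interval of that sequence are excluded so no
    site can be counted in both partitions. Multiallelic records are
    skipped with a logged count; a missing frequency is an error.
    """
    cds_by_id = {m.gene_id: m for m in cds_models}
    genomic_cds: dict[str, list[GeneModel]] = {}
    for m in cds_models:
        genomic_cds.setdefault(m.seq_id, []).append(m)

    sites: list[EditSite] = []
    summary = EditSummary()
    for v in variants:
        if len(v.alts) != 1 or len(v.ref) != 1 or len(v.alts[0]) != 1:
            summary.skipped_multiallelic += 1
            continue
        if v.frequency is None:
            raise ValueError(
                f"variant {v.seq_id}:{v.position + 1} has no allele-frequency field"
            )
        if v.frequency < cfg.edit_min_freq:
            continue
        ref, alt = v.ref.upper(), v.alts[0].upper()
        if v.seq_id in cds_by_id:
            # mapped onto a CDS reference: sense strand, only C→T qualifies
            model = cds_by_id[v.seq_id]
            if not 0 <= v.position < model.length:
                raise ValueError(
                    f"variant position {v.position} outside CDS {model.gene_id!r}"
                )
            if (ref, alt) == ("C", "T"):
                sites.append(
                    EditSite(
                        seq_id=v.seq_id,
                        position=v.position,
                        ref_base=ref,
                        alt_base=alt,
                        frequency=v.frequency,
                        context="coding",
                        codon_position=v.position % 3 + 1,
                    )
                )
                summary.coding += 1
        else:
            # genomic mapping: exclude CDS intervals, then C→T or T→C
            in_cds = any(
                m.contains(v.position) for m in genomic_cds.get(v.seq_id, ())
            )
            if in_cds:
                continue
            if (ref, alt) in (("C", "T"), ("T", "C")):
                sites.append(
                    EditSite(
                        seq_id=v.seq_id,
                        position=v.position,
                        ref_base=ref,
                        alt_base=alt,
                        frequency=v.frequency,
                        context="noncoding",
                    )
                )
                summary.noncoding += 1
    if summary.skipped_multiallelic:
        log.info("skipped %d multiallelic records", summary.skipped_multiallelic)
    return sites, summary


def codon_positions(
    edit_sites: Iterable[EditSite],
    cds_models: Sequence[GeneModel],
) -> dict[int, int]:
    """Histogram of coding edit sites by codon position {1, 2, 3}.

    Positions are 0-based CDS offsets; codon position is offset mod 3,
    one-based. CDS lengths must be multiples of 3; a site outside its CDS
    is an error.
    """
    cds_by_id = {m.gene_id: m for m in cds_models}
    for m in cds_models:
        if m.length % 3 != 0:
            raise ValueError(f"CDS {m.gene_id!r} length {m.length} is not a multiple of 3")
    counts = {1: 0, 2: 0, 3: 0}
    for s in edit_sites:
        if s.context != "coding":
            continue
        model = cds_by_id.get(s.seq_id)
        if model is None or not 0 <= s.position < model.length:
            raise ValueError(f"edit site {s.seq_id}:{s.position} outside any CDS")
        counts[s.position % 3 + 1] += 1
    return counts
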