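"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open; BED is consumed as 0-based
half-open and GFF3 as 1-based inclusive, converted on input. Depth and
pileup tables use 1-based positions, matching samtools conventions.
Malformed coordinates are rejected, never silently repaired.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import DepthProfile, GeneModel, PileupColumn, PresenceCall, Supermatrix, Tier

log = logging.getLogger(__name__)

#: genes treated as depth-normalization controls when the annotation
#: declares no roles at all (the usual large, universally mt-encoded trio)
DEFAULT_CONTROL_GENES = ("matR", "nad7", "nad4")

CALLS_COLUMNS = [
    "readset_id", "gene_id", "tier", "heat_value",
    "frac_above_absent_depth", "min_window_nfold", "control_factor", "orf_intact",
]


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(
    path: str | Path,
    dialect: str = "bed",
    default_controls: Sequence[str] = DEFAULT_CONTROL_GENES,
) -> list[GeneModel]:
    """Read gene models from a BED or GFF3 annotation.

    The locus role is read from a 7th BED column or a GFF3 ``role``
    attribute; when the annotation declares no roles anywhere, genes named
    in ``default_controls`` become controls and the rest queries.
    """
    dialect = dialect.lower()
    if dialect == "bed":
        raw = _read_bed(path)
    elif dialect in ("gff", "gff3"):
        raw = _read_gff3(path)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    any_role = any(role is not None for _, rows in raw for *_xs, role in rows)
    models = []
    for gene_id, rows in raw:
        seq_ids = {r[0] for r in rows}
        if len(seq_ids) > 1:
            raise ValueError(f"{gene_id}: intervals on multiple sequences")
        strands = {r[3] for r in rows}
        if len(strands) > 1:
            raise ValueError(f"{gene_id}: inconsistent strand")
        roles = {r[4] for r in rows if r[4] is not None}
        if len(roles) > 1:
            raise ValueError(f"{gene_id}: inconsistent role")
        if any_role:
            role = roles.pop() if roles else "query"
        else:
            role = "control" if gene_id in default_controls else "query"
        intervals = sorted((r[1], r[2]) for r in rows)
        models.append(
            GeneModel(
                gene_id=gene_id,
                seq_id=seq_ids.pop(),
                intervals=tuple(intervals),
                strand=strands.pop(),
                role=role,
            )
        )
    return models


def _read_bed(path: str | Path):
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        names=["seq_id", "start", "end", "gene_id", "score", "strand", "role"],
    )
    if df["gene_id"].isna().any():
        raise ValueError("BED rows need at least 4 columns (chrom start end name)")
    grouped: dict[str, list] = {}
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start < 0 or end <= start:
            raise ValueError(f"{row.gene_id}: bad BED interval {row.start}-{row.end}")
        strand = row.strand if isinstance(row.strand, str) and row.strand != "." else "+"
        if strand not in ("+", "-"):
            raise ValueError(f"{row.gene_id}: unknown strand symbol {row.strand!r}")
        role = row.role if isinstance(row.role, str) else None
        if role is not None and role not in ("query", "control"):
            raise ValueError(f"{row.gene_id}: unknown role {role!r}")
        grouped.setdefault(row.gene_id, []).append((row.seq_id, start, end, strand, role))
    return list(grouped.items())


def _read_gff3(path: str | Path):
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique", force=True,
    )
    features = list(db.all_features())
    kinds = {f.featuretype for f in features}
    # prefer exon/CDS parts when present, otherwise whole-gene features
    use_parts = bool(kinds & {"exon", "CDS"})
    grouped: dict[str, list] = {}
    for f in features:
        if use_parts and f.featuretype not in ("exon", "CDS"):
            continue
        if not use_parts and f.featuretype != "gene":
            continue
        gene_id = (
            f.attributes.get("gene_id", [None])[0]
            or f.attributes.get("Parent", [None])[0]
            or f.attributes.get("Name", [None])[0]
            or f.id
        )
        if gene_id is None:
            raise ValueError("GFF3 feature without gene_id/Parent/Name/ID")
        if f.start < 1 or f.end < f.start:
            raise ValueError(f"{gene_id}: bad GFF3 coordinates {f.start}-{f.end}")
        if f.strand not in ("+", "-", ".", None):
            raise ValueError(f"{gene_id}: unknown strand symbol {f.strand!r}")
        strand = f.strand if f.strand in ("+", "-") else "+"
        role = f.attributes.get("role", [None])[0]
        if role is not None and role not in ("query", "control"):
            raise ValueError(f"{gene_id}: unknown role {role!r}")
        # 1-based inclusive -> 0-based half-open
        grouped.setdefault(gene_id, []).append((f.seqid, f.start - 1, f.end, strand, role))
    return list(grouped.items())


# ---------------------------------------------------------------------------
# depth tables

def read_depth_table(
    path: str | Path,
    models: Sequence[GeneModel],
    readset_id: str = "readset",
) -> dict[str, DepthProfile]:
    """Read a per-base depth TSV (seq_id, 1-based pos, depth) into profiles.

    Positions absent from the table get depth 0. Minus-strand genes are
    reversed so index 0 is the gene's 5′ end. Rows on sequences covered by
    no model are ignored (a count is logged).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["seq_id", "pos", "depth"],
        dtype={"seq_id": str, "pos": np.int64, "depth": np.int64},
    )
    if (df["depth"] < 0).any():
        raise ValueError("negative depth in depth table")
    if (df["pos"] < 1).any():
        raise ValueError("depth table positions are 1-based; got position < 1")
    if df.duplicated(subset=["seq_id", "pos"]).any():
        raise ValueError("duplicate (seq_id, pos) rows in depth table")

    known = {m.seq_id for m in models}
    ignored = int((~df["seq_id"].isin(known)).sum())
    if ignored:
        log.info("depth table: ignored %d rows on unknown sequences", ignored)
    by_seq = {
        seq: dict(zip(sub["pos"].to_numpy(), sub["depth"].to_numpy()))
        for seq, sub in df[df["seq_id"].isin(known)].groupby("seq_id")
    }

    profiles = {}
    for m in models:
        table = by_seq.get(m.seq_id, {})
        parts = []
        for s, e in m.intervals:
            # table positions are 1-based
            parts.append([table.get(p + 1, 0) for p in range(s, e)])
        vec = np.concatenate([np.asarray(p, dtype=np.int64) for p in parts])
        if m.strand == "-":
            vec = vec[::-1]
        profiles[m.gene_id] = DepthProfile(m.gene_id, readset_id, vec)
    return profiles


def write_depth_table(
    profiles: Mapping[str, np.ndarray] | Mapping[str, DepthProfile],
    models: Sequence[GeneModel],
    path: str | Path,
) -> None:
    """Write per-base depths back out as a sparse seq/pos/depth TSV."""
    by_id = {m.gene_id: m for m in models}
    with open(path, "w") as fh:
        for gene_id, prof in profiles.items():
            depths = prof.depths if isinstance(prof, DepthProfile) else np.asarray(prof)
            m = by_id[gene_id]
            vec = depths[::-1] if m.strand == "-" else depths
            ref_positions = [p for s, e in m.intervals for p in range(s, e)]
            for pos, d in zip(ref_positions, vec):
                if d > 0:
                    fh.write(f"{m.seq_id}\t{pos + 1}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# pileup tables

def read_pileup_table(path: str | Path) -> dict[str, list[PileupColumn]]:
    """Read a pileup TSV (seq_id, 1-based pos, A, C, G, T counts)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["seq_id", "pos", "A", "C", "G", "T"],
        dtype={"seq_id": str, "pos": np.int64},
    )
    if (df[list("ACGT")].to_numpy() < 0).any():
        raise ValueError("negative count in pileup table")
    out: dict[str, list[PileupColumn]] = {}
    for row in df.itertuples(index=False):
        col = PileupColumn(
            gene_id=row.seq_id,
            position=int(row.pos) - 1,
            counts={"A": int(row.A), "C": int(row.C), "G": int(row.G), "T": int(row.T)},
        )
        out.setdefault(row.seq_id, []).append(col)
    for cols in out.values():
        cols.sort(key=lambda c: c.position)
    return out


def write_pileup_table(pileups: Mapping[str, Iterable[PileupColumn]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, cols in pileups.items():
            for c in sorted(cols, key=lambda c: c.position):
                fh.write(
                    f"{gene_id}\t{c.position + 1}\t{c.counts['A']}\t{c.counts['C']}"
                    f"\t{c.counts['G']}\t{c.counts['T']}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Identifier → sequence, order preserved, ids and residues verbatim."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# presence-call tables

def write_calls_table(calls: Sequence[PresenceCall], path: str | Path) -> None:
    """Write calls as TSV, readset-major, tier symbols verbatim.

    Rejects duplicate (gene, readset) pairs. An undefined ORF flag is
    written as NA.
    """
    seen = set()
    for c in calls:
        key = (c.gene_id, c.readset_id)
        if key in seen:
            raise ValueError(f"duplicate call for gene={c.gene_id} readset={c.readset_id}")
        seen.add(key)
    # group by readset in first-appearance order, gene order preserved within
    order: dict[str, list[PresenceCall]] = {}
    for c in calls:
        order.setdefault(c.readset_id, []).append(c)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for rs_calls in order.values():
            for c in rs_calls:
                orf = "NA" if c.orf_intact is None else str(bool(c.orf_intact)).lower()
                fh.write(
                    f"{c.readset_id}\t{c.gene_id}\t{c.tier.symbol}\t{c.heat_value!r}\t"
                    f"{c.frac_above_absent_depth!r}\t{c.min_window_nfold!r}\t"
                    f"{c.control_factor!r}\t{orf}\n"
                )


def read_calls_table(path: str | Path) -> list[PresenceCall]:
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"readset_id": str, "gene_id": str, "orf_intact": str},
    )
    if list(df.columns) != CALLS_COLUMNS:
        raise ValueError(f"unexpected calls-table header: {list(df.columns)}")
    calls = []
    for row in df.itertuples(index=False):
        orf = None if row.orf_intact in ("NA", None) else row.orf_intact == "true"
        calls.append(
            PresenceCall(
                gene_id=row.gene_id,
                readset_id=row.readset_id,
                tier=Tier.from_symbol(row.tier),
                heat_value=float(row.heat_value),
                frac_above_absent_depth=float(row.frac_above_absent_depth),
                min_window_nfold=float(row.min_window_nfold),
                control_factor=float(row.control_factor),
                orf_intact=orf,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# supermatrix output

def write_supermatrix(matrix: Supermatrix, path: str | Path, fmt: str = "fasta") -> None:
    """Write the concatenated alignment as FASTA or relaxed PHYLIP."""
    aln = MultipleSeqAlignment(
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(matrix.taxa, matrix.cells)
    )
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed", "phylip-relaxed": "phylip-relaxed"}[fmt]
    AlignIO.write(aln, str(path), fmt)


def write_partitions(matrix: Supermatrix, path: str | Path) -> None:
    """Write a RAxML-style partition file: ``DNA, gene = start-end`` (1-based)."""
    with open(path, "w") as fh:
        for gene, s, e in matrix.partitions:
            fh.write(f"DNA, {gene} = {s + 1}-{e}\n")
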