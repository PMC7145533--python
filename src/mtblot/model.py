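"""Domain types shared across the toolkit.

The central objects mirror the stages of an in silico Southern blot: a
:class:`GeneModel` describes a locus on a reference panel, a
:class:`DepthProfile` holds its raw per-base read depth in one readset, a
:class:`NormalizationFactor` calibrates expected single-copy mitochondrial
depth from control genes, and a :class:`PresenceCall` records the five-state
tier assigned to the gene together with the statistics that justified it.

Coordinates are 0-based half-open everywhere inside the package; conversion
to and from 1-based conventions happens only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Tier",
    "GeneModel",
    "DepthProfile",
    "NormalizationFactor",
    "NormalizedProfile",
    "ClassifierConfig",
    "PresenceCall",
    "PileupColumn",
    "EditSite",
    "Supermatrix",
]


class Tier(Enum):
    """Five-state presence tier with its text-rendering symbol.

    FIRST (+): enough depth to assemble an intact reading frame.
    SECOND (●): continuous coverage with log score above the cutoff.
    THIRD (○): average heat-map value above the heat threshold.
    ABSENT (−): little or no coverage while controls are well covered.
    AMBIGUOUS (?): no tier met and overall mitochondrial depth too low
    to call absence confidently.
    """

    FIRST = "+"
    SECOND = "●"      # ●
    THIRD = "○"       # ○
    ABSENT = "−"      # − (minus sign, not hyphen)
    AMBIGUOUS = "?"

    @property
    def symbol(self) -> str:
        return self.value

    @property
    def rank(self) -> int:
        """Ordering used for monotonicity checks: + > ● > ○ > −/?"""
        return {"FIRST": 3, "SECOND": 2, "THIRD": 1, "ABSENT": 0, "AMBIGUOUS": 0}[self.name]

    @classmethod
    def from_symbol(cls, symbol: str) -> "Tier":
        for tier in cls:
            if tier.value == symbol:
                return tier
        raise ValueError(f"unknown tier symbol: {symbol!r}")


@dataclass(frozen=True)
class GeneModel:
    """A named locus: ordered exon intervals on a reference sequence.

    ``intervals`` are 0-based half-open, sorted, and non-overlapping; the
    gene is analysed on the exon-concatenated coordinate system (introns
    excluded), 5′→3′ on the gene strand.
    """

    gene_id: str
    seq_id: str
    intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    role: str = "query"
    is_coding: bool = True

    def __post_init__(self) -> None:
        ivs = tuple((int(s), int(e)) for s, e in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValueError(f"{self.gene_id}: gene model has no intervals")
        last_end = None
        for s, e in ivs:
            if s < 0 or e <= s:
                raise ValueError(f"{self.gene_id}: bad interval ({s},{e})")
            if last_end is not None and s < last_end:
                raise ValueError(f"{self.gene_id}: overlapping or unsorted intervals")
            last_end = e
        if self.length < 1:
            raise ValueError(f"{self.gene_id}: zero-length gene")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if self.role not in ("query", "control"):
            raise ValueError(f"{self.gene_id}: role must be 'query' or 'control'")
        if self.role == "control" and not self.is_coding:
            raise ValueError(f"{self.gene_id}: control genes must be coding")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        """Membership of a 0-based reference position (half-open intervals)."""
        return any(s <= pos < e for s, e in self.intervals)

    def offset_of(self, pos: int) -> int:
        """Exon-concatenated 5′ offset of a 0-based reference position."""
        off = 0
        for s, e in self.intervals:
            if s <= pos < e:
                off += pos - s
                if self.strand == "-":
                    return self.length - 1 - off
                return off
            off += e - s
        raise ValueError(f"position {pos} outside {self.gene_id}")


@dataclass
class DepthProfile:
    """Raw per-base read depth for one gene in one readset.

    Index 0 is the gene's 5′ end on the gene strand; minus-strand genes are
    reversed at read time.
    """

    gene_id: str
    readset_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths)
        if d.ndim != 1 or d.size < 1:
            raise ValueError(f"{self.gene_id}: depth vector must be 1-D and non-empty")
        if np.any(d < 0):
            raise ValueError(f"{self.gene_id}: negative depth")
        self.depths = d.astype(np.int64)

    def __len__(self) -> int:
        return int(self.depths.size)

    @property
    def mean(self) -> float:
        return float(self.depths.mean())


@dataclass(frozen=True)
class NormalizationFactor:
    """Expected single-copy mt depth of a readset.

    ``factor`` is the mean of the per-control mean depths, each control
    weighted equally regardless of its length.
    """

    readset_id: str
    control_means: Mapping[str, float]
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError(f"{self.readset_id}: normalization factor must be > 0")


@dataclass
class NormalizedProfile:
    """Per-base n-fold depth: raw depth divided by the control factor."""

    gene_id: str
    readset_id: str
    nfold: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.nfold, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError(f"{self.gene_id}: n-fold vector must be 1-D and non-empty")
        if np.any(v < 0):
            raise ValueError(f"{self.gene_id}: negative n-fold value")
        self.nfold = v

    def __len__(self) -> int:
        return int(self.nfold.size)


# Tolerance for the log cutoff / n-fold cutoff correspondence check.
_LOG_NFOLD_TOL = 5e-4


@dataclass(frozen=True)
class ClassifierConfig:
    """Every tunable threshold of the pipeline, with field defaults.

    heat_min
        Minimum average heat-map value (mean depth / control factor) for a
        third-tier call; strict ``>``.
    log_min / nfold_min
        Second-tier cutoff expressed in log space (natural log of the
        n-fold) and as the equivalent n-fold value; ``exp(log_min)`` should
        match ``nfold_min`` (a warning is issued otherwise).
    absent_frac / absent_depth
        Automatic-absence gate: a locus where fewer than ``absent_frac`` of
        positions have raw depth strictly above ``absent_depth`` is
        ineligible for any presence tier.
    control_min
        Minimum control factor for an ABSENT (rather than AMBIGUOUS) call
        when no tier is met; strict ``>``.
    consensus_min_avg_depth
        Minimum gene-wide mean depth for an accepted consensus.
    min_match_len
        Minimum matched bases in a read's CIGAR to keep the alignment.
    edit_min_freq
        Minimum alternate-allele frequency for a counted RNA-edit variant
        (inclusive floor).
    supermatrix_min_positions
        Minimum non-gap, non-N positions for a taxon to stay in the
        supermatrix.
    plot_epsilon
        Pseudo-depth added before the natural-log transform.
    fold_boundary
        The coverage plot draws horizontal bounds at ±ln(fold_boundary).
    window
        Sliding-window width (bp) used to operationalise "continuous
        coverage across the full length"; also the read-filter match length.
    orf_start_codons / orf_max_ambiguous_frac
        Intact-reading-frame criteria for the consensus sequence.
    consensus_max_n_frac
        Maximum ambiguous-base fraction for the consensus quality filter.
    cigar_mode
        "total" (sum of M/=/X bases, default) or "longest_run".
    heat_saturation_quantile
        Heat-map rendering saturates the colour scale at this quantile.
    """

    heat_min: float = 0.25
    log_min: float = -2.0
    nfold_min: float = 0.135
    absent_frac: float = 0.5
    absent_depth: int = 5
    control_min: float = 15.0
    consensus_min_avg_depth: float = 6.0
    min_match_len: int = 25
    edit_min_freq: float = 0.2
    supermatrix_min_positions: int = 10000
    plot_epsilon: float = 1e-5
    fold_boundary: float = 6.0
    window: int = 25
    orf_start_codons: tuple[str, ...] = ("ATG",)
    orf_max_ambiguous_frac: float = 0.05
    consensus_max_n_frac: float = 0.2
    cigar_mode: str = "total"
    heat_saturation_quantile: float = 0.99

    def __post_init__(self) -> None:
        positive = (
            "heat_min", "nfold_min", "absent_frac", "absent_depth", "control_min",
            "consensus_min_avg_depth", "min_match_len", "edit_min_freq",
            "supermatrix_min_positions", "plot_epsilon", "fold_boundary", "window",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.absent_frac <= 1:
            raise ValueError("absent_frac must be in (0, 1]")
        if self.cigar_mode not in ("total", "longest_run"):
            raise ValueError("cigar_mode must be 'total' or 'longest_run'")
        if abs(math.exp(self.log_min) - self.nfold_min) > _LOG_NFOLD_TOL:
            warnings.warn(
                f"exp(log_min)={math.exp(self.log_min):.4f} disagrees with "
                f"nfold_min={self.nfold_min}: the two second-tier cutoffs are "
                "inconsistent",
                stacklevel=2,
            )

    def replace(self, **overrides) -> "ClassifierConfig":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_strings(cls, overrides: Mapping[str, str]) -> "ClassifierConfig":
        """Build a config from string key=value overrides (CLI surface)."""
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        base = cls()
        for key, raw in overrides.items():
            if key not in types:
                raise ValueError(f"unknown config field: {key}")
            current = getattr(base, key)
            if isinstance(current, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(raw)
            elif isinstance(current, float):
                kwargs[key] = float(raw)
            elif isinstance(current, tuple):
                kwargs[key] = tuple(raw.split(","))
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PresenceCall:
    """Tier assignment for one gene in one readset, with its evidence."""

    gene_id: str
    readset_id: str
    tier: Tier
    heat_value: float
    frac_above_absent_depth: float
    min_window_nfold: float
    control_factor: float
    orf_intact: Optional[bool] = None

    @property
    def symbol(self) -> str:
        return self.tier.symbol


@dataclass
class PileupColumn:
    """Base counts at one exon-concatenated gene position.

    Substitution-only: deletions and ambiguous reads are excluded upstream,
    so depth is the sum of the four base counts.
    """

    gene_id: str
    position: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for base in "ACGT":
            self.counts.setdefault(base, 0)
        extra = set(self.counts) - set("ACGT")
        if extra:
            raise ValueError(f"unexpected pileup bases: {sorted(extra)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative pileup count")
        if self.position < 0:
            raise ValueError("negative pileup position")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EditSite:
    """A candidate C-to-U RNA-edit site observed as a DNA/RNA variant."""

    seq_id: str
    position: int
    ref_base: str
    alt_base: str
    frequency: float
    context: str                      # "coding" | "noncoding"
    codon_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.context not in ("coding", "noncoding"):
            raise ValueError(f"bad context {self.context!r}")
        if self.context == "coding" and self.codon_position not in (1, 2, 3):
            raise ValueError("coding edit sites need a codon position in {1,2,3}")
        if not 0 <= self.frequency <= 1:
            raise ValueError("frequency must be in [0,1]")


@dataclass
class Supermatrix:
    """Concatenated multi-gene alignment with per-gene column partitions.

    ``cells`` is a (taxa × columns) single-character matrix; ``partitions``
    are half-open column ranges that tile the matrix in gene order.
    """

    taxa: list[str]
    partitions: list[tuple[str, int, int]]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype="<U1")
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D character matrix")
        if self.cells.shape[0] != len(self.taxa):
            raise ValueError("row count disagrees with taxa list")
        expected = 0
        for gene, s, e in self.partitions:
            if s != expected or e <= s:
                raise ValueError(f"partition {gene} does not tile the matrix")
            expected = e
        if expected != self.cells.shape[1]:
            raise ValueError("partitions do not cover all columns")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.cells.shape[1])

    def row(self, taxon: str) -> str:
        return "".join(self.cells[self.taxa.index(taxon)])
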