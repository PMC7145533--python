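"""Tier classification, heat-map matrices, and coverage-plot series.

This is the in silico Southern blot proper. A gene's *heat value* is its
mean depth relative to the control factor; presence is called in nested
tiers:

+ (FIRST)    enough depth to assemble an intact reading frame,
● (SECOND)   continuous coverage with window-mean n-fold above the log
             cutoff (exp(−2.0) ≈ 0.135),
○ (THIRD)    average heat value above 0.25,
− (ABSENT)   gate failed while the control factor shows the readset is
             well covered (> 15),
? (AMBIGUOUS) gate failed and the readset itself is too shallow to call
             absence.

A locus where fewer than half the positions have raw depth > 5 is
automatically ineligible for any presence tier (the absence gate).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import depth_norm
from .consensus import ConsensusResult, call_consensus, orf_intact
from .model import (
    ClassifierConfig,
    DepthProfile,
    GeneModel,
    NormalizationFactor,
    NormalizedProfile,
    PileupColumn,
    PresenceCall,
    Tier,
)

__all__ = [
    "heat_value",
    "min_window_nfold",
    "classify",
    "call_readset",
    "heatmap_matrix",
    "render_heatmap",
    "coverage_plot_series",
    "render_coverage_plot",
]

log = logging.getLogger(__name__)


def heat_value(profile: DepthProfile, factor: NormalizationFactor) -> float:
    """Mean raw depth of the gene divided by the control factor."""
    return profile.mean / factor.factor


def min_window_nfold(nprofile: NormalizedProfile, window: int) -> float:
    """Minimum sliding-window mean of the n-fold profile.

    Operationalises "continuous coverage across the full length of the
    gene": every window of the given width must clear the cutoff, so the
    minimum is the binding statistic. A window wider than the gene clamps
    to the gene length.
    """
    v = nprofile.nfold
    if v.size == 0:
        raise ValueError("empty profile")
    if window < 1:
        raise ValueError("window must be >= 1")
    w = min(window, v.size)
    # pairwise-summation window means: a cumulative-sum formulation drifts
    # at the last bit and can push a profile sitting exactly on the cutoff
    # to the wrong side
    from numpy.lib.stride_tricks import sliding_window_view

    means = sliding_window_view(v, w).mean(axis=1)
    return float(means.min())


def classify(
    profile: DepthProfile,
    nprofile: NormalizedProfile,
    factor: NormalizationFactor,
    consensus_result: Optional[ConsensusResult] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> PresenceCall:
    """Assign the five-state presence tier to one gene in one readset.

    Decision order: (1) absence gate on raw depth; (2) FIRST on an
    accepted consensus with intact reading frame; (3) SECOND on window-mean
    n-fold ≥ nfold_min; (4) THIRD on heat value > heat_min; (5) otherwise
    ABSENT when the control factor is > control_min, AMBIGUOUS when the
    readset is itself shallow.
    """
    if profile.gene_id != nprofile.gene_id:
        raise ValueError(
            f"gene mismatch: profile {profile.gene_id!r} vs n-fold {nprofile.gene_id!r}"
        )
    if profile.readset_id != factor.readset_id or profile.readset_id != nprofile.readset_id:
        raise ValueError(f"readset mismatch for gene {profile.gene_id!r}")
    if consensus_result is not None and consensus_result.gene_id != profile.gene_id:
        raise ValueError(
            f"consensus for {consensus_result.gene_id!r} paired with profile "
            f"{profile.gene_id!r}"
        )

    heat = heat_value(profile, factor)
    frac = depth_norm.fraction_above(profile, cfg.absent_depth)
    mwn = min_window_nfold(nprofile, cfg.window)
    eligible = frac >= cfg.absent_frac

    orf = None
    if consensus_result is not None:
        orf = consensus_result.orf_intact
        if orf is None:
            orf, _ = orf_intact(consensus_result.sequence, cfg)

    if eligible and consensus_result is not None and consensus_result.accepted and orf:
        tier = Tier.FIRST
    elif eligible and mwn >= cfg.nfold_min:
        tier = Tier.SECOND
    elif eligible and heat > cfg.heat_min:
        tier = Tier.THIRD
    elif factor.factor > cfg.control_min:
        tier = Tier.ABSENT
    else:
        tier = Tier.AMBIGUOUS

    return PresenceCall(
        gene_id=profile.gene_id,
        readset_id=profile.readset_id,
        tier=tier,
        heat_value=heat,
        frac_above_absent_depth=frac,
        min_window_nfold=mwn,
        control_factor=factor.factor,
        orf_intact=orf,
    )


def call_readset(
    models: Sequence[GeneModel],
    profiles: Mapping[str, DepthProfile],
    pileups: Optional[Mapping[str, Sequence[PileupColumn]]] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[list[PresenceCall], NormalizationFactor]:
    """Run the full blot on one readset: normalize, (optionally) assemble
    consensus sequences, and classify every gene in the panel.

    Controls are the models with role=control; their profiles must be
    present. When pileup columns are supplied for a coding gene, its
    consensus is called and checked for an intact frame, enabling FIRST.
    """
    controls = [m.gene_id for m in models if m.role == "control"]
    factor = depth_norm.control_factor(profiles, controls)
    calls = []
    for m in models:
        if m.gene_id not in profiles:
            raise ValueError(f"no depth profile for gene {m.gene_id!r}")
        prof = profiles[m.gene_id]
        nprof = depth_norm.normalize(prof, factor)
        cons = None
        if pileups is not None and m.gene_id in pileups and m.is_coding:
            cons = call_consensus(
                pileups[m.gene_id], cfg, length=m.length,
                readset_id=prof.readset_id, gene_id=m.gene_id,
            )
            ok, diags = orf_intact(cons.sequence, cfg)
            cons.orf_intact = ok
            cons.orf_diagnostics = diags
        calls.append(classify(prof, nprof, factor, cons, cfg))
    return calls, factor


# ---------------------------------------------------------------------------
# heat map

def heatmap_matrix(
    calls: Iterable[PresenceCall],
    readset_order: Optional[Sequence[str]] = None,
    gene_order: Optional[Sequence[str]] = None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Readsets × genes matrices of displayed heat values and tier symbols.

    Rows are readsets (phylogenetic order when supplied), columns genes.
    Genes failing the absence gate display 0 regardless of their raw heat
    value — they were automatically scored as absent. Every readset must
    cover the same gene panel (ragged inputs are rejected).
    """
    calls = list(calls)
    by_rs: dict[str, dict[str, PresenceCall]] = {}
    for c in calls:
        by_rs.setdefault(c.readset_id, {})[c.gene_id] = c
    readsets = list(readset_order) if readset_order else list(by_rs)
    panels = {rs: tuple(sorted(by_rs[rs])) for rs in readsets}
    if len(set(panels.values())) > 1:
        raise ValueError("ragged input: readsets cover different gene panels")
    genes = list(gene_order) if gene_order else list(by_rs[readsets[0]])
    values = pd.DataFrame(0.0, index=readsets, columns=genes)
    tiers = pd.DataFrame("", index=readsets, columns=genes)
    for rs in readsets:
        for g in genes:
            c = by_rs[rs][g]
            gate_ok = c.frac_above_absent_depth >= cfg.absent_frac
            values.loc[rs, g] = c.heat_value if gate_ok else 0.0
            tiers.loc[rs, g] = c.tier.symbol
    return values, tiers


def render_heatmap(
    values: pd.DataFrame,
    tiers: Optional[pd.DataFrame] = None,
    out_prefix: str = "heatmap",
    cfg: ClassifierConfig = ClassifierConfig(),
) -> list[str]:
    """Render the heat map (black → yellow/white) to SVG and PNG.

    The colour scale saturates at the configured quantile of the nonzero
    values so ultrahigh-coverage cells (plastid inserts, duplications) do
    not wash out the single-copy signal.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = values.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    vmax = float(np.quantile(nonzero, cfg.heat_saturation_quantile)) if nonzero.size else 1.0
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * values.shape[1] + 2), max(3.0, 0.35 * values.shape[0] + 1.5))
    )
    im = ax.imshow(arr, cmap="afmhot", vmin=0.0, vmax=max(vmax, 1e-9), aspect="auto")
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(values.shape[0]), values.index, fontsize=7)
    if tiers is not None:
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                ax.text(j, i, tiers.iat[i, j], ha="center", va="center",
                        fontsize=6, color="tab:cyan")
    fig.colorbar(im, ax=ax, label="n-fold mean depth")
    fig.tight_layout()
    paths = [f"{out_prefix}.svg", f"{out_prefix}.png"]
    for p in paths:
        fig.savefig(p)
    plt.close(fig)
    return paths


# ---------------------------------------------------------------------------
# coverage plot

@dataclass
class CoverageSeries:
    """Data behind one per-gene coverage panel."""

    gene_id: str
    readset_id: str
    x: np.ndarray              # 0-based gene positions
    y: np.ndarray              # ln(n-fold + ε)
    upper_bound: float         # +ln(fold_boundary)
    lower_bound: float         # −ln(fold_boundary)
    epsilon: float
    gene_start: int
    gene_end: int


def coverage_plot_series(
    nprofile: NormalizedProfile,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> CoverageSeries:
    """Log-transformed series plus the ±ln(fold_boundary) bounds.

    The bounds mark a symmetric fold deviation from expected mt coverage
    and separate mitochondrial signal (inside) from nuclear residuals
    (below) and plastid inserts (above).
    """
    if not cfg.fold_boundary > 1:
        raise ValueError("fold_boundary must be > 1")
    y = depth_norm.log_series(nprofile, cfg.plot_epsilon)
    bound = float(np.log(cfg.fold_boundary))
    return CoverageSeries(
        gene_id=nprofile.gene_id,
        readset_id=nprofile.readset_id,
        x=np.arange(len(nprofile)),
        y=y,
        upper_bound=bound,
        lower_bound=-bound,
        epsilon=cfg.plot_epsilon,
        gene_start=0,
        gene_end=len(nprofile),
    )


def render_coverage_plot(series: CoverageSeries, out_prefix: str = "coverage") -> list[str]:
    """Render one coverage panel (gene-boundary box, ± bounds) to SVG/PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.axvspan(series.gene_start - 0.5, series.gene_end - 0.5, color="0.85", zorder=0)
    ax.plot(series.x, series.y, lw=0.8, color="tab:blue")
    for b in (series.upper_bound, series.lower_bound):
        ax.axhline(b, color="0.3", ls="--", lw=0.8)
    ax.set_xlabel(f"{series.gene_id} position (bp)")
    ax.set_ylabel(f"ln(n-fold + {series.epsilon:g})")
    ax.set_title(f"{series.gene_id} — {series.readset_id}")
    fig.tight_layout()
    paths = [f"{out_prefix}.svg", f"{out_prefix}.png"]
    for p in paths:
        fig.savefig(p)
    plt.close(fig)
    return paths
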