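"""Control-gene depth normalization.

A readset's expected single-copy mitochondrial depth is calibrated from a
small panel of large, consistently mt-located control genes. Each gene's
raw per-base depth is divided by this factor, giving an n-fold profile
that sits near 1 for single-copy mt loci, near 2 for duplicated regions,
well above 1 for plastid inserts, and far below 1 for nuclear residuals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import DepthProfile, NormalizationFactor, NormalizedProfile

__all__ = ["control_factor", "normalize", "log_series", "fraction_above"]


def control_factor(
    profiles: Mapping[str, DepthProfile],
    controls: Sequence[str],
) -> NormalizationFactor:
    """Mean-of-means control depth: each control gene weighted equally.

    Raises ``ValueError("controls unusable")`` when a control profile is
    missing or the controls carry no coverage at all — such a readset
    cannot be normalized.
    """
    if not controls:
        raise ValueError("controls unusable: no control genes named")
    missing = [g for g in controls if g not in profiles]
    if missing:
        raise ValueError(f"controls unusable: missing profiles for {missing}")
    readsets = {profiles[g].readset_id for g in controls}
    if len(readsets) > 1:
        raise ValueError(f"control profiles span several readsets: {sorted(readsets)}")
    means = {g: profiles[g].mean for g in controls}
    factor = float(np.mean(list(means.values())))
    if factor <= 0:
        raise ValueError("controls unusable: all control genes have zero coverage")
    return NormalizationFactor(readset_id=readsets.pop(), control_means=means, factor=factor)


def normalize(profile: DepthProfile, factor: NormalizationFactor) -> NormalizedProfile:
    """Elementwise raw depth / control factor; raw zeros stay zero."""
    if profile.readset_id != factor.readset_id:
        raise ValueError(
            f"readset mismatch: profile {profile.readset_id!r} vs factor {factor.readset_id!r}"
        )
    return NormalizedProfile(
        gene_id=profile.gene_id,
        readset_id=profile.readset_id,
        nfold=profile.depths / factor.factor,
    )


def log_series(nprofile: NormalizedProfile, epsilon: float = 1e-5) -> np.ndarray:
    """Natural log of (n-fold + ε); ε keeps zero-coverage positions finite."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    return np.log(nprofile.nfold + epsilon)


def fraction_above(profile: DepthProfile, depth_cutoff: int) -> float:
    """Fraction of positions with raw depth strictly greater than the cutoff."""
    return float(np.mean(profile.depths > depth_cutoff))
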