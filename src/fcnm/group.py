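"""Group-level consensus networks from subject z-maps.

Per contrast: a voxel-wise one-sample t-test over subjects against 0,
one-sided (right tail — only positive connectivity is of interest),
corrected for multiple comparisons voxel-wise (Benjamini-Hochberg FDR or
Bonferroni FWE), then binarized with the t > 0 conjunction.  Binarized
contrast maps are overlaid into a probability map (per-voxel fraction of
contrasts including the voxel) and thresholded — at 50 % by default,
inclusive at the boundary — to yield the consensus network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .fc import FCMap


class GroupError(ValueError):
    pass


@dataclass
class GroupTMap:
    """Voxel-wise one-sample t statistics over subjects, one contrast."""

    contrast_id: str
    t: np.ndarray = field(repr=False)
    p: np.ndarray = field(repr=False)  # one-sided (right-tail)
    df: int = 0
    valid: np.ndarray = field(repr=False, default=None)
    correction: str | None = None
    alpha: float | None = None


@dataclass
class ProbabilityMap:
    """Per-voxel fraction of contrasts whose binarized map includes it."""

    direction: str
    fraction: np.ndarray = field(repr=False)
    n_contrasts: int = 0


@dataclass
class NetworkMask:
    """Consensus network: probability map thresholded (inclusive)."""

    direction: str
    volume: np.ndarray = field(repr=False)
    threshold_fraction: float = 0.5
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


def one_sample_t(zmaps: Sequence[FCMap] | np.ndarray, contrast_id: str = "") -> GroupTMap:
    """Voxel-wise one-sample t-test of subject z values against zero.

    Accepts a sequence of :class:`FCMap` (sharing a grid) or a plain
    (n_subjects, ...) array.  One-sided p = P(T_df > t).  Voxels with zero
    variance across subjects, or invalid in any subject map, are excluded.
    """
    if isinstance(zmaps, np.ndarray):
        data = np.asarray(zmaps, dtype=np.float64)
        valid = np.ones(data.shape[1:], dtype=bool)
    else:
        if len(zmaps) == 0:
            raise GroupError("no subject maps")
        shapes = {m.z.shape for m in zmaps}
        if len(shapes) != 1:
            raise GroupError(f"subject maps on mismatched grids: {shapes}")
        data = np.stack([m.z for m in zmaps]).astype(np.float64)
        valid = np.logical_and.reduce([m.valid for m in zmaps])
        if not contrast_id:
            contrast_id = zmaps[0].contrast_id
    n = data.shape[0]
    if n < 3:
        raise GroupError(f"need >= 3 subjects, got {n}")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    valid = valid & (sd > 0)
    t = np.zeros(mean.shape)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, mean / (sd / np.sqrt(n)), 0.0)
    p = np.ones(mean.shape)
    p[valid] = stats.t.sf(t[valid], df)
    return GroupTMap(contrast_id=contrast_id, t=t, p=p, df=df, valid=valid)


def fdr_bh(p: np.ndarray, valid: np.ndarray | None = None, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance mask over valid voxels.

    Rejects p_(i) for all i <= k*, where k* = max{k : p_(k) <= k q / m}
    and m is the number of valid voxels.
    """
    p = np.asarray(p, dtype=float)
    if valid is None:
        valid = np.ones(p.shape, dtype=bool)
    pv = p[valid]
    m = pv.size
    mask = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return mask
    order = np.argsort(pv, kind="stable")
    sorted_p = pv[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(sorted_p <= thresh)
    if below.size:
        k_star = below[-1]
        rej = np.zeros(m, dtype=bool)
        rej[order[: k_star + 1]] = True
        mask[valid] = rej
    return mask


def fwe_bonferroni(
    p: np.ndarray, valid: np.ndarray | None = None, alpha: float = 0.05
) -> np.ndarray:
    """Bonferroni voxel-level FWE mask: reject where p < alpha / m."""
    p = np.asarray(p, dtype=float)
    if valid is None:
        valid = np.ones(p.shape, dtype=bool)
    m = int(valid.sum())
    mask = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return mask
    mask[valid] = p[valid] < alpha / m
    return mask


CORRECTIONS = {"FDR_BH": fdr_bh, "FWE_bonferroni": fwe_bonferroni}


def correct(tmap: GroupTMap, method: str = "FDR_BH", alpha: float = 0.05) -> np.ndarray:
    """Dispatch multiple-comparison correction by name."""
    if method not in CORRECTIONS:
        raise GroupError(f"unknown correction {method!r}; use {list(CORRECTIONS)}")
    fn = CORRECTIONS[method]
    kw = {"q": alpha} if method == "FDR_BH" else {"alpha": alpha}
    mask = fn(tmap.p, tmap.valid, **kw)
    tmap.correction, tmap.alpha = method, alpha
    return mask


def binarize_contrast(tmap: GroupTMap, sig_mask: np.ndarray) -> np.ndarray:
    """1 where significant AND t > 0 (positive connectivity only)."""
    if sig_mask.shape != tmap.t.shape:
        raise GroupError("significance mask and t map on mismatched grids")
    return np.asarray(sig_mask, dtype=bool) & (tmap.t > 0)


def overlay_probability(
    binary_maps: Sequence[np.ndarray], direction: str = ""
) -> ProbabilityMap:
    """Per-voxel fraction of contrasts whose binarized map contains it."""
    if len(binary_maps) == 0:
        raise GroupError("need at least one contrast map")
    stack = np.stack([np.asarray(b, dtype=bool) for b in binary_maps])
    return ProbabilityMap(
        direction=direction,
        fraction=stack.mean(axis=0),
        n_contrasts=stack.shape[0],
    )


def threshold_consensus(
    pmap: ProbabilityMap, fraction: float = 0.5, provenance: dict | None = None
) -> NetworkMask:
    """Consensus mask: probability >= fraction (inclusive tie rule).

    The comparison is done on contrast counts to keep the boundary exact
    with an even number of contrasts.
    """
    if not (0 < fraction <= 1):
        raise GroupError(f"fraction must be in (0, 1], got {fraction}")
    counts = np.rint(pmap.fraction * pmap.n_contrasts)
    volume = counts >= fraction * pmap.n_contrasts - 1e-9
    prov = dict(provenance or {})
    prov.update({"n_contrasts": pmap.n_contrasts, "tie_rule": "inclusive_geq"})
    return NetworkMask(
        direction=pmap.direction,
        volume=volume,
        threshold_fraction=float(fraction),
        provenance=prov,
    )
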