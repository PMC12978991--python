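"""Correspondence of derived networks to canonical networks, and the
random-seed null-network experiment.

Spatial correspondence is quantified two ways: the proportion of a
canonical network's voxels covered by the derived network
(|A∩C|/|C|), and the Dice coefficient 2|A∩B|/(|A|+|B|).  Significance of
the correspondence is assessed with a volumetric random-relocation
permutation test: the network is re-derived from foci placed uniformly at
random in the brain mask (same per-contrast focus counts) and the observed
Dice is ranked against the null Dice values with the add-one estimator.
This preserves the random-placement, full-pipeline-rerun logic of
surface-based spin tests in a purely volumetric setting; externally
generated null networks can be supplied instead through a hook.

The chance baseline for the network itself is the same machinery run
against the network: ``null_networks`` re-derives many random-seed
networks and records their Dice with the actual network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .group import NetworkMask

#: Conventional 8-network label table: seven cortical systems plus one
#: subcortical network (amygdala, hippocampus, basal ganglia, thalamus).
CANONICAL_LABELS = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "ventral_attention",
    5: "limbic",
    6: "frontoparietal",
    7: "default",
    8: "subcortical",
}


class CompareError(ValueError):
    pass


@dataclass
class CanonicalAtlas:
    """Integer-labeled parcellation volume + label table."""

    volume: np.ndarray = field(repr=False)
    labels: dict[int, str] = field(default_factory=lambda: dict(CANONICAL_LABELS))

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        present = set(np.unique(self.volume)) - {0}
        unknown = present - set(self.labels)
        if unknown:
            raise CompareError(f"atlas contains unlabeled values: {sorted(unknown)}")

    def label_mask(self, label: int) -> np.ndarray:
        return self.volume == label


@dataclass
class OverlapResult:
    direction: str
    label: int
    label_name: str
    overlap_proportion: float
    dice: float
    p_perm: float | None = None


@dataclass
class NullDistribution:
    """Dice of random-seed null networks against the actual network."""

    dice: np.ndarray
    n_replicates: int
    rng_seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.dice))

    @property
    def sd(self) -> float:
        return float(np.std(self.dice, ddof=1)) if len(self.dice) > 1 else 0.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) of two binary volumes."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise CompareError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("Dice of two empty masks defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def overlap_proportion(
    network: NetworkMask | np.ndarray, atlas: CanonicalAtlas, label: int
) -> float:
    """|network ∩ canonical| / |canonical| for one atlas label."""
    vol = network.volume if isinstance(network, NetworkMask) else np.asarray(network)
    cmask = atlas.label_mask(label)
    denom = int(cmask.sum())
    if denom == 0:
        raise CompareError(f"atlas label {label} has no voxels")
    return int((vol.astype(bool) & cmask).sum()) / denom


def sample_random_foci(
    foci_per_contrast: Sequence[int], grid: VolumeGrid, rng: np.random.Generator
) -> list[np.ndarray]:
    """Uniform random foci: per contrast, the requested number of voxel
    centers drawn without replacement from the brain mask."""
    centers = grid.mask_centers_mm()
    out = []
    for n in foci_per_contrast:
        idx = rng.choice(len(centers), size=int(n), replace=False)
        out.append(centers[idx])
    return out


DeriveFn = Callable[[list[np.ndarray]], np.ndarray]


def null_networks(
    actual: NetworkMask | np.ndarray,
    foci_per_contrast: Sequence[int],
    derive: DeriveFn,
    grid: VolumeGrid,
    n: int = 1000,
    rng_seed: int = 0,
) -> NullDistribution:
    """Re-derive the full network ``n`` times from random contrast seeds
    and record each null network's Dice with the actual network.

    ``derive`` maps per-contrast focus coordinate lists to a binary
    consensus volume and must encapsulate the identical pipeline and
    configuration used for the actual network.
    """
    if n < 1:
        raise CompareError(f"need n >= 1 replicates, got {n}")
    actual_vol = (
        actual.volume if isinstance(actual, NetworkMask) else np.asarray(actual)
    ).astype(bool)
    rng = np.random.default_rng(rng_seed)
    vals = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-vs-empty Dice is a valid null value
        for i in range(n):
            foci = sample_random_foci(foci_per_contrast, grid, rng)
            vals[i] = dice(actual_vol, derive(foci))
    return NullDistribution(dice=vals, n_replicates=n, rng_seed=rng_seed)


def perm_test_dice(
    network: NetworkMask | np.ndarray,
    atlas: CanonicalAtlas,
    label: int,
    foci_per_contrast: Sequence[int],
    derive: DeriveFn,
    grid: VolumeGrid,
    n_perm: int = 1000,
    rng_seed: int = 0,
    null_masks: Sequence[np.ndarray] | None = None,
) -> float:
    """Permutation p-value for network-to-canonical Dice correspondence.

    The null re-derives the network from spatially randomized foci
    ``n_perm`` times; p = (1 + #{null Dice >= observed}) / (1 + n_perm)
    (add-one estimator, never 0).  Pre-computed null networks (e.g. from a
    surface spin test) can be passed via ``null_masks``.
    """
    if n_perm < 100 and null_masks is None:
        raise CompareError(f"need n_perm >= 100, got {n_perm}")
    vol = (
        network.volume if isinstance(network, NetworkMask) else np.asarray(network)
    ).astype(bool)
    cmask = atlas.label_mask(label)
    observed = dice(vol, cmask)
    rng = np.random.default_rng(rng_seed)
    if null_masks is None:
        null_masks = [
            derive(sample_random_foci(foci_per_contrast, grid, rng))
            for _ in range(n_perm)
        ]
    if all(not np.asarray(m).any() for m in null_masks):
        raise CompareError("degenerate null: every replicate network is empty")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_dice = np.array([dice(np.asarray(m), cmask) for m in null_masks])
    n_perm = len(null_dice)
    return float((1 + np.sum(null_dice >= observed)) / (1 + n_perm))


def report(
    overlaps: Sequence[OverlapResult],
    nulls: dict[str, NullDistribution] | None = None,
) -> pd.DataFrame:
    """One row per (direction, canonical label): overlap %, Dice, p.

    Serializable to TSV/JSON as-is; overlap proportions are echoed on the
    percentage scale used in polar plots.
    """
    if len(overlaps) == 0:
        raise CompareError("no overlap results to report")
    rows = [
        {
            "direction": o.direction,
            "label": o.label,
            "network": o.label_name,
            "overlap_pct": 100.0 * o.overlap_proportion,
            "dice": o.dice,
            "p_perm": o.p_perm,
        }
        for o in overlaps
    ]
    frame = pd.DataFrame(rows)
    if nulls:
        frame.attrs["null_dice"] = {
            d: {"mean": nd.mean, "sd": nd.sd, "n": nd.n_replicates}
            for d, nd in nulls.items()
        }
    return frame
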