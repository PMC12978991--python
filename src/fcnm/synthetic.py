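"""Synthetic cohorts with planted network structure.

Stands in for the large resting-state cohorts that a coordinate-network
mapping study draws on, with full ground truth so every downstream stage
can be validated: multi-subject 4D volumes whose voxels load on K planted
latent networks plus Gaussian noise, motion traces with occasional spikes,
foci drawn from inside planted source regions, and an atlas partition.

The generative model is a rank-1 block covariance per network: within one
subject, every voxel of network k follows

    y_v(t) = beta_k * s_k(t) + eps_v(t),

with s_k i.i.d. standard Gaussian latents shared across the network's
voxels and eps i.i.d. N(0, noise_sd^2); background voxels are pure noise.
The population correlation between two voxels of the same network is then
beta^2 / (beta^2 + noise_sd^2) in closed form, which calibrates the
seed-correlation stage.  Latents are temporally white by default (the
downstream statistics are correlation-based and do not model
autocorrelation); an AR(1) option exists for latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, Subject
from .compare import CANONICAL_LABELS, CanonicalAtlas
from .foci import FociTable
from .grid import VolumeGrid


class DesignError(ValueError):
    pass


@dataclass
class PlantedDesign:
    """Generative design for a synthetic cohort.

    ``networks`` maps a name to an (n, 3) voxel-index array; ``loadings``
    gives each network's signal amplitude beta (unitless, >= 0).
    ``tissue`` optionally names pure-noise regions (e.g. ``wm``/``csf``)
    used downstream as nuisance-signal masks; they may not overlap the
    networks.
    """

    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 3.0
    networks: dict[str, np.ndarray] = field(default_factory=dict)
    loadings: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    n_subjects: int = 30
    n_timepoints: int = 175
    tr_s: float = 2.0
    rng_seed: int = 0
    tissue: dict[str, np.ndarray] = field(default_factory=dict)
    ar1_coef: float = 0.0
    brain_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_timepoints < 20:
            raise DesignError(f"need n_timepoints >= 20, got {self.n_timepoints}")
        if self.noise_sd <= 0 or self.voxel_size_mm <= 0:
            raise DesignError("noise_sd and voxel_size_mm must be positive")
        if self.n_subjects < 1:
            raise DesignError("need at least one subject")
        for name in self.networks:
            beta = self.loadings.get(name)
            if beta is None:
                raise DesignError(f"network {name!r} has no loading")
            if beta < 0:
                raise DesignError(f"network {name!r}: loading must be >= 0")
        grid = self.grid()
        seen = np.zeros(self.grid_shape, dtype=bool)
        for name, vox in {**self.networks, **self.tissue}.items():
            vox = np.asarray(vox, dtype=int)
            if vox.ndim != 2 or vox.shape[1] != 3:
                raise DesignError(f"region {name!r}: voxel set must be (n, 3)")
            if np.any(vox < 0) or np.any(vox >= np.asarray(self.grid_shape)):
                raise DesignError(f"region {name!r}: voxels outside grid")
            if not grid.brain_mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
                raise DesignError(f"region {name!r}: voxels outside brain mask")
            if seen[vox[:, 0], vox[:, 1], vox[:, 2]].any():
                raise DesignError(f"region {name!r} overlaps another region")
            seen[vox[:, 0], vox[:, 1], vox[:, 2]] = True

    def grid(self) -> VolumeGrid:
        return VolumeGrid.pseudo_mni(
            self.grid_shape, self.voxel_size_mm, self.brain_mask
        )


@dataclass
class GroundTruth:
    """What the downstream pipeline is expected to recover."""

    grid: VolumeGrid
    networks: dict[str, np.ndarray]
    source_network_label: dict[str, str]  # direction -> network name
    target_network_labels: dict[str, list[str]]  # direction -> expected names
    foci_per_contrast: list[int] = field(default_factory=lambda: [3])

    def network_volume(self, name: str) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=bool)
        vox = self.networks[name]
        vol[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        return vol

    def target_volume(self, direction: str) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=bool)
        for name in self.target_network_labels[direction]:
            vol |= self.network_volume(name)
        return vol


def box_voxels(lo: tuple[int, int, int], hi: tuple[int, int, int]) -> np.ndarray:
    """(n, 3) voxel indices of the half-open box [lo, hi)."""
    axes = [np.arange(lo[a], hi[a]) for a in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    return np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)


def default_design(
    n_subjects: int = 30,
    beta: float = 1.0,
    noise_sd: float = 1.0,
    n_timepoints: int = 175,
    rng_seed: int = 0,
) -> tuple[PlantedDesign, GroundTruth]:
    """Desk-scale two-network design on the 20 x 24 x 20 grid at 3 mm.

    One 6^3-voxel source network per direction (hyper / hypo), two small
    pure-noise tissue boxes standing in for white matter and CSF, and the
    rest of the grid as background.  Both networks share the loading
    ``beta``; foci default to 3 per contrast.
    """
    networks = {
        "hyper_source": box_voxels((3, 4, 5), (9, 10, 11)),
        "hypo_source": box_voxels((12, 14, 8), (18, 20, 14)),
    }
    tissue = {
        "wm": box_voxels((1, 1, 1), (4, 4, 4)),
        "csf": box_voxels((16, 1, 16), (19, 4, 19)),
    }
    design = PlantedDesign(
        networks=networks,
        loadings={k: beta for k in networks},
        noise_sd=noise_sd,
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        rng_seed=rng_seed,
        tissue=tissue,
    )
    truth = GroundTruth(
        grid=design.grid(),
        networks=networks,
        source_network_label={"increase": "hyper_source", "decrease": "hypo_source"},
        target_network_labels={
            "increase": ["hyper_source"],
            "decrease": ["hypo_source"],
        },
        foci_per_contrast=[3],
    )
    return design, truth


def make_cohort(design: PlantedDesign, with_motion: bool = True) -> tuple[Cohort, VolumeGrid]:
    """Generate the cohort: per subject, network voxels carry the shared
    latent scaled by beta on top of i.i.d. Gaussian noise.

    Deterministic given ``design.rng_seed``.  Motion traces (gentle drift,
    occasional sub-threshold spikes) are attached when ``with_motion``.
    """
    grid = design.grid()
    rng = np.random.default_rng(design.rng_seed)
    T = design.n_timepoints
    subjects = []
    for s in range(design.n_subjects):
        data = rng.normal(0.0, design.noise_sd, size=(*design.grid_shape, T))
        for name, vox in design.networks.items():
            beta = design.loadings[name]
            latent = rng.standard_normal(T)
            if design.ar1_coef:
                a = design.ar1_coef
                for t in range(1, T):
                    latent[t] = a * latent[t - 1] + np.sqrt(1 - a * a) * latent[t]
            data[vox[:, 0], vox[:, 1], vox[:, 2], :] += beta * latent
        motion = None
        if with_motion:
            n_spikes = int(rng.integers(0, 3))
            spike_times = sorted(rng.choice(np.arange(5, T), n_spikes, replace=False))
            motion = make_motion(
                T,
                spike_times=spike_times,
                spike_mm=0.6,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        subjects.append(
            Subject(
                subject_id=f"sub-{s + 1:03d}",
                data=data.astype(np.float32),
                motion=motion,
            )
        )
    return Cohort(grid=grid, subjects=subjects), grid


def make_motion(
    n_timepoints: int,
    spike_times: list[int] | tuple[int, ...] = (),
    spike_mm: float = 0.0,
    rng_seed: int = 0,
    drift_mm: float = 0.05,
) -> np.ndarray:
    """T x 6 motion trace: smooth low-amplitude drift plus step
    displacements of ``spike_mm`` (x-translation) at ``spike_times``.

    Steps are persistent position changes, so each spike produces exactly
    one framewise-displacement excursion of magnitude ``spike_mm``.
    """
    if spike_mm < 0:
        raise DesignError(f"spike_mm must be >= 0, got {spike_mm}")
    for t in spike_times:
        if not (1 <= t < n_timepoints):
            raise DesignError(f"spike time {t} outside [1, {n_timepoints})")
    rng = np.random.default_rng(rng_seed)
    trace = np.zeros((n_timepoints, 6))
    if drift_mm > 0:
        # independent smooth stochastic drift per axis (Gaussian-smoothed
        # white noise), so the Friston-24 expansion stays full rank
        from scipy.ndimage import gaussian_filter1d

        raw = rng.standard_normal((n_timepoints, 6))
        smooth = gaussian_filter1d(raw, sigma=8.0, axis=0, mode="nearest")
        sd = smooth.std(axis=0)
        sd[sd == 0] = 1.0
        smooth = smooth / sd
        scales = np.array([drift_mm] * 3 + [drift_mm / 50.0] * 3)
        trace += smooth * scales
        # realignment estimates carry frame-to-frame measurement jitter;
        # without it the expanded motion design is rank-deficient at short T
        trace += rng.standard_normal((n_timepoints, 6)) * (0.02 * scales)
    for ts in spike_times:
        trace[ts:, 0] += spike_mm
    return trace


def emit_foci(
    truth: GroundTruth,
    n_contrasts: int,
    direction: str,
    rng_seed: int = 0,
) -> FociTable:
    """Sample per-contrast foci from inside the direction's source network.

    Each contrast draws its configured number of distinct voxel centers
    (mm, tagged MNI) without replacement from the source network.
    """
    if direction not in truth.source_network_label:
        raise DesignError(f"no source network for direction {direction!r}")
    source = truth.networks[truth.source_network_label[direction]]
    if len(source) == 0:
        raise DesignError("source network is empty")
    rng = np.random.default_rng(rng_seed)
    rows = []
    fpc = truth.foci_per_contrast
    for i in range(n_contrasts):
        n_f = int(fpc[i % len(fpc)])
        if n_f > len(source):
            raise DesignError(
                f"contrast {i}: {n_f} foci requested but source has {len(source)} voxels"
            )
        pick = rng.choice(len(source), size=n_f, replace=False)
        centers = truth.grid.voxel_to_mm(source[pick])
        for x, y, z in centers:
            rows.append(
                {
                    "study_id": f"synth{i + 1:02d}",
                    "contrast_id": f"{direction[:3]}_{i + 1:02d}",
                    "direction": direction,
                    "space": "MNI",
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    frame = pd.DataFrame(rows, columns=["study_id", "contrast_id", "direction", "space", "x", "y", "z"])
    return FociTable(frame, provenance={"generator": "emit_foci", "rng_seed": rng_seed})


def make_atlas(truth: GroundTruth) -> CanonicalAtlas:
    """Synthetic 8-network parcellation of the brain mask.

    The hyper-direction source box takes the subcortical label and the
    hypo-direction box the limbic label (echoing where treatment-change
    networks concentrate); remaining in-mask voxels are split into slabs
    along x across the other six labels.
    """
    grid = truth.grid
    vol = np.zeros(grid.shape, dtype=np.int16)
    others = [lab for lab in CANONICAL_LABELS if lab not in (5, 8)]
    x_edges = np.linspace(0, grid.shape[0], len(others) + 1)
    for i, lab in enumerate(others):
        lo, hi = int(x_edges[i]), int(x_edges[i + 1])
        vol[lo:hi, :, :] = lab
    hyper = truth.networks[truth.source_network_label["increase"]]
    hypo = truth.networks[truth.source_network_label["decrease"]]
    vol[hyper[:, 0], hyper[:, 1], hyper[:, 2]] = 8
    vol[hypo[:, 0], hypo[:, 1], hypo[:, 2]] = 5
    vol[~grid.brain_mask] = 0
    return CanonicalAtlas(volume=vol)
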