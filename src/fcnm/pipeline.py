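"""End-to-end driver: foci -> seeds -> FC -> group stats -> consensus ->
canonical-network comparison -> random-seed nulls.

The :class:`ConnectomeEngine` pre-standardizes every subject's in-mask
time series once, after which deriving a consensus network from any set
of contrast foci is a handful of matrix products per subject.  This is
what makes the null-network experiment (hundreds to a thousand full
pipeline re-runs with random seeds) tractable; a composition test
guarantees the engine matches the step-by-step module path exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import compare as _compare
from .cohort import Cohort, Subject
from .fc import FCError, R_CLIP
from .grid import VolumeGrid
from .group import (
    GroupTMap,
    NetworkMask,
    ProbabilityMap,
    binarize_contrast,
    correct,
    overlay_probability,
    threshold_consensus,
)
from .preprocess import (
    bandpass,
    build_confounds,
    gaussian_smooth,
    motion_exclude,
    nuisance_regress,
)
from .seeds import build_seed


@dataclass
class RunConfig:
    """All pipeline knobs, each with its default and rationale.

    Defaults follow the conventions of coordinate-based network mapping:
    4 mm seed spheres (1 and 7 mm as robustness alternates), voxel-level
    correction at alpha 0.05, a 50 % consensus threshold, 0.01-0.1 Hz
    band-pass, 0.5 mm FD spike threshold, 6 mm FWHM smoothing, 10 dummy
    volumes discarded, and 1000 random-seed null networks.
    """

    radius_mm: float = 4.0
    correction: str = "FDR_BH"  # or FWE_bonferroni
    alpha: float = 0.05
    consensus_fraction: float = 0.5
    bandpass_hz: tuple[float, float] = (0.01, 0.1)
    fd_spike_mm: float = 0.5
    fwhm_mm: float = 6.0
    discard_volumes: int = 10
    n_null: int = 1000
    rng_seed: int = 0
    tr_s: float = 2.0
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    use_global_signal: bool = True

    #: why each default is what it is (serialized with the config)
    rationale: dict = field(
        default_factory=lambda: {
            "radius_mm": "conventional sphere size for reported peaks; 1/7 mm robustness alternates",
            "correction": "voxel-level FDR (BH); Bonferroni FWE available for large cohorts",
            "consensus_fraction": "voxel kept when at least half the contrasts include it",
            "bandpass_hz": "standard resting-state fluctuation band",
            "fd_spike_mm": "Power FD spike threshold",
            "fwhm_mm": "common smoothing kernel for 3 mm voxels",
            "discard_volumes": "dummy scans dropped for signal equilibrium",
            "n_null": "random-seed networks for the chance baseline",
        }
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bandpass_hz"] = list(self.bandpass_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bandpass_hz" in d:
            d["bandpass_hz"] = tuple(d["bandpass_hz"])
        return cls(**d)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and offending artifact."""


def preprocess_subject(
    subject: Subject,
    grid: VolumeGrid,
    config: RunConfig,
    tissue_masks: dict[str, np.ndarray] | None = None,
) -> Subject | None:
    """Discard dummies, apply motion exclusion, regress nuisance
    covariates, band-pass, and smooth one subject.  Returns None when the
    subject is excluded for motion."""
    d = config.discard_volumes
    data = np.asarray(subject.data, dtype=np.float64)[..., d:]
    motion = subject.motion[d:] if subject.motion is not None else None
    if motion is not None and not motion_exclude(
        motion, config.trans_limit_mm, config.rot_limit_deg
    ):
        return None
    flat = data.reshape(-1, data.shape[3])
    midx = grid.mask_indices()
    ts = flat[midx, :].T  # T x V
    if motion is not None:
        signals: dict[str, np.ndarray] = {}
        if config.use_global_signal:
            signals["global"] = ts.mean(axis=1)
        for name, mask in (tissue_masks or {}).items():
            mvec = np.asarray(mask, dtype=bool).ravel()[midx]
            if mvec.any():
                signals[name] = ts[:, mvec].mean(axis=1)
        conf, names = build_confounds(motion, config.fd_spike_mm, signals)
        ts = nuisance_regress(ts, conf, names)
    ts = bandpass(ts, config.tr_s, *config.bandpass_hz)
    # fresh C-order array: reshape below must be a view for the assignment
    out = np.zeros(data.shape)
    out_flat = out.reshape(-1, out.shape[3])
    out_flat[midx, :] = ts.T
    if config.fwhm_mm > 0:
        for t in range(out.shape[3]):
            out[..., t] = gaussian_smooth(out[..., t], config.fwhm_mm, grid)
    return Subject(
        subject_id=subject.subject_id, data=out.astype(np.float32), motion=motion
    )


def preprocess_cohort(
    cohort: Cohort,
    config: RunConfig,
    tissue_masks: dict[str, np.ndarray] | None = None,
) -> Cohort:
    kept = []
    for s in cohort.subjects:
        try:
            ps = preprocess_subject(s, cohort.grid, config, tissue_masks)
        except Exception as exc:  # noqa: BLE001 - annotate stage + artifact
            raise PipelineError(f"preprocess failed for {s.subject_id}: {exc}") from exc
        if ps is not None:
            kept.append(ps)
    if not kept:
        raise PipelineError("preprocess: every subject excluded for motion")
    return Cohort(grid=cohort.grid, subjects=kept)


class ConnectomeEngine:
    """Pre-standardized cohort enabling fast repeated network derivation.

    Holds, per subject, the raw in-mask series (for seed means) and the
    centered unit-norm series (so seed-to-voxel Pearson correlation is one
    matrix product).  ``derive_network`` is a pure function of the foci
    and configuration, identical in output to composing the seed, FC and
    group modules step by step.
    """

    def __init__(self, cohort: Cohort, config: RunConfig | None = None):
        self.config = config or RunConfig()
        self.grid = cohort.grid
        self._midx = self.grid.mask_indices()
        # flat grid index -> masked column position
        self._pos = np.full(self.grid.n_voxels, -1, dtype=np.int64)
        self._pos[self._midx] = np.arange(len(self._midx))
        self.subject_ids = [s.subject_id for s in cohort.subjects]
        self._raw: list[np.ndarray] = []
        self._unit: list[np.ndarray] = []
        valid = np.ones(len(self._midx), dtype=bool)
        for s in cohort.subjects:
            X = cohort.timeseries_matrix(s)  # T x V float64
            col_mean = X.mean(axis=0)
            Xc = X - col_mean
            norms = np.linalg.norm(Xc, axis=0)
            # same zero-variance tolerance as fc_zmap (round-off of a
            # constant series is not variance)
            ok = norms > 1e-8 * np.sqrt(Xc.shape[0]) * (1.0 + np.abs(col_mean))
            valid &= ok
            U = np.zeros_like(Xc)
            U[:, ok] = Xc[:, ok] / norms[ok]
            self._raw.append(X)
            self._unit.append(U)
        self.valid_cols = valid
        self.n_subjects = len(self._raw)
        if self.n_subjects < 3:
            raise PipelineError(f"group stage needs >= 3 subjects, got {self.n_subjects}")

    # -- helpers ---------------------------------------------------------

    def _seed_columns(self, foci_mm: np.ndarray, radius_mm: float) -> np.ndarray:
        seed = build_seed(foci_mm, radius_mm, self.grid)
        cols = self._pos[seed.flat_indices()]
        return cols[cols >= 0]

    def contrast_tmaps(
        self, foci_per_contrast: list[np.ndarray], radius_mm: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
        """(C, V) t and one-sided p over masked voxels, df, validity."""
        radius = self.config.radius_mm if radius_mm is None else radius_mm
        cols = [self._seed_columns(f, radius) for f in foci_per_contrast]
        C, V, n = len(cols), len(self._midx), self.n_subjects
        sum_z = np.zeros((C, V))
        sum_z2 = np.zeros((C, V))
        for s in range(n):
            raw, unit = self._raw[s], self._unit[s]
            S = np.stack([raw[:, c].mean(axis=1) for c in cols], axis=1)
            S = S - S.mean(axis=0)
            norms = np.linalg.norm(S, axis=0)
            if np.any(norms == 0):
                bad = [i for i in range(C) if norms[i] == 0]
                raise FCError(f"zero-variance seed series (contrasts {bad})")
            S = S / norms
            r = S.T @ unit
            z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
            sum_z += z
            sum_z2 += z * z
        mean = sum_z / n
        var = np.maximum(sum_z2 - n * mean**2, 0.0) / (n - 1)
        sd = np.sqrt(var)
        valid = self.valid_cols[None, :] & (sd > 0)
        t = np.zeros((C, V))
        np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
        df = n - 1
        p = np.ones((C, V))
        p[valid] = stats.t.sf(t[valid], df)
        return t, p, df, valid

    def derive_network(
        self,
        foci_per_contrast: list[np.ndarray],
        direction: str = "",
        radius_mm: float | None = None,
        return_details: bool = False,
    ):
        """Full seed->FC->t->correct->binarize->overlay->threshold run.

        Returns the binary consensus volume; with ``return_details`` also
        the :class:`ProbabilityMap` and per-contrast binary volumes.
        """
        cfg = self.config
        t, p, df, valid = self.contrast_tmaps(foci_per_contrast, radius_mm)
        C, V = t.shape
        counts = np.zeros(V, dtype=np.int32)
        binaries = []
        for c in range(C):
            tmap = GroupTMap(
                contrast_id=f"c{c}",
                t=t[c],
                p=p[c],
                df=df,
                valid=valid[c],
            )
            sig = correct(tmap, cfg.correction, cfg.alpha)
            b = binarize_contrast(tmap, sig)
            counts += b
            if return_details:
                binaries.append(b)
        consensus_cols = counts >= cfg.consensus_fraction * C - 1e-9
        volume = np.zeros(self.grid.shape, dtype=bool)
        volume.ravel()[self._midx] = consensus_cols
        if not return_details:
            return volume
        frac = np.zeros(self.grid.shape)
        frac.ravel()[self._midx] = counts / C
        pmap = ProbabilityMap(direction=direction, fraction=frac, n_contrasts=C)
        network = NetworkMask(
            direction=direction,
            volume=volume,
            threshold_fraction=cfg.consensus_fraction,
            provenance={
                "radius_mm": radius_mm or cfg.radius_mm,
                "correction": cfg.correction,
                "alpha": cfg.alpha,
                "n_contrasts": C,
                "n_subjects": self.n_subjects,
            },
        )
        bvols = []
        for b in binaries:
            bv = np.zeros(self.grid.shape, dtype=bool)
            bv.ravel()[self._midx] = b
            bvols.append(bv)
        return network, pmap, bvols


@dataclass
class DirectionResult:
    direction: str
    network: NetworkMask
    probability: ProbabilityMap
    contrast_maps: list[np.ndarray]
    overlaps: list[_compare.OverlapResult] = field(default_factory=list)
    nulls: _compare.NullDistribution | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    directions: dict[str, DirectionResult]
    report: "object" = None  # pandas DataFrame when an atlas was supplied


def run_pipeline(
    config: RunConfig,
    foci_table,
    cohort: Cohort,
    atlas: _compare.CanonicalAtlas | None = None,
    tissue_masks: dict[str, np.ndarray] | None = None,
    preprocessed: bool = False,
) -> PipelineResult:
    """Execute the whole mapping for every direction present in the foci.

    Deterministic stages are bit-reproducible; the null-network stage is
    reproducible given ``config.rng_seed``.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    from .foci import convert_to_mni, group_contrasts

    foci_table = convert_to_mni(foci_table)
    if not preprocessed:
        cohort = preprocess_cohort(cohort, config, tissue_masks)
    engine = ConnectomeEngine(cohort, config)
    directions: dict[str, DirectionResult] = {}
    overlaps_all: list[_compare.OverlapResult] = []
    nulls_all: dict[str, _compare.NullDistribution] = {}
    present = [
        d for d in ("increase", "decrease") if (foci_table.frame["direction"] == d).any()
    ]
    for di, direction in enumerate(present):
        groups = group_contrasts(foci_table, direction)
        foci_lists = list(groups.values())
        try:
            network, pmap, bvols = engine.derive_network(
                foci_lists, direction=direction, return_details=True
            )
        except Exception as exc:
            raise PipelineError(f"group_network stage failed ({direction}): {exc}") from exc
        res = DirectionResult(
            direction=direction, network=network, probability=pmap, contrast_maps=bvols
        )
        if config.n_null > 0:
            fpc = [len(f) for f in foci_lists]
            rng_seed = int((config.rng_seed + 7919 * di) % (2**31 - 1))
            rng = np.random.default_rng(rng_seed)
            null_masks = [
                engine.derive_network(
                    _compare.sample_random_foci(fpc, engine.grid, rng)
                )
                for _ in range(config.n_null)
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vals = np.array([_compare.dice(network.volume, m) for m in null_masks])
            res.nulls = _compare.NullDistribution(
                dice=vals, n_replicates=config.n_null, rng_seed=rng_seed
            )
            nulls_all[direction] = res.nulls
        else:
            null_masks = None
        if atlas is not None:
            for label, name in atlas.labels.items():
                if not atlas.label_mask(label).any():
                    continue
                ov = _compare.overlap_proportion(network, atlas, label)
                dc = _compare.dice(network.volume, atlas.label_mask(label))
                p_perm = None
                if null_masks is not None:
                    try:
                        p_perm = _compare.perm_test_dice(
                            network,
                            atlas,
                            label,
                            [len(f) for f in foci_lists],
                            engine.derive_network,
                            engine.grid,
                            null_masks=null_masks,
                        )
                    except _compare.CompareError:
                        p_perm = None  # degenerate null; reported as missing
                res.overlaps.append(
                    _compare.OverlapResult(
                        direction=direction,
                        label=label,
                        label_name=name,
                        overlap_proportion=ov,
                        dice=dc,
                        p_perm=p_perm,
                    )
                )
            overlaps_all.extend(res.overlaps)
        directions[direction] = res
    rep = _compare.report(overlaps_all, nulls_all) if overlaps_all else None
    return PipelineResult(config=config, directions=directions, report=rep)
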