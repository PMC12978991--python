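"""NIfTI / TSV / YAML / JSON I/O for pipeline artifacts.

Volumes are NIfTI-1 via nibabel, float32 on disk (statistics accumulate
in float64 in memory).  Motion traces use the 6-column whitespace text
dialect of SPM realignment parameter files.  Every output directory can
carry a JSON provenance sidecar sufficient to re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, Subject
from .compare import CanonicalAtlas
from .grid import GridError, VolumeGrid


class IOError_(ValueError):
    pass


def read_volume(
    path: str | Path, expect_4d: bool | None = None
) -> tuple[np.ndarray, VolumeGrid]:
    """Load a NIfTI volume and its grid (brain mask defaults to all-true).

    ``expect_4d`` enforces dimensionality: passing a 3D file where 4D is
    required (or vice versa) is a typed error, not a silent reshape.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if expect_4d is True and data.ndim != 4:
        raise IOError_(f"{path}: expected 4D volume, got {data.ndim}D")
    if expect_4d is False and data.ndim != 3:
        raise IOError_(f"{path}: expected 3D volume, got {data.ndim}D")
    shape3 = data.shape[:3]
    grid = VolumeGrid(
        shape=shape3, affine=np.asarray(img.affine), brain_mask=np.ones(shape3, bool)
    )
    return data, grid


def write_volume(
    vol: np.ndarray, grid: VolumeGrid, path: str | Path, dtype=np.float32
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol, dtype=dtype), grid.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    data, grid = read_volume(path, expect_4d=False)
    return data > 0.5, grid


def read_motion(path: str | Path) -> np.ndarray:
    motion = np.loadtxt(path)
    motion = np.atleast_2d(motion)
    if motion.shape[1] != 6:
        raise IOError_(f"{path}: motion file must have 6 columns, got {motion.shape[1]}")
    return motion


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.8f")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """One ``{subject}_bold.nii.gz`` + ``{subject}_motion.txt`` per subject,
    plus the brain mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_volume(s.data, cohort.grid, out / f"{s.subject_id}_bold.nii.gz")
        if s.motion is not None:
            write_motion(s.motion, out / f"{s.subject_id}_motion.txt")
    write_volume(
        cohort.grid.brain_mask.astype(np.uint8),
        cohort.grid,
        out / "brain_mask.nii.gz",
        dtype=np.uint8,
    )


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    bolds = sorted(in_dir.glob("*_bold.nii.gz"))
    if not bolds:
        raise IOError_(f"no *_bold.nii.gz files in {in_dir}")
    mask_path = in_dir / "brain_mask.nii.gz"
    mask, mask_grid = (None, None)
    if mask_path.exists():
        mask, mask_grid = read_mask(mask_path)
    subjects = []
    grid = None
    for b in bolds:
        data, g = read_volume(b, expect_4d=True)
        if grid is None:
            bm = mask if mask is not None else np.ones(g.shape, bool)
            grid = VolumeGrid(shape=g.shape, affine=g.affine, brain_mask=bm)
        elif not grid.same_geometry(g):
            raise GridError(
                f"{b}: affine mismatch with first volume\n{g.affine}\nvs\n{grid.affine}"
            )
        sid = b.name.replace("_bold.nii.gz", "")
        mfile = in_dir / f"{sid}_motion.txt"
        motion = read_motion(mfile) if mfile.exists() else None
        subjects.append(
            Subject(subject_id=sid, data=np.asarray(data, np.float32), motion=motion)
        )
    return Cohort(grid=grid, subjects=subjects)


def read_atlas(volume_path: str | Path, labels_path: str | Path | None = None):
    data, grid = read_volume(volume_path, expect_4d=False)
    labels = None
    if labels_path is not None:
        tab = pd.read_csv(labels_path, sep="\t")
        labels = dict(zip(tab["label"].astype(int), tab["network"].astype(str)))
    vol = np.rint(data).astype(np.int16)
    atlas = (
        CanonicalAtlas(volume=vol, labels=labels)
        if labels is not None
        else CanonicalAtlas(volume=vol)
    )
    return atlas, grid


def write_atlas(atlas: CanonicalAtlas, grid: VolumeGrid, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(atlas.volume, grid, out / "atlas.nii.gz", dtype=np.int16)
    pd.DataFrame(
        {"label": list(atlas.labels), "network": list(atlas.labels.values())}
    ).to_csv(out / "atlas_labels.tsv", sep="\t", index=False)


def load_config(path: str | Path):
    from .pipeline import RunConfig

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir: str | Path, config, inputs: dict | None = None) -> None:
    """Config + software versions + input hashes, as a JSON sidecar."""
    import nibabel
    import scipy

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {
        "config": config.to_dict(),
        "versions": {
            "fcnm": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nibabel.__version__,
            "pandas": pd.__version__,
        },
        "input_hashes": {
            k: file_sha256(v) for k, v in (inputs or {}).items() if Path(v).is_file()
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
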