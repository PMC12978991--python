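"""Ingest and normalize study focus coordinates.

A *focus* is one reported peak coordinate from a published within-subject
contrast (post- vs pre-treatment), tagged with a direction of functional
change (``increase``/``decrease``) and a stereotaxic space (``MNI`` or
``TAL``).  Contrasts, not studies, are the unit of analysis: every contrast
contributes one set of foci and exactly one direction, and later votes once
in the consensus overlay.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DIRECTIONS = ("increase", "decrease")
SPACES = ("MNI", "TAL")
REQUIRED_COLUMNS = ("study_id", "contrast_id", "direction", "space", "x", "y", "z")

#: Lancaster et al. "icbm2tal" affine fitted for SPM-normalized data:
#: maps MNI (ICBM) mm coordinates to Talairach mm coordinates.  The
#: Talairach -> MNI conversion applies its inverse.
ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

COORD_LIMIT_MM = 120.0


class FociError(ValueError):
    """Base class for foci-table validation failures."""


class FociSchemaError(FociError):
    pass


class FociValueError(FociError):
    """Row-level validation failure; carries offending row indices."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


@dataclass
class FociTable:
    """Validated focus table plus provenance of where it came from."""

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = validate_frame(self.frame)

    @property
    def n_foci(self) -> int:
        return len(self.frame)

    @property
    def contrast_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["contrast_id"]))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate column schema, vocabularies, coordinate ranges and the
    one-direction-per-contrast rule. Returns a normalized copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FociSchemaError(f"missing required columns: {missing}")
    out = frame.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["study_id"] = out["study_id"].astype(str)
    out["contrast_id"] = out["contrast_id"].astype(str)
    out["direction"] = out["direction"].astype(str).str.strip().str.lower()
    out["space"] = out["space"].astype(str).str.strip().str.upper()

    bad = [i for i, d in enumerate(out["direction"]) if d not in DIRECTIONS]
    if bad:
        raise FociValueError(
            f"direction must be one of {DIRECTIONS}", bad
        )
    bad = [i for i, s in enumerate(out["space"]) if s not in SPACES]
    if bad:
        raise FociValueError(f"space must be one of {SPACES}", bad)

    for axis in ("x", "y", "z"):
        coerced = pd.to_numeric(out[axis], errors="coerce")
        bad = list(np.flatnonzero(coerced.isna().to_numpy()))
        if bad:
            raise FociValueError(f"non-numeric {axis} coordinate", [int(b) for b in bad])
        out[axis] = coerced.astype(float)
    coords = out[["x", "y", "z"]].to_numpy()
    bad = list(np.flatnonzero((np.abs(coords) > COORD_LIMIT_MM).any(axis=1)))
    if bad:
        raise FociValueError(
            f"coordinate magnitude exceeds {COORD_LIMIT_MM} mm", [int(b) for b in bad]
        )

    ndir = out.groupby("contrast_id", sort=False)["direction"].nunique()
    mixed = list(ndir.index[ndir > 1])
    if mixed:
        raise FociError(
            f"contrasts with more than one direction label: {mixed}"
        )
    return out.reset_index(drop=True)


def parse_foci(path: str | Path, dialect: str = "tsv") -> FociTable:
    """Parse a TSV (default) or CSV foci file into a validated table.

    Row order is preserved; schema and vocabulary violations raise
    :class:`FociSchemaError` / :class:`FociValueError` with row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FociSchemaError(f"empty foci file: {path}") from exc
    if len(frame) == 0:
        raise FociSchemaError(f"foci file has a header but no rows: {path}")
    table = FociTable(
        frame,
        provenance={
            "source_file": str(path),
            "dialect": dialect,
            "parsed_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        },
    )
    return table


def tal_to_mni(x: float, y: float, z: float) -> tuple[float, float, float]:
    """Convert one Talairach mm coordinate to MNI mm.

    Applies the inverse of the Lancaster icbm2tal (SPM flavour) affine.
    Pure function; batch conversion is row-wise application.
    """
    p = np.linalg.solve(ICBM_SPM2TAL, np.array([x, y, z, 1.0]))
    return (float(p[0]), float(p[1]), float(p[2]))


def convert_to_mni(table: FociTable) -> FociTable:
    """Return a copy with all TAL rows converted to MNI."""
    frame = table.frame.copy()
    tal = frame["space"] == "TAL"
    if tal.any():
        pts = frame.loc[tal, ["x", "y", "z"]].to_numpy()
        ones = np.hstack([pts, np.ones((len(pts), 1))])
        mni = np.linalg.solve(ICBM_SPM2TAL, ones.T).T[:, :3]
        frame.loc[tal, ["x", "y", "z"]] = mni
        frame.loc[tal, "space"] = "MNI"
    prov = dict(table.provenance)
    prov["tal_to_mni"] = "lancaster_icbm_spm2tal_inverse"
    return FociTable(frame, provenance=prov)


def group_contrasts(table: FociTable, direction: str) -> dict[str, np.ndarray]:
    """Per-contrast (n, 3) mm coordinate arrays for one direction.

    Only contrasts labelled with the requested direction are returned;
    duplicate coordinates within a contrast are collapsed to one (first
    occurrence kept).  All rows must already be in MNI space.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if (table.frame["space"] != "MNI").any():
        raise FociError("table contains TAL rows; run convert_to_mni first")
    groups: dict[str, np.ndarray] = {}
    sub = table.frame[table.frame["direction"] == direction]
    for cid, g in sub.groupby("contrast_id", sort=False):
        coords = g[["x", "y", "z"]].drop_duplicates().to_numpy(dtype=float)
        groups[cid] = coords
    if not groups:
        warnings.warn(f"no contrasts with direction={direction!r}", stacklevel=2)
    return groups
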