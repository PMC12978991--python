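"""In-memory containers for a resting-state cohort on a common grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid, require_same_grid


@dataclass
class Subject:
    """One subject's 4D BOLD data (x, y, z, t) plus motion parameters.

    ``motion`` follows the SPM realignment-parameter convention: T rows of
    three translations (mm) and three rotations (radians).
    """

    subject_id: str
    data: np.ndarray = field(repr=False)
    motion: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(
                f"subject {self.subject_id}: expected 4D data, got {self.data.ndim}D"
            )
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.ndim != 2 or self.motion.shape[1] != 6:
                raise ValueError(
                    f"subject {self.subject_id}: motion must be T x 6, "
                    f"got {self.motion.shape}"
                )
            if self.motion.shape[0] != self.data.shape[3]:
                raise ValueError(
                    f"subject {self.subject_id}: motion rows "
                    f"({self.motion.shape[0]}) != volumes ({self.data.shape[3]})"
                )

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])


@dataclass
class Cohort:
    """A list of subjects sharing one :class:`VolumeGrid`."""

    grid: VolumeGrid
    subjects: list[Subject]

    def __post_init__(self) -> None:
        for s in self.subjects:
            if s.data.shape[:3] != self.grid.shape:
                raise ValueError(
                    f"subject {s.subject_id}: data shape {s.data.shape[:3]} "
                    f"!= grid shape {self.grid.shape}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def timeseries_matrix(self, subject: Subject) -> np.ndarray:
        """(T, n_mask_voxels) float64 view of one subject's in-mask series."""
        flat = subject.data.reshape(-1, subject.data.shape[3])
        return np.asarray(flat[self.grid.mask_indices(), :].T, dtype=np.float64)


def check_cohort_grids(cohort: Cohort, *grids: VolumeGrid) -> None:
    require_same_grid(cohort.grid, *grids)
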