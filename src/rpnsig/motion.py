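"""Head-motion quality control from rigid-body realignment parameters.

Framewise displacement (FD) follows Power's convention: the sum of absolute
backward differences of the three translations (mm) plus the three rotations
converted to arc length on a 50 mm sphere.  Frames with FD above a threshold
(default 0.15 mm) are censored ("scrubbed"); subjects are excluded when mean
FD exceeds 0.15 mm or more than 30% of frames are scrubbed.  The Friston-24
expansion provides motion nuisance regressors: the 6 parameters, their
squares, their backward differences and the squared differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotionParams",
    "FDSeries",
    "CensorMask",
    "framewise_displacement",
    "friston24",
    "censor_mask",
    "subject_motion_exclusion",
    "read_motion_params",
]

FD_THRESHOLD_MM = 0.15
MEAN_FD_LIMIT_MM = 0.15
SCRUB_LIMIT = 0.30
SPHERE_RADIUS_MM = 50.0

FRISTON24_COLUMNS = tuple(
    f"{name}_{kind}"
    for kind in ("raw", "sq", "diff", "diffsq")
    for name in ("rx", "ry", "rz", "tx", "ty", "tz")
)


@dataclass
class MotionParams:
    """Per-frame rigid-body parameters: rotations (rad) and translations (mm)."""

    rotations: np.ndarray  # (T, 3) radians
    translations: np.ndarray  # (T, 3) mm
    tr: float = 2.5
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        if self.rotations.shape != self.translations.shape or self.rotations.shape[1] != 3:
            raise ValueError("rotations and translations must both be (T, 3)")
        if self.n_frames < 2:
            raise ValueError("at least 2 frames required")
        if not (np.all(np.isfinite(self.rotations)) and np.all(np.isfinite(self.translations))):
            raise ValueError("non-finite motion parameter")

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """(T, 6) array, rotations then translations."""
        return np.hstack([self.rotations, self.translations])


@dataclass
class FDSeries:
    """Framewise displacement (mm) with summary statistics."""

    values: np.ndarray
    radius: float = SPHERE_RADIUS_MM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean_fd(self) -> float:
        return float(self.values.mean())

    @property
    def median_fd(self) -> float:
        return float(np.median(self.values))

    @property
    def max_fd(self) -> float:
        return float(self.values.max())


@dataclass
class CensorMask:
    """Boolean per-frame retention mask (True = retain)."""

    retain: np.ndarray
    threshold: float = FD_THRESHOLD_MM

    def __post_init__(self) -> None:
        self.retain = np.asarray(self.retain, dtype=bool)

    @property
    def scrub_fraction(self) -> float:
        return float((~self.retain).sum() / self.retain.size)

    @property
    def n_retained(self) -> int:
        return int(self.retain.sum())


def framewise_displacement(motion: MotionParams, radius: float = SPHERE_RADIUS_MM) -> FDSeries:
    """Power framewise displacement; the first frame is defined as 0."""
    drot = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    dtrans = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dtrans + radius * drot])
    return FDSeries(values=fd, radius=radius)


def friston24(motion: MotionParams) -> np.ndarray:
    """(T, 24) nuisance block: [p, p², Δp, (Δp)²] for the 6 parameters.

    Backward differences; the first row of the derivative blocks is 0.
    Column order is :data:`FRISTON24_COLUMNS`.
    """
    p = motion.matrix
    dp = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    return np.hstack([p, p**2, dp, dp**2])


def censor_mask(fd: FDSeries, threshold: float = FD_THRESHOLD_MM,
                augment_neighbours: bool = False) -> CensorMask:
    """Retain frames with FD <= threshold (strictly above is scrubbed).

    ``augment_neighbours`` additionally drops the frame following each flagged
    frame (off by default; plain single-frame scrubbing is the reference
    behaviour).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    bad = fd.values > threshold
    if augment_neighbours:
        bad[1:] |= bad[:-1]
    return CensorMask(retain=~bad, threshold=threshold)


def subject_motion_exclusion(
    fd: FDSeries,
    mask: CensorMask,
    mean_fd_limit: float = MEAN_FD_LIMIT_MM,
    scrub_limit: float = SCRUB_LIMIT,
) -> tuple[str, list[str]]:
    """Subject-level QC decision.

    Mean FD is computed over all frames (pre-scrubbing).  Returns
    ``("keep"|"exclude", reasons)`` with every triggered reason listed.
    """
    reasons = []
    if fd.mean_fd > mean_fd_limit:
        reasons.append(f"mean FD {fd.mean_fd:.3f} mm > {mean_fd_limit} mm")
    if mask.scrub_fraction > scrub_limit:
        reasons.append(
            f"scrubbed fraction {mask.scrub_fraction:.2f} > {scrub_limit:.2f}"
        )
    return ("exclude" if reasons else "keep"), reasons


def read_motion_params(path, tr: float = 2.5, order: str = "rot-trans",
                       subject_id: str = "") -> MotionParams:
    """Read a 6-column whitespace/tab-delimited realignment parameter file.

    ``order`` is ``"rot-trans"`` (rotations in rad first, the realignment-tool
    convention) or ``"trans-rot"``.
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"expected 6 columns, found {arr.shape[1]}")
    if order == "rot-trans":
        rot, trans = arr[:, :3], arr[:, 3:]
    elif order == "trans-rot":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:
        raise ValueError("order must be 'rot-trans' or 'trans-rot'")
    return MotionParams(rotations=rot, translations=trans, tr=tr, subject_id=subject_id)


def qc_summary(fd: FDSeries, mask: CensorMask) -> dict:
    """JSON-serialisable QC record for one subject."""
    decision, reasons = subject_motion_exclusion(fd, mask)
    return {
        "mean_fd": fd.mean_fd,
        "median_fd": fd.median_fd,
        "max_fd": fd.max_fd,
        "scrub_fraction": mask.scrub_fraction,
        "decision": decision,
        "reasons": reasons,
    }
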