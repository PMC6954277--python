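"""Regional-timeseries signal cleaning.

Mirrors the standard resting-state confound-removal sequence on tabular
regional signals: anatomical-CompCor principal components extracted from a
noise-region signal matrix, nuisance regression (CompCor + Friston-24 +
linear trend) by ordinary least squares, an ideal Fourier-domain bandpass
(0.008–0.08 Hz by default) and finally frame censoring.  The fixed order —
regression, then filtering, then scrubbing — is the reference sequence; note
that filtering before censoring means censored frames still influenced the
filter output of retained frames.

Bandpass filtering here acts on regional averages rather than voxel data;
linear filters commute with spatial averaging only approximately once
grey-matter masking varies across subjects, so this is an approximation of
the voxel-level operation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .motion import CensorMask, MotionParams, censor_mask, framewise_displacement, friston24

__all__ = [
    "RegionalTimeseries",
    "NuisanceSet",
    "compcor_components",
    "nuisance_regression",
    "bandpass",
    "apply_censoring",
    "clean_timeseries",
]

MIN_FRAMES_AFTER_CENSORING = 50
BANDPASS_LOW_HZ = 0.008
BANDPASS_HIGH_HZ = 0.08


@dataclass
class RegionalTimeseries:
    """frames × nodes signal matrix with node metadata.

    When a global grey-matter node is present it is by convention the last
    node (label ``"mean GM"``).
    """

    data: np.ndarray
    labels: list[str]
    tr: float = 2.5
    modules: list[str] | None = None
    subject_id: str = ""
    censor: CensorMask | None = None
    retained_indices: np.ndarray | None = None  # original frame indices after censoring

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        if self.data.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[1]} signal columns but {len(self.labels)} labels"
            )
        if self.modules is not None and len(self.modules) != len(self.labels):
            raise ValueError("one module label per node required")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def to_tsv(self, path, sidecar: bool = True) -> None:
        df = pd.DataFrame(self.data, columns=self.labels)
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {"tr": self.tr, "subject_id": self.subject_id,
                    "modules": self.modules}
            Path(str(path)).with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path, tr: float | None = None) -> "RegionalTimeseries":
        df = pd.read_csv(path, sep="\t")
        meta_path = Path(str(path)).with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        if tr is None:
            tr = meta.get("tr", 2.5)
        return cls(data=df.to_numpy(), labels=list(df.columns), tr=tr,
                   modules=meta.get("modules"), subject_id=meta.get("subject_id", ""))


@dataclass
class NuisanceSet:
    """Named blocks of nuisance regressors, frames × q when stacked."""

    blocks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.blocks = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in self.blocks.items()}
        frames = {v.shape[0] for v in self.blocks.values()}
        if len(frames) > 1:
            raise ValueError(f"nuisance blocks disagree on frame count: {frames}")

    @property
    def matrix(self) -> np.ndarray:
        return np.hstack(list(self.blocks.values()))

    @property
    def n_frames(self) -> int:
        return next(iter(self.blocks.values())).shape[0]


def compcor_components(noise_signals: np.ndarray, n_components: int = 6) -> np.ndarray:
    """Leading principal components of a noise-region signal matrix.

    Columns are the top left-singular vectors of the column-demeaned noise
    matrix (unit norm, ordered by explained variance); each component's sign
    is fixed so that its largest-magnitude loading is positive.
    """
    x = np.atleast_2d(np.asarray(noise_signals, dtype=float))
    t, q = x.shape
    if q < n_components:
        raise ValueError(f"{q} noise signals cannot yield {n_components} components")
    if t <= n_components:
        raise ValueError("more frames than components required")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    comps = u[:, :n_components]
    loadings = vt[:n_components]
    flip = np.sign(loadings[np.arange(n_components), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return comps * flip


def nuisance_regression(
    ts: RegionalTimeseries, nuisance: NuisanceSet, add_linear_trend: bool = True
) -> RegionalTimeseries:
    """Residualise every node's signal against the nuisance set by OLS.

    The design always contains an intercept; a linear trend column is added
    unless already provided.  A rank-deficient design triggers a warning and
    a minimum-norm (pseudo-inverse) solution.
    """
    if nuisance.n_frames != ts.n_frames:
        raise ValueError("nuisance frame count does not match timeseries")
    t = ts.n_frames
    cols = [np.ones((t, 1))]
    if add_linear_trend:
        cols.append(np.linspace(-1.0, 1.0, t)[:, None])
    cols.append(nuisance.matrix)
    design = np.hstack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"rank-deficient nuisance design (rank {rank} < {design.shape[1]}); "
            "using pseudo-inverse", stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return replace(ts, data=resid)


def bandpass(
    ts: RegionalTimeseries,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
    method: str = "fourier",
    order: int = 4,
) -> RegionalTimeseries:
    """Temporal bandpass per node.

    ``method="fourier"`` (default) is an ideal discrete-Fourier filter:
    frequency bins inside [low, high] are kept, all others (including DC) are
    zeroed — idempotent by construction.  ``method="butterworth"`` applies a
    zero-phase Butterworth filter instead.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyquist:.4f} Hz")
    if method == "fourier":
        freqs = np.fft.rfftfreq(ts.n_frames, d=ts.tr)
        keep = (freqs >= low) & (freqs <= high)
        spec = np.fft.rfft(ts.data, axis=0)
        spec[~keep] = 0.0
        out = np.fft.irfft(spec, n=ts.n_frames, axis=0)
    elif method == "butterworth":
        sos = _sig.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
        out = _sig.sosfiltfilt(sos, ts.data - ts.data.mean(axis=0), axis=0)
    else:
        raise ValueError("method must be 'fourier' or 'butterworth'")
    return replace(ts, data=out)


def apply_censoring(
    ts: RegionalTimeseries, mask: CensorMask, min_frames: int = MIN_FRAMES_AFTER_CENSORING
) -> RegionalTimeseries:
    """Drop censored frames, keeping original frame indices for provenance."""
    if mask.retain.size != ts.n_frames:
        raise ValueError("mask length does not match frame count")
    idx = np.flatnonzero(mask.retain)
    if idx.size < min_frames:
        raise ValueError(
            f"only {idx.size} frames would remain after censoring "
            f"(minimum {min_frames})"
        )
    return replace(ts, data=ts.data[idx], censor=mask, retained_indices=idx)


def clean_timeseries(
    ts: RegionalTimeseries,
    motion: MotionParams,
    noise_signals: np.ndarray | None = None,
    n_compcor: int = 6,
    fd_threshold: float = 0.15,
    low: float = BANDPASS_LOW_HZ,
    high: float = BANDPASS_HIGH_HZ,
    min_frames: int = MIN_FRAMES_AFTER_CENSORING,
) -> tuple[RegionalTimeseries, dict]:
    """Full cleaning sequence: nuisance regression → bandpass → scrubbing.

    Returns the cleaned timeseries and a QC dictionary (FD summaries, scrub
    fraction, exclusion decision).
    """
    from .motion import qc_summary

    blocks = {"friston24": friston24(motion)}
    if noise_signals is not None:
        blocks["compcor"] = compcor_components(noise_signals, n_compcor)
    nuisance = NuisanceSet(blocks=blocks)
    fd = framewise_displacement(motion)
    mask = censor_mask(fd, threshold=fd_threshold)
    out = nuisance_regression(ts, nuisance)
    out = bandpass(out, low=low, high=high)
    out = apply_censoring(out, mask, min_frames=min_frames)
    return out, qc_summary(fd, mask)
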