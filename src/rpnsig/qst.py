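"""Quantitative sensory testing (QST) threshold computation and composite scoring.

Single-modality pain thresholds are computed from raw trials:

* thermal thresholds (heat/cold pain, HPT/CPT) as the arithmetic mean of the
  repeated threshold temperatures after discarding the first trial (a test
  stimulus),
* the mechanical pain threshold (MPT) as the log10 of the geometric mean
  pinprick force over ascending/descending staircase runs, and
* T50, the temperature producing a heat-pain rating of 50/100, from a
  second-order polynomial fit of rating against temperature.

Thresholds are aggregated into a composite pain-sensitivity score: each
modality is z-scored against reference (training-population) statistics, HPT
and MPT are sign-inverted so that larger values always mean *more* sensitive,
and the adjusted z-values are averaged.  Subjects with extreme values in at
least two of the three modalities (relative to user-supplied normative 95%
bounds) are flagged for exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QSTRecord",
    "ReferenceStats",
    "PainSensitivityScore",
    "NormativeBounds",
    "thermal_pain_threshold",
    "mechanical_pain_threshold",
    "t50_from_ratings",
    "composite_pain_sensitivity",
    "flag_extreme_qst",
    "score_trials_table",
]

#: modalities entering the composite score; HPT and MPT are sign-inverted
#: because *lower* heat/force thresholds mean higher sensitivity.
COMPOSITE_MODALITIES = ("hpt", "cpt", "mpt")
_SIGN = {"hpt": -1.0, "cpt": 1.0, "mpt": -1.0}


@dataclass
class QSTRecord:
    """Post-aggregation thresholds for one subject.

    ``hpt``/``cpt`` in °C, ``mpt`` in log10 mN.  Detection thresholds
    (``wdt``, ``cdt``, ``mdt``) and ``t50`` are optional pass-through values.
    """

    subject_id: str
    hpt: float | None = None
    cpt: float | None = None
    mpt: float | None = None
    wdt: float | None = None
    cdt: float | None = None
    mdt: float | None = None
    t50: float | None = None

    def __post_init__(self) -> None:
        if self.hpt is not None and self.cpt is not None and not self.hpt > self.cpt:
            raise ValueError(
                f"{self.subject_id}: heat pain threshold ({self.hpt}) must exceed "
                f"cold pain threshold ({self.cpt})"
            )
        if self.mpt is not None and not np.isfinite(self.mpt):
            raise ValueError(f"{self.subject_id}: MPT must be finite")


@dataclass
class ReferenceStats:
    """Per-modality mean/SD used for cross-study z-transformation."""

    hpt_mu: float
    hpt_sd: float
    cpt_mu: float
    cpt_sd: float
    mpt_mu: float
    mpt_sd: float
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for m in COMPOSITE_MODALITIES:
            if not getattr(self, f"{m}_sd") > 0:
                raise ValueError(f"{m} reference SD must be positive")

    def mu(self, modality: str) -> float:
        return getattr(self, f"{modality}_mu")

    def sd(self, modality: str) -> float:
        return getattr(self, f"{modality}_sd")

    @classmethod
    def from_json(cls, path) -> "ReferenceStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: v for k, v in d.items() if not k.startswith("_")})

    @classmethod
    def from_population(cls, records: Sequence[QSTRecord], source="population") -> "ReferenceStats":
        """Derive reference statistics from a training population (ddof=1)."""
        kw: dict = {"source": source}
        for m in COMPOSITE_MODALITIES:
            vals = np.asarray([getattr(r, m) for r in records], dtype=float)
            if np.isnan(vals).any():
                raise ValueError(f"missing {m} in population")
            kw[f"{m}_mu"] = float(vals.mean())
            kw[f"{m}_sd"] = float(vals.std(ddof=1))
        return cls(**kw)


@dataclass
class PainSensitivityScore:
    """Composite score: mean of sign-adjusted z-values over the used modalities."""

    subject_id: str
    score: float
    z_values: dict[str, float]
    n_modalities_used: int


@dataclass
class NormativeBounds:
    """Normative 95% percentile interval per modality (user-supplied)."""

    bounds: dict[str, tuple[float, float]]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        for m, (lo, hi) in self.bounds.items():
            if lo is None or hi is None:
                raise ValueError(
                    f"normative bounds for {m!r} are unset; extreme-value screening "
                    "requires explicit values (the shipped template holds placeholders)"
                )
            if not lo < hi:
                raise ValueError(f"normative bounds for {m!r}: lower must be < upper")

    @classmethod
    def from_json(cls, path) -> "NormativeBounds":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            bounds={m: tuple(v) for m, v in d["bounds"].items()},
            source=d.get("source", "unspecified"),
        )


def thermal_pain_threshold(trial_temperatures: Sequence[float]) -> float:
    """Mean threshold temperature after discarding the first (test) trial.

    Works for any trial count >= 2; the standard protocol acquires 6
    repetitions and averages the last five.
    """
    t = np.asarray(trial_temperatures, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("at least 2 trials required (first is a test stimulus)")
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite trial temperature")
    return float(t[1:].mean())


def mechanical_pain_threshold(run_forces: Sequence[float]) -> float:
    """log10 of the geometric mean force (mN) over staircase runs."""
    f = np.asarray(run_forces, dtype=float)
    if f.size < 1:
        raise ValueError("at least one staircase run value required")
    if not (np.all(np.isfinite(f)) and np.all(f > 0)):
        raise ValueError("forces must be finite and positive")
    return float(np.mean(np.log10(f)))


def t50_from_ratings(
    pairs: Iterable[tuple[float, float]], target_rating: float = 50.0
) -> float:
    """Temperature at which the fitted quadratic rating curve crosses ``target_rating``.

    Fits rating = a*T^2 + b*T + c by least squares, then solves for the root
    at the target rating lying within the stimulated temperature range.  When
    both roots fall inside the range, the larger (ascending-branch) root is
    returned.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("at least 3 (temperature, rating) pairs required")
    temps, ratings = arr[:, 0], arr[:, 1]
    if np.any((ratings < 0) | (ratings > 100)):
        raise ValueError("ratings must lie in [0, 100]")
    a, b, c = np.polyfit(temps, ratings, 2)
    tmin, tmax = temps.min(), temps.max()
    scale = max(abs(a) * (tmax - tmin) ** 2, abs(b) * (tmax - tmin))
    if scale < 1e-10:
        raise ValueError("degenerate fit: rating curve is constant")
    # quadratic degenerates to linear when curvature is negligible
    if abs(a) * (tmax - tmin) ** 2 < 1e-9 * max(abs(b) * (tmax - tmin), 1.0):
        roots = np.array([(target_rating - c) / b])
    else:
        roots = np.roots([a, b, c - target_rating])
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = real[(real >= tmin - 1e-9) & (real <= tmax + 1e-9)]
    if in_range.size == 0:
        raise ValueError(
            f"no temperature in [{tmin:g}, {tmax:g}] °C reaches rating {target_rating:g}"
        )
    return float(in_range.max())


def composite_pain_sensitivity(
    record: QSTRecord,
    ref: ReferenceStats,
    modalities: Sequence[str] = COMPOSITE_MODALITIES,
) -> PainSensitivityScore:
    """Composite pain-sensitivity score for one subject.

    z_m = (x_m − μ_m)/σ_m per modality; HPT and MPT z-values are multiplied by
    −1 so higher always means more pain-sensitive; the score is the arithmetic
    mean of the adjusted z-values over the requested modalities.
    """
    modalities = tuple(modalities)
    if not modalities or any(m not in COMPOSITE_MODALITIES for m in modalities):
        raise ValueError(f"modalities must be a non-empty subset of {COMPOSITE_MODALITIES}")
    z = {}
    for m in modalities:
        x = getattr(record, m)
        if x is None or not np.isfinite(x):
            raise ValueError(f"{record.subject_id}: modality {m!r} missing")
        z[m] = _SIGN[m] * (x - ref.mu(m)) / ref.sd(m)
    return PainSensitivityScore(
        subject_id=record.subject_id,
        score=float(np.mean(list(z.values()))),
        z_values=z,
        n_modalities_used=len(modalities),
    )


def flag_extreme_qst(
    record: QSTRecord, bounds: NormativeBounds
) -> tuple[str, dict[str, bool]]:
    """Screen one subject against normative bounds.

    A modality is flagged when its threshold falls outside the normative
    interval; the subject is excluded when at least two of the three scored
    modalities are flagged.  Returns ``("keep"|"exclude", flags)``.
    """
    missing = [m for m in COMPOSITE_MODALITIES if m not in bounds.bounds]
    if missing:
        raise ValueError(f"normative bounds missing for {missing}")
    flags = {}
    for m in COMPOSITE_MODALITIES:
        lo, hi = bounds.bounds[m]
        x = getattr(record, m)
        if x is None:
            raise ValueError(f"{record.subject_id}: modality {m!r} missing")
        flags[m] = not (lo <= x <= hi)
    decision = "exclude" if sum(flags.values()) >= 2 else "keep"
    return decision, flags


def score_trials_table(
    trials: pd.DataFrame,
    ref: ReferenceStats,
    bounds: NormativeBounds | None = None,
    modalities: Sequence[str] = COMPOSITE_MODALITIES,
) -> pd.DataFrame:
    """Score a long-format trial table into per-subject thresholds and scores.

    ``trials`` columns: subject_id, modality, trial_index, value (and
    optionally unit).  Thermal modalities (hpt, cpt, wdt, cdt) are averaged
    after dropping the first trial; mechanical modalities (mpt, mdt) are
    log-geometric-mean aggregated; a precomputed ``t50`` row passes through.
    """
    required = {"subject_id", "modality", "trial_index", "value"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial table must contain columns {sorted(required)}")
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        thresholds: dict[str, float] = {}
        for modality, mg in grp.groupby("modality"):
            vals = mg.sort_values("trial_index")["value"].to_numpy(dtype=float)
            if modality in ("hpt", "cpt", "wdt", "cdt"):
                thresholds[modality] = thermal_pain_threshold(vals)
            elif modality in ("mpt", "mdt"):
                thresholds[modality] = mechanical_pain_threshold(vals)
            elif modality == "t50":
                thresholds[modality] = float(vals[-1])
            else:
                raise ValueError(f"unknown modality {modality!r}")
        rec = QSTRecord(subject_id=str(sid), **thresholds)
        res = composite_pain_sensitivity(rec, ref, modalities)
        row = {"subject_id": str(sid), **thresholds,
               "score": res.score, "n_modalities_used": res.n_modalities_used}
        if bounds is not None:
            decision, flags = flag_extreme_qst(rec, bounds)
            row["excluded"] = decision == "exclude"
            row["n_flags"] = int(sum(flags.values()))
            row.update({f"flag_{m}": v for m, v in flags.items()})
        rows.append(row)
    return pd.DataFrame(rows)
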