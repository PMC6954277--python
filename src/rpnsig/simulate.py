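"""Synthetic cohorts with a planted sparse connectivity–trait structure.

Every pipeline stage can be exercised without real data.  Each subject i
carries a standard-normal latent trait s_i that drives both sides of the
analysis:

* **brain**: the subject's regional signals are draws from a zero-mean
  Gaussian graphical model whose precision matrix equals a common base
  precision with a small set of *planted edges* whose precision entries
  shift linearly with s_i (θ_e(i) = −(baseline + effect·s_i)); the diagonal
  is loaded so the minimum eigenvalue stays ≥ 0.05, and the implied
  covariance is standardised to a correlation matrix so marginal variances
  carry no trait information.  A shared global fluctuation g_t is added to
  every region and observed — plus measurement noise — as the global
  grey-matter node (last), mimicking the common physiological/vigilance
  component of the real global signal without coupling it to the planted
  structure.  Frames are AR(1) smoothed (marginal covariance preserved).
  Planting on the precision scale keeps positive definiteness controllable
  and makes the analytic partial correlation −θ_ij/√(θ_ii θ_jj) available
  as ground truth.
* **behaviour**: QST thresholds load on the same trait with loading λ —
  each modality's latent threshold is μ_m ± σ_m(λ·s_i + √(1−λ²)ε_m), signed
  so that a higher trait always means more pain-sensitive (lower HPT, higher
  CPT, lower MPT) — and are expanded into noisy trials (6 thermal
  repetitions, 10 pinprick runs).
* **motion**: rigid-body parameters follow a small random walk with
  Bernoulli displacement spikes that exceed the scrubbing threshold by
  construction.

All randomness derives from one root seed through per-subject substreams,
so cohorts are bit-for-bit reproducible and extensible without changing
existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motion import MotionParams
from .preprocess import RegionalTimeseries

__all__ = [
    "SyntheticConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "generate_cohort",
    "generate_motion",
    "ground_truth",
    "subject_precision",
    "analytic_partial_correlation",
]

MIN_EIGENVALUE = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Desk-scale cohort defaults: 20 regions + global node, 200 frames at
    TR 2.5 s, 4 planted edges with trait loading 0.8."""

    n_subjects: int = 60
    n_regions: int = 20
    n_frames: int = 200
    tr: float = 2.5
    planted_edges: tuple = ((0, 1), (2, 3), (4, 5), (6, 7))
    planted_baseline: float = 0.25  # partial-correlation magnitude at s = 0
    effect_size: float = 0.15  # precision-scale shift per unit trait
    trait_loading: float = 0.8  # λ linking the trait to QST thresholds
    ar_coefficient: float = 0.3  # temporal AR(1) smoothing φ
    global_coupling: float = 0.5  # weight of the shared fluctuation in each region
    global_noise_sd: float = 0.2  # measurement noise on the global node
    motion_walk_sd_trans: float = 0.01  # mm per step
    motion_walk_sd_rot: float = 2e-4  # rad per step
    spike_probability: float = 0.02
    spike_amplitude: float = 0.5  # mm, exceeds the 0.15 mm FD threshold
    n_noise_signals: int = 10  # simulated noise-region signals for CompCor
    hpt_mu: float = 44.5
    hpt_sd: float = 1.5  # °C
    cpt_mu: float = 15.0
    cpt_sd: float = 7.0  # °C
    mpt_mu: float = 1.8
    mpt_sd: float = 0.35  # log10 mN
    thermal_trial_sd: float = 0.3  # °C within-subject repetition noise
    pinprick_run_sd: float = 0.1  # log10 mN within-subject run noise
    seed: int = 0

    def __post_init__(self) -> None:
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions and i != j):
                raise ValueError(f"planted edge ({i}, {j}) outside the region set")
        if not 0 <= self.trait_loading <= 1:
            raise ValueError("trait_loading must be in [0, 1]")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not 0 <= self.spike_probability < 1:
            raise ValueError("spike_probability must be in [0, 1)")

    @property
    def node_labels(self) -> list[str]:
        return [f"region_{i:03d}" for i in range(1, self.n_regions + 1)] + ["mean GM"]

    @property
    def node_modules(self) -> list[str]:
        half = self.n_regions // 2
        return (
            ["module_A"] * half
            + ["module_B"] * (self.n_regions - half)
            + ["mean GM"]
        )


@dataclass
class SyntheticSubject:
    subject_id: str
    trait: float
    timeseries: RegionalTimeseries
    motion: MotionParams
    noise_signals: np.ndarray
    qst_trials: pd.DataFrame
    spike_frames: np.ndarray
    precision: np.ndarray  # region-level generating precision matrix


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    subjects: list[SyntheticSubject]

    @property
    def traits(self) -> np.ndarray:
        return np.asarray([s.trait for s in self.subjects])

    @property
    def qst_trials(self) -> pd.DataFrame:
        return pd.concat([s.qst_trials for s in self.subjects], ignore_index=True)


def subject_precision(config: SyntheticConfig, trait: float) -> np.ndarray:
    """Region-level precision matrix for a given trait value.

    Base precision is the identity; each planted edge (i, j) receives
    θ_ij = −(baseline + effect·s) so the implied partial correlation is
    ≈ +(baseline + effect·s).  The diagonal is loaded to keep the minimum
    eigenvalue ≥ 0.05.
    """
    m = config.n_regions
    theta = np.eye(m)
    for i, j in config.planted_edges:
        v = -(config.planted_baseline + config.effect_size * trait)
        theta[i, j] = theta[j, i] = v
    ev_min = np.linalg.eigvalsh(theta).min()
    if ev_min < MIN_EIGENVALUE:
        theta += (MIN_EIGENVALUE - ev_min) * np.eye(m)
    if np.linalg.eigvalsh(theta).min() <= 0:
        raise ValueError("base precision not positive definite after loading")
    return theta


def analytic_partial_correlation(theta: np.ndarray) -> np.ndarray:
    """Ground-truth partial correlations −θ_ij/√(θ_ii θ_jj), diagonal 0."""
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def _ar1(eps: np.ndarray, phi: float) -> np.ndarray:
    """AR(1) smoothing with preserved marginal (co)variance."""
    if phi == 0:
        return eps
    x = np.empty_like(eps)
    x[0] = eps[0]
    scale = np.sqrt(1 - phi**2)
    for k in range(1, eps.shape[0]):
        x[k] = phi * x[k - 1] + scale * eps[k]
    return x


def _region_signals(config, theta, rng, n_frames=None) -> np.ndarray:
    t = n_frames or config.n_frames
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)  # unit marginals: variance carries no trait signal
    chol = np.linalg.cholesky(corr)
    eps = rng.standard_normal((t, config.n_regions)) @ chol.T
    return _ar1(eps, config.ar_coefficient)


def generate_timeseries(
    config: SyntheticConfig, trait: float, rng: np.random.Generator,
    n_frames: int | None = None, subject_id: str = "",
) -> tuple[RegionalTimeseries, np.ndarray]:
    """Regional signals for one subject plus the generating precision."""
    theta = subject_precision(config, trait)
    x = _region_signals(config, theta, rng, n_frames)
    g = _ar1(rng.standard_normal(x.shape[0]), config.ar_coefficient)
    x = x + config.global_coupling * g[:, None]
    gm = g + config.global_noise_sd * rng.standard_normal(x.shape[0])
    data = np.column_stack([x, gm])
    ts = RegionalTimeseries(
        data=data,
        labels=config.node_labels,
        modules=config.node_modules,
        tr=config.tr,
        subject_id=subject_id,
    )
    return ts, theta


def generate_motion(
    config: SyntheticConfig, rng: np.random.Generator | int | None = None
) -> tuple[MotionParams, np.ndarray]:
    """Random-walk motion with displacement spikes; returns spike frames.

    Spikes add ``spike_amplitude`` mm to one translation for a single frame,
    guaranteeing the affected frame exceeds the default 0.15 mm FD threshold.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = config.n_frames
    rot = np.cumsum(rng.normal(0, config.motion_walk_sd_rot, (t, 3)), axis=0)
    trans = np.cumsum(rng.normal(0, config.motion_walk_sd_trans, (t, 3)), axis=0)
    spikes = np.flatnonzero(rng.random(t - 1) < config.spike_probability) + 1
    for f in spikes:
        trans[f, 0] += config.spike_amplitude
    return (
        MotionParams(rotations=rot, translations=trans, tr=config.tr),
        spikes,
    )


# physical bounds on latent thresholds: thermal thresholds cannot cross the
# 32 degC thermode baseline and stimulators cut off at 50.5 / 0 degC; pinprick
# forces span the 8-512 mN stimulator set
_QST_CLIP = {
    "hpt": (33.0, 50.5),
    "cpt": (0.0, 30.0),
    "mpt": (np.log10(8.0), np.log10(512.0)),
}


def _qst_trials(config, trait, rng, subject_id) -> pd.DataFrame:
    lam = config.trait_loading
    resid = np.sqrt(1 - lam**2)
    rows = []
    # sign convention: higher trait => more sensitive in every modality
    for modality, mu, sd, sign in (
        ("hpt", config.hpt_mu, config.hpt_sd, -1.0),
        ("cpt", config.cpt_mu, config.cpt_sd, +1.0),
    ):
        latent = mu + sign * sd * (lam * trait + resid * rng.standard_normal())
        latent = float(np.clip(latent, *_QST_CLIP[modality]))
        for k in range(6):  # first is the discarded test stimulus
            rows.append(
                {"subject_id": subject_id, "modality": modality, "trial_index": k,
                 "value": latent + config.thermal_trial_sd * rng.standard_normal(),
                 "unit": "degC"}
            )
    latent = config.mpt_mu - config.mpt_sd * (lam * trait + resid * rng.standard_normal())
    latent = float(np.clip(latent, *_QST_CLIP["mpt"]))
    for k in range(10):  # 5 ascending + 5 descending staircase runs
        logf = latent + config.pinprick_run_sd * rng.standard_normal()
        rows.append(
            {"subject_id": subject_id, "modality": "mpt", "trial_index": k,
             "value": 10.0**logf, "unit": "mN"}
        )
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full cohort from (config, seed); bit-for-bit reproducible.

    Each subject draws from an independent substream spawned from the root
    seed, so growing ``n_subjects`` leaves existing subjects unchanged.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = root.spawn(config.n_subjects)
    subjects = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sid = f"sub-{i + 1:03d}"
        trait = float(rng.standard_normal())
        ts, theta = generate_timeseries(config, trait, rng, subject_id=sid)
        mot, spikes = generate_motion(config, rng)
        noise = rng.standard_normal((config.n_frames, config.n_noise_signals))
        trials = _qst_trials(config, trait, rng, sid)
        subjects.append(
            SyntheticSubject(
                subject_id=sid, trait=trait, timeseries=ts, motion=mot,
                noise_signals=noise, qst_trials=trials, spike_frames=spikes,
                precision=theta,
            )
        )
    return SyntheticCohort(config=config, subjects=subjects)


def ground_truth(cohort: SyntheticCohort) -> dict:
    """Generating parameters, verbatim, for recovery scoring."""
    cfg = cohort.config
    return {
        "planted_edges": [list(e) for e in cfg.planted_edges],
        "planted_baseline": cfg.planted_baseline,
        "effect_size": cfg.effect_size,
        "trait_loading": cfg.trait_loading,
        "traits": {s.subject_id: s.trait for s in cohort.subjects},
        "seed": cfg.seed,
    }
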