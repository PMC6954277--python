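"""Permutation and bootstrap inference for connectome predictions.

Three procedures:

* permutation p-values for prediction metrics — observed scores are permuted
  against the fixed predictions and each metric's add-one p-value is the
  fraction of permutations at least as good as the observed value;
* bootstrap inference on signature weights — the full pipeline is refitted
  on resamples of (subject, score) pairs, and per-connection confidence
  intervals and two-sided sign p-values are computed *conditionally* on the
  connection having been K-best-selected in a resample (selection
  frequencies are always reported so unconditional summaries can be
  derived);
* permutation-based linear-model association between predicted scores and a
  candidate confound, with R² as the test statistic.

All procedures are reproducible given (seed, number of resamples) and record
both in their outputs.  Add-one estimators p = (1 + k)/(n + 1) never return
0 and never exceed 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PipelineHyperparams, fit_pipeline, prediction_metrics

__all__ = [
    "BootstrapSummary",
    "ConfoundResult",
    "permutation_test_metrics",
    "bootstrap_signature",
    "confound_association",
    "confound_table",
]


@dataclass
class BootstrapSummary:
    """Per-connection bootstrap table with resampling provenance."""

    table: pd.DataFrame  # feature, selection_frequency, ci_low, ci_high, p, n_selected
    B: int
    seed: int

    def __post_init__(self) -> None:
        sel = self.table["selection_frequency"]
        assert ((sel >= 0) & (sel <= 1)).all()


@dataclass
class ConfoundResult:
    r_squared: float
    p: float
    n: int
    cov_type: str
    n_perm: int
    seed: int


def permutation_test_metrics(
    y, y_pred, n_perm: int = 10_000, seed: int = 0
) -> dict[str, float]:
    """Add-one permutation p-values for MSE, explained variance and Pearson r.

    Observed scores are permuted against fixed predictions; "at least as
    good" means lower MSE, higher explained variance and higher r.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape or y.size < 5:
        raise ValueError("y and y_pred must share a length of at least 5")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution", stacklevel=2)
    obs = prediction_metrics(y, y_pred)
    rng = np.random.default_rng(seed)
    yp = rng.permuted(np.broadcast_to(y, (n_perm, y.size)), axis=1)
    err = yp - y_pred
    mse = (err**2).mean(axis=1)
    ev = 1.0 - err.var(axis=1) / y.var()
    ypc = yp - yp.mean(axis=1, keepdims=True)
    pc = y_pred - y_pred.mean()
    denom = np.sqrt((ypc**2).sum(axis=1)) * np.sqrt((pc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ypc @ pc) / denom
    out = {
        "p_mse": (1 + int((mse <= obs["mse"]).sum())) / (n_perm + 1),
        "p_explvar": (1 + int((ev >= obs["explained_variance"]).sum())) / (n_perm + 1),
        "n_perm": n_perm,
        "seed": seed,
    }
    if np.isnan(obs["pearson_r"]):
        out["p_r"] = np.nan
    else:
        out["p_r"] = (1 + int((r >= obs["pearson_r"]).sum())) / (n_perm + 1)
    return out


def bootstrap_signature(
    X,
    y,
    hp: PipelineHyperparams,
    B: int = 10_000,
    seed: int = 0,
    labels: list[str] | None = None,
) -> BootstrapSummary:
    """Bootstrap the full pipeline; conditional inference per connection.

    B resamples with replacement (size n) of the (subject, score) pairs are
    refitted at ``hp``.  For each feature ever K-best-selected: the 95%
    percentile CI and the two-sided sign p-value p = 2·min(#{w≤0}, #{w≥0}) /
    #selected (floored at 1/#selected, capped at 1) are computed over the
    resamples in which the feature was selected; selection_frequency is
    #selected/B.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("at least 10 subjects required for bootstrap inference")
    if B < 100:
        warnings.warn(f"B={B} bootstrap samples give unstable intervals", stacklevel=2)
    rng = np.random.default_rng(seed)
    weights: dict[int, list[float]] = {}
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        if np.ptp(y[idx]) == 0:  # degenerate resample: all scores identical
            continue
        fp = fit_pipeline(X[idx], y[idx], hp)
        for pos, fi in enumerate(fp.selected):
            weights.setdefault(int(fi), []).append(float(fp.coef[pos]))
    rows = []
    for fi in sorted(weights):
        w = np.asarray(weights[fi])
        k = w.size
        p = 2 * min((w <= 0).sum(), (w >= 0).sum()) / k
        p = min(max(p, 1.0 / k), 1.0)
        lo, hi = np.percentile(w, [2.5, 97.5])
        row = {
            "feature_index": fi,
            "selection_frequency": k / B,
            "n_selected": k,
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": float(p),
            "mean_weight": float(w.mean()),
        }
        if labels is not None:
            from .connectome import feature_pairs

            i, j = feature_pairs(len(labels))[fi]
            row["i_label"], row["j_label"] = labels[i], labels[j]
        rows.append(row)
    return BootstrapSummary(table=pd.DataFrame(rows), B=B, seed=seed)


def _dummy_design(cov: pd.Series) -> np.ndarray:
    d = pd.get_dummies(cov.astype("category"), drop_first=True)
    if d.shape[1] == 0:
        raise ValueError("constant covariate: association undefined")
    return d.to_numpy(dtype=float)


def _r_squared(y: np.ndarray, design: np.ndarray) -> float:
    dm = np.column_stack([np.ones(y.size), design])
    beta, *_ = np.linalg.lstsq(dm, y, rcond=None)
    resid = y - dm @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / sst)


def confound_association(
    score,
    covariate,
    cov_type: str = "continuous",
    n_perm: int = 10_000,
    seed: int = 0,
) -> ConfoundResult:
    """Permutation-based linear-model association of predictions with a covariate.

    Missing values are dropped pairwise.  The statistic is the OLS R² of the
    score on the (dummy-coded, if categorical) covariate; the covariate is
    permuted ``n_perm`` times and p = (1 + #{R²_perm ≥ R²_obs})/(n_perm + 1).
    """
    s = pd.Series(score, dtype=float)
    c = pd.Series(covariate)
    keep = s.notna() & c.notna()
    s, c = s[keep].to_numpy(), c[keep].reset_index(drop=True)
    n = s.size
    if n < 5:
        raise ValueError(f"only {n} paired non-missing values (need >= 5)")
    rng = np.random.default_rng(seed)
    if cov_type == "continuous":
        x = c.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant covariate: association undefined")
        sc = s - s.mean()
        xc = x - x.mean()
        ssy, ssx = (sc**2).sum(), (xc**2).sum()
        r2_obs = float((sc @ xc) ** 2 / (ssy * ssx))
        xp = rng.permuted(np.broadcast_to(xc, (n_perm, n)), axis=1)
        r2_perm = (xp @ sc) ** 2 / (ssy * ssx)
        n_ge = int((r2_perm >= r2_obs - 1e-12).sum())
    elif cov_type == "categorical":
        design = _dummy_design(c)
        r2_obs = _r_squared(s, design)
        n_ge = 0
        for _ in range(n_perm):
            n_ge += _r_squared(s, design[rng.permutation(n)]) >= r2_obs - 1e-12
    else:
        raise ValueError("cov_type must be 'continuous' or 'categorical'")
    return ConfoundResult(
        r_squared=r2_obs,
        p=(1 + n_ge) / (n_perm + 1),
        n=n,
        cov_type=cov_type,
        n_perm=n_perm,
        seed=seed,
    )


def confound_table(
    score,
    covariates: pd.DataFrame,
    types: dict[str, str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """R²/p association table over a covariate frame (uncorrected p-values).

    ``types`` maps column → {continuous, categorical}; unlisted numeric
    columns are treated as continuous, non-numeric as categorical.  No
    multiple-testing correction is applied.
    """
    types = types or {}
    rows = []
    for k, col in enumerate(covariates.columns):
        t = types.get(
            col,
            "continuous" if pd.api.types.is_numeric_dtype(covariates[col]) else "categorical",
        )
        res = confound_association(
            score, covariates[col], cov_type=t, n_perm=n_perm, seed=seed + k
        )
        rows.append(
            {"covariate": col, "n": res.n, "cov_type": t,
             "r_squared": res.r_squared, "p": res.p}
        )
    return pd.DataFrame(rows)
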