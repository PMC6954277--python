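"""Sparse connectome-based predictive modelling of a behavioural trait.

The machine-learning pipeline is the standard connectome-based predictive
modelling stack:

1. per-feature robust scaling, (x − median) / (Q75 − Q25), with unit scale
   where the IQR is zero;
2. K-best univariate filtering, keeping the K features with the largest
   |Pearson r| against the target (ties broken by ascending feature index);
3. elastic-net regression minimising

       (1/2n)·Σᵢ (yᵢ − b − xᵢᵀw)²  +  α·ρ·‖w‖₁  +  (α(1−ρ)/2)·‖w‖₂²

   with an unpenalised intercept b, L1 ratio ρ and regularisation weight α.

Hyperparameters (K, ρ, α) are selected by leave-one-subject-out (LOO) grid
search on mean squared error, refitting the *entire* pipeline — scaling,
selection and regression — inside every fold so no information leaks from
the held-out subject.  Every fit is certified against the elastic-net
subgradient (KKT) optimality conditions, so the solver's convergence is
checked independently of the solver.

The user-facing surface follows the statsmodels idiom:
:class:`ConnectomePredictiveModel` holds the data,
:meth:`ConnectomePredictiveModel.fit` returns
:class:`ConnectomePredictiveResults` carrying weights, cross-validated
predictions, metrics and a :meth:`~ConnectomePredictiveResults.summary`
table; the module-level functions (``fit_pipeline``, ``loo_grid_search``,
``learning_curve``, ``prediction_metrics``) are the underlying operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .signature import SignatureEntry, TrainedSignature

__all__ = [
    "PipelineHyperparams",
    "HyperparamGrid",
    "FittedPipeline",
    "PredictionResult",
    "fit_pipeline",
    "kkt_violation",
    "loo_grid_search",
    "learning_curve",
    "extract_signature",
    "prediction_metrics",
    "ConnectomePredictiveModel",
    "ConnectomePredictiveResults",
]

#: default hyperparameter grid of the reference training procedure
DEFAULT_K_VALUES = tuple(range(10, 201, 5))
DEFAULT_L1_RATIOS = (0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 0.999)
DEFAULT_ALPHAS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)


@dataclass(frozen=True)
class PipelineHyperparams:
    """One pipeline configuration: K-best size, L1 ratio and α."""

    k_best: int
    l1_ratio: float
    alpha: float

    def __post_init__(self) -> None:
        if self.k_best < 1:
            raise ValueError("k_best must be >= 1")
        if not 0 < self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in (0, 1]")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class HyperparamGrid:
    k_values: tuple = DEFAULT_K_VALUES
    l1_ratios: tuple = DEFAULT_L1_RATIOS
    alphas: tuple = DEFAULT_ALPHAS

    def __post_init__(self) -> None:
        if not (self.k_values and self.l1_ratios and self.alphas):
            raise ValueError("grid axes must be non-empty")

    def cells(self) -> list[PipelineHyperparams]:
        """All cells in deterministic tie-break order.

        Ordered by (smaller K, larger α, smaller L1 ratio): when several
        cells achieve the same LOO error the first — the sparsest and most
        regularised — wins.
        """
        return [
            PipelineHyperparams(k, r, a)
            for k in sorted(self.k_values)
            for a in sorted(self.alphas, reverse=True)
            for r in sorted(self.l1_ratios)
        ]


@dataclass
class FittedPipeline:
    """Frozen state of one scale → select → elastic-net fit."""

    hp: PipelineHyperparams
    median: np.ndarray  # (P,)
    iqr: np.ndarray  # (P,) with zeros replaced by 1
    selected: np.ndarray  # (K,) feature indices, ascending
    coef: np.ndarray  # (K,) weights on scaled selected features
    intercept: float
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        xs = (X[:, self.selected] - self.median[self.selected]) / self.iqr[self.selected]
        return self.intercept + xs @ self.coef


@dataclass
class PredictionResult:
    """Observed/predicted scores with metrics, recomputable from the pairs."""

    y: np.ndarray
    y_pred: np.ndarray
    metrics: dict[str, float]
    p_values: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"y": self.y, "y_pred": self.y_pred})


def _robust_scale_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    med = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    iqr = q75 - q25
    iqr[iqr == 0] = 1.0
    return med, iqr


def _select_k_best(Xs: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features with the largest |Pearson r| with y.

    Zero-variance features score 0.  Ties break toward the smaller feature
    index; the returned indices are ascending.
    """
    yc = y - y.mean()
    xc = Xs - Xs.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    absr = np.abs(np.nan_to_num(r, nan=0.0))
    order = np.lexsort((np.arange(absr.size), -absr))
    return np.sort(order[:k])


def fit_pipeline(
    X: np.ndarray, y: np.ndarray, hp: PipelineHyperparams
) -> FittedPipeline:
    """Fit the robust-scale → K-best → elastic-net pipeline."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("at least 4 subjects required")
    if hp.k_best > p:
        raise ValueError(f"k_best={hp.k_best} exceeds {p} features")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to predict")
    med, iqr = _robust_scale_params(X)
    Xs = (X - med) / iqr
    sel = _select_k_best(Xs, y, hp.k_best)
    enet = ElasticNet(
        alpha=hp.alpha, l1_ratio=hp.l1_ratio, max_iter=100_000, tol=1e-8
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(Xs[:, sel], y)
    return FittedPipeline(
        hp=hp,
        median=med,
        iqr=iqr,
        selected=sel,
        coef=enet.coef_.copy(),
        intercept=float(enet.intercept_),
        n_train=n,
    )


def kkt_violation(fp: FittedPipeline, X: np.ndarray, y: np.ndarray) -> float:
    """Maximum violation of the elastic-net subgradient optimality conditions.

    For the objective (1/2n)‖y − b − Xw‖² + αρ‖w‖₁ + (α(1−ρ)/2)‖w‖₂², at the
    optimum: for every active weight the smooth gradient plus αρ·sign(w) must
    vanish; for every zero weight the smooth gradient must lie within ±αρ;
    and the residuals must sum to zero (intercept).  The returned value is
    the largest violation across all three conditions — an optimality
    certificate independent of the solver.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    xs = (X[:, fp.selected] - fp.median[fp.selected]) / fp.iqr[fp.selected]
    r = y - fp.intercept - xs @ fp.coef
    alpha, rho = fp.hp.alpha, fp.hp.l1_ratio
    g = -(xs.T @ r) / n + alpha * (1 - rho) * fp.coef
    active = fp.coef != 0
    v = [abs(r.mean())]
    if active.any():
        v.append(np.max(np.abs(g[active] + alpha * rho * np.sign(fp.coef[active]))))
    if (~active).any():
        v.append(max(0.0, np.max(np.abs(g[~active])) - alpha * rho))
    return float(max(v))


def loo_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparamGrid | None = None,
    return_table: bool = False,
):
    """Leave-one-subject-out grid search minimising mean squared error.

    Every grid cell is evaluated with n folds, each refitting the full
    pipeline on n−1 subjects and predicting the left-out one.  Returns
    ``(best_hp, y_cv)`` — the cross-validated predictions at the winning
    cell — and optionally the per-cell results table.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("at least 5 subjects required for LOO grid search")
    grid = grid or HyperparamGrid()
    cells = grid.cells()
    best_hp, best_mse, best_ycv = None, np.inf, None
    records = []
    for hp in cells:
        if hp.k_best > X.shape[1]:
            continue
        ycv = np.empty(n)
        for i in range(n):
            tr = np.arange(n) != i
            fp = fit_pipeline(X[tr], y[tr], hp)
            ycv[i] = fp.predict(X[i : i + 1])[0]
        mse = float(np.mean((y - ycv) ** 2))
        records.append({**vars(hp), "loo_mse": mse})
        if mse < best_mse:
            best_hp, best_mse, best_ycv = hp, mse, ycv
    if best_hp is None:
        raise ValueError("no feasible grid cell (all k_best exceed the feature count)")
    if return_table:
        return best_hp, best_ycv, pd.DataFrame.from_records(records)
    return best_hp, best_ycv


def learning_curve(
    X: np.ndarray,
    y: np.ndarray,
    hp: PipelineHyperparams,
    train_fractions=(0.3, 0.5, 0.7, 0.9),
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/held-out error as a function of training-set size.

    For each fraction, ``n_repeats`` random subsets are fitted at ``hp`` and
    evaluated on the complementary subjects; fraction 1.0 reports only the
    training error.  Deterministic given ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    rows = []
    for frac in train_fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must be in (0, 1]")
        size = int(round(frac * n))
        if size < 5:
            raise ValueError(f"fraction {frac} leaves only {size} training subjects")
        tr_mse, te_mse = [], []
        for _ in range(n_repeats):
            idx = rng.permutation(n)
            tr, te = idx[:size], idx[size:]
            fp = fit_pipeline(X[tr], y[tr], hp)
            tr_mse.append(np.mean((y[tr] - fp.predict(X[tr])) ** 2))
            if te.size >= 2:
                te_mse.append(np.mean((y[te] - fp.predict(X[te])) ** 2))
        rows.append(
            {
                "fraction": frac,
                "n_train": size,
                "train_mse_mean": float(np.mean(tr_mse)),
                "train_mse_sd": float(np.std(tr_mse, ddof=1)) if len(tr_mse) > 1 else 0.0,
                "test_mse_mean": float(np.mean(te_mse)) if te_mse else np.nan,
                "test_mse_sd": float(np.std(te_mse, ddof=1)) if len(te_mse) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def extract_signature(
    fp: FittedPipeline,
    labels: list[str],
    atlas_indices: list[int | None] | None = None,
    provenance: dict | None = None,
) -> TrainedSignature:
    """Portable signature from a fitted pipeline: one entry per non-zero weight."""
    from .connectome import feature_pairs

    n = len(labels)
    pairs = feature_pairs(n)
    entries = []
    for pos, fi in enumerate(fp.selected):
        w = fp.coef[pos]
        if w == 0:
            continue
        i, j = pairs[fi]
        entries.append(
            SignatureEntry(
                i_label=labels[i],
                j_label=labels[j],
                weight=float(w),
                atlas_idx_i=None if atlas_indices is None else atlas_indices[i],
                atlas_idx_j=None if atlas_indices is None else atlas_indices[j],
                feature_index=int(fi),
                median=float(fp.median[fi]),
                iqr=float(fp.iqr[fi]),
            )
        )
    return TrainedSignature(
        entries=entries,
        mode="full",
        intercept=fp.intercept,
        hyperparams=vars(fp.hp),
        provenance={"n_train": fp.n_train, **(provenance or {})},
    )


def prediction_metrics(y, y_pred) -> dict[str, float]:
    """MSE, MAE, explained variance and Pearson r of predictions.

    Explained variance is 1 − Var(y − ŷ)/Var(y) (0 for any constant
    predictor); Pearson r is NaN when either side is constant.
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    if y.size < 3:
        raise ValueError("at least 3 pairs required")
    err = y - y_pred
    ev = 1.0 - err.var() / y.var()
    if np.ptp(y) == 0 or np.ptp(y_pred) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(y, y_pred)[0, 1])
    return {
        "mse": float(np.mean(err**2)),
        "mae": float(np.mean(np.abs(err))),
        "explained_variance": float(ev),
        "pearson_r": r,
    }


class ConnectomePredictiveModel:
    """Connectome features → behavioural score model.

    Parameters
    ----------
    X : (n_subjects, P) array
        Upper-triangle connectivity features, one row per subject.
    y : (n_subjects,) array
        Behavioural scores (e.g. the composite pain-sensitivity score).
    node_labels : list of str, optional
        Node order behind the feature space; enables signature extraction
        with named connections.  When given, P must equal n(n−1)/2.
    atlas_indices : list, optional
        Per-node atlas indices recorded in extracted signatures.
    """

    def __init__(self, X, y, node_labels=None, atlas_indices=None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows and y length disagree")
        if node_labels is not None:
            n = len(node_labels)
            if self.X.shape[1] != n * (n - 1) // 2:
                raise ValueError(
                    f"{self.X.shape[1]} features inconsistent with {n} node labels"
                )
        self.node_labels = list(node_labels) if node_labels is not None else None
        self.atlas_indices = atlas_indices

    @classmethod
    def from_matrices(cls, matrices, y, atlas_indices=None):
        """Build from per-subject :class:`~rpnsig.connectome.ConnectivityMatrix`."""
        from .connectome import vectorize_upper

        matrices = list(matrices)
        labels = matrices[0].labels
        for m in matrices:
            if m.labels != labels:
                raise ValueError("all matrices must share one node order")
        X = np.vstack([vectorize_upper(m).values for m in matrices])
        return cls(X, y, node_labels=labels, atlas_indices=atlas_indices)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, score_col: str = "score"):
        """Build from a wide table: one feature column per connection."""
        y = df[score_col].to_numpy(dtype=float)
        X = df.drop(columns=[score_col]).to_numpy(dtype=float)
        return cls(X, y)

    @property
    def n_subjects(self) -> int:
        return self.y.size

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def fit(self, hp: PipelineHyperparams) -> "ConnectomePredictiveResults":
        """Fit at fixed hyperparameters (no cross-validation)."""
        fp = fit_pipeline(self.X, self.y, hp)
        return ConnectomePredictiveResults(self, fp)

    def fit_loo(
        self, grid: HyperparamGrid | None = None
    ) -> "ConnectomePredictiveResults":
        """LOO grid search, then a final fit on all subjects at the best cell.

        The results object carries the pooled LOO predictions at the selected
        hyperparameters; internal-validation metrics derive from those.  Note
        the metrics share folds with the hyperparameter selection and are
        therefore mildly optimistic.
        """
        best_hp, y_cv, table = loo_grid_search(self.X, self.y, grid, return_table=True)
        fp = fit_pipeline(self.X, self.y, best_hp)
        return ConnectomePredictiveResults(self, fp, y_cv=y_cv, grid_table=table)

    def learning_curve(self, hp, **kw) -> pd.DataFrame:
        return learning_curve(self.X, self.y, hp, **kw)


class ConnectomePredictiveResults:
    """Fitted-model results: weights, signature, predictions, diagnostics."""

    def __init__(self, model, fitted: FittedPipeline, y_cv=None, grid_table=None):
        self.model = model
        self.fitted = fitted
        self.y_cv = None if y_cv is None else np.asarray(y_cv, dtype=float)
        self.grid_table = grid_table

    # -- estimates ---------------------------------------------------------
    @property
    def hyperparams(self) -> PipelineHyperparams:
        return self.fitted.hp

    @property
    def params(self) -> pd.Series:
        """Non-zero weights indexed by feature index (scaled-feature units)."""
        nz = self.fitted.coef != 0
        return pd.Series(
            self.fitted.coef[nz], index=self.fitted.selected[nz], name="weight"
        )

    @property
    def intercept(self) -> float:
        return self.fitted.intercept

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.fitted.coef))

    def signature(self, provenance: dict | None = None) -> TrainedSignature:
        if self.model.node_labels is None:
            raise ValueError("node labels required to extract a named signature")
        return extract_signature(
            self.fitted, self.model.node_labels, self.model.atlas_indices, provenance
        )

    # -- prediction --------------------------------------------------------
    def predict(self, X=None) -> np.ndarray:
        return self.fitted.predict(self.model.X if X is None else X)

    def evaluate(self, X, y, n_perm: int | None = None, seed: int = 0) -> PredictionResult:
        """External validation: predict new subjects and score the predictions."""
        y = np.asarray(y, dtype=float)
        y_pred = self.fitted.predict(X)
        res = PredictionResult(y=y, y_pred=y_pred, metrics=prediction_metrics(y, y_pred))
        if n_perm:
            from .inference import permutation_test_metrics

            res.p_values = permutation_test_metrics(y, y_pred, n_perm=n_perm, seed=seed)
        return res

    @property
    def cv_metrics(self) -> dict[str, float] | None:
        """Internal-validation metrics from the pooled LOO predictions."""
        if self.y_cv is None:
            return None
        return prediction_metrics(self.model.y, self.y_cv)

    # -- diagnostics -------------------------------------------------------
    def kkt_violation(self) -> float:
        return kkt_violation(self.fitted, self.model.X, self.model.y)

    def bootstrap(self, B: int = 10_000, seed: int = 0):
        from .inference import bootstrap_signature

        return bootstrap_signature(
            self.model.X, self.model.y, self.fitted.hp, B=B, seed=seed
        )

    def permutation_pvalues(self, n_perm: int = 10_000, seed: int = 0):
        if self.y_cv is None:
            raise ValueError("cross-validated predictions required (use fit_loo)")
        from .inference import permutation_test_metrics

        return permutation_test_metrics(self.model.y, self.y_cv, n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        hp = self.fitted.hp
        lines = [
            "Connectome predictive model — elastic net on K-best partial correlations",
            "=" * 74,
            f"subjects: {self.model.n_subjects:>5}    features: {self.model.n_features}",
            f"K-best: {hp.k_best}    l1_ratio: {hp.l1_ratio}    alpha: {hp.alpha}",
            f"non-zero weights: {self.n_nonzero}    intercept: {self.intercept:.4f}",
            f"KKT violation: {self.kkt_violation():.2e}",
        ]
        if self.cv_metrics is not None:
            m = self.cv_metrics
            lines.append(
                "LOO CV:  MSE {mse:.3f}  MAE {mae:.3f}  expl.var {explained_variance:.3f}"
                "  r {pearson_r:.3f}".format(**m)
            )
        lines.append("-" * 74)
        if self.model.node_labels is not None and self.n_nonzero:
            sig = self.signature()
            lines.append(f"{'connection':<40}{'weight':>10}")
            for e in sorted(sig.entries, key=lambda e: -abs(e.weight)):
                lines.append(f"{e.i_label + ' – ' + e.j_label:<40}{e.weight:>10.4f}")
        return "\n".join(lines)
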