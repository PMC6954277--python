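"""Sparse connectome signatures: extraction, serialization and application.

A trained signature is the portable form of a fitted sparse model: the
non-zero connection weights with their node pairs, the per-feature robust
scaling parameters learned on the training cohort, and the intercept.
Applying a signature to new connectivity data is a dot product between the
scaled connection values and the weights — no refitting.

Two modes exist.  ``full`` signatures carry scaler parameters and intercept
and yield absolute scores.  ``weights_only`` signatures (such as the packaged
published pain-sensitivity network signature, whose scaler parameters were
never published) yield scores defined only up to an increasing affine map —
sufficient for correlation-based validation, not for error metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SignatureEntry",
    "TrainedSignature",
    "apply_signature",
    "load_rpn_signature",
    "default_node_order",
]


@dataclass
class SignatureEntry:
    """One predictive connection: node pair, weight and training scaler."""

    i_label: str
    j_label: str
    weight: float
    atlas_idx_i: int | None = None
    atlas_idx_j: int | None = None
    i_module: str | None = None
    j_module: str | None = None
    feature_index: int | None = None
    median: float | None = None
    iqr: float | None = None


@dataclass
class TrainedSignature:
    """Sparse set of weighted connections plus application metadata."""

    entries: list[SignatureEntry]
    mode: str = "full"  # "full" | "weights_only"
    intercept: float | None = None
    hyperparams: dict | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("full", "weights_only"):
            raise ValueError("mode must be 'full' or 'weights_only'")
        if any(e.weight == 0 for e in self.entries):
            raise ValueError("signature entries must have non-zero weights")
        if self.mode == "full":
            bad = [e for e in self.entries if e.median is None or e.iqr is None]
            if bad or self.intercept is None:
                raise ValueError("full-mode signature requires scaler fields and intercept")

    @property
    def n_connections(self) -> int:
        return len(self.entries)

    @property
    def weights(self) -> np.ndarray:
        return np.asarray([e.weight for e in self.entries])

    def to_json(self, path) -> None:
        d = {
            "schema_version": 1,
            "mode": self.mode,
            "intercept": self.intercept,
            "hyperparams": self.hyperparams,
            "provenance": self.provenance,
            "entries": [
                {k: v for k, v in vars(e).items() if v is not None}
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedSignature":
        return cls(
            entries=[SignatureEntry(**e) for e in d["entries"]],
            mode=d.get("mode", "full"),
            intercept=d.get("intercept"),
            hyperparams=d.get("hyperparams"),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path) -> "TrainedSignature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _package_json(name: str) -> dict:
    with resources.files("rpnsig.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_rpn_signature() -> TrainedSignature:
    """The packaged published pain-sensitivity network signature.

    21 weighted partial-correlation connections over the 122-region functional
    atlas plus the global grey-matter node; ``weights_only`` mode.
    """
    return TrainedSignature.from_dict(_package_json("rpn_signature.json"))


def default_node_order() -> list[dict]:
    """The shipped 123-node order manifest (122 atlas regions + ``mean GM``).

    Each item has ``label``, ``module`` and ``atlas_index`` (1-based; None for
    the global grey-matter node, which is always last).
    """
    return _package_json("node_order.json")["nodes"]


def _node_positions(labels, atlas_indices):
    by_label = {}
    for pos, lab in enumerate(labels):
        by_label.setdefault(lab, pos)
    by_atlas = {}
    if atlas_indices is not None:
        for pos, ai in enumerate(atlas_indices):
            if ai is not None:
                by_atlas[ai] = pos
    return by_label, by_atlas


def resolve_entry_positions(
    sig: TrainedSignature,
    labels: list[str],
    atlas_indices: list[int | None] | None = None,
) -> list[tuple[int, int]]:
    """Node-pair positions of each signature entry within a node ordering.

    Entries are matched by atlas index when both sides carry one and an atlas
    index map is supplied, falling back to label matching.  Raises with the
    full list of unresolvable pairs.
    """
    by_label, by_atlas = _node_positions(labels, atlas_indices)

    def locate(label, atlas_idx):
        if atlas_idx is not None and atlas_idx in by_atlas:
            return by_atlas[atlas_idx]
        return by_label.get(label)

    positions, missing = [], []
    for e in sig.entries:
        i = locate(e.i_label, e.atlas_idx_i)
        j = locate(e.j_label, e.atlas_idx_j)
        if i is None or j is None or i == j:
            missing.append(f"{e.i_label}–{e.j_label}")
        else:
            positions.append((min(i, j), max(i, j)))
    if missing:
        raise KeyError(
            "signature node pairs absent from input node order: " + ", ".join(missing)
        )
    return positions


def apply_signature(
    sig: TrainedSignature,
    data,
    labels: list[str] | None = None,
    atlas_indices: list[int | None] | None = None,
) -> np.ndarray:
    """Predicted score(s) from connectivity data.

    ``data`` may be a :class:`~rpnsig.connectome.ConnectivityMatrix`, a
    :class:`~rpnsig.connectome.FeatureVector`, or an array of upper-triangle
    feature vectors (one row per subject; ``labels`` then names the nodes).
    Full-mode signatures return ``intercept + Σ w_e (x_e − median_e)/iqr_e``;
    weights-only signatures return the plain dot product ``Σ w_e x_e``,
    interpretable up to an increasing affine map.
    """
    from .connectome import ConnectivityMatrix, FeatureVector, feature_index

    if isinstance(data, ConnectivityMatrix):
        labels = data.labels
        iu = np.triu_indices(data.n_nodes, k=1)
        x = data.values[iu][None, :]
        squeeze = True
    elif isinstance(data, FeatureVector):
        labels = data.labels
        x = data.values[None, :]
        squeeze = True
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
        squeeze = x.shape[0] == 1 and np.asarray(data).ndim == 1
        if labels is None:
            raise ValueError("labels required when applying to a raw feature array")
    n = len(labels)
    if x.shape[1] != n * (n - 1) // 2:
        raise ValueError(
            f"{x.shape[1]} features inconsistent with {n} nodes"
        )
    if atlas_indices is None and n == 123:
        manifest = default_node_order()
        if [m["label"] for m in manifest] == list(labels):
            atlas_indices = [m["atlas_index"] for m in manifest]
    positions = resolve_entry_positions(sig, list(labels), atlas_indices)
    fidx = [feature_index(i, j, n) for i, j in positions]
    xe = x[:, fidx]
    w = sig.weights
    if sig.mode == "full":
        med = np.asarray([e.median for e in sig.entries])
        iqr = np.asarray([e.iqr for e in sig.entries])
        scores = sig.intercept + ((xe - med) / iqr) @ w
    else:
        scores = xe @ w
    return float(scores[0]) if squeeze else scores
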