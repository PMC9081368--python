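"""Hard-voting ensemble of three base classifiers.

Three scale-sensitive and scale-free learners — an SGD-trained linear
hinge-loss classifier, an SMO-trained linear support vector machine and a
random forest — are fitted on the same (optionally standardized) feature
matrix.  Prediction takes each member's hard 0/1 vote and returns the
2-of-3 majority; with three voters and binary labels no tie is possible.

Seeding: a master seed fans out to the three member seeds through
``numpy.random.SeedSequence(master).generate_state(3)`` (each reduced
mod 2**31), in the fixed member order sgd_linear, smo_svm, random_forest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import __version__
from .descriptors import EncoderConfig
from .errors import ModelError

#: Fixed member order; also the fan-out order of the per-member seeds.
MEMBER_KINDS = ("sgd_linear", "smo_svm", "random_forest")

_DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "sgd_linear": {"loss": "hinge", "alpha": 1e-4, "max_iter": 1000, "tol": 1e-3},
    "smo_svm": {"kernel": "linear", "C": 1.0},
    "random_forest": {"n_estimators": 100},
}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One base learner: its kind, hyperparameters and seed."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MEMBER_KINDS:
            raise ModelError(f"unknown learner kind {self.kind!r}; expected {MEMBER_KINDS}")

    def build(self):
        params = {**_DEFAULT_HYPERPARAMETERS[self.kind], **self.hyperparameters}
        if self.kind == "sgd_linear":
            return SGDClassifier(random_state=self.seed, **params)
        if self.kind == "smo_svm":
            return SVC(random_state=self.seed, **params)
        return RandomForestClassifier(random_state=self.seed, n_jobs=1, **params)


def member_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out to one seed per member kind."""
    state = np.random.SeedSequence(master_seed).generate_state(len(MEMBER_KINDS))
    return {k: int(s % 2**31) for k, s in zip(MEMBER_KINDS, state)}


def default_specs(master_seed: int = 0) -> list[BaseLearnerSpec]:
    """The three default base learners seeded from ``master_seed``."""
    seeds = member_seeds(master_seed)
    return [BaseLearnerSpec(kind=k, seed=seeds[k]) for k in MEMBER_KINDS]


@dataclass
class TrainedEnsemble:
    """Three fitted members plus the encoding contract they were trained under."""

    members: dict  # kind -> fitted sklearn estimator
    encoder_config: EncoderConfig
    feature_labels: list[str]
    scaler: StandardScaler | None
    metadata: dict

    def __post_init__(self) -> None:
        if tuple(self.members) != MEMBER_KINDS:
            raise ModelError(
                f"ensemble must hold exactly the members {MEMBER_KINDS}, "
                f"got {tuple(self.members)}"
            )

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_labels):
            raise ModelError(
                f"feature dimension mismatch: model expects "
                f"{len(self.feature_labels)} columns, received "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        return X

    def predict_vote(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (majority labels, per-member vote matrix of shape (n, 3))."""
        X = self._check_X(X)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        votes = np.column_stack(
            [self.members[k].predict(X) for k in MEMBER_KINDS]
        ).astype(int)
        labels = (votes.sum(axis=1) >= 2).astype(int)
        return labels, votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_vote(X)[0]


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[BaseLearnerSpec] | None = None,
    standardize: bool = True,
    encoder_config: EncoderConfig | None = None,
    feature_labels: list[str] | None = None,
    metadata: dict | None = None,
) -> TrainedEnsemble:
    """Fit the three base learners (one per kind) on (X, y).

    The optional standardizer (zero mean, unit variance per feature) is
    fitted on X before the members see it; it is stored with the model and
    applied at prediction time. Deterministic for fixed seeds and inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ModelError("X must be 2-D with one row per label")
    if not np.all(np.isfinite(X)):
        bad = sorted(set(np.where(~np.isfinite(X))[1].tolist()))
        raise ModelError(f"non-finite features in columns {bad[:10]}")
    classes, counts = np.unique(y, return_counts=True)
    if set(classes) != {0, 1}:
        raise ModelError(
            f"training needs examples of each class (0 and 1); got classes "
            f"{classes.tolist()} with counts {counts.tolist()}"
        )
    specs = specs if specs is not None else default_specs()
    kinds = sorted(s.kind for s in specs)
    if kinds != sorted(MEMBER_KINDS):
        raise ModelError(f"specs must cover {MEMBER_KINDS} exactly once, got {kinds}")
    scaler = None
    Xs = X
    if standardize:
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
    members = {}
    by_kind = {s.kind: s for s in specs}
    for kind in MEMBER_KINDS:
        members[kind] = by_kind[kind].build().fit(Xs, y)
    cfg = encoder_config or EncoderConfig()
    labels = (
        feature_labels
        if feature_labels is not None
        else [f"f{i}" for i in range(X.shape[1])]
    )
    if len(labels) != X.shape[1]:
        raise ModelError("feature_labels length must equal the column count")
    meta = {
        "version": __version__,
        "n_train": int(len(y)),
        "seeds": {s.kind: s.seed for s in specs},
        "standardize": standardize,
        **(metadata or {}),
    }
    return TrainedEnsemble(
        members=members,
        encoder_config=cfg,
        feature_labels=labels,
        scaler=scaler,
        metadata=meta,
    )


def save_model(model: TrainedEnsemble, path) -> None:
    """Serialize the ensemble to a single archive with a JSON manifest."""
    manifest = {
        "format": "mhcvote-ensemble",
        "version": __version__,
        "encoder_config": model.encoder_config.to_dict(),
        "n_features": len(model.feature_labels),
        "metadata": {k: v for k, v in model.metadata.items() if k != "seeds"},
        "seeds": model.metadata.get("seeds", {}),
    }
    payload = {
        "manifest_json": json.dumps(manifest),
        "members": model.members,
        "scaler": model.scaler,
        "feature_labels": model.feature_labels,
        "encoder_config": model.encoder_config.to_dict(),
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedEnsemble:
    """Load a saved ensemble; refuses files from a different package version."""
    try:
        payload = joblib.load(path)
        manifest = json.loads(payload["manifest_json"])
    except ModelError:
        raise
    except Exception as e:  # truncated / foreign file
        raise ModelError(f"cannot read model file {path}: {e}") from e
    if manifest.get("format") != "mhcvote-ensemble":
        raise ModelError(f"{path} is not an mhcvote model file")
    if manifest.get("version") != __version__:
        raise ModelError(
            f"model version {manifest.get('version')!r} does not match "
            f"package version {__version__!r}"
        )
    return TrainedEnsemble(
        members=payload["members"],
        encoder_config=EncoderConfig.from_dict(payload["encoder_config"]),
        feature_labels=payload["feature_labels"],
        scaler=payload["scaler"],
        metadata=payload["metadata"],
    )
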