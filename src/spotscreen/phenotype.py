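"""Three-class mitotic phenotype scoring.

Each segmented nucleus is classified as ``normal`` (interphase),
``spindle`` (mitotic arrest with a monopolar spindle: condensed, compact,
bright nucleus) or ``cytokinesis`` (failed division: enlarged multi-lobed
footprint) from its feature vector.  The classifier is a Gaussian
class-conditional model (quadratic discriminant) fitted on labelled
training nuclei after per-feature standardization; a transparent
rule-based fallback thresholding area and shape is also provided.

The per-field readout of the screen is the fraction of nuclei in each
class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CLASSES

__all__ = [
    "DEFAULT_FEATURES",
    "PhenotypeModel",
    "FieldReadout",
    "RuleThresholds",
    "fit_phenotype_model",
    "classify_nuclei",
    "classify_rules",
    "phenotype_fractions",
    "simulate_training_features",
    "train_default_model",
]

DEFAULT_FEATURES = ("num_pix", "extend", "circularity", "mean_intensity")


@dataclass
class PhenotypeModel:
    """Gaussian class-conditional (QDA) phenotype classifier.

    Stores per-class mean vectors and covariance matrices over a feature
    subset, class priors and the feature standardization parameters
    estimated from the training set.
    """

    classes: tuple[str, ...]
    features: tuple[str, ...]
    means: np.ndarray  # (k, d)
    covs: np.ndarray  # (k, d, d)
    priors: np.ndarray  # (k,)
    standardize_mean: np.ndarray  # (d,)
    standardize_sd: np.ndarray  # (d,)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "features": list(self.features),
            "means": self.means.tolist(),
            "covs": self.covs.tolist(),
            "priors": self.priors.tolist(),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(payload["classes"]),
            features=tuple(payload["features"]),
            means=np.asarray(payload["means"], float),
            covs=np.asarray(payload["covs"], float),
            priors=np.asarray(payload["priors"], float),
            standardize_mean=np.asarray(payload["standardize_mean"], float),
            standardize_sd=np.asarray(payload["standardize_sd"], float),
        )


def fit_phenotype_model(
    features: pd.DataFrame,
    feature_subset: tuple[str, ...] = DEFAULT_FEATURES,
    n_min: int = 10,
    ridge: float = 1e-6,
) -> PhenotypeModel:
    """Fit the Gaussian class-conditional model on labelled nuclei.

    ``features`` must carry a ``class`` column with every phenotype class
    represented by at least ``n_min`` examples.  Covariances are
    regularized by ``ridge * trace/d`` on the diagonal.
    """
    if "class" not in features.columns:
        raise ValueError("training features need a 'class' column")
    missing = [c for c in CLASSES if (features["class"] == c).sum() < n_min]
    if missing:
        raise ValueError(
            f"class {missing[0]!r} has fewer than {n_min} training examples"
        )
    missing_feat = [f for f in feature_subset if f not in features.columns]
    if missing_feat:
        raise ValueError(f"missing feature column {missing_feat[0]!r}")

    X = features.loc[:, list(feature_subset)].to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    d = len(feature_subset)
    means, covs, priors = [], [], []
    y = features["class"].to_numpy()
    for c in CLASSES:
        Zc = Z[y == c]
        m = Zc.mean(axis=0)
        # maximum-likelihood covariance: invariant under dataset replication
        cov = np.cov(Zc, rowvar=False, bias=True)
        cov = np.atleast_2d(cov)
        cov = cov + ridge * (np.trace(cov) / d) * np.eye(d)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"covariance of class {c!r} singular after regularization"
            ) from None
        means.append(m)
        covs.append(cov)
        priors.append(len(Zc) / len(Z))
    return PhenotypeModel(
        classes=CLASSES,
        features=tuple(feature_subset),
        means=np.asarray(means),
        covs=np.asarray(covs),
        priors=np.asarray(priors),
        standardize_mean=mu,
        standardize_sd=sd,
    )


def classify_nuclei(model: PhenotypeModel, features: pd.DataFrame) -> np.ndarray:
    """Assign the maximum-posterior class to each nucleus.

    Ties are broken by class order (normal < spindle < cytokinesis).
    Returns an array of class-name strings, empty for empty input.
    """
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ValueError(f"missing feature column {missing[0]!r}")
    if len(features) == 0:
        return np.array([], dtype=object)
    X = features.loc[:, list(model.features)].to_numpy(float)
    Z = (X - model.standardize_mean) / model.standardize_sd
    k = len(model.classes)
    scores = np.empty((len(Z), k))
    for i in range(k):
        cov = model.covs[i]
        diff = Z - model.means[i]
        sign, logdet = np.linalg.slogdet(cov)
        sol = np.linalg.solve(cov, diff.T).T
        maha = np.einsum("ij,ij->i", diff, sol)
        scores[:, i] = -0.5 * (maha + logdet) + math.log(model.priors[i])
    best = np.argmax(scores, axis=1)  # first max wins = canonical class order
    return np.asarray(model.classes, dtype=object)[best]


@dataclass(frozen=True)
class RuleThresholds:
    """Thresholds of the rule-based fallback classifier (area in px at the
    default 1.0 um/px sampling; rescale for other pixel sizes)."""

    cyto_min_area: float = 185.0
    cyto_max_extend: float = 0.58
    spindle_max_area: float = 100.0
    spindle_min_circularity: float = 0.55


def classify_rules(
    features: pd.DataFrame, thresholds: RuleThresholds | None = None
) -> np.ndarray:
    """Transparent threshold classifier on num_pix / extend / circularity,
    mirroring how the classes separate in the area-vs-extent feature plane."""
    thr = thresholds or RuleThresholds()
    n = len(features)
    out = np.full(n, "normal", dtype=object)
    if n == 0:
        return out
    area = features["num_pix"].to_numpy(float)
    extend = features["extend"].to_numpy(float)
    circ = features["circularity"].to_numpy(float)
    cyto = (area >= thr.cyto_min_area) | (extend <= thr.cyto_max_extend)
    spin = ~cyto & (area <= thr.spindle_max_area) & (circ >= thr.spindle_min_circularity)
    out[cyto] = "cytokinesis"
    out[spin] = "spindle"
    return out


@dataclass(frozen=True)
class FieldReadout:
    """Per-field phenotype readout: cell count and class fractions.

    ``fractions`` is None for an empty field (undefined, not NaN-propagated).
    """

    n_cells: int
    fractions: tuple[float, float, float] | None

    @property
    def defined(self) -> bool:
        return self.fractions is not None


def phenotype_fractions(labels: np.ndarray | list) -> FieldReadout:
    """Fraction of nuclei per phenotype class: class counts / n_cells."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        return FieldReadout(n_cells=0, fractions=None)
    fracs = tuple(float(np.sum(labels == c)) / n for c in CLASSES)
    return FieldReadout(n_cells=n, fractions=fracs)


# ---------------------------------------------------------------------------
# generator-backed training data


def simulate_training_features(
    seed: int = 0,
    fields_per_class: int = 3,
    cells_per_field: float = 70.0,
    field_shape: tuple[int, int] = (256, 256),
    segmentation=None,
    scene_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Labelled training nuclei from the synthetic generator.

    Renders class-pure fields (degenerate phenotype mixtures), segments
    them with the standard chain, and labels each detected nucleus by the
    ground-truth cell whose centroid falls inside its footprint.  The
    result stands in for the study's (unavailable) manually labelled
    training set and follows the measured, not nominal, feature
    distributions.
    """
    from . import metrics
    from .segment import SegmentationParams, segment_field
    from .synth import SceneSpec, render_field

    params = segmentation or SegmentationParams()
    rows = []
    for ci, cls in enumerate(CLASSES):
        mix = [0.0, 0.0, 0.0]
        mix[ci] = 1.0
        for j in range(fields_per_class):
            spec = SceneSpec(
                field_shape=field_shape,
                expected_cells=cells_per_field,
                phenotype_mix=tuple(mix),
                marker_spot=None,
                seed=int(np.random.SeedSequence([int(seed), ci, j]).generate_state(1)[0]),
                **(scene_kwargs or {}),
            )
            image, truth = render_field(spec)
            labels, feats = segment_field(image.channels["nuclei"], params)
            matched = metrics.match_centroids(
                labels, truth.cells[["centroid_r", "centroid_c"]].to_numpy()
            )
            hit = matched > 0
            feats = feats.set_index("label")
            picked = feats.loc[matched[hit]].reset_index()
            picked["class"] = cls
            rows.append(picked)
    return pd.concat(rows, ignore_index=True)


def train_default_model(seed: int = 0, **kwargs) -> PhenotypeModel:
    """Convenience: simulate a labelled training set and fit the model."""
    feats = simulate_training_features(seed=seed, **kwargs)
    return fit_phenotype_model(feats)
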