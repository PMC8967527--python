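"""Spiculation-sign recognition from radiomics and morphological features.

A spiculated nodule carries thin radial spikes; geometrically this shows
up as lower sphericity/circularity, higher perimeter-to-area and higher
radial-length variance than a smooth nodule of the same size. The
recogniser extracts a fixed, documented feature vector per nodule,
screens features with two-sample t-tests (χ² for categoricals), selects
among the survivors with an L1 (LASSO) logistic path whose penalty is
chosen by stratified cross-validated deviance, and fits two logistic
models — a radiomics model on the selected features and a morphology
model on the shape features. The combined score is the unweighted mean
of the two model probabilities; a nodule judged in the three anatomical
positions is called spiculated when at least one position meets the
sign (logical OR).

The modelling API follows the model/results pattern:

    >>> model = SpiculationSignModel(X, y)        # doctest: +SKIP
    >>> res = model.fit(folds=10, seed=7)         # doctest: +SKIP
    >>> print(res.summary())                      # doctest: +SKIP
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from . import multiview
from .metrics import ConfusionCounts, recognition_scores
from .nodules import circularity, max_area_slice
from .volio import CTVolume

FIRST_ORDER = ("fo_mean", "fo_variance", "fo_skewness", "fo_kurtosis",
               "fo_energy", "fo_entropy")
SHAPE_2D = ("circularity", "elongation", "perimeter_to_area", "radial_var")
SHAPE_3D = ("sphericity", "surface_to_volume", "equivalent_diameter_mm",
            "compactness")


# -- feature extraction ------------------------------------------------

def _first_order(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, np.float64)
    mean = float(v.mean())
    var = float(v.var())
    if var == 0.0:
        skew = kurt = 0.0  # constant region: moments degenerate to 0
        entropy = 0.0
    else:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))
        hist, _ = np.histogram(v, bins=32)
        p = hist[hist > 0] / hist.sum()
        entropy = float(-(p * np.log2(p)).sum())
    return {"fo_mean": mean, "fo_variance": var, "fo_skewness": skew,
            "fo_kurtosis": kurt, "fo_energy": float((v**2).mean()),
            "fo_entropy": entropy}


def shape_features_2d(mask2d: np.ndarray) -> dict[str, float]:
    """Circularity, elongation, perimeter/area and radial-length
    variance (normalised by the squared mean radius) of one 2D region."""
    mask2d = np.asarray(mask2d, bool)
    if not mask2d.any():
        raise ValueError("empty 2D region")
    area = float(mask2d.sum())
    padded = np.pad(mask2d.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    perim = sum(float(np.sqrt(((c[1:] - c[:-1]) ** 2).sum(axis=1)).sum())
                for c in contours) or 4.0
    props = measure.regionprops(mask2d.astype(np.uint8))[0]
    minor = max(props.axis_minor_length, 0.5)
    major = max(props.axis_major_length, minor)
    centroid = np.asarray(props.centroid)
    pts = np.concatenate([c - 1.0 for c in contours], axis=0)
    radii = np.sqrt(((pts - centroid) ** 2).sum(axis=1))
    rmean = float(radii.mean()) or 1.0
    return {
        "circularity": circularity(mask2d),
        "elongation": float(major / minor),
        "perimeter_to_area": float(perim / area),
        "radial_var": float(radii.var() / rmean**2),
    }


def shape_features_3d(mask: np.ndarray, spacing) -> dict[str, float]:
    mask = np.asarray(mask, bool)
    spacing = tuple(float(s) for s in spacing)
    count = int(mask.sum())
    volume = count * float(np.prod(spacing))
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, 0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)
    return {
        "sphericity": min(sphericity, 1.0),
        "surface_to_volume": float(area / volume),
        "equivalent_diameter_mm": float((6.0 * volume / np.pi) ** (1 / 3)),
        "compactness": min(float(36.0 * np.pi * volume**2 / area**3), 1.0),
    }


def extract_features(volume: CTVolume, candidate) -> dict[str, float]:
    """Full per-nodule feature vector (22 named values).

    ``candidate`` needs a 3D ``mask`` attribute (a
    :class:`~nodulekit.nodules.NoduleCandidate`) or may itself be a
    boolean mask. First-order intensity statistics come from the HU
    values inside the mask; 2D shape features are computed on the
    maximum-area slice in each of the three positions; 3D shape features
    use a marching-cubes surface in mm. Features depend only on the
    region's own geometry and intensities, so translating the nodule
    inside the volume leaves them unchanged.
    """
    mask = candidate if isinstance(candidate, np.ndarray) else candidate.mask
    mask = np.asarray(mask, bool)
    if mask.shape != volume.shape:
        raise ValueError("candidate mask must align with the volume")
    count = int(mask.sum())
    if count < 2:
        raise ValueError(
            "degenerate candidate (single voxel): shape features undefined")
    feats = _first_order(volume.voxels[mask])
    for pos in multiview.POSITIONS:
        pos2d = shape_features_2d(max_area_slice(mask, pos))
        feats.update({f"{pos}_{k}": v for k, v in pos2d.items()})
    feats.update(shape_features_3d(mask, volume.spacing))
    return feats


def extract_position_features(volume: CTVolume, candidate,
                              position: str) -> dict[str, float]:
    """Feature vector for judging one anatomical position: first-order
    and 3D features (shared) plus that position's 2D shape features
    under position-neutral names."""
    mask = candidate if isinstance(candidate, np.ndarray) else candidate.mask
    mask = np.asarray(mask, bool)
    if int(mask.sum()) < 2:
        raise ValueError("degenerate candidate (single voxel)")
    feats = _first_order(volume.voxels[mask])
    feats.update(shape_features_2d(max_area_slice(mask, position)))
    feats.update(shape_features_3d(mask, volume.spacing))
    return feats


def feature_table(volume_candidate_pairs) -> pd.DataFrame:
    """Stack per-nodule feature dicts into a DataFrame."""
    rows = [extract_features(v, c) for v, c in volume_candidate_pairs]
    return pd.DataFrame(rows)


# -- feature screening -------------------------------------------------

def _is_categorical(col: pd.Series) -> bool:
    return (col.dtype == bool or isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == object)


def screen_features(X: pd.DataFrame, y, alpha: float = 0.05) -> list[str]:
    """Univariate screen: two-sample t-test per continuous feature,
    χ² contingency test per categorical one; retain p < alpha.

    Constant features are excluded with a warning rather than an error.
    Raising alpha can only grow the retained set.
    """
    y = np.asarray(y).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two samples per class")
    retained = []
    for name in X.columns:
        col = X[name]
        if _is_categorical(col):
            table = pd.crosstab(col, y)
            if table.shape[0] < 2:
                warnings.warn(f"feature {name!r} is constant; excluded")
                continue
            _, p, _, _ = stats.chi2_contingency(table.values)
        else:
            a = col.values[y == 1].astype(float)
            b = col.values[y == 0].astype(float)
            if np.ptp(col.values.astype(float)) == 0:
                warnings.warn(f"feature {name!r} is constant; excluded")
                continue
            with warnings.catch_warnings():
                # near-constant features trip scipy's precision warning;
                # their p-values land near 1 and are dropped anyway
                warnings.simplefilter("ignore", RuntimeWarning)
                _, p = stats.ttest_ind(a, b)
        if np.isfinite(p) and p < alpha:
            retained.append(name)
    return retained


# -- model / results ---------------------------------------------------

def fuse_sign_decisions(per_position) -> bool:
    """At-least-one-position rule: OR of the three position decisions."""
    decisions = list(per_position)
    if len(decisions) != 3:
        raise ValueError("exactly three position decisions are required")
    return bool(any(bool(d) for d in decisions))


@dataclass
class _LogisticPart:
    features: list[str]
    center: np.ndarray
    scale: np.ndarray
    coef: np.ndarray
    intercept: float

    def proba(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].values.astype(float) - self.center) / self.scale
        logit = Z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -500, 500)))

    def to_json(self) -> dict:
        return {"features": self.features, "center": self.center.tolist(),
                "scale": self.scale.tolist(), "coef": self.coef.tolist(),
                "intercept": self.intercept}

    @classmethod
    def from_json(cls, d: dict) -> "_LogisticPart":
        return cls(d["features"], np.asarray(d["center"]),
                   np.asarray(d["scale"]), np.asarray(d["coef"]),
                   float(d["intercept"]))


class SpiculationSignModel:
    """Two-branch logistic sign recogniser with embedded feature selection.

    Parameters
    ----------
    X : DataFrame of extracted features (rows = nodules or positions).
    y : binary labels (1 = spiculated).
    morphology_features : names for the morphology branch; defaults to
        every shape feature (non-``fo_``) present in ``X``.
    alpha : univariate screening significance level.
    """

    def __init__(self, X: pd.DataFrame, y, morphology_features=None,
                 alpha: float = 0.05):
        self.X = pd.DataFrame(X).reset_index(drop=True)
        self.y = np.asarray(y).astype(int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if morphology_features is None:
            morphology_features = [c for c in self.X.columns
                                   if not c.startswith("fo_")]
        self.morphology_features = list(morphology_features)
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "spiculated",
                       **kw) -> "SpiculationSignModel":
        return cls(df.drop(columns=[label_col]), df[label_col], **kw)

    # internal: one full selection+fit on (X, y)
    def _fit_parts(self, X: pd.DataFrame, y: np.ndarray, folds: int,
                   seed: int, n_alphas: int):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import log_loss
        from sklearn.model_selection import StratifiedKFold

        screened = screen_features(X, y, self.alpha)
        if not screened:
            raise ValueError(
                "no features survive the univariate screen; relax alpha")
        cv = StratifiedKFold(n_splits=min(folds, int(np.bincount(y).min())),
                             shuffle=True, random_state=seed)
        center = X[screened].values.astype(float).mean(axis=0)
        scale = X[screened].values.astype(float).std(axis=0)
        scale[scale == 0] = 1.0
        Z = (X[screened].values.astype(float) - center) / scale
        # L1 path over a log-spaced penalty grid, chosen by CV deviance
        splits = list(cv.split(Z, y))
        best_c, best_dev = 1.0, np.inf
        for c in np.logspace(-2, 2, n_alphas):
            dev = 0.0
            for tr, te in splits:
                lr = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                        max_iter=2000)
                lr.fit(Z[tr], y[tr])
                dev += log_loss(y[te], lr.predict_proba(Z[te])[:, 1],
                                labels=[0, 1])
            if dev < best_dev:
                best_c, best_dev = c, dev
        lasso = LogisticRegression(l1_ratio=1.0, C=best_c, solver="liblinear",
                                   max_iter=2000)
        lasso.fit(Z, y)
        nz = np.flatnonzero(np.abs(lasso.coef_[0]) > 1e-8)
        selected = [screened[i] for i in nz] if nz.size else list(screened)

        def plain_logistic(names: list[str]) -> _LogisticPart:
            c = X[names].values.astype(float).mean(axis=0)
            s = X[names].values.astype(float).std(axis=0)
            s[s == 0] = 1.0
            Zn = (X[names].values.astype(float) - c) / s
            lr = LogisticRegression(C=100.0, max_iter=5000)
            lr.fit(Zn, y)
            return _LogisticPart(list(names), c, s, lr.coef_[0],
                                 float(lr.intercept_[0]))

        radiomics = plain_logistic(selected)
        morph_names = [m for m in self.morphology_features if m in X.columns]
        morph_screened = [m for m in screened if m in morph_names]
        morphology = plain_logistic(morph_screened or morph_names)
        return screened, selected, radiomics, morphology

    def select_features(self, folds: int = 10, seed: int = 0,
                        n_alphas: int = 50) -> list[str]:
        """The t-test + LASSO feature-selection path on the full data."""
        _, selected, _, _ = self._fit_parts(self.X, self.y, folds, seed,
                                            n_alphas)
        return selected

    def fit(self, folds: int = 10, seed: int = 0, n_alphas: int = 50,
            threshold: float = 0.5) -> "SignModelResults":
        """Select features, fit both logistic branches on all data, and
        evaluate by stratified k-fold cross-validation (default 10-fold).
        """
        from sklearn.model_selection import StratifiedKFold

        if folds < 2:
            raise ValueError("folds must be >= 2")
        y = self.y
        screened, selected, radiomics, morphology = self._fit_parts(
            self.X, y, folds, seed, n_alphas)

        n_splits = min(folds, int(np.bincount(y).min()))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                             random_state=seed)
        rows = []
        pooled = np.zeros(4, int)  # tp, fp, tn, fn
        for k, (tr, te) in enumerate(cv.split(self.X, y)):
            _, _, rad_k, mor_k = self._fit_parts(
                self.X.iloc[tr], y[tr], folds, seed + k + 1, n_alphas)
            proba = 0.5 * (rad_k.proba(self.X.iloc[te]) +
                           mor_k.proba(self.X.iloc[te]))
            pred = proba >= threshold
            truth = y[te].astype(bool)
            tp = int((pred & truth).sum())
            fp = int((pred & ~truth).sum())
            tn = int((~pred & ~truth).sum())
            fn = int((~pred & truth).sum())
            pooled += (tp, fp, tn, fn)
            sen = 100.0 * tp / (tp + fn) if tp + fn else np.nan
            spe = 100.0 * tn / (tn + fp) if tn + fp else np.nan
            rows.append({"fold": k, "sen": sen, "spe": spe})
        counts = ConfusionCounts(*map(int, pooled))
        sen, spe, fpf = recognition_scores(counts)
        return SignModelResults(
            model=self, screened=screened, selected=selected,
            radiomics=radiomics, morphology=morphology,
            threshold=threshold, cv_table=pd.DataFrame(rows),
            confusion=counts, sen=sen, spe=spe, fpf=fpf,
            folds=n_splits, seed=seed)


@dataclass
class SignModelResults:
    """Fitted sign model: selected features, coefficients, CV scores."""

    model: SpiculationSignModel
    screened: list[str]
    selected: list[str]
    radiomics: _LogisticPart
    morphology: _LogisticPart
    threshold: float
    cv_table: pd.DataFrame
    confusion: ConfusionCounts
    sen: float
    spe: float
    fpf: float
    folds: int
    seed: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Combined score: mean of the two branch probabilities."""
        return 0.5 * (self.radiomics.proba(X) + self.morphology.proba(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold

    def summary(self) -> str:
        lines = [
            "Spiculation sign model (t-test + LASSO + logistic)",
            "=" * 52,
            f"samples: {len(self.model.y)}   positives: {int(self.model.y.sum())}",
            f"screened features (p < {self.model.alpha}): {len(self.screened)}",
            f"LASSO-selected: {', '.join(self.selected)}",
            "",
            "radiomics branch coefficients (standardised):",
        ]
        for name, c in zip(self.radiomics.features, self.radiomics.coef):
            lines.append(f"  {name:28s} {c:+8.3f}")
        lines.append("morphology branch coefficients (standardised):")
        for name, c in zip(self.morphology.features, self.morphology.coef):
            lines.append(f"  {name:28s} {c:+8.3f}")
        lines += [
            "",
            f"{self.folds}-fold stratified CV (pooled): "
            f"SEN {self.sen:.1f}%  SPE {self.spe:.1f}%  FPF {self.fpf:.1f}%",
        ]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {"screened": self.screened, "selected": self.selected,
                "radiomics": self.radiomics.to_json(),
                "morphology": self.morphology.to_json(),
                "threshold": self.threshold,
                "sen": self.sen, "spe": self.spe, "fpf": self.fpf}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)


def load_sign_model(path: str) -> "SignModelResults":
    """Load a serialized sign model for prediction (no CV state)."""
    with open(path) as fh:
        d = json.load(fh)
    return SignModelResults(
        model=None, screened=d["screened"], selected=d["selected"],
        radiomics=_LogisticPart.from_json(d["radiomics"]),
        morphology=_LogisticPart.from_json(d["morphology"]),
        threshold=d["threshold"], cv_table=pd.DataFrame(),
        confusion=ConfusionCounts(0, 0, 0, 0), sen=d.get("sen", np.nan),
        spe=d.get("spe", np.nan), fpf=d.get("fpf", np.nan), folds=0, seed=0)
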