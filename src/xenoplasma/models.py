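"""Elastic-net tumor-volume regression and tumor-type classification.

Tumor volume is regressed on a marker panel after the transforms the
problem calls for: volumes are cube-root transformed (linearizing the
volume ~ diameter^3 geometry and damping the heteroskedastic large-volume
end), and RFU features are log10 transformed, centered and scaled with
training-set parameters only.  The elastic net blends L1/L2 penalties via
a mixing parameter alpha in [0, 1] and a strength lambda chosen by
grouped cross-validation (all samples of an animal stay in one fold, so
longitudinal correlation cannot leak across folds).

The tumor/no-tumor decision comes from scanning the empirically predicted
volumes of a holdout set as candidate thresholds; tumor-type calls use a
multinomial logistic model with the same penalty family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GroupKFold


# ---------------------------------------------------------------------------
# feature pipeline
# ---------------------------------------------------------------------------

@dataclass
class FeatureTransform:
    """log10 → center → scale, with training-set parameters frozen."""

    mean: pd.Series  # per analyte, log10 scale
    sd: pd.Series  # per analyte, log10 scale (ddof=1)

    @classmethod
    def fit(cls, rfu: pd.DataFrame) -> "FeatureTransform":
        log10 = np.log10(rfu)
        sd = log10.std(ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()]
        if len(constant):
            raise ValueError(
                f"constant training column(s): {list(constant)[:5]}"
            )
        return cls(mean=log10.mean(), sd=sd)

    def apply(self, rfu: pd.DataFrame) -> pd.DataFrame:
        log10 = np.log10(rfu[self.mean.index])
        return (log10 - self.mean) / self.sd


def make_design(
    values: pd.DataFrame,
    markers,
    transform: FeatureTransform | None = None,
) -> tuple[pd.DataFrame, FeatureTransform]:
    """Standardized feature table for a marker panel.

    Without *transform* the parameters are fit on *values* (training
    path); with it, the stored training parameters are applied unchanged
    (test path).
    """
    markers = sorted(markers)
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise KeyError(f"markers missing from matrix: {missing}")
    block = values[markers]
    if transform is None:
        transform = FeatureTransform.fit(block)
    return transform.apply(block), transform


def split_holdout(
    samples: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Animal-level train/holdout split, stratified by group.

    Whole animals (all their timepoints) go to one side, mirroring a
    study design that holds out n animals per group.  Returns (train
    sample ids, holdout sample ids).
    """
    if not 0 < fraction < 1:
        raise ValueError("holdout fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_animals: list = []
    for _, grp in samples.groupby("Group"):
        animals = list(dict.fromkeys(grp["AnimalId"]))
        n_test = max(1, int(round(fraction * len(animals))))
        chosen = rng.permutation(animals)[:n_test]
        test_animals.extend(chosen)
    is_test = samples["AnimalId"].isin(test_animals)
    return samples.index[~is_test], samples.index[is_test]


# ---------------------------------------------------------------------------
# elastic-net volume model
# ---------------------------------------------------------------------------

@dataclass
class VolumePredictor:
    """Fitted elastic-net panel on the cube-root volume scale."""

    markers: list[str]
    coef: pd.Series  # per marker, transformed scale
    intercept: float
    mixing: float  # alpha in [0, 1]: 1 = lasso, 0 = ridge
    strength: float  # lambda >= 0
    transform: FeatureTransform | None
    cv_results: pd.DataFrame | None = None

    @property
    def panel(self) -> list[str]:
        """Markers with nonzero coefficients."""
        return list(self.coef.index[self.coef != 0])

    def score_linear(self, x: pd.DataFrame) -> np.ndarray:
        return x[self.coef.index].to_numpy() @ self.coef.to_numpy() \
            + self.intercept


def _lambda_max(x: np.ndarray, y: np.ndarray, mixing: float) -> float:
    yc = y - y.mean()
    lam = np.abs(x.T @ yc).max() / (len(y) * max(mixing, 0.05))
    return float(max(lam, 1e-12))


def _fit_enet(x, y, mixing, lam, seed):
    if lam == 0:
        xc = np.column_stack([np.ones(len(x)), x])
        beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
        return beta[1:], float(beta[0])
    model = ElasticNet(alpha=lam, l1_ratio=mixing, max_iter=50000,
                       random_state=seed)
    model.fit(x, y)
    return model.coef_, float(model.intercept_)


def train_elastic_net(
    x: pd.DataFrame,
    volumes,
    animals,
    mixing_grid=None,
    n_lambda: int = 50,
    folds: int = 5,
    seed: int = 0,
    include_ols: bool = False,
    selection: str = "1se",
) -> VolumePredictor:
    """Grid-search elastic net for cube-root tumor volume.

    *x* is the standardized design from :func:`make_design`; *animals*
    groups samples for leakage-safe :class:`GroupKFold` cross-validation.
    The mixing grid spans [0, 1]; for each mixing value the strength grid
    is log-spaced over [lambda_max * 1e-4, lambda_max].  The model is
    refit on all training data at the chosen grid point: the CV-MSE
    minimizer (``selection="min"``) or, by default, the most-penalized
    point within one standard error of that minimum (``"1se"``, the
    usual rule for parsimonious biomarker panels).  With ``include_ols``
    the unpenalized point ``lambda = 0`` joins the grid.
    """
    y = np.cbrt(np.asarray(volumes, dtype=float))
    xv = x.to_numpy(dtype=float)
    animals = np.asarray(animals)
    if mixing_grid is None:
        mixing_grid = np.round(np.linspace(0.1, 1.0, 7), 3)
    n_groups = len(np.unique(animals))
    folds = min(folds, n_groups)
    if folds < 2:
        raise ValueError("need at least 2 animal groups for cross-validation")
    splitter = GroupKFold(n_splits=folds)
    splits = list(splitter.split(xv, y, groups=animals))
    for tr, te in splits:
        if np.ptp(y[tr]) == 0:
            raise ValueError("degenerate CV fold: no variance in response")

    rows = []
    for mixing in mixing_grid:
        lam_max = _lambda_max(xv, y, mixing)
        lams = np.geomspace(lam_max * 1e-4, lam_max, n_lambda)
        if include_ols:
            lams = np.append(lams, 0.0)
        for lam in lams:
            fold_mse = []
            for tr, te in splits:
                coef, icpt = _fit_enet(xv[tr], y[tr], mixing, lam, seed)
                pred = xv[te] @ coef + icpt
                fold_mse.append(float(((pred - y[te]) ** 2).mean()))
            rows.append({
                "mixing": float(mixing), "lambda": float(lam),
                "cv_mse": float(np.mean(fold_mse)),
                "cv_se": float(np.std(fold_mse, ddof=1)
                               / np.sqrt(len(fold_mse))),
            })
    cv = pd.DataFrame(rows)
    best = cv.loc[cv["cv_mse"].idxmin()]
    if selection == "1se":
        within = cv[cv["cv_mse"] <= best["cv_mse"] + best["cv_se"]]
        best = within.sort_values(["lambda", "mixing"]).iloc[-1]
    elif selection != "min":
        raise ValueError(f"unknown selection rule {selection!r}")
    coef, icpt = _fit_enet(xv, y, best["mixing"], best["lambda"], seed)
    return VolumePredictor(
        markers=list(x.columns),
        coef=pd.Series(coef, index=x.columns),
        intercept=icpt,
        mixing=float(best["mixing"]),
        strength=float(best["lambda"]),
        transform=None,  # attached by callers that own the transform
        cv_results=cv,
    )


def predict_volume(predictor: VolumePredictor, x: pd.DataFrame) -> np.ndarray:
    """Invert the cube-root transform; negative scores clamp to 0 mm^3."""
    score = predictor.score_linear(x)
    return np.where(score > 0, score ** 3, 0.0)


def evaluate_r2(actual_volumes, predicted_volumes) -> float:
    """Explained variance on the cube-root (fitting) scale."""
    a = np.cbrt(np.asarray(actual_volumes, dtype=float))
    p = np.cbrt(np.asarray(predicted_volumes, dtype=float))
    if len(a) < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(((a - p) ** 2).sum()) / ss_tot


# ---------------------------------------------------------------------------
# operating point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float  # mm^3; tumor-bearing iff prediction > threshold
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int


MAX_SPEC_AT_FULL_SENS = "max-specificity-at-full-sensitivity"
YOUDEN = "youden"


def scan_operating_point(
    predicted, tumor_labels, rule: str = MAX_SPEC_AT_FULL_SENS
) -> tuple[list[OperatingPoint], OperatingPoint]:
    """Threshold scan over the empirical predicted volumes.

    Candidate thresholds are the distinct predicted values themselves; a
    sample is called tumor-bearing iff its prediction exceeds the
    threshold.  The selected point maximizes specificity subject to
    sensitivity = 1 (default), or Youden's J; ties prefer the larger
    threshold.  With no threshold reaching sensitivity 1 the default rule
    falls back to Youden while the full curve is still returned.
    """
    pred = np.asarray(predicted, dtype=float)
    labels = np.asarray(tumor_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both tumor and non-tumor samples")
    points = []
    for t in np.unique(pred):
        called = pred > t
        tp = int((called & labels).sum())
        fn = int((~called & labels).sum())
        fp = int((called & ~labels).sum())
        tn = int((~called & ~labels).sum())
        points.append(OperatingPoint(float(t), tp / (tp + fn), tn / (tn + fp),
                                     tp, fp, tn, fn))
    if rule == MAX_SPEC_AT_FULL_SENS:
        full = [p for p in points if p.sensitivity == 1.0]
        if full:
            selected = max(full, key=lambda p: (p.specificity, p.threshold))
            return points, selected
        rule = YOUDEN
    if rule == YOUDEN:
        selected = max(points, key=lambda p: (p.sensitivity + p.specificity - 1,
                                              p.threshold))
        return points, selected
    raise ValueError(f"unknown rule {rule!r}")


def impute_zero_volumes(
    samples: pd.DataFrame,
    target_line: str,
    tumor_lines,
) -> pd.Series:
    """Volumes for a line-specific model: other tumor lines imputed to 0.

    Samples of *target_line* keep their measured volume; samples of any
    other tumor line are set to 0 (they carry no target-line tumor);
    controls are already 0.
    """
    tumor_lines = set(tumor_lines)
    if target_line not in tumor_lines:
        raise ValueError(f"unknown line label {target_line!r}")
    unknown = set(samples["Group"]) - tumor_lines - {"control", "calibrator"}
    if unknown:
        raise ValueError(f"unknown line label(s) {sorted(unknown)}")
    vol = pd.to_numeric(samples["TumorVolume_mm3"]).copy()
    other = samples["Group"].isin(tumor_lines - {target_line})
    vol[other] = 0.0
    return vol


# ---------------------------------------------------------------------------
# multinomial tumor-type classifier
# ---------------------------------------------------------------------------

@dataclass
class TypeClassifier:
    classes: list[str]
    model: LogisticRegression
    transform: FeatureTransform | None
    mixing: float
    strength_c: float
    roc: dict[str, tuple[np.ndarray, np.ndarray, float]] = field(
        default_factory=dict)
    accuracy: float | None = None

    def predict_proba(self, x: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(x.to_numpy(dtype=float))

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return self.model.predict(x.to_numpy(dtype=float))


def train_type_classifier(
    x: pd.DataFrame,
    labels,
    animals,
    mixing_grid=(0.2, 0.5, 0.8),
    c_grid=(0.1, 1.0, 10.0),
    folds: int = 3,
    seed: int = 0,
) -> TypeClassifier:
    """Multinomial logistic regression with an elastic-net penalty.

    Grid-searches the mixing parameter and inverse strength C by grouped
    CV accuracy (animals stay whole).  Class probabilities come from the
    softmax, so rows sum to 1.
    """
    y = np.asarray(labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    xv = x.to_numpy(dtype=float)
    animals = np.asarray(animals)
    folds = min(folds, len(np.unique(animals)))
    splits = list(GroupKFold(n_splits=folds).split(xv, y, groups=animals))
    for tr, _ in splits:
        missing = set(classes) - set(y[tr])
        if missing:
            raise ValueError(f"class(es) {sorted(missing)} absent from a "
                             "training fold")

    def fit(mixing, c):
        # elastic-net penalty: saga solver with a float l1_ratio
        return LogisticRegression(
            solver="saga", l1_ratio=float(mixing), C=float(c),
            max_iter=5000, random_state=seed,
        )

    best = None
    for mixing in mixing_grid:
        for c in c_grid:
            correct = 0
            for tr, te in splits:
                clf = fit(mixing, c)
                clf.fit(xv[tr], y[tr])
                correct += int((clf.predict(xv[te]) == y[te]).sum())
            acc = correct / len(y)
            if best is None or acc > best[0]:
                best = (acc, mixing, c)
    _, mixing, c = best
    model = fit(mixing, c)
    model.fit(xv, y)
    return TypeClassifier(classes=list(model.classes_), model=model,
                          transform=None, mixing=float(mixing),
                          strength_c=float(c))


def evaluate_classifier(
    clf: TypeClassifier, x: pd.DataFrame, labels
) -> TypeClassifier:
    """Attach holdout one-vs-rest ROC curves and overall accuracy."""
    y = np.asarray(labels)
    proba = clf.predict_proba(x)
    clf.accuracy = float((clf.predict(x) == y).mean())
    for k, cls in enumerate(clf.classes):
        binary = (y == cls).astype(int)
        if binary.min() == binary.max():
            continue
        fpr, tpr, _ = roc_curve(binary, proba[:, k])
        clf.roc[cls] = (fpr, tpr, float(auc(fpr, tpr)))
    return clf
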