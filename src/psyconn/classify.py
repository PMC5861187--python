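"""Eight-class one-against-all RBF-SVM classification of network edge features.

Scores are discretized into ``n_classes`` (default 8) levels by
``clamp(ceil(n_classes * (x - min) / (max - min)), 1, n_classes)`` — the
fraction of the observed score range, scaled to the class count and rounded
up, with the minimum mapped to class 1.  One binary RBF-SVM
(``K(x, y) = exp(-gamma * ||x - y||^2)``) is trained per observed class
against all others; the predicted class maximizes the binary decision
value, ties going to the lowest class index.  Hyperparameters (C, gamma)
are grid-searched over dyadic grids (defaults C = 2^-5..2^15,
gamma = 2^-15..2^15) to maximize leave-one-out cross-validated accuracy.

Accuracy is judged against two chance levels: the theoretical
``100 / n_classes`` and the binomial-corrected level — the smallest
accuracy whose correct-count clears the (1 - alpha) quantile of a
Binomial(n, 1/n_classes) null, which grows as samples shrink (about 17%
for 150 samples with 8 classes, versus the theoretical 12.5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .connectivity import ConnectivityStack
from .errors import AlignmentError, DegenerateDesignError, InsufficientDataError
from .nbs import NetworkComponent, edge_index_pairs

__all__ = [
    "ClassLabelMap",
    "FeatureMatrix",
    "ClassifierReport",
    "OaaSvmModel",
    "discretize",
    "component_features",
    "train_oaa_svm",
    "loocv_evaluate",
    "chance_levels",
    "significance_vs_chance",
    "apply_classifiers",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16))  # 21 values
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 16))  # 31 values

# guard against float fuzz flipping an exactly-integer product across a
# class boundary before the round-up
_CEIL_DECIMALS = 9


@dataclass
class ClassLabelMap:
    """Per-subject class labels for one parameter with the min/max used.

    The stored training min/max are reused when discretizing held-out
    subjects, so train and test labels share one scale.
    """

    parameter: str
    labels: pd.Series  # int class in 1..n_classes, indexed by subject id
    vmin: float
    vmax: float
    n_classes: int = 8

    def apply(self, scores: pd.Series) -> pd.Series:
        """Discretize new scores with the stored training min/max."""
        x = scores.astype(float)
        if (x < self.vmin).any() or (x > self.vmax).any():
            warnings.warn("scores outside the training range; clamped", stacklevel=2)
        frac = (x.clip(self.vmin, self.vmax) - self.vmin) / (self.vmax - self.vmin)
        raw = np.ceil(np.round(self.n_classes * frac, _CEIL_DECIMALS))
        return pd.Series(
            np.clip(raw, 1, self.n_classes).astype(int), index=scores.index
        )


def discretize(scores: pd.Series, n_classes: int = 8, parameter: str = "") -> ClassLabelMap:
    """Discretize observed scores into ``n_classes`` levels by range fraction.

    ``class = clamp(ceil(n_classes * (x - min) / (max - min)), 1, n_classes)``:
    exact-integer products keep their value (there is no digit to round up),
    and x = min (which ceils to 0) is clamped into class 1.
    """
    obs = scores.dropna().astype(float)
    if obs.empty or obs.max() == obs.min():
        raise DegenerateDesignError(f"scores for {parameter or scores.name!r} are constant")
    lab = ClassLabelMap(
        parameter=parameter or str(scores.name),
        labels=pd.Series(dtype=int),
        vmin=float(obs.min()),
        vmax=float(obs.max()),
        n_classes=n_classes,
    )
    lab.labels = lab.apply(obs)
    return lab


@dataclass
class FeatureMatrix:
    """Subjects x edges correlation features for one network component."""

    values: np.ndarray  # (n_subjects, n_edges)
    edge_ids: list[tuple[int, int]]  # ROI id pairs, component edge order
    subject_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.edge_ids)):
            raise AlignmentError("feature matrix shape does not match ids")


def component_features(stack: ConnectivityStack, component: NetworkComponent) -> FeatureMatrix:
    """Extract the component's edge correlations for every subject."""
    roi_pos = {rid: k for k, rid in enumerate(stack.roi_ids)}
    try:
        cols = [(roi_pos[i], roi_pos[j]) for i, j in component.edges]
    except KeyError as exc:
        raise AlignmentError(f"component ROI {exc} not in the connectivity stack") from exc
    vals = np.stack([stack.matrices[:, a, b] for a, b in cols], axis=1)
    return FeatureMatrix(values=vals, edge_ids=list(component.edges), subject_ids=list(stack.subject_ids))


# ---------------------------------------------------------------------------
# one-against-all machinery

def _fit_oaa(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> dict[int, SVC]:
    """One binary RBF-SVM per class present with >= 1 positive and 1 negative."""
    svms = {}
    for cls in np.unique(y):
        pos = y == cls
        if pos.all():
            continue
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X, np.where(pos, 1, -1))
        svms[int(cls)] = clf
    return svms


def _decide(svms: dict[int, SVC], X: np.ndarray) -> np.ndarray:
    """Predicted class per row: argmax of decision values, ties to lowest class."""
    classes = sorted(svms)
    dec = np.column_stack([svms[c].decision_function(X) for c in classes])
    return np.asarray(classes)[np.argmax(dec, axis=1)]


def _scale(train: np.ndarray, *others: np.ndarray):
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((arr - mean) / sd for arr in (train, *others)) + (mean, sd)


def _loocv_predict(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> np.ndarray:
    """Leave-one-out predictions; per fold the scaler is refit on the n-1."""
    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte, *_ = _scale(X[mask], X[i : i + 1])
        svms = _fit_oaa(Xtr, y[mask], C, gamma)
        if not svms:  # left-out subject was the only member of its class
            preds[i] = int(np.bincount(y[mask]).argmax())
            continue
        preds[i] = _decide(svms, Xte)[0]
    return preds


@dataclass
class OaaSvmModel:
    """A trained one-against-all multiclass RBF-SVM with its preprocessing."""

    parameter: str
    svms: dict[int, SVC]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    C: float
    gamma: float
    label_map: ClassLabelMap
    edge_ids: list[tuple[int, int]]
    loocv_accuracy_pct: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_sd
        return _decide(self.svms, Xs)


def train_oaa_svm(
    features: FeatureMatrix,
    labels: ClassLabelMap,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> OaaSvmModel:
    """Grid-search (C, gamma) by LOOCV accuracy and fit the final model.

    The grid is scanned in ascending (C, gamma) order and a strictly better
    accuracy is required to displace the incumbent, so ties break toward
    smaller C, then smaller gamma.  The final per-class SVMs are refit on
    all subjects with the winning pair.  The procedure is deterministic:
    ``seed`` is accepted for interface symmetry but no randomness is used.
    """
    y = labels.labels.reindex(features.subject_ids)
    if y.isna().any():
        raise AlignmentError("labels missing for some feature-matrix subjects")
    y = y.to_numpy(dtype=int)
    if features.values.size == 0:
        raise ValueError("empty feature matrix")
    if np.unique(y).size < 2:
        raise DegenerateDesignError("need at least 2 distinct classes to train")

    best = None  # (accuracy, C, gamma, preds)
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            preds = _loocv_predict(features.values, y, C, gamma)
            acc = float(np.mean(preds == y))
            if best is None or acc > best[0]:
                best = (acc, C, gamma, preds)
    acc, C, gamma, _ = best
    Xs, mean, sd = _scale(features.values)
    svms = _fit_oaa(Xs, y, C, gamma)
    return OaaSvmModel(
        parameter=labels.parameter,
        svms=svms,
        scaler_mean=mean,
        scaler_sd=sd,
        C=float(C),
        gamma=float(gamma),
        label_map=labels,
        edge_ids=list(features.edge_ids),
        loocv_accuracy_pct=100.0 * acc,
    )


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class ClassifierReport:
    """LOOCV (or held-out) evaluation of one network's classifier."""

    parameter: str
    y_true: np.ndarray
    y_pred: np.ndarray
    n_classes: int
    best_c: float | None = None
    best_gamma: float | None = None
    confusion: np.ndarray = field(init=False)
    accuracy_pct: float = field(init=False)
    sensitivity_pct: float = field(init=False)
    specificity_pct: float = field(init=False)
    theoretical_chance_pct: float = field(init=False)
    corrected_chance_pct: float = field(init=False)
    p_vs_chance: float = field(init=False)

    def __post_init__(self):
        yt = np.asarray(self.y_true, dtype=int)
        yp = np.asarray(self.y_pred, dtype=int)
        k = self.n_classes
        cm = np.zeros((k, k), dtype=int)
        for a, b in zip(yt, yp):
            cm[a - 1, b - 1] += 1
        self.confusion = cm
        n = len(yt)
        self.accuracy_pct = 100.0 * np.trace(cm) / n
        sens, spec = [], []
        for c in range(k):
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = n - tp - fn - fp
            if tp + fn > 0:
                sens.append(tp / (tp + fn))
            if tn + fp > 0:
                spec.append(tn / (tn + fp))
        self.sensitivity_pct = 100.0 * float(np.mean(sens)) if sens else float("nan")
        self.specificity_pct = 100.0 * float(np.mean(spec)) if spec else float("nan")
        theo, corr = chance_levels(self.n_classes, n)
        self.theoretical_chance_pct = theo
        self.corrected_chance_pct = corr
        n_correct = int(np.trace(cm))
        self.p_vs_chance = float(
            stats.binomtest(n_correct, n, 1.0 / self.n_classes, alternative="greater").pvalue
        )

    @property
    def n_subjects(self) -> int:
        return len(self.y_true)

    @property
    def correct(self) -> np.ndarray:
        return (np.asarray(self.y_true) == np.asarray(self.y_pred)).astype(int)


def loocv_evaluate(
    features: FeatureMatrix,
    labels: ClassLabelMap,
    C: float,
    gamma: float,
) -> ClassifierReport:
    """Leave-one-out evaluation at fixed hyperparameters.

    Each subject is predicted by a one-against-all model trained on the
    other n - 1 subjects (scaler included in each fold).
    """
    y = labels.labels.reindex(features.subject_ids).to_numpy(dtype=int)
    n_obs_classes = np.unique(y).size
    if len(y) < n_obs_classes:
        raise InsufficientDataError("fewer subjects than observed classes")
    preds = _loocv_predict(features.values, y, C, gamma)
    return ClassifierReport(
        parameter=labels.parameter,
        y_true=y,
        y_pred=preds,
        n_classes=labels.n_classes,
        best_c=C,
        best_gamma=gamma,
    )


def chance_levels(n_classes: int, n_samples: int, alpha: float = 0.05) -> tuple[float, float]:
    """Theoretical and binomial-corrected chance accuracy, in percent.

    The theoretical level is ``100 / n_classes``.  The corrected level is
    ``100 * k / n_samples`` where k is the smallest correct-count whose
    cumulative probability under Binomial(n_samples, 1/n_classes) reaches
    1 - alpha — i.e. the smallest accuracy a guesser exceeds with
    probability < alpha.  With 8 classes and 150 samples this is
    26/150 = 17.33%, well above the theoretical 12.5%.
    """
    if n_classes < 2 or n_samples < 1:
        raise ValueError("need n_classes >= 2 and n_samples >= 1")
    theoretical = 100.0 / n_classes
    p0 = 1.0 / n_classes
    k = n_samples  # fallback: even perfect accuracy is not significant
    for kk in range(n_samples + 1):
        if stats.binom.cdf(kk, n_samples, p0) >= 1.0 - alpha:
            k = kk
            break
    return theoretical, 100.0 * k / n_samples


def significance_vs_chance(
    report: ClassifierReport, alpha: float = 0.05, method: str = "binomial"
) -> tuple[bool, float]:
    """Is the report's accuracy significantly above chance?

    ``method="binomial"`` (primary): exact one-sided binomial test of the
    correct-count against p0 = 1/n_classes.  ``method="t"`` (secondary,
    mirroring a one-sample t-test on per-fold accuracies): one-sample
    t-test of the 0/1 correctness vector against 1/n_classes.
    """
    if method == "binomial":
        p = report.p_vs_chance
    elif method == "t":
        res = stats.ttest_1samp(report.correct, 1.0 / report.n_classes, alternative="greater")
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return bool(p < alpha), p


def apply_classifiers(
    new_features: FeatureMatrix,
    model: OaaSvmModel,
    true_scores: pd.Series | None = None,
) -> tuple[np.ndarray, ClassifierReport | None]:
    """Predict classes for a held-out population with a trained model.

    New features must carry the training edge ids in order.  When true
    scores are supplied they are discretized with the *stored training*
    min/max and compared, producing a report whose chance levels reflect
    the held-out sample size.
    """
    if list(new_features.edge_ids) != list(model.edge_ids):
        raise AlignmentError("feature edge ids do not match the trained model")
    preds = model.predict(new_features.values)
    if true_scores is None:
        return preds, None
    y_true = model.label_map.apply(true_scores.reindex(new_features.subject_ids)).to_numpy()
    report = ClassifierReport(
        parameter=model.parameter,
        y_true=y_true,
        y_pred=preds,
        n_classes=model.label_map.n_classes,
        best_c=model.C,
        best_gamma=model.gamma,
    )
    return preds, report
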