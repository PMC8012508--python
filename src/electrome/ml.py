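"""Windowed-feature classification of electrome recordings.

Each recording is cut into overlapping windows; for every window the FFT
amplitude spectrum, the Welch PSD and the CWT scalogram magnitudes are
summarised by six statistics each (mean, max, min, variance, skewness,
kurtosis), giving 18 raw spectral features, plus the window's approximate
entropy.  The 18 spectral features are z-scored and reduced by PCA to
three scores, so the final feature vector per window is
(PCA1, PCA2, PCA3, entropy).  A battery of seven classifiers plus a
stratified dummy baseline is evaluated by repeated stratified k-fold
cross-validation; a model is considered informative only when its mean
accuracy clears the dummy's.

Windows cut from one recording overlap by 30 % and share its slow
components, so the default fold scheme (windows of one recording may
appear in both train and test folds) leaks recording identity into the
evaluation.  A group-aware scheme that keeps each recording's windows in
a single fold is available via ``group_aware=True`` and is the honest
choice when recordings, not windows, are the experimental unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .complexity import apen
from .descriptive import dispersion
from .io import Recording, WindowSet, segment
from .spectral import cwt_scalogram, fft_spectrum, psd

__all__ = [
    "FeatureMatrix",
    "ModelReport",
    "MODEL_REGISTRY",
    "extract_window_features",
    "extract_dataset_features",
    "pca_features",
    "evaluate_models",
    "sensitivity_precision",
    "scatter_plot",
    "compare_conditions",
    "COMPARISONS",
    "accuracy_summary",
]

RAW_FEATURE_COLUMNS = [
    f"{rep}_{stat}"
    for rep in ("fft", "psd", "cwt")
    for stat in ("mean", "max", "min", "var", "skew", "kurt")
]
FINAL_FEATURE_COLUMNS = ["PCA1", "PCA2", "PCA3", "entropy"]


@dataclass
class FeatureMatrix:
    """Per-window feature table with class labels and source-recording ids."""

    df: pd.DataFrame
    feature_columns: list[str]
    label_col: str = "label"
    group_col: str = "group_id"
    explained_variance_ratio: np.ndarray | None = None

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.label_col].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.df[self.group_col].to_numpy()

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ModelReport:
    """Cross-validated performance of one classifier."""

    model: str
    accuracy_mean: float  # percent
    accuracy_sd: float  # percent, SD over repeats
    sensitivity: dict  # class -> percent (NaN when undefined)
    precision: dict  # class -> percent (NaN when undefined)
    n_repeats: int
    k_folds: int
    seed: int
    params: dict = field(default_factory=dict)


def _model_registry(seed: int) -> dict[str, object]:
    """The frozen classifier battery (library-default hyperparameters).

    Scale-sensitive models (SVC variants, k-NN, Gaussian process) are
    wrapped in a standardising pipeline.
    """
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "svc_rbf": make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed)),
        "linear_svc": make_pipeline(
            StandardScaler(), LinearSVC(max_iter=5000, random_state=seed)
        ),
        "gaussian_process": make_pipeline(
            StandardScaler(), GaussianProcessClassifier(random_state=seed)
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier()),
        "random_forest": RandomForestClassifier(random_state=seed),
        "gaussian_nb": GaussianNB(),
        "dummy_stratified": DummyClassifier(strategy="stratified", random_state=seed),
    }


MODEL_REGISTRY: Callable[[int], dict] = _model_registry


def _window_entropy(x: np.ndarray, m: int = 2, r_coef: float = 0.2) -> float:
    sd = float(np.std(x))
    if sd == 0:
        return float("nan")
    return apen(x, m=m, r=r_coef * sd)


def extract_window_features(
    ws: WindowSet,
    label: str | None = None,
    group_id: str | None = None,
    m: int = 2,
    r_coef: float = 0.2,
) -> FeatureMatrix:
    """Raw spectral-summary features plus entropy, one row per window.

    Each window yields 18 spectral statistics (six per representation:
    FFT amplitudes, Welch PSD, CWT magnitudes) and its approximate
    entropy (m = 2, r = 0.2·SD of the window).  Constant windows, whose
    entropy and kurtosis are undefined, are dropped with a warning.
    """
    parent = ws.parent
    if label is None:
        label = parent.label
    if group_id is None:
        group_id = parent.plant_id
    rows = []
    for idx, x in enumerate(ws.arrays()):
        if x.size < 256:
            raise ValueError("windows must hold at least 256 samples")
        if np.std(x) == 0:
            import warnings

            warnings.warn(f"dropping constant window {idx} of {group_id}")
            continue
        win = Recording(
            samples=x, fs=parent.fs, plant_id=f"{group_id}-w{idx}",
            treatment=parent.treatment, phase=parent.phase,
        )
        reps = {
            "fft": fft_spectrum(win).values,
            "psd": psd(win).values,
            "cwt": cwt_scalogram(win).magnitude.ravel(),
        }
        row: dict[str, object] = {}
        for name, vals in reps.items():
            d = dispersion(vals)
            row[f"{name}_mean"] = d.mean
            row[f"{name}_max"] = float(np.max(vals))
            row[f"{name}_min"] = float(np.min(vals))
            row[f"{name}_var"] = d.sd**2
            row[f"{name}_skew"] = d.skewness
            row[f"{name}_kurt"] = d.kurtosis
        row["entropy"] = _window_entropy(x, m=m, r_coef=r_coef)
        row["label"] = label
        row["group_id"] = group_id
        row["window"] = idx
        rows.append(row)
    df = pd.DataFrame(rows)
    return FeatureMatrix(df=df, feature_columns=RAW_FEATURE_COLUMNS + ["entropy"])


def extract_dataset_features(
    dataset: Mapping[str, Sequence[Recording]],
    n_windows: int = 10,
    overlap_fraction: float = 0.3,
) -> FeatureMatrix:
    """Window and featurise every recording of a labelled dataset."""
    frames = []
    for label, recs in dataset.items():
        for rec in recs:
            fm = extract_window_features(
                segment(rec, n_windows=n_windows, overlap_fraction=overlap_fraction),
                label=label,
                group_id=rec.plant_id,
            )
            frames.append(fm.df)
    df = pd.concat(frames, ignore_index=True)
    return FeatureMatrix(df=df, feature_columns=RAW_FEATURE_COLUMNS + ["entropy"])


def pca_features(raw: FeatureMatrix, n_components: int = 3) -> FeatureMatrix:
    """Reduce the 18 spectral features to PCA scores; keep entropy as-is.

    Columns are z-scored before the decomposition.  Component signs follow
    a deterministic convention: the loading of largest magnitude in each
    component is made positive.  The final feature set per window is
    (PCA1..PCA{n_components}, entropy).
    """
    spectral_cols = [c for c in raw.feature_columns if c != "entropy"]
    if len(raw.df) <= n_components:
        raise ValueError("need more rows than PCA components")
    X = raw.df[spectral_cols].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("raw features contain NaN")
    Xz = StandardScaler().fit_transform(X)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xz)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    df = raw.df[["label", "group_id"]].copy()
    if "window" in raw.df.columns:
        df["window"] = raw.df["window"]
    for j in range(n_components):
        df[f"PCA{j + 1}"] = scores[:, j]
    df["entropy"] = raw.df["entropy"].to_numpy()
    cols = [f"PCA{j + 1}" for j in range(n_components)] + ["entropy"]
    return FeatureMatrix(
        df=df, feature_columns=cols,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def _seeded_clone(est, rs: int):
    """Clone an estimator, re-seeding every random_state parameter.

    Each (repeat, fold) fit gets its own derived random state so that
    stochastic models — the stratified dummy above all — resample their
    randomness across the repeated splits, while the whole evaluation
    stays deterministic given the master seed.
    """
    model = clone(est)
    params = {
        k: rs for k in model.get_params(deep=True) if k.endswith("random_state")
    }
    if params:
        model.set_params(**params)
    return model


def _fold_iter(y, groups, k_folds, shuffle_seed, group_aware):
    if group_aware:
        cv = StratifiedGroupKFold(n_splits=k_folds, shuffle=True,
                                  random_state=shuffle_seed)
        return cv.split(np.zeros(len(y)), y, groups=groups)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=shuffle_seed)
    return cv.split(np.zeros(len(y)), y)


def evaluate_models(
    fm: FeatureMatrix,
    models: Mapping[str, object] | None = None,
    k_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    group_aware: bool = False,
) -> list[ModelReport]:
    """Repeated stratified k-fold evaluation of the classifier battery.

    Each repeat reshuffles the stratified folds; a repeat's accuracy is
    the mean over its folds, and the report carries the mean ± SD over
    repeats (in percent) plus per-class sensitivity and precision pooled
    over the folds of the first repeat.  Fully deterministic given
    (fm, seed).
    """
    y = fm.y
    X = fm.X
    groups = fm.groups
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for cls, cnt in zip(classes, counts):
        if cnt < k_folds:
            raise ValueError(f"class '{cls}' has fewer rows ({cnt}) than k_folds")
    if models is None:
        models = _model_registry(seed)
    reports = []
    for name, est in models.items():
        accs = np.empty(n_repeats)
        pooled_true: list = []
        pooled_pred: list = []
        for rep in range(n_repeats):
            fold_accs = []
            for fold, (tr, te) in enumerate(
                _fold_iter(y, groups, k_folds, seed + rep, group_aware)
            ):
                rs = (seed * 100003 + rep * 1009 + fold) % (2**31)
                model = _seeded_clone(est, rs)
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
                fold_accs.append(float(np.mean(pred == y[te])))
                if rep == 0:
                    pooled_true.extend(y[te])
                    pooled_pred.extend(pred)
            accs[rep] = float(np.mean(fold_accs))
        sens, prec = _rates_from_confusion(
            np.asarray(pooled_true), np.asarray(pooled_pred), classes
        )
        reports.append(
            ModelReport(
                model=name,
                accuracy_mean=float(100.0 * accs.mean()),
                accuracy_sd=float(100.0 * accs.std(ddof=1)) if n_repeats > 1 else 0.0,
                sensitivity=sens,
                precision=prec,
                n_repeats=n_repeats,
                k_folds=k_folds,
                seed=seed,
                params=_describe_params(est),
            )
        )
    return reports


def _describe_params(est) -> dict:
    try:
        return {k: v for k, v in est.get_params(deep=False).items()
                if isinstance(v, (int, float, str, bool, type(None)))}
    except Exception:
        return {}


def _rates_from_confusion(y_true, y_pred, classes):
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    sens: dict = {}
    prec: dict = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        sens[str(cls)] = float(100.0 * tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
        prec[str(cls)] = float(100.0 * tp / (tp + fp)) if (tp + fp) > 0 else float("nan")
    return sens, prec


def sensitivity_precision(
    model,
    fm: FeatureMatrix,
    k_folds: int = 5,
    seed: int = 0,
    group_aware: bool = False,
) -> tuple[dict, dict]:
    """Per-class sensitivity TP/(TP+FN) and precision TP/(TP+FP).

    Predictions are pooled over a stratified k-fold split (each row is
    predicted exactly once, by a model trained on the other folds).
    Classes absent from the pooled predictions get NaN rates.
    """
    y = fm.y
    X = fm.X
    classes = np.unique(y)
    y_pred = np.empty_like(y)
    for fold, (tr, te) in enumerate(_fold_iter(y, fm.groups, k_folds, seed, group_aware)):
        est = _seeded_clone(model, (seed * 100003 + fold) % (2**31))
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
    return _rates_from_confusion(y, y_pred, classes)


def scatter_plot(
    fm: FeatureMatrix,
    coords: tuple[str, str] = ("PCA1", "entropy"),
    path=None,
):
    """Scatter of two features, one colour per class; optionally saved.

    Returns the matplotlib Figure.  Output files are deterministic for a
    fixed FeatureMatrix (no timestamps embedded).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    cx, cy = coords
    for c in coords:
        if c not in fm.df.columns:
            raise ValueError(f"unknown feature '{c}'")
    if len(fm.df) == 0:
        raise ValueError("empty feature matrix")
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sub in fm.df.groupby(fm.label_col):
        ax.scatter(sub[cx], sub[cy], s=18, alpha=0.8, label=str(label))
    ax.set_xlabel(cx)
    ax.set_ylabel(cy)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120, metadata=_no_date_metadata(str(path)))
        plt.close(fig)
    return fig


def _no_date_metadata(path: str) -> dict | None:
    if path.endswith(".svg"):
        return {"Date": None}
    return None


# The five condition comparisons of the host-detection design.
COMPARISONS: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("CB-before_vs_CB-after", ("CB-before",), ("CB-after",)),
    ("CW-before_vs_CW-after", ("CW-before",), ("CW-after",)),
    ("CB-before_vs_CW-before", ("CB-before",), ("CW-before",)),
    ("CB-after_vs_CW-after", ("CB-after",), ("CW-after",)),
    ("CB_vs_CW", ("CB-before", "CB-after"), ("CW-before", "CW-after")),
)


def compare_conditions(
    dataset: Mapping[str, Sequence[Recording]],
    comparisons=COMPARISONS,
    n_windows: int = 10,
    overlap_fraction: float = 0.3,
    k_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    group_aware: bool = False,
) -> dict[str, list[ModelReport]]:
    """Evaluate the classifier battery on each condition comparison.

    For every comparison the relevant classes are pooled into two groups,
    featurised (windowing → spectral summaries → PCA + entropy, with the
    PCA fitted on that comparison's windows only) and scored with
    ``evaluate_models``.  Returns one list of ModelReports per comparison.
    """
    raw = extract_dataset_features(
        dataset, n_windows=n_windows, overlap_fraction=overlap_fraction
    )
    results: dict[str, list[ModelReport]] = {}
    for name, side_a, side_b in comparisons:
        for cls in (*side_a, *side_b):
            if cls not in dataset:
                raise ValueError(f"comparison '{name}' needs missing group '{cls}'")
        sub = raw.df[raw.df["label"].isin(side_a + side_b)].copy()
        sub["label"] = np.where(sub["label"].isin(side_a), "A:" + "+".join(side_a),
                                "B:" + "+".join(side_b))
        fm = pca_features(
            FeatureMatrix(df=sub.reset_index(drop=True),
                          feature_columns=raw.feature_columns)
        )
        results[name] = evaluate_models(
            fm, k_folds=k_folds, n_repeats=n_repeats, seed=seed,
            group_aware=group_aware,
        )
    return results


def accuracy_summary(results: Mapping[str, Sequence[ModelReport]]) -> pd.DataFrame:
    """Accuracy table: rows = comparisons, columns = models (percent)."""
    data = {
        comp: {r.model: r.accuracy_mean for r in reports}
        for comp, reports in results.items()
    }
    return pd.DataFrame(data).T
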