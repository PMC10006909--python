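"""Classifier-level fusion of textural and deep features, and its evaluation.

Six fusion schemes combine the texture battery with the CNN tap features
before a single supervised classifier:

1. ``Concat``        — plain column concatenation;
2. ``FS+Concat``     — feature selection within each source, then concatenation;
3. ``Concat+FS``     — concatenation, then feature selection;
4. ``Concat+PSO``    — concatenation, then binary-PSO selection;
5. ``KPCA+Concat``   — 300 kernel-PCA components per source, concatenated (600);
6. ``Concat+KPCA``   — concatenation, then 500 kernel-PCA components.

Every data-dependent reduction is fitted on training rows only and applied
to test rows.  Evaluation trains an SVM with a 3rd-degree polynomial kernel,
a 100-tree random forest, and AdaBoost with 100 entropy-based decision trees,
and reports accuracy, sensitivity, specificity and AUC on the 0-100 scale
with HCC as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dimred import (
    KernelPCA,
    KpcaConfig,
    PSOConfig,
    cfs_select,
    combine_selections,
    iga_select,
    pso_select,
)
from .patch_io import HCC, PAR

__all__ = [
    "SCHEMES",
    "FusionConfig",
    "ClassifierReport",
    "FusionTransformer",
    "fuse",
    "evaluate",
    "avg_dif",
    "run_experiment_grid",
]

SCHEMES = ("Concat", "FS+Concat", "Concat+FS", "Concat+PSO", "KPCA+Concat", "Concat+KPCA")


@dataclass
class FusionConfig:
    """One fusion scheme plus its dimensionality-reduction parameters."""

    scheme: str = "Concat"
    fs_method: str = "cfs&iga"  # cfs | iga | cfs&iga (intersection)
    kpca: KpcaConfig = field(default_factory=lambda: KpcaConfig(kernel="gaussian"))
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_components_joint: int = 500
    n_components_each: int = 300

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.fs_method not in ("cfs", "iga", "cfs&iga"):
            raise ValueError(f"unknown fs_method {self.fs_method!r}")


def _select(x: pd.DataFrame, y, method: str) -> list[str]:
    if method == "cfs":
        return cfs_select(x, y)
    if method == "iga":
        return iga_select(x, y)
    cfs = cfs_select(x, y)
    iga = iga_select(x, y)
    return combine_selections(cfs, iga)


def _capped_kpca(config: KpcaConfig, n_components: int, n_train: int) -> KpcaConfig:
    cap = min(n_components, n_train)
    if cap < n_components:
        warnings.warn(f"reducing KPCA components from {n_components} to {cap} "
                      f"(only {n_train} training rows)")
    return replace(config, n_components=cap)


class FusionTransformer:
    """Fits a fusion scheme on training rows; transforms any aligned rows."""

    def __init__(self, config: FusionConfig, seed: int = 0):
        self.config = config
        self.seed = seed

    def fit(self, texture: pd.DataFrame, deep: pd.DataFrame, labels) -> "FusionTransformer":
        if len(texture) != len(deep):
            raise ValueError(f"row mismatch: texture {len(texture)} vs deep {len(deep)}")
        cfg = self.config
        scheme = cfg.scheme
        y = np.asarray(labels)
        self._texture_cols = list(texture.columns)
        self._deep_cols = list(deep.columns)
        if scheme == "Concat":
            pass
        elif scheme == "FS+Concat":
            self._sel_t = _select(texture, y, cfg.fs_method)
            self._sel_d = _select(deep, y, cfg.fs_method)
        elif scheme in ("Concat+FS", "Concat+PSO"):
            joint = pd.concat([texture, deep], axis=1)
            if scheme == "Concat+FS":
                self._sel_j = _select(joint, y, cfg.fs_method)
            else:
                pso = replace(cfg.pso, seed=self.seed)
                self._sel_j = pso_select(joint, y, pso)
        elif scheme == "KPCA+Concat":
            kc = _capped_kpca(cfg.kpca, cfg.n_components_each, len(texture))
            self._kpca_t = KernelPCA(kc).fit(texture)
            self._kpca_d = KernelPCA(kc).fit(deep)
        elif scheme == "Concat+KPCA":
            joint = pd.concat([texture, deep], axis=1)
            kc = _capped_kpca(cfg.kpca, cfg.n_components_joint, len(joint))
            self._kpca_j = KernelPCA(kc).fit(joint)
        return self

    def transform(self, texture: pd.DataFrame, deep: pd.DataFrame) -> pd.DataFrame:
        if len(texture) != len(deep):
            raise ValueError(f"row mismatch: texture {len(texture)} vs deep {len(deep)}")
        scheme = self.config.scheme
        if scheme == "Concat":
            return pd.concat([texture.reset_index(drop=True),
                              deep.reset_index(drop=True)], axis=1)
        if scheme == "FS+Concat":
            return pd.concat([texture[self._sel_t].reset_index(drop=True),
                              deep[self._sel_d].reset_index(drop=True)], axis=1)
        if scheme in ("Concat+FS", "Concat+PSO"):
            joint = pd.concat([texture.reset_index(drop=True),
                               deep.reset_index(drop=True)], axis=1)
            return joint[self._sel_j]
        if scheme == "KPCA+Concat":
            st = self._kpca_t.transform(texture)
            sd = self._kpca_d.transform(deep)
            cols = ([f"kpca_tex_{i}" for i in range(st.shape[1])]
                    + [f"kpca_deep_{i}" for i in range(sd.shape[1])])
            return pd.DataFrame(np.hstack([st, sd]), columns=cols)
        joint = pd.concat([texture.reset_index(drop=True),
                           deep.reset_index(drop=True)], axis=1)
        sj = self._kpca_j.transform(joint)
        return pd.DataFrame(sj, columns=[f"kpca_joint_{i}" for i in range(sj.shape[1])])


def fuse(texture: pd.DataFrame, deep: pd.DataFrame, labels, config: FusionConfig,
         seed: int = 0, train_index=None) -> dict[str, pd.DataFrame]:
    """Apply one fusion scheme; reductions are fitted on training rows only.

    With ``train_index`` given, returns ``{"train": ..., "test": ...}`` fused
    matrices (test rows are all rows not in ``train_index``); without it, the
    scheme is fitted and applied to all rows (key ``"all"``).
    """
    y = np.asarray(labels)
    if train_index is None:
        ft = FusionTransformer(config, seed).fit(texture, deep, y)
        return {"all": ft.transform(texture, deep)}
    train_index = np.asarray(train_index)
    mask = np.zeros(len(texture), dtype=bool)
    mask[train_index] = True
    ft = FusionTransformer(config, seed).fit(
        texture.iloc[train_index], deep.iloc[train_index], y[train_index])
    test_index = np.flatnonzero(~mask)
    return {
        "train": ft.transform(texture.iloc[train_index], deep.iloc[train_index]),
        "test": ft.transform(texture.iloc[test_index], deep.iloc[test_index]),
    }


@dataclass
class ClassifierReport:
    """Per-classifier medical performance metrics (percent; HCC positive)."""

    metrics: dict[str, dict[str, float]]
    confusion: dict[str, tuple[int, int, int, int]]  # TP, FN, TN, FP
    settings: dict

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.metrics).T[["accuracy", "sensitivity", "specificity", "auc"]]

    def mean_metrics(self) -> dict[str, float]:
        df = self.summary()
        return {k: float(df[k].mean()) for k in df.columns}


def _default_classifiers(seed: int, svm_max_iter: int = -1,
                         n_estimators: int = 100) -> dict:
    return {
        "svm_poly3": SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale",
                         max_iter=svm_max_iter, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=n_estimators,
                                                random_state=seed, n_jobs=1),
        "adaboost_trees": AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy", min_samples_leaf=2,
                                             random_state=seed),
            n_estimators=n_estimators, random_state=seed),
    }


def evaluate(f_train: pd.DataFrame, y_train, f_test: pd.DataFrame, y_test,
             seed: int = 0, classifiers: dict | None = None) -> ClassifierReport:
    """Train the classifier suite and compute test metrics from the confusion matrix.

    Sensitivity is the true-positive rate of the HCC class, specificity the
    true-negative rate (PAR), and AUC the rank statistic of the classifier's
    decision scores for HCC.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    for name, y in (("train", y_train), ("test", y_test)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set contains a single class")
    classifiers = classifiers or _default_classifiers(seed)
    scaler = StandardScaler().fit(f_train)
    x_tr = scaler.transform(f_train)
    x_te = scaler.transform(f_test)
    y01_tr = (y_train == HCC).astype(int)
    y01_te = (y_test == HCC).astype(int)
    metrics, confusion = {}, {}
    for name, clf in classifiers.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(x_tr, y01_tr)
            pred = clf.predict(x_te)
            if hasattr(clf, "predict_proba"):
                score = clf.predict_proba(x_te)[:, list(clf.classes_).index(1)]
            else:
                score = clf.decision_function(x_te)
        tp = int(np.sum((pred == 1) & (y01_te == 1)))
        fn = int(np.sum((pred == 0) & (y01_te == 1)))
        tn = int(np.sum((pred == 0) & (y01_te == 0)))
        fp = int(np.sum((pred == 1) & (y01_te == 0)))
        metrics[name] = {
            "accuracy": 100.0 * (tp + tn) / len(y01_te),
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else 0.0,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else 0.0,
            "auc": 100.0 * float(roc_auc_score(y01_te, score)),
        }
        confusion[name] = (tp, fn, tn, fp)
    settings = {name: {k: v for k, v in clf.get_params().items()
                       if k in ("kernel", "degree", "n_estimators", "criterion")}
                for name, clf in classifiers.items()}
    return ClassifierReport(metrics=metrics, confusion=confusion, settings=settings)


def avg_dif(current, other, convention: str = "algebraic") -> float:
    """Mean of the four per-metric differences between two (acc, sens, spec, auc)
    quadruples on the 0-100 scale.

    ``convention='algebraic'`` returns current minus other; ``'table'``
    returns the opposite sign (other minus current), matching the usual
    presentation where improvements over prior methods print as negative
    differences for the prior method's row.
    """
    cur = np.asarray(current, dtype=float)
    oth = np.asarray(other, dtype=float)
    if cur.shape != (4,) or oth.shape != (4,):
        raise ValueError("expected two quadruples (accuracy, sensitivity, specificity, auc)")
    value = float(np.mean(cur - oth))
    if convention == "table":
        return -value
    if convention != "algebraic":
        raise ValueError(f"unknown convention {convention!r}")
    return value


def run_experiment_grid(texture: pd.DataFrame, deep_by_backbone: dict[str, pd.DataFrame],
                        labels, train_index, schemes=SCHEMES, seed: int = 0,
                        configs: dict | None = None,
                        classifiers_factory=None) -> dict[str, pd.DataFrame]:
    """Evaluate every backbone x scheme combination.

    Returns ``{"grid": per-combination mean metrics over the three
    classifiers, "per_scheme": mean and standard deviation of the grid
    accuracies per scheme}`` mirroring how combination studies tabulate
    results.
    """
    y = np.asarray(labels)
    train_index = np.asarray(train_index)
    mask = np.zeros(len(texture), dtype=bool)
    mask[train_index] = True
    test_index = np.flatnonzero(~mask)
    rows = []
    for backbone, deep in deep_by_backbone.items():
        for scheme in schemes:
            config = (configs or {}).get(scheme) or FusionConfig(scheme=scheme)
            if config.scheme != scheme:
                config = replace(config, scheme=scheme)
            ft = FusionTransformer(config, seed).fit(
                texture.iloc[train_index], deep.iloc[train_index], y[train_index])
            f_tr = ft.transform(texture.iloc[train_index], deep.iloc[train_index])
            f_te = ft.transform(texture.iloc[test_index], deep.iloc[test_index])
            clfs = classifiers_factory(seed) if classifiers_factory else None
            report = evaluate(f_tr, y[train_index], f_te, y[test_index],
                              seed=seed, classifiers=clfs)
            rows.append({"backbone": backbone, "scheme": scheme,
                         **report.mean_metrics()})
    grid = pd.DataFrame(rows)
    per_scheme = grid.groupby("scheme")["accuracy"].agg(["mean", "std"]).reset_index()
    return {"grid": grid, "per_scheme": per_scheme}
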