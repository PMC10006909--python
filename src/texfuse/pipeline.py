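"""End-to-end orchestration of the synthetic fusion benchmark.

This module wires the stages together: generate a two-class speckle patch
benchmark, compute the texture battery once (it is per-patch, so no fitting
is involved), then for each pipeline seed draw a stratified 75/25 split,
fine-tune the tiny CNN on the training patches, tap its features, and run
every fusion scheme through the classifier suite.

The ``desk_classifiers`` configuration bounds the cost of the tree ensembles
(depth-3 AdaBoost base learners, 40 boosting rounds) so a full 6-scheme
x 3-seed sweep on 2000 patches completes in minutes on one core; the
study-default settings remain available through :func:`texfuse.fusion.evaluate`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .deep import DeepFeatureSpec, TrainConfig, build_backbone, extract_features, finetune
from .dimred import KpcaConfig, PSOConfig
from .fusion import SCHEMES, FusionConfig, FusionTransformer, evaluate
from .patch_io import split_dataset
from .synthetic import HCC_DEFAULTS, PAR_DEFAULTS, build_benchmark_dataset
from .texture import TextureConfig, texture_feature_matrix

__all__ = ["desk_classifiers", "desk_fusion_config", "synthetic_fusion_benchmark"]


def desk_classifiers(seed: int) -> dict:
    """Classifier suite with bounded ensemble cost for desk-scale sweeps."""
    return {
        "svm_poly3": SVC(kernel="poly", degree=3, coef0=1.0, gamma="scale",
                         random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=100, random_state=seed,
                                                n_jobs=1),
        "adaboost_trees": AdaBoostClassifier(
            estimator=DecisionTreeClassifier(criterion="entropy", max_depth=3,
                                             min_samples_leaf=2, random_state=seed),
            n_estimators=40, random_state=seed),
    }


def desk_fusion_config(scheme: str) -> FusionConfig:
    """Fusion configuration with a reduced PSO search budget for sweeps."""
    return FusionConfig(
        scheme=scheme,
        kpca=KpcaConfig(kernel="gaussian"),
        pso=PSOConfig(swarm_size=12, iterations=15, inner_subsample=400),
    )


def synthetic_fusion_benchmark(
    n_per_class: int = 1000,
    dataset_seed: int = 123,
    pipeline_seeds=(0, 1, 2),
    schemes=SCHEMES,
    cnn_epochs: int = 5,
    texture_config: TextureConfig | None = None,
    params_hcc=HCC_DEFAULTS,
    params_par=PAR_DEFAULTS,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the fusion benchmark; returns rows (seed, scheme, acc/sens/spec/auc).

    The dataset is generated once from ``dataset_seed``; each pipeline seed
    controls the train/test split, the CNN initialization and training, and
    the classifier randomness.  Metrics are the means over the three
    classifiers on the held-out test rows.
    """
    patches = build_benchmark_dataset(n_per_class, params_hcc, params_par,
                                      seed=dataset_seed)
    texture = texture_feature_matrix(patches, texture_config, progress=progress)
    texture = texture.drop(columns="label")
    labels = np.array([p.label for p in patches])
    index_of = {id(p): i for i, p in enumerate(patches)}
    rows = []
    for seed in pipeline_seeds:
        parts = split_dataset(patches, "conventional", seed=seed)
        order = [index_of[id(p)] for p in parts["train"] + parts["test"]]
        n_train = len(parts["train"])
        tex_o = texture.iloc[order].reset_index(drop=True)
        lab_o = labels[order]
        model = build_backbone(DeepFeatureSpec("tiny_test_cnn", seed=seed))
        finetune(model, parts["train"], TrainConfig(epochs=cnn_epochs),
                 seed=seed, mode="full")
        deep = extract_features(model, parts["train"] + parts["test"])
        tr = np.arange(n_train)
        for scheme in schemes:
            if progress:
                print(f"  seed {seed}: scheme {scheme}", flush=True)
            cfg = desk_fusion_config(scheme)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ft = FusionTransformer(cfg, seed).fit(
                    tex_o.iloc[tr], deep.iloc[tr], lab_o[tr])
                f_tr = ft.transform(tex_o.iloc[tr], deep.iloc[tr])
                f_te = ft.transform(tex_o.iloc[n_train:], deep.iloc[n_train:])
                report = evaluate(f_tr, lab_o[tr], f_te, lab_o[n_train:],
                                  seed=seed, classifiers=desk_classifiers(seed))
            rows.append({"seed": seed, "scheme": scheme, **report.mean_metrics()})
    return pd.DataFrame(rows)
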