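"""The imagistic model: relevance ranking, cross-correlations, feature maps.

The imagistic model summarizes what distinguishes the tumor class from the
parenchyma class in feature space:

* a relevance ranking of the textural features inside the fused vectors —
  the mean of each textural feature's information-gain score across its
  combinations with every CNN backbone;
* per-feature class-conditional statistics (mean, standard deviation and a
  20-bin histogram probability distribution) for each relevant feature;
* a Pearson correlation table between textural and deep features (columns
  with zero variance are recorded as undefined, not coerced to a number);
* feature-map images — the fused feature vector reshaped into the maximal
  square gray image — and their per-class mean / standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimred import info_gain_scores
from .patch_io import HCC, PAR

__all__ = [
    "ImagisticModel",
    "rank_relevance",
    "pearson_cross_correlations",
    "feature_map_image",
    "map_statistics",
    "assemble_imagistic_model",
]


def rank_relevance(fused_by_backbone: dict[str, pd.DataFrame], labels,
                   textural_names: list[str]) -> pd.Series:
    """Mean information-gain score of each textural feature across backbone combos.

    Each fused matrix must contain the textural columns; a textural feature
    absent from a combination contributes a 0 score for it.  Returned series
    is sorted in descending relevance.
    """
    totals = pd.Series(0.0, index=list(textural_names))
    for _, fused in fused_by_backbone.items():
        scores = info_gain_scores(fused, labels)
        present = scores.reindex(totals.index).fillna(0.0)
        totals = totals.add(present)
    means = totals / max(len(fused_by_backbone), 1)
    return means.sort_values(ascending=False, kind="stable")


def pearson_cross_correlations(texture: pd.DataFrame, deep: pd.DataFrame) -> pd.DataFrame:
    """Full textural x deep Pearson coefficient table.

    Zero-variance columns yield NaN entries (recorded undefined), never a
    coerced numeric value.
    """
    if len(texture) != len(deep):
        raise ValueError("matrices must be row-aligned")
    xt = texture.to_numpy(dtype=float)
    xd = deep.to_numpy(dtype=float)
    xt = xt - xt.mean(axis=0)
    xd = xd - xd.mean(axis=0)
    st = np.sqrt((xt ** 2).sum(axis=0))
    sd = np.sqrt((xd ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (xt.T @ xd) / np.outer(st, sd)
    corr[np.outer(st == 0, np.ones_like(sd, dtype=bool))] = np.nan
    corr[np.outer(np.ones_like(st, dtype=bool), sd == 0)] = np.nan
    return pd.DataFrame(corr, index=texture.columns, columns=deep.columns)


def feature_map_image(vector) -> np.ndarray:
    """Reshape a feature vector into the maximal square gray image in [0, 1].

    The side is floor(sqrt(len)); the first side^2 values are reshaped
    row-major and min-max rescaled.  A constant vector maps to all zeros.
    """
    v = np.asarray(vector, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("vector must have at least one element")
    side = int(np.floor(np.sqrt(v.size)))
    img = v[: side * side].reshape(side, side)
    lo, hi = img.min(), img.max()
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def map_statistics(images_by_class: dict[str, list[np.ndarray]]) -> dict:
    """Mean gray level and standard deviation of the class-mean feature maps.

    The per-class statistics are computed on the pixelwise mean image of the
    class (one representative map per class); per-image statistics are also
    retained.  Emits HCC - PAR differences when both classes are present.
    """
    out: dict = {"per_class": {}, "per_image": {}}
    for cls, images in images_by_class.items():
        if not images:
            raise ValueError(f"class {cls}: need at least one image")
        stack = np.stack([np.asarray(im, dtype=float) for im in images])
        mean_img = stack.mean(axis=0)
        out["per_class"][cls] = {
            "mean_gray": float(mean_img.mean()),
            "std_gray": float(mean_img.std()),
        }
        out["per_image"][cls] = [
            {"mean_gray": float(im.mean()), "std_gray": float(im.std())} for im in stack
        ]
    if HCC in out["per_class"] and PAR in out["per_class"]:
        h, p = out["per_class"][HCC], out["per_class"][PAR]
        out["differences"] = {
            "mean_gray_hcc_minus_par": h["mean_gray"] - p["mean_gray"],
            "std_gray_hcc_minus_par": h["std_gray"] - p["std_gray"],
        }
    return out


@dataclass
class ImagisticModel:
    """Relevant features with class statistics, correlations and map properties."""

    relevant_features: dict[str, float]  # name -> mean relevance score
    per_feature_stats: dict[str, dict[str, dict]]  # name -> class -> stats
    correlation_table: pd.DataFrame
    map_properties: dict

    def to_json(self) -> str:
        corr = self.correlation_table.where(pd.notna(self.correlation_table), None)
        return json.dumps({
            "relevant_features": self.relevant_features,
            "per_feature_stats": self.per_feature_stats,
            "correlation_table": {
                "index": list(corr.index),
                "columns": list(corr.columns),
                "values": corr.to_numpy(dtype=object).tolist(),
            },
            "map_properties": self.map_properties,
        })

    @classmethod
    def from_json(cls, text: str) -> "ImagisticModel":
        doc = json.loads(text)
        ct = doc["correlation_table"]
        corr = pd.DataFrame(
            np.array(ct["values"], dtype=object), index=ct["index"], columns=ct["columns"]
        ).astype(float)
        return cls(doc["relevant_features"], doc["per_feature_stats"], corr,
                   doc["map_properties"])


def _class_stats(values: np.ndarray, bins: int = 20) -> dict:
    hist, edges = np.histogram(values, bins=bins)
    total = hist.sum()
    probs = (hist / total) if total else hist.astype(float)
    return {
        "mean": float(values.mean()),
        "std": float(values.std()),
        "prob_distribution": probs.tolist(),
        "bin_edges": edges.tolist(),
    }


def assemble_imagistic_model(
    ranking: pd.Series,
    features: pd.DataFrame,
    labels,
    correlations: pd.DataFrame,
    map_properties: dict,
    top_k: int | None = 20,
) -> ImagisticModel:
    """Assemble the model document from its computed components.

    ``ranking`` is the output of :func:`rank_relevance`; ``features`` holds
    the feature values used for the class-conditional statistics.  Raises a
    descriptive error when a required component is missing.
    """
    for name, comp in (("ranking", ranking), ("features", features),
                       ("correlations", correlations), ("map_properties", map_properties)):
        if comp is None or (hasattr(comp, "__len__") and len(comp) == 0):
            raise ValueError(f"imagistic-model assembly: missing component {name!r}")
    y = np.asarray(labels)
    relevant = ranking if top_k is None else ranking.iloc[:top_k]
    stats: dict[str, dict] = {}
    for feat in relevant.index:
        if feat not in features.columns:
            raise ValueError(f"imagistic-model assembly: feature {feat!r} missing from matrix")
        col = features[feat].to_numpy(dtype=float)
        stats[feat] = {cls: _class_stats(col[y == cls]) for cls in (HCC, PAR)}
    return ImagisticModel(
        relevant_features={k: float(v) for k, v in relevant.items()},
        per_feature_stats=stats,
        correlation_table=correlations,
        map_properties=map_properties,
    )
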