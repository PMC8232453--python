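"""Network-level signatures and the classification harness.

A network's signature bundles its summary statistics (node/edge counts,
average degree |E|/|V|, reciprocity, average directed clustering and closure
coefficients) with the eight pattern features: the node-averages of the four
clustering patterns and the four closure patterns (undefined node values
counted as zero).  The eight pattern features are the input to a
leave-one-out cross-validated tree classifier harness that predicts a
network's domain (trust, food web, citation, ...) and reports
impurity-based feature importances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import LeaveOneOut
from sklearn.tree import DecisionTreeClassifier

from .clustering import (
    average_coefficient,
    clustering_patterns,
    local_directed_clustering,
)
from .closure import closure_patterns, local_directed_closure
from .graph import DirectedGraph

__all__ = [
    "CLUSTERING_FEATURES",
    "CLOSURE_FEATURES",
    "ALL_FEATURES",
    "NetworkSignature",
    "signature",
    "signatures_frame",
    "standardize",
    "pearson",
    "loocv_classify",
    "feature_importance",
]

CLUSTERING_FEATURES = ["c_head", "c_mid", "c_end", "c_cyc"]
CLOSURE_FEATURES = ["e_head", "e_mid", "e_end", "e_cyc"]
ALL_FEATURES = CLUSTERING_FEATURES + CLOSURE_FEATURES

_FEATURE_SETS = {
    "clustering": CLUSTERING_FEATURES,
    "closure": CLOSURE_FEATURES,
    "both": ALL_FEATURES,
}

_MODELS = {
    "tree": DecisionTreeClassifier,
    "forest": RandomForestClassifier,
    "boosted": GradientBoostingClassifier,
}


@dataclass(frozen=True)
class NetworkSignature:
    name: Optional[str]
    n_nodes: int
    n_edges: int
    avg_degree: float
    reciprocity: float
    avg_c_d: float
    avg_e_d: float
    c_head: float
    c_mid: float
    c_end: float
    c_cyc: float
    e_head: float
    e_mid: float
    e_end: float
    e_cyc: float
    class_label: Optional[str] = None


def signature(
    g: DirectedGraph, name: Optional[str] = None, label: Optional[str] = None
) -> NetworkSignature:
    """Summary statistics plus the eight averaged pattern features."""
    if g.n_nodes == 0:
        raise ValueError("signature of an empty graph")
    c_pat = {f: [] for f in CLUSTERING_FEATURES}
    e_pat = {f: [] for f in CLOSURE_FEATURES}
    c_d, e_d = [], []
    for i in g.nodes:
        c_d.append(local_directed_clustering(g, i))
        e_d.append(local_directed_closure(g, i))
        ch, cm, ce, cc = clustering_patterns(g, i)
        eh, em, ee, ec = closure_patterns(g, i)
        for f, v in zip(CLUSTERING_FEATURES, (ch, cm, ce, cc)):
            c_pat[f].append(v)
        for f, v in zip(CLOSURE_FEATURES, (eh, em, ee, ec)):
            e_pat[f].append(v)
    return NetworkSignature(
        name=name,
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        avg_degree=g.average_degree(),
        reciprocity=g.reciprocity() if g.n_edges else 0.0,
        avg_c_d=average_coefficient(c_d),
        avg_e_d=average_coefficient(e_d),
        **{f: average_coefficient(v) for f, v in c_pat.items()},
        **{f: average_coefficient(v) for f, v in e_pat.items()},
        class_label=label,
    )


def signatures_frame(sigs: Sequence[NetworkSignature]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in sigs])


def standardize(x: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Per-column zero mean and unit variance; constant columns map to 0."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("standardize needs a 2-D array with >= 2 rows")
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)
    const = std == 0.0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) mapped to 0")
        std = np.where(const, 1.0, std)
    return (arr - mean) / std


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("pearson undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def _features_labels(signatures: pd.DataFrame, feature_set) -> tuple[np.ndarray, np.ndarray]:
    features = _FEATURE_SETS.get(feature_set, feature_set)
    if isinstance(features, str) or not all(f in signatures.columns for f in features):
        raise ValueError(f"unknown feature set {feature_set!r}")
    X = signatures[list(features)].to_numpy(dtype=float)
    y = signatures["class_label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        few = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with a single member cannot be cross-validated: {few}")
    return X, y


def loocv_classify(
    signatures: pd.DataFrame,
    feature_set: str = "both",
    model: str = "tree",
    repeats: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Mean leave-one-out accuracy over ``repeats`` seeded model fits.

    Tree-based models are stochastic (tie-breaking, bootstrapping), so the
    LOOCV accuracy is itself averaged over repeated runs, each with its own
    derived random state.
    """
    X, y = _features_labels(signatures, feature_set)
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    ss = np.random.SeedSequence(seed)
    accs = []
    for child in ss.spawn(repeats):
        state = int(child.generate_state(1)[0] % (2**31))
        clf = _MODELS[model](random_state=state)
        correct = 0
        for train, test in LeaveOneOut().split(X):
            clf.fit(X[train], y[train])
            correct += int(clf.predict(X[test])[0] == y[test][0])
        accs.append(correct / len(y))
    return float(np.mean(accs))


def feature_importance(
    signatures: pd.DataFrame,
    feature_set: str = "both",
    model: str = "tree",
    repeats: int = 1000,
    seed: Optional[int] = None,
) -> pd.Series:
    """Average normalised impurity-decrease importance per feature.

    Scores are nonnegative and sum to one in every repeat; when a fit yields
    no splits at all (degenerate data) the importance is taken as uniform.
    """
    X, y = _features_labels(signatures, feature_set)
    features = _FEATURE_SETS.get(feature_set, list(feature_set))
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    ss = np.random.SeedSequence(seed)
    total = np.zeros(X.shape[1])
    for child in ss.spawn(repeats):
        state = int(child.generate_state(1)[0] % (2**31))
        clf = _MODELS[model](random_state=state).fit(X, y)
        imp = np.asarray(clf.feature_importances_, dtype=float)
        s = imp.sum()
        imp = imp / s if s > 0 else np.full_like(imp, 1.0 / len(imp))
        total += imp
    return pd.Series(total / repeats, index=list(features))
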