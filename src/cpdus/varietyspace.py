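"""Post-selection variety analyses.

Correlation structure and multicollinearity (Pearson |r| flags and variance
inflation factors) of a trait table, the confusion matrix of a classifier,
a t-SNE embedding with intra-/inter-cluster distance summaries, and
per-variety k-means grouping plus a Ward dendrogram exported as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import linkage
from skbio.tree import TreeNode
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix as _sk_confusion

from .schema import TRAIT_IDS, trait_def

__all__ = [
    "CorrelationReport",
    "VIFReport",
    "ConfusionReport",
    "EmbeddingSummary",
    "VarietyClustering",
    "pearson_report",
    "vif_report",
    "confusion",
    "tsne_summary",
    "variety_clustering",
]


def _numeric_trait_columns(table: pd.DataFrame) -> list[str]:
    """Continuous and ordinal trait columns present in the table.

    Tables whose columns are not schema traits (e.g. planted feature tables)
    fall back to every numeric non-identifier column.
    """
    cols = [
        c for c in table.columns
        if c in TRAIT_IDS and trait_def(c).scale in ("continuous", "ordinal")
    ]
    if cols:
        return cols
    return [
        c for c in table.select_dtypes("number").columns
        if c not in ("variety_id", "flower_id")
    ]


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    flagged: pd.DataFrame  # columns: trait_a, trait_b, r
    threshold: float

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def pearson_report(
    table: pd.DataFrame,
    threshold: float = 0.5,
    columns: list[str] | None = None,
) -> CorrelationReport:
    """Pairwise Pearson correlations with |r| >= ``threshold`` flagged.

    Constant columns correlate with nothing; their entries are set to 0
    (1 on the diagonal) with a warning.
    """
    cols = columns or _numeric_trait_columns(table)
    if len(cols) < 2:
        raise ValueError("need at least two numeric traits")
    if len(table) < 3:
        raise ValueError("need at least three samples")
    X = table[cols]
    constant = [c for c in cols if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns get r=0: {constant}", stacklevel=2)
    corr = X.corr().fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                pairs.append({"trait_a": a, "trait_b": b, "r": float(r)})
    return CorrelationReport(corr, pd.DataFrame(pairs, columns=["trait_a", "trait_b", "r"]), threshold)


@dataclass
class VIFReport:
    vif: pd.Series  # per trait, +inf for perfect collinearity
    flagged: list[str]
    threshold: float

    @property
    def max_vif(self) -> float:
        return float(self.vif.max())


def vif_report(
    table: pd.DataFrame,
    flag_threshold: float = 10.0,
    columns: list[str] | None = None,
) -> VIFReport:
    """Variance inflation factor per trait: 1 / (1 - R^2).

    R^2 comes from an OLS regression (with intercept) of each trait on all
    the others.  Perfectly collinear traits get a +inf sentinel.  Constant
    columns are excluded with a warning.
    """
    cols = columns or _numeric_trait_columns(table)
    cols = [c for c in cols if c in table.columns]
    keep = []
    for c in cols:
        if table[c].nunique() <= 1:
            warnings.warn(f"constant column {c} excluded from VIF", stacklevel=2)
        else:
            keep.append(c)
    if len(keep) < 2:
        raise ValueError("VIF needs at least two varying traits")
    if len(table) <= len(keep):
        raise ValueError("VIF needs more samples than traits")
    X = table[keep].to_numpy(dtype=float)
    out = {}
    for i, c in enumerate(keep):
        others = np.delete(X, i, axis=1)
        r2 = sm.OLS(X[:, i], sm.add_constant(others)).fit().rsquared
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif = pd.Series(out)
    return VIFReport(vif, list(vif.index[vif > flag_threshold]), flag_threshold)


@dataclass
class ConfusionReport:
    matrix: pd.DataFrame  # rows = truth, cols = prediction
    accuracy: float  # percent
    per_class_recall: pd.Series
    most_confused: pd.DataFrame  # off-diagonal cells sorted by count


def confusion(predictions, truth) -> ConfusionReport:
    """Confusion matrix with accuracy, per-class recall and top confusions."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    extra = set(predictions) - set(truth)
    if extra:
        raise ValueError(f"predicted labels never seen in truth: {sorted(extra)}")
    labels = np.unique(truth)
    m = _sk_confusion(truth, predictions, labels=labels)
    mat = pd.DataFrame(m, index=labels, columns=labels)
    acc = 100.0 * np.trace(m) / m.sum()
    recall = pd.Series(np.diag(m) / np.maximum(m.sum(axis=1), 1), index=labels)
    off = [
        {"truth": labels[i], "predicted": labels[j], "count": int(m[i, j])}
        for i in range(len(labels))
        for j in range(len(labels))
        if i != j and m[i, j] > 0
    ]
    off_frame = pd.DataFrame(off, columns=["truth", "predicted", "count"]).sort_values(
        "count", ascending=False, ignore_index=True
    )
    return ConfusionReport(mat, float(acc), recall, off_frame)


@dataclass
class EmbeddingSummary:
    embedding: pd.DataFrame  # columns: dim1, dim2, label
    intra_radius: pd.Series  # mean distance to own-class centroid
    inter_centroid: pd.DataFrame  # pairwise centroid distances
    overlap_pairs: list[tuple]
    method: str  # "tsne" or "pca"


def tsne_summary(
    table: pd.DataFrame,
    labels,
    seed: int = 0,
    perplexity: float = 30.0,
    columns: list[str] | None = None,
) -> EmbeddingSummary:
    """2-D t-SNE embedding plus cluster-distance summary statistics.

    The per-class intra radius is the mean distance of samples to their class
    centroid in the embedding; class pairs whose centroid distance is
    smaller than the sum of their intra radii are reported as overlapping.
    Below 50 samples t-SNE is unreliable and a PCA embedding is used
    instead, with a warning.
    """
    cols = columns or _numeric_trait_columns(table)
    X = table[cols].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    labels = np.asarray(labels)
    if len(X) < 50:
        warnings.warn("fewer than 50 samples: falling back to PCA", stacklevel=2)
        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
        method = "pca"
    else:
        perplexity = min(perplexity, (len(X) - 1) / 3.0)
        emb = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
        method = "tsne"
    frame = pd.DataFrame({"dim1": emb[:, 0], "dim2": emb[:, 1], "label": labels})
    classes = np.unique(labels)
    centroids = {c: emb[labels == c].mean(axis=0) for c in classes}
    intra = pd.Series(
        {c: float(np.linalg.norm(emb[labels == c] - centroids[c], axis=1).mean()) for c in classes}
    )
    inter = pd.DataFrame(
        [[float(np.linalg.norm(centroids[a] - centroids[b])) for b in classes] for a in classes],
        index=classes,
        columns=classes,
    )
    overlap = [
        (a, b)
        for i, a in enumerate(classes)
        for b in classes[i + 1 :]
        if inter.loc[a, b] < intra[a] + intra[b]
    ]
    return EmbeddingSummary(frame, intra, inter, overlap, method)


@dataclass
class VarietyClustering:
    means: pd.DataFrame  # per-variety encoded mean vectors
    assignments: pd.Series  # variety -> cluster id
    linkage_matrix: np.ndarray
    newick: str


def _encode_variety_means(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Per-variety means: z-scored numeric traits, one-hot-averaged nominals."""
    pieces = []
    for c in columns:
        scale = trait_def(c).scale if c in TRAIT_IDS else "continuous"
        if scale == "nominal":
            onehot = pd.get_dummies(table[c], prefix=c).astype(float)
            pieces.append(onehot)
        else:
            pieces.append(table[[c]].astype(float))
    enc = pd.concat(pieces, axis=1)
    enc["variety_id"] = table["variety_id"].values
    means = enc.groupby("variety_id").mean()
    std = means.std(ddof=0)
    return (means - means.mean()) / std.where(std > 0, 1.0)


def variety_clustering(
    table: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    columns: list[str] | None = None,
) -> VarietyClustering:
    """Group varieties by k-means on per-variety mean traits, plus a tree.

    K-means yields flat groups but no hierarchy, so the same variety means
    also feed Ward-linkage agglomerative clustering; the dendrogram is
    exported as a Newick string with branch lengths from the merge heights.
    """
    cols = columns or [c for c in table.columns if c in TRAIT_IDS]
    means = _encode_variety_means(table, cols)
    if k > len(means):
        raise ValueError(f"k={k} exceeds the {len(means)} varieties")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(means.to_numpy())
    assignments = pd.Series(km.labels_, index=means.index, name="cluster")
    Z = linkage(means.to_numpy(), method="ward", metric="euclidean")
    tree = TreeNode.from_linkage_matrix(Z, [str(v) for v in means.index])
    newick = str(tree).strip()
    return VarietyClustering(means, assignments, Z, newick)
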