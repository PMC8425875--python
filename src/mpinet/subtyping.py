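"""Two-step tumor subtyping machinery.

Pipeline: z-scored expression of core network proteins -> 2-component PCA ->
consensus clustering (PAM over subsamples) at K=2 -> orientation by marker
genes (the cluster with LOWER mean marker expression is C1) -> random-forest
gene ranking -> elastic-net classifiers (GL1 for C1/C2, GL2 for S1/S2 within
C1) -> optional TME-based sub-clustering of C1.

Raw PCA signs are arbitrary, so the PC1-PC2 discriminant is reported as a
consistency diagnostic, not used for label assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA projection
# --------------------------------------------------------------------------


@dataclass
class PCAProjection:
    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # genes x components
    explained_variance_ratio: np.ndarray

    def project(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Project a genes x samples matrix onto the stored loadings."""
        common = [g for g in self.loadings.index if g in matrix.index]
        sub = matrix.loc[common].to_numpy(dtype=float)
        load = self.loadings.loc[common].to_numpy(dtype=float)
        return pd.DataFrame(
            sub.T @ load, index=matrix.columns, columns=self.loadings.columns
        )


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> PCAProjection:
    """PCA of a z-scored genes x samples matrix; samples are observations.

    Components are ordered by explained variance. Sign convention: the
    largest-magnitude loading of each component is made positive so repeated
    runs agree; downstream labeling never depends on the raw sign.
    """
    if matrix.shape[0] < n_components:
        raise ValueError("need at least as many genes as components")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = matrix.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # genes x components
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAProjection(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


# --------------------------------------------------------------------------
# PAM (k-medoids) and consensus clustering
# --------------------------------------------------------------------------


def _pam(points: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 50):
    """Partitioning around medoids on Euclidean distance (alternating
    assignment / medoid update from a seeded random start)."""
    n = points.shape[0]
    if n < k:
        raise ValueError(f"cannot fit {k} medoids to {n} points")
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    medoids = np.sort(rng.choice(n, size=k, replace=False))
    labels = np.argmin(d[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_medoids = np.sort(new_medoids)
        new_labels = np.argmin(d[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


@dataclass
class ConsensusResult:
    labels: pd.Series                 # sample -> 1..K
    consensus_matrix: pd.DataFrame    # samples x samples in [0, 1]
    k: int
    max_k: int
    reps: int
    subsample_fraction: float
    seed: int


def consensus_cluster(
    points: pd.DataFrame,
    k: int = 2,
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    max_k: int = 10,
) -> ConsensusResult:
    """Consensus clustering: PAM over item subsamples, co-clustering frequency.

    *points* is samples x features (typically the first two PCs). For each of
    *reps* subsamples of *subsample_fraction* of the samples, PAM with K=*k*
    is run on Euclidean distance; the consensus matrix entry for a pair is
    the co-clustering frequency among subsamples containing both. Final
    labels come from average-linkage hierarchical clustering of
    1 - consensus cut at *k*.
    """
    x = points.to_numpy(dtype=float)
    n = x.shape[0]
    sub_n = max(int(round(subsample_fraction * n)), 1)
    if sub_n < k:
        raise ValueError("subsample smaller than the number of clusters")
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=sub_n, replace=False)
        labels = _pam(x[idx], k, rng)
        same = labels[:, None] == labels[None, :]
        together[np.ix_(idx, idx)] += same
        sampled[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 1..K by first appearance for determinism
    remap, next_label = {}, 1
    final = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = next_label
            next_label += 1
        final[i] = remap[lab]
    return ConsensusResult(
        labels=pd.Series(final, index=points.index, name="cluster"),
        consensus_matrix=pd.DataFrame(consensus, index=points.index, columns=points.index),
        k=k,
        max_k=max_k,
        reps=reps,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Subtype model
# --------------------------------------------------------------------------


@dataclass
class SubtypeModel:
    gene_list: list
    projection: PCAProjection
    consensus: ConsensusResult
    marker_genes: list
    labels: pd.Series                  # sample -> 'C1' / 'C2'
    discriminant: pd.Series            # PC1 - PC2 per sample
    discriminant_agreement: float      # fraction agreeing with labels


def fit_subtype_model(
    cohort,
    net,
    marker_genes: set,
    k: int = 2,
    reps: int = 250,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    core_min_degree: int = 4,
) -> SubtypeModel:
    """Fit the two-subtype model on a z-scored cohort and a filtered network.

    Core proteins (degree > *core_min_degree*) present in the cohort form the
    feature set; their expression is reduced to two PCs and consensus-
    clustered. The cluster with the lower mean expression of *marker_genes*
    becomes C1 (poor prognosis, metabolically down-regulated).
    """
    from mpinet.network import core_mipros

    core = [g for g in core_mipros(net, core_min_degree) if g in cohort.expression.index]
    if len(core) < 2:
        raise ValueError("fewer than 2 core proteins overlap the cohort")
    markers = sorted(m for m in marker_genes if m in cohort.expression.index)
    if not markers:
        raise ValueError("no marker genes present in the cohort")
    sub = cohort.expression.loc[core]
    proj = pca_project(sub, n_components=2)
    cons = consensus_cluster(
        proj.scores, k=k, reps=reps, subsample_fraction=subsample_fraction, seed=seed
    )
    marker_expr = cohort.expression.loc[markers]
    means = {
        c: float(marker_expr.loc[:, cons.labels[cons.labels == c].index].to_numpy().mean())
        for c in sorted(cons.labels.unique())
    }
    c1_cluster = min(means, key=lambda c: (means[c], c))
    labels = cons.labels.map(lambda c: "C1" if c == c1_cluster else "C2")
    disc = proj.scores["PC1"] - proj.scores["PC2"]
    agree = float(np.mean((disc < 0) == (labels == "C1")))
    agreement = max(agree, 1.0 - agree)  # raw PC signs are arbitrary
    return SubtypeModel(
        gene_list=core,
        projection=proj,
        consensus=cons,
        marker_genes=markers,
        labels=labels.rename("subtype"),
        discriminant=disc.rename("discriminant"),
        discriminant_agreement=agreement,
    )


# --------------------------------------------------------------------------
# RF gene ranking and elastic-net classifiers
# --------------------------------------------------------------------------


def rf_gene_importance(
    matrix: pd.DataFrame,
    labels,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank genes by random-forest impurity-decrease importance."""
    labels = pd.Series(labels).reindex(matrix.columns)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("labels must contain at least 2 classes")
    x = matrix.to_numpy(dtype=float).T
    y = labels.to_numpy()
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(x, y)
    df = pd.DataFrame({"gene": matrix.index, "importance": rf.feature_importances_})
    return df.sort_values(
        ["importance", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def top_genes(importance_table: pd.DataFrame, k: int = 30) -> list:
    return importance_table["gene"].head(k).tolist()


@dataclass
class ClassifierModel:
    """Elastic-net logistic classifier over a fixed ordered gene list.

    Prediction z-scores the target cohort's rows for the listed genes using
    the stored recipe ('per_cohort': standardize within the target cohort).
    """

    genes: list
    coefficients: np.ndarray
    intercept: float
    classes: list                      # [negative_class, positive_class]
    l1_ratio: float
    c: float
    normalization: str = "per_cohort"  # or "stored": use training mean/sd
    threshold: float = 0.5
    version: int = 1
    train_mean: np.ndarray | None = None
    train_sd: np.ndarray | None = None

    def _prepare(self, matrix: pd.DataFrame) -> np.ndarray:
        present = [g for g in self.genes if g in matrix.index]
        if not present:
            raise ValueError("no classifier genes overlap the target matrix")
        x = np.zeros((matrix.shape[1], len(self.genes)))
        for j, g in enumerate(self.genes):
            if g not in matrix.index:
                continue
            v = matrix.loc[g].to_numpy(dtype=float)
            if self.normalization == "per_cohort":
                sd = v.std(ddof=1)
                v = (v - v.mean()) / sd if sd > 0 else v * 0.0
            elif self.normalization == "stored":
                v = (v - self.train_mean[j]) / self.train_sd[j]
            x[:, j] = v
        return x

    def predict_proba(self, matrix: pd.DataFrame) -> pd.Series:
        x = self._prepare(matrix)
        z = x @ self.coefficients + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=matrix.columns, name="probability")

    def predict(self, matrix: pd.DataFrame) -> pd.Series:
        proba = self.predict_proba(matrix)
        return proba.map(lambda p: self.classes[1] if p > self.threshold else self.classes[0])

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "train_mean": [float(v) for v in self.train_mean]
            if self.train_mean is not None else None,
            "train_sd": [float(v) for v in self.train_sd]
            if self.train_sd is not None else None,
            "genes": list(self.genes),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "classes": list(self.classes),
            "l1_ratio": self.l1_ratio,
            "c": self.c,
            "normalization": self.normalization,
            "threshold": self.threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=payload["genes"],
            coefficients=np.array(payload["coefficients"], dtype=float),
            intercept=payload["intercept"],
            classes=payload["classes"],
            l1_ratio=payload["l1_ratio"],
            c=payload["c"],
            normalization=payload["normalization"],
            threshold=payload["threshold"],
            version=payload["version"],
            train_mean=np.array(payload["train_mean"], dtype=float)
            if payload.get("train_mean") is not None else None,
            train_sd=np.array(payload["train_sd"], dtype=float)
            if payload.get("train_sd") is not None else None,
        )


def train_classifier(
    matrix: pd.DataFrame,
    labels,
    l1_ratio: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    c_grid=(0.01, 0.1, 1.0, 10.0),
    normalization: str = "per_cohort",
) -> ClassifierModel:
    """Elastic-net-penalized logistic model on a gene-restricted matrix.

    Penalty strength is picked by seeded stratified cross-validation over
    *c_grid*; the winning C is refit on all samples. Features are z-scored
    within the training cohort and the recipe is stored for transfer.
    """
    labels = pd.Series(labels).reindex(matrix.columns)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("train_classifier expects exactly 2 classes")
    counts = labels.value_counts()
    if counts.min() < 20:
        raise ValueError("need at least 20 samples per class")
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = ((values - mu) / sd).T
    y = (labels == classes[1]).astype(int).to_numpy()
    folds = min(cv_folds, int(counts.min()))
    best_c, best_score = None, -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for c in c_grid:
        clf = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=c, max_iter=5000)
        score = cross_val_score(clf, x, y, cv=skf, scoring="accuracy").mean()
        if score > best_score + 1e-12:
            best_c, best_score = c, score
    clf = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=best_c, max_iter=5000)
    clf.fit(x, y)
    return ClassifierModel(
        genes=list(matrix.index),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        classes=classes,
        l1_ratio=l1_ratio,
        c=float(best_c),
        normalization=normalization,
        train_mean=mu.ravel().copy(),
        train_sd=sd.ravel().copy(),
    )


def two_step_predict(
    gl1: ClassifierModel,
    gl2: ClassifierModel,
    matrix: pd.DataFrame,
) -> pd.Series:
    """GL1 splits C1/C2; GL2 refines predicted-C1 samples into S1/S2."""
    first = gl1.predict(matrix)
    c1_samples = first.index[first == "C1"]
    out = first.copy()
    if len(c1_samples) == 0:
        logger.warning("no samples predicted C1; returning C2-only labeling")
        return out.rename("subtype")
    second = gl2.predict(matrix[list(c1_samples)])
    out.loc[c1_samples] = second
    return out.rename("subtype")


# --------------------------------------------------------------------------
# TME sub-clustering
# --------------------------------------------------------------------------


def sub_cluster_tme(
    tme_matrix: pd.DataFrame,
    c1_samples: set,
    k: int = 2,
    survival: pd.DataFrame | None = None,
    reps: int = 250,
    seed: int = 0,
) -> pd.Series:
    """Split C1 samples into S1/S2 from z-scored TME cell-type profiles.

    When *survival* (columns time, event, indexed by sample) is supplied, S1
    is the cluster with the higher event hazard (worse prognosis, ranked by
    the sign of a univariate Cox fit); otherwise the larger cluster is S1.
    """
    from mpinet.stats import zscore_normalize

    samples = [s for s in tme_matrix.columns if s in c1_samples]
    if len(samples) < 10:
        raise ValueError("need at least 10 C1 samples for sub-clustering")
    sub = tme_matrix[samples]
    sub = sub.loc[sub.std(axis=1, ddof=1) > 0]
    z = zscore_normalize(sub)
    cons = consensus_cluster(z.T, k=k, reps=reps, seed=seed)
    labels = cons.labels
    order = _order_clusters_by_hazard(labels, survival)
    mapping = {c: f"S{i + 1}" for i, c in enumerate(order)}
    return labels.map(mapping).rename("subtype")


def _order_clusters_by_hazard(labels: pd.Series, survival: pd.DataFrame | None) -> list:
    clusters = sorted(labels.unique())
    if survival is None:
        sizes = labels.value_counts()
        return sorted(clusters, key=lambda c: (-sizes[c], c))
    common = [s for s in labels.index if s in survival.index]
    df = pd.DataFrame(
        {
            "time": survival.loc[common, "time"].astype(float),
            "event": survival.loc[common, "event"].astype(int),
        }
    )
    from lifelines import CoxPHFitter

    hazards = {}
    for c in clusters:
        df["x"] = (labels.loc[common] == c).astype(int).to_numpy()
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            hazards[c] = float(cph.params_["x"])
        except Exception:  # degenerate survival: fall back to size ordering
            hazards[c] = 0.0
    return sorted(clusters, key=lambda c: (-hazards[c], c))
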