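"""Bipartite metabolite-protein link prediction from network topology.

Six association features are computed on the undirected bipartite view of
the network, always with the candidate edge excluded (leakage control):

  f1  preferential attachment: deg(m) * deg(p)
  f2  number of length-3 paths m-p'-m'-p
  f3  Jaccard of N(m) with the union of protein neighborhoods of N(p)
  f4  Jaccard of N(p) with the union of metabolite neighborhoods of N(m)
  f5  inverse shortest-path length between m and p (0 if disconnected)
  f6  resource allocation over length-3 paths: sum of 1/(deg(p')*deg(m'))

A seeded random forest is trained on labeled pairs; ROC/AUROC come from
out-of-fold probabilities of a stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from mpinet.network import MPINetwork

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "preferential_attachment",
    "path3_count",
    "jaccard_met_side",
    "jaccard_prot_side",
    "inverse_shortest_path",
    "resource_allocation3",
)


def sample_negative_pairs(
    net: MPINetwork,
    n: int,
    seed: int = 0,
    exclude: set | None = None,
) -> list[tuple[str, str]]:
    """Uniform sample of metabolite-protein non-edges, without replacement."""
    exclude = exclude or set()
    mets = net.metabolites
    prots = net.proteins
    candidates = [
        (m, p)
        for m in mets
        for p in prots
        if not net.has_edge(m, p) and (m, p) not in exclude
    ]
    if n > len(candidates):
        raise ValueError(f"requested {n} negatives but only {len(candidates)} non-edges exist")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(idx)]


class _AdjacencyView:
    """Undirected neighbor lookup with one optional edge masked out."""

    def __init__(self, net: MPINetwork, masked: tuple[str, str] | None):
        self.net = net
        self.masked = masked

    def met_neighbors(self, m: str) -> set[str]:
        out = self.net.metabolite_partners(m)
        if self.masked and self.masked[0] == m:
            out.discard(self.masked[1])
        return out

    def prot_neighbors(self, p: str) -> set[str]:
        out = self.net.protein_partners(p)
        if self.masked and self.masked[1] == p:
            out.discard(self.masked[0])
        return out


def compute_pair_features(
    net: MPINetwork,
    metabolite_id: str,
    protein_id: str,
    exclude_candidate_edge: bool = True,
) -> dict:
    """Feature vector for one candidate pair; see module docstring for f1..f6."""
    if metabolite_id not in net._met_index:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    if protein_id not in net._prot_index:
        raise KeyError(f"unknown protein {protein_id!r}")
    masked = None
    if exclude_candidate_edge and net.has_edge(metabolite_id, protein_id):
        masked = (metabolite_id, protein_id)
    adj = _AdjacencyView(net, masked)

    nm = adj.met_neighbors(metabolite_id)     # proteins adjacent to m
    np_ = adj.prot_neighbors(protein_id)      # metabolites adjacent to p

    f1 = float(len(nm) * len(np_))

    # length-3 paths m - p' - m' - p and the resource-allocation variant
    f2 = 0.0
    f6 = 0.0
    for m_prime in np_:
        if m_prime == metabolite_id:
            continue
        shared = nm & adj.met_neighbors(m_prime)
        shared.discard(protein_id)
        f2 += len(shared)
        for p_prime in shared:
            deg_pp = len(adj.prot_neighbors(p_prime))
            deg_mp = len(adj.met_neighbors(m_prime))
            if deg_pp and deg_mp:
                f6 += 1.0 / (deg_pp * deg_mp)

    union_from_p = set()
    for m_prime in np_:
        union_from_p |= adj.met_neighbors(m_prime)
    f3 = _jaccard(nm, union_from_p)

    union_from_m = set()
    for p_prime in nm:
        union_from_m |= adj.prot_neighbors(p_prime)
    f4 = _jaccard(np_, union_from_m)

    f5 = _inverse_shortest_path(adj, metabolite_id, protein_id)

    return {
        "metabolite_id": metabolite_id,
        "protein_id": protein_id,
        FEATURE_NAMES[0]: f1,
        FEATURE_NAMES[1]: f2,
        FEATURE_NAMES[2]: f3,
        FEATURE_NAMES[3]: f4,
        FEATURE_NAMES[4]: f5,
        FEATURE_NAMES[5]: f6,
    }


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    union = len(a | b)
    return inter / union if union else 0.0


def _inverse_shortest_path(adj: _AdjacencyView, m: str, p: str) -> float:
    """BFS on the bipartite graph from m to p; 1/distance, 0 if unreachable."""
    frontier = {("m", m)}
    seen = {("m", m)}
    dist = 0
    while frontier:
        dist += 1
        nxt = set()
        for kind, node in frontier:
            if kind == "m":
                for q in adj.met_neighbors(node):
                    if q == p:
                        return 1.0 / dist
                    if ("p", q) not in seen:
                        seen.add(("p", q))
                        nxt.add(("p", q))
            else:
                for q in adj.prot_neighbors(node):
                    if ("m", q) not in seen:
                        seen.add(("m", q))
                        nxt.add(("m", q))
        frontier = nxt
    return 0.0


def feature_table(net: MPINetwork, pairs, exclude_candidate_edge: bool = True) -> pd.DataFrame:
    rows = [
        compute_pair_features(net, m, p, exclude_candidate_edge=exclude_candidate_edge)
        for m, p in pairs
    ]
    return pd.DataFrame(rows)


@dataclass
class LinkModel:
    forest: RandomForestClassifier
    feature_names: tuple
    seed: int
    cv_folds: int
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auroc: float
    oof_probabilities: pd.DataFrame   # pair, label, probability

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        return self.forest.predict_proba(x)[:, 1]


def train_link_model(
    positives: list,
    negatives: list,
    net: MPINetwork,
    n_trees: int = 500,
    cv_folds: int = 5,
    seed: int = 0,
) -> LinkModel:
    """Random forest on pair features with out-of-fold ROC/AUROC.

    Known positive edges are featurized with the candidate edge excluded so
    the label never leaks through the topology.
    """
    if len(positives) < 50 or len(negatives) < 50:
        raise ValueError("need at least 50 pairs per class")
    pos = feature_table(net, positives, exclude_candidate_edge=True)
    neg = feature_table(net, negatives, exclude_candidate_edge=True)
    features = pd.concat([pos, neg], ignore_index=True)
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    x = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    oof = np.full(len(y), np.nan)
    for attempt in range(3):
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed + attempt)
        try:
            for train_idx, test_idx in skf.split(x, y):
                if len(np.unique(y[train_idx])) < 2:
                    raise ValueError("single-class fold")
                rf = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed, n_jobs=1
                )
                rf.fit(x[train_idx], y[train_idx])
                oof[test_idx] = rf.predict_proba(x[test_idx])[:, 1]
            break
        except ValueError as exc:
            logger.warning("refolding after degenerate split (%s)", exc)
    else:
        raise ValueError("could not form non-degenerate stratified folds")
    auroc = float(roc_auc_score(y, oof))
    fpr, tpr, _ = roc_curve(y, oof)
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(x, y)
    oof_df = features[["metabolite_id", "protein_id"]].copy()
    oof_df["label"] = y
    oof_df["probability"] = oof
    return LinkModel(
        forest=final,
        feature_names=FEATURE_NAMES,
        seed=seed,
        cv_folds=cv_folds,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auroc=auroc,
        oof_probabilities=oof_df,
    )


def predict_high_confidence(
    model: LinkModel,
    candidates: list,
    net: MPINetwork,
    threshold: float = 0.9,
    allow_known_edges: bool = False,
) -> pd.DataFrame:
    """Score candidate pairs and keep those with probability strictly above
    *threshold*, sorted descending."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    pairs = list(candidates)
    if not allow_known_edges:
        pairs = [(m, p) for m, p in pairs if not net.has_edge(m, p)]
    if not pairs:
        return pd.DataFrame(columns=["metabolite_id", "protein_id", "probability"])
    features = feature_table(net, pairs, exclude_candidate_edge=True)
    features["probability"] = model.predict_proba(features)
    out = features[features["probability"] > threshold]
    return (
        out[["metabolite_id", "protein_id", "probability"]]
        .sort_values(
            ["probability", "metabolite_id", "protein_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        .reset_index(drop=True)
    )


def pathway_connection_map(
    predictions: pd.DataFrame,
    metabolite_sets,
    universe: set,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(protein, pathway) hypergeometric enrichment of predicted partners.

    Long-format table with columns protein_id, pathway, overlap, p,
    significant (p < alpha); proteins without predictions are absent.
    """
    from scipy import stats as sps

    rows = []
    for protein, grp in predictions.groupby("protein_id"):
        predicted = set(grp["metabolite_id"]) & universe
        if not predicted:
            continue
        for pid in metabolite_sets:
            members = metabolite_sets.members(pid) & universe
            if not members:
                continue
            overlap = len(predicted & members)
            p = float(
                sps.hypergeom.sf(overlap - 1, len(universe), len(members), len(predicted))
            )
            rows.append(
                {
                    "protein_id": protein,
                    "pathway": pid,
                    "overlap": overlap,
                    "p": min(p, 1.0),
                    "significant": p < alpha,
                }
            )
    df = pd.DataFrame(rows, columns=["protein_id", "pathway", "overlap", "p", "significant"])
    return df.sort_values(["protein_id", "pathway"], kind="mergesort").reset_index(drop=True)
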