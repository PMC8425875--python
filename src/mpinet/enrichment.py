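"""Ranked-list set enrichment (weighted KS running sum) and per-sample scoring.

The permutation null is built from set-size-matched random sets drawn from
the ranked universe (gene-set permutation); rankings produced from fold
changes or accumulation scores carry no sample-level phenotype to permute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 5


@dataclass
class RankedList:
    """Item ids with real scores, sorted descending; ties broken by id."""

    ids: list
    scores: np.ndarray

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list ids must be unique")

    @classmethod
    def from_scores(cls, score_map) -> "RankedList":
        if isinstance(score_map, pd.Series):
            score_map = score_map.to_dict()
        items = sorted(score_map.items(), key=lambda kv: (-kv[1], kv[0]))
        ids = [k for k, _ in items]
        if len(set(ids)) != len(ids):
            raise ValueError("ranked list ids must be unique")
        return cls(ids=ids, scores=np.array([v for _, v in items], dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


def gsea_es(
    ranked: RankedList,
    item_set: set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score: extremum of the weighted KS running sum.

    Hits increment by |score|^weight_exponent (normalized over hits); misses
    decrement by 1/(N - N_hits). ES is the running-sum value of largest
    absolute deviation from zero.
    """
    n = len(ranked)
    hit = np.fromiter((i in item_set for i in ranked.ids), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must intersect the ranking without covering it")
    weights = np.abs(ranked.scores) ** weight_exponent
    hit_weights = np.where(hit, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # all-zero hit scores: fall back to unweighted increments
        hit_weights = hit.astype(float)
        total = hit_weights.sum()
    increments = hit_weights / total - (~hit) / (n - n_hit)
    running = np.cumsum(increments)
    es = _signed_extremum(running)
    return es, running


def _signed_extremum(running: np.ndarray) -> float:
    """Max-|deviation| extremum; the positive side wins (near-)ties.

    The 1e-12 band keeps the sign choice stable under floating-point
    accumulation-order differences when |max| and |min| coincide.
    """
    rmax, rmin = float(running.max()), float(running.min())
    return rmax if rmax >= -rmin - 1e-12 else rmin


def _null_es(rng, ranked, set_size, n_permutations, weight_exponent):
    n = len(ranked)
    null = np.empty(n_permutations)
    idx = np.arange(n)
    weights = np.abs(ranked.scores) ** weight_exponent
    miss_step = None
    for i in range(n_permutations):
        pick = rng.choice(idx, size=set_size, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[pick] = True
        hw = np.where(hit, weights, 0.0)
        total = hw.sum()
        if total == 0:
            hw = hit.astype(float)
            total = hw.sum()
        inc = hw / total - (~hit) / (n - set_size)
        running = np.cumsum(inc)
        null[i] = _signed_extremum(running)
    return null


def gsea(
    ranked: RankedList,
    sets,
    n_permutations: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Set enrichment over a ranked list with a random-set permutation null.

    NES = ES / mean(|null ES| of the matching sign); p is the empirical
    fraction of same-sign null ES at least as extreme; FDR follows the
    canonical NES-based procedure pooled over all tested sets.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if n_permutations < 100:
        logger.warning("n_permutations=%d is low; p-values will be coarse", n_permutations)
    rng = np.random.default_rng(seed)
    universe = set(ranked.ids)
    records = []
    null_by_size: dict[int, np.ndarray] = {}
    for set_id in sets:
        members = sets.members(set_id) & universe
        if len(members) < min_set_size:
            logger.info("skipping set %s: only %d members in ranking", set_id, len(members))
            continue
        es, running = gsea_es(ranked, members, weight_exponent)
        size = len(members)
        if size not in null_by_size:
            null_by_size[size] = _null_es(rng, ranked, size, n_permutations, weight_exponent)
        null = null_by_size[size]
        same_sign = null[null * es > 0] if es != 0 else null
        if same_sign.size == 0:
            p = 1.0 / (n_permutations + 1)
            nes = 0.0
        else:
            p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
            nes = es / np.mean(np.abs(same_sign))
        leading = _leading_edge(ranked, members, running, es)
        records.append(
            {
                "set": set_id,
                "size": size,
                "ES": es,
                "NES": float(nes),
                "p": float(p),
                "leading_edge": ";".join(leading),
                "_null": null,
            }
        )
    df = pd.DataFrame.from_records(records)
    if len(df) == 0:
        return pd.DataFrame(columns=["set", "size", "ES", "NES", "p", "FDR", "leading_edge"])
    df["FDR"] = _nes_fdr(df)
    df = df.drop(columns=["_null"])
    return df[["set", "size", "ES", "NES", "p", "FDR", "leading_edge"]].sort_values(
        ["p", "set"], kind="mergesort"
    ).reset_index(drop=True)


def _leading_edge(ranked, members, running, es):
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        span = range(0, peak + 1)
    else:
        span = range(peak, len(ranked.ids))
    return [ranked.ids[i] for i in span if ranked.ids[i] in members]


def _nes_fdr(df: pd.DataFrame) -> np.ndarray:
    """NES-based FDR: null NES pooled over all sets' permutations."""
    null_nes = []
    for _, row in df.iterrows():
        null = row["_null"]
        pos = null[null > 0]
        neg = null[null < 0]
        pos_mean = pos.mean() if pos.size else np.nan
        neg_mean = np.abs(neg).mean() if neg.size else np.nan
        scaled = np.where(null > 0, null / pos_mean, null / neg_mean)
        null_nes.append(scaled[np.isfinite(scaled)])
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    obs = df["NES"].to_numpy()
    fdr = np.ones(len(df))
    for i, nes in enumerate(obs):
        if nes == 0 or null_nes.size == 0:
            fdr[i] = 1.0
            continue
        if nes > 0:
            frac_null = np.mean(null_nes >= nes) if (null_nes > 0).any() else 1.0
            frac_obs = np.mean(obs >= nes)
        else:
            frac_null = np.mean(null_nes <= nes) if (null_nes < 0).any() else 1.0
            frac_obs = np.mean(obs <= nes)
        fdr[i] = min(1.0, frac_null / max(frac_obs, 1e-12))
    return fdr


def build_immune_gene_list(
    cohort,
    labels,
    immune_pathways,
    fdr_threshold: float = 0.01,
    fold_change: float = 1.5,
    up_label="C1",
    down_label="C2",
) -> set:
    """Immune-pathway genes significantly up in *up_label* vs *down_label*.

    Selection: FDR < fdr_threshold and linear fold change > fold_change
    (i.e. log2FC > log2(fold_change)), intersected with the immune-pathway
    membership.
    """
    from mpinet.stats import ExpressionCohort, unpaired_differential

    clin = cohort.clinical.copy()
    labels = pd.Series(labels)
    clin["group"] = labels.reindex(clin.index) if len(clin) else labels
    if len(clin) == 0:
        clin = pd.DataFrame({"group": labels})
    tagged = ExpressionCohort(cohort.expression, clin)
    de = unpaired_differential(tagged, up_label, down_label)
    log2_cut = np.log2(fold_change)
    hits = set(de.index[(de["p_adjusted"] < fdr_threshold) & (de["log2FC"] > log2_cut)])
    immune = immune_pathways.all_members()
    result = hits & immune
    if not result:
        logger.warning("immune gene list is empty under the current thresholds")
    return result


def sample_set_score(
    matrix: pd.DataFrame,
    item_set: set,
    method: str = "ssgsea_like",
    rank_exponent: float = 0.25,
) -> pd.Series:
    """Per-sample rank-based enrichment score of *item_set* (ssGSEA-style).

    For each sample, genes are ranked by expression; the score is the sum of
    the running-sum differences between the weighted in-set rank ECDF and the
    out-of-set ECDF. Scores are min-max normalized by their range across
    samples (constant matrices yield identical scores of 0).
    """
    if method != "ssgsea_like":
        raise ValueError(f"unknown method {method!r}")
    genes = [g for g in matrix.index]
    in_set = np.fromiter((g in item_set for g in genes), dtype=bool, count=len(genes))
    if in_set.sum() < 3:
        raise ValueError("set must share at least 3 genes with the matrix")
    n = len(genes)
    n_out = n - int(in_set.sum())
    scores = {}
    values = matrix.to_numpy(dtype=float)
    for j, sample in enumerate(matrix.columns):
        col = values[:, j]
        # rank 1 = lowest expression; weight by rank^exponent for hits
        order = np.argsort(np.argsort(col, kind="mergesort"), kind="mergesort") + 1
        desc = np.argsort(-col, kind="mergesort")
        hit_sorted = in_set[desc]
        w = order[desc].astype(float) ** rank_exponent
        hit_w = np.where(hit_sorted, w, 0.0)
        total = hit_w.sum()
        ecdf_hit = np.cumsum(hit_w) / total
        ecdf_miss = np.cumsum(~hit_sorted) / n_out
        scores[sample] = float(np.sum(ecdf_hit - ecdf_miss))
    out = pd.Series(scores, name="score")
    rng_ = out.max() - out.min()
    if rng_ > 0:
        out = (out - out.min()) / rng_
    else:
        out = out * 0.0
    return out
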