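"""Seeded generators for every input the pipeline consumes.

Networks with heavy-tailed metabolite degrees (including hubs exceeding the
common-metabolite filter), cohorts with two planted expression subtypes and
subtype-dependent exponential survival, metabolite-accumulation scenarios
with planted producer/consumer fold changes, and planted-block instances for
link prediction. Every generator is a pure function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mpinet.network import MPIEdge, MPINetwork, PathwayCollection
from mpinet.stats import ExpressionCohort


@dataclass
class SynthConfig:
    seed: int = 0
    # network
    n_metabolites: int = 300
    n_proteins: int = 400
    mean_degree: float = 6.0
    hub_fraction: float = 0.01
    hub_min_degree: int = 201
    role_mix: tuple = (0.45, 0.45, 0.10)  # substrate, product, both
    # cohort
    n_samples: int = 200
    n_genes: int = 2000
    n_informative: int = 50
    effect_size: float = 1.0
    frac_down_in_c1: float = 0.8
    paired_normals: bool = False
    # survival
    baseline_hazard: float = 1.0 / 1000.0
    hazard_ratio: float = 3.0
    censoring_fraction: float = 0.3
    # accumulation
    accumulation_up: float = 1.0
    accumulation_down: float = 1.0
    accumulation_noise: float = 0.0
    # link prediction
    n_blocks: int = 4
    p_within: float = 0.30
    p_between: float = 0.01

    def __post_init__(self):
        for p in (self.hub_fraction, self.frac_down_in_c1, self.censoring_fraction,
                  self.p_within, self.p_between, *self.role_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if abs(sum(self.role_mix) - 1.0) > 1e-9:
            raise ValueError("role_mix must sum to 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _met_ids(n):
    return [f"M{i:05d}" for i in range(1, n + 1)]


def _prot_ids(n):
    return [f"P{i:05d}" for i in range(1, n + 1)]


def gen_mpi_network(cfg: SynthConfig) -> tuple[MPINetwork, dict]:
    """Directed bipartite network with heavy-tailed metabolite degrees.

    A ``hub_fraction`` of metabolites receive degree >= ``hub_min_degree``
    (to exercise the common-metabolite filter); the rest draw Zipf-like
    degrees with the configured mean. Returns (network, truth) where truth
    records hub ids and per-edge roles.
    """
    if cfg.n_metabolites < 1 or cfg.n_proteins < 1:
        raise ValueError("network sizes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    mets = _met_ids(cfg.n_metabolites)
    prots = _prot_ids(cfg.n_proteins)
    n_hubs = int(round(cfg.hub_fraction * cfg.n_metabolites))
    if n_hubs and cfg.hub_min_degree > cfg.n_proteins:
        raise ValueError(
            f"hub_min_degree={cfg.hub_min_degree} exceeds n_proteins={cfg.n_proteins}"
        )
    hubs = set(rng.choice(cfg.n_metabolites, size=n_hubs, replace=False).tolist())
    # heavy tail: geometric-ish degrees, clipped to the protein count
    degrees = np.minimum(
        rng.geometric(p=min(1.0, 1.0 / cfg.mean_degree), size=cfg.n_metabolites),
        cfg.n_proteins,
    )
    roles = np.array(["substrate", "product", "both"])
    edges = []
    for i, met in enumerate(mets):
        if i in hubs:
            deg = int(rng.integers(cfg.hub_min_degree, cfg.n_proteins + 1))
        else:
            deg = int(degrees[i])
        partners = rng.choice(cfg.n_proteins, size=deg, replace=False)
        edge_roles = rng.choice(roles, size=deg, p=list(cfg.role_mix))
        for j, r in zip(partners, edge_roles):
            edges.append(MPIEdge(met, prots[j], str(r), frozenset({"synthetic"})))
    net = MPINetwork(edges, metabolites=mets, proteins=prots)
    truth = {"hubs": sorted(mets[i] for i in hubs)}
    return net, truth


def _solve_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(C < T) = target, where
    T ~ Exp(h_i) and P(censored | h) = c / (c + h)."""
    if target <= 0:
        return 0.0

    def frac(c):
        return float(np.mean(c / (c + hazards))) - target

    lo, hi = 1e-12, 1e6 * hazards.max()
    return brentq(frac, lo, hi)


def gen_cohort(
    cfg: SynthConfig, net: MPINetwork | None = None, sample_seed: int | None = None
) -> tuple[ExpressionCohort, pd.Series, dict]:
    """Cohort with two planted subtypes and subtype-dependent survival.

    Gene universe: core-protein ids from *net* first (so informative genes
    are subtype signal carried by network proteins), padded with filler
    genes to ``n_genes``. Informative genes shift by ±``effect_size`` in C1
    (a ``frac_down_in_c1`` share shifted down). Survival is exponential with
    hazard multiplied by ``hazard_ratio`` for C1 and exponential censoring
    calibrated to ``censoring_fraction``.

    ``sample_seed`` redraws the sample-level randomness (expression noise,
    subtype assignment, survival) while keeping the planted gene layout of
    ``cfg.seed`` — i.e. an independent cohort from the same generative
    process. Returns (cohort, truth labels, truth dict with marker genes).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    rng_samples = (
        rng if sample_seed is None else np.random.default_rng(sample_seed + 1_000_003)
    )
    if net is not None:
        from mpinet.network import core_mipros

        base_genes = core_mipros(net)
        if len(base_genes) < cfg.n_informative:
            base_genes = net.proteins
    else:
        base_genes = []
    if cfg.n_informative > cfg.n_genes:
        raise ValueError("n_informative exceeds n_genes")
    genes = list(base_genes)[: cfg.n_genes]
    fill = cfg.n_genes - len(genes)
    genes += [f"G{i:05d}" for i in range(1, fill + 1)]
    # plant the signal inside the network's core proteins when a net is given
    pool = len(base_genes[: cfg.n_genes]) if base_genes else len(genes)
    if pool < cfg.n_informative:
        pool = len(genes)
    informative = sorted(
        rng.choice(pool, size=cfg.n_informative, replace=False).tolist()
    ) if cfg.n_informative else []
    n_down = int(round(cfg.frac_down_in_c1 * len(informative)))
    down_idx = set(informative[:n_down])
    up_idx = set(informative[n_down:])

    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    is_c1 = rng_samples.random(cfg.n_samples) < 0.5
    x = rng_samples.standard_normal((cfg.n_genes, cfg.n_samples))
    for gi in down_idx:
        x[gi, is_c1] -= cfg.effect_size
    for gi in up_idx:
        x[gi, is_c1] += cfg.effect_size

    hazards = np.where(is_c1, cfg.baseline_hazard * cfg.hazard_ratio, cfg.baseline_hazard)
    event_times = rng_samples.exponential(1.0 / hazards)
    c_rate = _solve_censor_rate(hazards, cfg.censoring_fraction)
    if c_rate > 0:
        censor_times = rng_samples.exponential(1.0 / c_rate, size=cfg.n_samples)
    else:
        censor_times = np.full(cfg.n_samples, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    clinical = pd.DataFrame(
        {
            "time": np.maximum(observed, 1e-6),
            "event": event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    expr = pd.DataFrame(x, index=genes, columns=samples)

    if cfg.paired_normals:
        normals = [f"N{i:04d}" for i in range(1, cfg.n_samples + 1)]
        xn = rng_samples.standard_normal((cfg.n_genes, cfg.n_samples))
        expr_n = pd.DataFrame(xn, index=genes, columns=normals)
        expr = pd.concat([expr, expr_n], axis=1)
        clinical = pd.concat(
            [
                clinical.assign(group="tumor", pair_id=samples),
                pd.DataFrame(
                    {"time": np.nan, "event": 0, "group": "normal", "pair_id": samples},
                    index=pd.Index(normals, name="sample_id"),
                ),
            ]
        )
    truth_labels = pd.Series(
        np.where(is_c1, "C1", "C2"), index=samples, name="true_subtype"
    )
    truth = {
        "informative_genes": [genes[i] for i in informative],
        "marker_genes": [genes[i] for i in sorted(down_idx)],
        "up_in_c1_genes": [genes[i] for i in sorted(up_idx)],
    }
    return ExpressionCohort(expr, clinical), truth_labels, truth


def gen_accumulation_scenario(
    cfg: SynthConfig, net: MPINetwork, target_metabolite: str | None = None
) -> tuple[dict, pd.DataFrame, str]:
    """Plant a producer-up / consumer-down fold-change pattern for one metabolite.

    The target's pure producers get +accumulation_up, pure consumers get
    -accumulation_down (reversible partners are left at noise level: their
    contributions cancel by construction); all other proteins draw
    Normal(0, accumulation_noise). Ground truth for the target is
    a*|pure UpPs| + b*|pure DownPs| exactly.

    Returns (log2fc mapping, ground-truth table, target id).
    """
    from mpinet.network import metabolite_neighborhood
    from mpinet.deltam import delta_m

    rng = np.random.default_rng(cfg.seed + 2)
    if target_metabolite is None:
        # pick the best-evidenced metabolite: most directed (non-reversible)
        # partners, requiring at least one pure producer and one pure consumer
        best, best_key = None, (-1, -1)
        for met in net.metabolites:
            up, down = metabolite_neighborhood(net, met)
            pure_up, pure_down = up - down, down - up
            key = (min(len(pure_up), len(pure_down)), len(pure_up) + len(pure_down))
            if pure_up and pure_down and key > best_key:
                best, best_key = met, key
        if best is None:
            raise ValueError("no metabolite with both a pure producer and a pure consumer")
        target_metabolite = best
    up, down = metabolite_neighborhood(net, target_metabolite)
    pure_up = up - down
    pure_down = down - up
    if not pure_up or not pure_down:
        raise ValueError(f"target {target_metabolite!r} lacks directed partners")
    log2fc = {
        p: float(rng.normal(0.0, cfg.accumulation_noise)) if cfg.accumulation_noise > 0 else 0.0
        for p in net.proteins
    }
    for p in pure_up:
        log2fc[p] = cfg.accumulation_up
    for p in pure_down:
        log2fc[p] = -cfg.accumulation_down
    truth = delta_m(net, log2fc)
    return log2fc, truth, target_metabolite


def gen_link_instance(
    cfg: SynthConfig,
) -> tuple[MPINetwork, list, list, dict]:
    """Planted-block bipartite instance for link prediction.

    Metabolites and proteins are split into ``n_blocks`` blocks; same-block
    pairs connect with ``p_within``, cross-block with ``p_between``. A share
    of the within-block edges is held out: those pairs are the positive-like
    candidates; an equal number of cross-block non-edges form the negative
    candidates. Returns (network, positives, candidates, truth).
    """
    if cfg.n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if cfg.p_between >= cfg.p_within:
        raise ValueError("p_between must be below p_within for a planted structure")
    rng = np.random.default_rng(cfg.seed + 3)
    mets = _met_ids(cfg.n_metabolites)
    prots = _prot_ids(cfg.n_proteins)
    met_block = rng.integers(cfg.n_blocks, size=cfg.n_metabolites)
    prot_block = rng.integers(cfg.n_blocks, size=cfg.n_proteins)
    # heterogeneous node activity -> heavy-ish degree tail, so degree-based
    # features carry signal as they do on curated networks
    met_act = rng.lognormal(mean=-0.18, sigma=0.6, size=cfg.n_metabolites)
    prot_act = rng.lognormal(mean=-0.18, sigma=0.6, size=cfg.n_proteins)
    roles = np.array(["substrate", "product", "both"])
    edges = []
    held_out = []
    negatives_pool = []
    for i, met in enumerate(mets):
        for j, prot in enumerate(prots):
            same = met_block[i] == prot_block[j]
            base = cfg.p_within if same else cfg.p_between
            p_edge = min(1.0, base * met_act[i] * prot_act[j])
            if rng.random() < p_edge:
                if same and rng.random() < 0.2:
                    held_out.append((met, prot))
                else:
                    role = str(rng.choice(roles, p=list(cfg.role_mix)))
                    edges.append(MPIEdge(met, prot, role, frozenset({"synthetic"})))
            elif not same:
                negatives_pool.append((met, prot))
    net = MPINetwork(edges, metabolites=mets, proteins=prots)
    positives = [(e.metabolite_id, e.protein_id) for e in net.edges]
    n_cand = min(len(held_out), len(negatives_pool))
    neg_idx = rng.choice(len(negatives_pool), size=n_cand, replace=False)
    neg_candidates = [negatives_pool[i] for i in sorted(neg_idx)]
    candidates = held_out[:n_cand] + neg_candidates
    truth = {
        "positive_candidates": held_out[:n_cand],
        "negative_candidates": neg_candidates,
        "met_block": {m: int(b) for m, b in zip(mets, met_block)},
        "prot_block": {p: int(b) for p, b in zip(prots, prot_block)},
    }
    return net, positives, candidates, truth


def gen_pathway_sets(
    ids: list,
    n_sets: int = 10,
    set_size: int = 15,
    seed: int = 0,
    prefix: str = "SET",
) -> PathwayCollection:
    """Random disjoint-ish member sets over *ids* (for enrichment tests)."""
    rng = np.random.default_rng(seed)
    coll = PathwayCollection()
    ids = list(ids)
    for i in range(1, n_sets + 1):
        members = rng.choice(len(ids), size=min(set_size, len(ids)), replace=False)
        coll.add(f"{prefix}{i:03d}", {ids[j] for j in members}, category="synthetic")
    return coll


def gen_tme_matrix(
    samples: list,
    labels: pd.Series | None = None,
    n_cell_types: int = 12,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Cell-type x sample enrichment matrix with an optional planted 2-block
    structure over *labels* (values 'S1'/'S2')."""
    rng = np.random.default_rng(seed)
    cells = [f"CT{i:02d}" for i in range(1, n_cell_types + 1)]
    x = rng.standard_normal((n_cell_types, len(samples)))
    if labels is not None:
        mask = np.array([labels.get(s) == "S1" for s in samples])
        x[: n_cell_types // 2, mask] += effect_size
    return pd.DataFrame(x, index=cells, columns=samples), labels
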