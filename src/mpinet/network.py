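"""Directed bipartite metabolite-protein network: model, I/O, and filters.

The network stores at most one edge per (metabolite, protein) pair. Edge
``role`` records whether the metabolite is a ``substrate`` (consumed by the
protein), a ``product`` (produced by it), or ``both`` (reversible). Degree is
the number of distinct partners.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

VALID_ROLES = ("substrate", "product", "both")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class MPIEdge:
    """A single metabolite-protein interaction.

    role='substrate' means the metabolite is consumed by the protein
    (edge leaves the metabolite); 'product' means the protein produces it
    (edge points to the metabolite); 'both' means reversible.
    """

    metabolite_id: str
    protein_id: str
    role: str
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"invalid role {self.role!r}; expected one of {VALID_ROLES}")
        if not self.sources:
            raise ValueError("edge must carry at least one source tag")


class MPINetwork:
    """Directed bipartite graph of metabolites and proteins.

    Maintains per-node edge indices; bipartiteness is structural (edges are
    always metabolite-protein pairs).
    """

    def __init__(
        self,
        edges: Iterable[MPIEdge] = (),
        metabolites: Iterable[str] = (),
        proteins: Iterable[str] = (),
    ):
        self._edges: dict[tuple[str, str], MPIEdge] = {}
        self._met_index: dict[str, set[str]] = {m: set() for m in metabolites}
        self._prot_index: dict[str, set[str]] = {p: set() for p in proteins}
        for e in edges:
            self._add(e)

    def _add(self, edge: MPIEdge) -> None:
        key = (edge.metabolite_id, edge.protein_id)
        if key in self._edges:
            raise ValueError(f"duplicate edge for pair {key}; integrate first")
        self._edges[key] = edge
        self._met_index.setdefault(edge.metabolite_id, set()).add(edge.protein_id)
        self._prot_index.setdefault(edge.protein_id, set()).add(edge.metabolite_id)

    # ------------------------------------------------------------------ views
    @property
    def edges(self) -> list[MPIEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    @property
    def metabolites(self) -> list[str]:
        return sorted(self._met_index)

    @property
    def proteins(self) -> list[str]:
        return sorted(self._prot_index)

    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, metabolite_id: str, protein_id: str) -> bool:
        return (metabolite_id, protein_id) in self._edges

    def get_edge(self, metabolite_id: str, protein_id: str) -> MPIEdge:
        return self._edges[(metabolite_id, protein_id)]

    def metabolite_degree(self, metabolite_id: str) -> int:
        return len(self._met_index.get(metabolite_id, ()))

    def protein_degree(self, protein_id: str) -> int:
        return len(self._prot_index.get(protein_id, ()))

    def metabolite_partners(self, metabolite_id: str) -> set[str]:
        return set(self._met_index.get(metabolite_id, ()))

    def protein_partners(self, protein_id: str) -> set[str]:
        return set(self._prot_index.get(protein_id, ()))

    # ------------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["metabolite_id", "protein_id", "role", "source"])
            for e in self.edges:
                w.writerow([e.metabolite_id, e.protein_id, e.role, ";".join(sorted(e.sources))])

    @classmethod
    def from_tsv(cls, path) -> "MPINetwork":
        edges = []
        for row in _iter_mpi_rows(path):
            line_no, met, prot, role, source = row
            sources = frozenset(source.split(";")) if source else frozenset({"unknown"})
            edges.append(MPIEdge(met, prot, role, sources))
        return cls(edges)


def _iter_mpi_rows(path):
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = {name: i for i, name in enumerate(header)}
        required = ("metabolite_id", "protein_id", "role")
        missing = [c for c in required if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        src_col = cols.get("source")
        bad_lines = []
        rows = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                met = row[cols["metabolite_id"]].strip()
                prot = row[cols["protein_id"]].strip()
                role = row[cols["role"]].strip()
            except IndexError:
                bad_lines.append((line_no, "too few fields"))
                continue
            if role not in VALID_ROLES:
                bad_lines.append((line_no, f"unknown role {role!r}"))
                continue
            if not met or not prot:
                bad_lines.append((line_no, "empty identifier"))
                continue
            source = row[src_col].strip() if src_col is not None and src_col < len(row) else ""
            rows.append((line_no, met, prot, role, source))
        if bad_lines:
            detail = "; ".join(f"line {n}: {msg}" for n, msg in bad_lines)
            raise FormatError(f"{path}: malformed rows — {detail}")
    return rows


def read_mpi_edges(path, source_tag: str) -> list[MPIEdge]:
    """Read one source's edge list from TSV, tagging every edge with *source_tag*.

    The TSV must carry header columns metabolite_id, protein_id, role with
    role in {substrate, product, both}. Malformed rows raise
    :class:`FormatError` listing the offending line numbers.
    """
    return [
        MPIEdge(met, prot, role, frozenset({source_tag}))
        for _, met, prot, role, _ in _iter_mpi_rows(path)
    ]


def _merge_roles(roles: set[str]) -> str:
    if "both" in roles or len(roles) > 1:
        return "both"
    return next(iter(roles))


def integrate_networks(edge_lists: Sequence[Iterable[MPIEdge]]) -> MPINetwork:
    """Union edge lists into one network, deduplicating on (metabolite, protein).

    Sources are unioned. Roles merge to 'both' whenever a pair is seen as
    substrate in one source and product in another, or as 'both' anywhere.
    """
    roles: dict[tuple[str, str], set[str]] = {}
    sources: dict[tuple[str, str], set[str]] = {}
    for edge_list in edge_lists:
        for e in edge_list:
            key = (e.metabolite_id, e.protein_id)
            roles.setdefault(key, set()).add(e.role)
            sources.setdefault(key, set()).update(e.sources)
    edges = [
        MPIEdge(met, prot, _merge_roles(roles[(met, prot)]), frozenset(sources[(met, prot)]))
        for met, prot in sorted(roles)
    ]
    return MPINetwork(edges)


def remove_common_metabolites(net: MPINetwork, max_degree: int = 200) -> MPINetwork:
    """Drop metabolites whose degree strictly exceeds *max_degree*.

    The default of 200 removes currency metabolites (water, ATP, ...) that
    connect to a large share of the proteome and would otherwise dominate
    every neighborhood.
    """
    if max_degree < 0:
        raise ValueError(f"max_degree must be >= 0, got {max_degree}")
    keep = {m for m in net.metabolites if net.metabolite_degree(m) <= max_degree}
    return MPINetwork(
        (e for e in net.edges if e.metabolite_id in keep),
        metabolites=sorted(keep),
        proteins=net.proteins,  # may leave isolated proteins; see prune
    )


def prune_isolated_proteins(net: MPINetwork) -> MPINetwork:
    """Remove degree-0 proteins from the protein index.

    Because the edge-list representation only indexes nodes with incident
    edges, rebuilding from the surviving edges is sufficient.
    """
    return MPINetwork(net.edges)


def core_mipros(net: MPINetwork, min_degree_exclusive: int = 4) -> list[str]:
    """Proteins with degree strictly greater than *min_degree_exclusive*, sorted."""
    return sorted(p for p in net.proteins if net.protein_degree(p) > min_degree_exclusive)


def metabolite_neighborhood(net: MPINetwork, metabolite_id: str) -> tuple[set[str], set[str]]:
    """Split a metabolite's partners into producers (UpPs) and consumers (DownPs).

    UpPs are proteins whose edge points to the metabolite (role=product);
    DownPs are proteins whose edge leaves it (role=substrate). Reversible
    partners (role=both) appear in both sets.
    """
    if metabolite_id not in net._met_index:
        raise KeyError(f"metabolite {metabolite_id!r} not in network")
    up, down = set(), set()
    for prot in net.metabolite_partners(metabolite_id):
        role = net.get_edge(metabolite_id, prot).role
        if role in ("product", "both"):
            up.add(prot)
        if role in ("substrate", "both"):
            down.add(prot)
    return up, down


# --------------------------------------------------------------------------
# Pathway collections (GMT)
# --------------------------------------------------------------------------


class PathwayCollection:
    """Mapping pathway_id -> {name, category, members}; GMT round-trippable."""

    def __init__(self, pathways: Mapping[str, Mapping] | None = None):
        self._pathways: dict[str, dict] = {}
        if pathways:
            for pid, rec in pathways.items():
                self.add(pid, set(rec["members"]), rec.get("name", pid), rec.get("category", ""))

    def add(self, pathway_id: str, members: set[str], name: str | None = None,
            category: str = "") -> None:
        if not members:
            raise ValueError(f"pathway {pathway_id!r} has no members")
        self._pathways[pathway_id] = {
            "name": name or pathway_id,
            "category": category,
            "members": set(members),
        }

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self):
        return iter(sorted(self._pathways))

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def members(self, pathway_id: str) -> set[str]:
        return set(self._pathways[pathway_id]["members"])

    def name(self, pathway_id: str) -> str:
        return self._pathways[pathway_id]["name"]

    def items(self):
        for pid in self:
            yield pid, self._pathways[pid]

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for pid in self._pathways:
            out |= self._pathways[pid]["members"]
        return out

    @classmethod
    def from_gmt(cls, path) -> "PathwayCollection":
        coll = cls()
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}: line {line_no}: GMT rows need name, description, "
                        f"and at least one member"
                    )
                name, desc = fields[0], fields[1]
                members = {f for f in fields[2:] if f.strip()}
                if not members:
                    raise FormatError(f"{path}: line {line_no}: set {name!r} has no members")
                coll.add(name, members, name=name, category=desc)
        return coll

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in self:
                rec = self._pathways[pid]
                fh.write("\t".join([pid, rec["category"] or "na", *sorted(rec["members"])]) + "\n")


def node_set_enrichment(
    node_set: set[str],
    pathways: PathwayCollection,
    universe: set[str],
    correction: str = "BH",
) -> pd.DataFrame:
    """Hypergeometric over-representation of *node_set* in each pathway.

    p is the upper tail P(X >= overlap) with pathway members intersected
    with *universe* first; pathways with empty intersection are skipped.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not node_set <= universe:
        raise ValueError("node_set must be a subset of universe")
    if correction not in ("BH", "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    n_universe = len(universe)
    n_set = len(node_set)
    records = []
    for pid in pathways:
        members = pathways.members(pid) & universe
        if not members:
            continue
        overlap = len(node_set & members)
        # upper tail: P(X >= overlap) for hypergeom(M=universe, n=pathway, N=set)
        p = float(sps.hypergeom.sf(overlap - 1, n_universe, len(members), n_set))
        records.append((pid, pathways.name(pid), len(members), overlap, min(p, 1.0)))
    df = pd.DataFrame(records, columns=["pathway", "name", "pathway_size", "overlap", "p"])
    if len(df):
        from mpinet.stats import adjust_pvalues

        df["p_adjusted"] = adjust_pvalues(df["p"].to_numpy(), method=correction)
        df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df


# --------------------------------------------------------------------------
# PPI utilities
# --------------------------------------------------------------------------


@dataclass
class CommunityPartition:
    """Node -> module label assignment with the achieved modularity."""

    labels: dict[str, int]
    modularity: float

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, set()).add(node)
        return out


def read_ppi_edges(path) -> list[tuple[str, str]]:
    """Read an undirected PPI edge list TSV with columns protein_a, protein_b."""
    edges = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise FormatError(f"{path}: expected header with protein_a, protein_b")
        for row in reader:
            if len(row) >= 2 and row[0].strip() and row[1].strip():
                edges.append((row[0].strip(), row[1].strip()))
    return edges


def detect_communities(
    edge_list: Iterable[tuple[str, str]],
    node_subset: set[str] | None = None,
    seed: int = 0,
) -> CommunityPartition:
    """Greedy-modularity community detection on an induced PPI subgraph.

    The graph is restricted to *node_subset* (when given); nodes without any
    surviving edge are dropped before partitioning. Tie-breaking is made
    deterministic by lexicographically sorting nodes and edges on input.
    """
    g = nx.Graph()
    for a, b in sorted(set(tuple(sorted(e)) for e in edge_list)):
        if a == b:
            continue
        if node_subset is not None and (a not in node_subset or b not in node_subset):
            continue
        g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        return CommunityPartition(labels={}, modularity=0.0)
    communities = list(nx.community.greedy_modularity_communities(g))
    communities.sort(key=lambda c: (-len(c), min(c)))
    labels = {}
    for idx, comm in enumerate(communities, start=1):
        for node in comm:
            labels[node] = idx
    q = nx.community.modularity(g, communities)
    return CommunityPartition(labels=labels, modularity=float(q))


def read_id_mapping(path) -> dict[str, str]:
    """Optional two-column id -> display-name table; no translation performed."""
    mapping = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if len(row) >= 2:
                mapping[row[0].strip()] = row[1].strip()
    return mapping
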