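"""Candidate intersection, shared targets, MCC hubs, network and drugs.

Screen hits that push cells toward the contractile phenotype are
intersected with miRNAs up-regulated in contractile (low-serum) cells;
their predicted targets are grouped by how many distinct miRNAs share
them (k-way sharing); hub genes are ranked per miRNA by Maximal Clique
Centrality,

    MCC(v) = Σ over maximal cliques C ∋ v, |C| ≥ 2 of (|C| − 1)!,

within the protein-interaction subgraph induced by that miRNA's own
targets; and network genes are joined to a drug–gene interaction table
to propose (miRNA, target, drug) triples.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MirnaNamingError",
    "normalize_mirna",
    "intersect_candidates",
    "shared_targets",
    "mcc_scores",
    "select_hubs",
    "HubNetwork",
    "build_network",
    "map_drugs",
]

_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let|miR)\b|mir|let|miR)")
_ARM_SUFFIX = re.compile(r"-(3p|5p)$")


class MirnaNamingError(ValueError):
    """Raised when two miRNA lists use incompatible naming schemes."""


def normalize_mirna(name: str) -> str:
    """Canonical miRNA name: species prefix stripped, lower-cased,
    arm suffix (-3p/-5p) preserved.  'hsa-miR-145-5p' → 'mir-145-5p'."""
    n = name.strip()
    n = _SPECIES_PREFIX.sub("", n)
    return n.lower()


def _base(name: str) -> str:
    return _ARM_SUFFIX.sub("", name)


def intersect_candidates(
    screen_hits: list[str], de_up: list[str]
) -> tuple[list[str], dict[str, int]]:
    """Intersect contractile screen hits with up-regulated miRNAs.

    Both lists are name-normalized first.  If the same base miRNA
    appears with an arm suffix in one list but without in the other the
    schemes are incompatible and a ``MirnaNamingError`` is raised rather
    than silently part-matching.  Returns the intersection ordered by
    screen rank plus Venn summary counts.
    """
    a = [normalize_mirna(m) for m in screen_hits]
    b = [normalize_mirna(m) for m in de_up]

    def arm_map(names: list[str]) -> dict[str, set[bool]]:
        out: dict[str, set[bool]] = {}
        for n in names:
            out.setdefault(_base(n), set()).add(bool(_ARM_SUFFIX.search(n)))
        return out

    arms_a, arms_b = arm_map(a), arm_map(b)
    for basename in set(arms_a) & set(arms_b):
        if arms_a[basename] != arms_b[basename]:
            raise MirnaNamingError(
                f"miRNA {basename!r} named with an arm suffix in one list "
                f"but not the other; resolve naming explicitly"
            )

    set_b = set(b)
    seen: set[str] = set()
    overlap = []
    for m in a:
        if m in set_b and m not in seen:
            overlap.append(m)
            seen.add(m)
    venn = {
        "screen_only": len(set(a) - set_b),
        "de_only": len(set_b - set(a)),
        "overlap": len(overlap),
    }
    if not overlap:
        warnings.warn("screen and DE candidate lists are disjoint", stacklevel=2)
    return overlap, venn


def shared_targets(table: pd.DataFrame, k_min: int = 1) -> pd.DataFrame:
    """Group genes by the number k of distinct miRNAs predicted to target
    them; keep strata with k ≥ k_min.

    ``table`` needs columns (mirna, gene).  Returns a DataFrame indexed
    by gene with columns ``k`` and ``mirnas`` (sorted tuple), ordered by
    k descending then gene name.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    dedup = table[["mirna", "gene"]].drop_duplicates()
    grouped = dedup.groupby("gene")["mirna"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    out = pd.DataFrame(
        {"k": grouped.map(len), "mirnas": grouped}
    )
    out = out[out["k"] >= k_min]
    return out.sort_index().sort_values("k", ascending=False, kind="stable")


def mcc_scores(
    graph: nx.Graph, max_cliques: int = 1_000_000
) -> dict[str, float]:
    """Maximal Clique Centrality for every node of a simple graph.

    Maximal cliques are enumerated with Bron–Kerbosch (pivoting);
    MCC(v) sums (|C| − 1)! over maximal cliques of size ≥ 2 containing
    v.  Isolated nodes score 0.  Graphs whose clique count exceeds
    ``max_cliques`` abort with an error advising subgraph extraction.
    """
    if any(True for _ in nx.selfloop_edges(graph)):
        raise ValueError("graph must be simple (no self-loops)")
    scores: dict[str, float] = {v: 0.0 for v in graph.nodes}
    n_cliques = 0
    for clique in nx.find_cliques(graph):
        n_cliques += 1
        if n_cliques > max_cliques:
            raise RuntimeError(
                f"more than {max_cliques} maximal cliques; extract a "
                f"subgraph of interest before scoring"
            )
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


@dataclass
class HubNetwork:
    """Per-miRNA top-MCC targets and their deduplicated union."""

    per_mirna_hubs: dict[str, list[str]]
    mcc: dict[str, dict[str, float]]
    hub_set: list[str] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        union: list[str] = []
        for hubs in self.per_mirna_hubs.values():
            for g in hubs:
                if g not in seen:
                    seen.add(g)
                    union.append(g)
        self.hub_set = union


def select_hubs(
    table: pd.DataFrame,
    graph: nx.Graph,
    per_mirna_top: int = 3,
) -> HubNetwork:
    """Top hub targets per miRNA by MCC within the subgraph induced by
    that miRNA's own target genes.

    Genes absent from the interaction graph count as isolated (MCC 0).
    Ties break by MCC descending, then degree descending, then gene
    name.  miRNAs with fewer targets than ``per_mirna_top`` contribute
    all of them, with a warning.
    """
    per_mirna: dict[str, list[str]] = {}
    mcc_all: dict[str, dict[str, float]] = {}
    for mirna, grp in table.groupby("mirna", sort=True):
        targets = sorted(set(grp["gene"]))
        sub = graph.subgraph([g for g in targets if g in graph]).copy()
        sub.add_nodes_from(targets)
        scores = mcc_scores(sub)
        if len(targets) < per_mirna_top:
            warnings.warn(
                f"{mirna}: only {len(targets)} targets (< {per_mirna_top})",
                stacklevel=2,
            )
        ranked = sorted(
            targets,
            key=lambda g: (-scores[g], -sub.degree(g), g),
        )
        per_mirna[str(mirna)] = ranked[:per_mirna_top]
        mcc_all[str(mirna)] = scores
    return HubNetwork(per_mirna_hubs=per_mirna, mcc=mcc_all)


def build_network(
    shared: pd.DataFrame,
    hubs: HubNetwork,
    graph: nx.Graph,
    k_min: int = 4,
) -> nx.Graph:
    """Merge the k ≥ k_min shared-target stratum with the hub set into one
    annotated network.

    Node attributes: role (shared/hub/both), k (0 if not shared),
    mcc (max over miRNAs for hub genes), mirnas (comma-joined targeting
    miRNAs where known).  Edges are the protein-interaction edges
    induced on the node set.  Export with ``networkx.write_graphml``.
    """
    shared_sel = shared[shared["k"] >= k_min]
    nodes: dict[str, dict] = {}
    for gene, row in shared_sel.iterrows():
        nodes[gene] = {
            "role": "shared",
            "k": int(row["k"]),
            "mirnas": ",".join(row["mirnas"]),
            "mcc": 0.0,
        }
    for mirna, hub_genes in hubs.per_mirna_hubs.items():
        for g in hub_genes:
            if g in nodes:
                if nodes[g]["role"] == "shared":
                    nodes[g]["role"] = "both"
            else:
                nodes[g] = {"role": "hub", "k": 0, "mirnas": "", "mcc": 0.0}
            nodes[g]["mcc"] = max(
                nodes[g]["mcc"], hubs.mcc.get(mirna, {}).get(g, 0.0)
            )
            hub_mirnas = set(
                nodes[g]["mirnas"].split(",")
            ) if nodes[g]["mirnas"] else set()
            if nodes[g]["role"] == "hub":
                hub_mirnas.add(mirna)
                nodes[g]["mirnas"] = ",".join(sorted(hub_mirnas))

    net = nx.Graph()
    for gene, attrs in nodes.items():
        net.add_node(gene, **attrs)
    for u, v in graph.edges:
        if u in nodes and v in nodes and u != v:
            net.add_edge(u, v)
    return net


def map_drugs(
    network_genes,
    drug_table: pd.DataFrame,
    target_table: pd.DataFrame,
    hub_genes=None,
) -> tuple[pd.DataFrame, float]:
    """Join network genes with the drug–gene table.

    Returns (triples, coverage): triples has one (mirna, gene, drug) row
    per combination of a targeting miRNA and an interacting drug;
    coverage is the fraction of ``hub_genes`` (default: all
    ``network_genes``) with at least one drug.
    """
    genes = list(dict.fromkeys(network_genes))
    hub_genes = list(dict.fromkeys(hub_genes)) if hub_genes is not None else genes
    drugs = drug_table[drug_table["gene"].isin(genes)]
    tt = target_table[["mirna", "gene"]].drop_duplicates()
    triples = (
        tt[tt["gene"].isin(genes)]
        .merge(drugs, on="gene", how="inner")
        .loc[:, ["mirna", "gene", "drug"]]
        .sort_values(["mirna", "gene", "drug"], ignore_index=True)
    )
    druggable = set(drugs["gene"])
    coverage = (
        sum(1 for g in hub_genes if g in druggable) / len(hub_genes)
        if hub_genes
        else 0.0
    )
    return triples, coverage
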