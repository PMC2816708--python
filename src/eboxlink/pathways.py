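"""Pathway over-representation and bipartite pathway-gene networks.

Each pathway is tested for enrichment of significantly regulated genes with
a one-sided Fisher exact test on the 2x2 (in-pathway x significant) table
over a declared gene universe; raw and BH-adjusted p-values are reported
side by side.  Significant pathways and their significant member genes are
then assembled into a bipartite network in which a gene's hub score is the
number of pathways containing it; "critical" genes are those connected to
at least k significant pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy import stats

from ._util import ParseError, ValidationError
from .expression import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    description: str
    members: frozenset


def read_gmt(path) -> list[PathwaySet]:
    """Read a GMT file (one pathway per line: id, description, members).

    Duplicate members within a line are collapsed; a line with fewer than
    three fields is a parse error naming the line.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            out.append(PathwaySet(fields[0], fields[1], frozenset(fields[2:])))
    return out


def write_gmt(pathways: list[PathwaySet], path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.description, *sorted(p.members)]) + "\n")


@dataclass(frozen=True)
class PathwayEnrichment:
    """Fisher-exact enrichment outcome for one pathway."""

    pathway_id: str
    genes_total: int        # pathway genes present in the universe
    genes_significant: int  # of those, significantly regulated
    p_fisher: float
    direction: str          # "up" | "down" | "mixed"

    def __post_init__(self):
        if self.genes_significant > self.genes_total:
            raise ValidationError(f"{self.pathway_id}: significant > total")


def fisher_pathway(
    sig_genes,
    members,
    universe,
    directions: dict[str, str] | None = None,
    pathway_id: str = "",
) -> PathwayEnrichment:
    """One-sided (enrichment) Fisher exact test over the declared universe.

    Direction is the majority sign of the significant in-pathway genes;
    ties (or no direction information) are labelled "mixed".
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    members_u = set(members) & universe
    if not members_u:
        raise ValidationError(f"pathway {pathway_id!r} has no genes in the universe")
    sig = set(sig_genes) & universe
    a = len(sig & members_u)
    b = len(sig - members_u)
    c = len(members_u - sig)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    n_up = n_down = 0
    for g in sig & members_u:
        d_ = (directions or {}).get(g)
        n_up += d_ == "up"
        n_down += d_ == "down"
    direction = "up" if n_up > n_down else "down" if n_down > n_up else "mixed"
    return PathwayEnrichment(pathway_id, len(members_u), a, float(p), direction)


def enrich_pathways(
    sig_genes,
    pathways: list[PathwaySet],
    universe,
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-pathway enrichment table with raw and BH-adjusted p-values.

    Pathways with no genes in the universe are skipped with a warning.
    """
    rows = []
    for p in pathways:
        try:
            e = fisher_pathway(sig_genes, p.members, universe, directions, p.pathway_id)
        except ValidationError as exc:
            logger.warning("skipping pathway: %s", exc)
            continue
        universe_n = len(set(universe))
        sig_n = len(set(sig_genes) & set(universe))
        rows.append(
            {
                "pathway_id": e.pathway_id,
                "direction": e.direction,
                "p_raw": e.p_fisher,
                "genes_total": e.genes_total,
                "genes_significant": e.genes_significant,
                "expected_significant": e.genes_total * sig_n / universe_n,
            }
        )
    df = pd.DataFrame(
        rows, columns=["pathway_id", "direction", "p_raw", "genes_total",
                       "genes_significant", "expected_significant"]
    )
    df["p_bh"] = bh_adjust(df["p_raw"].values) if len(df) else []
    return df.sort_values(["p_raw", "pathway_id"]).reset_index(drop=True)


@dataclass
class BipartiteNetwork:
    """Bipartite pathway-gene graph with significance flags and hub scores."""

    graph: nx.Graph
    p_cut: float

    @property
    def pathway_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "pathway")

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    def hub_score(self, gene: str) -> int:
        return self.graph.degree(gene)

    def significant_pathways(self) -> list[str]:
        return [n for n in self.pathway_nodes if self.graph.nodes[n]["significant"]]

    def edge_list_frame(self) -> pd.DataFrame:
        rows = [
            {"pathway_id": p, "gene_id": g}
            for p, g in sorted(
                (u, v) if self.graph.nodes[u]["kind"] == "pathway" else (v, u)
                for u, v in self.graph.edges
            )
        ]
        return pd.DataFrame(rows, columns=["pathway_id", "gene_id"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, str(path))


def build_bipartite(
    enrichments: pd.DataFrame,
    sig_directions: dict[str, str],
    pathways: list[PathwaySet],
    p_cut: float = 0.05,
) -> BipartiteNetwork:
    """Assemble the bipartite network of pathways and significant genes.

    Nodes are created for every pathway with at least one significant member
    gene; edges join significant genes to the pathways containing them.
    Pathway nodes carry a ``significant`` flag (raw Fisher p < p_cut) and an
    over/under-representation label; gene nodes carry their hub score
    (= degree) as an attribute.  Node insertion is sorted for determinism.
    """
    by_id = {p.pathway_id: p for p in pathways}
    g = nx.Graph()
    sig = set(sig_directions)
    for row in enrichments.sort_values("pathway_id").itertuples(index=False):
        members = by_id[row.pathway_id].members
        sig_members = sorted(sig & members)
        if not sig_members:
            continue
        significant = bool(row.p_raw < p_cut)
        expected = getattr(row, "expected_significant", float("nan"))
        if significant:
            representation = "over" if row.genes_significant >= expected else "under"
        else:
            representation = "none"
        g.add_node(
            row.pathway_id,
            kind="pathway",
            significant=significant,
            representation=representation,
            p_raw=float(row.p_raw),
            direction=row.direction,
        )
        for gene in sig_members:
            if gene not in g:
                g.add_node(gene, kind="gene", direction=sig_directions.get(gene, ""))
            g.add_edge(row.pathway_id, gene)
    for gene in [n for n, d in g.nodes(data=True) if d["kind"] == "gene"]:
        g.nodes[gene]["hub_score"] = g.degree(gene)
    return BipartiteNetwork(g, p_cut)


def critical_genes(
    network: BipartiteNetwork, min_significant_pathways: int = 2
) -> pd.DataFrame:
    """Genes connected to >= k significant pathways, ranked by hub score.

    Ties break alphabetically for determinism.
    """
    sig_paths = set(network.significant_pathways())
    rows = []
    for gene in network.gene_nodes:
        n_sig = sum(1 for nb in network.graph.neighbors(gene) if nb in sig_paths)
        if n_sig >= min_significant_pathways:
            rows.append(
                {"gene_id": gene, "n_significant_pathways": n_sig,
                 "hub_score": network.hub_score(gene)}
            )
    df = pd.DataFrame(rows, columns=["gene_id", "n_significant_pathways", "hub_score"])
    return df.sort_values(
        ["hub_score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
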