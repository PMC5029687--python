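"""Driver definition and directed signaling-network analysis.

A prognosis "driver" is a gene whose epigenomic or genomic alteration is
concordant with its transcriptional change in the high-risk group:
hypermethylated & underexpressed, hypomethylated & overexpressed,
amplified & overexpressed, or recurrently mutated. Drivers present in a
signed directed edge resource (SIGNOR-style) are linked to differentially
expressed genes with direct activating/inhibitory edges; the largest
weakly connected component and its hub genes summarize the result.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["identify_drivers", "read_edge_list", "build_network",
           "largest_component", "hub_genes"]

_UP = {"up_in_high", "up"}
_DOWN = {"down_in_high", "down"}


def identify_drivers(dm_gene_table: pd.DataFrame | None,
                     deg_table: pd.DataFrame,
                     amplified_genes=(),
                     mutated_genes=()) -> pd.DataFrame:
    """Assemble the driver table from the per-layer results.

    Parameters
    ----------
    dm_gene_table : output of :func:`reopair.diffomics.dm_genes`
        (gene_id, direction in {'hyper','hypo'}); may be None/empty.
    deg_table : DiffTable of expression with a ``significant`` column.
    amplified_genes : genes with significant copy-number gain in the
        high-risk group (driver when also overexpressed).
    mutated_genes : genes from the mutation-frequency screen (drivers
        regardless of expression direction).

    Returns a DataFrame (gene, driver_class, expression_direction); a
    gene may carry several classes (one row per class).
    """
    degs = deg_table[deg_table["significant"]]
    expr_dir = {}
    for _, row in degs.iterrows():
        expr_dir[row["feature_id"]] = ("up" if row["direction"] in _UP
                                       else "down")
    rows = []
    if dm_gene_table is not None and len(dm_gene_table):
        for _, row in dm_gene_table.iterrows():
            g, d = row["gene_id"], row["direction"]
            e = expr_dir.get(g)
            if d == "hyper" and e == "down":
                rows.append((g, "hyper_down", "down"))
            elif d == "hypo" and e == "up":
                rows.append((g, "hypo_up", "up"))
    for g in amplified_genes:
        if expr_dir.get(g) == "up":
            rows.append((g, "amplified_up", "up"))
    for g in mutated_genes:
        rows.append((g, "mutated", expr_dir.get(g, "none")))
    return pd.DataFrame(rows, columns=["gene", "driver_class",
                                       "expression_direction"])


def read_edge_list(path) -> pd.DataFrame:
    """Parse a SIGNOR-style signed edge list TSV.

    Expects columns source, target, effect (header required; extra
    columns ignored). Effects containing 'up-regulates' / 'activat' map
    to 'activating'; 'down-regulates' / 'inhibit' to 'inhibitory'; other
    rows are dropped with a logged count, as are malformed rows and
    self-loops.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        src, tgt, eff = cols["source"], cols["target"], cols["effect"]
    except KeyError as exc:
        raise ValueError(f"{path}: edge list needs source/target/effect "
                         f"columns") from exc
    rows, dropped = [], 0
    for _, r in df.iterrows():
        s, t, e = r[src], r[tgt], r[eff]
        if pd.isna(s) or pd.isna(t) or pd.isna(e) or s == t:
            dropped += 1
            continue
        e = str(e).lower()
        if "up-regulates" in e or "activat" in e:
            sign = "activating"
        elif "down-regulates" in e or "inhibit" in e:
            sign = "inhibitory"
        else:
            dropped += 1
            continue
        rows.append((str(s), str(t), sign))
    if dropped:
        logger.info("%d edge rows dropped (malformed, self-loop or "
                    "unrecognized effect)", dropped)
    out = pd.DataFrame(rows, columns=["source", "target", "sign"])
    return out.drop_duplicates(ignore_index=True)


def build_network(drivers: pd.DataFrame, deg_table: pd.DataFrame,
                  edges: pd.DataFrame) -> nx.MultiDiGraph:
    """Directed network of drivers plus directly linked DEGs.

    Nodes are drivers found in the edge resource together with
    significant DEGs having at least one direct edge to or from such a
    driver; edges are the resource edges with both endpoints included.
    Edges are deduplicated on (source, target, sign).
    """
    edges = edges.drop_duplicates(subset=["source", "target", "sign"])
    edges = edges[edges["source"] != edges["target"]]
    resource_nodes = set(edges["source"]) | set(edges["target"])
    driver_genes = set(drivers["gene"]) & resource_nodes
    degs = set(deg_table.loc[deg_table["significant"], "feature_id"])

    touches_driver = (edges["source"].isin(driver_genes)
                      | edges["target"].isin(driver_genes))
    linked_degs = ((set(edges.loc[touches_driver, "source"])
                    | set(edges.loc[touches_driver, "target"]))
                   & degs) - driver_genes
    nodes = driver_genes | linked_degs

    g = nx.MultiDiGraph()
    classes = drivers.groupby("gene")["driver_class"].apply(sorted).to_dict()
    expr_dir = {}
    for _, row in deg_table[deg_table["significant"]].iterrows():
        expr_dir[row["feature_id"]] = ("up" if row["direction"] in _UP
                                       else "down")
    for n in sorted(nodes):
        g.add_node(n, is_driver=n in driver_genes,
                   driver_classes=classes.get(n, []),
                   expression_direction=expr_dir.get(n, "none"))
    kept = edges[edges["source"].isin(nodes) & edges["target"].isin(nodes)]
    for _, r in kept.iterrows():
        g.add_edge(r["source"], r["target"], key=r["sign"], sign=r["sign"])
    return g


def largest_component(net: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Largest weakly connected component; ties broken by the
    lexicographically smallest member gene."""
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    comps = sorted(nx.weakly_connected_components(net),
                   key=lambda c: (-len(c), min(c)))
    return net.subgraph(comps[0]).copy()


def hub_genes(net: nx.MultiDiGraph, min_degree: int = 7) -> pd.DataFrame:
    """Genes with total degree (in + out, sign-blind) >= min_degree,
    sorted by degree descending then name."""
    rows = [(n, d) for n, d in net.degree() if d >= min_degree]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def network_tables(net: nx.MultiDiGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for TSV export."""
    nodes = pd.DataFrame(
        [(n, d["is_driver"], ";".join(d["driver_classes"]),
          d["expression_direction"]) for n, d in net.nodes(data=True)],
        columns=["gene", "is_driver", "driver_classes",
                 "expression_direction"])
    edges = pd.DataFrame(
        [(u, v, d["sign"]) for u, v, d in net.edges(data=True)],
        columns=["source", "target", "sign"])
    return (nodes.sort_values("gene", ignore_index=True),
            edges.sort_values(["source", "target", "sign"],
                              ignore_index=True))
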