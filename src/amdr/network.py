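"""Epistasis-enriched network construction and export.

Significant pairwise interactions become weighted edges between SNPs (or,
with a SNP-to-gene map, between genes). Edge weight is the calibrated odds
ratio pOR; a larger pOR marks a stronger interaction. Two SNPs of the same
gene may interact, producing a flagged gene-level self-edge.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import InteractionResult

__all__ = ["build_network", "export_network", "read_edge_tsv"]

log = logging.getLogger(__name__)


def build_network(
    results: list[InteractionResult],
    rule: str = "fdr",
    threshold: float = 0.05,
    level: str | None = None,
    gene_map: dict[str, str] | None = None,
    snp_labels: list[str] | None = None,
) -> nx.MultiGraph:
    """Build the network of significant pairwise interactions.

    Parameters
    ----------
    results
        Pairwise (k=2) interaction results.
    rule, threshold
        Significance rule: keep edges with ``fdr`` (default) or ``pvalue``
        below ``threshold``.
    level
        ``"snp"`` or ``"gene"``; defaults to gene when ``gene_map`` is given.
    gene_map
        SNP label -> gene name. At gene level parallel edges are kept, each
        annotated with its SNP pair; within-gene interactions become
        self-edges flagged ``within_gene``.
    """
    if rule not in ("fdr", "pvalue"):
        raise ValueError("significance rule must be 'fdr' or 'pvalue'")
    if level is None:
        level = "gene" if gene_map else "snp"
    if level == "gene" and not gene_map:
        raise ValueError("gene-level network requires a gene_map")
    if level not in ("snp", "gene"):
        raise ValueError("level must be 'snp' or 'gene'")
    g = nx.MultiGraph(significance_rule=rule, threshold=threshold, level=level)
    for r in results:
        if r.spec.k != 2:
            raise ValueError("the epistasis network is defined for pairwise interactions")
        p = r.fdr if rule == "fdr" else r.pvalue
        if not p < threshold:
            continue
        a, b = (
            r.spec.labels(snp_labels) if snp_labels
            else tuple(str(i) for i in r.spec.loci)
        )
        if level == "gene":
            na, nb = gene_map.get(a, a), gene_map.get(b, b)
        else:
            na, nb = a, b
        within = na == nb
        if within:
            log.info("within-gene interaction %s x %s collapses to a self-edge", a, b)
        g.add_edge(
            na, nb,
            pOR=r.corrected["OR"], pvalue=r.pvalue, fdr=r.fdr,
            snp_a=a, snp_b=b, within_gene=within,
        )
    return g


def _pen_widths(net: nx.MultiGraph) -> dict[tuple, float]:
    """Monotone pOR -> pen-width map for DOT output (range 1..4)."""
    weights = [d["pOR"] for *_, d in net.edges(data=True)]
    if not weights:
        return {}
    lo, hi = min(weights), max(weights)
    span = hi - lo
    return {
        (u, v, k): 1.0 + (3.0 * (d["pOR"] - lo) / span if span > 0 else 0.0)
        for u, v, k, d in net.edges(keys=True, data=True)
    }


def export_network(net: nx.MultiGraph, fmt: str, path: str | Path) -> None:
    """Write the network as ``edge-tsv``, ``dot`` or ``graphml``."""
    path = Path(path)
    if fmt == "edge-tsv":
        rows = [
            {
                "node_a": u, "node_b": v, "pOR": d["pOR"],
                "pvalue": d["pvalue"], "fdr": d["fdr"],
                "snp_a": d.get("snp_a", u), "snp_b": d.get("snp_b", v),
            }
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(
            rows, columns=["node_a", "node_b", "pOR", "pvalue", "fdr", "snp_a", "snp_b"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "dot":
        widths = _pen_widths(net)
        lines = ["graph epistasis {"]
        for node in net.nodes:
            lines.append(f'    "{node}";')
        for u, v, k, d in net.edges(keys=True, data=True):
            lines.append(
                f'    "{u}" -- "{v}" [label="{d["pOR"]:.2f}", '
                f'penwidth={widths[(u, v, k)]:.2f}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = nx.MultiGraph()
        g.add_nodes_from(net.nodes)
        for u, v, d in net.edges(data=True):
            g.add_edge(u, v, **{k: _graphml_safe(x) for k, x in d.items()})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _graphml_safe(x):
    return bool(x) if isinstance(x, bool) else x


def read_edge_tsv(path: str | Path) -> nx.MultiGraph:
    """Rebuild a network from its edge-TSV export."""
    df = pd.read_csv(path, sep="\t")
    g = nx.MultiGraph()
    for row in df.itertuples(index=False):
        g.add_edge(
            str(row.node_a), str(row.node_b),
            pOR=float(row.pOR), pvalue=float(row.pvalue), fdr=float(row.fdr),
            snp_a=str(row.snp_a), snp_b=str(row.snp_b),
            within_gene=str(row.node_a) == str(row.node_b),
        )
    return g
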