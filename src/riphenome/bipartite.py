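"""Bipartite gene-phenotype integration.

Each QTL positional-candidate list and each expression-correlate list
becomes a phenotype vertex; every gene in a list is a gene vertex connected
to it by an (unweighted, deduplicated) edge.  A gene's degree counts the
phenotype lists it appears in, so ranking genes by connectivity surfaces the
genes most broadly associated with the trait panel.  The top 5%/10% slice of
the ranking is tested for gene-set over-representation with a one-sided
hypergeometric test against a gene universe.
"""

from __future__ import annotations

from math import ceil
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["build_bipartite", "connectivity_ranking", "top_slice",
           "hypergeometric_enrichment"]


def build_bipartite(lists: Mapping[str, Iterable[str]]) -> nx.Graph:
    """Bipartite graph from named gene lists.

    One phenotype vertex per list, one gene vertex per distinct gene, an
    edge wherever the gene occurs in the list (duplicates collapse).  Node
    kinds are stored in the ``kind`` attribute ("phenotype"/"gene").
    """
    if len(lists) == 0:
        raise ValueError("empty list collection")
    G = nx.Graph()
    for name in lists:
        G.add_node(name, kind="phenotype")
    for name, genes in lists.items():
        for g in genes:
            if G.nodes.get(g, {}).get("kind") == "phenotype":
                raise ValueError(f"id {g!r} used as both gene and list name")
            G.add_node(g, kind="gene")
            G.add_edge(g, name)
    return G


def connectivity_ranking(G: nx.Graph) -> pd.DataFrame:
    """Genes ranked by degree descending, ties broken by gene id (stable)."""
    genes = [n for n, d in G.nodes(data=True) if d.get("kind") == "gene"]
    if len(genes) == 0:
        raise ValueError("graph has no gene vertices")
    df = pd.DataFrame({"gene": genes,
                       "degree": [G.degree[g] for g in genes]})
    return (df.sort_values(["degree", "gene"],
                           ascending=[False, True], kind="mergesort")
              .reset_index(drop=True))


def top_slice(ranking: pd.DataFrame, fraction: float,
              min_degree: int | None = None) -> list[str]:
    """Top ``ceil(fraction * n_genes)`` genes from the connectivity ranking.

    Ties at the cut are included only up to the slice size (the ranking's
    deterministic id order decides).  ``min_degree`` (e.g. 2) first
    eliminates singleton genes: genes appearing in only one list carry no
    convergent evidence.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    r = ranking if min_degree is None else \
        ranking[ranking["degree"] >= min_degree]
    size = ceil(fraction * len(r))
    return r["gene"].head(size).tolist()


def hypergeometric_enrichment(slice_genes: Iterable[str],
                              sets: Mapping[str, Iterable[str]],
                              universe: Iterable[str],
                              adjust: bool = True) -> pd.DataFrame:
    """Gene-set over-representation of a gene slice by hypergeometric test.

    For each set, ``p = P(X >= k)`` with X hypergeometric(N = |universe|,
    K = |set in universe|, n = |slice|) and k the observed overlap.  Sets
    are intersected with the universe first; the slice must be a subset of
    the universe.  Adds a Benjamini-Hochberg column unless ``adjust=False``.
    """
    uni = set(universe)
    if len(uni) == 0:
        raise ValueError("empty gene universe")
    sl = set(slice_genes)
    stray = sl - uni
    if stray:
        raise ValueError(f"slice genes outside universe: "
                         f"{sorted(stray)[:5]}")
    N, n = len(uni), len(sl)
    rows = []
    for name, members in sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & sl)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, p))
    out = pd.DataFrame(rows, columns=["set", "K", "k", "p"]).set_index("set")
    if adjust and len(out):
        m = len(out)
        order = np.argsort(out["p"].to_numpy(), kind="mergesort")
        adj = out["p"].to_numpy()[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        padj = np.empty(m)
        padj[order] = np.clip(adj, 0, 1)
        out["p_bh"] = padj
    return out.sort_values(["p", "set"])
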