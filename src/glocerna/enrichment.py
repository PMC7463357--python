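"""Hypergeometric gene-set enrichment for cancer hallmarks.

Hallmark capabilities are represented by GO-term gene sets; the query is
the set of PCGs adjacent to ce-lncRNAs in the ceRNA network, either
network-wide or per lncRNA. Significance is the upper-tail
hypergeometric p (raw p < 0.05 calls a set enriched; BH q-values are
reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .network import lncrna_nodes, pcg_nodes
from .types import GeneSetCollection

SIGNIFICANCE = 0.05


@dataclass
class EnrichmentResult:
    set_id: str
    hallmark_label: str
    k: int  # overlap of query and set within the universe
    K: int  # set size within the universe
    nq: int  # query size within the universe
    N: int  # universe size
    p_value: float
    q_value: float | None = None


def enrich(query_genes, gene_set, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one gene set.

    Query and set are intersected with the universe before testing, so
    genes outside the universe never influence the result.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    q = set(query_genes) & universe
    s = set(gene_set) & universe
    k, big_k, nq, n = len(q & s), len(s), len(q), len(universe)
    p = float(min(hypergeom.sf(k - 1, n, big_k, nq), 1.0))
    return EnrichmentResult("", "", k, big_k, nq, n, p)


def _collection_enrichment(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    rows = []
    for set_id in sorted(collection.sets):
        res = enrich(query, collection.sets[set_id], universe)
        rows.append(
            {
                "set_id": set_id,
                "hallmark_label": collection.labels.get(set_id, ""),
                "k": res.k,
                "K": res.K,
                "nq": res.nq,
                "N": res.N,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(
        rows, columns=["set_id", "hallmark_label", "k", "K", "nq", "N", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_value"] < SIGNIFICANCE
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def hallmark_enrichment(
    net, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Network-wide enrichment: the query is the union of all PCGs
    adjacent to any ce-lncRNA; one row per gene set.

    A hallmark is called enriched when any of its GO-term sets is
    significant at raw p < 0.05 (see :func:`enriched_hallmarks`).
    """
    query = pcg_nodes(net)
    return _collection_enrichment(query, collection, universe)


def enriched_hallmarks(
    enrichment_table: pd.DataFrame, hallmark_map: pd.DataFrame
) -> list[str]:
    """Hallmarks with at least one significant GO-term set, given the
    two-column (hallmark, set_id) map."""
    sig_sets = set(
        enrichment_table.loc[enrichment_table["significant"], "set_id"]
    )
    return sorted(
        hallmark_map.loc[hallmark_map["set_id"].isin(sig_sets), "hallmark"].unique()
    )


def per_lncrna_hallmarks(
    net, collection: GeneSetCollection, universe
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-ce-lncRNA enrichment: each lncRNA's query is its own PCG
    neighborhood.

    Returns the table of significant (lncRNA, set) rows and a Series of
    enriched-set counts per lncRNA, ranked by count descending with ties
    broken by lncRNA id.
    """
    rows = []
    counts: dict[str, int] = {}
    for lnc in sorted(lncrna_nodes(net)):
        neighbors = set(net.neighbors(lnc))
        if not neighbors:
            counts[lnc] = 0
            continue
        table = _collection_enrichment(neighbors, collection, universe)
        sig = table.loc[table["significant"]]
        counts[lnc] = int(len(sig))
        for _, r in sig.iterrows():
            rows.append(
                {
                    "lncrna_id": lnc,
                    "set_id": r["set_id"],
                    "hallmark_label": r["hallmark_label"],
                    "p_value": r["p_value"],
                    "q_value": r["q_value"],
                }
            )
    table = pd.DataFrame(
        rows, columns=["lncrna_id", "set_id", "hallmark_label", "p_value", "q_value"]
    )
    count_series = pd.Series(counts, name="enriched_sets")
    count_series = count_series.sort_index().sort_values(
        ascending=False, kind="mergesort"
    )
    return table, count_series
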