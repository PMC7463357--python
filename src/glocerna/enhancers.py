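"""Super-/typical-enhancer gene assignment and THZ1 sensitivity.

SE/TE regions (already called upstream from H3K27ac data) are assigned
to genes by three rules — gene body overlapping the region, TSS within a
window of the region center ("proximal"), and the single closest TSS —
and ce-lncRNAs carrying an SE (or TE) assignment in any cell line are
labelled accordingly. THZ1 sensitivity classifies active genes whose
expression drops more than a fold-change cutoff under CDK7 inhibition
relative to DMSO at the evaluation timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as net_mod
from .exceptions import ValidationError
from .types import EnhancerRegionSet, GeneCoordinateTable

logger = logging.getLogger(__name__)

RULE_RANK = {"overlap": 0, "proximal": 1, "closest": 2}


@dataclass
class EnhancerAssignment:
    gene_id: str
    cell_line: str
    enhancer_class: str
    rule: str
    distance: int


def assign_enhancers(
    regions: EnhancerRegionSet,
    coords: GeneCoordinateTable,
    proximal_window: int = 50_000,
) -> pd.DataFrame:
    """Assign every region to genes by the overlap / proximal / closest
    rules and return one row per (gene, cell line, class).

    * overlap — the gene body intersects the region (distance 0);
    * proximal — the strand-aware TSS lies within ``proximal_window`` bp
      of the region center;
    * closest — the single gene with minimal TSS-to-center distance on
      the region's chromosome (ties broken by gene id).

    The union is deduplicated per (gene, cell_line, enhancer_class),
    keeping the strongest rule (overlap > proximal > closest) and its
    distance. Regions on chromosomes absent from the coordinate table
    are skipped with a warning.
    """
    out: dict[tuple[str, str, str], tuple[str, int]] = {}
    coords_by_chrom = dict(tuple(coords.records.groupby("chrom")))

    def _offer(gene: str, line: str, cls: str, rule: str, dist: int) -> None:
        key = (gene, line, cls)
        prev = out.get(key)
        if prev is None or RULE_RANK[rule] < RULE_RANK[prev[0]]:
            out[key] = (rule, dist)

    for _, region in regions.records.iterrows():
        genes = coords_by_chrom.get(region["chrom"])
        if genes is None:
            logger.warning(
                "region %s:%d-%d: chromosome absent from gene coordinates",
                region["chrom"],
                region["start"],
                region["end"],
            )
            continue
        center = (int(region["start"]) + int(region["end"])) // 2
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        tss = genes["tss"].to_numpy()
        ids = genes["gene_id"].to_numpy()
        line, cls = region["cell_line"], region["enhancer_class"]

        dist = np.abs(tss - center)
        overlap = (starts < int(region["end"])) & (int(region["start"]) < ends)
        for gid in ids[overlap]:
            _offer(gid, line, cls, "overlap", 0)
        proximal = dist <= proximal_window
        for gid, d in zip(ids[proximal], dist[proximal]):
            _offer(gid, line, cls, "proximal", int(d))
        # closest: minimal distance, ties by lexicographic gene id
        order = np.lexsort((ids, dist))
        gid, d = ids[order[0]], int(dist[order[0]])
        _offer(gid, line, cls, "closest", d)

    rows = [
        {
            "gene_id": g,
            "cell_line": line,
            "enhancer_class": cls,
            "rule": rule,
            "distance": dist,
        }
        for (g, line, cls), (rule, dist) in sorted(out.items())
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "cell_line", "enhancer_class", "rule", "distance"]
    )


def label_se_te_lncrnas(
    assignments: pd.DataFrame, ce_lncrnas
) -> tuple[dict[str, str], pd.DataFrame]:
    """Label each ce-lncRNA SE, TE or none by the any-cell-line union
    rule: SE if SE-assigned in any cell line, else TE if TE-assigned in
    any, else none. Also returns the per-cell-line detail rows."""
    ce = set(ce_lncrnas)
    detail = assignments.loc[assignments["gene_id"].isin(ce)].reset_index(drop=True)
    labels: dict[str, str] = {}
    se_genes = set(detail.loc[detail["enhancer_class"] == "SE", "gene_id"])
    te_genes = set(detail.loc[detail["enhancer_class"] == "TE", "gene_id"])
    for lnc in sorted(ce):
        if lnc in se_genes:
            labels[lnc] = "SE"
        elif lnc in te_genes:
            labels[lnc] = "TE"
        else:
            labels[lnc] = "none"
    return labels, detail


def thz1_sensitive(
    timecourse: pd.DataFrame,
    genes=None,
    fold_cutoff: float = 1.5,
    timepoint: float = 12,
    active_min: float = 1.0,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Classify THZ1-sensitive genes at the evaluation timepoint.

    ``timecourse`` has columns ``gene_id, treatment, timepoint, value``
    (FPKM-like). Genes whose DMSO value at the timepoint is <= the
    activity floor (FPKM > 1 required) are excluded as inactive; for the
    rest the fold change is (DMSO + eps) / (THZ1 + eps) and a gene is
    sensitive when it strictly exceeds ``fold_cutoff``. Genes missing
    either condition are skipped with a log message.
    """
    required = {"gene_id", "treatment", "timepoint", "value"}
    if not required.issubset(timecourse.columns):
        raise ValidationError(f"timecourse needs columns {sorted(required)}")
    at_tp = timecourse.loc[timecourse["timepoint"] == timepoint]
    pivot = at_tp.pivot_table(
        index="gene_id", columns="treatment", values="value", aggfunc="first"
    )
    if genes is not None:
        pivot = pivot.loc[pivot.index.intersection(set(genes))]
    rows = []
    for gid, row in pivot.sort_index().iterrows():
        dmso = row.get("DMSO")
        thz1 = row.get("THZ1")
        if pd.isna(dmso) or pd.isna(thz1):
            logger.warning("gene %s missing DMSO or THZ1 at %sh; skipped", gid, timepoint)
            continue
        if dmso <= active_min:
            continue  # inactive gene, excluded from the analysis
        fc = (dmso + eps) / (thz1 + eps)
        rows.append(
            {
                "gene_id": gid,
                "dmso": float(dmso),
                "thz1": float(thz1),
                "fold_change": float(fc),
                "sensitive": bool(fc > fold_cutoff),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "dmso", "thz1", "fold_change", "sensitive"]
    )


def thz1_network(
    sensitivity_by_line: dict[str, pd.DataFrame],
    net,
    require_shared: bool = True,
):
    """THZ1-sensitive ceRNA subnetwork.

    Seeds are the sensitive lncRNAs of each cell line's sensitivity
    table, intersected across lines when ``require_shared`` (the shared
    THZ1-sensitive ce-lncRNAs), otherwise their union; the result is the
    first-neighbor subnetwork of those seeds.
    """
    sets = [
        set(df.loc[df["sensitive"], "gene_id"]) for df in sensitivity_by_line.values()
    ]
    if not sets:
        seeds: set[str] = set()
    elif require_shared:
        seeds = set.intersection(*sets)
    else:
        seeds = set.union(*sets)
    return net_mod.extract_subnetwork(net, sorted(seeds))
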