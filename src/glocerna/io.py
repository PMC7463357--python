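"""Readers and writers for every external table the pipeline consumes.

All tabular inputs are plain TSV; genomic intervals follow the BED
convention (0-based, half-open). Readers validate eagerly and raise a
specific :mod:`glocerna.exceptions` type naming the offending record.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .exceptions import FileFormatError, PairingError, ValidationError
from .types import (
    ClinicalTable,
    EnhancerRegionSet,
    GeneCoordinateTable,
    GeneSetCollection,
    InteractionSet,
    MatchedExpressionMatrix,
)

logger = logging.getLogger(__name__)


def read_pairing(path: str | Path) -> pd.DataFrame:
    """Read the sample-to-(patient, tissue) map.

    TSV with columns ``sample``, ``patient_id``, ``tissue`` where tissue is
    ``N`` (normal) or ``T`` (tumor).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "patient_id", "tissue"}
    if not required.issubset(df.columns):
        raise FileFormatError(f"pairing file needs columns {sorted(required)}")
    if not df["tissue"].isin(["N", "T"]).all():
        bad = df.loc[~df["tissue"].isin(["N", "T"]), "tissue"].iloc[0]
        raise FileFormatError(f"tissue must be N or T, got {bad!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FileFormatError(f"sample {dup!r} appears twice in pairing file")
    return df


def read_matched_expression(
    path: str | Path, pairing: str | Path | pd.DataFrame
) -> MatchedExpressionMatrix:
    """Read a gene x sample expression TSV into a matched N/T container.

    The expression file has columns ``gene_id``, ``gene_class`` then one
    column per sample; ``pairing`` maps each sample column to a
    ``(patient_id, tissue)`` pair. Every patient must contribute exactly
    one normal and one tumor column. Column order in the file is
    irrelevant: output columns follow sorted patient id order.
    """
    if not isinstance(pairing, pd.DataFrame):
        pairing = read_pairing(pairing)
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "gene_class" not in df.columns:
        raise FileFormatError("expression file needs gene_id and gene_class columns")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FileFormatError(f"gene {dup!r} listed twice")
    gene_class = df.set_index("gene_id")["gene_class"]
    expr = df.set_index("gene_id").drop(columns=["gene_class"])

    missing_cols = set(pairing["sample"]) - set(expr.columns)
    if missing_cols:
        raise PairingError(
            f"pairing references absent sample columns: {sorted(missing_cols)}"
        )
    unmapped = set(expr.columns) - set(pairing["sample"])
    if unmapped:
        logger.warning("ignoring %d unmapped sample columns", len(unmapped))
        expr = expr.drop(columns=sorted(unmapped))

    by_patient = pairing.groupby("patient_id")["tissue"].apply(list)
    for patient, tissues in by_patient.items():
        if sorted(tissues) != ["N", "T"]:
            raise PairingError(
                f"patient {patient!r} needs exactly one N and one T sample, "
                f"got {sorted(tissues)}"
            )

    sample_of = pairing.set_index(["patient_id", "tissue"])["sample"]
    patients = sorted(by_patient.index)
    normal = expr[[sample_of[p, "N"] for p in patients]].copy()
    tumor = expr[[sample_of[p, "T"] for p in patients]].copy()
    normal.columns = patients
    tumor.columns = patients

    # disjoint lncRNA / PCG id spaces are enforced by the single
    # gene_class column; class labels themselves checked in the container
    mat = MatchedExpressionMatrix(
        normal=normal.astype(float), tumor=tumor.astype(float), gene_class=gene_class
    )
    return mat


def read_interactions(path: str | Path) -> InteractionSet:
    """Read a starBase-like miRNA-target TSV (mirna_id, target_id,
    target_class); duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna_id", "target_id", "target_class"}
    if not required.issubset(df.columns):
        raise FileFormatError(f"interaction file needs columns {sorted(required)}")
    iset = InteractionSet(df.itertuples(index=False, name=None))
    if len(iset) == 0:
        logger.warning("interaction file %s is empty", path)
    else:
        logger.info(
            "read %d interactions: %d miRNAs, %d lncRNAs, %d PCGs",
            len(iset),
            len(iset.mirnas),
            len(iset.targets("lncRNA")),
            len(iset.targets("PCG")),
        )
    return iset


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id <TAB> description <TAB> member...``.

    Duplicate members within a set collapse; a line without members is a
    format error.
    """
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise FileFormatError(f"GMT line {lineno} has no members")
            set_id, desc = parts[0], parts[1]
            if set_id in sets:
                raise FileFormatError(f"duplicate gene set id {set_id!r}")
            sets[set_id] = frozenset(p for p in parts[2:] if p.strip())
            labels[set_id] = desc
    return GeneSetCollection(sets=sets, labels=labels)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read patient_id / time / event survival TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return ClinicalTable(records=df)


def read_regions(path: str | Path) -> EnhancerRegionSet:
    """Read a 5-column BED-like region file:
    ``chrom start end enhancer_class cell_line`` (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "enhancer_class", "cell_line"],
        dtype={"chrom": str, "enhancer_class": str, "cell_line": str},
    )
    return EnhancerRegionSet(records=df)


def read_gene_coords(path: str | Path) -> GeneCoordinateTable:
    """Read gene_id / chrom / start / end / strand TSV (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return GeneCoordinateTable(records=df)


def read_hallmark_map(path: str | Path) -> pd.DataFrame:
    """Read the two-column hallmark-to-gene-set map (hallmark, set_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"hallmark", "set_id"}.issubset(df.columns):
        raise FileFormatError("hallmark map needs columns hallmark, set_id")
    return df


def write_results(result_set: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with deterministic column order.

    Floats use 17 significant digits so a round-trip read reproduces
    every numeric field to well below 1e-12.
    """
    try:
        result_set.to_csv(path, sep="\t", index=False, float_format="%.17g")
    except OSError as exc:
        raise ValidationError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
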