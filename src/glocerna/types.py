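"""Core in-memory containers.

Expression data lives in pandas DataFrames indexed by gene id with one
column per patient; the matched-cohort container keeps the normal and
tumor matrices aligned on both axes so that per-patient log2 fold changes
are a plain elementwise operation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ValidationError

LNCRNA = "lncRNA"
PCG = "PCG"
GENE_CLASSES = (LNCRNA, PCG)


@dataclass
class MatchedExpressionMatrix:
    """Paired normal/tumor expression for ``m`` genes over ``n`` patients.

    Attributes
    ----------
    normal, tumor
        ``m x n`` DataFrames of non-negative expression values, identically
        indexed by gene id (rows) and patient id (columns).
    gene_class
        Series mapping each gene id to ``"lncRNA"`` or ``"PCG"``.
    """

    normal: pd.DataFrame
    tumor: pd.DataFrame
    gene_class: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.normal.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.normal.columns

    @property
    def n_genes(self) -> int:
        return self.normal.shape[0]

    @property
    def n_patients(self) -> int:
        return self.normal.shape[1]

    def genes_of_class(self, gene_class: str) -> pd.Index:
        return self.gene_class.index[self.gene_class == gene_class]

    def validate(self) -> None:
        if self.normal.shape != self.tumor.shape:
            raise ValidationError(
                f"normal {self.normal.shape} and tumor {self.tumor.shape} "
                "matrices differ in shape"
            )
        if not self.normal.index.equals(self.tumor.index):
            raise ValidationError("normal/tumor gene ids differ")
        if not self.normal.columns.equals(self.tumor.columns):
            raise ValidationError("normal/tumor patient ids differ")
        if self.normal.index.has_duplicates:
            dup = self.normal.index[self.normal.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.normal.columns.has_duplicates:
            dup = self.normal.columns[self.normal.columns.duplicated()][0]
            raise ValidationError(f"duplicate patient id: {dup!r}")
        missing = self.normal.index.difference(self.gene_class.index)
        if len(missing):
            raise ValidationError(f"gene class undefined for {list(missing)[:5]}")
        bad = set(self.gene_class.unique()) - set(GENE_CLASSES)
        if bad:
            raise ValidationError(f"unknown gene class labels: {sorted(bad)}")
        for name, df in (("normal", self.normal), ("tumor", self.tumor)):
            vals = df.to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValidationError(f"non-finite value in {name} matrix")
            if (vals < 0).any():
                g, p = np.argwhere(vals < 0)[0]
                raise ValidationError(
                    f"negative expression in {name} matrix at gene "
                    f"{df.index[g]!r}, patient {df.columns[p]!r}"
                )


@dataclass
class RelativeExpressionMatrix:
    """Per-patient log2 fold changes (tumor minus normal), ``m x n``."""

    e: pd.DataFrame
    pseudocount: float = 0.0

    @property
    def gene_ids(self) -> pd.Index:
        return self.e.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.e.columns

    @property
    def n_patients(self) -> int:
        return self.e.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        from .exceptions import GeneLookupError

        try:
            return self.e.loc[gene_id].to_numpy(dtype=float)
        except KeyError as exc:
            raise GeneLookupError(f"unknown gene id {gene_id!r}") from exc


class InteractionSet:
    """Deduplicated miRNA-target edges with a consistent target class map.

    Parameters
    ----------
    edges
        Iterable of ``(mirna_id, target_id, target_class)`` triples;
        duplicates collapse, but a target observed with two classes is a
        hard error.
    """

    def __init__(self, edges) -> None:
        seen: set[tuple[str, str, str]] = set()
        target_class: dict[str, str] = {}
        for mirna, target, cls in edges:
            if cls not in GENE_CLASSES:
                raise ValidationError(
                    f"target class must be one of {GENE_CLASSES}, got {cls!r}"
                )
            prev = target_class.get(target)
            if prev is not None and prev != cls:
                raise ConsistencyError(
                    f"target {target!r} labelled both {prev!r} and {cls!r}"
                )
            target_class[target] = cls
            seen.add((mirna, target, cls))
        self.edges: frozenset[tuple[str, str, str]] = frozenset(seen)
        self.target_class: dict[str, str] = target_class

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionSet) and self.edges == other.edges

    @property
    def mirnas(self) -> set[str]:
        return {m for m, _, _ in self.edges}

    def targets(self, gene_class: str | None = None) -> set[str]:
        if gene_class is None:
            return {t for _, t, _ in self.edges}
        return {t for _, t, c in self.edges if c == gene_class}

    def mirnas_of_target(self, target_id: str) -> set[str]:
        return {m for m, t, _ in self.edges if t == target_id}

    def target_to_mirnas(self, gene_class: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for m, t, c in self.edges:
            if c == gene_class:
                out.setdefault(t, set()).add(m)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. cancer-hallmark GO proxies) with optional
    hallmark labels per set."""

    sets: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ClinicalTable:
    """Survival records: one row per patient with time (days) and event."""

    records: pd.DataFrame  # columns patient_id, time, event

    def __post_init__(self) -> None:
        df = self.records
        required = {"patient_id", "time", "event"}
        if not required.issubset(df.columns):
            raise ValidationError(f"clinical table needs columns {sorted(required)}")
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"duplicate patient id {dup!r} in clinical table")
        if (df["time"] <= 0).any():
            raise ValidationError("non-positive survival time")
        if not df["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 or 1")
        self.records = df.reset_index(drop=True)

    def indexed(self) -> pd.DataFrame:
        return self.records.set_index("patient_id")


@dataclass
class EnhancerRegionSet:
    """SE/TE regions per cell line, 0-based half-open coordinates."""

    records: pd.DataFrame  # columns chrom, start, end, enhancer_class, cell_line

    def __post_init__(self) -> None:
        df = self.records
        required = {"chrom", "start", "end", "enhancer_class", "cell_line"}
        if not required.issubset(df.columns):
            raise ValidationError(f"region table needs columns {sorted(required)}")
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValidationError(
                f"bad region interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if not df["enhancer_class"].isin(["SE", "TE"]).all():
            raise ValidationError("enhancer_class must be SE or TE")
        self.records = df.reset_index(drop=True)


@dataclass
class GeneCoordinateTable:
    """Gene body intervals with strand; TSS is the 5' end (strand-aware)."""

    records: pd.DataFrame  # columns gene_id, chrom, start, end, strand

    def __post_init__(self) -> None:
        df = self.records
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(df.columns):
            raise ValidationError(f"coordinate table needs columns {sorted(required)}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValidationError(f"duplicate gene id {dup!r} in coordinates")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValidationError(
                f"gene {bad['gene_id']}: start {bad['start']} >= end {bad['end']}"
            )
        if not df["strand"].isin(["+", "-"]).all():
            bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
            raise ValidationError(f"unknown strand {bad!r}")
        df = df.copy()
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
        self.records = df.reset_index(drop=True)
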