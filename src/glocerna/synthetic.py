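"""Synthetic cohort generator with planted ceRNA ground truth.

Emulates every input the pipeline consumes: a matched normal/tumor
expression cohort in which a configurable number of lncRNA-PCG pairs
carry a shared, per-patient latent fold-change signal (the ceRNA
coupling), a miRNA-target interaction table in which every planted pair
(true or decoy) shares at least one miRNA, expression-linked survival
times, SE/TE regions over a toy two-chromosome genome, a THZ1/DMSO
treatment time course with designated sensitive genes, and hallmark-like
gene sets seeded with true-pair PCGs.

The generative model for a true pair (l, g) in patient i is

    s_i ~ Rademacher(1/2)                     per-patient direction
    z_i ~ Normal(s_i * mu, sigma_signal)      shared latent log2FC
    e_l,i = z_i + Normal(0, sigma_noise)      lncRNA log2FC
    e_g,i = z_i + Normal(0, sigma_noise)      PCG log2FC

so a true pair can be concordantly up in some patients and down in
others — the tumor-heterogeneity situation the local DEC criterion is
designed for — and its population correlation is
(mu^2 + sigma_signal^2) / (mu^2 + sigma_signal^2 + sigma_noise^2).
``per_sample_signs=False`` instead fixes the sign per pair (half the
pairs up, half down), which adds a mean shift detectable by paired
differential expression but drops the planted correlation to
sigma_signal^2 / (sigma_signal^2 + sigma_noise^2). All other genes have
independent log2FC ~ Normal(0, null_fc_sd). Tumor expression is
normal * 2^log2FC over a log-normal normal-tissue baseline. Decoy pairs
share miRNAs but have independent expression, isolating the
direction-consistency criteria from the pairing criterion.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .types import (
    ClinicalTable,
    EnhancerRegionSet,
    GeneCoordinateTable,
    GeneSetCollection,
    InteractionSet,
    MatchedExpressionMatrix,
)

HALLMARKS = (
    "Sustaining proliferative signaling",
    "Resisting cell death",
    "Genome instability",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale matched cohort: 20 patients, 200
    lncRNAs and 600 PCGs, 100 true ceRNA pairs with a 4-fold mean effect
    (mu = 2 log2 units) against 900 shared-miRNA decoys, and matched
    signal/noise spreads of 0.5 log2 units.
    """

    n_patients: int = 20
    n_lncrnas: int = 200
    n_pcgs: int = 600
    n_mirnas: int | None = None  # default: one per planted pair
    n_true_pairs: int = 100
    n_decoy_pairs: int = 900
    effect_mean: float = 2.0  # mu, log2 units
    effect_sd: float = 0.5  # sigma_signal
    noise_sd: float = 0.5  # sigma_noise
    null_fc_sd: float = 0.5  # sigma0 for unplanted genes
    baseline_log_mean: float = 5.0  # log2 scale of normal tissue expression
    baseline_log_sd: float = 1.0
    hazard_beta: float = 1.5  # log-hazard per SD of the linked gene
    censor_rate: float = 0.2
    survival_scale_days: float = 730.0
    n_se_lncrnas: int = 10
    n_te_lncrnas: int = 10
    n_thz1_sensitive: int = 5
    thz1_fold: float = 2.0
    cell_lines: tuple[str, ...] = ("TE7", "KYSE510")
    per_sample_signs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_lncrnas, self.n_pcgs) < 1:
            raise ConfigError("counts must be >= 1")
        if self.n_true_pairs < 0 or self.n_decoy_pairs < 0:
            raise ConfigError("pair counts must be >= 0")
        if self.n_true_pairs > min(self.n_lncrnas, self.n_pcgs):
            raise ConfigError(
                "n_true_pairs exceeds the number of distinct genes available"
            )
        free_pairs = (self.n_lncrnas - self.n_true_pairs) * (
            self.n_pcgs - self.n_true_pairs
        )
        if self.n_decoy_pairs > free_pairs:
            raise ConfigError("n_decoy_pairs exceeds available unplanted pairs")
        for name in ("effect_sd", "noise_sd", "null_fc_sd", "baseline_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ConfigError("censor_rate must lie in [0, 1)")
        if min(self.n_se_lncrnas, self.n_te_lncrnas, self.n_thz1_sensitive) < 0:
            raise ConfigError("SE/TE/sensitive counts must be >= 0")
        # SE/TE lncRNAs are drawn from the true ce-lncRNAs; the counts
        # cap naturally at n_true_pairs for small configurations


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    true_pairs: pd.DataFrame  # lncrna_id, pcg_id, effect_sign, effect_mean
    decoy_pairs: pd.DataFrame  # lncrna_id, pcg_id
    survival_gene: str
    se_lncrnas: list[str] = field(default_factory=list)
    te_lncrnas: list[str] = field(default_factory=list)
    thz1_sensitive_genes: list[str] = field(default_factory=list)

    @property
    def true_pair_set(self) -> set[tuple[str, str]]:
        return set(
            zip(self.true_pairs["lncrna_id"], self.true_pairs["pcg_id"])
        )

    @property
    def true_lncrnas(self) -> set[str]:
        return set(self.true_pairs["lncrna_id"])


def _gene_ids(config: SyntheticConfig) -> tuple[list[str], list[str]]:
    lncs = [f"LNC{i:04d}" for i in range(config.n_lncrnas)]
    pcgs = [f"PCG{i:04d}" for i in range(config.n_pcgs)]
    return lncs, pcgs


def plan_truth(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[InteractionSet, SyntheticTruth]:
    """Choose the planted structure: true/decoy pairs, shared-miRNA
    wiring, the survival-linked gene, SE/TE lncRNAs and THZ1-sensitive
    genes. Expression is sampled separately so several cohorts can share
    one truth."""
    lncs, pcgs = _gene_ids(config)
    true_lncs = list(rng.choice(lncs, size=config.n_true_pairs, replace=False))
    true_pcgs = list(rng.choice(pcgs, size=config.n_true_pairs, replace=False))
    signs = np.ones(config.n_true_pairs, dtype=int)
    signs[config.n_true_pairs // 2 :] = -1
    true_pairs = pd.DataFrame(
        {
            "lncrna_id": true_lncs,
            "pcg_id": true_pcgs,
            "effect_sign": signs,
            "effect_mean": config.effect_mean,
        }
    )

    free_lncs = sorted(set(lncs) - set(true_lncs))
    free_pcgs = sorted(set(pcgs) - set(true_pcgs))
    n_free = len(free_lncs) * len(free_pcgs)
    decoy_idx = rng.choice(n_free, size=config.n_decoy_pairs, replace=False)
    decoy_pairs = pd.DataFrame(
        {
            "lncrna_id": [free_lncs[i // len(free_pcgs)] for i in decoy_idx],
            "pcg_id": [free_pcgs[i % len(free_pcgs)] for i in decoy_idx],
        }
    )

    # one dedicated miRNA per planted pair guarantees every true and
    # decoy pair (and nothing else) shares >= 1 miRNA
    planted = pd.concat(
        [true_pairs[["lncrna_id", "pcg_id"]], decoy_pairs], ignore_index=True
    )
    n_mirnas = config.n_mirnas or len(planted)
    if n_mirnas < len(planted):
        raise ConfigError("n_mirnas must cover one miRNA per planted pair")
    edges = []
    for i, row in planted.iterrows():
        mir = f"miR-{i:04d}"
        edges.append((mir, row["lncrna_id"], "lncRNA"))
        edges.append((mir, row["pcg_id"], "PCG"))
    # surplus miRNAs target a single gene each: no extra pairs arise
    for j in range(len(planted), n_mirnas):
        edges.append((f"miR-{j:04d}", lncs[j % len(lncs)], "lncRNA"))
    interactions = InteractionSet(edges)

    se = true_lncs[: config.n_se_lncrnas]
    te = true_lncs[config.n_se_lncrnas : config.n_se_lncrnas + config.n_te_lncrnas]
    sensitive = (se + te)[: config.n_thz1_sensitive]
    truth = SyntheticTruth(
        true_pairs=true_pairs,
        decoy_pairs=decoy_pairs,
        survival_gene=true_lncs[0] if true_lncs else lncs[0],
        se_lncrnas=se,
        te_lncrnas=te,
        thz1_sensitive_genes=sensitive,
    )
    return interactions, truth


def sample_expression(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> MatchedExpressionMatrix:
    """Draw one matched N/T cohort for a planted truth."""
    lncs, pcgs = _gene_ids(config)
    genes = lncs + pcgs
    m, n = len(genes), config.n_patients
    row_of = {g: i for i, g in enumerate(genes)}

    normal = 2.0 ** rng.normal(config.baseline_log_mean, config.baseline_log_sd, (m, n))
    log2fc = rng.normal(0.0, config.null_fc_sd, (m, n))
    for _, pair in truth.true_pairs.iterrows():
        if config.per_sample_signs:
            signs = rng.choice([-1.0, 1.0], size=n)
        else:
            signs = np.full(n, float(pair["effect_sign"]))
        z = rng.normal(signs * pair["effect_mean"], config.effect_sd)
        log2fc[row_of[pair["lncrna_id"]]] = z + rng.normal(0, config.noise_sd, n)
        log2fc[row_of[pair["pcg_id"]]] = z + rng.normal(0, config.noise_sd, n)
    tumor = normal * 2.0**log2fc

    patients = [f"P{i:03d}" for i in range(n)]
    gene_class = pd.Series(
        ["lncRNA"] * len(lncs) + ["PCG"] * len(pcgs), index=genes
    )
    return MatchedExpressionMatrix(
        normal=pd.DataFrame(normal, index=genes, columns=patients),
        tumor=pd.DataFrame(tumor, index=genes, columns=patients),
        gene_class=gene_class,
    )


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[MatchedExpressionMatrix, InteractionSet, SyntheticTruth]:
    """One matched cohort plus interactions and ground truth,
    deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    interactions, truth = plan_truth(config, rng)
    matrix = sample_expression(config, truth, rng)
    return matrix, interactions, truth


def generate_paired_cohorts(
    config: SyntheticConfig, n_cohorts: int = 2
) -> tuple[list[MatchedExpressionMatrix], InteractionSet, SyntheticTruth]:
    """Several independent expression cohorts sharing one planted truth —
    the two-dataset robustness design."""
    rng = np.random.default_rng(config.seed)
    interactions, truth = plan_truth(config, rng)
    cohorts = [sample_expression(config, truth, rng) for _ in range(n_cohorts)]
    return cohorts, interactions, truth


def generate_clinical(
    config: SyntheticConfig,
    matrix: MatchedExpressionMatrix,
    truth: SyntheticTruth,
) -> ClinicalTable:
    """Survival times exponentially distributed with log-hazard
    ``hazard_beta`` per standard deviation of the linked gene's tumor
    expression; censoring is independent at ``censor_rate``."""
    rng = np.random.default_rng([config.seed, 7])
    expr = matrix.tumor.loc[truth.survival_gene].to_numpy(dtype=float)
    z = (expr - expr.mean()) / expr.std() if expr.std() > 0 else np.zeros_like(expr)
    rate = np.exp(config.hazard_beta * z) / config.survival_scale_days
    times = rng.exponential(1.0 / rate)
    events = np.ones(len(times), dtype=int)
    censored = rng.random(len(times)) < config.censor_rate
    times = np.where(censored, times * rng.uniform(0.05, 1.0, len(times)), times)
    events[censored] = 0
    return ClinicalTable(
        records=pd.DataFrame(
            {
                "patient_id": list(matrix.patient_ids),
                "time": np.maximum(times, 1e-3),
                "event": events,
            }
        )
    )


def generate_gene_coords(config: SyntheticConfig) -> GeneCoordinateTable:
    """Toy two-chromosome genome: genes 1 kb long, spaced 200 kb apart,
    alternating chromosome and strand."""
    lncs, pcgs = _gene_ids(config)
    genes = lncs + pcgs
    rows = []
    for i, gid in enumerate(genes):
        chrom = f"chr{1 + i % 2}"
        start = 100_000 + (i // 2) * 200_000
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "start": start,
                "end": start + 1_000,
                "strand": "+" if i % 4 < 2 else "-",
            }
        )
    return GeneCoordinateTable(records=pd.DataFrame(rows))


def generate_regions(
    config: SyntheticConfig,
    coords: GeneCoordinateTable,
    truth: SyntheticTruth,
) -> EnhancerRegionSet:
    """SE regions overlapping each planted SE lncRNA's body and TE
    regions overlapping each planted TE lncRNA, in every cell line."""
    coord = coords.records.set_index("gene_id")
    rows = []
    for line in config.cell_lines:
        for cls, genes in (("SE", truth.se_lncrnas), ("TE", truth.te_lncrnas)):
            for gid in genes:
                g = coord.loc[gid]
                rows.append(
                    {
                        "chrom": g["chrom"],
                        "start": int(g["start"]) + 200,
                        "end": int(g["start"]) + 800,
                        "enhancer_class": cls,
                        "cell_line": line,
                    }
                )
    return EnhancerRegionSet(records=pd.DataFrame(rows))


def generate_timecourse(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    cell_line: str,
    n_inactive: int = 3,
) -> pd.DataFrame:
    """THZ1/DMSO time course for the SE/TE lncRNAs of one cell line.

    Sensitive genes get a 12 h THZ1 value equal to DMSO divided by
    ``thz1_fold`` (> the 1.5 cutoff); other active genes keep fold
    change exactly 1; ``n_inactive`` extra genes sit below the FPKM > 1
    activity floor and must be excluded downstream.
    """
    rng = np.random.default_rng(
        [config.seed, 11, zlib.crc32(cell_line.encode()) % 2**31]
    )
    genes = list(truth.se_lncrnas) + list(truth.te_lncrnas)
    sensitive = set(truth.thz1_sensitive_genes)
    inactive = [f"LOWEXP{i:02d}" for i in range(n_inactive)]
    timepoints = (2, 4, 6, 8, 12)
    rows = []
    for gid in genes + inactive:
        dmso_level = 0.5 if gid in inactive else float(rng.uniform(5, 50))
        for tp in timepoints:
            rows.append(
                {
                    "gene_id": gid,
                    "treatment": "DMSO",
                    "timepoint": tp,
                    "value": dmso_level,
                }
            )
            if gid in sensitive:
                frac = tp / 12.0
                value = dmso_level / (1.0 + (config.thz1_fold - 1.0) * frac)
            else:
                value = dmso_level
            rows.append(
                {
                    "gene_id": gid,
                    "treatment": "THZ1",
                    "timepoint": tp,
                    "value": value,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "treatment", "timepoint", "value"])


def generate_gene_sets(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Hallmark-like GO gene sets over the PCG universe: two sets seeded
    with true-pair PCGs (so the ceRNA network enriches them) and four
    background sets of random PCGs, with a hallmark -> set map."""
    rng = np.random.default_rng([config.seed, 13])
    _, pcgs = _gene_ids(config)
    true_pcgs = list(truth.true_pairs["pcg_id"])
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    half = max(len(true_pcgs) // 2, 1)
    sets["GO:0000001"] = frozenset(true_pcgs[:half])
    sets["GO:0000002"] = frozenset(
        true_pcgs[half:] or true_pcgs[:1]
    ) | frozenset(rng.choice(pcgs, size=10, replace=False))
    for i in range(3, 7):
        sets[f"GO:{i:07d}"] = frozenset(rng.choice(pcgs, size=30, replace=False))
    for i, sid in enumerate(sorted(sets)):
        labels[sid] = HALLMARKS[i % len(HALLMARKS)]
    hallmark_map = pd.DataFrame(
        {"hallmark": [labels[s] for s in sorted(sets)], "set_id": sorted(sets)}
    )
    return GeneSetCollection(sets=sets, labels=labels), hallmark_map


# ---------------------------------------------------------------------------
# file emission for the CLI / pipeline


def write_expression(
    matrix: MatchedExpressionMatrix, expr_path: Path, pairing_path: Path
) -> None:
    """Write the matched cohort as an expression TSV plus pairing TSV."""
    cols = {}
    pairing_rows = []
    for p in matrix.patient_ids:
        for tissue, df in (("N", matrix.normal), ("T", matrix.tumor)):
            sample = f"{p}_{tissue}"
            cols[sample] = df[p]
            pairing_rows.append({"sample": sample, "patient_id": p, "tissue": tissue})
    out = pd.DataFrame(cols)
    out.insert(0, "gene_class", matrix.gene_class.loc[out.index])
    out.insert(0, "gene_id", out.index)
    out.to_csv(expr_path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(pairing_rows).to_csv(pairing_path, sep="\t", index=False)


def simulate_to_dir(config: SyntheticConfig, outdir: str | Path) -> dict[str, str]:
    """Emit every synthetic input as plain-text files; returns a manifest
    of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, interactions, truth = generate_cohort(config)

    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    write_expression(matrix, _p("expression.tsv"), _p("pairing.tsv"))
    pd.DataFrame(
        sorted(interactions.edges), columns=["mirna_id", "target_id", "target_class"]
    ).to_csv(_p("interactions.tsv"), sep="\t", index=False)

    clinical = generate_clinical(config, matrix, truth)
    clinical.records.to_csv(_p("clinical.tsv"), sep="\t", index=False)

    coords = generate_gene_coords(config)
    coords.records[["gene_id", "chrom", "start", "end", "strand"]].to_csv(
        _p("gene_coords.tsv"), sep="\t", index=False
    )
    regions = generate_regions(config, coords, truth)
    regions.records[["chrom", "start", "end", "enhancer_class", "cell_line"]].to_csv(
        _p("regions.bed"), sep="\t", index=False, header=False
    )

    for line in config.cell_lines:
        tc = generate_timecourse(config, truth, line)
        tc.to_csv(_p(f"timecourse_{line}.tsv"), sep="\t", index=False)

    collection, hallmark_map = generate_gene_sets(config, truth)
    with open(_p("hallmarks.gmt"), "w") as fh:
        for sid in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[sid]))
            fh.write(f"{sid}\t{collection.labels[sid]}\t{members}\n")
    hallmark_map.to_csv(_p("hallmark_map.tsv"), sep="\t", index=False)

    truth_json = {
        "true_pairs": truth.true_pairs.to_dict(orient="records"),
        "decoy_pairs": truth.decoy_pairs.to_dict(orient="records"),
        "survival_gene": truth.survival_gene,
        "se_lncrnas": truth.se_lncrnas,
        "te_lncrnas": truth.te_lncrnas,
        "thz1_sensitive_genes": truth.thz1_sensitive_genes,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
    }
    with open(_p("truth.json"), "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return paths
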