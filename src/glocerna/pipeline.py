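"""End-to-end orchestration: simulate -> pairs -> score -> network ->
enrichment -> survival -> enhancers -> THZ1, driven by one config.

Every stage writes plain TSV artifacts; the manifest records each
artifact's path, row count and SHA-256 plus a hash of the configuration,
so a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enhancers as enh
from . import enrichment as enr
from . import io as gio
from . import network as net_mod
from . import survival as surv
from .core import GloceRNAConfig, ce_lncrnas, run_glocerna
from .exceptions import GlocernaError
from .pairing import build_candidate_pairs, shared_mirna_test
from .synthetic import SyntheticConfig, simulate_to_dir

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pairs", "run", "network", "enrich", "survival", "enhancers", "thz1")


@dataclass
class RunConfig:
    """One-file description of a pipeline run."""

    outdir: str = "glocerna_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    glocerna: GloceRNAConfig = field(default_factory=GloceRNAConfig)
    stages: dict[str, bool] = field(default_factory=dict)
    thz1_fold_cutoff: float = 1.5
    thz1_timepoint: float = 12.0
    thz1_require_shared: bool = True
    proximal_window: int = 50_000

    def __post_init__(self) -> None:
        self.synthetic.seed = self.seed
        for name in self.stages:
            if name not in STAGES:
                raise GlocernaError(f"unknown stage {name!r}")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        glo = GloceRNAConfig(**raw.pop("glocerna", {}))
        return cls(synthetic=syn, glocerna=glo, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["cell_lines"] = list(d["synthetic"]["cell_lines"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: RunConfig) -> None:
        self.outdir = outdir
        self.data: dict = {
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "artifacts": {},
            "stages_completed": [],
            "error": None,
        }

    def add(self, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / f"{name}.tsv"
        gio.write_results(df, path)
        self.data["artifacts"][name] = {
            "path": str(path),
            "rows": int(len(df)),
            "sha256": _sha256(path),
        }
        return path

    def add_file(self, name: str, path: Path, rows: int | None = None) -> None:
        self.data["artifacts"][name] = {
            "path": str(path),
            "rows": rows,
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the
    manifest dict (also written to ``<outdir>/manifest.json``).

    A stage failure aborts all downstream stages; the partial manifest
    is still written before the error propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)

    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:
        manifest.data["error"] = str(exc)
        manifest.write()
        raise
    manifest.write()
    return manifest.data


def _run_stages(config: RunConfig, outdir: Path, manifest: _Manifest) -> None:
    from .synthetic import (
        generate_clinical,
        generate_cohort,
        generate_gene_coords,
        generate_gene_sets,
        generate_regions,
        generate_timecourse,
    )

    syn = config.synthetic

    if not config.enabled("simulate"):
        raise GlocernaError("pipeline requires the simulate stage for its inputs")
    input_dir = outdir / "inputs"
    paths = simulate_to_dir(syn, input_dir)
    for name, p in paths.items():
        manifest.add_file(f"input:{name}", Path(p))
    manifest.data["stages_completed"].append("simulate")

    # read the inputs back through the I/O layer so the pipeline
    # exercises exactly what an external run would
    matrix = gio.read_matched_expression(
        paths["expression.tsv"], paths["pairing.tsv"]
    )
    interactions = gio.read_interactions(paths["interactions.tsv"])
    _, _, truth = generate_cohort(syn)

    results = None
    network = None

    if config.enabled("pairs"):
        pairs = build_candidate_pairs(interactions)
        hyper = shared_mirna_test(pairs, interactions)
        manifest.add("pairs", hyper)
        manifest.data["stages_completed"].append("pairs")
    else:
        pairs = build_candidate_pairs(interactions)

    if config.enabled("run"):
        results = run_glocerna(matrix, pairs, config.glocerna)
        manifest.add("results", results)
        manifest.data["stages_completed"].append("run")

    if config.enabled("network") and results is not None:
        network = net_mod.build_network(results)
        manifest.add("network_edges", net_mod.edge_table(network))
        manifest.add("topology", net_mod.topology_table(network))
        manifest.add("similarity", net_mod.lncrna_similarity(network))
        manifest.data["stages_completed"].append("network")

    if config.enabled("enrich") and network is not None:
        collection, hallmark_map = generate_gene_sets(syn, truth)
        universe = {p.pcg_id for p in pairs}
        table = enr.hallmark_enrichment(network, collection, universe)
        manifest.add("enrichment", table)
        per_table, counts = enr.per_lncrna_hallmarks(network, collection, universe)
        manifest.add("per_lncrna_enrichment", per_table)
        manifest.add(
            "lncrna_hallmark_counts",
            counts.rename_axis("lncrna_id").reset_index(),
        )
        manifest.data["stages_completed"].append("enrich")

    if config.enabled("survival") and results is not None:
        clinical = gio.read_clinical(paths["clinical.tsv"])
        functional = results.loc[results["functional"]]
        targets: list = sorted(
            set(functional["lncrna_id"]) | set(functional["pcg_id"])
        )
        targets += list(zip(functional["lncrna_id"], functional["pcg_id"]))
        screen = surv.survival_screen(targets, matrix.tumor, clinical)
        manifest.add("survival", screen)
        manifest.data["stages_completed"].append("survival")

    assignments = None
    if config.enabled("enhancers"):
        coords = generate_gene_coords(syn)
        regions = generate_regions(syn, coords, truth)
        assignments = enh.assign_enhancers(regions, coords, config.proximal_window)
        manifest.add("enhancer_assignments", assignments)
        if results is not None:
            labels, _ = enh.label_se_te_lncrnas(assignments, ce_lncrnas(results))
            manifest.add(
                "se_te_labels",
                pd.DataFrame(
                    {"lncrna_id": list(labels), "label": list(labels.values())}
                ),
            )
        manifest.data["stages_completed"].append("enhancers")

    if config.enabled("thz1") and network is not None and assignments is not None:
        labels, _ = enh.label_se_te_lncrnas(assignments, ce_lncrnas(results))
        se_te = [l for l, lab in labels.items() if lab in ("SE", "TE")]
        sens_by_line = {}
        for line in syn.cell_lines:
            tc = generate_timecourse(syn, truth, line)
            sens = enh.thz1_sensitive(
                tc,
                genes=se_te,
                fold_cutoff=config.thz1_fold_cutoff,
                timepoint=config.thz1_timepoint,
            )
            sens_by_line[line] = sens
            manifest.add(f"thz1_sensitivity_{line}", sens)
        sub = enh.thz1_network(
            sens_by_line, network, require_shared=config.thz1_require_shared
        )
        manifest.add("thz1_network_edges", net_mod.edge_table(sub))
        manifest.data["stages_completed"].append("thz1")
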