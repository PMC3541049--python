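"""End-to-end orchestration: simulate -> digest -> process -> assign ->
cluster -> stats -> geochem, with one master seed, parameter echo in
every output header, and a JSON run manifest.

Each stage writes its intermediate in the documented text formats, so
any stage can be re-run individually from files with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import community as community_mod
from .digest import DEFAULT_ENZYMES, FORWARD, PrimerPair, write_fasta, write_signature_table
from .peaks import (
    BinTable,
    bin_across_samples,
    consensus_duplicates,
    denoise,
    export_window,
    write_peak_table,
)
from .synthetic import (
    DYE_TO_END,
    FORWARD_DYE,
    REVERSE_DYE,
    NoiseSpec,
    simulate_study,
)
from .thermo import (
    CONDITIONS,
    REACTIONS,
    ThermoTable,
    delta_g_prime,
    records_to_frame,
    select_reduced,
    write_enrichment_table,
)

__all__ = ["RunConfig", "run_all", "process_profiles"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full run; all stage randomness derives
    from the single master seed."""

    seed: int = 0
    outdir: str = "trflp_run"
    # generator
    carbons: tuple = ("acetate", "lactate", "glucose")
    minerals: tuple = ("ferrihydrite", "goethite", "hematite")
    n_dilutions: int = 5
    taxa_per_pool: int = 5
    concentration: float = 5.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_replicates: int = 2
    amplicon_length: int = 1450
    # peak processing
    window_low: float = 50.0
    window_high: float = 550.0
    denoise_k: float = 3.0
    replicate_tol: float = 0.5
    bin_gap: float = 1.0
    # assignment / clustering / selection
    assign_tol: float = 1.0
    cut_height: float = 0.7
    selection_threshold: float = 10.0

    def validate(self) -> None:
        if self.window_low > self.window_high:
            raise ValueError("window_low exceeds window_high")
        for name in ("denoise_k", "replicate_tol", "bin_gap", "assign_tol",
                     "cut_height", "selection_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.taxa_per_pool < 1 or self.n_replicates < 1:
            raise ValueError("taxa_per_pool and n_replicates must be >= 1")


def process_profiles(profiles, config: RunConfig):
    """Window -> denoise -> duplicate consensus -> cross-sample binning.

    Returns {(enzyme, end): BinTable} keyed on the six digests.
    """
    cleaned: dict = {}
    for p in profiles:
        q = denoise(
            export_window(p, config.window_low, config.window_high), config.denoise_k
        )
        cleaned.setdefault(p.key(), {})[p.replicate] = q
    consensus_by_digest: dict = {}
    for (sid, enzyme, dye), reps in cleaned.items():
        ordered = [reps[r] for r in sorted(reps)]
        cons = ordered[0]
        for other in ordered[1:]:
            cons = consensus_duplicates(cons, other, config.replicate_tol)
        consensus_by_digest.setdefault((enzyme, DYE_TO_END[dye]), []).append(cons)
    return {
        key: bin_across_samples(profs, config.bin_gap, enzyme=key[0], dye=key[1])
        for key, profs in consensus_by_digest.items()
    }


def _write_bin_table(bt: BinTable, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# enzyme={bt.enzyme} end={bt.dye} gap={config.bin_gap} "
            f"k={config.denoise_k} window={config.window_low}-{config.window_high} "
            f"seed={config.seed}\n"
        )
        bt.table.to_csv(fh, sep="\t", float_format="%.6g")


def run_all(config: RunConfig) -> dict:
    """Execute the full stage sequence; returns the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            k: (asdict(v) if isinstance(v, NoiseSpec) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                outputs = fn()
            except Exception as exc:  # surface the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = [str(p) for p in outputs]
            logger.info("stage %s -> %s", name, outputs)
            return outputs
        return wrap

    primers = PrimerPair()
    study = simulate_study(
        seed=config.seed,
        carbons=config.carbons,
        minerals=config.minerals,
        n_dilutions=config.n_dilutions,
        taxa_per_pool=config.taxa_per_pool,
        concentration=config.concentration,
        noise=config.noise,
        n_replicates=config.n_replicates,
        amplicon_length=config.amplicon_length,
        primers=primers,
    )

    @stage("simulate")
    def _simulate():
        fasta = out / "phylotypes.fasta"
        peaks = out / "peaks.tsv"
        enrich = out / "enrichments.tsv"
        meta = out / "samples.tsv"
        write_fasta(study.records, fasta)
        write_peak_table(study.profiles, peaks, comment=f"seed={config.seed}")
        write_enrichment_table(study.fe_records, enrich, comment=f"seed={config.seed}")
        study.metadata.to_csv(meta, sep="\t", index=False)
        return [fasta, peaks, enrich, meta]

    @stage("digest")
    def _digest():
        path = out / "signatures.tsv"
        write_signature_table(study.records, path, primers)
        return [path]

    bin_tables = process_profiles(study.profiles, config)

    @stage("process")
    def _process():
        paths = []
        for (enzyme, end), bt in sorted(bin_tables.items()):
            path = out / f"bins_{enzyme}_{end}.tsv"
            _write_bin_table(bt, path, config)
            paths.append(path)
        return paths

    library = assign_mod.SignatureLibrary.from_records(study.records, primers)
    matrix = assign_mod.build_matrix(bin_tables, library, tol=config.assign_tol)

    @stage("assign")
    def _assign():
        path = out / "community_matrix.tsv"
        with open(path, "w") as fh:
            fh.write(f"# tol={config.assign_tol} seed={config.seed}\n")
            df = matrix.abundance.copy()
            df["unknown"] = matrix.unknown
            df.to_csv(fh, sep="\t", float_format="%.6g")
        return [path]

    primary = bin_tables[(DEFAULT_ENZYMES[0].name, FORWARD)]
    dm = community_mod.bray_curtis(primary)
    tree = community_mod.upgma(dm)
    clusters = community_mod.cut_tree(tree, config.cut_height)
    ccc = community_mod.cophenetic_correlation(dm, tree)

    @stage("cluster")
    def _cluster():
        nwk = out / "dendrogram.nwk"
        cl = out / "clusters.tsv"
        dmat = out / "bray_curtis.tsv"
        nwk.write_text(community_mod.to_newick(tree) + "\n")
        with open(cl, "w") as fh:
            fh.write(f"# cut_height={config.cut_height} cophenetic_correlation={ccc:.4f}\n")
            clusters.to_csv(fh, sep="\t")
        with open(dmat, "w") as fh:
            fh.write(f"# Bray-Curtis over {DEFAULT_ENZYMES[0].name} {FORWARD} bins\n")
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
                fh, sep="\t", float_format="%.6g"
            )
        return [nwk, cl, dmat]

    meta = study.metadata.set_index("sample_id")
    meta.index = meta.index.astype(str)

    @stage("stats")
    def _stats():
        path = out / "kruskal_wallis.tsv"
        carbon = meta["carbon"]
        by_cluster = community_mod.kruskal_by_factor(
            matrix, carbon, response="cluster", clusters=clusters
        )
        by_abundance = community_mod.kruskal_by_factor(matrix, carbon)
        df = pd.concat([by_cluster, by_abundance], ignore_index=True)
        with open(path, "w") as fh:
            fh.write("# factor=carbon; response=cluster membership, then per-bin abundance\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        return [path]

    @stage("fe-select")
    def _select():
        path = out / "fe_selection.tsv"
        selected, tallies = select_reduced(study.fe_records, config.selection_threshold)
        with open(path, "w") as fh:
            fh.write(
                f"# threshold={config.selection_threshold} "
                f"n_selected={len(selected)} n_total={len(study.fe_records)}\n"
            )
            tallies.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        return [path]

    @stage("thermo")
    def _thermo():
        path = out / "thermo.tsv"
        table = ThermoTable.default()
        rows = [
            {"reaction": "acetate_goethite", "conditions": "acetate_enrichment"},
            {"reaction": "lactate_goethite", "conditions": "lactate_enrichment"},
            {"reaction": "lactate_sulfate", "conditions": "lactate_enrichment"},
        ]
        for row in rows:
            row["energy_yield_kj_per_mol"] = delta_g_prime(
                REACTIONS[row["reaction"]], table, CONDITIONS[row["conditions"]]
            )
        with open(path, "w") as fh:
            fh.write("# positive = thermodynamically favorable, per mole of donor\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.4f")
        return [path]

    manifest["cophenetic_correlation"] = ccc
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
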