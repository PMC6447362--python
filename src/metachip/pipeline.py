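"""End-to-end orchestration: simulate/load -> filter -> profile -> enrich.

A run is driven by a single :class:`RunConfig` (optionally read from YAML),
executes the stages in dependency order and writes machine-parseable outputs
to the run directory:

* ``rpkm.tsv`` — per-gene counts, RPKM and expression class
* ``metagene.tsv`` — per-track, per-stratum averaged profiles
* ``enrichment.tsv`` — one row per exon–intron–exon triplet
* ``percent_profiles.tsv`` — exon/intron percent-of-length enrichment
* ``summary.json`` — rank-sum tests, box stats, correlations, drop counts
* ``run_manifest.json`` — everything needed to reproduce the run

On a stage failure the partially written outputs of this run are removed
before the error propagates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .annotations import (
    AnalysisParams,
    derive_all_triplets,
    filter_genes,
    parse_refgene,
)
from .coverage import read_bedgraph, track_total
from .enrichment import (
    exon_correlation,
    exon_vs_intron_summary,
    percent_length_profile,
    triplet_enrichment,
)
from .expression import expression_table, read_bed_reads
from .metagene import gene_profiles, metagene_average, write_metagene_tsv
from .simulate import SimulationSpec, simulate, write_dataset

log = logging.getLogger("metachip")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    params: AnalysisParams = field(default_factory=AnalysisParams)
    simulation: Optional[SimulationSpec] = None
    chip_bedgraph: Optional[str] = None    # UPF1-like track
    pol2_bedgraph: Optional[str] = None
    input_bedgraph: Optional[str] = None
    reads_bed: Optional[str] = None
    reads_total_mapped: Optional[int] = None  # library size for RPKM; default: n reads supplied
    annotation: Optional[str] = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        params = AnalysisParams(**raw.pop("params", {}))
        sim_raw = raw.pop("simulation", None)
        seed = raw.get("seed", 0)
        sim = None
        if sim_raw is not None:
            sim_raw.setdefault("seed", seed)
            for key in ("exon_count_range", "exon_bp_range", "intron_bp_range", "gap_bp_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = SimulationSpec(**sim_raw)
        return cls(params=params, simulation=sim, **raw)

    def validate(self) -> None:
        if self.simulation is None:
            missing = [
                name
                for name in ("chip_bedgraph", "input_bedgraph", "annotation")
                if getattr(self, name) is None
            ]
            if missing:
                raise ConfigError(
                    f"simulation disabled and required inputs missing: {', '.join(missing)}"
                )
            for name in ("chip_bedgraph", "pol2_bedgraph", "input_bedgraph", "reads_bed", "annotation"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _ranksum_dict(r) -> dict:
    return {
        "U": r.u_statistic,
        "z": r.z_value,
        "p_value": r.p_value,
        "method": r.method,
        "n1": r.n1,
        "n2": r.n2,
    }


def run(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    params = config.params

    def _register(path: Path) -> Path:
        written.append(path)
        return path

    try:
        # ---- stage: inputs -------------------------------------------------
        if config.simulation is not None:
            log.info("stage simulate: %d genes, seed %d", config.simulation.n_genes, config.simulation.seed)
            data = simulate(config.simulation)
            sim_paths = write_dataset(data, out / "sim")
            written.extend(Path(p) for p in sim_paths.values())
            genes = data.genes
            chip = data.tracks["upf1"]
            pol2 = data.tracks.get("pol2")
            input_track = data.tracks["input"]
            reads = data.rna_reads
            if config.reads_total_mapped is None:
                config.reads_total_mapped = data.rna_declared_total
        else:
            log.info("stage load: reading tracks and annotation")
            genes = parse_refgene(config.annotation)
            chip = read_bedgraph(config.chip_bedgraph, label="chip")
            input_track = read_bedgraph(config.input_bedgraph, label="input")
            pol2 = read_bedgraph(config.pol2_bedgraph, label="pol2") if config.pol2_bedgraph else None
            reads = read_bed_reads(config.reads_bed) if config.reads_bed else []

        # ---- stage: filter -------------------------------------------------
        kept = filter_genes(genes, params)
        log.info("stage filter: %d/%d genes isolated and uniquely named", len(kept), len(genes))

        # ---- stage: expression --------------------------------------------
        strata: dict[str, list] = {}
        if reads:
            table, stats = expression_table(
                reads, kept, params, total_mapped=config.reads_total_mapped
            )
            path = _register(out / "rpkm.tsv")
            table.to_csv(path, sep="\t", index=False)
            class_of = dict(zip(table["gene"], table["activity_class"]))
            strata = {
                "active": [g for g in kept if class_of[g.name] in ("active", "high")],
                "inactive": [g for g in kept if class_of[g.name] == "inactive"],
                "high": [g for g in kept if class_of[g.name] == "high"],
            }
            expression_stats = {
                "assigned": stats.assigned,
                "ambiguous": stats.ambiguous,
                "no_feature": stats.no_feature,
                "n_active": len(strata["active"]),
                "n_inactive": len(strata["inactive"]),
                "n_high": len(strata["high"]),
            }
            log.info("stage expression: %s", expression_stats)
        else:
            strata = {"all": list(kept)}
            expression_stats = {"note": "no reads supplied; single stratum 'all'"}

        # ---- stage: metagene ----------------------------------------------
        named_tracks = [("chip", chip), ("input", input_track)]
        if pol2 is not None:
            named_tracks.append(("pol2", pol2))
        metagenes = []
        normalisers = {}
        for tname, track in named_tracks:
            summary = track_total(track, read_length_bp=params.read_length_bp)
            normalisers[tname] = {
                "total_signal": summary.total_signal,
                "normaliser": summary.normaliser,
                "basis": summary.basis,
            }
            for sname, members in strata.items():
                if not members:
                    continue
                profiles, skipped = gene_profiles(track, members, params)
                if not profiles:
                    continue
                metagenes.append(metagene_average(profiles, summary, stratum=f"{tname}:{sname}"))
        path = _register(out / "metagene.tsv")
        with open(path, "w") as fh:
            write_metagene_tsv(metagenes, fh, params)
        log.info("stage metagene: %d curves", len(metagenes))

        # ---- stage: enrichment ---------------------------------------------
        triplets = derive_all_triplets(kept, params)
        enrich_summary: dict = {"note": "no triplets (single-exon or short-intron genes only)"}
        percent_rows: list[tuple] = []
        if triplets:
            result = triplet_enrichment(chip, input_track, triplets, read_length_bp=params.read_length_bp)
            path = _register(out / "enrichment.tsv")
            result.to_frame().to_csv(path, sep="\t", index=False)
            if result.n_retained >= 2:
                summary = exon_vs_intron_summary(result)
                enrich_summary = {
                    "tests": {k: _ranksum_dict(v) for k, v in summary["tests"].items()},
                    "box": summary["box"],
                    "n_triplets": summary["n_triplets"],
                    "n_dropped_zero_input": summary["n_dropped_zero_input"],
                    "n_dropped_zero_chip": summary["n_dropped_zero_chip"],
                }
            exons = [t for g in kept for t in g.exons]
            introns = [t.intron for t in triplets]
            for fclass, feats in (("exon", exons), ("intron", introns)):
                if not feats:
                    continue
                prof = percent_length_profile(
                    chip, input_track, feats, feature_class=fclass,
                    read_length_bp=params.read_length_bp,
                )
                for pct, val in enumerate(prof.mean):
                    percent_rows.append((pct, fclass, val, prof.n_features))
            path = _register(out / "percent_profiles.tsv")
            with open(path, "w") as fh:
                fh.write("percent\tfeature_class\tmean_enrichment\tn_features\n")
                for pct, fclass, val, n in percent_rows:
                    fh.write(f"{pct}\t{fclass}\t{val:.6g}\t{n}\n")
            log.info("stage enrichment: %d triplets", len(triplets))

        # ---- stage: correlation ---------------------------------------------
        correlation = None
        if pol2 is not None and len(kept) >= 3:
            report = exon_correlation(chip, pol2, kept, read_length_bp=params.read_length_bp)
            path = _register(out / "exon_correlation.tsv")
            report["table"].to_csv(path, sep="\t", index=False)
            correlation = {k: v for k, v in report.items() if k != "table"}
            log.info("stage correlate: pearson r=%.3f over %d exons",
                     correlation["pearson_r"], correlation["n_exons"])

        # ---- summary & manifest ---------------------------------------------
        summary_json = {
            "enrichment": enrich_summary,
            "expression": expression_stats,
            "correlation": correlation,
            "normalisers": normalisers,
            "n_genes_input": len(genes),
            "n_genes_kept": len(kept),
            "seed": config.seed,
        }
        path = _register(out / "summary.json")
        path.write_text(json.dumps(summary_json, indent=1, sort_keys=True, default=float))

        manifest = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "params": dataclasses.asdict(params),
            "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
            "normalisers": normalisers,
            "outputs": sorted(str(p) for p in written),
        }
        mpath = out / "run_manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
        return manifest
    except Exception:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise
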