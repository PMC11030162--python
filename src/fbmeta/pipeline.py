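"""End-to-end orchestration: simulate -> tpm -> taxonomy -> classify ->
modules -> cazymes, with a manifest recording config hash, seed and file
checksums so reruns are verifiably byte-identical."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io_formats
from .cazyme_profile import (
    build_profile,
    group_targets_below,
    load_substrate_map,
    target_share_table,
)
from .kegg_modules import nitrogenase_screen, screen_modules
from .quantify import CountMatrix, compute_tpm, filter_kofam
from .sample_status import StatusThresholds, classify_samples
from .synthetic_data import default_spec, generate, load_default_modules, write_bundle
from .taxonomy import aggregate_by_rank, assign_best_hit, group_below_threshold

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: Path = Path("fbmeta_run")
    focal: str = "Fomes"
    rank: str = "family"
    cazyme_rank: str = "phylum"
    below_threshold: float = 0.01
    wildcard_satisfied: bool = True
    iterations: int = 1000
    thresholds: StatusThresholds = field(default_factory=StatusThresholds)
    simulate: dict | None = None  # n_healthy, n_rotten, depth, ...
    inputs: dict | None = None  # pre-existing file paths

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        thresholds = StatusThresholds(**raw.pop("thresholds", {}))
        cfg = cls(
            seed=int(raw.pop("seed", 0)),
            outdir=Path(raw.pop("outdir", "fbmeta_run")),
            focal=raw.pop("focal", "Fomes"),
            rank=raw.pop("rank", "family"),
            cazyme_rank=raw.pop("cazyme_rank", "phylum"),
            below_threshold=float(raw.pop("below_threshold", 0.01)),
            wildcard_satisfied=raw.pop("wildcard", "satisfied") != "unsatisfied",
            iterations=int(raw.pop("iterations", 1000)),
            thresholds=thresholds,
            simulate=raw.pop("simulate", None),
            inputs=raw.pop("inputs", None),
        )
        if raw:
            raise ConfigError(f"unknown config keys: {sorted(raw)}")
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.below_threshold < 1:
            raise ConfigError("below_threshold must be in (0, 1)")
        for name in ("mg_low", "mg_high", "mt_rescue"):
            value = getattr(self.thresholds, name)
            if not 0 <= value <= 1:
                raise ConfigError(f"threshold {name} out of [0, 1]")
        if self.simulate is None and self.inputs is None:
            raise ConfigError("config needs either a simulate block or an inputs block")
        if self.inputs is not None:
            required = ("counts_mg", "counts_mt", "fasta", "hits", "taxmap", "kofam", "dbcan", "metadata")
            for key in required:
                if key not in self.inputs:
                    raise ConfigError(f"inputs block missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input path does not exist: {self.inputs[key]}")


def _seed_for(root: int, stage: str) -> int:
    """Derive a stage seed from the root seed (documented derivation)."""
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest dict."""
    config.validate()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, Path]

    stage = "simulate"
    try:
        if config.simulate is not None:
            sim = dict(config.simulate)
            n_healthy = int(sim.pop("n_healthy", 5))
            n_rotten = int(sim.pop("n_rotten", 5))
            spec = default_spec(**{k: v for k, v in sim.items()})
            bundle = generate(spec, n_healthy, n_rotten, seed=_seed_for(config.seed, stage))
            inputs = write_bundle(bundle, out / "inputs")
        else:
            inputs = {k: Path(v) for k, v in config.inputs.items()}

        stage = "tpm"
        lengths = io_formats.read_fasta_lengths(inputs["fasta"])
        mg_counts = io_formats.read_counts_tsv(inputs["counts_mg"])
        mt_counts = io_formats.read_counts_tsv(inputs["counts_mt"])
        mg_tpm = compute_tpm(CountMatrix(mg_counts, "metagenome"), lengths)
        mt_tpm = compute_tpm(CountMatrix(mt_counts, "metatranscriptome"), lengths)
        io_formats.write_counts_tsv(mg_tpm.data.round(4), out / "tpm_mg.tsv")
        io_formats.write_counts_tsv(mt_tpm.data.round(4), out / "tpm_mt.tsv")

        stage = "taxonomy"
        hits = io_formats.read_blast6(inputs["hits"])
        taxmap = io_formats.read_taxmap_tsv(inputs["taxmap"])
        lineages = assign_best_hit(hits, taxmap)
        profiles = {}
        for layer, tpm in (("metagenome", mg_tpm), ("metatranscriptome", mt_tpm)):
            profile = aggregate_by_rank(tpm, lineages, rank=config.rank)
            profile = group_below_threshold(profile, config.below_threshold)
            profile.round(4).to_csv(out / f"taxon_profile_{layer}.tsv", sep="\t")
            profiles[layer] = profile

        stage = "classify"
        metadata = io_formats.read_metadata_tsv(inputs["metadata"])
        putative = dict(metadata["putative_status"])
        mt_reads = (
            dict(metadata["mt_reads"])
            if "mt_reads" in metadata.columns
            else {s: int(mt_counts.loc[s].sum()) for s in mt_counts.index}
        )
        status = classify_samples(
            mg_tpm,
            mt_tpm,
            lineages,
            config.focal,
            putative,
            mt_read_counts=mt_reads,
            thresholds=config.thresholds,
            iterations=config.iterations,
            seed=_seed_for(config.seed, stage),
        )
        status.report.round(6).to_csv(out / "sample_status.tsv", sep="\t")
        status.distances.round(4).to_csv(out / "distances.tsv", sep="\t")

        stage = "modules"
        annotations = filter_kofam(io_formats.read_kofam_tsv(inputs["kofam"]))
        modules = (
            io_formats.read_module_flatfile(inputs["modules"])
            if "modules" in inputs
            else load_default_modules()
        )
        groups = dict(status.report["final_status"])
        module_table = screen_modules(
            modules,
            mg_tpm,
            annotations,
            lineages,
            groups=groups,
            wildcard_satisfied=config.wildcard_satisfied,
        )
        module_table.to_csv(out / "module_completeness.tsv", sep="\t", index=False)
        nif = nitrogenase_screen(
            annotations, {"metagenome": mg_tpm, "metatranscriptome": mt_tpm}
        )
        nif.to_csv(out / "nitrogenase_screen.tsv", sep="\t", index=False)

        stage = "cazymes"
        dbcan = io_formats.read_dbcan_tsv(inputs["dbcan"])
        gene_cazy: dict[str, list[str]] = {}
        for row in dbcan:
            gene_cazy.setdefault(row.gene_id, []).append(row.cazy_family)
        smap = load_substrate_map(inputs.get("smap"))
        for layer, tpm in (("metagenome", mg_tpm), ("metatranscriptome", mt_tpm)):
            profile = build_profile(
                tpm, gene_cazy, lineages, config.focal, smap, rank=config.cazyme_rank
            )
            profile = group_targets_below(profile, config.below_threshold)
            shares = target_share_table(profile)
            shares["layer"] = layer
            shares.round(6).to_csv(out / f"cazyme_profile_{layer}.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_fingerprint(config), sort_keys=True).encode()
        ).hexdigest(),
        "input_checksums": {k: _sha256(Path(p)) for k, p in sorted(inputs.items())},
        "output_checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_fingerprint(config: RunConfig) -> dict:
    return {
        "seed": config.seed,
        "focal": config.focal,
        "rank": config.rank,
        "cazyme_rank": config.cazyme_rank,
        "below_threshold": config.below_threshold,
        "wildcard_satisfied": config.wildcard_satisfied,
        "iterations": config.iterations,
        "thresholds": vars(config.thresholds),
        "simulate": config.simulate,
        "inputs": {k: str(v) for k, v in (config.inputs or {}).items()},
    }
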