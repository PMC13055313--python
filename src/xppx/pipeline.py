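"""End-to-end orchestration: simulate/load -> scan -> call -> integrate -> summarize.

A run is a pure function of its configuration and seed; outputs are a
per-protein inventory TSV, a candidate-funnel JSON, per-layer
functional-category summaries, and a log. Output tables carry a header
comment with the tool version and a hash of the configuration so runs
can be audited and reproduced.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .categorize import (
    CategorySummary,
    format_pct,
    read_category_map,
    summarize,
    write_summary,
)
from .differential import (
    LAYER_PROTEIN,
    LAYER_RNA,
    AbundanceTable,
    FoldChangeRecord,
    Thresholds,
    fold_change,
    normalize_counts,
    read_abundance_tsv,
    write_fold_changes,
)
from .integrate import (
    FunnelCounts,
    RegulatoryCall,
    annotate_stalling,
    build_funnel,
    classify_all,
    write_inventory,
)
from .motif import ProteinRecord, proteome_motif_table, read_fasta, write_motif_table
from .simulate import SimConfig, generate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_table1"]

logger = logging.getLogger("xppx")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class InputError(ValueError):
    """Malformed or missing input data (exit code 1 at the CLI)."""


@dataclass
class PipelineConfig:
    """Where the inputs come from and which cutoffs the run uses."""

    out_dir: Path = Path("xppx_out")
    seed: int = 0
    # either a simulation block ...
    sim: SimConfig | None = None
    # ... or paths to real inputs
    fasta: Path | None = None
    rna: Path | None = None
    protein: Path | None = None
    protein_is_ratio: bool = True
    catmap: Path | None = None
    atlas: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    pseudocount: float = 0.5
    stall_window: int = 1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be positive")
        if self.stall_window < 0:
            raise ConfigError("stall_window must be >= 0")
        if self.sim is None and not (self.fasta and self.rna and self.protein):
            raise ConfigError(
                "either a simulation block or --fasta/--rna/--protein inputs "
                "are required"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        for key in ("fasta", "rna", "protein", "catmap", "atlas"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            for key in ("rna_effect", "te_effect", "seq_length"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            try:
                raw["sim"] = SimConfig(**sim)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid simulation block: {exc}") from exc
        if "thresholds" in raw and raw["thresholds"] is not None:
            try:
                raw["thresholds"] = Thresholds(**raw["thresholds"])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid thresholds: {exc}") from exc
        for key in ("fasta", "rna", "protein", "catmap", "atlas"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


@dataclass
class PipelineResult:
    calls: list[RegulatoryCall]
    funnel: FunnelCounts
    rna_records: list[FoldChangeRecord]
    protein_records: list[FoldChangeRecord]
    summary_rna: CategorySummary | None
    summary_protein: CategorySummary | None
    paths: dict[str, Path]


def read_atlas(path: str | Path) -> list[tuple[str, int]]:
    """Read a stalling atlas TSV: protein_id <tab> position (1-based)."""
    entries: list[tuple[str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].lower() in ("protein_id", "protein"):
                continue
            if len(row) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            try:
                entries.append((row[0], int(row[1])))
            except ValueError as exc:
                raise InputError(
                    f"{path}:{lineno}: position must be an integer"
                ) from exc
    return entries


def _load_inputs(
    config: PipelineConfig,
) -> tuple[list[ProteinRecord], AbundanceTable, AbundanceTable, dict]:
    truth_info: dict = {}
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        dataset = generate_dataset(sim)
        sim_dir = config.out_dir / "simulated"
        write_dataset(dataset, sim_dir)
        truth_info = {"truth": dataset.truth, "sim_dir": sim_dir}
        return dataset.proteome, dataset.counts, dataset.protein, truth_info
    try:
        proteome = read_fasta(config.fasta)
        counts = read_abundance_tsv(config.rna, LAYER_RNA)
        protein = read_abundance_tsv(
            config.protein, LAYER_PROTEIN, is_ratio=config.protein_is_ratio
        )
    except (ValueError, OSError) as exc:
        raise InputError(str(exc)) from exc
    return proteome, counts, protein, truth_info


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full classification pipeline and write all outputs."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stamp = f"xppx v{__version__} config={config.config_hash()}"
    try:
        logger.info("config: %s", json.dumps(_jsonable(config.to_dict())))
        logger.info("seed: %d", config.seed)

        proteome, counts, protein, extra = _load_inputs(config)
        logger.info(
            "inputs: %d proteins, %d transcripts, %d protein features",
            len(proteome),
            len(counts.feature_ids),
            len(protein.feature_ids),
        )

        motif_table = proteome_motif_table(proteome)
        flags = {pid: has for pid, (has, _) in motif_table.items()}
        logger.info("motif scan: %d/%d proteins carry XPPX", sum(flags.values()), len(flags))

        cpm = normalize_counts(counts)
        rna_records = fold_change(cpm, config.thresholds, config.pseudocount)
        protein_records = fold_change(protein, config.thresholds)
        calls = classify_all(rna_records, protein_records, flags, config.thresholds)

        if config.atlas is not None:
            atlas = read_atlas(config.atlas)
            calls = annotate_stalling(calls, atlas, motif_table, config.stall_window)
            logger.info(
                "stall atlas: %d calls with support (window ±%d)",
                sum(c.stall_support for c in calls),
                config.stall_window,
            )

        funnel = build_funnel(
            calls,
            detected_rna=len(counts.feature_ids),
            detected_protein=len(protein.feature_ids),
            rna_records=rna_records,
        )
        logger.info("funnel: %s", json.dumps(funnel.to_dict()))

        catmap = read_category_map(config.catmap) if config.catmap else None

        paths = {
            "motifs": out / "motifs.tsv",
            "rna_fold_changes": out / "rna_fold_changes.tsv",
            "protein_fold_changes": out / "protein_fold_changes.tsv",
            "inventory": out / "inventory.tsv",
            "funnel": out / "funnel.json",
            "log": log_path,
        }
        write_motif_table(motif_table, paths["motifs"], header_comment=stamp)
        write_fold_changes(rna_records, paths["rna_fold_changes"], header_comment=stamp)
        write_fold_changes(
            protein_records, paths["protein_fold_changes"], header_comment=stamp
        )
        write_inventory(calls, paths["inventory"], header_comment=stamp)
        with open(paths["funnel"], "w") as fh:
            json.dump(funnel.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

        summary_rna = summary_protein = None
        if catmap is not None:
            summary_rna = summarize(rna_records, catmap)
            summary_protein = summarize(protein_records, catmap)
            paths["summary_rna"] = out / "category_summary_rna.tsv"
            paths["summary_protein"] = out / "category_summary_protein.tsv"
            paths["table1"] = out / "category_summary_combined.tsv"
            write_summary(summary_rna, paths["summary_rna"], header_comment=stamp)
            write_summary(
                summary_protein, paths["summary_protein"], header_comment=stamp
            )
            shared = [
                c for c in summary_rna.categories if c in set(summary_protein.categories)
            ]
            render_table1(
                _restrict(summary_rna, shared),
                _restrict(summary_protein, shared),
                paths["table1"],
                header_comment=stamp,
            )
        if "sim_dir" in extra:
            paths["simulated"] = extra["sim_dir"]
        logger.info("wrote %d outputs to %s", len(paths), out)
        return PipelineResult(
            calls=calls,
            funnel=funnel,
            rna_records=rna_records,
            protein_records=protein_records,
            summary_rna=summary_rna,
            summary_protein=summary_protein,
            paths=paths,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()


def _restrict(summary: CategorySummary, categories: Sequence[str]) -> CategorySummary:
    keep = set(categories)
    rows = tuple(r for r in summary.rows if r.category in keep)
    return CategorySummary(rows=rows)


def render_table1(
    summary_rna: CategorySummary,
    summary_protein: CategorySummary,
    path: str | Path | None = None,
    header_comment: str | None = None,
) -> list[list[str]]:
    """Side-by-side per-category table for the two layers.

    Columns: category, then Increase/Decrease/Total/Total(%) for the
    transcript layer followed by the same four for the protein layer.
    Both summaries must cover the same categories in the same order.
    """
    if summary_rna.categories != summary_protein.categories:
        only_rna = [
            c for c in summary_rna.categories if c not in summary_protein.categories
        ]
        only_prot = [
            c for c in summary_protein.categories if c not in summary_rna.categories
        ]
        raise ValueError(
            "category universes differ between layers: "
            f"rna-only={only_rna}, protein-only={only_prot}"
        )
    header = [
        "category",
        "rna_increase",
        "rna_decrease",
        "rna_total",
        "rna_total_pct",
        "protein_increase",
        "protein_decrease",
        "protein_total",
        "protein_total_pct",
    ]
    rows = [header]
    for r_rna, r_prot in zip(summary_rna.rows, summary_protein.rows):
        rows.append(
            [
                r_rna.category,
                str(r_rna.n_up),
                str(r_rna.n_down),
                str(r_rna.n_total),
                format_pct(r_rna.pct),
                str(r_prot.n_up),
                str(r_prot.n_down),
                str(r_prot.n_total),
                format_pct(r_prot.pct),
            ]
        )
    if path is not None:
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerows(rows)
    return rows
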