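"""Normalization and fold-change calling for paired wild/mutant omics tables.

Two layers with deliberately different, asymmetric cutoffs:

* transcripts (RNA-seq counts): a gene is differentially expressed when
  |log2 fold change| exceeds 1, i.e. ratio > 2 or < 0.5 on the linear
  scale (strict inequalities);
* proteins (iTRAQ reporter ratios): up when ratio > 1.5, down when
  ratio < 0.7 — an asymmetric band reflecting the compressed dynamic
  range of isobaric-tag quantification.

Counts are scaled to counts-per-million per replicate, replicates are
summarized by the arithmetic mean (the proteome side of the study pooled
biological replicates before labelling), and a pseudocount stabilizes
RNA ratios at low counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "Thresholds",
    "AbundanceTable",
    "FoldChangeRecord",
    "normalize_counts",
    "fold_change",
    "call_transcript",
    "call_protein",
    "read_abundance_tsv",
    "write_fold_changes",
    "fold_changes_to_frame",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

LAYER_RNA = "rna"
LAYER_PROTEIN = "protein"

WILD = "wild"
MUTANT = "mutant"


@dataclass(frozen=True)
class Thresholds:
    """Linear-scale fold-change cutoffs; calls use strict inequalities."""

    rna_up: float = 2.0
    rna_down: float = 0.5
    protein_up: float = 1.5
    protein_down: float = 0.7

    def __post_init__(self) -> None:
        for name, down, up in (
            ("rna", self.rna_down, self.rna_up),
            ("protein", self.protein_down, self.protein_up),
        ):
            if not (0 < down < 1 < up):
                raise ValueError(
                    f"{name} thresholds must satisfy 0 < down < 1 < up, "
                    f"got down={down}, up={up}"
                )


@dataclass
class AbundanceTable:
    """A feature x replicate abundance matrix for one omics layer.

    ``values`` is indexed by feature id with columns named
    ``<condition>_<replicate>`` where condition is ``wild`` or ``mutant``.
    When ``is_ratio`` is True the columns hold precomputed mutant/wild
    ratios (iTRAQ reporter style) and no wild columns are required.
    """

    values: pd.DataFrame
    layer: str
    is_ratio: bool = False

    def __post_init__(self) -> None:
        if self.layer not in (LAYER_RNA, LAYER_PROTEIN):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.is_ratio and self.layer == LAYER_RNA:
            raise ValueError("ratio-style input is only supported for the protein layer")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be nonnegative")
        if not self.is_ratio:
            for cond in (WILD, MUTANT):
                if not self._condition_columns(cond):
                    raise ValueError(f"no replicate column for condition {cond!r}")

    def _condition_columns(self, condition: str) -> list[str]:
        return [c for c in self.values.columns if c.split("_")[0] == condition]

    @property
    def wild_columns(self) -> list[str]:
        return self._condition_columns(WILD)

    @property
    def mutant_columns(self) -> list[str]:
        return self._condition_columns(MUTANT)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


def normalize_counts(table: AbundanceTable) -> AbundanceTable:
    """Scale each replicate column of an RNA count table to counts-per-million.

    A replicate with zero total counts cannot be normalized and raises an
    error naming the replicate.
    """
    if table.layer != LAYER_RNA:
        raise ValueError("normalize_counts applies to the rna layer only")
    totals = table.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"replicate {zero.index[0]!r} has total count 0")
    cpm = table.values / totals * 1e6
    return AbundanceTable(values=cpm, layer=LAYER_RNA)


@dataclass(frozen=True)
class FoldChangeRecord:
    """Mutant/wild ratio for one feature with a directional call."""

    feature_id: str
    ratio: float
    log2fc: float = field(default=math.nan)
    call: str = UNCHANGED
    layer: str = LAYER_RNA

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError(f"{self.feature_id}: ratio must be positive")
        if math.isnan(self.log2fc):
            object.__setattr__(self, "log2fc", math.log2(self.ratio))
        elif abs(self.log2fc - math.log2(self.ratio)) > 1e-4:
            raise ValueError(
                f"{self.feature_id}: log2fc {self.log2fc} inconsistent with "
                f"ratio {self.ratio}"
            )


def call_transcript(log2fc: float, log2_threshold: float = 1.0) -> str:
    """DEG call from a log2 fold change: |log2FC| must *exceed* the cutoff."""
    if not math.isfinite(log2fc):
        raise ValueError(f"log2fc must be finite, got {log2fc}")
    if log2fc > log2_threshold:
        return UP
    if log2fc < -log2_threshold:
        return DOWN
    return UNCHANGED


def call_protein(ratio: float, up: float = 1.5, down: float = 0.7) -> str:
    """Differential-protein call from a linear ratio (strict inequalities)."""
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if ratio > up:
        return UP
    if ratio < down:
        return DOWN
    return UNCHANGED


def _call_for_layer(layer: str, ratio: float, thresholds: Thresholds) -> str:
    if layer == LAYER_RNA:
        if ratio > thresholds.rna_up:
            return UP
        if ratio < thresholds.rna_down:
            return DOWN
        return UNCHANGED
    return call_protein(ratio, thresholds.protein_up, thresholds.protein_down)


def fold_change(
    table: AbundanceTable,
    thresholds: Thresholds | None = None,
    pseudocount: float = 0.5,
) -> list[FoldChangeRecord]:
    """Per-feature mutant/wild ratio, log2 fold change, and directional call.

    RNA tables are expected CPM-normalized; the pseudocount is added to
    each condition mean so ratios stay finite at zero counts. Protein
    abundance tables take the plain ratio of condition means; ratio-style
    protein tables average the ratio columns directly.
    """
    thresholds = thresholds or Thresholds()
    if table.is_ratio:
        ratios = table.values.mean(axis=1)
        if (ratios <= 0).any():
            bad = ratios.index[ratios <= 0][0]
            raise ValueError(f"feature {bad!r}: nonpositive ratio")
    else:
        wild_mean = table.values[table.wild_columns].mean(axis=1)
        mut_mean = table.values[table.mutant_columns].mean(axis=1)
        if table.layer == LAYER_RNA:
            if pseudocount < 0:
                raise ValueError("pseudocount must be nonnegative")
            if pseudocount == 0 and (wild_mean == 0).any():
                bad = wild_mean.index[wild_mean == 0][0]
                raise ValueError(
                    f"feature {bad!r}: wild-type mean is 0; a positive "
                    "pseudocount is required"
                )
            ratios = (mut_mean + pseudocount) / (wild_mean + pseudocount)
        else:
            if (wild_mean <= 0).any():
                bad = wild_mean.index[wild_mean <= 0][0]
                raise ValueError(f"feature {bad!r}: wild-type mean abundance is 0")
            ratios = mut_mean / wild_mean
    records = []
    for fid, ratio in ratios.items():
        ratio = float(ratio)
        records.append(
            FoldChangeRecord(
                feature_id=str(fid),
                ratio=ratio,
                log2fc=math.log2(ratio),
                call=_call_for_layer(table.layer, ratio, thresholds),
                layer=table.layer,
            )
        )
    return records


def read_abundance_tsv(
    path: str | Path, layer: str, is_ratio: bool = False
) -> AbundanceTable:
    """Read a TSV whose first column is the feature id.

    Remaining columns are ``<condition>_<replicate>`` values (or ratio
    columns when ``is_ratio``). Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no value columns found")
    return AbundanceTable(values=df.astype(float), layer=layer, is_ratio=is_ratio)


def read_fold_changes(path: str | Path) -> list[FoldChangeRecord]:
    """Read a fold-change TSV written by :func:`write_fold_changes`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"feature_id", "ratio", "log2fc", "call", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        FoldChangeRecord(
            feature_id=str(row.feature_id),
            ratio=float(row.ratio),
            log2fc=float(row.log2fc),
            call=str(row.call),
            layer=str(row.layer),
        )
        for row in df.itertuples()
    ]


def fold_changes_to_frame(records: Sequence[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "ratio": [r.ratio for r in records],
            "log2fc": [r.log2fc for r in records],
            "call": [r.call for r in records],
            "layer": [r.layer for r in records],
        }
    ).set_index("feature_id")


def write_fold_changes(
    records: Iterable[FoldChangeRecord],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    df = fold_changes_to_frame(list(records))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")
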