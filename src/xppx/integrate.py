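"""Cross-omics classification of regulatory mode and the candidate funnel.

A protein whose abundance drops in the *efp* mutant may do so because its
transcript dropped (transcriptional regulation), because ribosomes stall
at a diproline XPPX motif that EF-P would normally resolve (direct
translational regulation), or as a secondary consequence of the mutant's
pleiotropy. Conversely, a protein whose apparent level rises while its
transcript rises even more is translationally attenuated but masked.

Classification rules, applied in order:

1. protein down AND mRNA down            -> transcriptional
2. protein down AND XPPX AND mRNA ¬down  -> efp_direct_candidate
3. protein down AND no XPPX AND mRNA ¬down -> secondary
4. protein up AND XPPX AND TE ratio < protein down-cutoff
                                         -> translational_attenuation_masked
5. otherwise                             -> unclassified

where the translational-efficiency (TE) ratio is the mutant/wild protein
ratio divided by the mutant/wild mRNA ratio: TE < 1 means less protein
made per transcript. Candidates can additionally be cross-referenced
against a ribosome-stalling atlas (Ribo-seq stall sites as (protein,
position) pairs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .differential import DOWN, UP, FoldChangeRecord, Thresholds
from .motif import MotifHit

__all__ = [
    "MODE_EFP_DIRECT",
    "MODE_TRANSCRIPTIONAL",
    "MODE_SECONDARY",
    "MODE_MASKED",
    "MODE_UNCLASSIFIED",
    "RegulatoryCall",
    "FunnelCounts",
    "classify_protein",
    "classify_all",
    "build_funnel",
    "annotate_stalling",
    "calls_to_frame",
    "write_inventory",
]

MODE_EFP_DIRECT = "efp_direct_candidate"
MODE_TRANSCRIPTIONAL = "transcriptional"
MODE_SECONDARY = "secondary"
MODE_MASKED = "translational_attenuation_masked"
MODE_UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class RegulatoryCall:
    """Integrated per-protein classification with its evidence flags."""

    protein_id: str
    rna_call: str
    protein_call: str
    has_xppx: bool
    te_ratio: float
    mode: str
    stall_support: bool = False
    no_rna_evidence: bool = False


@dataclass(frozen=True)
class FunnelCounts:
    """Nested candidate counts: detected -> changed -> down -> XPPX -> direct."""

    n_detected_rna: int = 0
    n_detected_protein: int = 0
    n_rna_up: int = 0
    n_rna_down: int = 0
    n_protein_up: int = 0
    n_protein_down: int = 0
    n_down_with_xppx: int = 0
    n_down_mrna_driven: int = 0
    n_efp_direct: int = 0

    def __post_init__(self) -> None:
        if not (
            self.n_efp_direct <= self.n_down_with_xppx <= self.n_protein_down
        ):
            raise ValueError(
                "funnel must nest: n_efp_direct <= n_down_with_xppx "
                f"<= n_protein_down, got {self}"
            )
        if self.n_down_mrna_driven > self.n_protein_down:
            raise ValueError(
                "n_down_mrna_driven cannot exceed n_protein_down"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_detected_rna": self.n_detected_rna,
            "n_detected_protein": self.n_detected_protein,
            "n_rna_up": self.n_rna_up,
            "n_rna_down": self.n_rna_down,
            "n_protein_up": self.n_protein_up,
            "n_protein_down": self.n_protein_down,
            "n_down_with_xppx": self.n_down_with_xppx,
            "n_down_mrna_driven": self.n_down_mrna_driven,
            "n_efp_direct": self.n_efp_direct,
        }


def classify_protein(
    rna: FoldChangeRecord | None,
    prot: FoldChangeRecord,
    has_xppx: bool,
    te_down_threshold: float = 0.7,
) -> RegulatoryCall:
    """Assign one protein its regulatory mode from paired fold changes.

    A protein absent from the RNA table is treated as mRNA-unchanged
    (ratio 1) and flagged ``no_rna_evidence``: lacking a demonstrated
    mRNA decrease, it may still be a direct candidate.
    """
    if prot is None:
        raise ValueError("protein fold-change record is required")
    if rna is not None and rna.feature_id != prot.feature_id:
        raise ValueError(
            f"feature mismatch: rna {rna.feature_id!r} vs protein "
            f"{prot.feature_id!r}"
        )
    no_rna = rna is None
    rna_call = "unchanged" if no_rna else rna.call
    rna_ratio = 1.0 if no_rna else rna.ratio
    te_ratio = prot.ratio / rna_ratio

    if prot.call == DOWN and rna_call == DOWN:
        mode = MODE_TRANSCRIPTIONAL
    elif prot.call == DOWN and has_xppx:
        mode = MODE_EFP_DIRECT
    elif prot.call == DOWN:
        mode = MODE_SECONDARY
    elif prot.call == UP and has_xppx and te_ratio < te_down_threshold:
        mode = MODE_MASKED
    else:
        mode = MODE_UNCLASSIFIED

    return RegulatoryCall(
        protein_id=prot.feature_id,
        rna_call=rna_call,
        protein_call=prot.call,
        has_xppx=has_xppx,
        te_ratio=te_ratio,
        mode=mode,
        no_rna_evidence=no_rna,
    )


def classify_all(
    rna_records: Iterable[FoldChangeRecord],
    prot_records: Iterable[FoldChangeRecord],
    motif_flags: Mapping[str, bool],
    thresholds: Thresholds | None = None,
) -> list[RegulatoryCall]:
    """Classify every detected protein against the transcript table.

    ``motif_flags`` maps protein id -> has_xppx; proteins missing from it
    are taken as motif-free. The TE cutoff for the masked class reuses
    the protein down-threshold.
    """
    thresholds = thresholds or Thresholds()
    rna_by_id = {r.feature_id: r for r in rna_records}
    return [
        classify_protein(
            rna_by_id.get(p.feature_id),
            p,
            bool(motif_flags.get(p.feature_id, False)),
            te_down_threshold=thresholds.protein_down,
        )
        for p in prot_records
    ]


def build_funnel(
    calls: Sequence[RegulatoryCall],
    detected_rna: int = 0,
    detected_protein: int = 0,
    rna_records: Sequence[FoldChangeRecord] | None = None,
) -> FunnelCounts:
    """Count the nested candidate sets over a complete set of calls.

    Transcriptome-wide up/down counts come from ``rna_records`` when
    given (the RNA table usually covers genes with no detected protein);
    otherwise they are counted over the calls' rna_call fields.
    """
    if rna_records is not None:
        n_rna_up = sum(r.call == UP for r in rna_records)
        n_rna_down = sum(r.call == DOWN for r in rna_records)
    else:
        n_rna_up = sum(c.rna_call == UP for c in calls)
        n_rna_down = sum(c.rna_call == DOWN for c in calls)
    return FunnelCounts(
        n_detected_rna=detected_rna,
        n_detected_protein=detected_protein,
        n_rna_up=n_rna_up,
        n_rna_down=n_rna_down,
        n_protein_up=sum(c.protein_call == UP for c in calls),
        n_protein_down=sum(c.protein_call == DOWN for c in calls),
        n_down_with_xppx=sum(
            c.protein_call == DOWN and c.has_xppx for c in calls
        ),
        n_down_mrna_driven=sum(c.mode == MODE_TRANSCRIPTIONAL for c in calls),
        n_efp_direct=sum(c.mode == MODE_EFP_DIRECT for c in calls),
    )


def annotate_stalling(
    calls: Sequence[RegulatoryCall],
    atlas: Iterable[tuple[str, int]],
    hits: Mapping[str, tuple[bool, Sequence[MotifHit]]],
    window: int = 1,
) -> list[RegulatoryCall]:
    """Flag calls whose XPPX hits lie near a ribosome-stalling atlas site.

    ``stall_support`` becomes True iff the atlas lists a position within
    +/- ``window`` residues of any XPPX hit in that protein. Atlas rows
    for proteins absent from the call set are ignored with a warning
    (the atlas strain and growth conditions differ from the experiment).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    known = {c.protein_id for c in calls}
    sites: dict[str, list[int]] = {}
    for protein_id, position in atlas:
        if protein_id not in known:
            warnings.warn(
                f"stalling-atlas entry for unknown protein {protein_id!r} ignored",
                stacklevel=2,
            )
            continue
        sites.setdefault(protein_id, []).append(int(position))
    annotated = []
    for call in calls:
        positions = sites.get(call.protein_id, [])
        _, protein_hits = hits.get(call.protein_id, (False, []))
        support = any(
            abs(site - hit.position) <= window
            for site in positions
            for hit in protein_hits
        )
        annotated.append(replace(call, stall_support=support))
    return annotated


def calls_to_frame(calls: Sequence[RegulatoryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "rna_call": [c.rna_call for c in calls],
            "protein_call": [c.protein_call for c in calls],
            "has_xppx": [c.has_xppx for c in calls],
            "te_ratio": [c.te_ratio for c in calls],
            "mode": [c.mode for c in calls],
            "stall_support": [c.stall_support for c in calls],
            "no_rna_evidence": [c.no_rna_evidence for c in calls],
        }
    ).set_index("protein_id")


def write_inventory(
    calls: Sequence[RegulatoryCall],
    path,
    header_comment: str | None = None,
) -> None:
    """Write the per-protein inventory TSV (one row per detected protein)."""
    df = calls_to_frame(calls)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")
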