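"""Regulatory-mode classification, funnel counts, stall-atlas annotation."""

from __future__ import annotations

import numpy as np
import pytest

from xppx.differential import DOWN, UNCHANGED, UP, FoldChangeRecord, Thresholds
from xppx.evaluate import classify_dataset
from xppx.integrate import (
    MODE_EFP_DIRECT,
    MODE_MASKED,
    MODE_SECONDARY,
    MODE_TRANSCRIPTIONAL,
    MODE_UNCLASSIFIED,
    FunnelCounts,
    RegulatoryCall,
    annotate_stalling,
    build_funnel,
    classify_protein,
)
from xppx.motif import MotifHit
from xppx.simulate import SimConfig, generate_dataset


def rna_record(log2fc: float, fid: str = "p") -> FoldChangeRecord:
    ratio = 2.0**log2fc
    return FoldChangeRecord(
        feature_id=fid,
        ratio=ratio,
        call=UP if log2fc > 1 else DOWN if log2fc < -1 else UNCHANGED,
        layer="rna",
    )


def prot_record(ratio: float, fid: str = "p") -> FoldChangeRecord:
    return FoldChangeRecord(
        feature_id=fid,
        ratio=ratio,
        call=UP if ratio > 1.5 else DOWN if ratio < 0.7 else UNCHANGED,
        layer="protein",
    )


class TestClassify:
    @pytest.mark.parametrize(
        "prot_ratio,rna_log2fc,has_xppx,expected",
        [
            (0.5, 0.0, True, MODE_EFP_DIRECT),
            (0.5, -2.0, True, MODE_TRANSCRIPTIONAL),  # mRNA decrease wins
            (2.0, 2.5, True, MODE_MASKED),  # up, but less protein per mRNA
            (1.0, 0.0, False, MODE_UNCLASSIFIED),
            (0.5, 0.0, False, MODE_SECONDARY),
            (2.0, 2.5, False, MODE_UNCLASSIFIED),  # masked class needs the motif
            (2.0, 0.0, True, MODE_UNCLASSIFIED),  # TE not below cutoff
        ],
    )
    def test_modes(self, prot_ratio, rna_log2fc, has_xppx, expected):
        call = classify_protein(
            rna_record(rna_log2fc), prot_record(prot_ratio), has_xppx
        )
        assert call.mode == expected

    def test_te_ratio_value(self):
        call = classify_protein(rna_record(2.5), prot_record(2.0), True)
        assert call.te_ratio == pytest.approx(2.0 / 2.0**2.5)
        assert call.mode == MODE_MASKED

    def test_transcriptional_precedence_over_direct(self):
        # a protein that is down at both layers is mRNA-driven even with
        # the motif present
        call = classify_protein(rna_record(-3.0), prot_record(0.4), True)
        assert call.mode == MODE_TRANSCRIPTIONAL

    def test_missing_rna_record_may_still_be_direct(self):
        call = classify_protein(None, prot_record(0.5), True)
        assert call.mode == MODE_EFP_DIRECT
        assert call.no_rna_evidence
        assert call.rna_call == UNCHANGED
        assert call.te_ratio == pytest.approx(0.5)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_protein(
                rna_record(0.0, "a"), prot_record(0.5, "b"), True
            )


def toy_calls() -> list[RegulatoryCall]:
    def call(pid, rna, prot, xppx, mode, te=1.0):
        return RegulatoryCall(
            protein_id=pid,
            rna_call=rna,
            protein_call=prot,
            has_xppx=xppx,
            te_ratio=te,
            mode=mode,
        )

    return [
        call("p1", UNCHANGED, DOWN, True, MODE_EFP_DIRECT, 0.5),
        call("p2", UP, DOWN, True, MODE_EFP_DIRECT, 0.2),
        call("p3", DOWN, DOWN, True, MODE_TRANSCRIPTIONAL, 1.0),
        call("p4", UNCHANGED, DOWN, False, MODE_SECONDARY, 0.6),
        call("p5", UP, UP, True, MODE_MASKED, 0.4),
        call("p6", UNCHANGED, UNCHANGED, False, MODE_UNCLASSIFIED, 1.0),
    ]


class TestFunnel:
    def test_empty(self):
        f = build_funnel([], 0, 0)
        assert all(v == 0 for v in f.to_dict().values())

    def test_toy_enumeration(self):
        f = build_funnel(toy_calls(), detected_rna=10, detected_protein=6)
        assert f.n_protein_down == 4
        assert f.n_down_with_xppx == 3
        assert f.n_efp_direct == 2
        assert f.n_down_mrna_driven == 1
        assert f.n_protein_up == 1
        assert f.n_detected_protein == 6

    def test_nesting_invariant_enforced(self):
        with pytest.raises(ValueError, match="nest"):
            FunnelCounts(n_efp_direct=5, n_down_with_xppx=2, n_protein_down=6)

    def test_set_algebra_identity_on_simulated_data(self):
        # direct candidates are exactly (protein-down ∩ XPPX) \ (rna-down)
        ds = generate_dataset(SimConfig(n_genes=400, seed=11))
        calls, rna, prot = classify_dataset(ds)
        prot_down = {r.feature_id for r in prot if r.call == DOWN}
        rna_down = {r.feature_id for r in rna if r.call == DOWN}
        xppx = {c.protein_id for c in calls if c.has_xppx}
        direct = {c.protein_id for c in calls if c.mode == MODE_EFP_DIRECT}
        assert direct == (prot_down & xppx) - rna_down

    def test_threshold_tightening_monotone(self):
        ds = generate_dataset(SimConfig(n_genes=400, seed=12))
        downs = []
        for cutoff in [0.7, 0.6, 0.5, 0.4]:
            thr = Thresholds(protein_down=cutoff)
            calls, _, _ = classify_dataset(ds, thresholds=thr)
            downs.append(sum(c.protein_call == DOWN for c in calls))
        assert downs == sorted(downs, reverse=True)


class TestStalling:
    def hits_for(self, pid, positions):
        return (
            bool(positions),
            [
                MotifHit(protein_id=pid, position=p, motif="APPV", kind="xppx")
                for p in positions
            ],
        )

    def base_call(self, pid="p1"):
        return RegulatoryCall(
            protein_id=pid,
            rna_call=UNCHANGED,
            protein_call=DOWN,
            has_xppx=True,
            te_ratio=0.5,
            mode=MODE_EFP_DIRECT,
        )

    def test_exact_site_window_zero(self):
        calls = annotate_stalling(
            [self.base_call()], [("p1", 10)], {"p1": self.hits_for("p1", [10])}, 0
        )
        assert calls[0].stall_support is True

    def test_window_boundary(self):
        hits = {"p1": self.hits_for("p1", [10])}
        off_by_one = [("p1", 11)]
        assert not annotate_stalling([self.base_call()], off_by_one, hits, 0)[0].stall_support
        assert annotate_stalling([self.base_call()], off_by_one, hits, 1)[0].stall_support

    def test_unknown_protein_warns_and_ignored(self):
        with pytest.warns(UserWarning, match="ghost"):
            calls = annotate_stalling(
                [self.base_call()], [("ghost", 5)], {"p1": self.hits_for("p1", [5])}, 2
            )
        assert calls[0].stall_support is False

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            annotate_stalling([], [], {}, -1)

    def test_random_atlas_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        window = 2
        calls, atlas, hits = [], [], {}
        for i in range(50):
            pid = f"p{i}"
            calls.append(self.base_call(pid))
            hit_pos = sorted(rng.integers(1, 200, size=rng.integers(0, 4)).tolist())
            hits[pid] = self.hits_for(pid, hit_pos)
            for pos in rng.integers(1, 200, size=rng.integers(0, 3)):
                atlas.append((pid, int(pos)))
        annotated = annotate_stalling(calls, atlas, hits, window)
        for call in annotated:
            expected = any(
                abs(site - h.position) <= window
                for p, site in atlas
                if p == call.protein_id
                for h in hits[call.protein_id][1]
            )
            assert call.stall_support == expected
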