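"""CPM normalization and dual-threshold fold-change calling."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xppx.differential import (
    DOWN,
    UNCHANGED,
    UP,
    AbundanceTable,
    FoldChangeRecord,
    Thresholds,
    call_protein,
    call_transcript,
    fold_change,
    normalize_counts,
    read_abundance_tsv,
    read_fold_changes,
    write_fold_changes,
)


def rna_table(data: dict, index=None) -> AbundanceTable:
    return AbundanceTable(
        values=pd.DataFrame(data, index=index), layer="rna"
    )


class TestNormalize:
    def test_whole_library_single_gene(self):
        t = rna_table({"wild_1": [10.0], "mutant_1": [5.0]}, index=["g1"])
        cpm = normalize_counts(t)
        assert cpm.values.loc["g1", "wild_1"] == pytest.approx(1e6)

    def test_proportionality(self):
        t = rna_table(
            {"wild_1": [3.0, 1.0], "mutant_1": [1.0, 1.0]}, index=["a", "b"]
        )
        cpm = normalize_counts(t)
        assert cpm.values["wild_1"].tolist() == pytest.approx([750000.0, 250000.0])

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 500, size=(50, 6)).astype(float)
        cols = [f"wild_{i}" for i in range(3)] + [f"mutant_{i}" for i in range(3)]
        t = rna_table({c: counts[:, i] for i, c in enumerate(cols)})
        cpm = normalize_counts(t)
        assert cpm.values.sum(axis=0).tolist() == pytest.approx([1e6] * 6)

    def test_zero_library_names_replicate(self):
        t = rna_table({"wild_1": [0.0, 0.0], "mutant_1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="wild_1"):
            normalize_counts(t)


class TestCalls:
    @pytest.mark.parametrize(
        "log2fc,expected",
        [(1.2, UP), (1.0, UNCHANGED), (-1.0, UNCHANGED), (-3.0, DOWN), (0.0, UNCHANGED)],
    )
    def test_transcript(self, log2fc, expected):
        assert call_transcript(log2fc) == expected

    @pytest.mark.parametrize(
        "ratio,expected",
        [(1.6, UP), (1.5, UNCHANGED), (0.7, UNCHANGED), (0.69, DOWN), (1.0, UNCHANGED)],
    )
    def test_protein(self, ratio, expected):
        assert call_protein(ratio) == expected

    def test_transcript_mirror_symmetric(self):
        for r in [1.1, 1.5, 1.9, 2.1, 3.0, 5.0]:
            fwd = call_transcript(math.log2(r))
            rev = call_transcript(math.log2(1 / r))
            assert (fwd, rev) in {(UP, DOWN), (DOWN, UP), (UNCHANGED, UNCHANGED)}

    def test_protein_band_is_asymmetric(self):
        # 1.45 sits inside the unchanged band but its reciprocal is down
        assert call_protein(1.45) == UNCHANGED
        assert call_protein(1 / 1.45) == DOWN

    def test_layer_dependence_on_ratio_grid(self):
        # the two layers use different bands: 1.8-fold is protein-up but
        # transcript-unchanged; 1.3-fold is unchanged in both
        for r, protein_call, rna_call in [
            (1.3, UNCHANGED, UNCHANGED),
            (1.8, UP, UNCHANGED),
            (0.6, DOWN, UNCHANGED),
            (0.4, DOWN, DOWN),
            (2.5, UP, UP),
        ]:
            assert call_protein(r) == protein_call
            assert call_transcript(math.log2(r)) == rna_call

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0), st.floats(min_value=0.0, max_value=2.0))
    def test_monotonicity(self, ratio, bump):
        order = {DOWN: 0, UNCHANGED: 1, UP: 2}
        assert order[call_protein(ratio + bump)] >= order[call_protein(ratio)]
        assert order[call_transcript(math.log2(ratio + bump))] >= order[
            call_transcript(math.log2(ratio))
        ]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            call_transcript(float("nan"))
        with pytest.raises(ValueError):
            call_protein(0.0)


class TestFoldChange:
    def test_rna_exact_arithmetic(self):
        t = rna_table(
            {"wild_1": [10.0], "mutant_1": [40.0]}, index=["g"]
        )
        (rec,) = fold_change(t, pseudocount=0.0)
        assert rec.ratio == pytest.approx(4.0)
        assert rec.log2fc == pytest.approx(2.0)
        assert rec.call == UP

    def test_rna_pseudocount_stabilizes_zero(self):
        t = rna_table({"wild_1": [0.0], "mutant_1": [8.0]}, index=["g"])
        (rec,) = fold_change(t, pseudocount=0.5)
        assert rec.ratio == pytest.approx(8.5 / 0.5)

    def test_protein_ratio_down(self):
        t = AbundanceTable(
            values=pd.DataFrame({"ratio": [0.5]}, index=["p"]),
            layer="protein",
            is_ratio=True,
        )
        (rec,) = fold_change(t)
        assert rec.call == DOWN

    def test_identical_means_unchanged(self):
        t = rna_table(
            {"wild_1": [30.0], "wild_2": [10.0], "mutant_1": [20.0], "mutant_2": [20.0]},
            index=["g"],
        )
        (rec,) = fold_change(t)
        assert rec.ratio == pytest.approx(1.0)
        assert rec.call == UNCHANGED

    def test_protein_abundance_columns(self):
        t = AbundanceTable(
            values=pd.DataFrame(
                {"wild_1": [100.0], "mutant_1": [60.0]}, index=["p"]
            ),
            layer="protein",
        )
        (rec,) = fold_change(t)
        assert rec.ratio == pytest.approx(0.6)
        assert rec.call == DOWN

    def test_record_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FoldChangeRecord(feature_id="x", ratio=2.0, log2fc=0.5)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rna_table({"wild_1": [1.0, 2.0], "mutant_1": [1.0, 2.0]}, index=["a", "a"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            rna_table({"wild_1": [-1.0], "mutant_1": [1.0]})

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="mutant"):
            rna_table({"wild_1": [1.0]})

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            Thresholds(protein_down=1.2)


class TestIO:
    def test_round_trip(self, tmp_path):
        t = rna_table(
            {"wild_1": [10.0, 100.0], "mutant_1": [40.0, 25.0]}, index=["a", "b"]
        )
        records = fold_change(normalize_counts(t))
        path = tmp_path / "fc.tsv"
        write_fold_changes(records, path, header_comment="v0")
        back = read_fold_changes(path)
        assert [r.feature_id for r in back] == ["a", "b"]
        assert [r.call for r in back] == [r.call for r in records]
        assert back[0].ratio == pytest.approx(records[0].ratio, rel=1e-5)

    def test_abundance_tsv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"wild_1": [3.0, 1.0], "mutant_1": [6.0, 2.0]},
            index=pd.Index(["a", "b"], name="feature_id"),
        )
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t")
        t = read_abundance_tsv(path, "rna")
        assert t.feature_ids == ["a", "b"]
        assert t.wild_columns == ["wild_1"]
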