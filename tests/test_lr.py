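"""LR score closed forms, reliability semantics, and bias gate logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cafkit.lr import (
    biased_interactions,
    count_interactions,
    lr_score,
    score_all,
    validate_pairs,
)

from conftest import make_adata

pos = st.floats(min_value=1e-6, max_value=1e3, allow_nan=False)


class TestScore:
    def test_symmetry_point_is_exactly_half(self):
        assert lr_score(1.7, 1.7, 1.7) == 0.5

    def test_zero_ligand_gives_zero(self):
        assert lr_score(0.0, 5.0, 1.0) == 0.0
        assert lr_score(5.0, 0.0, 1.0) == 0.0

    def test_closed_form_example(self):
        assert lr_score(4, 1, 1) == pytest.approx(2 / 3, rel=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(pos, pos, pos)
    def test_matches_closed_form_and_is_bounded(self, l, r, mu):
        s = lr_score(l, r, mu)
        assert s == pytest.approx(
            np.sqrt(l * r) / (mu + np.sqrt(l * r)), abs=1e-12
        )
        assert 0 <= s < 1

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(pos, pos, pos, pos)
    def test_monotone_in_ligand_expression(self, l, dl, r, mu):
        assert lr_score(l + dl, r, mu) >= lr_score(l, r, mu)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            lr_score(-1, 1, 1)
        with pytest.raises(ValueError):
            lr_score(1, 1, 0)


def _two_pop_adata(values, n_samples=3, n_per=12):
    """Cells x 4 genes AnnData with two populations across samples; every
    cell carries the same expression vector ``values``."""
    n = 2 * n_per * n_samples
    X = np.tile(np.asarray(values, dtype=float), (n, 1))
    pops = np.tile(np.repeat(["src", "tgt"], n_per), n_samples)
    samples = np.repeat([f"S{i}" for i in range(n_samples)], 2 * n_per)
    return make_adata(X, population=pops, sample=samples)


class TestScoreAll:
    def test_identical_samples_give_identical_scores(self):
        adata = _two_pop_adata([2.0, 4.0, 1.0, 0.5], n_samples=6)
        pairs = pd.DataFrame({"ligand": ["G000"], "receptor": ["G001"]})
        rec = score_all(adata, pairs, "src", "tgt", min_cells=5)
        cols = [c for c in rec.columns if c.startswith("score_")]
        scores = rec[cols].to_numpy().ravel()
        assert len(set(np.round(scores, 12))) == 1
        assert rec["median_score"].iloc[0] == pytest.approx(scores[0])

    def test_median_exactly_half_is_not_reliable(self):
        # constant matrix: l = r = mu, every score is exactly 0.5
        adata = _two_pop_adata([3.0, 3.0, 3.0, 3.0])
        pairs = pd.DataFrame({"ligand": ["G000"], "receptor": ["G002"]})
        rec = score_all(adata, pairs, "src", "tgt", min_cells=5)
        assert rec["median_score"].iloc[0] == 0.5
        assert not rec["reliable"].iloc[0]

    def test_pair_with_absent_gene_skipped(self):
        adata = _two_pop_adata([1.0, 2.0, 3.0, 4.0])
        pairs = pd.DataFrame(
            {"ligand": ["G000", "G001"], "receptor": ["MISSING", "G002"]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            rec = score_all(adata, pairs, "src", "tgt", min_cells=5)
        assert len(rec) == 1 and rec["ligand"].iloc[0] == "G001"

    def test_small_samples_excluded_from_median(self):
        adata = _two_pop_adata([1.0, 2.0, 3.0, 4.0], n_samples=3, n_per=12)
        # shrink one sample below min_cells
        keep = ~((adata.obs["sample"] == "S0") & (adata.obs.index.str.endswith(
            ("1", "2", "3", "4", "5", "6", "7", "8"))))
        sub = adata[keep].copy()
        pairs = pd.DataFrame({"ligand": ["G000"], "receptor": ["G001"]})
        rec = score_all(sub, pairs, "src", "tgt", min_cells=10)
        assert rec["n_samples"].iloc[0] == 2
        assert np.isnan(rec["score_S0"].iloc[0])

    def test_duplicate_pairs_rejected(self):
        pairs = pd.DataFrame(
            {"ligand": ["a", "a"], "receptor": ["b", "b"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            validate_pairs(pairs)

    def test_scores_invariant_under_cell_permutation(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(size=(72, 4))
        pops = np.tile(np.repeat(["src", "tgt"], 12), 3)
        samples = np.repeat(["S0", "S1", "S2"], 24)
        adata = make_adata(X, population=pops, sample=samples)
        pairs = pd.DataFrame({"ligand": ["G000"], "receptor": ["G003"]})
        rec1 = score_all(adata, pairs, "src", "tgt", min_cells=5)
        perm = rng.permutation(72)
        rec2 = score_all(adata[perm].copy(), pairs, "src", "tgt", min_cells=5)
        assert rec1["median_score"].iloc[0] == pytest.approx(
            rec2["median_score"].iloc[0], rel=1e-12
        )


class TestCounting:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["ligand", "receptor", "source", "target", "reliable"]
        )

    def test_empty_records_give_empty_matrix(self):
        assert count_interactions(pd.DataFrame()).empty

    def test_reliable_counts_per_direction(self):
        rec = self._records(
            [
                ("l1", "r1", "CAF", "Cancer", True),
                ("l2", "r2", "CAF", "Cancer", True),
                ("l3", "r3", "Cancer", "CAF", True),
                ("l4", "r4", "CAF", "Cancer", False),
                ("l5", "r5", "CAF", "CAF", True),
            ]
        )
        table = count_interactions(rec)
        assert table.loc["CAF", "Cancer"] == 2
        assert table.loc["Cancer", "CAF"] == 1
        no_auto = count_interactions(rec, include_autocrine=False)
        assert no_auto.loc["CAF", "CAF"] == 0

    def test_invariant_under_record_order(self):
        rec = self._records(
            [
                ("l1", "r1", "A", "B", True),
                ("l2", "r2", "B", "A", True),
            ]
        )
        t1 = count_interactions(rec)
        t2 = count_interactions(rec.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())


def _record_pair(ligand, median_a, median_b):
    base = {
        "ligand": ligand,
        "receptor": "R_" + ligand,
        "target_a": "Cancer",
        "target_b": "Cancer",
    }
    a = {**base, "median_score_a": median_a}
    b = {**base, "median_score_b": median_b}
    return {**a, **b}


class TestBiasGates:
    def _de(self, genes, log2fc, p_adj):
        return pd.DataFrame(
            {"log2FC": log2fc, "p_adj": p_adj},
            index=pd.Index(genes, name="gene"),
        )

    def _split(self, rows, de):
        merged = pd.DataFrame(rows)
        rec_a = merged[
            ["ligand", "receptor", "median_score_a", "target_a"]
        ].rename(columns={"median_score_a": "median_score", "target_a": "target"})
        rec_b = merged[
            ["ligand", "receptor", "median_score_b", "target_b"]
        ].rename(columns={"median_score_b": "median_score", "target_b": "target"})
        return biased_interactions(rec_a, rec_b, de)

    def test_delta_exactly_at_threshold_excluded(self):
        rows = [_record_pair("L1", 0.70, 0.60)]  # delta exactly 0.1
        a, b = self._split(rows, self._de(["L1"], [3.0], [1e-9]))
        assert a.empty and b.empty

    def test_failing_fdr_gate_excluded(self):
        rows = [_record_pair("L1", 0.9, 0.55)]
        a, b = self._split(rows, self._de(["L1"], [3.0], [0.02]))
        assert a.empty and b.empty

    def test_recovers_direction_and_sets_disjoint(self):
        rows = [
            _record_pair("L1", 0.9, 0.55),  # A-biased
            _record_pair("L2", 0.45, 0.80),  # B-biased
            _record_pair("L3", 0.52, 0.49),  # delta too small
        ]
        de = self._de(["L1", "L2", "L3"], [3.0, -3.0, 3.0], [1e-9, 1e-9, 1e-9])
        a, b = self._split(rows, de)
        assert list(a["ligand"]) == ["L1"]
        assert list(b["ligand"]) == ["L2"]
        assert not (set(map(tuple, a[["ligand", "receptor"]].values))
                    & set(map(tuple, b[["ligand", "receptor"]].values)))

    def test_reliability_required_on_winning_side(self):
        rows = [_record_pair("L1", 0.48, 0.30)]  # delta 0.18 but below 0.5
        a, b = self._split(rows, self._de(["L1"], [3.0], [1e-9]))
        assert a.empty and b.empty

    def test_receptor_gate_for_reverse_direction(self):
        rows = [_record_pair("L1", 0.9, 0.55)]
        de = self._de(["R_L1"], [3.0], [1e-9])
        merged = pd.DataFrame(rows)
        rec_a = merged[
            ["ligand", "receptor", "median_score_a", "target_a"]
        ].rename(columns={"median_score_a": "median_score", "target_a": "target"})
        rec_b = merged[
            ["ligand", "receptor", "median_score_b", "target_b"]
        ].rename(columns={"median_score_b": "median_score", "target_b": "target"})
        a, b = biased_interactions(rec_a, rec_b, de, gate_gene="receptor")
        assert list(a["receptor"]) == ["R_L1"]
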