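"""Differential expression: normalization, BH adjustment, threshold
calls, overlaps and transcript-protein concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from phaomics import omics_de
from phaomics.omics_de import (
    ArraySet,
    bh_adjust,
    call_protein_de,
    call_transcript_de,
    normalize_and_logratio,
    overlap_and_concordance,
    signed_fold,
    strict_cutoff_filter,
    transcript_de_table,
)


def _bh_oracle(p):
    """Independent step-up implementation (explicit loop)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    previous = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(p[i] * m / rank, previous, 1.0)
        adjusted[i] = value
        previous = value
    return adjusted


class TestBhAdjust:
    def test_hand_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_and_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 200)))
            mine = bh_adjust(p)
            assert np.allclose(mine, _bh_oracle(list(p)), atol=1e-12)
            assert np.allclose(
                mine, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50).map(np.array)
    )
    def test_dominates_input_and_capped(self, p):
        out = bh_adjust(p)
        assert np.all(out >= p - 1e-15)
        assert np.all(out <= 1.0)


def _arrays_from_ratios(log2_ratios, bg=0.0):
    """ArraySet whose corrected log ratios equal the given matrix."""
    log2_ratios = np.asarray(log2_ratios, dtype=float)
    n, k = log2_ratios.shape
    ref = np.full((n, k), 1000.0)
    test = ref * np.exp2(log2_ratios)
    bg_mat = np.full((n, k), bg)
    return ArraySet(
        locus_tags=[f"PP{i:04d}" for i in range(n)],
        test_fg=test + bg_mat,
        test_bg=bg_mat.copy(),
        ref_fg=ref + bg_mat,
        ref_bg=bg_mat.copy(),
    )


class TestNormalize:
    def test_equal_channels_give_zero_ratios(self):
        arrays = _arrays_from_ratios(np.zeros((11, 3)))
        ratios = normalize_and_logratio(arrays)
        assert np.allclose(ratios.to_numpy(), 0.0, atol=1e-12)

    def test_single_fourfold_probe(self):
        mat = np.zeros((11, 2))
        mat[0, :] = 2.0  # log2 of 4
        ratios = normalize_and_logratio(_arrays_from_ratios(mat))
        assert np.allclose(ratios.iloc[0], 2.0, atol=1e-9)

    def test_background_over_foreground_stays_finite(self):
        n = 5
        test_fg = np.full((n, 2), 500.0)
        bg = np.full((n, 2), 400.0)
        test_fg[0] = 100.0  # fg < bg for this probe
        arrays = ArraySet(
            locus_tags=[f"g{i}" for i in range(n)],
            test_fg=test_fg,
            test_bg=bg,
            ref_fg=np.full((n, 2), 500.0),
            ref_bg=bg.copy(),
        )
        ratios = normalize_and_logratio(arrays).to_numpy()
        assert np.all(np.isfinite(ratios))


class TestSignedFold:
    def test_table_convention(self):
        assert signed_fold(np.log2(6.7)) == pytest.approx(6.7)
        assert signed_fold(-np.log2(6.7)) == pytest.approx(-6.7)

    @given(st.floats(1e-6, 10))
    def test_odd_symmetry(self, x):
        # away from the unchanged point, sign flips and magnitude holds
        assert signed_fold(-x) == pytest.approx(-signed_fold(x), rel=1e-9)

    @given(st.floats(-10, 10))
    def test_magnitude_at_least_one(self, x):
        assert abs(signed_fold(x)) >= 1.0


def _results(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "locus_tag", "log2_fold_change", "fold_change_signed",
            "p_value", "adj_p_value",
        ],
    ).set_index("locus_tag")


class TestTranscriptCalls:
    def test_up_call(self):
        table = _results([("PP2638", np.log2(3.9), 3.9, 0.0005, 0.001)])
        called, summary = call_transcript_de(table)
        assert called.loc["PP2638", "call"] == "up"
        assert summary.n_up == 1

    def test_small_fold_not_significant(self):
        table = _results([("g1", np.log2(1.5), 1.5, 0.0005, 0.001)])
        called, summary = call_transcript_de(table)
        assert called.loc["g1", "call"] == "ns"
        assert summary.n_total == 0

    def test_threshold_is_strict(self):
        table = _results([("g1", 1.0, 2.0, 0.001, 0.001)])
        called, _ = call_transcript_de(table, fc_threshold=2.0)
        assert called.loc["g1", "call"] == "ns"

    def test_counts_match_brute_force_filter(self, rng):
        n = 500
        fold = signed_fold(rng.normal(0, 2, n))
        adj = rng.uniform(0, 0.2, n)
        table = _results(
            [(f"g{i}", np.nan, fold[i], np.nan, adj[i]) for i in range(n)]
        )
        _, summary = call_transcript_de(table)
        expected_up = sum(1 for i in range(n) if fold[i] > 2 and adj[i] < 0.05)
        expected_down = sum(
            1 for i in range(n) if fold[i] < -2 and adj[i] < 0.05
        )
        assert summary.n_up == expected_up
        assert summary.n_down == expected_down

    def test_order_invariance(self, rng):
        n = 200
        fold = signed_fold(rng.normal(0, 2, n))
        adj = rng.uniform(0, 0.1, n)
        table = _results(
            [(f"g{i}", np.nan, fold[i], np.nan, adj[i]) for i in range(n)]
        )
        _, forward = call_transcript_de(table)
        _, shuffled = call_transcript_de(table.sample(frac=1, random_state=1))
        assert forward.n_up == shuffled.n_up
        assert forward.n_down == shuffled.n_down


class TestStrictCutoff:
    def test_retains_strong_hit(self):
        table = _results([("g1", np.log2(10), 10.0, 0.01, 0.1)])
        assert len(strict_cutoff_filter(table)) == 1

    def test_boundary_fold_excluded(self):
        table = _results([("g1", np.log2(3.5), 3.5, 0.01, 0.1)])
        assert len(strict_cutoff_filter(table)) == 0

    def test_uses_raw_p_not_adjusted(self):
        table = _results([("g1", np.log2(5), 5.0, 0.01, 0.5)])
        assert len(strict_cutoff_filter(table)) == 1


class TestDeTable:
    def test_planted_effect_is_recovered(self, rng):
        n = 50
        effects = np.zeros(n)
        effects[0] = 3.0
        ratios = pd.DataFrame(
            effects[:, None] + rng.normal(0, 0.05, (n, 3)),
            index=[f"g{i}" for i in range(n)],
        )
        table = transcript_de_table(ratios)
        assert table.loc["g0", "fold_change_signed"] == pytest.approx(8.0, rel=0.3)
        assert table.loc["g0", "adj_p_value"] < 0.05
        assert np.all(table["adj_p_value"] >= table["p_value"] - 1e-15)

    def test_requires_replicates(self):
        with pytest.raises(ValueError, match="replicate"):
            transcript_de_table(pd.DataFrame({"a": [0.1, 0.2]}))


def _spot_table(rows):
    return pd.DataFrame(
        rows, columns=["spot_id", "locus_tag", "gel_id", "condition", "volume"]
    )


class TestProteinCalls:
    def test_strong_up_call(self):
        rows = []
        for gel in range(3):
            rows.append((1, "PP4841", f"t{gel}", "test", 26.4 * (1 + 0.02 * gel)))
            rows.append((1, "PP4841", f"r{gel}", "ref", 1.0 * (1 + 0.02 * gel)))
        calls = call_protein_de(_spot_table(rows))
        assert calls.loc[1, "call"] == "up"
        assert calls.loc[1, "ratio"] == pytest.approx(26.4, rel=0.03)

    def test_twofold_threshold_is_inclusive(self):
        rows = []
        for gel in range(3):
            jitter = 1 + 0.001 * (gel - 1)
            rows.append((1, "g", f"t{gel}", "test", 2.0 * jitter))
            rows.append((1, "g", f"r{gel}", "ref", 1.0 * jitter))
        calls = call_protein_de(_spot_table(rows))
        assert calls.loc[1, "ratio"] >= 2.0 - 1e-9
        assert calls.loc[1, "call"] == "up"

    def test_mild_ratio_not_significant(self):
        rows = []
        for gel in range(3):
            rows.append((1, "g", f"t{gel}", "test", 1.2))
            rows.append((1, "g", f"r{gel}", "ref", 1.0))
        assert call_protein_de(_spot_table(rows)).loc[1, "call"] == "ns"

    def test_presence_absence_flags(self):
        rows = [
            (1, "ga", "t0", "test", 5.0),
            (2, "gb", "r0", "ref", 5.0),
        ]
        calls = call_protein_de(_spot_table(rows))
        assert calls.loc[1, "call"] == "only_in_test"
        assert calls.loc[2, "call"] == "only_in_ref"


class TestOverlapConcordance:
    def test_shared_loci(self):
        de_a = _results(
            [("a", 0, 4, 0, 0.01), ("b", 0, 4, 0, 0.01), ("c", 0, 4, 0, 0.01)]
        )
        de_b = _results(
            [("b", 0, 4, 0, 0.01), ("c", 0, 4, 0, 0.01), ("d", 0, 4, 0, 0.01)]
        )
        called_a, _ = call_transcript_de(de_a)
        called_b, _ = call_transcript_de(de_b)
        result = overlap_and_concordance(called_a, called_b)
        assert result["shared_loci"] == ["b", "c"]
        assert result["n_shared"] == 2

    def test_concordance_directions(self):
        transcript = _results(
            [("up_gene", 0, 4.0, 0, 0.01), ("ns_gene", 0, 1.1, 0, 0.9)]
        )
        called, _ = call_transcript_de(transcript)
        protein = pd.DataFrame(
            {
                "locus_tag": ["up_gene", "ns_gene"],
                "ratio": [3.0, 3.0],
                "p_value": [0.01, 0.01],
                "call": ["up", "up"],
            },
            index=pd.Index([1, 2], name="spot_id"),
        )
        result = overlap_and_concordance(called, called, protein)
        table = result["concordance"].set_index("locus_tag")
        assert bool(table.loc["up_gene", "concordant"])
        assert not bool(table.loc["ns_gene", "concordant"])
        assert result["n_concordant"] == 1

    def test_planted_counts_match_oracle(self, rng):
        loci = [f"g{i}" for i in range(100)]
        calls_a = rng.choice(["up", "down", "ns"], 100, p=[0.2, 0.2, 0.6])
        calls_b = rng.choice(["up", "down", "ns"], 100, p=[0.2, 0.2, 0.6])
        de_a = pd.DataFrame({"call": calls_a}, index=pd.Index(loci, name="locus_tag"))
        de_b = pd.DataFrame({"call": calls_b}, index=pd.Index(loci, name="locus_tag"))
        result = overlap_and_concordance(de_a, de_b)
        expected = {
            locus
            for locus, a, b in zip(loci, calls_a, calls_b)
            if a != "ns" and b != "ns"
        }
        assert set(result["shared_loci"]) == expected
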