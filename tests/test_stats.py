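"""Pooling, dose-response regression, BH adjustment, MoA scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bh_adjust_oracle, ols_slope_oracle
from aggscreen.stats import (
    DMSO_DILUTION,
    adjust_pvalues,
    dose_response,
    fit_dose_responses,
    moa_scores,
    pool_by_condition,
    volcano_table,
    _dose_axis,
)


def _nuclei(rows):
    return pd.DataFrame(rows, columns=["field_id", "da", "qc_pass"])


def _meta(rows):
    return pd.DataFrame(
        rows,
        columns=["field_id", "compound", "moa", "concentration_m", "cell_line"],
    )


def _summary(conc, means, compound="c1", cell_line="A", moa="m1"):
    return pd.DataFrame(
        {
            "compound": compound, "cell_line": cell_line, "moa": moa,
            "concentration_m": conc, "mean_da": means,
            "sd_da": 0.0, "n_cells": 10,
        }
    )


class TestPooling:
    def test_mean_sd_n(self):
        nuc = _nuclei([("f1", 1.0, True), ("f1", 2.0, True), ("f1", 3.0, True)])
        meta = _meta([("f1", "c1", "m1", 1e-6, "A")])
        out = pool_by_condition(nuc, meta)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["mean_da"], row["sd_da"], row["n_cells"]) == (2.0, 1.0, 3)

    def test_qc_failures_are_excluded(self):
        nuc = _nuclei([("f1", 1.0, False), ("f1", 5.0, False)])
        meta = _meta([("f1", "c1", "m1", 1e-6, "A")])
        assert pool_by_condition(nuc, meta).empty

    def test_unknown_field_rejected(self):
        nuc = _nuclei([("ghost", 1.0, True)])
        meta = _meta([("f1", "c1", "m1", 1e-6, "A")])
        with pytest.raises(ValueError):
            pool_by_condition(nuc, meta)


class TestDoseAxis:
    def test_dmso_placed_three_decades_below_lowest_dose(self):
        x = _dose_axis(np.array([0.0, 1e-8, 1e-7, 1e-6, 1e-5]))
        assert np.allclose(sorted(x), [-11, -8, -7, -6, -5])
        assert DMSO_DILUTION == 1000.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            _dose_axis(np.zeros(3))


class TestDoseResponse:
    CONC = [0.0, 1e-8, 1e-7, 1e-6, 1e-5]

    def test_exact_linear_relationship_recovered(self):
        x = _dose_axis(np.array(self.CONC))
        res = dose_response(_summary(self.CONC, 2.0 + 0.7 * x))
        assert res.slope == pytest.approx(0.7, abs=1e-12)
        assert res.slope_se == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 0.0 and res.active and res.direction == 1

    def test_constant_response_is_null(self):
        res = dose_response(_summary(self.CONC, np.full(5, 3.3)))
        assert res.slope == 0.0 and res.p_value == 1.0
        assert not res.active and res.direction == 0

    def test_matches_closed_form_ols_and_t_cdf(self):
        rng = np.random.default_rng(0)
        x = _dose_axis(np.array(self.CONC))
        for _ in range(20):
            y = 1.0 + 0.3 * x + rng.normal(0, 0.5, 5)
            res = dose_response(_summary(self.CONC, y))
            slope, _, se, t, p = ols_slope_oracle(x, y)
            assert res.slope == pytest.approx(slope, abs=1e-10)
            assert res.slope_se == pytest.approx(se, abs=1e-10)
            assert res.t_stat == pytest.approx(t, rel=1e-9)
            assert res.p_value == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize(
        "conc", [[0.0, 1e-8], [1e-8, 1e-7, 1e-6], [0.0, 0.0, 1e-8, 1e-7]]
    )
    def test_bad_condition_sets_rejected(self, conc):
        with pytest.raises(ValueError):
            dose_response(_summary(conc, np.arange(len(conc), dtype=float)))

    def test_alpha_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        summaries = pd.concat(
            [
                _summary(self.CONC, rng.normal(5, 0.3, 5), compound=f"c{i}")
                for i in range(40)
            ]
        )
        strict = fit_dose_responses(summaries, alpha=0.01)
        loose = fit_dose_responses(summaries, alpha=0.05)
        assert strict["active"].sum() <= loose["active"].sum()


class TestBH:
    def test_hand_computed_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        assert adjust_pvalues([0.2]) == pytest.approx([0.2])
        assert np.allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_dominates_raw_p_and_is_order_invariant(self, p, rnd):
        adj = adjust_pvalues(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        assert np.allclose(adj, bh_adjust_oracle(p))
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = adjust_pvalues([p[i] for i in perm])
        assert np.allclose(shuffled, adj[perm])


def _responses(rows):
    return pd.DataFrame(
        rows, columns=["compound", "cell_line", "moa", "slope", "p_value",
                       "active", "direction"]
    )


class TestMoaScores:
    def test_hand_computed_mixed_moa(self):
        rows = [
            (f"c{i}", "A", "moa1", s, 0.01 if d else 0.5, bool(d), d)
            for i, (s, d) in enumerate(
                [(1.0, 1), (2.0, 1), (-1.0, -1), (0.1, 0), (0.2, 0)]
            )
        ]
        out = moa_scores(_responses(rows))
        assert len(out) == 1
        assert out.iloc[0]["score"] == pytest.approx(0.2)
        assert out.iloc[0]["n_compounds"] == 5

    def test_fully_active_moa_reaches_bound(self):
        rows = [(f"c{i}", "A", "moa1", 1.0, 0.001, True, 1) for i in range(6)]
        assert moa_scores(_responses(rows)).iloc[0]["score"] == 1.0

    def test_small_moa_is_omitted(self):
        rows = [(f"c{i}", "A", "tiny", 1.0, 0.001, True, 1) for i in range(4)]
        assert moa_scores(_responses(rows)).empty

    def test_score_invariant_under_compound_permutation(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"c{i}", "A", "moa1", 0.0, 0.5, bool(d), int(d))
            for i, d in enumerate(rng.choice([-1, 0, 1], size=9))
        ]
        df = _responses(rows)
        base = moa_scores(df).iloc[0]["score"]
        shuffled = moa_scores(df.sample(frac=1, random_state=7)).iloc[0]["score"]
        assert shuffled == base
        assert abs(base) <= 1.0


class TestVolcano:
    def test_alpha_line_and_values(self):
        rows = [("c1", "A", "m", 2.0, 0.05, False, 0),
                ("c2", "A", "m", -1.0, 0.0, True, -1)]
        out = volcano_table(_responses(rows), alpha=0.05)
        assert out.attrs["alpha"] == 0.05
        assert out.iloc[0]["neg_log10_p"] == pytest.approx(1.301029995663981)
        assert out.iloc[1]["neg_log10_p"] == 300.0  # capped at the ceiling

    def test_inactive_compound_stays_flagged_inactive(self):
        rows = [("c1", "A", "m", 99.0, 0.9, False, 0)]
        assert not volcano_table(_responses(rows)).iloc[0]["active"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            volcano_table(_responses([]))
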