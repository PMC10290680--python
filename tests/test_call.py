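"""Per-line t-tests, Fisher combination, BH adjustment, null model and the
candidate decision rule — against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats
from hypothesis import given, settings, strategies as st

import ppbscreen as pb
from ppbscreen.call import (P_FLOOR, bh_adjust, call_candidates,
                            estimate_null_model, fisher_combine,
                            per_line_test)


def _profile(layout, log2_values):
    """Series over layout channels from log2 values."""
    return pd.Series(np.exp2(np.asarray(log2_values, dtype=float)),
                     index=list(layout.channels))


def _bh_oracle(p):
    """Brute-force step-up: q_i = min over j with p_j >= p_i of p_(j)*n/rank."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPerLineTest:
    def test_symmetric_null_gives_half(self, small_layout):
        prof = _profile(small_layout, [3.0] * 6)
        p, fc = per_line_test(prof, small_layout, "H1")
        assert p == 0.5 and fc == 0.0

    def test_textbook_pooled_t(self, small_layout):
        """Line log2 {10.0, 10.2} vs blanks {8.0, 8.1}: hand pooled-t."""
        prof = _profile(small_layout, [10.0, 10.2, 0.0, 0.0, 8.0, 8.1])
        p, fc = per_line_test(prof, small_layout, "H1")
        assert fc == pytest.approx(10.1 - 8.05)
        x, y = np.array([10.0, 10.2]), np.array([8.0, 8.1])
        sp2 = (x.var(ddof=1) + y.var(ddof=1)) / 2  # equal group sizes, df=2
        t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert p == pytest.approx(float(scipy.stats.t.sf(t, 2)), rel=1e-12)

    def test_three_blank_design_df3(self, layout):
        """2 replicates vs 3 blanks: df = 3 pooled t, one-tailed."""
        log2 = np.zeros(11)
        log2[0], log2[1] = 10.0, 10.2          # HepG2 replicates
        log2[8], log2[9], log2[10] = 8.0, 8.1, 7.9
        p, fc = per_line_test(_profile(layout, log2), layout, "HepG2")
        assert fc == pytest.approx(2.1)
        x = np.array([10.0, 10.2])
        y = np.array([8.0, 8.1, 7.9])
        sp2 = (x.var(ddof=1) + 2 * y.var(ddof=1)) / 3
        t = 2.1 / math.sqrt(sp2 * (1 / 2 + 1 / 3))
        assert p == pytest.approx(float(scipy.stats.t.sf(t, 3)), rel=1e-12)

    def test_one_tailed_direction(self, small_layout):
        prof = _profile(small_layout, [7.0, 7.1, 0.0, 0.0, 9.0, 9.2])
        p, fc = per_line_test(prof, small_layout, "H1")
        assert fc < 0 and p > 0.5

    def test_zero_variance_unequal_means_floored(self, small_layout):
        prof = _profile(small_layout, [10.0, 10.0, 0.0, 0.0, 8.0, 8.0])
        p, fc = per_line_test(prof, small_layout, "H1")
        assert p == P_FLOOR and fc == 2.0

    def test_nonpositive_intensity_rejected(self, small_layout):
        prof = pd.Series([1.0, 1.0, 1.0, 1.0, 0.0, 1.0],
                         index=list(small_layout.channels))
        with pytest.raises(pb.ContractError):
            per_line_test(prof, small_layout, "H1")


class TestFisherCombine:
    def test_all_ones(self):
        x2, cp = fisher_combine([1.0, 1.0, 1.0, 1.0])
        assert x2 == 0.0 and cp == 1.0

    def test_hand_logsum(self):
        """p = (0.1, 0.2, 0.3, 0.4): X2 = -2 sum(ln p) ~ 12.065."""
        ps = [0.1, 0.2, 0.3, 0.4]
        x2, cp = fisher_combine(ps)
        oracle_x2 = -2.0 * sum(math.log(p) for p in ps)
        assert x2 == pytest.approx(oracle_x2, rel=1e-14)
        assert x2 == pytest.approx(12.065, abs=5e-3)
        # independent tail oracle: chi2(2L) sf == regularized upper gamma
        assert cp == pytest.approx(
            float(scipy.special.gammaincc(4, x2 / 2)), rel=1e-12)

    def test_dominant_small_p(self):
        _, cp = fisher_combine([1e-12, 1.0, 1.0, 1.0])
        assert cp < 1e-8

    def test_zero_p_floored_not_crashing(self):
        x2, cp = fisher_combine([0.0, 1.0])
        assert np.isfinite(x2) and 0.0 <= cp <= 1.0

    def test_contract_errors(self):
        with pytest.raises(pb.ContractError):
            fisher_combine([])
        with pytest.raises(pb.ContractError):
            fisher_combine([1.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-300, 1.0), min_size=1, max_size=8))
    def test_matches_gamma_tail_oracle(self, ps):
        x2, cp = fisher_combine(ps)
        assert x2 == pytest.approx(-2.0 * sum(math.log(p) for p in ps),
                                   rel=1e-12)
        assert cp == pytest.approx(
            float(scipy.special.gammaincc(len(ps), x2 / 2)),
            rel=1e-9, abs=1e-300)

    def test_calibrated_on_independent_uniforms(self):
        """Combined p of independent uniform p-values is itself uniform."""
        rng = np.random.default_rng(0)
        cps = [fisher_combine(rng.uniform(size=4))[1] for _ in range(2000)]
        assert scipy.stats.kstest(cps, "uniform").statistic < 0.05


class TestBHAdjust:
    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]),
                                      [1.0, 1.0, 1.0])

    def test_hand_stepup(self):
        """(0.01, 0.02, 0.03, 0.04) -> all 0.04 by the step-up minimum."""
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_bruteforce_oracle(self, ps):
        q = bh_adjust(ps)
        oracle = _bh_oracle(ps)
        # atol absorbs denormal rounding (multiplication-order ulps ~1e-323)
        np.testing.assert_allclose(q, oracle, rtol=1e-12, atol=1e-305)
        assert (q >= np.asarray(ps) - 1e-15).all()

    def test_random_vectors_against_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ps = rng.uniform(size=rng.integers(1, 200))
            np.testing.assert_allclose(bh_adjust(ps), _bh_oracle(ps),
                                       rtol=1e-12)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0


def _table_from_log2(layout, log2_matrix, proteins):
    rel = np.exp2(np.asarray(log2_matrix, dtype=float))
    rel = rel / rel.mean(axis=1, keepdims=True)
    idx = pd.Index(proteins, name="protein")
    return pb.ProteinQuantTable(
        pd.DataFrame(rel, index=idx, columns=list(layout.channels)),
        pd.Series(1, index=idx))


class TestNullModel:
    def test_identical_replicates_degenerate(self, layout):
        table = _table_from_log2(layout, np.zeros((5, 11)),
                                 [f"P{i}" for i in range(5)])
        with pytest.raises(pb.DegeneracyError):
            estimate_null_model(table, layout)

    def test_gaussian_sd_recovered(self, layout):
        """5000 replicate log2 ratios from N(0, 0.2): sigma0 within 5%."""
        rng = np.random.default_rng(31)
        n = 1250                                  # x 4 lines = 5000 ratios
        log2 = np.zeros((n, 11))
        for j in (1, 3, 5, 7):                    # second replicate channels
            log2[:, j] = rng.normal(0.0, 0.2, n)  # ratio SD exactly 0.2
        table = _table_from_log2(layout, log2, [f"P{i}" for i in range(n)])
        null = estimate_null_model(table, layout, "mle")
        assert null.n_ratios == 5000
        assert null.sigma0 == pytest.approx(0.2, rel=0.05)
        assert abs(null.mu0) < 0.02
        mad = estimate_null_model(table, layout, "mad")
        assert mad.sigma0 == pytest.approx(0.2, rel=0.08)

    def test_low_support_property(self):
        nm = pb.NullModel(0.0, 0.1, n_ratios=10, estimator="mle")
        assert nm.low_support
        with pytest.raises(pb.DegeneracyError):
            pb.NullModel(0.0, 0.0, 100, "mle")


class TestCallCandidates:
    def _simulated(self, layout, **kw):
        cfg_kw = dict(n_proteins=300, seed=77)
        cfg_kw.update(kw)
        psms, truth = pb.simulate_experiment(pb.SimConfig(**cfg_kw), layout)
        res = pb.run_pipeline(psms, layout)
        return res, truth

    def test_decision_rule_is_conjunction(self, layout):
        res, _ = self._simulated(layout)
        d = res.candidates.data
        rule = (d["q_value"] < 0.01) & (d["z_score"] > 3.0)
        assert (d["is_candidate"] == rule).all()
        assert (d["q_value"] >= d["combined_p"] - 1e-12).all()
        assert (d["fisher_x2"] >= 0).all()

    @pytest.mark.parametrize("q,z,expected", [
        (0.005, 3.5, True), (0.005, 2.9, False), (0.02, 5.0, False)])
    def test_threshold_combinations(self, q, z, expected):
        assert ((q < 0.01) and (z > 3.0)) is expected  # the documented rule
        df = pd.DataFrame({
            "protein": ["P1"], "p_A": [q], "log2fc_A": [z * 0.1],
            "fisher_x2": [1.0], "combined_p": [q], "q_value": [q],
            "z_score": [z], "is_candidate": [expected]})
        pb.CandidateTable(df, pb.NullModel(0.0, 0.1, 100, "mle"), ("A",),
                          0.01, 3.0)  # inconsistent flags would raise

    def test_fc_rule_variants(self, layout):
        res, _ = self._simulated(layout)
        table = res.proteins
        null = res.candidates.null_model
        fcs = {rule: call_candidates(table, layout, null, fc_rule=rule)
               for rule in ("max", "mean", "all")}
        cols = [f"log2fc_{l}" for l in layout.cell_lines]
        d = fcs["max"].data.set_index("protein")
        fc_mat = d[cols].to_numpy()
        np.testing.assert_allclose(
            d["z_score"].to_numpy(),
            (fc_mat.max(axis=1) - null.mu0) / null.sigma0)
        dm = fcs["mean"].data.set_index("protein")
        np.testing.assert_allclose(
            dm["z_score"].to_numpy(),
            (fc_mat.mean(axis=1) - null.mu0) / null.sigma0)
        da = fcs["all"].data.set_index("protein")
        np.testing.assert_allclose(
            da["z_score"].to_numpy(),
            (fc_mat.min(axis=1) - null.mu0) / null.sigma0)

    def test_row_and_channel_order_invariance(self, layout):
        res, _ = self._simulated(layout)
        table = res.proteins
        null = res.candidates.null_model
        base = call_candidates(table, layout, null)

        # permute protein rows
        perm = table.relative.sample(frac=1, random_state=1)
        shuffled = pb.ProteinQuantTable(
            perm, table.n_psms.reindex(perm.index))
        out = call_candidates(shuffled, layout, null)
        merged = out.data.set_index("protein").reindex(
            base.data["protein"])
        np.testing.assert_allclose(
            merged["combined_p"].to_numpy(),
            base.data["combined_p"].to_numpy(), rtol=1e-12)
        assert set(out.candidates) == set(base.candidates)

        # permute channel columns together with the layout channel order
        rev = list(layout.channels)[::-1]
        layout_rev = pb.ChannelLayout(tuple(rev), layout.roles,
                                      layout.species, layout.blank_reference)
        table_rev = pb.ProteinQuantTable(
            table.relative[rev], table.n_psms)
        out_rev = call_candidates(table_rev, layout_rev, null)
        np.testing.assert_allclose(
            out_rev.data["combined_p"].to_numpy(),
            base.data["combined_p"].to_numpy(), rtol=1e-12)

    def test_per_line_p_uniform_under_null(self, layout):
        """With no binders the per-line one-tailed p-values are uniform."""
        psms, _ = pb.simulate_experiment(
            pb.SimConfig(n_proteins=2000, binder_fraction=0.0, seed=11),
            layout)
        res = pb.run_pipeline(psms, layout)
        for line in layout.cell_lines:
            pv = res.candidates.data[f"p_{line}"].to_numpy()
            assert scipy.stats.kstest(pv, "uniform").statistic < 0.05

    def test_no_candidates_under_pure_null(self, layout):
        psms, _ = pb.simulate_experiment(
            pb.SimConfig(n_proteins=1000, binder_fraction=0.0, seed=19),
            layout)
        res = pb.run_pipeline(psms, layout)
        assert int(res.candidates.data["is_candidate"].sum()) == 0
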