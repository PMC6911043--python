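"""Differential-splicing calling, Bayes-factor surrogate, cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ssclip import splicing, synthetic
from ssclip.io import PsiMatrix, ValidationError
from ssclip.synthetic import SimConfig


def bf_integration_oracle(ia, ea, ib, eb):
    """Beta(1,1)-binomial Bayes factor by direct numerical integration of the
    marginal likelihoods (binomial constants cancel between models)."""
    def beta_integral(i, e):
        mode = i / (i + e) if i + e > 0 else 0.5
        log_peak = i * np.log(mode if mode > 0 else 1) + e * np.log1p(-mode if mode < 1 else 0)

        def f(p):
            with np.errstate(divide="ignore"):
                lg = i * np.log(p) + e * np.log1p(-p) - log_peak
            return np.exp(lg)

        val, _ = integrate.quad(f, 0, 1, epsabs=1e-14, epsrel=1e-12, limit=200)
        return np.log(val) + log_peak

    log_bf = (beta_integral(ia, ea) + beta_integral(ib, eb)
              - beta_integral(0, 0) - beta_integral(ia + ib, ea + eb))
    return float(np.exp(log_bf))


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    n, r, k = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r + k - n), min(r, k) + 1)
    pmf = stats.hypergeom.pmf(support, n, r, k)
    p_obs = stats.hypergeom.pmf(a, n, r, k)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestPsiFromCounts:
    @pytest.mark.parametrize("inc,exc,expected", [
        (8, 2, 0.8), (0, 5, 0.0), (5, 0, 1.0),
    ])
    def test_values(self, inc, exc, expected):
        assert splicing.psi_from_counts(inc, exc) == pytest.approx(expected)

    def test_no_reads_is_missing(self):
        assert np.isnan(splicing.psi_from_counts(0, 0))


class TestBayesFactor:
    def test_identical_large_counts_favour_shared_model(self):
        assert splicing.bayes_factor((50, 50), (50, 50)) < 1.0

    def test_opposite_extremes_give_large_bf(self):
        assert splicing.bayes_factor((20, 0), (0, 20)) > 5.0

    def test_zero_reads_is_uninformative(self):
        assert splicing.bayes_factor((15, 5), (0, 0)) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            splicing.bayes_factor((-1, 2), (3, 4))

    def test_matches_numerical_integration_oracle(self):
        """Closed form equals the integration oracle to 1e-6 relative error
        over a grid of counts up to 50."""
        grid = [0, 1, 2, 5, 12, 27, 50]
        rng = np.random.default_rng(0)
        combos = [(ia, ea, ib, eb)
                  for ia in grid for ea in grid for ib in grid for eb in grid]
        for ia, ea, ib, eb in rng.permutation(combos)[:400]:
            got = splicing.bayes_factor((ia, ea), (ib, eb))
            want = bf_integration_oracle(ia, ea, ib, eb)
            assert got == pytest.approx(want, rel=1e-6)


class TestCallDifferentialEvents:
    def _events(self, rows):
        recs = []
        for i, (iw, ew, im, em, etype) in enumerate(rows):
            recs.append((f"e{i}", etype, f"s{i}", "wild_type", iw, ew))
            recs.append((f"e{i}", etype, f"s{i}", "mutant", im, em))
        return pd.DataFrame(recs, columns=[
            "event_id", "event_type", "site_id", "condition",
            "inclusion_reads", "exclusion_reads"])

    def test_gates(self):
        calls = splicing.call_differential_events(self._events([
            (10, 30, 30, 10, "SE"),   # dpsi 0.5, strong BF, reads 40 -> called
            (10, 30, 13, 27, "SE"),   # dpsi < 0.10 at similar counts -> none
            (4, 3, 3, 4, "SE"),       # reads < 10 -> none
        ]))
        calls = calls.set_index("event_id")
        assert calls.loc["e0", "call"] == "mut_preferred"
        assert calls.loc["e0", "bayes_factor"] >= 5
        assert calls.loc["e1", "call"] == "none"
        assert calls.loc["e2", "call"] == "none"

    def test_sign_symmetry(self):
        """Swapping the two conditions negates every dpsi and swaps the calls."""
        events = self._events([(10, 30, 35, 5, "SE"), (30, 10, 5, 35, "RI"),
                               (20, 20, 22, 18, "SE")])
        fwd = splicing.call_differential_events(events)
        rev = splicing.call_differential_events(
            events, conditions=("mutant", "wild_type"))
        np.testing.assert_allclose(fwd["dpsi"], -rev["dpsi"])
        np.testing.assert_allclose(fwd["bayes_factor"], rev["bayes_factor"])
        swap = {"mut_preferred": "wt_preferred", "wt_preferred": "mut_preferred",
                "none": "none"}
        assert rev["call"].map(swap).tolist() == fwd["call"].tolist()

    def test_sensitivity_on_generator(self, small_reference):
        _, sites = small_reference
        cfg = SimConfig(n_genes=60)
        psi, counts, truth = synthetic.simulate_psi_cohort(sites, cfg, 4)
        calls = splicing.call_differential_events(counts)
        merged = calls.merge(truth[["event_id", "affected"]], on="event_id")
        sens = (merged.loc[merged["affected"], "call"] != "none").mean()
        assert sens > 0.8


class TestEventTypeFrequency:
    def test_matching_proportions_give_p_one(self):
        calls = pd.DataFrame({
            "event_type": ["SE"] * 30 + ["RI"] * 30,
            "call": ["mut_preferred"] * 60,
        })
        table, chi2, p = splicing.event_type_frequency_test(
            calls, {"SE": 100, "RI": 100})
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # observed [50, 10] vs expected [30, 30]: chi2 = 400/30 + 400/30
        calls = pd.DataFrame({
            "event_type": ["SE"] * 50 + ["RI"] * 10,
            "call": ["mut_preferred"] * 60,
        })
        _, chi2, p = splicing.event_type_frequency_test(calls, {"SE": 5, "RI": 5})
        assert chi2 == pytest.approx(400 / 30 + 400 / 30)

    def test_zero_expected_category_merged(self):
        calls = pd.DataFrame({
            "event_type": ["SE"] * 10 + ["NAGNAG"] * 2,
            "call": ["mut_preferred"] * 12,
        })
        table, chi2, p = splicing.event_type_frequency_test(
            calls, {"SE": 50, "RI": 10, "NAGNAG": 0})
        assert "NAGNAG" not in table["event_type"].tolist()
        assert table["observed"].sum() == 12


class TestSe3ssTrinucleotides:
    def test_all_increased_cag(self, small_reference):
        _, sites = small_reference
        cag_sites = sites[sites["acceptor"] == "CAG"].head(4)
        calls = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(4)],
            "event_type": "SE",
            "site_id": cag_sites["site_id"].to_numpy(),
            "dpsi": [0.3, 0.2, 0.4, 0.25],
            "call": "mut_preferred",
        })
        freq = splicing.se_3ss_trinucleotides(calls, sites)
        row = freq.set_index("trinucleotide")
        assert row.loc["CAG", "increased"] == 1.0

    def test_no_calls_gives_empty_table(self, small_reference):
        _, sites = small_reference
        calls = pd.DataFrame({"event_id": [], "event_type": [], "site_id": [],
                              "dpsi": [], "call": []})
        assert splicing.se_3ss_trinucleotides(calls, sites).empty

    def test_cag_enriched_among_mutant_included(self, small_reference):
        _, sites = small_reference
        cfg = SimConfig(n_genes=60)
        psi, counts, truth = synthetic.simulate_psi_cohort(sites, cfg, 8)
        calls = splicing.call_differential_events(counts)
        freq = splicing.se_3ss_trinucleotides(calls, sites).set_index("trinucleotide")
        assert freq.loc["CAG", "increased"] > freq.loc["CAG", "decreased"]
        assert freq.loc["TAG", "increased"] < freq.loc["TAG", "decreased"]


class TestCohort:
    def _psi(self, group_i, group_ii):
        values = pd.DataFrame(
            np.vstack([np.concatenate([row_i, row_ii])
                       for row_i, row_ii in zip(group_i, group_ii)]),
            index=[f"e{k}" for k in range(len(group_i))],
            columns=[f"m{j}" for j in range(len(group_i[0]))]
            + [f"w{j}" for j in range(len(group_ii[0]))],
        )
        groups = pd.Series(["mutant"] * len(group_i[0])
                           + ["wild_type"] * len(group_ii[0]),
                           index=values.columns)
        return PsiMatrix(values, groups)

    def test_identical_distributions_not_called(self):
        psi = self._psi([[0.5, 0.52, 0.48, 0.5, 0.5]], [[0.5, 0.49, 0.51, 0.5, 0.5]])
        calls = splicing.cohort_call(psi)
        assert not calls["called"].any()

    def test_clear_shift_called_with_direction(self):
        jit = np.array([0.0, 0.001, -0.001, 0.002, -0.002])
        psi = self._psi([0.8 + jit], [0.6 + jit])
        calls = splicing.cohort_call(psi)
        assert calls.loc[0, "called"]
        assert calls.loc[0, "direction"] == "increased"
        # Welch t-test oracle on the same rows
        t, p = stats.ttest_ind(0.8 + jit, 0.6 + jit, equal_var=False)
        assert calls.loc[0, "t_p"] == pytest.approx(p)

    def test_single_value_group_skipped(self):
        psi = self._psi([[0.8, np.nan, np.nan, np.nan, np.nan]],
                        [[0.6, 0.61, 0.59, 0.6, 0.62]])
        calls = splicing.cohort_call(psi)
        assert not calls.loc[0, "tested"]
        assert not calls.loc[0, "called"]


class TestCagTagFisher:
    def _calls(self, rows, sites):
        return pd.DataFrame(rows, columns=["event_id", "site_id", "dmedian",
                                           "called"])

    def test_balanced_table_gives_or_one(self, small_reference):
        _, sites = small_reference
        cag = sites[sites["acceptor"] == "CAG"]["site_id"].to_numpy()
        tag = sites[sites["acceptor"] == "TAG"]["site_id"].to_numpy()
        rows = []
        for i in range(10):
            rows.append((f"c{i}", cag[i], 0.1 if i < 5 else -0.1, True))
            rows.append((f"t{i}", tag[i], 0.1 if i < 5 else -0.1, True))
        res = splicing.cohort_cag_tag_test(self._calls(rows, sites), sites)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self, small_reference):
        _, sites = small_reference
        cag = sites[sites["acceptor"] == "CAG"]["site_id"].to_numpy()
        tag = sites[sites["acceptor"] == "TAG"]["site_id"].to_numpy()
        rows = [(f"c{i}", cag[i], 0.2, True) for i in range(10)]
        rows += [(f"t{i}", tag[i], -0.2, True) for i in range(10)]
        res = splicing.cohort_cag_tag_test(self._calls(rows, sites), sites)
        assert res.table.tolist() == [[10, 0], [0, 10]]
        assert res.p == pytest.approx(fisher_enumeration_oracle(res.table))

    def test_zero_margin_warns_p_one(self, small_reference):
        _, sites = small_reference
        cag = sites[sites["acceptor"] == "CAG"]["site_id"].to_numpy()
        rows = [(f"c{i}", cag[i], 0.2, True) for i in range(5)]
        res = splicing.cohort_cag_tag_test(self._calls(rows, sites), sites)
        assert res.p == 1.0


class TestEventZscores:
    def _psi(self):
        values = pd.DataFrame(
            {"m1": [0.7, 0.5, 0.9], "w1": [0.4, 0.4, 0.2],
             "w2": [0.5, 0.5, 0.2], "w3": [0.6, 0.6, 0.2]},
            index=["e1", "e2", "e3"])
        groups = pd.Series(["mutant", "wild_type", "wild_type", "wild_type"],
                           index=values.columns)
        return PsiMatrix(values, groups)

    def test_formula(self):
        z = splicing.event_zscores(self._psi())
        # WT mean 0.5, sd 0.1 -> mutant 0.7 gives Z = 2.0
        assert z.loc["e1", "m1"] == pytest.approx(2.0)
        # mutant equal to the WT mean gives Z = 0
        assert z.loc["e2", "m1"] == pytest.approx(0.0)
        # WT sd 0 -> missing
        assert np.isnan(z.loc["e3", "m1"])

    def test_held_out_wt_zscores_center_on_zero(self, small_reference):
        """Wild-type samples scored against the rest of their own group have
        mean Z approximately zero."""
        _, sites = small_reference
        cfg = SimConfig(n_genes=60)
        psi, _, _ = synthetic.simulate_psi_cohort(sites, cfg, 6)
        wt = psi.samples_in("wild_type")
        held_out = wt[:40]
        groups = psi.groups.loc[wt].copy()
        groups[held_out] = "held_out"
        sub = PsiMatrix(psi.values[wt], groups)
        z = splicing.event_zscores(sub, wt_group="wild_type")
        assert set(z.columns) == set(held_out)
        assert abs(np.nanmean(z.to_numpy())) < 0.05


class TestOverlapAssociation:
    def test_concordant_toy_matches_enumeration(self):
        ref = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(20)],
            "dpsi": [0.3] * 10 + [-0.3] * 10,
        })
        z = pd.DataFrame({"m1": [2.0] * 10 + [-2.0] * 10},
                         index=[f"e{i}" for i in range(20)])
        res = splicing.overlap_association(ref, z)
        assert res.table.tolist() == [[10, 0], [0, 10]]
        assert res.p == pytest.approx(fisher_enumeration_oracle(res.table))

    def test_no_extreme_z_rejected(self):
        ref = pd.DataFrame({"event_id": ["e1"], "dpsi": [0.3]})
        z = pd.DataFrame({"m1": [0.5]}, index=["e1"])
        with pytest.raises(ValidationError, match="empty contingency"):
            splicing.overlap_association(ref, z)

    def test_shuffled_directions_are_uncalibrated_null(self):
        """With directions independent of Z the association p-values are not
        systematically small."""
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(30):
            ids = [f"e{i}" for i in range(60)]
            z = pd.DataFrame({"m1": rng.normal(0, 2, 60)}, index=ids)
            ref = pd.DataFrame({
                "event_id": ids,
                "dpsi": rng.choice([-0.3, 0.3], 60),
            })
            pvals.append(splicing.overlap_association(ref, z).p)
        assert np.mean(np.array(pvals) < 0.05) < 0.2
        assert np.mean(pvals) > 0.3
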