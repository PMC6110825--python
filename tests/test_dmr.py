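"""Site filtering, window tiling, and the two-group window test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methperm as mp
from methperm.dmr import dmr_summary, differentially_methylated_genes


def _calls(rows):
    """Build a per-sample call frame from (pos, m, n, methylated) rows."""
    return pd.DataFrame(
        [("chr1", p, m, n, sig) for p, m, n, sig in rows],
        columns=["chrom", "pos", "m", "n", "methylated"])


TWO_GROUPS = {"care_1": "care", "nocare_1": "nocare"}


class TestFilterSites:
    def test_hand_enumerated_bookkeeping(self):
        # site 10: fine in both samples, significant in one -> kept
        # site 20: coverage 171 in s2 -> removed
        # site 30: coverage 0 in s2 -> removed
        # site 40: never significant -> removed
        s1 = _calls([(10, 5, 30, True), (20, 5, 30, True),
                     (30, 5, 30, True), (40, 0, 30, False)])
        s2 = _calls([(10, 0, 170, False), (20, 0, 171, False),
                     (30, 0, 0, False), (40, 0, 30, False)])
        out = mp.filter_sites({"s1": s1, "s2": s2})
        assert list(out.index.get_level_values("pos")) == [10]

    def test_site_missing_from_one_sample_removed(self):
        s1 = _calls([(10, 5, 30, True), (50, 5, 30, True)])
        s2 = _calls([(10, 1, 30, False)])
        out = mp.filter_sites({"s1": s1, "s2": s2})
        assert list(out.index.get_level_values("pos")) == [10]

    def test_disjoint_universes_raise(self):
        s1 = _calls([(10, 5, 30, True)])
        s2 = _calls([(20, 5, 30, True)])
        with pytest.raises(ValueError, match="disjoint"):
            mp.filter_sites({"s1": s1, "s2": s2})

    def test_boundary_coverage_170_kept(self):
        s1 = _calls([(10, 5, 170, True)])
        s2 = _calls([(10, 5, 170, False)])
        out = mp.filter_sites({"s1": s1, "s2": s2})
        assert len(out) == 1


class TestBinWindows:
    @staticmethod
    def _filtered(positions):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": positions,
            "m_s1": 1, "n_s1": 10, "m_s2": 1, "n_s2": 10,
        }).set_index(["chrom", "pos"])
        return df

    def test_two_cpgs_keep_window(self):
        win = mp.bin_windows(self._filtered([50, 150]))
        assert len(win) == 1
        assert win.loc[0, "start"] == 0 and win.loc[0, "cpg_count"] == 2
        assert win.loc[0, "n_s1"] == 20

    def test_singleton_window_dropped(self):
        win = mp.bin_windows(self._filtered([250]))
        assert win.empty

    def test_boundary_position_goes_to_next_window(self):
        win = mp.bin_windows(self._filtered([199, 200, 201]), min_cpg=1)
        starts = dict(zip(win["start"], win["cpg_count"]))
        assert starts == {0: 1, 200: 2}

    def test_tiling_is_a_partition(self):
        rng = np.random.default_rng(0)
        pos = np.unique(rng.integers(0, 10_000, size=500))
        win = mp.bin_windows(self._filtered(pos), min_cpg=1)
        assert win["cpg_count"].sum() == len(pos)
        assert (win["start"] % 200 == 0).all()
        assert ((win["end"] - win["start"]) == 200).all()


def _window_frame(per_sample):
    """Row frame from {sid: (m, n)}."""
    data = {"chrom": ["chr1"], "start": [0], "end": [200], "cpg_count": [2]}
    for sid, (m, n) in per_sample.items():
        data[f"m_{sid}"] = [m]
        data[f"n_{sid}"] = [n]
    return pd.DataFrame(data)


class TestWindowTest:
    def test_equal_proportions_not_significant(self):
        win = _window_frame({"care_1": (30, 100), "nocare_1": (30, 100)})
        out = mp.test_windows(win, TWO_GROUPS)
        assert out.loc[0, "diff"] == 0.0
        assert out.loc[0, "p_value"] > 0.99

    def test_fisher_matches_hypergeometric_tail(self):
        win = _window_frame({"care_1": (30, 100), "nocare_1": (10, 100)})
        out = mp.test_windows(win, TWO_GROUPS, backend="fisher")
        # brute-force two-sided Fisher: sum of all tables with
        # probability <= that of the observed table
        observed = stats.hypergeom.pmf(30, 200, 40, 100)
        brute = sum(
            stats.hypergeom.pmf(k, 200, 40, 100)
            for k in range(0, 41)
            if stats.hypergeom.pmf(k, 200, 40, 100) <= observed * (1 + 1e-9)
        )
        assert out.loc[0, "p_value"] == pytest.approx(brute, rel=1e-9)
        assert out.loc[0, "diff"] == pytest.approx(20.0)

    @pytest.mark.parametrize("table", [
        {"care_1": (12, 40), "care_2": (3, 25), "nocare_1": (1, 30),
         "nocare_2": (8, 22)},
        {"care_1": (0, 15), "care_2": (0, 10), "nocare_1": (5, 20),
         "nocare_2": (2, 18)},
    ])
    def test_glm_matches_statsmodels_fit(self, table):
        # independent route: iteratively fitted binomial GLM with a
        # group covariate, LRT against the intercept-only model
        import statsmodels.api as sm

        groups = {s: s.rsplit("_", 1)[0] for s in table}
        win = _window_frame(table)
        out = mp.test_windows(win, groups)

        endog = np.array([[m, n - m] for m, n in table.values()])
        x_alt = np.column_stack([
            np.ones(len(table)),
            [1.0 if g == "care" else 0.0
             for g in (s.rsplit("_", 1)[0] for s in table)]])
        fit_alt = sm.GLM(endog, x_alt, family=sm.families.Binomial()).fit()
        fit_null = sm.GLM(endog, x_alt[:, :1],
                          family=sm.families.Binomial()).fit()
        lrt = 2 * (fit_alt.llf - fit_null.llf)
        p_ref = stats.chi2.sf(max(lrt, 0.0), df=1)
        assert out.loc[0, "p_value"] == pytest.approx(p_ref, abs=1e-6)

    def test_uncovered_group_is_untested(self):
        win = _window_frame({"care_1": (0, 0), "nocare_1": (5, 10)})
        out = mp.test_windows(win, TWO_GROUPS)
        assert np.isnan(out.loc[0, "p_value"])

    def test_sign_convention_positive_means_higher_in_care(self):
        win = _window_frame({"care_1": (8, 10), "nocare_1": (2, 10)})
        out = mp.test_windows(win, TWO_GROUPS)
        assert out.loc[0, "diff"] == pytest.approx(60.0)

    def test_single_window_wrapper(self):
        counts = pd.DataFrame({
            "sample_id": ["care_1", "nocare_1"],
            "m": [30, 10], "n": [100, 100]})
        p, diff = mp.test_window(counts, TWO_GROUPS, backend="fisher")
        assert diff == pytest.approx(20.0) and 0 < p < 1

    def test_null_pvalues_roughly_uniform(self):
        # exchangeable data: window p-values must be (super-)uniform
        rng = np.random.default_rng(7)
        n_win = 5_000
        data = {"chrom": "chr1",
                "start": np.arange(n_win) * 200,
                "end": np.arange(n_win) * 200 + 200,
                "cpg_count": 3}
        for sid in ("care_1", "care_2", "care_3",
                    "nocare_1", "nocare_2", "nocare_3"):
            n = rng.poisson(90, n_win) + 3
            data[f"m_{sid}"] = rng.binomial(n, 0.4)
            data[f"n_{sid}"] = n
        win = pd.DataFrame(data)
        groups = {s: s.rsplit("_", 1)[0] for s in
                  ("care_1", "care_2", "care_3",
                   "nocare_1", "nocare_2", "nocare_3")}
        out = mp.test_windows(win, groups)
        p = out["p_value"].to_numpy()
        # allow super-uniformity: the empirical CDF may sit below the
        # diagonal but not above it by more than the 10% tolerance
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = np.array([(p <= g).mean() for g in grid])
        assert (ecdf <= grid + 0.10).all()


class TestCallDmrs:
    def test_bh_identity_for_single_window(self):
        win = _window_frame({"care_1": (30, 100), "nocare_1": (10, 100)})
        tested = mp.test_windows(win, TWO_GROUPS)
        tested.loc[0, "p_value"] = 0.001
        tested.loc[0, "diff"] = 10.0
        called = mp.call_dmrs(tested)
        assert called.loc[0, "q_value"] == pytest.approx(0.001)
        assert bool(called.loc[0, "is_dmr"])

    def test_small_difference_never_a_dmr(self):
        win = _window_frame({"care_1": (30, 100), "nocare_1": (10, 100)})
        tested = mp.test_windows(win, TWO_GROUPS)
        tested.loc[0, "p_value"] = 1e-10
        tested.loc[0, "diff"] = 3.0
        called = mp.call_dmrs(tested)
        assert not bool(called.loc[0, "is_dmr"])

    def test_exact_min_diff_is_a_dmr(self):
        win = _window_frame({"care_1": (30, 100), "nocare_1": (10, 100)})
        tested = mp.test_windows(win, TWO_GROUPS)
        tested.loc[0, "p_value"] = 1e-10
        tested.loc[0, "diff"] = 5.0
        assert bool(mp.call_dmrs(tested).loc[0, "is_dmr"])

    def test_fdr_calibration_on_null_windows(self):
        # no group effect planted: flagged windows stay at or below
        # the FDR level on average across seeds
        total_dmrs, total_windows = 0, 0
        sids = ["care_1", "care_2", "care_3",
                "nocare_1", "nocare_2", "nocare_3"]
        group_map = {s: s.rsplit("_", 1)[0] for s in sids}
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_win = 2_000
            data = {"chrom": "chr1",
                    "start": np.arange(n_win) * 200,
                    "end": np.arange(n_win) * 200 + 200,
                    "cpg_count": 3}
            for sid in sids:
                n = rng.poisson(90, n_win) + 3
                data[f"m_{sid}"] = rng.binomial(n, 0.3)
                data[f"n_{sid}"] = n
            called = mp.call_dmrs(
                mp.test_windows(pd.DataFrame(data), group_map))
            total_dmrs += int(called["is_dmr"].sum())
            total_windows += n_win
        assert total_dmrs <= 0.01 * total_windows

    def test_summary_recomputes_hypermethylation_bias(self):
        win = pd.concat([
            _window_frame({"care_1": (80, 100), "nocare_1": (10, 100)}),
            _window_frame({"care_1": (10, 100), "nocare_1": (80, 100)}),
        ], ignore_index=True)
        tested = mp.test_windows(win, TWO_GROUPS)
        called = mp.call_dmrs(tested)
        s = dmr_summary(called)
        assert s["n_dmrs"] == 2 and s["frac_hyper_care"] == 0.5


class TestAnnotate:
    GENES = pd.DataFrame({
        "gene_id": ["A", "B"],
        "chrom": ["chr1", "chr1"],
        "start": [0, 360],
        "end": [250, 500],
        "strand": ["+", "-"],
    })

    @staticmethod
    def _dmr(start, end):
        return pd.DataFrame({
            "chrom": ["chr1"], "start": [start], "end": [end],
            "is_dmr": [True], "diff": [10.0]})

    def test_partial_overlap_counts(self):
        out = mp.annotate_dmrs(self._dmr(100, 300), self.GENES)
        assert out.loc[0, "gene_ids"] == ["A"]

    def test_window_spanning_two_genes(self):
        out = mp.annotate_dmrs(self._dmr(240, 440), self.GENES)
        assert out.loc[0, "gene_ids"] == ["A", "B"]
        assert differentially_methylated_genes(out) == {"A", "B"}

    def test_intergenic_window_maps_to_nothing(self):
        out = mp.annotate_dmrs(self._dmr(250, 260), self.GENES)
        assert out.loc[0, "gene_ids"] == []

    def test_half_open_adjacency_is_no_overlap(self):
        out = mp.annotate_dmrs(self._dmr(250, 260), self.GENES)
        assert "A" not in out.loc[0, "gene_ids"]
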