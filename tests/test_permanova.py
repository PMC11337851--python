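import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from lrdmeta import (
    DistanceMatrix,
    MODEL_TERMS,
    SampleDesign,
    build_design,
    factor_term,
    permanova_sequential,
)
from lrdmeta.containers import TIMEPOINT_DAYS, TREATMENT_FLAGS


def _euclid_dm(points):
    ids = [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(ids, squareform(pdist(np.atleast_2d(points))))


def _microcosm_designs(layout=None, replicates=1):
    layout = layout or [("BC", [0, 1, 2, 3, 4]), ("DISP", [0, 1, 2, 3, 4]),
                        ("WAF", [0, 1, 2, 3, 4]), ("CEWAF", [0, 1, 2, 3, 4]),
                        ("CEWAFN", [0, 1, 4])]
    out = []
    for treatment, ts in layout:
        O, D, N = TREATMENT_FLAGS[treatment]
        for t in ts:
            for r in range(1, replicates + 1):
                out.append(SampleDesign(f"{treatment}_t{t}_r{r}", treatment,
                                        O, D, N, t, TIMEPOINT_DAYS[t], r))
    return out


class TestBuildDesign:
    def test_factor_flags_per_treatment(self):
        designs = _microcosm_designs()
        terms = dict(build_design(designs))
        df = pd.DataFrame({"trt": [d.treatment for d in designs]})
        odn = terms["O:D:N"].ravel()
        assert set(df.trt[odn == 1]) == {"CEWAFN"}
        assert set(df.trt[terms["O"].ravel() == 1]) == {"WAF", "CEWAF", "CEWAFN"}
        assert set(df.trt[terms["D"].ravel() == 1]) == {"DISP", "CEWAF", "CEWAFN"}

    def test_terms_in_model_order(self):
        names = [n for n, _ in build_design(_microcosm_designs())]
        assert names == MODEL_TERMS

    def test_two_timepoints_one_df(self, rng):
        designs = _microcosm_designs(layout=[("BC", [0, 1]), ("WAF", [0, 1])],
                                     replicates=3)
        dm = _euclid_dm(rng.normal(size=(len(designs), 1)))
        rep = permanova_sequential(dm, build_design(designs), n_perm=9, seed=0)
        assert int(rep.table.set_index("term").loc["t", "df"]) == 1

    def test_time_linear_single_column(self):
        terms = dict(build_design(_microcosm_designs(), time_linear=True))
        assert terms["t"].shape[1] == 1


class TestPseudoF:
    def test_equals_classical_anova_f_on_euclidean_distances(self, rng):
        y = rng.normal(size=18)
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        rep = permanova_sequential(_euclid_dm(y[:, None]), factor_term(labels),
                                  n_perm=9, seed=0)
        f_direct = f_oneway(y[:6], y[6:12], y[12:]).statistic
        assert rep.table.loc[0, "F"] == pytest.approx(f_direct, abs=1e-9)

    def test_matches_skbio_permanova_statistic(self, rng):
        """Cross-check against scikit-bio's one-way PERMANOVA."""
        X = rng.normal(size=(16, 3))
        labels = ["a"] * 8 + ["b"] * 8
        D = squareform(pdist(X))
        ids = [f"s{i}" for i in range(16)]
        rep = permanova_sequential(DistanceMatrix(ids, D), factor_term(labels),
                                  n_perm=9, seed=0)
        ref = skbio.stats.distance.permanova(skbio.DistanceMatrix(D, ids),
                                             labels, permutations=9)
        assert rep.table.loc[0, "F"] == pytest.approx(ref["test statistic"],
                                                      abs=1e-9)

    def test_ss_decomposition_and_gower_identity(self, rng):
        designs = _microcosm_designs(replicates=3)
        dm = _euclid_dm(rng.normal(size=(len(designs), 2)))
        rep = permanova_sequential(dm, build_design(designs), n_perm=9, seed=0)
        t = rep.table.set_index("term")
        terms_ss = t.loc[MODEL_TERMS, "SS"].sum()
        assert terms_ss + t.loc["Residual", "SS"] == \
            pytest.approx(t.loc["Total", "SS"], abs=1e-9)
        n = len(designs)
        gower_total = (dm.values ** 2).sum() / (2 * n)  # sum over i<j of d^2 / n
        assert t.loc["Total", "SS"] == pytest.approx(gower_total, abs=1e-9)

    def test_total_ss_permutation_invariant(self, rng):
        y = rng.normal(size=(12, 2))
        dm = _euclid_dm(y)
        rep1 = permanova_sequential(dm, factor_term(["a", "b"] * 6), n_perm=9, seed=0)
        perm = rng.permutation(12)
        dm2 = DistanceMatrix([dm.ids[i] for i in perm],
                             dm.values[np.ix_(perm, perm)])
        rep2 = permanova_sequential(dm2, factor_term(["a", "b"] * 6), n_perm=9, seed=0)
        assert rep1.total_ss == pytest.approx(rep2.total_ss, abs=1e-9)


class TestPermutationTest:
    def test_complete_separation_attains_minimum_p(self, rng):
        # two well-separated clouds: no permutation can reach F_obs
        y = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(100, 0.1, 10)])
        rep = permanova_sequential(_euclid_dm(y[:, None]),
                                  factor_term(["a"] * 10 + ["b"] * 10),
                                  n_perm=999, seed=3)
        assert rep.table.loc[0, "p_value"] == pytest.approx(1 / 1000)

    def test_deterministic_for_fixed_seed(self, rng):
        y = rng.normal(size=14)
        dm = _euclid_dm(y[:, None])
        terms = factor_term(["a", "b"] * 7)
        r1 = permanova_sequential(dm, terms, n_perm=99, seed=11)
        r2 = permanova_sequential(dm, terms, n_perm=99, seed=11)
        assert r1.table.equals(r2.table)

    def test_p_values_on_grid(self, rng):
        y = rng.normal(size=12)
        rep = permanova_sequential(_euclid_dm(y[:, None]),
                                  factor_term(["a", "b"] * 6), n_perm=19, seed=5)
        p = rep.table.loc[0, "p_value"]
        assert (p * 20) == pytest.approx(round(p * 20))
        assert p >= 1 / 20


class TestDegenerateDesigns:
    def test_aliased_term_gets_zero_df_without_crash(self, rng):
        y = rng.normal(size=(10, 2))
        col = np.array([[1.0]] * 5 + [[0.0]] * 5)
        terms = [("first", col), ("duplicate", col.copy())]
        rep = permanova_sequential(_euclid_dm(y), terms, n_perm=19, seed=0)
        t = rep.table.set_index("term")
        assert int(t.loc["duplicate", "df"]) == 0
        assert np.isnan(t.loc["duplicate", "F"])
        assert any("aliased" in n for n in rep.notes)

    def test_saturated_model_reports_nan(self, rng):
        y = rng.normal(size=(4, 2))
        labels = ["a", "b", "c", "d"]  # 3 df model + intercept = n
        rep = permanova_sequential(_euclid_dm(y), factor_term(labels),
                                  n_perm=19, seed=0)
        assert np.isnan(rep.table.loc[0, "F"])
        assert any("saturated" in n for n in rep.notes)

    def test_all_equal_distances_no_test(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        rep = permanova_sequential(dm, factor_term(["a", "a", "b", "b"]),
                                  n_perm=19, seed=0)
        assert np.isnan(rep.table.loc[0, "p_value"])
        assert any("zero" in n for n in rep.notes)

    def test_microcosm_confounding_structure(self, rng):
        # nutrients occur only inside CEWAFN (t0, t1, t4): the O:D:N:t
        # interaction can only span 2 extra df beyond O:D:N
        designs = _microcosm_designs(replicates=3)
        dm = _euclid_dm(rng.normal(size=(len(designs), 2)))
        rep = permanova_sequential(dm, build_design(designs), n_perm=9, seed=0)
        t = rep.table.set_index("term")
        assert int(t.loc["O:D:N", "df"]) == 1
        assert int(t.loc["O:D:N:t", "df"]) == 2
        assert int(t.loc["Residual", "df"]) == len(designs) - 1 - 22
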