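"""Trimmed-mean, SMM-pairwise and Cliff rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microwear import (
    MeasurementTable,
    StatsConfig,
    cliff,
    compare_parameters,
    pairwise_t3,
    trimmed_moments,
    welch_yuen,
)
from microwear.errors import DesignError, SampleSizeError
from microwear.registry import ALL_PARAMS
from microwear.robust_stats import smm_cdf
from microwear.surface_io import META_COLUMNS


class TestTrimmedMoments:
    def test_small_n_no_trim(self):
        m = trimmed_moments([1, 2, 3, 4, 100], 0.15)  # g = floor(0.75) = 0
        assert m["mean"] == pytest.approx(22.0)
        assert m["h"] == 5

    def test_one_per_tail(self):
        m = trimmed_moments(np.arange(1, 11), 0.15)  # g = 1
        assert m["mean"] == pytest.approx(5.5)
        assert m["h"] == 8

    def test_gamma_zero_is_ordinary_moments(self, rng):
        x = rng.standard_normal(25)
        m = trimmed_moments(x, 0.0)
        assert m["mean"] == pytest.approx(x.mean())
        assert m["winvar"] == pytest.approx(x.var(ddof=1))

    def test_too_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            trimmed_moments([1.0], 0.15)


class TestWelchYuen:
    def test_identical_samples_null(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        r = welch_yuen([x, x.copy()])
        assert r["Ft"] == 0.0 and r["p"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gamma_zero_matches_welch_t_oracle(self, seed):
        g = np.random.default_rng(seed)
        x = g.standard_normal(12) * 2 + 1
        y = g.standard_normal(9) * 5
        r = welch_yuen([x, y], StatsConfig(gamma=0.0))
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert r["Ft"] == pytest.approx(t**2, rel=1e-9)
        assert r["p"] == pytest.approx(p, rel=1e-9)
        assert r["nu1"] == 1

    def test_three_group_omnibus_null_uniformity(self, rng):
        # sanity: p roughly uniform under a normal null for J = 3
        ps = []
        for _ in range(200):
            groups = [rng.standard_normal(20) for _ in range(3)]
            ps.append(welch_yuen(groups, StatsConfig(gamma=0.15))["p"])
        assert 0.01 < np.mean(np.array(ps) <= 0.05) < 0.12

    def test_degenerate_group_named(self):
        with pytest.raises(SampleSizeError, match="group 1"):
            welch_yuen([np.arange(10.0), np.array([1.0])])


class TestPairwiseT3:
    def test_two_groups_reduce_to_welch_yuen(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(12) * 3
        cfg = StatsConfig(gamma=0.15)
        t3 = pairwise_t3([x, y], cfg)
        wy = welch_yuen([x, y], cfg)
        assert len(t3) == 1
        assert t3[0]["p"] == pytest.approx(wy["p"], abs=1e-6)
        assert t3[0]["stat"] ** 2 == pytest.approx(wy["Ft"], rel=1e-9)

    def test_three_identical_groups_all_null(self):
        x = np.arange(10.0)
        res = pairwise_t3([x, x.copy(), x.copy()])
        assert len(res) == 3
        assert all(r["p"] == pytest.approx(1.0) for r in res)

    def test_smm_quantile_against_monte_carlo(self):
        # maximum modulus of 3 independent t-variates sharing one chi(30)
        rng = np.random.default_rng(42)
        n = 1_000_000
        zmax = np.abs(rng.standard_normal((n, 3))).max(axis=1)
        u = np.sqrt(rng.chisquare(30, n) / 30)
        q95 = np.quantile(zmax / u, 0.95)
        assert smm_cdf(q95, 3, 30) == pytest.approx(0.95, abs=0.005)

    def test_smm_c1_is_two_sided_t(self):
        for q in (0.5, 1.5, 2.5):
            assert smm_cdf(q, 1, 20) == pytest.approx(
                1 - 2 * stats.t.sf(q, 20), abs=1e-8
            )


class TestCliff:
    def test_identical_samples(self):
        r = cliff([1, 2, 3], [1, 2, 3])
        assert r["ph"] == pytest.approx(0.5) and r["p"] == pytest.approx(1.0)

    def test_complete_separation_by_enumeration(self):
        r = cliff([4, 5, 6], [1, 2, 3])
        assert r["ph"] == 1.0 and r["delta"] == 1.0

    def test_ties_weighted_half(self):
        r = cliff([1, 2], [2, 3])  # pairs: 1<2,1<3,2=2,2<3 -> ph = 0.5/4
        assert r["ph"] == pytest.approx(0.125)

    def test_swap_symmetry(self, rng):
        x, y = rng.standard_normal(14), rng.standard_normal(11) + 0.5
        a, b = cliff(x, y), cliff(y, x)
        assert a["ph"] == pytest.approx(1 - b["ph"])
        assert a["p"] == pytest.approx(b["p"], rel=1e-12)
        assert a["pl"] == pytest.approx(1 - b["pu"], abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20) * 2
        r = cliff(x, y)
        assert 0.0 <= r["pl"] <= r["ph"] <= r["pu"] <= 1.0

    def test_location_shift_monotone_in_delta(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        deltas = [abs(cliff(x + s, y)["delta"]) for s in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert deltas == sorted(deltas)


class TestAffineInvariance:
    def test_all_three_tests_invariant_to_common_affine_map(self, rng):
        x = rng.lognormal(size=20)
        y = rng.lognormal(sigma=1.5, size=25) + 0.3
        a, b = 3.7, -12.0
        cfg = StatsConfig(gamma=0.15)
        w1, w2 = welch_yuen([x, y], cfg), welch_yuen([a * x + b, a * y + b], cfg)
        assert w2["Ft"] == pytest.approx(w1["Ft"], rel=1e-9)
        t1, t2 = pairwise_t3([x, y], cfg), pairwise_t3([a * x + b, a * y + b], cfg)
        assert t2[0]["p"] == pytest.approx(t1[0]["p"], rel=1e-9)
        c1, c2 = cliff(x, y), cliff(a * x + b, a * y + b)
        assert c2["ph"] == pytest.approx(c1["ph"]) and c2["p"] == pytest.approx(c1["p"])


def _table_from_groups(values_by_group):
    rows = []
    for gi, (pop, vals) in enumerate(values_by_group.items()):
        for i, v in enumerate(vals):
            row = {c: "x" for c in META_COLUMNS}
            row.update(specimen=f"S{gi}_{i}", population=pop, tooth="P4", facet="9",
                       scan="1")
            row.update({p: float(v) for p in ALL_PARAMS})
            rows.append(row)
    return MeasurementTable(pd.DataFrame(rows))


class TestCompareParameters:
    def test_duplicated_groups_nothing_flagged(self):
        vals = list(np.linspace(0, 1, 12))
        t = _table_from_groups({"A": vals, "B": vals})
        out = compare_parameters(t, "population")
        assert len(out) == 30
        assert not out["significant"].any()

    def test_single_level_rejected(self):
        t = _table_from_groups({"A": [1, 2, 3, 4]})
        with pytest.raises(DesignError):
            compare_parameters(t, "population")

    def test_row_count_and_columns_mirror_report(self, rng):
        t = _table_from_groups({"A": rng.standard_normal(10), "B": rng.standard_normal(10) + 5})
        out = compare_parameters(t, "population")
        for col in ("Ft", "p_welch", "nu1", "nu2", "t3_stat", "t3_df", "p_t3",
                    "ph", "pl", "pu", "p_cliff", "significant", "stars"):
            assert col in out.columns
        assert sorted(out["parameter"]) == sorted(ALL_PARAMS)
        assert out["significant"].all()  # strong separation on every parameter

    def test_holm_never_decreases_p(self, rng):
        t = _table_from_groups({"A": rng.standard_normal(10), "B": rng.standard_normal(10) + 1})
        raw = compare_parameters(t, "population", StatsConfig(adjust="none"))
        adj = compare_parameters(t, "population", StatsConfig(adjust="holm"))
        assert (adj["p_welch"] >= raw["p_welch"] - 1e-15).all()
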