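import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from indirect_ri.cleaning import (
    DEFAULT_BOUNDS,
    clean_dataset,
    deduplicate_earliest,
    filter_age,
    filter_plausible,
    fit_age_partition_tree,
    fit_box_cox,
    flag_outliers,
    radical_exclusion,
    tukey_outlier_mask,
)
from indirect_ri.data_model import Stratum, cleaning_scheme, default_scheme

from conftest import make_dataset


class TestDeduplicateEarliest:
    def test_keeps_earliest_visit(self, tiny_dataset):
        out = deduplicate_earliest(tiny_dataset)
        a = out.df[(out.df.subject_id == "A") & (out.df.analyte == "creatinine")]
        assert len(a) == 1 and a.iloc[0]["value"] == 30.0

    def test_identity_when_unique(self, tiny_dataset):
        once = deduplicate_earliest(tiny_dataset)
        twice = deduplicate_earliest(once)  # idempotent
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_matches_groupby_minimum_oracle(self, rng):
        import datetime
        rows = []
        subjects = [f"S{i}" for i in range(300)]
        for k in range(1000):
            sid = subjects[rng.integers(0, 300)]
            d = datetime.date(2017, 1, 1) + datetime.timedelta(
                days=int(rng.integers(0, 360)))
            rows.append((sid, d, 5.0, "male", "creatinine",
                         float(np.round(rng.uniform(20, 40), 2))))
        ds = make_dataset(rows)
        out = deduplicate_earliest(ds)
        # independent oracle: per subject, min date then min value
        oracle = (ds.df.sort_values(["date", "value"])
                  .groupby(["subject_id", "analyte"]).head(1))
        assert len(out) == ds.df.groupby(["subject_id", "analyte"]).ngroups
        merged = out.df.merge(oracle, on=["subject_id", "analyte"],
                              suffixes=("", "_o"))
        assert (merged["date"] == merged["date_o"]).all()
        assert (merged["value"] == merged["value_o"]).all()

    def test_date_tie_broken_by_lowest_value(self):
        ds = make_dataset([
            ("A", "2017-03-01", 5.0, "male", "creatinine", 33.0),
            ("A", "2017-03-01", 5.0, "male", "creatinine", 30.0),
        ])
        out = deduplicate_earliest(ds)
        assert out.df.iloc[0]["value"] == 30.0


class TestFilterAge:
    def test_half_open_window(self):
        ds = make_dataset([
            ("A", "2017-01-01", 0.5, "male", "creatinine", 30.0),
            ("B", "2017-01-01", 1.0, "male", "creatinine", 30.0),
            ("C", "2017-01-01", 16.99, "male", "creatinine", 30.0),
            ("D", "2017-01-01", 17.0, "male", "creatinine", 30.0),
        ])
        out = filter_age(ds)
        assert sorted(out.df.subject_id) == ["B", "C"]

    def test_empty_input(self, tiny_dataset):
        empty = tiny_dataset.subset(np.zeros(len(tiny_dataset), bool))
        assert len(filter_age(empty)) == 0

    def test_uniform_ages_kept_fraction(self, rng):
        ages = rng.uniform(0, 20, 10_000)
        ds = make_dataset([(f"S{i}", "2017-01-01", float(a), "male",
                            "creatinine", 30.0) for i, a in enumerate(ages)])
        frac = len(filter_age(ds)) / len(ds)
        assert frac == pytest.approx(16 / 20, abs=0.015)  # ~4 binomial SEs

    def test_bad_window_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            filter_age(tiny_dataset, 17, 1)


class TestBoxCox:
    def test_lognormal_sample_gives_lambda_near_zero(self, rng):
        x = np.exp(rng.normal(3.0, 0.5, 5000))
        assert abs(fit_box_cox(x).lam) < 0.1

    def test_normal_sample_gives_lambda_near_one(self, rng):
        x = rng.normal(50, 5, 5000)
        x = x[x > 0]
        assert fit_box_cox(x).lam == pytest.approx(1.0, abs=0.2)

    def test_matches_dense_grid_search(self, rng):
        """MLE lambda agrees with an exhaustive profile-likelihood grid."""
        x = np.exp(rng.normal(0, 0.4, 200)) + rng.uniform(0, 0.5, 200)
        fit = fit_box_cox(x)
        grid = np.arange(-3, 3, 1e-4)
        lls = np.array([stats.boxcox_llf(l, x) for l in grid])
        lam_grid = grid[np.argmax(lls)]
        assert fit.lam == pytest.approx(lam_grid, abs=2e-4)
        assert fit.loglik >= lls.max() - 1e-6

    def test_non_positive_input_suggests_shift(self):
        with pytest.raises(ValueError, match="shift"):
            fit_box_cox(np.linspace(-1, 10, 50))

    def test_lambda_one_is_affine_shift(self, rng):
        from indirect_ri.cleaning import BoxCoxFit
        x = rng.uniform(1, 10, 100)
        y = BoxCoxFit(lam=1.0, loglik=0.0).transform(x)
        assert np.allclose(y, x - 1)


class TestTukey:
    def test_gross_outlier_flagged(self):
        x = np.concatenate([np.arange(1, 101, dtype=float), [1000.0]])
        mask, fences = tukey_outlier_mask(x)
        assert mask.sum() == 1 and x[mask][0] == 1000.0
        assert fences.lower <= fences.q1 <= fences.q3 <= fences.upper

    def test_no_outliers_in_tight_symmetric_data(self):
        x = np.concatenate([np.linspace(-1, 1, 50)])
        mask, _ = tukey_outlier_mask(x)
        assert mask.sum() == 0

    def test_normal_flag_rate_near_nominal(self, rng):
        """Tukey flags ~0.7% of normal data (fences at about +/-2.70 SD)."""
        x = rng.standard_normal(10_000)
        mask, _ = tukey_outlier_mask(x)
        assert mask.mean() == pytest.approx(0.007, abs=0.003)

    def test_transformed_flags_equal_raw_fence_flags(self, rng):
        """Monotonicity: flags on the Box-Cox scale match back-mapped fences."""
        x = np.exp(rng.normal(1.0, 0.6, 500))
        fit = fit_box_cox(x)
        mask, fences = tukey_outlier_mask(x, fit)
        raw_mask = (x < fences.lower_raw) | (x > fences.upper_raw)
        assert np.array_equal(mask, raw_mask)

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_fences_scale_equivariant(self, c):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        _, f1 = tukey_outlier_mask(x)
        _, f2 = tukey_outlier_mask(c * x)
        assert f2.lower == pytest.approx(c * f1.lower, rel=1e-9)
        assert f2.upper == pytest.approx(c * f1.upper, rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tukey_outlier_mask(np.array([1.0, 2.0, 3.0]))


class TestRadicalExclusion:
    def _panel(self, rng, n=200, planted=("S003", "S007", "S011")):
        """Complete renal panels with gross outliers planted in known
        subjects, one analyte each.  The background is uniform (+/-10% of the
        analyte mean), which produces no Tukey exceedances of its own, so the
        planted subjects are exactly the flaggable set."""
        means = {"creatinine": 35.0, "urea": 4.3, "uric_acid": 250.0}
        analytes = list(means)
        rows = []
        for i in range(n):
            sid = f"S{i:03d}"
            for a in analytes:
                v = float(means[a] * rng.uniform(0.9, 1.1))
                if sid in planted and a == analytes[planted.index(sid) % 3]:
                    v = means[a] * 3.0
                rows.append((sid, "2017-06-01", 8.0, "male", a, v))
        return make_dataset(rows)

    def test_planted_outlier_subjects_removed_everywhere(self, rng):
        planted = ("S003", "S007", "S011")
        ds = self._panel(rng, planted=planted)
        out, report = radical_exclusion(ds, cleaning_scheme())
        assert set(planted) == set(ds.df.subject_id) - set(out.df.subject_id)
        assert report["n_flagged_subjects"] == 3
        # removed from every analyte, not only the offending one
        assert not out.df.subject_id.isin(planted).any()

    def test_no_outliers_is_identity(self):
        x = np.linspace(30, 40, 50)
        rows = [(f"S{i}", "2017-06-01", 8.0, "male", a, float(v + off))
                for a, off in (("creatinine", 0), ("urea", -26), ("uric_acid", 200))
                for i, v in enumerate(x)]
        ds = make_dataset(rows)
        out, _ = radical_exclusion(ds, cleaning_scheme())
        assert len(out) == len(ds)

    def test_partially_observed_subjects_judged_on_evidence(self, rng):
        ds = self._panel(rng, n=50, planted=())
        keep = ~((ds.df.subject_id == "S001") & (ds.df.analyte == "uric_acid"))
        ds = ds.subset(keep)
        _, report = radical_exclusion(ds, cleaning_scheme())
        assert report["n_partially_observed"] == 1


class TestFullChain:
    def test_counts_never_increase(self, rng):
        from indirect_ri.synthetic import default_study_spec, generate_lis
        lis, _ = generate_lis(default_study_spec(), 300, 7)
        _, report = clean_dataset(lis, cleaning_scheme())
        seq = [report["input"], report["post_plausibility"],
               report["post_dedup"], report["post_age_filter"],
               report["post_outlier"]]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_plausibility_bounds_drop_extremes(self):
        ds = make_dataset([
            ("A", "2017-01-01", 5.0, "male", "creatinine", 30.0),
            ("B", "2017-01-01", 5.0, "male", "creatinine", 9999.0),
            ("C", "2017-01-01", 5.0, "male", "urea", 0.01),
        ])
        out, dropped = filter_plausible(ds, DEFAULT_BOUNDS)
        assert dropped == 2 and list(out.df.subject_id) == ["A"]


class TestAgePartitionTree:
    def _records(self, rng, means_by_band, n=3000, sex_gap=0.0):
        rows = []
        for i in range(n):
            age = float(rng.uniform(1, 17))
            sex = "male" if rng.random() < 0.5 else "female"
            mean = next(m for (lo, hi), m in means_by_band.items()
                        if lo <= age < hi)
            if sex == "male":
                mean += sex_gap
            rows.append((f"S{i}", "2017-01-01", age, sex, "creatinine",
                         float(rng.normal(mean, 2.0))))
        return make_dataset(rows)

    def test_recovers_published_style_cuts(self, rng):
        ds = self._records(rng, {(1, 6): 29.0, (6, 12): 41.0, (12, 17): 57.0})
        tree = fit_age_partition_tree(ds, "creatinine", max_leaves=3)
        assert tree.cut_points == [6.0, 12.0]

    def test_constant_mean_yields_single_leaf(self, rng):
        ds = self._records(rng, {(1, 17): 40.0}, n=1000)
        tree = fit_age_partition_tree(ds, "creatinine")
        assert tree.cut_points == []

    def test_single_jump_matches_exhaustive_search(self, rng):
        ds = self._records(rng, {(1, 9): 30.0, (9, 17): 50.0})
        tree = fit_age_partition_tree(ds, "creatinine", max_leaves=2)
        # exhaustive single-split oracle over integer cuts
        ages = ds.df.age.to_numpy()
        vals = ds.df.value.to_numpy()

        def sse(v):
            return ((v - v.mean()) ** 2).sum() if v.size else 0.0

        gains = {c: sse(vals) - sse(vals[ages < c]) - sse(vals[ages >= c])
                 for c in range(2, 17)}
        assert tree.cut_points == [max(gains, key=gains.get)] == [9.0]

    def test_sex_split_detected_in_adolescent_band(self, rng):
        ds = self._records(rng, {(1, 12): 35.0, (12, 17): 55.0}, sex_gap=8.0,
                           n=4000)
        tree = fit_age_partition_tree(ds, "creatinine", max_leaves=2,
                                      sex_split_rel_gain=0.05)
        assert tree.cut_points == [12.0]
        assert tree.sex_split_per_leaf[-1]  # gap planted in the top band

    def test_max_leaves_validation(self, tiny_dataset):
        with pytest.raises(ValueError):
            fit_age_partition_tree(tiny_dataset, "creatinine", max_leaves=1)
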