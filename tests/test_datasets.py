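"""Loading, normalization, merging and distribution metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mnrelations as mn
from mnrelations.datasets import (
    DatasetError,
    EmptyDatasetError,
    InsufficientDataError,
    PairMismatchError,
    StateError,
    StudyDataset,
)


def _ds(x, y, **kw):
    kw.setdefault("study_id", "s1")
    kw.setdefault("species", "cat")
    kw.setdefault("prop_x", "R")
    kw.setdefault("prop_y", "I_th")
    return StudyDataset(x=np.asarray(x, float), y=np.asarray(y, float), **kw)


class TestLoading:
    def _write(self, tmp_path, rows):
        path = tmp_path / "data.csv"
        pd.DataFrame(rows, columns=list(mn.datasets.CSV_COLUMNS)).to_csv(
            path, index=False
        )
        return path

    def test_units_converted_to_si(self, tmp_path):
        rows = [
            ("a", "cat", "R", "I_th", 1.0, 5.0, "MOhm", "nA"),
            ("a", "cat", "R", "I_th", 2.0, 3.0, "MOhm", "nA"),
            ("a", "cat", "R", "I_th", 4.0, 2.0, "MOhm", "nA"),
        ]
        ds = mn.load_dataset(self._write(tmp_path, rows))
        assert np.allclose(ds.x, [1e6, 2e6, 4e6])
        assert np.allclose(ds.y, [5e-9, 3e-9, 2e-9])

    def test_non_positive_rows_dropped_with_warning(self, tmp_path, caplog):
        rows = [
            ("a", "cat", "R", "I_th", 0.0, 5.0, "MOhm", "nA"),
            ("a", "cat", "R", "I_th", 2.0, 3.0, "MOhm", "nA"),
            ("a", "cat", "R", "I_th", 4.0, 2.0, "MOhm", "nA"),
        ]
        with caplog.at_level("WARNING"):
            ds = mn.load_dataset(self._write(tmp_path, rows))
        assert len(ds) == 2
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_multi_block_file_returns_one_dataset_per_block(self, tmp_path):
        rows = [
            ("a", "cat", "S_MN", "ACV", 40.0, 60.0, "percent", "m/s"),
            ("a", "cat", "S_MN", "ACV", 80.0, 90.0, "percent", "m/s"),
            ("b", "cat", "S_MN", "ACV", 50.0, 70.0, "percent", "m/s"),
            ("a", "cat", "ACV", "AHP", 60.0, 0.1, "m/s", "s"),
        ]
        blocks = mn.load_datasets(self._write(tmp_path, rows))
        assert len(blocks) == 3  # independent text scan: 3 header groups
        with pytest.raises(DatasetError):
            mn.load_dataset(self._write(tmp_path, rows))

    def test_unknown_property_and_empty_file_errors(self, tmp_path):
        rows = [("a", "cat", "bogus", "I_th", 1.0, 1.0, "MOhm", "nA")]
        with pytest.raises(Exception):
            mn.load_datasets(self._write(tmp_path, rows))
        rows = [("a", "cat", "R", "I_th", -1.0, 1.0, "MOhm", "nA")]
        with pytest.raises(EmptyDatasetError):
            mn.load_datasets(self._write(tmp_path, rows))

    def test_roundtrip_through_csv(self, tmp_path, corpus_csv):
        studies = mn.load_datasets(corpus_csv)
        assert sum(len(s) for s in studies) == 6 * 30


class TestNormalize:
    def test_max_maps_to_100(self):
        ds = mn.normalize_study(_ds([2, 4, 8], [1, 2, 4]))
        assert np.allclose(ds.x, [25, 50, 100])

    def test_single_point_degenerate(self):
        ds = mn.normalize_study(_ds([3.0], [7.0]))
        assert ds.x[0] == 100 and ds.y[0] == 100

    def test_columns_scaled_independently(self):
        ds = mn.normalize_study(_ds([3, 6], [10, 5]))
        assert np.allclose(ds.x, [50, 100])
        assert np.allclose(ds.y, [100, 50])

    def test_double_normalization_forbidden(self):
        ds = mn.normalize_study(_ds([1, 2], [1, 2]))
        with pytest.raises(StateError):
            mn.normalize_study(ds)

    @given(
        vals=st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30),
        c=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, vals, c):
        x = np.asarray(vals)
        a = mn.normalize_study(_ds(x, x))
        b = mn.normalize_study(_ds(c * x, x))
        assert np.allclose(a.x, b.x, rtol=1e-12)


class TestMerge:
    def test_counts_and_provenance(self):
        a = mn.normalize_study(_ds([1, 2, 3], [1, 2, 3], study_id="a"))
        b = mn.normalize_study(_ds([1, 2, 3, 4], [1, 2, 3, 4], study_id="b"))
        g = mn.merge_global([a, b])
        assert len(g) == 7
        assert set(g.study) == {"a", "b"}

    def test_single_member_identity(self):
        a = mn.normalize_study(_ds([1, 2, 3], [3, 2, 1]))
        g = mn.merge_global([a])
        assert np.array_equal(g.x, a.x) and np.array_equal(g.y, a.y)

    def test_mixed_pairs_and_unnormalized_rejected(self):
        a = mn.normalize_study(_ds([1, 2], [1, 2]))
        b = mn.normalize_study(_ds([1, 2], [1, 2], prop_y="C"))
        with pytest.raises(PairMismatchError):
            mn.merge_global([a, b])
        with pytest.raises(StateError):
            mn.merge_global([_ds([1, 2], [1, 2])])

    def test_synthetic_corpus_merge_contract(self):
        spec = mn.SyntheticSpec(
            seed=3,
            wiring={("AHP", "ACV"): 4},
            points_per_study=30,
            require_reachable=False,
        )
        studies = [mn.generate_study(spec, ("AHP", "ACV"), j)
                   for j in range(4)]
        g = mn.merge_global([mn.normalize_study(s) for s in studies])
        assert len(g) == 120
        for sid in np.unique(g.study):
            m = g.study == sid
            assert np.isclose(g.x[m].max(), 100)
            assert np.isclose(g.y[m].max(), 100)


class TestMetrics:
    def test_hand_arithmetic_small_sample(self):
        m = mn.distribution_metrics([1, 2, 3])
        assert m.range == 2 and m.mean == 2
        assert np.isclose(m.cov, 0.5)  # sample sd = 1
        assert m.me_md == 1.0

    def test_constant_sample(self):
        m = mn.distribution_metrics([5, 5, 5])
        assert m.range == 0 and m.cov == 0 and m.me_md == 1

    def test_skewed_sample(self):
        m = mn.distribution_metrics([10, 20, 30, 100])
        assert m.range == 90 and m.mean == 40
        assert np.isclose(m.me_md, 0.625)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            mn.distribution_metrics([1.0])

    @given(
        vals=st.lists(st.floats(0.1, 1e3), min_size=3, max_size=20),
        c=st.floats(0.01, 100),
    )
    def test_scaling_behaviour(self, vals, c):
        base = mn.distribution_metrics(vals)
        scaled = mn.distribution_metrics(c * np.asarray(vals))
        assert np.isclose(scaled.range, c * base.range, rtol=1e-9)
        assert np.isclose(scaled.mean, c * base.mean, rtol=1e-9)
        assert np.isclose(scaled.cov, base.cov, rtol=1e-9, atol=1e-12)
        assert np.isclose(scaled.me_md, base.me_md, rtol=1e-9)


class TestHomogeneity:
    def test_identical_studies_fully_homogeneous(self):
        m = mn.distribution_metrics([10, 50, 90])
        agg = mn.homogeneity_check([m, m, m])
        assert agg.all_homogeneous
        assert all(v == pytest.approx(0, abs=1e-12)
                   for v in agg.sd_g.values())

    def test_spread_means_fail_threshold(self):
        a = mn.DistributionMetrics(range=50, mean=50, cov=0.3, me_md=0.9)
        b = mn.DistributionMetrics(range=50, mean=70, cov=0.3, me_md=0.9)
        agg = mn.homogeneity_check([a, b])
        assert np.isclose(agg.mean_g["mean"], 60)
        assert np.isclose(agg.sd_g["mean"], 14.142, atol=1e-3)
        assert not agg.homogeneous["mean"]
        assert agg.homogeneous["range"]

    def test_single_study_not_assessable(self):
        m = mn.distribution_metrics([10, 50, 90])
        agg = mn.homogeneity_check([m])
        assert not agg.all_homogeneous
        assert np.isnan(agg.sd_g["mean"])

    def test_low_noise_synthetic_studies_homogeneous(self):
        spec = mn.SyntheticSpec(
            seed=21, sigma_log=0.05, subrange=None,
            wiring={("ACV", "S_MN"): 4}, points_per_study=50,
        )
        studies = [
            mn.normalize_study(mn.generate_study(spec, ("ACV", "S_MN"), j))
            for j in range(4)
        ]
        agg = mn.homogeneity_check(
            [mn.distribution_metrics(s.y) for s in studies]
        )
        assert agg.all_homogeneous
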