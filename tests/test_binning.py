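import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seston.binning import (
    ClassScheme,
    DEFAULT_SCHEME,
    classes_for,
    fnu_to_class,
    split_dataset,
)


class TestFnuToClass:
    @pytest.mark.parametrize(
        "fnu,expected",
        [
            (0.25, 0),
            (0.0, 0),
            (0.497, 0),  # falls in the printed-label gap; half-open rule
            (0.5, 1),  # boundary value goes to the higher class
            (2.5, 3),
            (10.0, 5),
            (44.99, 9),
            (45.0, 10),
            (55.0, 10),  # upper end closed
        ],
    )
    def test_examples(self, fnu, expected):
        assert fnu_to_class(fnu) == expected

    @pytest.mark.parametrize("bad", [-0.1, 55.01, 60.0, float("nan"), float("inf")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            fnu_to_class(bad)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=0.0, max_value=55.0, allow_nan=False))
    def test_every_value_maps_to_exactly_one_class(self, fnu):
        k = fnu_to_class(fnu)
        lo, hi = DEFAULT_SCHEME.effective_interval(k)
        assert 0 <= k <= 10
        assert lo <= fnu and (fnu < hi or (k == 10 and fnu <= hi))

    def test_dense_grid_exhaustive_and_exclusive(self):
        grid = np.linspace(0.0, 55.0, 20001)
        ks = classes_for(grid)
        assert set(np.unique(ks)) == set(range(11))
        # class index non-decreasing along the grid: exclusive intervals
        assert np.all(np.diff(ks) >= 0)

    def test_midpoints_round_trip(self):
        for k in range(11):
            assert fnu_to_class(DEFAULT_SCHEME.midpoint(k)) == k


class TestClassScheme:
    def test_default_has_11_ordered_intervals(self):
        assert DEFAULT_SCHEME.n_classes == 11
        lowers = DEFAULT_SCHEME.lowers
        assert lowers[0] == 0.0
        assert np.all(np.diff(lowers) > 0)
        assert DEFAULT_SCHEME.boundaries[-1][1] == 55.0

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            ClassScheme(boundaries=tuple(DEFAULT_SCHEME.boundaries[:10]),
                        labels=tuple(DEFAULT_SCHEME.labels[:10]))
        shifted = [(lo + 1.0, hi + 1.0) for lo, hi in DEFAULT_SCHEME.boundaries]
        with pytest.raises(ValueError):
            ClassScheme(boundaries=tuple(shifted), labels=DEFAULT_SCHEME.labels)

    def test_config_round_trip(self):
        text = DEFAULT_SCHEME.to_config()
        back = ClassScheme.from_config(text)
        assert back.boundaries == DEFAULT_SCHEME.boundaries
        assert back.labels == DEFAULT_SCHEME.labels


class TestSplitDataset:
    @staticmethod
    def _manifest(n, fnu=20.0):
        return pd.DataFrame(
            {"image_id": [f"img{i}" for i in range(n)], "fnu_true": [fnu] * n}
        )

    def test_single_class_split_counts(self):
        parts = split_dataset(self._manifest(100), (0.75, 0.15, 0.10), seed=0)
        assert len(parts["train"]) == 75
        assert len(parts["test"]) == 15
        assert len(parts["val"]) == 10

    def test_partition_property(self, small_dataset):
        _, manifest = small_dataset
        parts = split_dataset(manifest, seed=3)
        ids = [set(p["image_id"]) for p in parts.values()]
        assert ids[0] | ids[1] | ids[2] == set(manifest["image_id"])
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_stratified_within_one_image_of_target(self, small_dataset):
        _, manifest = small_dataset
        parts = split_dataset(manifest, (0.75, 0.15, 0.10), seed=3)
        for k in range(11):
            n_class = (manifest["class_index"] == k).sum()
            for name, frac in zip(("train", "test", "val"), (0.75, 0.15, 0.10)):
                got = (parts[name]["class_index"] == k).sum()
                assert abs(got - frac * n_class) <= 1

    def test_deterministic_under_seed(self, small_dataset):
        _, manifest = small_dataset
        a = split_dataset(manifest, seed=11)
        b = split_dataset(manifest, seed=11)
        for name in ("train", "test", "val"):
            assert list(a[name]["image_id"]) == list(b[name]["image_id"])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._manifest(10), (0.5, 0.5, 0.5), seed=0)
        with pytest.raises(ValueError):
            split_dataset(self._manifest(10), (1.0, -0.5, 0.5), seed=0)

    def test_empty_class_warns_and_skips(self, caplog):
        manifest = self._manifest(20, fnu=20.0)  # only class 6 populated
        with caplog.at_level("WARNING"):
            parts = split_dataset(manifest, seed=0)
        assert sum(len(p) for p in parts.values()) == 20
        assert any("empty" in r.message for r in caplog.records)
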