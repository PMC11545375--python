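"""PGM I/O, feature-table I/O, and dataset partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stenoselect.data import (
    GrayImage,
    LabeledDataset,
    PGMParseError,
    load_feature_table,
    read_pgm,
    save_feature_table,
    split_dataset,
    write_pgm,
)


class TestPGM:
    def test_minimal_ascii_pgm(self, tmp_path):
        p = tmp_path / "m.pgm"
        p.write_bytes(b"P2 1 1 255 0")
        img = read_pgm(p)
        assert (img.height, img.width, img.maxval) == (1, 1, 255)
        assert img.pixels[0, 0] == 0

    def test_ascii_and_binary_dialects_agree(self, tmp_path, rng):
        img = GrayImage(rng.integers(0, 256, (64, 64)))
        write_pgm(img, tmp_path / "a.pgm", binary=False)
        write_pgm(img, tmp_path / "b.pgm", binary=True)
        a, b = read_pgm(tmp_path / "a.pgm"), read_pgm(tmp_path / "b.pgm")
        assert np.array_equal(a.pixels, b.pixels)
        assert a.height == a.width == 64

    def test_header_comments_tolerated(self, tmp_path):
        p = tmp_path / "c.pgm"
        p.write_bytes(b"P2\n# a comment\n2 1\n# another\n255\n7 9\n")
        img = read_pgm(p)
        assert img.pixels.tolist() == [[7, 9]]

    @pytest.mark.parametrize(
        "payload, fragment",
        [
            (b"P3 1 1 255 0", "magic"),
            (b"P2 1 1", "end of file"),
            (b"P2 1 1 255", "truncated raster"),
            (b"P5 2 2 255 \x00\x01", "truncated raster"),
            (b"P2 x 1 255 0", "non-integer"),
        ],
    )
    def test_malformed_inputs_raise_with_offset(self, tmp_path, payload, fragment):
        p = tmp_path / "bad.pgm"
        p.write_bytes(payload)
        with pytest.raises(PGMParseError, match=fragment) as err:
            read_pgm(p)
        assert "byte offset" in str(err.value)

    @settings(max_examples=25, deadline=None)
    @given(
        h=st.integers(1, 12),
        w=st.integers(1, 12),
        binary=st.booleans(),
        wide=st.booleans(),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, tmp_path_factory, h, w, binary, wide, seed):
        maxval = 65535 if wide else 255
        gen = np.random.default_rng(seed)
        img = GrayImage(gen.integers(0, maxval + 1, (h, w)), maxval=maxval)
        path = tmp_path_factory.mktemp("pgm") / "x.pgm"
        write_pgm(img, path, binary=binary)
        assert read_pgm(path) == img


class TestFeatureTable:
    def test_basic_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b,label\n1,2,0\n3,4,1\n5,6,0\n")
        ds = load_feature_table(p)
        assert ds.features.shape == (3, 2)
        assert ds.labels.tolist() == [0, 1, 0]
        assert ds.feature_names == ["a", "b"]

    def test_duplicate_column_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("a,a,label\n1,2,0\n")
        with pytest.raises(ValueError, match="'a'"):
            load_feature_table(p)

    def test_missing_label_column(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="label"):
            load_feature_table(p)

    def test_round_trip(self, tmp_path, rng):
        ds = LabeledDataset(
            rng.standard_normal((10, 5)),
            rng.integers(0, 2, 10),
            [f"f{i}" for i in range(5)],
        )
        save_feature_table(ds, tmp_path / "r.csv")
        back = load_feature_table(tmp_path / "r.csv")
        np.testing.assert_allclose(back.features, ds.features)
        assert back.labels.tolist() == ds.labels.tolist()
        assert back.feature_names == ds.feature_names


class TestSplit:
    @staticmethod
    def _balanced(n):
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        return LabeledDataset(np.random.default_rng(0).standard_normal((n, 3)),
                              labels, ["a", "b", "c"])

    def test_study_scale_split(self):
        ds = self._balanced(608)
        part = split_dataset(ds, (458, 50, 100), seed=0)
        assert (len(part.train_idx), len(part.validation_idx), len(part.test_idx)) == (458, 50, 100)
        part.validate_covering(608)

    def test_empty_split_forbidden(self):
        ds = self._balanced(10)
        with pytest.raises(ValueError):
            split_dataset(ds, (10, 0, 0), seed=0)

    def test_counts_must_sum(self):
        ds = self._balanced(10)
        with pytest.raises(ValueError, match="sum"):
            split_dataset(ds, (5, 3, 3), seed=0)

    def test_deterministic_for_fixed_seed(self):
        ds = self._balanced(40)
        a = split_dataset(ds, (20, 10, 10), seed=5)
        b = split_dataset(ds, (20, 10, 10), seed=5)
        for s in ("train_idx", "validation_idx", "test_idx"):
            assert np.array_equal(getattr(a, s), getattr(b, s))

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**16), stratified=st.booleans())
    def test_disjoint_covering_property(self, seed, stratified):
        ds = self._balanced(60)
        part = split_dataset(ds, (30, 12, 18), seed=seed, stratified=stratified)
        part.validate_covering(60)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**16))
    def test_stratified_balanced_within_one(self, seed):
        ds = self._balanced(61)
        part = split_dataset(ds, (31, 14, 16), seed=seed)
        for idx in (part.train_idx, part.validation_idx, part.test_idx):
            pos = ds.labels[idx].sum()
            assert abs(pos - (len(idx) - pos)) <= 1 + 1  # class sizes differ by 1
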