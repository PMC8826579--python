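"""Data model, long-format CSV round trips and the stratified split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grassid as g
from grassid.datamodel import read_split, write_split
from grassid.errors import (
    CompletenessError,
    DimensionError,
    DuplicateError,
    StratificationError,
)


class TestRoundTrip:
    def test_write_read_preserves_everything(self, toy, tmp_path):
        path = tmp_path / "toy.csv"
        g.write_feature_table(toy, path)
        back = g.read_feature_table(path)
        assert back.species_list == toy.species_list
        assert back.perspective_list == toy.perspective_list
        assert back.ids == toy.ids
        for a, b in zip(toy.observations, back.observations):
            assert a.species == b.species
            for p in toy.perspective_list:
                np.testing.assert_array_equal(a.features[p], b.features[p])

    def test_full_precision_round_trip(self, tmp_path):
        vals = np.array([1 / 3, np.pi, 1e-17, -2.5000000000000004])
        obs = [
            g.Observation("o1", "a", {"P": vals}),
            g.Observation("o2", "a", {"P": vals * 7}),
            g.Observation("o3", "b", {"P": -vals}),
            g.Observation("o4", "b", {"P": vals + 1}),
        ]
        ds = g.ObservationSet(obs)
        path = tmp_path / "f.csv"
        g.write_feature_table(ds, path)
        back = g.read_feature_table(path)
        for a, b in zip(ds.observations, back.observations):
            np.testing.assert_array_equal(a.features["P"], b.features["P"])

    def test_writing_twice_is_byte_identical(self, small_synth, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        g.write_feature_table(small_synth, p1)
        g.write_feature_table(small_synth, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_row_order_in_file_is_irrelevant(self, toy, tmp_path):
        path = tmp_path / "toy.csv"
        g.write_feature_table(toy, path)
        df = pd.read_csv(path)
        shuffled = df.sample(frac=1.0, random_state=3)
        path2 = tmp_path / "shuffled.csv"
        shuffled.to_csv(path2, index=False)
        back = g.read_feature_table(path2)
        assert back.ids == toy.ids
        assert back.species_list == toy.species_list

    def test_empty_set_writes_header_only(self, tmp_path):
        ds = g.ObservationSet([], species_list=("a",), perspective_list=("P",))
        path = tmp_path / "empty.csv"
        g.write_feature_table(ds, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("obs_id,species,perspective")


class TestReadValidation:
    def _frame(self, toy):
        return toy.to_frame()

    def test_missing_perspective_names_offender(self, toy, tmp_path):
        df = self._frame(toy)
        df = df[~((df.obs_id == "obs_01_02") & (df.perspective == "P2"))]
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(CompletenessError, match="obs_01_02"):
            g.read_feature_table(path)

    def test_duplicate_obs_perspective_rejected(self, toy, tmp_path):
        df = self._frame(toy)
        df = pd.concat([df, df.iloc[[0]]])
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DuplicateError):
            g.read_feature_table(path)

    def test_ragged_feature_columns_rejected(self, toy, tmp_path):
        df = self._frame(toy)
        df.loc[df.index[0], "f1"] = np.nan
        path = tmp_path / "ragged.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DimensionError):
            g.read_feature_table(path)

    def test_incomplete_allowed_with_flag(self, toy, tmp_path):
        df = self._frame(toy)
        df = df[~((df.obs_id == "obs_01_02") & (df.perspective == "P2"))]
        path = tmp_path / "partial.csv"
        df.to_csv(path, index=False)
        ds = g.read_feature_table(path, allow_incomplete=True)
        assert len(ds) == 12

    def test_inconsistent_dims_rejected_in_memory(self):
        obs = [
            g.Observation("o1", "a", {"P": np.zeros(2)}),
            g.Observation("o2", "a", {"P": np.zeros(3)}),
        ]
        with pytest.raises(DimensionError):
            g.ObservationSet(obs)


class TestStratifiedSplit:
    def test_study_scale_counts(self):
        cfg = g.SyntheticConfig(
            n_species=31, n_per_species=80, perspectives=("A",), dim=2,
            discriminability={"A": 0.0}, seed=5,
        )
        ds = g.generate_dataset(cfg)
        split = g.stratified_split(ds, seed=0)  # defaults 65 / 15
        assert len(split.train_ids) == 31 * 65 == 2015
        assert len(split.test_ids) == 31 * 15 == 465
        labels = ds.labels()
        for s in ds.species_list:
            assert sum(labels[i] == s for i in split.train_ids) == 65
            assert sum(labels[i] == s for i in split.test_ids) == 15

    def test_minimal_split(self):
        obs = [
            g.Observation(f"o{i}{s}", s, {"P": np.array([float(i)])})
            for s in "ab" for i in range(2)
        ]
        ds = g.ObservationSet(obs)
        split = g.stratified_split(ds, 1, 1, seed=0)
        assert not (split.train_ids & split.test_ids)
        assert split.train_ids | split.test_ids == set(ds.ids)

    def test_wrong_count_names_species(self, toy):
        with pytest.raises(StratificationError, match="sp_"):
            g.stratified_split(toy, 65, 15, seed=0)

    def test_same_seed_same_split(self, small_synth):
        a = g.stratified_split(small_synth, 7, 3, seed=42)
        b = g.stratified_split(small_synth, 7, 3, seed=42)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_split_invariant_to_observation_order(self, small_synth):
        reversed_set = g.ObservationSet(
            list(reversed(small_synth.observations)),
            species_list=small_synth.species_list,
            perspective_list=small_synth.perspective_list,
        )
        a = g.stratified_split(small_synth, 7, 3, seed=9)
        b = g.stratified_split(reversed_set, 7, 3, seed=9)
        assert a.train_ids == b.train_ids

    @settings(max_examples=25, deadline=None)
    @given(
        n_species=st.integers(2, 6),
        n_train=st.integers(1, 5),
        n_test=st.integers(1, 5),
        seed=st.integers(0, 2**20),
    )
    def test_partition_property(self, n_species, n_train, n_test, seed):
        """Disjoint, exhaustive, exactly sized per species for every valid input."""
        n = n_train + n_test
        obs = [
            g.Observation(f"o_{k}_{i}", f"s{k}", {"P": np.array([float(i)])})
            for k in range(n_species) for i in range(n)
        ]
        ds = g.ObservationSet(obs)
        split = g.stratified_split(ds, n_train, n_test, seed=seed)
        assert not (split.train_ids & split.test_ids)
        assert split.train_ids | split.test_ids == set(ds.ids)
        labels = ds.labels()
        for k in range(n_species):
            assert sum(labels[i] == f"s{k}" for i in split.train_ids) == n_train

    def test_split_file_round_trip(self, small_synth, tmp_path):
        split = g.stratified_split(small_synth, 7, 3, seed=2)
        path = tmp_path / "split.csv"
        write_split(split, path)
        back = read_split(path)
        assert back.train_ids == split.train_ids
        assert back.test_ids == split.test_ids
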