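import numpy as np
import pandas as pd
import pytest

from rbcforecast import (
    SynthSpec,
    exclude_timepoints,
    flag_anomalous_timepoints,
    generate_dataset,
    read_dataset,
    split_replicates,
    write_dataset,
)
from rbcforecast.dataset import MetabolomicsDataset
from rbcforecast.exceptions import (
    DataFormatError,
    DomainError,
    IncompleteDataError,
    InsufficientDataError,
    UnknownIdentifierError,
)


def _tiny_csv(tmp_path, drop_row=False, negative=False):
    rows = []
    for mid, comp in [("glc", "extracellular"), ("atp", "intracellular")]:
        for rep in ["r1", "r2"]:
            for t in [0.0, 3.0, 7.0]:
                rows.append((mid, comp, rep, t, 1.0 + t))
    if drop_row:
        rows.pop()
    if negative:
        rows[0] = ("glc", "extracellular", "r1", 0.0, -1.0)
    df = pd.DataFrame(
        rows,
        columns=["metabolite_id", "compartment", "replicate_id", "time_days", "concentration"],
    )
    path = tmp_path / "tiny.csv"
    df.to_csv(path, index=False)
    return path


class TestReadDataset:
    def test_minimal_complete_grid(self, tmp_path):
        ds = read_dataset(_tiny_csv(tmp_path), biomarker_ids=["glc"])
        assert ds.n_metabolites == 2 and ds.n_replicates == 2 and ds.n_timepoints == 3
        assert ds.target_ids == ("atp",)

    def test_missing_cell_is_completeness_error(self, tmp_path):
        with pytest.raises(IncompleteDataError):
            read_dataset(_tiny_csv(tmp_path, drop_row=True), biomarker_ids=["glc"])

    def test_missing_column_is_format_error(self, tmp_path):
        path = _tiny_csv(tmp_path)
        df = pd.read_csv(path).drop(columns=["compartment"])
        df.to_csv(path, index=False)
        with pytest.raises(DataFormatError):
            read_dataset(path, biomarker_ids=["glc"])

    def test_negative_concentration_is_domain_error(self, tmp_path):
        with pytest.raises(DomainError):
            read_dataset(_tiny_csv(tmp_path, negative=True), biomarker_ids=["glc"])

    def test_unknown_biomarker_is_reference_error(self, tmp_path):
        with pytest.raises(UnknownIdentifierError):
            read_dataset(_tiny_csv(tmp_path), biomarker_ids=["lactate"])

    def test_row_order_is_irrelevant(self, tmp_path):
        path = _tiny_csv(tmp_path)
        df = pd.read_csv(path).sample(frac=1.0, random_state=0)
        shuffled = tmp_path / "shuffled.csv"
        df.to_csv(shuffled, index=False)
        a = read_dataset(path, ["glc"])
        b = read_dataset(shuffled, ["glc"])
        assert np.array_equal(a.concentrations, b.concentrations)

    def test_roundtrip_through_csv(self, tmp_path, default_data):
        ds, _ = default_data
        path = tmp_path / "full.csv"
        write_dataset(ds, path)
        back = read_dataset(path, ds.biomarker_ids)
        assert back.metabolite_ids == ds.metabolite_ids
        assert back.replicate_ids == ds.replicate_ids
        assert np.array_equal(back.time_days, ds.time_days)
        assert np.array_equal(back.concentrations, ds.concentrations)


class TestExcludeTimepoints:
    def test_day31_exclusion_leaves_13_points(self, default_data):
        ds, _ = default_data
        assert ds.n_timepoints == 14
        out = exclude_timepoints(ds, [31.0])
        assert out.n_timepoints == 13
        assert 31.0 not in out.time_days
        keep = ds.time_days != 31.0
        assert np.array_equal(out.concentrations, ds.concentrations[:, :, keep])

    def test_empty_exclusion_is_identity(self, default_data):
        ds, _ = default_data
        assert exclude_timepoints(ds, []) is ds

    def test_day_off_grid_is_reference_error(self, default_data):
        ds, _ = default_data
        with pytest.raises(UnknownIdentifierError):
            exclude_timepoints(ds, [32.0])


class TestAnomalyFlagging:
    def test_identical_replicates_yield_no_flags(self):
        ds, _ = generate_dataset(
            SynthSpec(seed=1, noise_sd=0.0, bag_sd=0.0, n_signal_targets=4, n_noise_targets=0)
        )
        assert flag_anomalous_timepoints(ds) == []

    def test_planted_day31_artifact_is_flagged(self):
        ds, truth = generate_dataset(SynthSpec(seed=2, day31_artifact=True))
        flags = set(flag_anomalous_timepoints(ds, cv_ratio_threshold=3.0))
        planted = set(truth.artifact_cells)
        assert planted, "generator must plant artifact cells"
        # the planted spike must be detected for the large majority of
        # extracellular metabolites (a few can be masked by chance)
        found = len(planted & flags) / len(planted)
        assert found > 0.9
        assert all(t == 31.0 for t, _ in planted)

    def test_infinite_threshold_flags_nothing(self):
        ds, _ = generate_dataset(SynthSpec(seed=2, day31_artifact=True))
        assert flag_anomalous_timepoints(ds, cv_ratio_threshold=np.inf) == []

    def test_excluded_day_is_never_flagged(self):
        ds, _ = generate_dataset(SynthSpec(seed=2, day31_artifact=True))
        out = exclude_timepoints(ds, [31.0])
        flags = flag_anomalous_timepoints(out)
        assert all(t != 31.0 for t, _ in flags)

    def test_single_replicate_is_insufficient(self):
        ds, _ = generate_dataset(
            SynthSpec(seed=1, n_replicates=1, n_signal_targets=2, n_noise_targets=0)
        )
        with pytest.raises(InsufficientDataError):
            flag_anomalous_timepoints(ds)


class TestSplitReplicates:
    def test_even_split_is_half_half_disjoint(self, default_data):
        ds, _ = default_data
        split = split_replicates(ds, 0)
        assert len(split.training_replicates) == 10
        assert len(split.testing_replicates) == 10
        assert not set(split.training_replicates) & set(split.testing_replicates)
        assert set(split.training_replicates) | set(split.testing_replicates) == set(
            ds.replicate_ids
        )

    def test_same_seed_is_deterministic(self, default_data):
        ds, _ = default_data
        assert split_replicates(ds, 7) == split_replicates(ds, 7)

    def test_two_replicates_split_one_and_one(self):
        ds, _ = generate_dataset(
            SynthSpec(seed=1, n_replicates=2, n_signal_targets=2, n_noise_targets=0)
        )
        split = split_replicates(ds, 0)
        assert len(split.training_replicates) == 1
        assert len(split.testing_replicates) == 1

    def test_odd_count_training_gets_extra(self):
        ds, _ = generate_dataset(
            SynthSpec(seed=1, n_replicates=5, n_signal_targets=2, n_noise_targets=0)
        )
        split = split_replicates(ds, 0)
        assert len(split.training_replicates) == 3

    def test_assignment_frequency_is_uniform(self, default_data):
        # each replicate lands in training with frequency 1/2 up to
        # 3 binomial standard errors over many seeds
        ds, _ = default_data
        n_seeds = 400
        counts = {r: 0 for r in ds.replicate_ids}
        for seed in range(n_seeds):
            for r in split_replicates(ds, seed).training_replicates:
                counts[r] += 1
        se = np.sqrt(0.25 / n_seeds)
        for r, c in counts.items():
            assert abs(c / n_seeds - 0.5) < 3 * se


def test_dataset_invariants_rejected():
    with pytest.raises(DataFormatError):
        MetabolomicsDataset(
            metabolite_ids=("a",),
            compartments=("nowhere",),
            replicate_ids=("r1",),
            time_days=np.array([0.0]),
            concentrations=np.ones((1, 1, 1)),
            biomarker_ids=(),
        )
    with pytest.raises(DomainError):
        MetabolomicsDataset(
            metabolite_ids=("a",),
            compartments=("intracellular",),
            replicate_ids=("r1",),
            time_days=np.array([0.0, 1.0]),
            concentrations=np.array([[[1.0, -1.0]]]),
            biomarker_ids=(),
        )
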