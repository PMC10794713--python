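"""Alignment filtering, TPM arithmetic, coverage tracks and class percentages."""

import numpy as np
import pandas as pd
import pytest

from capsidmorph.rnaquant import (
    ReferenceSet,
    adjusted_tpm,
    bp_percent_by_class,
    count_per_cds,
    filter_mapq,
    filter_three_prime,
    normalize_coverage,
    per_base_coverage,
    quantify_replicates,
    read_alignments_sam,
    smooth_coverage,
    tpm,
)
from capsidmorph.synthetic import AlignmentSimSpec, gen_read_alignments, write_alignments_sam

from conftest import make_alignments


class TestFilters:
    def test_mapq_equality_retention(self):
        alns = make_alignments(
            [("r1", "CP", 0, 100, 60), ("r2", "CP", 0, 100, 60), ("r3", "CP", 0, 100, 30), ("r4", "CP", 0, 100, 0)]
        )
        assert filter_mapq(alns)["read_id"].tolist() == ["r1", "r2"]

    def test_empty_passthrough(self):
        empty = make_alignments([])
        assert len(filter_mapq(empty)) == 0

    def test_generator_mapq_fraction_round_trip(self):
        spec = AlignmentSimSpec(
            references=(("CP", 807, "CP"),),
            composition=(1.0,),
            n_reads=10_000,
            mapq_high_fraction=0.8,
            seed=5,
        )
        alns = gen_read_alignments(spec)[0]
        assert len(filter_mapq(alns)) / len(alns) == pytest.approx(0.8, abs=0.02)

    @pytest.mark.parametrize(
        "end, kept", [(780, True), (700, False), (807, True), (757, True), (756, False)]
    )
    def test_three_prime_window_on_end_coordinate(self, end, kept, two_ref_set):
        alns = make_alignments([("r1", "CP", 100, end, 60)])
        out = filter_three_prime(alns, two_ref_set, window=50)
        assert (len(out) == 1) is kept

    def test_unknown_reference_named_in_error(self, two_ref_set):
        alns = make_alignments([("r1", "nope", 0, 100, 60)])
        with pytest.raises(KeyError, match="nope"):
            filter_three_prime(alns, two_ref_set)

    def test_filters_commute(self, two_ref_set, rng):
        rows = [
            (
                f"r{i}",
                "CP",
                int(s),
                int(s) + 50,
                int(rng.choice([0, 30, 60])),
            )
            for i, s in enumerate(rng.integers(0, 757, size=200))
        ]
        alns = make_alignments(rows)
        a = filter_three_prime(filter_mapq(alns), two_ref_set)
        b = filter_mapq(filter_three_prime(alns, two_ref_set))
        pd.testing.assert_frame_equal(a, b)


class TestTpm:
    def test_counting(self):
        alns = make_alignments(
            [("r1", "A", 0, 5, 60), ("r2", "A", 0, 5, 60), ("r3", "A", 0, 5, 60), ("r4", "B", 0, 5, 60)]
        )
        counts = count_per_cds(alns)
        assert counts.to_dict() == {"A": 3, "B": 1}

    def test_equal_rates_split_evenly(self):
        refs = ReferenceSet(lengths={"A": 1000, "B": 500})
        values = tpm(pd.Series({"A": 100, "B": 50}), refs)
        assert values["A"] == pytest.approx(500_000)
        assert values["B"] == pytest.approx(500_000)

    def test_single_expressed_ref_takes_all(self):
        refs = ReferenceSet(lengths={"A": 1000, "B": 500})
        values = tpm(pd.Series({"A": 10, "B": 0}), refs)
        assert values["A"] == pytest.approx(1e6)

    def test_all_zero_flagged(self):
        refs = ReferenceSet(lengths={"A": 1000})
        values = tpm(pd.Series({"A": 0}), refs)
        assert values.attrs["all_zero"] and values["A"] == 0.0

    def test_matches_rate_normalization_oracle(self, rng):
        ids = [f"g{i}" for i in range(20)]
        lengths = {g: int(l) for g, l in zip(ids, rng.integers(200, 5000, size=20))}
        counts = pd.Series({g: int(c) for g, c in zip(ids, rng.integers(0, 1000, size=20))})
        refs = ReferenceSet(lengths=lengths)
        values = tpm(counts, refs)
        rates = np.array([counts[g] / lengths[g] for g in ids])
        expected = rates / rates.sum() * 1e6
        assert values.reindex(ids).to_numpy() == pytest.approx(expected, abs=1e-9)
        assert values.sum() == pytest.approx(1e6, abs=1e-3)


class TestAdjustedTpm:
    def test_hand_worked_example(self):
        rep1 = pd.Series({"A": 8e5, "B": 2e5, "C": 0.0})
        rep2 = pd.Series({"A": 6e5, "B": 3e5, "C": 1e5})
        out = adjusted_tpm(rep1, rep2)
        assert "C" not in out.index
        assert out.loc["A", "rep2"] == pytest.approx(666_666.67, abs=0.5)
        assert out.loc["B", "rep2"] == pytest.approx(333_333.33, abs=0.5)
        assert out.loc["A", "mean"] == pytest.approx(733_333.33, abs=0.5)
        assert out.loc["B", "mean"] == pytest.approx(266_666.67, abs=0.5)
        for col in ("rep1", "rep2", "mean"):
            assert out[col].sum() == pytest.approx(1e6, abs=1e-3)

    def test_single_replicate_presence_discarded(self):
        rep1 = pd.Series({"A": 9e5, "B": 1e5})
        rep2 = pd.Series({"A": 1e6, "B": 0.0})
        assert adjusted_tpm(rep1, rep2).index.tolist() == ["A"]

    def test_identical_replicates_unchanged(self):
        rep = pd.Series({"A": 7e5, "B": 3e5})
        out = adjusted_tpm(rep, rep.copy())
        assert out["mean"].to_dict() == pytest.approx(rep.to_dict())

    def test_no_renormalize_mode_averages_raw_survivors(self):
        rep1 = pd.Series({"A": 8e5, "B": 2e5, "C": 0.0})
        rep2 = pd.Series({"A": 6e5, "B": 3e5, "C": 1e5})
        out = adjusted_tpm(rep1, rep2, renormalize=False)
        assert out.loc["A", "mean"] == pytest.approx(7e5)
        assert out["rep2"].sum() < 1e6

    def test_disjoint_replicates_rejected(self):
        with pytest.raises(ValueError, match="no transcripts"):
            adjusted_tpm(pd.Series({"A": 1e6, "B": 0.0}), pd.Series({"A": 0.0, "B": 1e6}))


class TestCoverage:
    def one_ref(self, length=20):
        return ReferenceSet(lengths={"A": length})

    def test_single_read_block(self):
        tracks = per_base_coverage(make_alignments([("r1", "A", 0, 10, 60)]), self.one_ref())
        assert tracks["A"].tolist() == [1.0] * 10 + [0.0] * 10

    def test_stacked_reads(self):
        alns = make_alignments([("r1", "A", 5, 15, 60), ("r2", "A", 5, 15, 60)])
        assert per_base_coverage(alns, self.one_ref())["A"][5:15].tolist() == [2.0] * 10

    def test_matches_brute_force_overlap_counting(self, rng):
        length = 100
        rows = []
        for i in range(200):
            s = int(rng.integers(0, length - 1))
            e = int(rng.integers(s + 1, length + 1))
            rows.append((f"r{i}", "A", s, e, 60))
        alns = make_alignments(rows)
        track = per_base_coverage(alns, self.one_ref(length))["A"]
        brute = np.zeros(length)
        for _, _, s, e, _ in rows:
            for b in range(s, e):
                brute[b] += 1
        assert track.tolist() == brute.tolist()

    def test_normalization_to_one_million_bases(self):
        tracks = {"A": np.full(10, 3.0), "B": np.full(10, 1.0)}
        out = normalize_coverage(tracks)
        total = sum(t.sum() for t in out.values())
        assert total == pytest.approx(1e6, abs=1e-3)
        assert out["A"].sum() == pytest.approx(7.5e5)
        assert out["B"].sum() == pytest.approx(2.5e5)

    def test_uniform_coverage_value_cancels(self):
        out = normalize_coverage({"A": np.full(40, 17.0)})
        assert out["A"] == pytest.approx(1e6 / 40)

    def test_single_covered_base(self):
        out = normalize_coverage({"A": np.array([0.0, 5.0, 0.0])})
        assert out["A"][1] == pytest.approx(1e6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_coverage({"A": np.zeros(10)})

    def test_smoothing_constant_unchanged(self):
        track = np.full(100, 4.2)
        assert smooth_coverage(track, 40) == pytest.approx(track)

    def test_smoothing_impulse_plateau(self):
        track = np.zeros(200)
        track[100] = 1.0
        smoothed = smooth_coverage(track, 40)
        interior = smoothed[smoothed > 0]
        assert len(interior) == 40
        assert interior == pytest.approx(1 / 40)

    def test_smoothing_window_one_is_identity(self, rng):
        track = rng.uniform(0, 5, size=50)
        assert smooth_coverage(track, 1) == pytest.approx(track)

    def test_smoothing_stays_within_input_range(self, rng):
        track = rng.uniform(0, 100, size=300)
        smoothed = smooth_coverage(track, 40)
        assert smoothed.min() >= track.min() - 1e-9
        assert smoothed.max() <= track.max() + 1e-9


class TestClassPercent:
    def test_single_class_is_everything(self):
        refs = ReferenceSet(lengths={"rrsA": 1542}, classes={"rrsA": "rRNA"})
        alns = make_alignments([("r1", "rrsA", 0, 500, 60), ("r2", "rrsA", 100, 600, 60)])
        out = bp_percent_by_class(alns, refs)
        assert out["rRNA"] == 100.0

    def test_equal_bp_split(self, two_ref_set):
        alns = make_alignments([("r1", "CP", 0, 400, 60), ("r2", "hns", 0, 400, 60)])
        out = bp_percent_by_class(alns, two_ref_set)
        assert out["CP"] == out["other"] == 50.0
        assert sum(out.values()) == pytest.approx(100.0)

    def test_empty_rejected(self, two_ref_set):
        with pytest.raises(ValueError):
            bp_percent_by_class(make_alignments([]), two_ref_set)


class TestSamRoundTrip:
    def test_write_then_read_preserves_table(self, tmp_path, two_ref_set):
        alns = make_alignments(
            [("r1", "CP", 0, 100, 60), ("r2", "hns", 10, 410, 30), ("r3", "CP", 757, 807, 60)]
        )
        path = tmp_path / "mini.sam"
        write_alignments_sam(alns, two_ref_set, path)
        table, lengths = read_alignments_sam(path)
        pd.testing.assert_frame_equal(table, alns)
        assert lengths == {"CP": 807, "hns": 807}


class TestEndToEnd:
    def test_composition_recovery_through_full_pipeline(self, two_ref_set):
        """Injected 70/30 read composition comes back as adjusted TPM fractions."""
        spec = AlignmentSimSpec(
            references=(("CP", 807, "CP"), ("hns", 807, "other")),
            composition=(0.7, 0.3),
            read_length_dist=(400.0, 60.0),
            three_prime_bias=1.0,
            n_reads=10_000,
            mapq_high_fraction=1.0,
            seed=17,
        )
        reps = gen_read_alignments(spec)
        result = quantify_replicates(reps, two_ref_set)
        cp_fraction = result.adjusted.loc["CP", "mean"] / 1e6
        assert cp_fraction == pytest.approx(0.7, abs=0.02)
        assert result.adjusted["mean"].sum() == pytest.approx(1e6, abs=1e-3)
        assert result.bp_percent["CP"] == pytest.approx(70.0, abs=2.0)
        total_norm = sum(t.sum() for t in result.coverage_norm.values())
        assert total_norm == pytest.approx(1e6, abs=1e-3)

    def test_duplicate_read_ids_rejected(self, two_ref_set):
        alns = make_alignments([("r1", "CP", 0, 100, 60), ("r1", "CP", 0, 100, 60)])
        with pytest.raises(ValueError, match="duplicate read_id"):
            quantify_replicates([alns, alns], two_ref_set)
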