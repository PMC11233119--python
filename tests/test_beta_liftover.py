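"""Replicate aggregation and beta-matrix conversion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from methlift import (
    BetaMatrix,
    SimulationConfig,
    aggregate_replicates,
    build_id_mapping,
    convert_beta,
    make_platform_pair,
    simulate_cohort,
    simulate_signal_frame,
)
from methlift.beta_liftover import read_beta_tsv, write_beta_tsv

NA = math.nan


class TestAggregateReplicates:
    def test_mean_of_two(self):
        assert aggregate_replicates([0.2, 0.4], "mean") == pytest.approx(0.3)

    def test_best_detection_picks_argmin_p(self):
        got = aggregate_replicates([0.2, 0.9], "best_detection", detection_p=[0.5, 0.001])
        assert got == 0.9

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_mean_over_all_missingness_patterns(self, n):
        """Mean skips missing entries; all-missing stays missing (brute force)."""
        base = [0.2, 0.4, 0.9][:n]
        for pattern in itertools.product([True, False], repeat=n):
            vals = [NA if miss else v for v, miss in zip(base, pattern)]
            got = aggregate_replicates(vals, "mean")
            finite = [v for v in vals if not math.isnan(v)]
            if finite:
                assert got == pytest.approx(sum(finite) / len(finite))
            else:
                assert math.isnan(got)

    def test_best_detection_skips_masked_and_missing(self):
        got = aggregate_replicates(
            [0.1, 0.5, 0.9],
            "best_detection",
            detection_p=[0.001, 0.01, NA],
            masked=[True, False, False],
        )
        assert got == 0.5

    def test_best_detection_falls_back_to_mean_when_nothing_eligible(self):
        got = aggregate_replicates(
            [0.2, 0.4], "best_detection", detection_p=[NA, NA]
        )
        assert got == pytest.approx(0.3)
        got = aggregate_replicates(
            [0.2, 0.4], "best_detection", detection_p=[0.1, 0.1], masked=[True, True]
        )
        assert got == pytest.approx(0.3)

    def test_tie_breaks_to_first_candidate(self):
        assert aggregate_replicates([0.7, 0.1], "best_detection", detection_p=[0.01, 0.01]) == 0.7

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregate_replicates([], "mean")
        with pytest.raises(ValueError):
            aggregate_replicates([0.5], "best_detection")
        with pytest.raises(ValueError):
            aggregate_replicates([0.5], "no_such_strategy")


class TestBetaMatrix:
    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BetaMatrix("X", pd.DataFrame({"s1": [1.2]}, index=["cg1"]))

    def test_rejects_duplicate_probes(self):
        with pytest.raises(ValueError, match="duplicate"):
            BetaMatrix("X", pd.DataFrame({"s1": [0.1, 0.2]}, index=["cg1", "cg1"]))

    def test_tsv_round_trip_preserves_missing(self, tmp_path):
        b = BetaMatrix(
            "X", pd.DataFrame({"s1": [0.25, NA], "s2": [0.5, 1.0]}, index=["cg1", "cg2"])
        )
        path = tmp_path / "betas.tsv"
        write_beta_tsv(b, path)
        assert "NA" in path.read_text()
        back = read_beta_tsv(path, platform="X")
        pd.testing.assert_frame_equal(back.values, b.values, check_names=False)


def brute_force_convert(b, mapping, strategy, p_lookup=None, mask_lookup=None):
    """Per-cell nested-loop recomputation of convert_beta (independent oracle)."""
    by_target = {}
    for pair in mapping.pairs:
        if pair.source_id in set(b.values.index):
            by_target.setdefault(pair.target_id, []).append(pair.source_id)
    out = {}
    for tgt in sorted(by_target):
        sources = sorted(by_target[tgt])
        row = {}
        for sample in b.sample_ids:
            vals = [b.values.at[s, sample] for s in sources]
            if strategy == "mean":
                row[sample] = aggregate_replicates(vals, "mean")
            else:
                p = [p_lookup.get(s, NA) for s in sources]
                m = [mask_lookup.get(s, False) for s in sources]
                row[sample] = aggregate_replicates(vals, "best_detection", p, m)
        out[tgt] = row
    return pd.DataFrame(out).T.reindex(columns=b.sample_ids)


@pytest.fixture
def suffixed_cohort(cfg, platform_pair):
    _, suffixed, _ = platform_pair
    betas, _, _ = simulate_cohort(cfg, suffixed, 2)
    return betas


class TestConvertBeta:
    def test_broadcast_duplicates_source_row_verbatim(self):
        src = BetaMatrix("A", pd.DataFrame({"s1": [0.3], "s2": [0.8]}, index=["cg1"]))
        tgt_ids = ["cg1_TC11", "cg1_BC11"]
        from methlift.probe_identity import MappingPair, MappingTable

        mapping = MappingTable("A", "B", [MappingPair("cg1", t) for t in tgt_ids])
        out = convert_beta(src, mapping)
        for t in tgt_ids:
            assert list(out.values.loc[t]) == [0.3, 0.8]

    def test_identity_mapping_preserves_values(self, cfg, platform_pair):
        # a replicate-free platform mapped to itself is a true identity
        legacy, _, _ = platform_pair
        betas, _, _ = simulate_cohort(cfg, legacy, 2)
        identity = build_id_mapping(legacy, legacy)
        for strategy in ("mean", "best_detection"):
            signal = simulate_signal_frame(cfg, legacy) if strategy == "best_detection" else None
            out = convert_beta(betas, identity, strategy, signal=signal)
            expected = betas.values.sort_index()
            pd.testing.assert_frame_equal(out.values, expected, check_names=False)

    @pytest.mark.parametrize("strategy", ["mean", "best_detection"])
    def test_matches_per_cell_brute_force(self, cfg, platform_pair, suffixed_cohort, strategy):
        _, suffixed, _ = platform_pair
        legacy, _, _ = platform_pair
        mapping = build_id_mapping(suffixed, legacy)
        signal = simulate_signal_frame(cfg, suffixed)
        out = convert_beta(suffixed_cohort, mapping, strategy, signal=signal)
        expected = brute_force_convert(
            suffixed_cohort,
            mapping,
            strategy,
            p_lookup=signal.data["detection_p"].to_dict(),
            mask_lookup=signal.data["masked"].to_dict(),
        )
        pd.testing.assert_frame_equal(out.values, expected, check_names=False)

    def test_round_trip_on_one_to_one_subset(self, cfg, platform_pair, suffixed_cohort):
        legacy, suffixed, fwd = platform_pair
        rev = build_id_mapping(suffixed, legacy)
        to_legacy = convert_beta(suffixed_cohort, rev)
        back = convert_beta(to_legacy, fwd)
        # one-to-one prefixes: exactly one probe on each side
        from methlift import replicate_groups

        one_to_one = [
            ids[0]
            for prefix, ids in replicate_groups(suffixed).items()
            if len(ids) == 1 and prefix in replicate_groups(legacy)
        ]
        orig = suffixed_cohort.values.loc[one_to_one].sort_index()
        pd.testing.assert_frame_equal(back.values.loc[orig.index], orig, check_names=False)

    def test_output_within_contributing_range(self, cfg, platform_pair, suffixed_cohort):
        legacy, suffixed, _ = platform_pair
        mapping = build_id_mapping(suffixed, legacy)
        signal = simulate_signal_frame(cfg, suffixed)
        by_target = {}
        for p in mapping.pairs:
            by_target.setdefault(p.target_id, []).append(p.source_id)
        for strategy in ("mean", "best_detection"):
            out = convert_beta(suffixed_cohort, mapping, strategy, signal=signal)
            for tgt in out.values.index:
                contrib = suffixed_cohort.values.loc[by_target[tgt]]
                lo, hi = contrib.min(), contrib.max()
                row = out.values.loc[tgt]
                ok = row.isna() | ((row >= lo - 1e-12) & (row <= hi + 1e-12))
                assert ok.all()

    def test_sample_columns_invariant(self, platform_pair, suffixed_cohort):
        legacy, suffixed, _ = platform_pair
        out = convert_beta(suffixed_cohort, build_id_mapping(suffixed, legacy))
        assert out.sample_ids == suffixed_cohort.sample_ids

    def test_conversion_to_replicate_richer_platform_grows_rows(self, platform_pair):
        legacy, suffixed, fwd = platform_pair
        cfg = SimulationConfig(seed=11, n_prefixes=40)
        betas, _, _ = simulate_cohort(cfg, legacy, 1)
        out = convert_beta(betas, fwd)
        shared_sources = {p.source_id for p in fwd.pairs}
        assert out.shape[0] >= len(shared_sources)

    def test_respect_mask_excludes_masked_from_mean(self):
        from methlift.probe_identity import MappingPair, MappingTable
        from methlift.signal_liftover import SignalFrame

        b = BetaMatrix(
            "A", pd.DataFrame({"s1": [0.2, 0.8]}, index=["cg1_TC11", "cg1_BC11"])
        )
        mapping = MappingTable(
            "A", "B", [MappingPair("cg1_TC11", "cg1"), MappingPair("cg1_BC11", "cg1")]
        )
        sig = SignalFrame(
            "A",
            pd.DataFrame(
                {"M": [1.0, 1.0], "U": [1.0, 1.0], "detection_p": [0.01, 0.01],
                 "masked": [False, True]},
                index=["cg1_TC11", "cg1_BC11"],
            ),
        )
        assert convert_beta(b, mapping, "mean", signal=sig).values.at["cg1", "s1"] == pytest.approx(0.5)
        assert convert_beta(
            b, mapping, "mean", signal=sig, respect_mask=True
        ).values.at["cg1", "s1"] == pytest.approx(0.2)

    def test_platform_mismatch_raises(self, platform_pair, suffixed_cohort):
        legacy, suffixed, fwd = platform_pair  # fwd expects legacy input
        with pytest.raises(ValueError, match="platform"):
            convert_beta(suffixed_cohort, fwd)

    def test_pairs_missing_from_matrix_are_skipped(self, platform_pair, suffixed_cohort):
        legacy, suffixed, _ = platform_pair
        mapping = build_id_mapping(suffixed, legacy)
        half = BetaMatrix(
            suffixed_cohort.platform,
            suffixed_cohort.values.iloc[: len(suffixed_cohort.values) // 2],
        )
        out = convert_beta(half, mapping)
        fed_targets = {
            p.target_id for p in mapping.pairs if p.source_id in set(half.values.index)
        }
        assert set(out.values.index) == fed_targets
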