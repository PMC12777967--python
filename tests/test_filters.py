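"""Candidate-selection stack: background, cancer-support, strategies, MHC."""

import numpy as np
import pandas as pd
import pytest

from splicepep.filters import (
    FilterConfig,
    allframes_filter,
    annotation_filter,
    apply_mhc_threshold,
    background_filter,
    cancer_support_filter,
    foreground_default_rule,
    normalization_factors,
    novel_frame_only,
    requant_filter,
)
from splicepep.genome_io import ExpressionTable
from splicepep.kmers import KmerRecord


def krec(kmer, is_junction=True, junction_keys=None, frame_annotated=True,
         variant_mode="ref"):
    keys = junction_keys if junction_keys is not None else (("c", 10, 50),)
    positions = (((0, 10), (50, 67)) if is_junction else ((0, 27),))
    return KmerRecord(
        kmer=kmer, gene_id="g", offset=0, is_junction=is_junction,
        junction_keys=keys if is_junction else (),
        genomic_positions=positions, frame_annotated=frame_annotated,
        junction_annotated=(True,) if is_junction else (),
        stop_interrupted=False, has_somatic=False, variant_mode=variant_mode)


class TestAnnotationFilter:
    def test_annotated_window_removed_and_novel_kept(self):
        kmers = [krec("MKTAYIAKQ"), krec("QQQQQQQQQ")]
        proteins = ["XXMKTAYIAKQRZZ".replace("Z", "G").replace("X", "G")]
        out = annotation_filter(kmers, proteins, 9)
        assert [k.kmer for k in out] == ["QQQQQQQQQ"]

    def test_empty_annotation_identity(self):
        kmers = [krec("MKTAYIAKQ")]
        assert annotation_filter(kmers, [], 9) == kmers


class TestBackgroundFilter:
    def _expr(self, rows):
        return pd.DataFrame(rows, columns=["b1", "b2", "b3"])

    def test_single_read_removed_at_u1(self):
        expr = self._expr({"AAA": [1.0, 0.0, 0.0]}).T
        expr = pd.DataFrame({"b1": [1.0], "b2": [0.0], "b3": [0.0]},
                            index=["AAAAAAAAA"])
        out = background_filter([krec("AAAAAAAAA")], expr, FilterConfig(u=1))
        assert out == []

    def test_kept_when_u2_and_r_disabled(self):
        expr = pd.DataFrame({"b1": [1.0], "b2": [0.0], "b3": [0.0]},
                            index=["AAAAAAAAA"])
        out = background_filter([krec("AAAAAAAAA")], expr,
                                FilterConfig(u=2, R=None))
        assert len(out) == 1

    def test_read_threshold_removes(self):
        expr = pd.DataFrame({"b1": [6.0], "b2": [0.0], "b3": [0.0]},
                            index=["AAAAAAAAA"])
        out = background_filter([krec("AAAAAAAAA")], expr,
                                FilterConfig(u=3, R=5.0))
        assert out == []

    def test_absent_kmer_kept(self):
        expr = pd.DataFrame(columns=["b1"], dtype=float)
        out = background_filter([krec("AAAAAAAAA")], expr, FilterConfig(u=1))
        assert len(out) == 1

    def test_commutes_with_annotation_filter(self):
        kmers = [krec("MKTAYIAKQ"), krec("AAAAAAAAA"), krec("QQQQQQQQQ")]
        proteins = ["GGMKTAYIAKQGG"]
        expr = pd.DataFrame({"b1": [2.0]}, index=["AAAAAAAAA"])
        cfg = FilterConfig(u=1)
        one = background_filter(annotation_filter(kmers, proteins, 9), expr, cfg)
        two = annotation_filter(background_filter(kmers, expr, cfg), proteins, 9)
        assert [k.kmer for k in one] == [k.kmer for k in two] == ["QQQQQQQQQ"]


class TestCancerSupport:
    def test_kept_with_cohort_support(self):
        expr = pd.DataFrame({"target": [3.0], "s1": [25.0], "s2": [0.0]},
                            index=["AAAAAAAAA"])
        out = cancer_support_filter([krec("AAAAAAAAA")], expr, "target",
                                    FilterConfig(T=20.0, l=1, t=1.0))
        assert len(out) == 1

    def test_removed_when_target_unexpressed(self):
        expr = pd.DataFrame({"target": [0.0], "s1": [99.0]},
                            index=["AAAAAAAAA"])
        out = cancer_support_filter([krec("AAAAAAAAA")], expr, "target",
                                    FilterConfig(t=1.0, l=0))
        assert out == []

    def test_l_zero_only_target_threshold_applies(self):
        expr = pd.DataFrame({"target": [2.0], "s1": [0.0]},
                            index=["AAAAAAAAA"])
        out = cancer_support_filter([krec("AAAAAAAAA")], expr, "target",
                                    FilterConfig(T=1e9, l=0, t=1.0))
        assert len(out) == 1

    def test_whitelist_restricts_recurrence(self):
        expr = pd.DataFrame({"target": [5.0], "s1": [30.0], "s2": [30.0]},
                            index=["AAAAAAAAA"])
        cfg = FilterConfig(T=20.0, l=2, t=1.0,
                           sample_whitelist=frozenset({"s1"}))
        out = cancer_support_filter([krec("AAAAAAAAA")], expr, "target", cfg)
        assert out == []

    def test_missing_target_errors(self):
        expr = pd.DataFrame({"s1": [1.0]}, index=["AAAAAAAAA"])
        with pytest.raises(ValueError, match="target"):
            cancer_support_filter([], expr, "nope", FilterConfig())


class TestForegroundRule:
    def _run(self, target, cohort_max):
        expr = pd.DataFrame({"target": [target], "s1": [cohort_max]},
                            index=["AAAAAAAAA"])
        factors = pd.Series({"target": 1.0, "s1": 1.0})
        return foreground_default_rule([krec("AAAAAAAAA")], expr, "target",
                                       factors)

    def test_cohort_rescues_unexpressed_target(self):
        assert len(self._run(0.0, 21.0)) == 1

    def test_single_target_read_suffices(self):
        assert len(self._run(1.0, 0.0)) == 1

    def test_below_normalized_threshold_removed(self):
        assert self._run(0.0, 19.9) == []


class TestStrategies:
    def _bg(self, counts):
        return ExpressionTable(
            ["b1", "b2"],
            junction_counts={("c", 10, 50): np.array(counts)},
            segment_counts={})

    def test_requant_keeps_unread_junction(self):
        out = requant_filter([krec("AAAAAAAAA")], self._bg([0.0, 0.0]))
        assert len(out) == 1

    def test_requant_removes_read_junction(self):
        out = requant_filter([krec("AAAAAAAAA")], self._bg([2.0, 0.0]))
        assert out == []

    def test_requant_is_frame_blind(self):
        novel_frame = krec("AAAAAAAAA", frame_annotated=False)
        assert requant_filter([novel_frame], self._bg([2.0, 0.0])) == []

    def test_requant_germline_sequence_exclusion(self):
        germ = krec("AAAAAAAAA", variant_mode="germline")
        out = requant_filter([germ], self._bg([0.0, 0.0]),
                             background_kmer_strings=frozenset({"AAAAAAAAA"}))
        assert out == []

    def test_allframes_sequence_membership(self):
        kept = allframes_filter([krec("AAAAAAAAA"), krec("QQQQQQQQQ")],
                                frozenset({"AAAAAAAAA"}))
        assert [k.kmer for k in kept] == ["QQQQQQQQQ"]

    def test_negative_control_selector(self):
        kmers = [krec("AAAAAAAAA", frame_annotated=True),
                 krec("QQQQQQQQQ", frame_annotated=False)]
        assert [k.kmer for k in novel_frame_only(kmers)] == ["QQQQQQQQQ"]


class TestMhc:
    TABLE = pd.DataFrame({
        "kmer": ["AAAAAAAAA", "AAAAAAAAA", "QQQQQQQQQ", "WWWWWWWWW"],
        "allele": ["A*02:01", "B*07:02", "A*02:01", "A*02:01"],
        "rank_percent": [1.5, 8.0, 2.0, 9.0],
    })

    def test_rank_below_threshold_kept(self):
        out = apply_mhc_threshold([krec("AAAAAAAAA")], self.TABLE,
                                  FilterConfig(mhc_rank_threshold=2.0))
        assert len(out) == 1

    def test_boundary_inclusive(self):
        out = apply_mhc_threshold([krec("QQQQQQQQQ")], self.TABLE,
                                  FilterConfig(mhc_rank_threshold=2.0))
        assert len(out) == 1

    def test_no_allele_under_threshold_removed(self):
        out = apply_mhc_threshold([krec("WWWWWWWWW")], self.TABLE,
                                  FilterConfig(mhc_rank_threshold=2.0))
        assert out == []

    def test_unscored_kept_or_dropped_per_config(self):
        kmers = [krec("MISSINGKM")]
        assert apply_mhc_threshold(
            kmers, self.TABLE, FilterConfig(keep_unscored=True)) == kmers
        assert apply_mhc_threshold(
            kmers, self.TABLE, FilterConfig(keep_unscored=False)) == []


class TestNormalization:
    def test_median_sample_gets_factor_one(self):
        sizes = pd.Series({"a": 100.0, "b": 200.0, "c": 400.0})
        factors = normalization_factors(sizes)
        assert factors["b"] == 1.0
        assert factors["a"] == 0.5 and factors["c"] == 2.0

    def test_normalized_thresholding(self):
        expr = pd.DataFrame({"target": [2.0], "s1": [10.0]},
                            index=["AAAAAAAAA"])
        factors = pd.Series({"target": 1.0, "s1": 3.0})
        cfg = FilterConfig(T=25.0, l=1, t=1.0, normalize=True)
        out = cancer_support_filter([krec("AAAAAAAAA")], expr, "target", cfg,
                                    factors)
        assert len(out) == 1  # 10 * 3 = 30 >= 25


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(5)
    kmers = [krec(f"K{i:08d}") for i in range(60)]
    fg = pd.DataFrame(rng.integers(0, 30, size=(60, 4)).astype(float),
                      index=[k.kmer for k in kmers],
                      columns=["target", "s1", "s2", "s3"])
    bg = pd.DataFrame(rng.integers(0, 3, size=(60, 5)).astype(float),
                      index=[k.kmer for k in kmers],
                      columns=[f"b{i}" for i in range(5)])
    return kmers, fg, bg


class TestMonotonicity:
    def test_counts_monotone_in_each_parameter(self, cohort):
        kmers, fg, bg = cohort

        def n_cancer(**kw):
            return len(cancer_support_filter(
                kmers, fg, "target", FilterConfig(**kw)))

        def n_bg(**kw):
            return len(background_filter(kmers, bg, FilterConfig(**kw)))

        for grid, key, direction in [
            ([0.0, 5.0, 10.0, 20.0], "T", -1),
            ([0, 1, 2, 3], "l", -1),
            ([0.0, 1.0, 5.0, 15.0], "t", -1),
        ]:
            base = {"T": 5.0, "l": 1, "t": 1.0}
            counts = []
            for value in grid:
                base[key] = value
                counts.append(n_cancer(**base))
            deltas = np.diff(counts) * direction
            assert (deltas >= 0).all(), (key, counts)

        u_counts = [n_bg(u=value) for value in [1, 2, 3, 4]]
        assert (np.diff(u_counts) >= 0).all(), u_counts
        # u set above the cohort size so only the read-level clause acts
        r_counts = [n_bg(u=6, R=value) for value in [1.0, 2.0, 3.0]]
        assert (np.diff(r_counts) >= 0).all(), r_counts
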