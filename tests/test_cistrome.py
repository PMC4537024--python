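import numpy as np
import pandas as pd
import pytest

from tamdereg.cistrome import (
    ConsensusPeak,
    assign_genes,
    filter_peaks,
    intersect_with_targets,
    reproducible_peaks,
)
from tamdereg.types import GeneAnnotation, GeneClassificationReport, Peak


def mk_peak(chrom="chr1", start=100, end=200, sample="S1", tags=100, igg=0, lib=10**6, igg_lib=10**6):
    return Peak(chrom, start, end, sample, tags, igg, lib, igg_lib)


class TestFilterPeaks:
    def test_tag_boundary_inclusive_with_igg_pseudocount(self):
        # 30 tags, zero IgG, equal libsizes: FC = 30 / 1 = 30
        assert filter_peaks([mk_peak(tags=30, igg=0)]) == [mk_peak(tags=30, igg=0)]

    def test_tag_count_below_threshold_dropped_despite_high_fc(self):
        assert filter_peaks([mk_peak(tags=29, igg=0)]) == []

    def test_fold_change_uses_normalized_counts(self):
        # 100 vs IgG 99 (+1 pseudocount) at equal libsizes: FC exactly 1.0 < 2
        assert filter_peaks([mk_peak(tags=100, igg=99)]) == []
        # halving the IgG libsize doubles the normalized control level
        assert filter_peaks([mk_peak(tags=100, igg=24, igg_lib=2 * 10**6)]) == [
            mk_peak(tags=100, igg=24, igg_lib=2 * 10**6)
        ]


class TestReproduciblePeaks:
    def test_overlapping_peaks_merge_to_union_span(self):
        by_sample = {
            "S1": [mk_peak(start=100, end=200, sample="S1")],
            "S2": [mk_peak(start=150, end=250, sample="S2")],
            "S3": [],
        }
        [c] = reproducible_peaks(by_sample, min_samples=2)
        assert (c.start, c.end) == (100, 250)
        assert c.supporting_samples == {"S1", "S2"}

    def test_single_sample_support_dropped(self):
        by_sample = {"S1": [mk_peak()], "S2": [], "S3": []}
        assert reproducible_peaks(by_sample, min_samples=2) == []

    def test_adjacent_half_open_intervals_do_not_merge(self):
        by_sample = {
            "S1": [mk_peak(start=100, end=200, sample="S1")],
            "S2": [mk_peak(start=200, end=300, sample="S2")],
        }
        assert reproducible_peaks(by_sample, min_samples=2) == []

    def test_merge_is_order_independent(self):
        rng = np.random.default_rng(5)
        peaks = [
            mk_peak(start=int(s), end=int(s) + 150, sample=f"S{i % 3 + 1}")
            for i, s in enumerate(rng.integers(0, 5000, size=60))
        ]
        def consensus_of(order):
            by_sample = {"S1": [], "S2": [], "S3": []}
            for p in order:
                by_sample[p.sample_id].append(p)
            return [
                (c.chrom, c.start, c.end, frozenset(c.supporting_samples))
                for c in reproducible_peaks(by_sample, min_samples=2)
            ]
        base = consensus_of(peaks)
        for seed in range(3):
            rng2 = np.random.default_rng(seed)
            shuffled = [peaks[i] for i in rng2.permutation(len(peaks))]
            assert consensus_of(shuffled) == base

    def test_min_samples_above_sample_count_is_error(self):
        with pytest.raises(ValueError):
            reproducible_peaks({"S1": []}, min_samples=2)


class TestAssignGenes:
    def _ann(self, tss, chrom="chr1", gene="G1"):
        return [GeneAnnotation(gene, gene, chrom, "+", tss)]

    def _cons(self, start, end, chrom="chr1"):
        return [ConsensusPeak(chrom, start, end, {"S1", "S2"}, [])]

    def test_within_window_inclusive(self):
        out = assign_genes(self._cons(140000, 140500), self._ann(100000))
        assert bool(out.loc["G1", "peak_associated"])
        assert out.loc["G1", "nearest_peak_distance"] == 40000

    def test_beyond_window_exclusive(self):
        out = assign_genes(self._cons(150001, 150100), self._ann(100000))
        assert not bool(out.loc["G1", "peak_associated"])
        assert out.loc["G1", "nearest_peak_distance"] == 50001

    def test_tss_inside_peak_distance_zero(self):
        out = assign_genes(self._cons(99000, 101000), self._ann(100000))
        assert out.loc["G1", "nearest_peak_distance"] == 0

    def test_window_monotonicity(self):
        rng = np.random.default_rng(1)
        cons = [
            ConsensusPeak("chr1", int(s), int(s) + 400, {"a", "b"}, [])
            for s in rng.integers(0, 10**7, size=50)
        ]
        ann = [
            GeneAnnotation(f"G{i}", f"G{i}", "chr1", "+", int(t))
            for i, t in enumerate(rng.integers(0, 10**7, size=200))
        ]
        small = assign_genes(cons, ann, window_bp=20000)["peak_associated"]
        large = assign_genes(cons, ann, window_bp=80000)["peak_associated"]
        assert (large | ~small).all()  # small => large

    def test_matches_brute_force_scan(self):
        """Sorted-array assignment equals the all-pairs distance oracle."""
        rng = np.random.default_rng(42)
        cons = [
            ConsensusPeak(f"chr{int(c)}", int(s), int(s) + int(w), {"a", "b"}, [])
            for c, s, w in zip(
                rng.integers(1, 4, 120), rng.integers(0, 5 * 10**6, 120), rng.integers(100, 2000, 120)
            )
        ]
        ann = [
            GeneAnnotation(f"G{i}", f"G{i}", f"chr{int(c)}", "+", int(t))
            for i, (c, t) in enumerate(
                zip(rng.integers(1, 5, 300), rng.integers(0, 5 * 10**6, 300))
            )
        ]
        out = assign_genes(cons, ann, window_bp=50000)
        for g in ann:
            dists = [
                0
                if p.start <= g.tss < p.end
                else min(abs(g.tss - p.start), abs(g.tss - (p.end - 1)))
                for p in cons
                if p.chrom == g.chrom
            ]
            expected = bool(dists and min(dists) <= 50000)
            assert bool(out.loc[g.gene_id, "peak_associated"]) == expected


class TestIntersections:
    def test_set_arithmetic(self):
        table = pd.DataFrame(
            {
                "agonist_up_mdm": [True, True, True, False],
                "ligand_regulated": [True, True, True, False],
                "peak_associated_mdm": [True, True, False, True],
                "peak_associated_tam": [False, True, False, False],
            },
            index=["G1", "G2", "G3", "G4"],
        )
        counts = intersect_with_targets(GeneClassificationReport(table=table))
        assert counts["ligand_regulated"] == 3
        assert counts["ligand_regulated&peak_associated_mdm"] == 2
        assert counts["ligand_regulated&peak_associated_tam"] == 1
        assert counts["ligand_regulated&peak_any"] == 2

    def test_planted_peaks_make_targets_equal_intersection(self, default_sim):
        """When peaks are planted at target genes only, the target set and
        the target-with-peak set coincide on the has_peak subset."""
        design, study, truth, annotation, peaks = default_sim
        from tamdereg.cistrome import filter_peaks, reproducible_peaks

        filtered = {s: filter_peaks(ps) for s, ps in peaks.items()}
        cons = reproducible_peaks(filtered, min_samples=2)
        out = assign_genes(cons, annotation)
        flagged = set(out.index[out["peak_associated"]])
        planted = set(truth.index[truth["has_peak"]])
        assert flagged <= planted  # decoys are sample-unique: none survive
        assert len(flagged & planted) / len(planted) >= 0.95
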