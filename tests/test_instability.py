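"""WGII in both dialects against a per-base brute-force oracle, plus burden
categories."""

import numpy as np
import pytest

from enzfam.io import Segment, SegmentProfile
from enzfam.instability import cna_burden, wgii, wgii_allele_specific, wgii_logr


def brute_force_wgii(profile, low=-0.2, high=0.2):
    """Independent oracle: mark every base aberrant or not, average the
    per-chromosome aberrant fractions."""
    if profile.dialect == "logr":
        total = sum(s.length for s in profile.segments)
        center = sum(s.value * s.length for s in profile.segments) / total
    fractions = []
    for chrom, clen in sorted(profile.chrom_lengths.items()):
        segs = profile.chrom_segments(chrom)
        if not segs:
            continue
        base = np.zeros(clen, dtype=bool)
        for s in segs:
            if profile.dialect == "allele_specific":
                aberrant = int(s.value) != int(np.floor(profile.ploidy + 0.5))
            else:
                c = s.value - center
                aberrant = c < low or c > high
            if aberrant:
                base[s.start:s.end] = True
        fractions.append(base.mean())
    return float(np.mean(fractions)) if fractions else float("nan")


def random_profile(rng, dialect):
    chrom_lengths = {f"chr{i}": int(rng.integers(5_000, 20_000)) for i in range(1, 4)}
    segments = []
    for chrom, clen in chrom_lengths.items():
        cuts = np.unique(rng.integers(1, clen, size=rng.integers(1, 6)))
        bounds = [0, *cuts.tolist(), clen]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if dialect == "allele_specific":
                value = float(rng.integers(0, 5))
            else:
                value = float(rng.normal(0, 0.4))
            segments.append(Segment(chrom, a, b, value))
    return SegmentProfile(
        "S", dialect, segments,
        ploidy=2.0 if dialect == "allele_specific" else None,
        chrom_lengths=chrom_lengths,
    )


class TestAlleleSpecific:
    def test_all_at_ploidy_is_zero(self):
        prof = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 1000, 2), Segment("chr2", 0, 500, 2)],
            ploidy=2.0, chrom_lengths={"chr1": 1000, "chr2": 500},
        )
        assert wgii_allele_specific(prof).wgii == 0.0

    def test_unweighted_chromosome_mean_hand_value(self):
        # chr1 100 kb with 50 kb aberrant (0.5), chr2 200 kb with 40 kb (0.2)
        prof = SegmentProfile(
            "S", "allele_specific",
            [
                Segment("chr1", 0, 50_000, 3), Segment("chr1", 50_000, 100_000, 2),
                Segment("chr2", 0, 40_000, 1), Segment("chr2", 40_000, 200_000, 2),
            ],
            ploidy=2.0, chrom_lengths={"chr1": 100_000, "chr2": 200_000},
        )
        res = wgii_allele_specific(prof)
        assert res.per_chrom_fraction == {"chr1": 0.5, "chr2": 0.2}
        assert res.wgii == pytest.approx(0.35)

    def test_whole_genome_aberrant_is_one(self):
        prof = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 1000, 1), Segment("chr2", 0, 500, 4)],
            ploidy=2.0, chrom_lengths={"chr1": 1000, "chr2": 500},
        )
        assert wgii_allele_specific(prof).wgii == 1.0

    def test_unsegmented_chromosome_excluded_from_mean(self):
        prof = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 1000, 1)],
            ploidy=2.0, chrom_lengths={"chr1": 1000, "chr2": 500},
        )
        res = wgii_allele_specific(prof)
        assert res.wgii == 1.0
        assert res.excluded_chroms == ["chr2"]


class TestLogr:
    def test_constant_logr_any_level_is_zero(self):
        for level in (-0.7, 0.0, 1.3):
            prof = SegmentProfile(
                "S", "logr",
                [Segment("chr1", 0, 600, level), Segment("chr1", 600, 1000, level)],
                chrom_lengths={"chr1": 1000},
            )
            assert wgii_logr(prof).wgii == 0.0

    def test_half_genome_above_center_hand_value(self):
        # center = 0.15; deviations are ±0.15... need |dev| > 0.2: use 0.3 shift
        prof = SegmentProfile(
            "S", "logr",
            [Segment("chr1", 0, 500, 0.0), Segment("chr1", 500, 1000, 0.6)],
            chrom_lengths={"chr1": 1000},
        )
        # center = 0.3; centered = ∓0.3 → both halves aberrant? no: ±0.3 both
        # outside ±0.2 → wgii 1.0.  Use asymmetric lengths instead.
        prof = SegmentProfile(
            "S", "logr",
            [Segment("chr1", 0, 500, 0.3), Segment("chr1", 500, 1000, 0.0),
             Segment("chr2", 0, 1000, 0.0)],
            chrom_lengths={"chr1": 1000, "chr2": 1000},
        )
        # center = 0.075; centered chr1a = 0.225 (>0.2, aberrant), others -0.075
        res = wgii_logr(prof)
        assert res.per_chrom_fraction["chr1"] == pytest.approx(0.5)
        assert res.per_chrom_fraction["chr2"] == 0.0
        assert res.wgii == pytest.approx(0.25)

    def test_boundary_exactly_at_window_edge_not_aberrant(self):
        prof = SegmentProfile(
            "S", "logr",
            [Segment("chr1", 0, 900, 0.0), Segment("chr1", 900, 1000, 1.8)],
            chrom_lengths={"chr1": 1000},
        )
        # center = 0.18; seg2 centered = 1.62 aberrant; seg1 centered −0.18 not
        res = wgii_logr(prof)
        assert res.per_chrom_fraction["chr1"] == pytest.approx(0.1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("dialect", ["allele_specific", "logr"])
    def test_matches_per_base_oracle(self, dialect):
        rng = np.random.default_rng(99)
        for _ in range(100):
            prof = random_profile(rng, dialect)
            assert wgii(prof).wgii == pytest.approx(brute_force_wgii(prof), abs=1e-12)

    def test_invariant_under_segment_splitting(self):
        prof = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 600, 3), Segment("chr1", 600, 1000, 2)],
            ploidy=2.0, chrom_lengths={"chr1": 1000},
        )
        split = SegmentProfile(
            "S", "allele_specific",
            [
                Segment("chr1", 0, 200, 3), Segment("chr1", 200, 600, 3),
                Segment("chr1", 600, 800, 2), Segment("chr1", 800, 1000, 2),
            ],
            ploidy=2.0, chrom_lengths={"chr1": 1000},
        )
        assert wgii(prof).wgii == wgii(split).wgii

    def test_monotone_in_added_aberration(self):
        base = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 500, 3), Segment("chr1", 500, 1000, 2)],
            ploidy=2.0, chrom_lengths={"chr1": 1000},
        )
        more = SegmentProfile(
            "S", "allele_specific",
            [Segment("chr1", 0, 500, 3), Segment("chr1", 500, 700, 1),
             Segment("chr1", 700, 1000, 2)],
            ploidy=2.0, chrom_lengths={"chr1": 1000},
        )
        assert wgii(more).wgii >= wgii(base).wgii


class TestCnaBurden:
    def _prof(self, segs):
        return SegmentProfile(
            "S", "allele_specific", segs, ploidy=2.0, chrom_lengths={"chr1": 10_000}
        )

    def test_no_aberration(self):
        prof = self._prof([Segment("chr1", 0, 10_000, 2)])
        assert cna_burden(prof) == (0, "0")

    def test_three_disjoint_runs(self):
        prof = self._prof(
            [
                Segment("chr1", 0, 1000, 1), Segment("chr1", 1000, 2000, 2),
                Segment("chr1", 2000, 3000, 3), Segment("chr1", 3000, 4000, 2),
                Segment("chr1", 4000, 5000, 1), Segment("chr1", 5000, 10_000, 2),
            ]
        )
        assert cna_burden(prof) == (3, "≥3")

    def test_abutting_aberrant_segments_merge_into_one_run(self):
        prof = self._prof(
            [
                Segment("chr1", 0, 1000, 1), Segment("chr1", 1000, 2000, 3),
                Segment("chr1", 2000, 10_000, 2),
            ]
        )
        assert cna_burden(prof) == (1, "≥1")
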