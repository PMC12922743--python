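"""Weighted genome instability index (WGII) and copy-number-alteration burden.

WGII is the per-chromosome fraction of aberrant genome averaged (unweighted)
across chromosomes, which keeps large chromosomes from dominating the score.
Two dialects are supported:

* ``allele_specific`` — a segment is aberrant when its integer total copy
  number differs from the sample's rounded ploidy.
* ``logr`` — segments are centered on the length-weighted genome mean logR
  and called aberrant when the centered value falls strictly outside
  [−0.2, 0.2].

Unsegmented gaps count as non-aberrant (the denominator is the chromosome
length); chromosomes with no segmented base are excluded from the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import SegmentProfile
from .status import round_half_up

logger = logging.getLogger(__name__)


@dataclass
class WgiiResult:
    sample_id: str
    wgii: float
    per_chrom_fraction: dict[str, float]
    dialect: str
    excluded_chroms: list[str] = field(default_factory=list)


def _aberrant_intervals(
    profile: SegmentProfile, low: float = -0.2, high: float = 0.2
) -> dict[str, list[tuple[int, int]]]:
    """Chrom → aberrant [start, end) intervals under the profile's dialect."""
    out: dict[str, list[tuple[int, int]]] = {c: [] for c in profile.chrom_lengths}
    if profile.dialect == "allele_specific":
        base = round_half_up(profile.ploidy)
        for seg in profile.segments:
            if int(seg.value) != base:
                out.setdefault(seg.chrom, []).append((seg.start, seg.end))
    else:
        total_len = sum(s.length for s in profile.segments)
        if total_len == 0:
            return out
        center = sum(s.value * s.length for s in profile.segments) / total_len
        for seg in profile.segments:
            centered = seg.value - center
            if centered < low or centered > high:  # strictly outside the window
                out.setdefault(seg.chrom, []).append((seg.start, seg.end))
    return out


def _wgii_from_intervals(
    profile: SegmentProfile, aberrant: dict[str, list[tuple[int, int]]]
) -> WgiiResult:
    fractions: dict[str, float] = {}
    excluded: list[str] = []
    segmented: dict[str, int] = {}
    for seg in profile.segments:
        segmented[seg.chrom] = segmented.get(seg.chrom, 0) + seg.length
    for chrom, clen in sorted(profile.chrom_lengths.items()):
        if segmented.get(chrom, 0) == 0:
            excluded.append(chrom)
            logger.debug(
                "sample %s: %s has no segmented bp, excluded from WGII",
                profile.sample_id, chrom,
            )
            continue
        ab = sum(e - s for s, e in aberrant.get(chrom, ()))
        fractions[chrom] = ab / clen
    wgii = sum(fractions.values()) / len(fractions) if fractions else float("nan")
    return WgiiResult(profile.sample_id, wgii, fractions, profile.dialect, excluded)


def wgii_allele_specific(profile: SegmentProfile) -> WgiiResult:
    """WGII with aberrance defined as total copy number ≠ rounded ploidy."""
    if profile.dialect != "allele_specific":
        raise ValueError("profile must carry the allele_specific dialect")
    return _wgii_from_intervals(profile, _aberrant_intervals(profile))


def wgii_logr(profile: SegmentProfile, low: float = -0.2, high: float = 0.2) -> WgiiResult:
    """WGII with aberrance defined against the genome-mean logR window."""
    if profile.dialect != "logr":
        raise ValueError("profile must carry the logr dialect")
    return _wgii_from_intervals(profile, _aberrant_intervals(profile, low, high))


def wgii(profile: SegmentProfile) -> WgiiResult:
    """Dialect-dispatching WGII."""
    if profile.dialect == "allele_specific":
        return wgii_allele_specific(profile)
    return wgii_logr(profile)


def cna_burden(profile: SegmentProfile) -> tuple[int, str]:
    """Number of copy-number alterations and its nested burden category.

    An alteration is a maximal run of contiguous (abutting) aberrant segments
    on one chromosome; abutting aberrant segments with different values merge
    into one alteration, a non-aberrant segment or gap breaks the run.
    Categories: "0", "≥1", "≥2", "≥3".
    """
    aberrant = _aberrant_intervals(profile)
    n = 0
    for chrom, intervals in aberrant.items():
        intervals = sorted(intervals)
        prev_end = None
        for s, e in intervals:
            if prev_end is None or s > prev_end:
                n += 1
            prev_end = e
    category = "0" if n == 0 else ("≥1" if n == 1 else ("≥2" if n == 2 else "≥3"))
    return n, category
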