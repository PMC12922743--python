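"""Seeded synthetic-cohort generators with planted effects.

Each generator is a pure function of its spec: the master seed is combined
with a per-generator stream name, so identical specs always produce identical
output and adding a new generator never perturbs the existing streams.

The generators emulate the statistical structure of the real inputs the
pipeline was designed for — per-gene mutation counts over a length-
heterogeneous gene universe with an optionally enriched enzyme family,
copy-number profiles with a planted aberrant-genome fraction, driver-evidence
tables with planted hemizygous-essential genes, and arrayed-screen plates
with planted effect genes — not their sequence content.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ENZYME_FAMILIES,
    GeneModel,
    IndelRecord,
    MutationEvent,
    Segment,
    SegmentProfile,
    StructuralVariant,
)

#: Class mix for deleterious events; the recurrence rule uses the class set,
#: not the mix, so these weights only shape per-class tallies.
DELETERIOUS_CLASS_WEIGHTS = {
    "missense": 0.7,
    "nonsense": 0.1,
    "splice_site": 0.1,
    "frameshift_del": 0.1,
}

CONTROL_LABEL = "NEG_CTRL"


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named RNG stream: one independent stream per generator."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class CohortSpec:
    """Study conditions for one synthetic mutation cohort.

    Defaults mirror a mid-sized tumor cohort: ~1000 genes spanning the 11
    enzyme families plus a non-enzyme remainder, median gene size 20 kb with
    log-normal spread, and a baseline deleterious rate of 1e-7 per bp per
    patient.  At 200 patients a median gene then accumulates ~0.4 expected
    deleterious events cohort-wide, so roughly 5-10% of background genes are
    recurrently mutated (>=2 patients) - the regime the recurrence statistic
    is designed for, where a planted rate multiplier shifts the recurrent
    fraction without saturating it.
    """

    n_genes: int = 1000
    n_patients: int = 200
    family_proportions: dict[str, float] = field(
        default_factory=lambda: {f: 0.06 for f in ENZYME_FAMILIES}
    )
    median_bp: float = 20_000.0
    sigma: float = 0.6
    baseline_mut_rate: float = 1e-7
    planted_family: str | None = None
    rate_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.family_proportions.values())
        if total > 1.0 + 1e-9:
            raise ValueError(f"family proportions sum to {total} > 1")
        if self.rate_multiplier < 1.0:
            raise ValueError("rate_multiplier must be >= 1")
        for fam in self.family_proportions:
            if fam not in ENZYME_FAMILIES:
                raise ValueError(f"unknown family {fam!r}")


@dataclass
class InstabilitySpec:
    """Conditions for synthetic copy-number profiles with a target WGII."""

    n_samples: int = 20
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_000_000 for i in range(1, 11)}
    )
    target_wgii: float = 0.0
    dialect: str = "allele_specific"
    ploidy: float = 2.0
    max_runs_per_chrom: int = 2
    wgii_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_wgii <= 1.0:
            raise ValueError("target_wgii must be in [0, 1]")


@dataclass
class DriverTableSpec:
    """Planted truth for the hemizygous-driver classifier."""

    n_genes: int = 200
    planted_hemizygous: list[str] = field(default_factory=list)
    planted_biallelic_tsg: list[str] = field(default_factory=list)
    dependency_noise_sd: float = 0.15
    cohort_n: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.planted_hemizygous) & set(self.planted_biallelic_tsg)
        if overlap:
            raise ValueError(f"planted sets overlap: {sorted(overlap)}")


def simulate_gene_universe(spec: CohortSpec) -> list[GeneModel]:
    """Draw a gene universe with log-normal lengths and family labels.

    Genes are laid out consecutively (1-kb gaps) round-robin over 23
    chromosomes; the coordinates only matter for overlap-based rules.
    """
    rng = stream_rng(spec.seed, "gene_universe")
    lengths = np.maximum(
        (spec.median_bp * np.exp(spec.sigma * rng.standard_normal(spec.n_genes))).astype(int),
        300,
    )
    fams = list(spec.family_proportions)
    probs = [spec.family_proportions[f] for f in fams]
    probs.append(max(0.0, 1.0 - sum(probs)))
    labels = rng.choice(len(fams) + 1, size=spec.n_genes, p=np.asarray(probs) / sum(probs))
    n_chroms = 23
    cursor = {f"chr{i}": 0 for i in range(1, n_chroms + 1)}
    genes = []
    for i in range(spec.n_genes):
        chrom = f"chr{(i % n_chroms) + 1}"
        start = cursor[chrom]
        end = start + int(lengths[i])
        cursor[chrom] = end + 1000
        fam = fams[labels[i]] if labels[i] < len(fams) else None
        genes.append(
            GeneModel(
                gene_id=f"G{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                enzyme_family=fam,
                enzyme_class="hydrolases" if fam is not None else None,
            )
        )
    return genes


def simulate_mutations(universe: list[GeneModel], spec: CohortSpec) -> list[MutationEvent]:
    """Poisson mutation counts per patient×gene with an optional planted family.

    Per patient and gene the deleterious event count is
    ``Poisson(length_bp × baseline_mut_rate × multiplier)`` where the
    multiplier applies only to genes of the planted family.
    """
    if spec.baseline_mut_rate <= 0:
        raise ValueError("baseline_mut_rate must be > 0")
    rng = stream_rng(spec.seed, "mutations")
    lengths = np.array([g.length_bp for g in universe], dtype=float)
    mult = np.ones(len(universe))
    if spec.planted_family is not None:
        planted = np.array([g.enzyme_family == spec.planted_family for g in universe])
        mult[planted] = spec.rate_multiplier
    lam = lengths * spec.baseline_mut_rate * mult
    counts = rng.poisson(lam[None, :].repeat(spec.n_patients, axis=0))
    classes = list(DELETERIOUS_CLASS_WEIGHTS)
    weights = np.array(list(DELETERIOUS_CLASS_WEIGHTS.values()))
    events: list[MutationEvent] = []
    pat_idx, gene_idx = np.nonzero(counts)
    reps = counts[pat_idx, gene_idx]
    pat_idx = np.repeat(pat_idx, reps)
    gene_idx = np.repeat(gene_idx, reps)
    cls_idx = rng.choice(len(classes), size=len(pat_idx), p=weights / weights.sum())
    for p, g, c in zip(pat_idx, gene_idx, cls_idx):
        events.append(
            MutationEvent(
                sample_id=f"P{p:04d}",
                gene_id=universe[g].gene_id,
                variant_class=classes[c],
            )
        )
    return events


def simulate_segments(spec: InstabilitySpec) -> list[SegmentProfile]:
    """Profiles whose realized WGII lies within ±0.05 of ``target_wgii``.

    Per chromosome an aberrant fraction is drawn near the target (clipped
    normal jitter) and placed as 1..``max_runs_per_chrom`` disjoint runs; the
    rest of the chromosome sits at ploidy (allele_specific) or at logR 0
    (logr).  Aberrant runs get copy number ploidy±1 or logR ±0.5 with random
    sign, so the logr dialect's genome-mean centering stays near zero.
    """
    rng = stream_rng(spec.seed, "segments")
    base_cn = int(np.floor(spec.ploidy + 0.5))
    profiles = []
    for s in range(spec.n_samples):
        segments: list[Segment] = []
        for chrom, clen in spec.chrom_lengths.items():
            frac = spec.target_wgii
            if 0.0 < frac < 1.0 and spec.wgii_jitter > 0:
                frac = float(np.clip(frac + spec.wgii_jitter * rng.standard_normal(), 0.0, 1.0))
            ab_total = int(round(frac * clen))
            if ab_total <= 0:
                segments.append(_normal_segment(spec, chrom, 0, clen))
                continue
            if ab_total >= clen:
                segments.append(_aberrant_segment(spec, rng, base_cn, chrom, 0, clen))
                continue
            n_runs = int(rng.integers(1, spec.max_runs_per_chrom + 1)) if ab_total > 1 else 1
            cuts = np.sort(rng.integers(1, ab_total, size=n_runs - 1)) if n_runs > 1 else np.array([], int)
            run_lens = np.diff(np.concatenate(([0], cuts, [ab_total])))
            run_lens = run_lens[run_lens > 0]
            # place runs into the normal backbone at sorted random offsets
            free = clen - ab_total
            offsets = np.sort(rng.integers(0, free + 1, size=len(run_lens)))
            pos = 0
            prev_off = 0
            for off, rl in zip(offsets, run_lens):
                gap = off - prev_off
                if gap > 0:
                    segments.append(_normal_segment(spec, chrom, pos, pos + gap))
                    pos += gap
                segments.append(_aberrant_segment(spec, rng, base_cn, chrom, pos, pos + int(rl)))
                pos += int(rl)
                prev_off = off
            if pos < clen:
                segments.append(_normal_segment(spec, chrom, pos, clen))
        segments = _merge_abutting(segments)
        profiles.append(
            SegmentProfile(
                sample_id=f"S{s:03d}",
                dialect=spec.dialect,
                segments=segments,
                ploidy=spec.ploidy if spec.dialect == "allele_specific" else None,
                purity=1.0 if spec.dialect == "allele_specific" else None,
                chrom_lengths=dict(spec.chrom_lengths),
            )
        )
    return profiles


def _normal_segment(spec: InstabilitySpec, chrom: str, start: int, end: int) -> Segment:
    value = float(int(np.floor(spec.ploidy + 0.5))) if spec.dialect == "allele_specific" else 0.0
    return Segment(chrom, start, end, value)


def _aberrant_segment(
    spec: InstabilitySpec, rng: np.random.Generator, base_cn: int, chrom: str, start: int, end: int
) -> Segment:
    sign = 1 if rng.random() < 0.5 else -1
    if spec.dialect == "allele_specific":
        value = float(max(0, base_cn + sign))
        if value == base_cn:  # ploidy 0 edge
            value = float(base_cn + 1)
    else:
        value = 0.5 * sign
    return Segment(chrom, start, end, value)


def _merge_abutting(segments: list[Segment]) -> list[Segment]:
    """Merge abutting equal-value segments so profiles stay minimal."""
    out: list[Segment] = []
    for seg in sorted(segments, key=lambda s: (s.chrom, s.start)):
        if out and out[-1].chrom == seg.chrom and out[-1].end == seg.start and out[-1].value == seg.value:
            out[-1] = Segment(seg.chrom, out[-1].start, seg.end, seg.value)
        else:
            out.append(seg)
    return out


def simulate_driver_tables(spec: DriverTableSpec) -> pd.DataFrame:
    """Evidence table with planted hemizygous-essential and biallelic TSG genes.

    Planted hemizygous genes: dependency below −1 (noise, clipped), ≥3 focal
    events at a rate above 0.1%, biallelic rate 0.  Planted biallelic TSGs:
    dependency above −1 and biallelic rate ≥1%.  Background genes satisfy
    neither pattern (non-essential, biallelic rate between the two cutoffs,
    sub-recurrent focal counts).
    """
    rng = stream_rng(spec.seed, "driver_tables")
    hemi, tsg = set(spec.planted_hemizygous), set(spec.planted_biallelic_tsg)
    min_focal_rate = 0.001
    rows = []
    for i in range(spec.n_genes):
        gid = f"G{i:05d}"
        noise = spec.dependency_noise_sd * rng.standard_normal()
        if gid in hemi:
            dep = min(-1.05, -1.5 + noise)
            focal = int(max(3, np.ceil(min_focal_rate * spec.cohort_n) + 1 + rng.poisson(3)))
            biallelic = 0.0
        elif gid in tsg:
            dep = max(-0.95, -0.3 + noise)
            focal = int(3 + rng.poisson(3))
            biallelic = float(0.01 + 0.02 * rng.random())
        else:
            dep = float(np.clip(-0.2 + 2 * noise, -0.95, 0.5))
            focal = int(rng.integers(0, 3))
            biallelic = float(0.002 + 0.006 * rng.random())
        rows.append((gid, dep, focal, spec.cohort_n, biallelic))
    return pd.DataFrame(
        rows, columns=["gene_id", "dependency_score", "focal_count", "cohort_n", "biallelic_rate"]
    )


def simulate_screen(
    n_genes: int = 96,
    n_hit_genes: int = 9,
    effect_shift: float = 0.0,
    cells_per_well: int = 200,
    n_replicates: int = 3,
    n_control_wells: int = 8,
    log_mu: float = 0.0,
    log_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format plate tables for an arrayed knockdown screen.

    One plate per biological replicate; three construct wells per gene
    (mirroring a three-siRNA/three-guide design) plus negative-control wells
    on every plate.  Per-cell intensities are log-normal; the first
    ``n_hit_genes`` genes get ``effect_shift`` added on the log scale
    (``log_sd`` units are the control-cell SD, so a shift of ``2 * log_sd``
    is a two-control-SD effect).
    """
    rng = stream_rng(seed, "screen")
    rows: list[tuple] = []
    hit_genes = {f"GENE{i:03d}" for i in range(n_hit_genes)}
    for rep in range(1, n_replicates + 1):
        plate = f"plate_R{rep}"
        well_no = 0
        for c in range(n_control_wells):
            well_no += 1
            vals = np.exp(log_mu + log_sd * rng.standard_normal(cells_per_well))
            rows.extend(
                (plate, f"W{well_no:03d}", CONTROL_LABEL, rep, float(v)) for v in vals
            )
        for i in range(n_genes):
            gene = f"GENE{i:03d}"
            shift = effect_shift if gene in hit_genes else 0.0
            for _ in range(3):
                well_no += 1
                vals = np.exp(log_mu + shift + log_sd * rng.standard_normal(cells_per_well))
                rows.extend(
                    (plate, f"W{well_no:03d}", gene, rep, float(v)) for v in vals
                )
    return pd.DataFrame(rows, columns=["plate", "well", "gene", "replicate", "intensity"])


def simulate_svs(
    sample_ids: list[str],
    n_svs_per_sample: int = 50,
    dup_size_log10_mean: float = 5.0,
    homology_mean_nt: float = 2.0,
    seed: int = 0,
    group_shift: dict[str, float] | None = None,
) -> list[StructuralVariant]:
    """SV catalogs with log-normal sizes and geometric homology lengths.

    ``group_shift`` maps sample id → shift (in log10 bp) applied to that
    sample's DUP sizes, used to plant genotype-group size-spectrum effects.
    """
    rng = stream_rng(seed, "svs")
    out: list[StructuralVariant] = []
    for sid in sample_ids:
        shift = (group_shift or {}).get(sid, 0.0)
        for _ in range(n_svs_per_sample):
            svtype = ["DEL", "DUP", "INV", "TRA"][int(rng.integers(0, 4))]
            mean = dup_size_log10_mean + (shift if svtype == "DUP" else 0.0)
            size = int(10 ** (mean + 0.5 * rng.standard_normal()))
            hom = int(rng.geometric(1.0 / (1.0 + homology_mean_nt)) - 1)
            chrom1 = f"chr{int(rng.integers(1, 23))}"
            pos1 = int(rng.integers(1_000, 10_000_000))
            if svtype == "TRA":
                chrom2 = f"chr{int(rng.integers(1, 23))}"
                while chrom2 == chrom1:
                    chrom2 = f"chr{int(rng.integers(1, 23))}"
                pos2 = int(rng.integers(1_000, 10_000_000))
            else:
                chrom2, pos2 = chrom1, pos1 + max(50, size)
            out.append(
                StructuralVariant(sid, svtype, chrom1, pos1, chrom2, pos2, min(hom, 1000))
            )
    return out


def simulate_indels(
    sample_ids: list[str],
    n_indels_per_sample: int = 100,
    p_long_deletion: float = 0.2,
    seed: int = 0,
    group_p_long: dict[str, float] | None = None,
) -> list[IndelRecord]:
    """Indel catalogs; ``group_p_long`` plants a per-sample excess of 5+ nt
    deletions (the NHEJ/HRD-linked class)."""
    rng = stream_rng(seed, "indels")
    out = []
    for sid in sample_ids:
        p_long = (group_p_long or {}).get(sid, p_long_deletion)
        for _ in range(n_indels_per_sample):
            kind = "deletion" if rng.random() < 0.6 else "insertion"
            if kind == "deletion" and rng.random() < p_long:
                length = int(5 + rng.geometric(0.3))
            else:
                length = int(min(4, rng.geometric(0.55)))
            out.append(IndelRecord(sid, kind, max(1, length)))
    return out
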