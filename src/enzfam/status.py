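"""Three-rule mutant annotation and genotype-group assignment.

A gene is annotated mutant in a sample when any of three rules fires:
(i) a nonsynonymous SNV in the gene, (ii) somatic copy-number loss covering
at least 50% of the gene body, (iii) an SV breakend inside the gene body
(the operational reading of "predicted to disrupt the open reading frame" —
no transcript model is consumed).  Zygosity is called from allele-specific
copy number: homozygous loss when ≥50% of the gene is at total copy 0,
heterozygous loss when ≥50% sits between 1 and one below the rounded ploidy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel, MutationEvent, SegmentProfile, StructuralVariant

NONSYNONYMOUS = frozenset(
    {"missense", "nonsense", "splice_site", "frameshift_del", "inframe"}
)


@dataclass
class GeneStatus:
    sample_id: str
    gene_id: str
    is_mutant: bool
    fired_rules: frozenset[str]  # subset of {"snv", "cn_loss", "sv_orf"}
    zygosity: str  # "wt" | "het_loss" | "hom_loss" | "na"

    def __post_init__(self) -> None:
        assert self.is_mutant == bool(self.fired_rules)
        if self.zygosity == "hom_loss":
            assert "cn_loss" in self.fired_rules


@dataclass
class GroupRule:
    """One genotype-group label with its gene → required-zygosity map.

    ``wt`` requirements match samples where the gene shows neither loss;
    specificity (number of non-wt requirements) breaks ties so the most
    specific label wins (e.g. AQR+TP53 beats AQR).
    """

    label: str
    requirements: dict[str, str]

    @property
    def specificity(self) -> int:
        return sum(1 for z in self.requirements.values() if z != "wt")


@dataclass
class GenotypeGroup:
    sample_id: str
    label: str


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def overlap_fraction(gene: GeneModel, seg_start: int, seg_end: int) -> float:
    """Fraction of the gene body covered by [seg_start, seg_end)."""
    inter = max(0, min(gene.end, seg_end) - max(gene.start, seg_start))
    return inter / gene.length_bp


def _covered_fraction(gene: GeneModel, intervals: list[tuple[int, int]]) -> float:
    """Fraction of the gene body covered by the union of the intervals."""
    clipped = sorted(
        (max(s, gene.start), min(e, gene.end)) for s, e in intervals
    )
    covered = 0
    cursor = gene.start
    for s, e in clipped:
        if e <= cursor:
            continue
        covered += e - max(s, cursor)
        cursor = e
    return covered / gene.length_bp


def annotate_gene_status(
    gene: GeneModel,
    events: list[MutationEvent],
    profile: SegmentProfile | None,
    svs: list[StructuralVariant],
    somatic_only: bool = False,  # reserved: events carry no germline flag here
    loss_fraction: float = 0.5,
) -> GeneStatus:
    """Apply the three mutant rules for one gene in one sample.

    A missing profile skips the copy-number rule and records zygosity ``na``
    rather than silently calling wild type.  Only allele-specific profiles
    yield zygosity; logR profiles also give ``na``.
    """
    fired: set[str] = set()
    if any(
        ev.gene_id == gene.gene_id and ev.variant_class in NONSYNONYMOUS
        for ev in events
    ):
        fired.add("snv")

    zygosity = "na"
    if profile is not None and profile.dialect == "allele_specific":
        ploidy_cn = round_half_up(profile.ploidy)
        segs = [
            s for s in profile.chrom_segments(gene.chrom)
            if s.end > gene.start and s.start < gene.end
        ]
        loss = [(s.start, s.end) for s in segs if s.value < ploidy_cn]
        hom = [(s.start, s.end) for s in segs if s.value == 0]
        het = [(s.start, s.end) for s in segs if 1 <= s.value < ploidy_cn]
        if _covered_fraction(gene, loss) >= loss_fraction:
            fired.add("cn_loss")
        if _covered_fraction(gene, hom) >= loss_fraction:
            zygosity = "hom_loss"
        elif _covered_fraction(gene, het) >= loss_fraction:
            zygosity = "het_loss"
        else:
            zygosity = "wt"

    for sv in svs:
        for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
            if chrom == gene.chrom and gene.start < pos < gene.end:
                fired.add("sv_orf")

    return GeneStatus(
        sample_id=profile.sample_id if profile is not None else (
            events[0].sample_id if events else (svs[0].sample_id if svs else "")
        ),
        gene_id=gene.gene_id,
        is_mutant=bool(fired),
        fired_rules=frozenset(fired),
        zygosity=zygosity,
    )


def assign_genotype_groups(
    statuses: list[GeneStatus],
    rules: list[GroupRule],
) -> tuple[list[GenotypeGroup], dict[str, str]]:
    """Give each sample the most specific fully-satisfied group label.

    Returns (assignments, excluded) where ``excluded`` maps unassignable
    samples to the reason.  A ``wt`` requirement is satisfied by zygosity
    ``wt``; ``na`` zygosity satisfies nothing.
    """
    by_sample: dict[str, dict[str, str]] = {}
    for st in statuses:
        by_sample.setdefault(st.sample_id, {})[st.gene_id] = st.zygosity
    assigned: list[GenotypeGroup] = []
    excluded: dict[str, str] = {}
    for sid in sorted(by_sample):
        zyg = by_sample[sid]
        matches = [
            r for r in rules
            if all(zyg.get(g) == req for g, req in r.requirements.items())
        ]
        if not matches:
            excluded[sid] = "no group rule satisfied"
            continue
        best = max(matches, key=lambda r: r.specificity)
        assigned.append(GenotypeGroup(sid, best.label))
    return assigned, excluded


def cooccurrence_test(
    status: pd.DataFrame, gene_a: str, gene_b: str
) -> tuple[np.ndarray, float, float]:
    """2×2 co-mutation test between two genes over samples.

    ``status`` is a samples×genes boolean mutant matrix.  Returns the table
    [[both, a_only], [b_only, neither]], the odds ratio (infinite sentinel on
    a zero denominator cell) and the two-sided Fisher exact p.  A gene mutant
    in zero (or all) samples gives a degenerate table with p = 1.
    """
    a = status[gene_a].astype(bool)
    b = status[gene_b].astype(bool)
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return table, math.nan, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    bc = table[0, 1] * table[1, 0]
    odds = math.inf if bc == 0 else (table[0, 0] * table[1, 1]) / bc
    return table, odds, float(p)
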