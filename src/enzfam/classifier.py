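"""Essential × hemizygous quadrant classification of candidate driver genes.

A gene is a hemizygous driver candidate when it is (i) essential — CRISPR
dependency score below −1, (ii) recurrently focally mutated — at least three
focal somatic alterations and a pan-cancer focal rate above 0.1% (the
combinator and rates are configurable; an OR reading with a 0.5% biallelic
cutoff is also in circulation and exposed via ``Thresholds``), and (iii)
depleted for biallelic inactivation — biallelic rate below 0.1%.  The
essential∧biallelic quadrant is expected empty on real-like data: two-hit
inactivation of an essential gene is cell-lethal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .enrichment import cgc_enrichment
from .io import GeneModel

QUADRANTS = (
    "essential_hemizygous",
    "essential_biallelic",
    "nonessential_hemizygous",
    "nonessential_biallelic",
    "not_recurrent",
)


@dataclass(frozen=True)
class Thresholds:
    dep_cut: float = -1.0
    min_focal: int = 3
    min_rate: float = 0.001
    max_biallelic: float = 0.001
    recurrence_combinator: str = "AND"  # "AND" | "OR"

    def __post_init__(self) -> None:
        if self.recurrence_combinator not in ("AND", "OR"):
            raise ValueError("recurrence_combinator must be 'AND' or 'OR'")


@dataclass
class GeneEvidence:
    gene_id: str
    dependency_score: float | None
    focal_count: int
    cohort_n: int
    biallelic_rate: float
    family: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_n <= 0:
            raise ValueError("cohort_n must be > 0")
        if not 0.0 <= self.biallelic_rate <= 1.0:
            raise ValueError("biallelic_rate must lie in [0, 1]")

    @property
    def focal_rate(self) -> float:
        return self.focal_count / self.cohort_n


@dataclass
class DriverClassification:
    gene_id: str
    essential: bool
    recurrent: bool
    biallelic_depleted: bool
    quadrant: str
    is_hemizygous_driver: bool


class MissingEvidence(ValueError):
    """Evidence incomplete; the gene is excluded, never defaulted."""


def classify_gene(ev: GeneEvidence, thresholds: Thresholds = Thresholds()) -> DriverClassification:
    """Place one gene in its quadrant and flag hemizygous driver candidates."""
    if ev.dependency_score is None or (
        isinstance(ev.dependency_score, float) and math.isnan(ev.dependency_score)
    ):
        raise MissingEvidence(f"{ev.gene_id}: missing dependency score")
    essential = ev.dependency_score < thresholds.dep_cut
    by_count = ev.focal_count >= thresholds.min_focal
    by_rate = ev.focal_rate > thresholds.min_rate
    recurrent = (by_count and by_rate) if thresholds.recurrence_combinator == "AND" else (by_count or by_rate)
    biallelic_depleted = ev.biallelic_rate < thresholds.max_biallelic
    if not recurrent:
        quadrant = "not_recurrent"
    elif essential:
        quadrant = "essential_hemizygous" if biallelic_depleted else "essential_biallelic"
    else:
        quadrant = "nonessential_hemizygous" if biallelic_depleted else "nonessential_biallelic"
    return DriverClassification(
        gene_id=ev.gene_id,
        essential=essential,
        recurrent=recurrent,
        biallelic_depleted=biallelic_depleted,
        quadrant=quadrant,
        is_hemizygous_driver=essential and recurrent and biallelic_depleted,
    )


def classify_cohort(
    evidence: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[list[DriverClassification], list[str], dict[str, int], dict[str, str]]:
    """Classify every gene in an evidence table.

    Expects columns gene_id, dependency_score, focal_count, cohort_n,
    biallelic_rate (family optional).  Returns (classifications, driver gene
    ids sorted by dependency score, quadrant counts, excluded genes with
    reasons).
    """
    classifications: list[DriverClassification] = []
    excluded: dict[str, str] = {}
    dep = {}
    for row in evidence.itertuples(index=False):
        ev = GeneEvidence(
            gene_id=str(row.gene_id),
            dependency_score=None if pd.isna(row.dependency_score) else float(row.dependency_score),
            focal_count=int(row.focal_count),
            cohort_n=int(row.cohort_n),
            biallelic_rate=float(row.biallelic_rate),
            family=str(row.family) if hasattr(row, "family") and not pd.isna(row.family) else None,
        )
        try:
            cl = classify_gene(ev, thresholds)
        except MissingEvidence as exc:
            excluded[ev.gene_id] = str(exc)
            continue
        classifications.append(cl)
        dep[cl.gene_id] = ev.dependency_score
    drivers = sorted(
        (c.gene_id for c in classifications if c.is_hemizygous_driver),
        key=lambda g: dep[g],
    )
    counts = {q: 0 for q in QUADRANTS}
    for c in classifications:
        counts[c.quadrant] += 1
    return classifications, drivers, counts, excluded


def driver_family_enrichment(
    drivers: list[str], universe: list[GeneModel], family: str
) -> tuple[float, float]:
    """Fisher's exact test of one family's share among drivers vs the rest of
    the universe (same 2×2 construction as the CGC enrichment)."""
    family_genes = {g.gene_id for g in universe if g.enzyme_family == family}
    return cgc_enrichment(family_genes, set(drivers), universe)
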