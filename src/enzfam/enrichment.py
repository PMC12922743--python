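"""Coverage-matched permutation enrichment of mutations per enzyme family.

Per cancer type and gene set (an enzyme family or class), the statistic is
the number of genes recurrently mutated — carrying a deleterious variant
(missense, nonsense, splice site, frameshift deletion) in at least two
distinct patients.  The null is built by repeatedly sampling gene sets from
the universe matched in number and within ±5% of the reference set's total
genomic coverage, and recounting.  The standardized mean difference (SMD) is
(observed − permutation mean) / permutation SD; the empirical p-value uses
the add-one estimator (r+1)/(n+1), which is strictly positive and therefore
combinable across cancer types with Fisher's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import DELETERIOUS_CLASSES, GeneModel, MutationEvent


@dataclass
class EnrichmentResult:
    family: str
    cancer_type: str
    observed_count: int
    perm_mean: float
    perm_sd: float
    smd: float
    p_emp: float
    n_perm: int
    smd_undefined: bool = False


@dataclass
class FamilySummary:
    family: str
    mean_smd: float
    smd_p5: float
    smd_p95: float
    combined_p: float
    per_type: list[EnrichmentResult] = field(default_factory=list)


def recurrent_gene_indicator(
    events: list[MutationEvent],
    universe: list[GeneModel],
    min_patients: int = 2,
) -> np.ndarray:
    """Boolean vector over the universe: gene has deleterious events in at
    least ``min_patients`` distinct patients."""
    index = {g.gene_id: i for i, g in enumerate(universe)}
    patients: list[set[str]] = [set() for _ in universe]
    for ev in events:
        if ev.is_deleterious and ev.gene_id in index:
            patients[index[ev.gene_id]].add(ev.sample_id)
    return np.array([len(p) >= min_patients for p in patients], dtype=bool)


def count_recurrently_mutated_genes(
    events: list[MutationEvent],
    universe: list[GeneModel],
    gene_set: set[str],
    min_patients: int = 2,
) -> int:
    """Number of genes in ``gene_set`` mutated (deleteriously) in at least
    ``min_patients`` distinct patients.  Silent/other classes never count."""
    universe_ids = {g.gene_id for g in universe}
    foreign = gene_set - universe_ids
    if foreign:
        raise ValueError(f"gene_set contains genes outside the universe: {sorted(foreign)}")
    recurrent = recurrent_gene_indicator(events, universe, min_patients)
    in_set = np.array([g.gene_id in gene_set for g in universe])
    return int((recurrent & in_set).sum())


class MatchingError(RuntimeError):
    """No coverage-matched draw found within the attempt budget."""


def sample_matched_gene_set(
    universe: list[GeneModel],
    reference_set: set[str],
    rng: np.random.Generator,
    coverage_tol: float = 0.05,
    max_attempts: int = 10_000,
) -> set[str]:
    """Rejection-sample a gene set matched in number and, within
    ``coverage_tol``, in total genomic coverage to ``reference_set``."""
    ids = [g.gene_id for g in universe]
    lengths = np.array([g.length_bp for g in universe], dtype=float)
    ref_idx = [i for i, gid in enumerate(ids) if gid in reference_set]
    if len(ref_idx) != len(reference_set):
        raise ValueError("reference_set contains genes outside the universe")
    k = len(ref_idx)
    target = lengths[ref_idx].sum()
    lo, hi = (1 - coverage_tol) * target, (1 + coverage_tol) * target
    best_ratio = math.inf
    for _ in range(max_attempts):
        pick = rng.choice(len(ids), size=k, replace=False)
        total = lengths[pick].sum()
        if lo <= total <= hi:
            return {ids[i] for i in pick}
        best_ratio = min(best_ratio, abs(total / target - 1.0))
    raise MatchingError(
        f"no matched set of size {k} within ±{coverage_tol:.0%} after "
        f"{max_attempts} attempts (closest coverage deviation {best_ratio:.3f})"
    )


def _matched_null_counts(
    recurrent: np.ndarray,
    lengths: np.ndarray,
    k: int,
    target: float,
    n_perm: int,
    rng: np.random.Generator,
    coverage_tol: float,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Vectorized rejection sampling of ``n_perm`` matched-set recurrence
    counts (same distribution as repeated :func:`sample_matched_gene_set`)."""
    n = len(lengths)
    lo, hi = (1 - coverage_tol) * target, (1 + coverage_tol) * target
    counts: list[np.ndarray] = []
    have = 0
    attempts = 0
    batch = max(64, n_perm)
    rec = recurrent.astype(np.int64)
    while have < n_perm:
        if attempts > max_attempts and have == 0:
            raise MatchingError(
                f"no matched set of size {k} within ±{coverage_tol:.0%} after "
                f"{attempts} attempted draws"
            )
        idx = np.argsort(rng.random((batch, n)), axis=1)[:, :k]
        totals = lengths[idx].sum(axis=1)
        ok = (totals >= lo) & (totals <= hi)
        attempts += batch
        if ok.any():
            counts.append(rec[idx[ok]].sum(axis=1))
            have += int(ok.sum())
    return np.concatenate(counts)[:n_perm]


def permutation_enrichment(
    events: list[MutationEvent],
    universe: list[GeneModel],
    gene_set: set[str],
    rng: np.random.Generator,
    n_perm: int = 10_000,
    min_patients: int = 2,
    coverage_tol: float = 0.05,
    family: str = "",
    cancer_type: str = "",
) -> EnrichmentResult:
    """Observed recurrence count vs the coverage-matched permuted background.

    ``p_emp = (r+1)/(n_perm+1)`` with r the number of permutation counts at
    or above the observed; SMD uses the sample SD (n−1).  A degenerate null
    (zero SD with observed off the mean) is flagged, never given a value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    recurrent = recurrent_gene_indicator(events, universe, min_patients)
    return _permutation_enrichment_counts(
        recurrent,
        np.array([g.length_bp for g in universe], dtype=float),
        {g.gene_id: i for i, g in enumerate(universe)},
        gene_set,
        rng,
        n_perm,
        coverage_tol,
        family,
        cancer_type,
    )


def _permutation_enrichment_counts(
    recurrent: np.ndarray,
    lengths: np.ndarray,
    index: dict[str, int],
    gene_set: set[str],
    rng: np.random.Generator,
    n_perm: int,
    coverage_tol: float,
    family: str,
    cancer_type: str,
) -> EnrichmentResult:
    foreign = [gid for gid in gene_set if gid not in index]
    if foreign:
        raise ValueError(f"gene_set contains genes outside the universe: {sorted(foreign)}")
    set_idx = np.array([index[gid] for gid in gene_set], dtype=int)
    observed = int(recurrent[set_idx].sum())
    target = float(lengths[set_idx].sum())
    null = _matched_null_counts(
        recurrent, lengths, len(set_idx), target, n_perm, rng, coverage_tol
    )
    return result_from_null(observed, null, family=family, cancer_type=cancer_type)


def result_from_null(
    observed: int,
    null_counts,
    family: str = "",
    cancer_type: str = "",
) -> EnrichmentResult:
    """Build an :class:`EnrichmentResult` from an explicit null sample.

    ``p_emp = (r+1)/(n+1)``; SMD uses the sample SD (ddof=1) of the null
    counts and is flagged undefined when the null is degenerate but the
    observed count differs from it.
    """
    null = np.asarray(null_counts, dtype=float)
    n_perm = null.size
    perm_mean = float(null.mean())
    perm_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    r = int((null >= observed).sum())
    p_emp = (r + 1) / (n_perm + 1)
    if perm_sd > 0:
        smd, undef = (observed - perm_mean) / perm_sd, False
    elif observed == perm_mean:
        smd, undef = 0.0, False
    else:
        smd, undef = math.nan, True
    return EnrichmentResult(
        family=family,
        cancer_type=cancer_type,
        observed_count=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        smd=smd,
        p_emp=p_emp,
        n_perm=n_perm,
        smd_undefined=undef,
    )


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: X = −2 Σ ln p, p_comb from chi-square with 2k df."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = float(-2.0 * np.log(p).sum())
    return x, float(stats.chi2.sf(x, 2 * p.size))


def summarize_family(results: list[EnrichmentResult]) -> FamilySummary:
    """Aggregate per-cancer-type results for one family.

    Mean SMD over defined entries, 5th/95th percentiles (linear
    interpolation) as the cancer-type-specific effect range, and the Fisher
    combination of the per-type empirical p-values.
    """
    if not results:
        raise ValueError("no results to summarize")
    family = results[0].family
    smds = np.array([r.smd for r in results if not r.smd_undefined], dtype=float)
    _, combined_p = fisher_combine([r.p_emp for r in results])
    if smds.size:
        mean_smd = float(smds.mean())
        p5, p95 = (float(v) for v in np.percentile(smds, [5, 95]))
    else:
        mean_smd = p5 = p95 = math.nan
    return FamilySummary(
        family=family,
        mean_smd=mean_smd,
        smd_p5=p5,
        smd_p95=p95,
        combined_p=combined_p,
        per_type=list(results),
    )


def family_enrichment_analysis(
    events_by_cancer_type: dict[str, list[MutationEvent]],
    universe: list[GeneModel],
    rng: np.random.Generator,
    label: str = "enzyme_family",
    n_perm: int = 10_000,
    min_patients: int = 2,
    coverage_tol: float = 0.05,
) -> list[FamilySummary]:
    """Run the full enrichment over every family (or class) label present.

    ``label`` selects which annotation partitions the universe; the class-
    level analysis is the same code path with ``label="enzyme_class"``.
    """
    lengths = np.array([g.length_bp for g in universe], dtype=float)
    index = {g.gene_id: i for i, g in enumerate(universe)}
    families = sorted(
        {getattr(g, label) for g in universe if getattr(g, label) is not None}
    )
    sets = {
        fam: {g.gene_id for g in universe if getattr(g, label) == fam}
        for fam in families
    }
    summaries = []
    recurrent_by_type = {
        ct: recurrent_gene_indicator(ev, universe, min_patients)
        for ct, ev in events_by_cancer_type.items()
    }
    for fam in families:
        per_type = [
            _permutation_enrichment_counts(
                recurrent_by_type[ct], lengths, index, sets[fam], rng,
                n_perm, coverage_tol, fam, ct,
            )
            for ct in events_by_cancer_type
        ]
        summaries.append(summarize_family(per_type))
    return summaries


def cgc_enrichment(
    family_genes: set[str], cgc_genes: set[str], universe: list[GeneModel]
) -> tuple[float, float]:
    """Fisher's exact test of CGC membership inside vs outside a family.

    Returns (odds ratio, two-sided p); a zero denominator cell yields an
    infinite odds ratio with the exact p still computed.
    """
    ids = {g.gene_id for g in universe}
    if not family_genes <= ids or not cgc_genes <= ids:
        raise ValueError("family_genes and cgc_genes must lie within the universe")
    a = len(family_genes & cgc_genes)
    b = len(family_genes - cgc_genes)
    c = len(cgc_genes - family_genes)
    d = len(ids - family_genes - cgc_genes)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return odds, float(p)
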