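"""Arrayed-screen scoring: γH2AX-positive fractions, SSMD, replicate-combined
hit calling.

Per plate, a positivity threshold is set at a quantile (default 95th) of the
pooled negative-control cell intensities; every well is then summarized as
its fraction of positive cells.  Per gene and replicate a one-sided rank-sum
test compares the gene's construct wells (three per gene) against the
plate's control wells; per-replicate p-values are Fisher-combined and genes
with combined p below α are hits.  The SSMD — mean difference over the root
summed variances — is the reported effect size.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import fisher_combine
from .simulate import CONTROL_LABEL


def positivity_threshold(control_intensities, quantile: float = 0.95) -> float:
    """Quantile of pooled negative-control cell intensities (one plate)."""
    vals = np.asarray(control_intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("no control cells")
    return float(np.quantile(vals, quantile))


def pct_positive(intensities, threshold: float) -> float:
    """Fraction of cells with intensity strictly above the threshold."""
    vals = np.asarray(intensities, dtype=float)
    if vals.size == 0:
        raise ValueError("empty well")
    return float((vals > threshold).mean())


def ssmd(gene_values, control_values) -> float:
    """Strictly standardized mean difference with sample variances (n−1).

    Undefined (NaN) when either side has fewer than two observations — never
    silently 0.
    """
    g = np.asarray(gene_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if g.size < 2 or c.size < 2:
        return math.nan
    denom = math.sqrt(g.var(ddof=1) + c.var(ddof=1))
    diff = g.mean() - c.mean()
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / denom)


def _one_sided_rank_p(gene_vals: np.ndarray, ctrl_vals: np.ndarray) -> float:
    """Exact one-sided (greater) rank-sum p when tie-free and small, else
    the tie-corrected normal approximation."""
    pooled = np.concatenate([gene_vals, ctrl_vals])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(gene_vals), len(ctrl_vals)) <= 8 and not has_ties) else "asymptotic"
    return float(
        min(1.0, stats.mannwhitneyu(gene_vals, ctrl_vals, alternative="greater", method=method).pvalue)
    )


def score_screen(
    wells: pd.DataFrame,
    alpha: float = 0.05,
    quantile: float = 0.95,
    control_label: str = CONTROL_LABEL,
) -> pd.DataFrame:
    """Score a long-format screen table (plate, well, gene, replicate,
    intensity — one row per cell).

    Thresholding is strictly per plate (no cross-plate pooling).  Genes
    missing from a replicate are combined over the replicates they appear in.
    Returns one row per gene with mean positive fraction per replicate, SSMD
    over all wells vs all control wells, per-replicate p-values, the Fisher
    combined p and the hit flag.
    """
    required = {"plate", "well", "gene", "replicate", "intensity"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing column(s): {sorted(missing)}")

    thresholds = {
        plate: positivity_threshold(
            grp.loc[grp["gene"] == control_label, "intensity"], quantile
        )
        for plate, grp in wells.groupby("plate")
    }
    positive = wells["intensity"] > wells["plate"].map(thresholds)
    per_well = (
        wells.assign(positive=positive)
        .groupby(["plate", "replicate", "gene", "well"])["positive"]
        .mean()
        .rename("pct_positive")
        .reset_index()
    )

    ctrl = per_well[per_well["gene"] == control_label]
    gene_rows = []
    for gene, gdf in per_well[per_well["gene"] != control_label].groupby("gene"):
        rep_p: dict[int, float] = {}
        rep_pct: dict[int, float] = {}
        for (plate, rep), rdf in gdf.groupby(["plate", "replicate"]):
            cvals = ctrl[(ctrl["plate"] == plate) & (ctrl["replicate"] == rep)][
                "pct_positive"
            ].to_numpy()
            gvals = rdf["pct_positive"].to_numpy()
            rep_p[rep] = _one_sided_rank_p(gvals, cvals)
            rep_pct[rep] = float(gvals.mean())
        _, p_combined = fisher_combine(list(rep_p.values()))
        gene_rows.append(
            {
                "gene_id": gene,
                "ssmd": ssmd(gdf["pct_positive"].to_numpy(), ctrl["pct_positive"].to_numpy()),
                **{f"pct_positive_rep{r}": v for r, v in sorted(rep_pct.items())},
                **{f"p_rep{r}": v for r, v in sorted(rep_p.items())},
                "n_replicates": len(rep_p),
                "p_combined": p_combined,
                "is_hit": p_combined < alpha,
            }
        )
    return pd.DataFrame(gene_rows).sort_values("p_combined").reset_index(drop=True)
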