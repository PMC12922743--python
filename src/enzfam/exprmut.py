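"""Gene-expression effect on the length-normalized deleterious mutation rate.

Per gene the rate is the number of deleterious events (missense, nonsense,
frameshift, in-frame) divided by gene length in kilobases; genes with fewer
than three events are excluded from fitting.  Zero inflation is handled by a
two-part hurdle: a logistic model for whether the rate is positive and a
linear model of log rate on expression (controlling for gene length) over the
positive-rate genes.  The reported effect is the positive-part expression
slope; a positive effect means higher expression associates with a higher
mutation rate.  One model is fit per (cancer type, gene class); within each
class the per-fit p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

MIN_EVENTS = 3


@dataclass
class HurdleFit:
    slope: float
    slope_se: float
    p: float
    zero_part: dict[str, float] | None
    positive_part: dict[str, float]
    n_total: int
    n_positive: int
    zero_part_skipped: bool = False


@dataclass
class ClassFit:
    gene_class: str
    mean_effect: float
    pct_significant: float
    n_tested: int
    detail: pd.DataFrame = field(default_factory=pd.DataFrame)


def mutation_rate(n_deleterious: int, length_kb: float) -> float:
    """Deleterious mutations per kilobase of gene body."""
    if length_kb <= 0:
        raise ValueError("length_kb must be > 0")
    if n_deleterious < 0:
        raise ValueError("n_deleterious must be >= 0")
    return n_deleterious / length_kb


def hurdle_fit(records: pd.DataFrame, plain_linear: bool = False) -> HurdleFit:
    """Two-part fit of mutation rate on expression, controlling for length.

    ``records`` needs columns expression, length_kb and mutation_rate.  Part
    one is a logistic regression of (rate > 0); part two a linear regression
    of log(rate) over positive-rate records.  ``plain_linear`` fits the rate
    untransformed on all records instead (sensitivity path).
    """
    df = records.reset_index(drop=True)
    positive = df["mutation_rate"] > 0
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("no positive part: all mutation rates are zero")
    if n_pos < 10:
        raise ValueError(f"need >= 10 positive-rate records, have {n_pos}")
    if df["expression"].nunique() < 2:
        raise ValueError("expression is constant; slope unidentifiable")

    X_cols = ["expression", "length_kb"]
    if plain_linear:
        X = sm.add_constant(df[X_cols])
        fit = sm.OLS(df["mutation_rate"], X).fit()
        return HurdleFit(
            slope=float(fit.params["expression"]),
            slope_se=float(fit.bse["expression"]),
            p=float(fit.pvalues["expression"]),
            zero_part=None,
            positive_part=dict(fit.params),
            n_total=len(df),
            n_positive=n_pos,
            zero_part_skipped=True,
        )

    zero_part = None
    skipped = False
    if positive.all():
        skipped = True
    else:
        try:
            logit = sm.Logit(
                positive.astype(float), sm.add_constant(df[X_cols])
            ).fit(disp=0)
            zero_part = dict(logit.params)
        except Exception:  # separation etc.: zero part is advisory only
            skipped = True

    pos = df[positive]
    X = sm.add_constant(pos[X_cols])
    fit = sm.OLS(np.log(pos["mutation_rate"]), X).fit()
    return HurdleFit(
        slope=float(fit.params["expression"]),
        slope_se=float(fit.bse["expression"]),
        p=float(fit.pvalues["expression"]),
        zero_part=zero_part,
        positive_part=dict(fit.params),
        n_total=len(df),
        n_positive=n_pos,
        zero_part_skipped=skipped,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def prepare_records(
    table: pd.DataFrame, min_events: int = MIN_EVENTS
) -> pd.DataFrame:
    """Apply the ≥``min_events`` filter and derive mutation_rate.

    Expects columns gene_id, gene_class, n_deleterious, length_kb,
    expression.
    """
    df = table.copy()
    df["mutation_rate"] = df["n_deleterious"] / df["length_kb"]
    return df[df["n_deleterious"] >= min_events].reset_index(drop=True)


def class_summary(
    fits: pd.DataFrame, alpha: float = 0.05
) -> list[ClassFit]:
    """Summarize per-(cancer type, class) fits into per-class rows.

    ``fits`` needs columns gene_class, effect, p (one row per fitted model).
    BH adjustment is applied within class; ``pct_significant`` is the
    percentage of tested fits with q < α.  A class with nothing tested is
    emitted with missing summaries.
    """
    out: list[ClassFit] = []
    for cls, grp in fits.groupby("gene_class", sort=True):
        grp = grp.copy()
        tested = grp[~grp["p"].isna()]
        if len(tested) == 0:
            out.append(ClassFit(str(cls), math.nan, math.nan, 0, grp))
            continue
        grp.loc[tested.index, "q"] = bh_adjust(tested["p"])
        out.append(
            ClassFit(
                gene_class=str(cls),
                mean_effect=float(tested["effect"].mean()),
                pct_significant=float(100.0 * (grp.loc[tested.index, "q"] < alpha).mean()),
                n_tested=len(tested),
                detail=grp,
            )
        )
    return out
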