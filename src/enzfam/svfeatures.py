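"""SV size and homology spectra, indel classes, exposure normalization, and
their genotype-group associations.

All extractors emit per-sample proportions that sum to 1 within a feature
class; a class with an empty denominator is emitted as missing, never as 0.
Size bins are half-open on kb boundaries ([0,1kb), [1,10kb), [10,100kb),
[100kb,1Mb), [1Mb,∞)); breakpoint homology uses inclusive integer bins
0–3, 4–11 and 12–1000 nt; indels split into 1, 2–4 and 5+ nt within each
kind.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IndelRecord, StructuralVariant

logger = logging.getLogger(__name__)

SIZE_BIN_EDGES = [0, 1_000, 10_000, 100_000, 1_000_000]
SIZE_BIN_LABELS = ["0-1kb", "1-10kb", "10-100kb", "100kb-1Mb", ">1Mb"]
HOMOLOGY_BIN_LABELS = ["hom_0-3", "hom_4-11", "hom_12-1000"]
INDEL_BIN_LABELS = ["1nt", "2-4nt", "5+nt"]


@dataclass
class FeatureVector:
    sample_id: str
    features: dict[str, float] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)

    def update(self, other: "FeatureVector") -> "FeatureVector":
        self.features.update(other.features)
        self.denominators.update(other.denominators)
        return self


def _size_bin(size_bp: int) -> str:
    for edge, label in zip(SIZE_BIN_EDGES[1:], SIZE_BIN_LABELS[:-1]):
        if size_bp < edge:
            return label
    return SIZE_BIN_LABELS[-1]


def bin_sv_sizes(sample_id: str, svs: list[StructuralVariant]) -> FeatureVector:
    """DEL and DUP size spectra, each normalized within its own type.

    TRA and INV carry no size and are excluded; a sample with no events of a
    type leaves that type's proportions missing.
    """
    fv = FeatureVector(sample_id)
    for svtype in ("DEL", "DUP"):
        sizes = [
            sv.size_bp for sv in svs
            if sv.sample_id == sample_id and sv.sv_type == svtype and sv.size_bp is not None
        ]
        fv.denominators[f"{svtype}-size"] = len(sizes)
        if not sizes:
            continue
        counts = {label: 0 for label in SIZE_BIN_LABELS}
        for s in sizes:
            counts[_size_bin(s)] += 1
        for label, c in counts.items():
            fv.features[f"{svtype}_{label}"] = c / len(sizes)
    return fv


def _homology_bin(homlen: int) -> str:
    if homlen <= 3:
        return HOMOLOGY_BIN_LABELS[0]
    if homlen <= 11:
        return HOMOLOGY_BIN_LABELS[1]
    if homlen > 1000:
        logger.warning("homology length %d clamped into the 12-1000 bin", homlen)
    return HOMOLOGY_BIN_LABELS[2]


def bin_homology(sample_id: str, svs: list[StructuralVariant]) -> FeatureVector:
    """Breakpoint-homology spectrum over all of a sample's SVs."""
    fv = FeatureVector(sample_id)
    homs = [sv.homology_len_nt for sv in svs if sv.sample_id == sample_id]
    fv.denominators["homology"] = len(homs)
    if not homs:
        return fv
    counts = {label: 0 for label in HOMOLOGY_BIN_LABELS}
    for h in homs:
        counts[_homology_bin(h)] += 1
    for label, c in counts.items():
        fv.features[label] = c / len(homs)
    return fv


def _indel_bin(length_nt: int) -> str:
    if length_nt == 1:
        return INDEL_BIN_LABELS[0]
    if length_nt <= 4:
        return INDEL_BIN_LABELS[1]
    return INDEL_BIN_LABELS[2]


def indel_class_proportions(sample_id: str, indels: list[IndelRecord]) -> FeatureVector:
    """1 / 2–4 / 5+ nt proportions, separately for deletions and insertions."""
    fv = FeatureVector(sample_id)
    for kind in ("deletion", "insertion"):
        lens = [i.length_nt for i in indels if i.sample_id == sample_id and i.kind == kind]
        fv.denominators[f"{kind}-class"] = len(lens)
        if not lens:
            continue
        counts = {label: 0 for label in INDEL_BIN_LABELS}
        for ln in lens:
            counts[_indel_bin(ln)] += 1
        for label, c in counts.items():
            fv.features[f"{kind}_{label}"] = c / len(lens)
    return fv


def normalize_exposures(sample_id: str, counts: dict[str, float]) -> FeatureVector:
    """Signature exposures as fractions of the sample's total SNV count."""
    fv = FeatureVector(sample_id)
    total = sum(counts.values())
    fv.denominators["sbs-exposure"] = int(total)
    if total <= 0:
        return fv
    for sig, c in counts.items():
        fv.features[sig] = c / total
    return fv


def feature_group_regression(
    values: pd.Series | np.ndarray,
    groups: pd.Series | list[str],
    reference: str = "WT",
) -> pd.DataFrame:
    """OLS of a feature on disjoint group indicators vs a reference group.

    With disjoint groups each coefficient is the group-mean shift relative to
    the reference; p-values are two-sided t-tests.  Groups with fewer than 2
    samples keep their coefficient but are flagged unstable.
    """
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    levels = [g for g in groups.unique() if g != reference]
    if reference not in set(groups):
        raise ValueError(f"reference group {reference!r} absent from data")
    X = pd.DataFrame({g: (groups == g).astype(float).to_numpy() for g in levels})
    X = sm.add_constant(X)
    fit = sm.OLS(values, X).fit()
    rows = []
    for g in levels:
        rows.append(
            {
                "group": g,
                "coefficient": float(fit.params[g]),
                "se": float(fit.bse[g]),
                "p": float(fit.pvalues[g]),
                "n": int((groups == g).sum()),
                "unstable": bool((groups == g).sum() < 2),
            }
        )
    return pd.DataFrame(rows)


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when the smaller sample has ≤8 observations and there
    are no ties; normal approximation with tie correction otherwise.  A fully
    tied comparison (zero rank variance) returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return float(len(a) * len(b) / 2), 1.0
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))


def adjust_within_class(results: pd.DataFrame, p_col: str = "p", by: str = "feature_class") -> pd.DataFrame:
    """Benjamini-Hochberg adjustment applied separately per feature class."""
    out = results.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(by).groups.items():
        p = out.loc[idx, p_col].to_numpy(dtype=float)
        out.loc[idx, "q"] = multipletests(p, method="fdr_bh")[1]
    return out


def feature_table(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Assemble per-sample FeatureVectors into a wide table (NaN = missing)."""
    rows = {fv.sample_id: fv.features for fv in vectors}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
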