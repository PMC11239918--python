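"""Panel gene-expression normalization, nearest-centroid subtyping and signature scores.

Counts come from a targeted expression panel (192 genes: 185 analysis
genes plus 7 housekeeping genes).  Normalization is the standard panel
convention: log2(count+1) per gene minus the per-sample arithmetic mean
of the log2 housekeeping counts; housekeeping rows are dropped from the
output.  Intrinsic subtype is called by correlation to centroid profiles
(Spearman by default, as in research-based PAM50 practice); signature
scores are weighted means of normalized expression; single-gene
signatures (e.g. ERBB2 mRNA) reduce to the gene's normalized value.
Tertile grouping splits a reference cohort into three equal-rank groups
and applies the resulting cutpoints to new samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: the panel's housekeeping set
HOUSEKEEPING_GENES = ("ACTB", "MRPL19", "GAPD", "PSMC4", "PUM1", "RPLP0", "SF3A1")


class NormalizationError(ValueError):
    pass


class SubtypingError(ValueError):
    pass


class ScoringError(ValueError):
    pass


def normalize_counts(
    counts: pd.DataFrame, housekeeping: Sequence[str] = HOUSEKEEPING_GENES
) -> pd.DataFrame:
    """Housekeeping-anchored log2 normalization of a genes x samples count matrix.

    Each entry becomes ``log2(count+1) - mean_hk(log2(hk_count+1))`` for
    its sample; housekeeping rows are removed from the result.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise NormalizationError(f"duplicated gene identifier: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise NormalizationError(f"duplicated sample identifier: {dup!r}")
    missing = [g for g in housekeeping if g not in counts.index]
    if missing:
        raise NormalizationError(f"housekeeping genes missing from matrix: {missing}")
    if (counts.to_numpy() < 0).any():
        raise NormalizationError("counts must be non-negative")

    hk = counts.loc[list(housekeeping)]
    zero_hk = hk.columns[(hk == 0).all(axis=0)]
    if len(zero_hk):
        raise NormalizationError(
            f"sample {zero_hk[0]!r} has all-zero housekeeping counts"
        )
    log2 = np.log2(counts.astype(float) + 1.0)
    hk_mean = log2.loc[list(housekeeping)].mean(axis=0)
    normalized = log2.sub(hk_mean, axis=1)
    return normalized.drop(index=list(housekeeping))


@dataclass(frozen=True)
class SubtypeCall:
    subtype: str
    correlations: Mapping[str, float]
    tie: bool


def assign_subtype(
    profile: pd.Series,
    centroids: pd.DataFrame,
    method: str = "spearman",
    min_coverage: float = 0.9,
) -> SubtypeCall:
    """Nearest-centroid subtype call by correlation over shared genes.

    ``centroids`` is genes x subtypes.  The call is the argmax
    correlation; exact ties break to the first subtype in column order
    and are flagged.  Requires the profile to cover at least
    ``min_coverage`` of the centroid genes.
    """
    shared = centroids.index.intersection(profile.index)
    coverage = len(shared) / len(centroids.index)
    if coverage < min_coverage:
        raise SubtypingError(
            f"profile covers {coverage:.0%} of centroid genes "
            f"(< required {min_coverage:.0%})"
        )
    x = profile.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise SubtypingError("profile is constant over centroid genes; correlation undefined")

    corr_fn = {"spearman": _spearman, "pearson": _pearson}.get(method)
    if corr_fn is None:
        raise ValueError(f"unknown correlation method {method!r}")
    cors = {}
    for name in centroids.columns:
        c = centroids.loc[shared, name].to_numpy(dtype=float)
        cors[name] = corr_fn(x, c)
    best = max(cors.values())
    winners = [n for n in centroids.columns if _close(cors[n], best)]
    return SubtypeCall(subtype=winners[0], correlations=cors, tie=len(winners) > 1)


def _close(a: float, b: float, tol: float = 1e-12) -> bool:
    return abs(a - b) <= tol


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    r = stats.spearmanr(x, y).statistic
    return float(r)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def signature_score(profile: pd.Series, weights: Mapping[str, float]) -> float:
    """Weighted mean of normalized expression over the signature genes present.

    Weights are renormalized to the genes actually present, so partial
    panel coverage shifts the score only through the missing genes'
    values.  A single-gene signature returns that gene's value.
    """
    if not weights:
        raise ScoringError("signature has no genes")
    present = {g: w for g, w in weights.items() if g in profile.index}
    if not present:
        raise ScoringError("no signature gene present in profile")
    wsum = sum(present.values())
    if wsum == 0:
        raise ScoringError("signature weights sum to zero over present genes")
    if not all(math.isfinite(w) for w in present.values()):
        raise ScoringError("signature weights must be finite")
    return float(sum(w * profile[g] for g, w in present.items()) / wsum)


def score_signature_matrix(
    normalized: pd.DataFrame, signatures: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Signature x sample score table for a normalized matrix."""
    rows = {
        name: {s: signature_score(normalized[s], w) for s in normalized.columns}
        for name, w in signatures.items()
    }
    return pd.DataFrame(rows).T.loc[list(signatures)]


@dataclass(frozen=True)
class TertileModel:
    """Tertile cutpoints fit on a reference cohort.

    New samples with score <= cutpoint_low are "low", <= cutpoint_high
    are "medium", above that "high" (boundary values go to the lower
    group).
    """

    cutpoint_low: float
    cutpoint_high: float
    reference_n: int
    group_sizes: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.cutpoint_low > self.cutpoint_high:
            raise ValueError("cutpoint_low must be <= cutpoint_high")


def fit_tertiles(scores: Sequence[float]) -> TertileModel:
    """Split a reference score list into three equal-rank groups.

    Low takes ranks 1..ceil(n/3), medium the next ceil(2n/3)-ceil(n/3),
    high the rest (so n=77 gives 26/26/25).  Cutpoints are midpoints
    between the boundary order statistics.
    """
    values = np.asarray(scores, dtype=float)
    if len(np.unique(values)) < 3:
        raise ScoringError("tertile fit needs at least 3 distinct reference values")
    n = len(values)
    n_low = math.ceil(n / 3)
    n_low_med = math.ceil(2 * n / 3)
    order = np.sort(values)
    cut_low = (order[n_low - 1] + order[n_low]) / 2.0
    cut_high = (order[n_low_med - 1] + order[n_low_med]) / 2.0
    return TertileModel(
        cutpoint_low=float(cut_low),
        cutpoint_high=float(cut_high),
        reference_n=n,
        group_sizes=(n_low, n_low_med - n_low, n - n_low_med),
    )


def apply_tertiles(scores: Sequence[float], model: TertileModel) -> list[str]:
    """Label scores as low/medium/high against fitted cutpoints."""
    labels = []
    for s in scores:
        if s <= model.cutpoint_low:
            labels.append("low")
        elif s <= model.cutpoint_high:
            labels.append("medium")
        else:
            labels.append("high")
    return labels
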