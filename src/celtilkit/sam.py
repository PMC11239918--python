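"""Two-class unpaired significance analysis of microarrays (SAM).

SAM ranks genes by a moderated t-like statistic

    d_i = (mean_2i - mean_1i) / (s_i + s0)

where s_i is the pooled standard error of the mean difference and s0 is
a small "fudge factor" that damps the otherwise inflated d of low-
variance genes.  s0 is chosen over a percentile grid of the s_i
distribution so that the spread of d is as uniform as possible across
the range of s (minimum coefficient of variation of windowed median
absolute deviations).  Significance is assessed against label
permutations: the sorted observed d is compared with the expected order
statistics averaged over permutations, a threshold Δ defines asymmetric
call cutoffs, and the false discovery rate of each Δ is estimated as
π0 x (mean number of permuted exceedances) / (observed calls), with
π0 estimated from the fraction of observed d falling inside the central
50% of the permuted d distribution.  The reported gene set is the
smallest Δ whose estimated FDR is below the requested threshold; each
gene also gets a q-value (the smallest FDR at which it would be called).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class SAMError(ValueError):
    pass


@dataclass(frozen=True)
class SAMConfig:
    n_permutations: int = 1000
    fdr_threshold: float = 0.10
    seed: int = 0
    s0_percentiles: tuple[float, ...] = tuple(np.arange(0, 100.01, 5.0))
    n_delta_grid: int = 60

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise SAMError("n_permutations must be >= 1")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise SAMError("fdr_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SAMResult:
    d: pd.Series                 # observed d-statistic per gene
    d_expected: np.ndarray       # expected order statistics (sorted scale)
    s0: float
    pi0: float
    delta: float                 # chosen threshold (inf if nothing callable)
    cut_low: float
    cut_up: float
    fdr: float                   # estimated FDR at the chosen delta
    significant: pd.Index        # genes called at the chosen delta
    qvalues: pd.Series           # per-gene minimum FDR at which called


def _d_stat(x: np.ndarray, idx2: np.ndarray, idx1: np.ndarray, s0: float):
    """Moderated difference statistic for one label assignment."""
    n1, n2 = len(idx1), len(idx2)
    m1 = x[:, idx1].mean(axis=1)
    m2 = x[:, idx2].mean(axis=1)
    ss1 = ((x[:, idx1] - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x[:, idx2] - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1 / n1 + 1 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return (m2 - m1) / (s + s0), s


def _choose_s0(r: np.ndarray, s: np.ndarray, percentiles: Sequence[float]) -> float:
    """Tusher-style fudge factor: minimize the coefficient of variation of
    windowed MADs of d across the range of s."""
    qs = np.percentile(s, np.arange(0, 101, 1))
    # 100 windows of s by percentile
    bins = np.clip(np.searchsorted(qs[1:-1], s, side="right"), 0, 98)
    best_s0, best_cv = 0.0, np.inf
    for pct in percentiles:
        s0 = float(np.percentile(s, pct))
        d = r / (s + s0)
        mads = []
        for b in range(99):
            sel = d[bins == b]
            if len(sel) >= 2:
                med = np.median(sel)
                mads.append(np.median(np.abs(sel - med)) / 0.64)
        mads = np.asarray(mads)
        if len(mads) < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, s0
    return best_s0


def _calls(d_sorted: np.ndarray, d_exp: np.ndarray, delta: float):
    """Asymmetric cutoffs for a given delta on the SAM plot."""
    diffs = d_sorted - d_exp
    up = d_sorted[diffs >= delta]
    low = d_sorted[diffs <= -delta]
    cut_up = float(up.min()) if len(up) else np.inf
    cut_low = float(low.max()) if len(low) else -np.inf
    return cut_low, cut_up


def sam_two_class(
    expr: pd.DataFrame, labels: Sequence[int], cfg: SAMConfig = SAMConfig()
) -> SAMResult:
    """Two-class unpaired SAM on a genes x samples matrix.

    ``labels`` holds 0/1 per sample (column order); class 1 minus
    class 0 is the reported direction.  Fully deterministic given
    ``cfg.seed`` and ``cfg.n_permutations``.
    """
    y = np.asarray(labels, dtype=int)
    if expr.shape[1] != len(y):
        raise SAMError("labels length must match sample count")
    idx1 = np.flatnonzero(y == 0)
    idx2 = np.flatnonzero(y == 1)
    if len(idx1) < 2 or len(idx2) < 2:
        raise SAMError("need >= 2 samples per class")
    x = expr.to_numpy(dtype=float)
    genes = expr.index

    r = x[:, idx2].mean(axis=1) - x[:, idx1].mean(axis=1)
    _, s = _d_stat(x, idx2, idx1, 0.0)
    s0 = _choose_s0(r, s, cfg.s0_percentiles)
    d = r / (s + s0)

    order = np.argsort(d)
    d_sorted = d[order]

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    n2 = len(idx2)
    perm_sorted = np.empty((cfg.n_permutations, len(genes)))
    for b in range(cfg.n_permutations):
        perm = rng.permutation(n)
        p2, p1 = perm[:n2], perm[n2:]
        db, _ = _d_stat(x, p2, p1, s0)
        perm_sorted[b] = np.sort(db)
    d_exp = perm_sorted.mean(axis=0)

    # pi0 from the central 50% of the permuted d distribution
    q25, q75 = np.percentile(perm_sorted, [25, 75])
    pi0 = min(1.0, np.mean((d >= q25) & (d <= q75)) / 0.5)

    # delta grid over the attained |d_sorted - d_exp|
    devs = np.abs(d_sorted - d_exp)
    grid = np.unique(np.quantile(devs[devs > 0], np.linspace(0, 1, cfg.n_delta_grid)))
    qvalues = pd.Series(np.ones(len(genes)), index=genes)
    chosen = None
    for delta in grid:
        cut_low, cut_up = _calls(d_sorted, d_exp, float(delta))
        called = (d >= cut_up) | (d <= cut_low)
        n_called = int(called.sum())
        if n_called == 0:
            continue
        false_counts = ((perm_sorted >= cut_up) | (perm_sorted <= cut_low)).sum(axis=1)
        fdr = min(1.0, pi0 * float(np.mean(false_counts)) / n_called)
        qvalues[called] = np.minimum(qvalues[called], fdr)
        if chosen is None and fdr <= cfg.fdr_threshold:
            chosen = (float(delta), cut_low, cut_up, fdr, called)
    if chosen is None:
        return SAMResult(
            d=pd.Series(d, index=genes),
            d_expected=d_exp,
            s0=s0,
            pi0=float(pi0),
            delta=np.inf,
            cut_low=-np.inf,
            cut_up=np.inf,
            fdr=1.0,
            significant=genes[:0],
            qvalues=qvalues,
        )
    delta, cut_low, cut_up, fdr, called = chosen
    return SAMResult(
        d=pd.Series(d, index=genes),
        d_expected=d_exp,
        s0=s0,
        pi0=float(pi0),
        delta=delta,
        cut_low=cut_low,
        cut_up=cut_up,
        fdr=fdr,
        significant=genes[called],
        qvalues=qvalues,
    )
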