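"""Association statistics linking baseline biomarkers to CelTIL response.

Exact contingency tests (two-sided Fisher for 2x2, Freeman–Halton for
r x c), cross-product odds ratios with Wald intervals, maximum-likelihood
logistic regression, rank-based ROC AUC (Mann–Whitney with midranks),
and two-tailed t tests.  Every result is wrapped in an
:class:`AssociationResult` carrying effect, 95% CI, p-value, method tag
and sample size.  p-values are reported raw (no multiplicity adjustment
here; FDR control lives in the SAM module).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class AssociationResult:
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    n: int
    flags: tuple[str, ...] = ()


class StatsError(ValueError):
    pass


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise StatsError("contingency table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError("contingency table cells must be non-negative integers")
    if t.sum() == 0:
        raise StatsError("contingency table total must be positive")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the probability-mass ordering: sum of hypergeometric
    probabilities of all margin-preserving tables no more likely than
    the observed one.  Non-2x2 input dispatches to
    :func:`fisher_exact_rxc`.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        return fisher_exact_rxc(t)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def fisher_exact_rxc(table, max_total: int = 200) -> float:
    """Two-sided Freeman–Halton exact test for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables whose probability does not exceed the
    observed one (within a small relative tolerance for float ties).
    Totals above ``max_total`` refuse with a hint to use a Monte-Carlo
    fallback.
    """
    t = _as_table(table)
    n = int(t.sum())
    if n > max_total:
        raise StatsError(
            f"table total {n} too large for exact enumeration "
            f"(max {max_total}); use a Monte-Carlo approximation"
        )
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    # P(T) = prod(r_i!) prod(c_j!) / (N! prod(n_ij!)); constant part in logs
    log_const = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    log_p_obs = log_const - gammaln(t + 1).sum()
    threshold = log_p_obs + 1e-7  # tolerate float ties

    total_p = 0.0

    def recurse(row: int, remaining_cols: np.ndarray, log_cells: float) -> None:
        nonlocal total_p
        if row == len(row_sums) - 1:
            # last row forced by the column margins
            lp = log_const - (log_cells + gammaln(remaining_cols + 1).sum())
            if lp <= threshold:
                total_p += math.exp(lp)
            return
        for cells in _row_compositions(int(row_sums[row]), remaining_cols):
            recurse(
                row + 1,
                remaining_cols - cells,
                log_cells + gammaln(cells + 1).sum(),
            )

    recurse(0, col_sums.copy(), 0.0)
    return float(min(total_p, 1.0))


def _row_compositions(total: int, caps: np.ndarray):
    """All ways to write ``total`` as a sum over cells with per-cell caps."""
    ncol = len(caps)

    def rec(j: int, left: int, prefix: list[int]):
        if j == ncol - 1:
            if left <= caps[j]:
                yield np.array(prefix + [left], dtype=np.int64)
            return
        # keep enough for the remaining columns' caps
        max_here = min(int(caps[j]), left)
        min_here = max(0, left - int(caps[j + 1 :].sum()))
        for v in range(min_here, max_here + 1):
            yield from rec(j + 1, left - v, prefix + [v])

    yield from rec(0, total, [])


def odds_ratio(table, haldane: bool = False) -> AssociationResult:
    """Cross-product odds ratio for a 2x2 table with Wald CI and p.

    A zero cell makes the OR infinite or zero; with ``haldane=True`` the
    Haldane–Anscombe 0.5 correction is applied to every cell instead.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise StatsError("odds_ratio needs a 2x2 table")
    n = int(t.sum())
    a, b, c, d = t.ravel().astype(float)
    flags: list[str] = []
    if 0 in (a, b, c, d):
        if haldane:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            flags.append("haldane_corrected")
        else:
            flags.append("zero_cell")
            orr = math.inf if (b == 0 or c == 0) else 0.0
            return AssociationResult(
                effect=orr,
                ci_low=math.nan,
                ci_high=math.nan,
                p_value=math.nan,
                method="odds_ratio",
                n=n,
                flags=tuple(flags),
            )
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(orr)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return AssociationResult(
        effect=orr,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p_value=float(p),
        method="odds_ratio",
        n=n,
        flags=tuple(flags),
    )


def logistic_fit(
    y: Sequence[int],
    X,
    names: Sequence[str] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> list[AssociationResult]:
    """Maximum-likelihood logistic regression (1–2 covariates).

    Newton/IRLS fit; returns one :class:`AssociationResult` per
    covariate with OR = exp(coefficient), Wald 95% CI and p.  Complete
    separation or non-convergence comes back flagged rather than raising.
    """
    yv = np.asarray(y, dtype=float)
    Xv = np.atleast_2d(np.asarray(X, dtype=float))
    if Xv.shape[0] != len(yv):
        Xv = Xv.T
    if Xv.shape[0] != len(yv):
        raise StatsError("X and y lengths differ")
    if not (0 < yv.sum() < len(yv)):
        raise StatsError("need at least one event and one non-event")
    for j in range(Xv.shape[1]):
        if np.ptp(Xv[:, j]) == 0:
            raise StatsError(f"covariate {j} is constant")
    if names is None:
        names = [f"x{j + 1}" for j in range(Xv.shape[1])]

    design = sm.add_constant(Xv, has_constant="add")
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(yv, design).fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0
            )
        if not fit.mle_retvals.get("converged", True):
            flags.append("non_converged")
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except (PerfectSeparationError, np.linalg.LinAlgError):
        flags.append("separation")
        params = np.full(design.shape[1], np.nan)
        bse = np.full(design.shape[1], np.nan)
        pvals = np.full(design.shape[1], np.nan)
    # huge |coef| with huge SE is separation in disguise
    if not flags and np.any(np.abs(params[1:]) > 20):
        flags.append("separation")

    results = []
    for j, name in enumerate(names, start=1):
        coef, se = params[j], bse[j]
        results.append(
            AssociationResult(
                effect=float(np.exp(coef)),
                ci_low=float(np.exp(coef - Z_95 * se)),
                ci_high=float(np.exp(coef + Z_95 * se)),
                p_value=float(pvals[j]),
                method=f"logistic:{name}",
                n=len(yv),
                flags=tuple(flags),
            )
        )
    return results


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> AssociationResult:
    """ROC AUC via the Mann–Whitney rank statistic (midranks for ties).

    The p-value is the two-sided normal approximation with tie
    correction; the CI is Hanley–McNeil, clipped to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise StatsError("roc_auc needs both classes present")
    ranks = sps.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    auc = u / (n1 * n0)
    p = float(
        sps.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided",
                         method="asymptotic").pvalue
    )
    # Hanley & McNeil (1982) variance
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (
        n1 * n0
    )
    se = math.sqrt(max(var, 0.0))
    return AssociationResult(
        effect=float(auc),
        ci_low=float(max(0.0, auc - Z_95 * se)),
        ci_high=float(min(1.0, auc + Z_95 * se)),
        p_value=p,
        method="roc_auc",
        n=len(y),
    )


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
) -> AssociationResult:
    """Two-tailed t test; Welch by default for the unpaired case."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if paired:
        if len(xv) != len(yv) or len(xv) < 2:
            raise StatsError("paired t test needs >= 2 pairs of equal length")
        diff = xv - yv
        if np.ptp(diff) == 0 and diff[0] == 0:
            raise StatsError("all paired differences are zero")
        res = sps.ttest_rel(xv, yv)
        effect = float(diff.mean())
        se = float(diff.std(ddof=1) / math.sqrt(len(diff)))
        df = len(diff) - 1
    else:
        if len(xv) < 2 or len(yv) < 2:
            raise StatsError("unpaired t test needs n >= 2 per group")
        if np.ptp(xv) == 0 and np.ptp(yv) == 0:
            raise StatsError("zero variance in both groups")
        res = sps.ttest_ind(xv, yv, equal_var=equal_var)
        effect = float(xv.mean() - yv.mean())
        se = math.sqrt(xv.var(ddof=1) / len(xv) + yv.var(ddof=1) / len(yv))
        df = float(res.df)
    tcrit = float(sps.t.ppf(0.975, df))
    return AssociationResult(
        effect=effect,
        ci_low=effect - tcrit * se,
        ci_high=effect + tcrit * se,
        p_value=float(res.pvalue),
        method="t_test_paired" if paired else "t_test_welch" if not equal_var else "t_test_pooled",
        n=len(xv) + (0 if paired else len(yv)),
    )
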