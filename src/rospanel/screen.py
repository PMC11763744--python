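"""Transcriptome-wide Spearman correlation screen against IC25 values.

The screen correlates each gene's basal expression across cell lines with
the per-line IC25 of one treatment, keeps genes significant at a raw
two-sided p < alpha, and builds the top-k gene lists (top-20 per
correlation sign, top-500 overall) used for cross-treatment comparison.

Spearman r is the Pearson correlation of average-tie ranks. Two-sided
p-values use the t approximation t = r*sqrt((n-2)/(1-r^2)) with n-2
degrees of freedom by default; a full-permutation exact p is available
for n <= 8. No multiple-testing correction is applied for selection
(matching the raw p < 0.05 screening convention); Benjamini-Hochberg
q-values are reported as an extra column for reference only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rospanel.errors import ValidationError

logger = logging.getLogger(__name__)

#: Minimum paired observations required for a per-gene record.
MIN_PAIRS = 10

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class SpearmanResult:
    """A single Spearman correlation with its two-sided p-value."""

    r: float
    p: float
    n: int
    #: True when |r| = 1 and the t approximation cannot produce a finite
    #: statistic; p is then the smallest representable positive float.
    p_at_bound: bool = False

    def __iter__(self):  # allows ``r, p = spearman(x, y)``
        return iter((self.r, self.p))


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average", axis=-1)


def _pearson_of_ranks(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    rx = rx - rx.mean(axis=-1, keepdims=True)
    ry = ry - ry.mean(axis=-1, keepdims=True)
    denom = np.sqrt((rx * rx).sum(axis=-1) * (ry * ry).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx * ry).sum(axis=-1) / denom
    return np.clip(r, -1.0, 1.0)


def _t_approx_p(r: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided p via the t approximation; flags |r| = 1 boundary cases."""
    r = np.asarray(r, dtype=float)
    at_bound = np.isclose(np.abs(r), 1.0)
    safe_r = np.where(at_bound, 0.0, r)
    t = safe_r * np.sqrt((n - 2) / (1.0 - safe_r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(at_bound, np.nextafter(0.0, 1.0), p)
    # a two-sided p is capped at 1 and must stay positive for log-scale use
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return p, at_bound


def _exact_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Exact two-sided p by enumerating all n! permutations of one margin."""
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r_perm = _pearson_of_ranks(rx, ry[list(perm)])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def t_approx_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Spearman r at sample size n via the t approximation.

    Useful for consistency checks against published (r, p) pairs where r
    is only available rounded: evaluating the p at the rounding-interval
    endpoints brackets the p the original screen computed.
    """
    if n < 3:
        raise ValidationError(f"need n >= 3, got {n}")
    p, _ = _t_approx_p(np.array([float(r)]), n)
    return float(p[0])


def spearman(x, y, method: str = "t_approx") -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    Parameters
    ----------
    x, y
        Paired observation vectors of equal length n >= 3 with finite
        values. Ties are handled by average ranks.
    method
        ``"t_approx"`` (default) or ``"exact"`` (full permutation
        enumeration, only for n <= 8).

    Raises
    ------
    ValidationError
        For unequal lengths, n < 3, non-finite values, a constant input
        vector (rank correlation undefined), or ``method="exact"`` with
        n > 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError(f"need at least 3 paired observations, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input vector: rank correlation undefined")

    rx, ry = _rank(x), _rank(y)
    r = float(_pearson_of_ranks(rx, ry))

    if method == "t_approx":
        p, at_bound = _t_approx_p(np.array([r]), n)
        return SpearmanResult(r=r, p=float(p[0]), n=n, p_at_bound=bool(at_bound[0]))
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValidationError(
                f"exact permutation p allowed only for n <= {_EXACT_MAX_N}, got {n}"
            )
        return SpearmanResult(r=r, p=_exact_p(rx, ry, r), n=n)
    raise ValidationError(f"unknown p-value method {method!r}")


@dataclass
class ScreenResult:
    """All per-gene correlation records of one treatment's screen.

    ``records`` has one row per gene that produced a defined correlation:
    columns gene, r, p, q, n, sign ('+'/'-'; zero-r genes carry '' and are
    excluded from signed lists), p_at_bound. ``dropped`` maps gene ->
    diagnostic for genes excluded (constant expression, too few pairs).
    """

    treatment: str
    records: pd.DataFrame
    alpha: float = 0.05
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["p"] < self.alpha]

    def n_significant(self) -> int:
        return int((self.records["p"] < self.alpha).sum())


def _sorted_candidates(records: pd.DataFrame) -> pd.DataFrame:
    # sort key: p ascending, then |r| descending, then gene id
    key = records.assign(_absr=records["r"].abs())
    return key.sort_values(
        ["p", "_absr", "gene"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absr")


def screen(
    matrix,
    ic25_by_line,
    treatment: str,
    alpha: float = 0.05,
    p_method: str = "t_approx",
    min_pairs: int = MIN_PAIRS,
) -> ScreenResult:
    """Correlate every gene's expression with a treatment's IC25 values.

    Parameters
    ----------
    matrix
        An :class:`~rospanel.expression.ExpressionMatrix` (genes x cell
        lines, log2). The annotation filter is expected to have been
        applied; a warning is logged otherwise.
    ic25_by_line
        Mapping or Series cell line -> IC25. Lines with missing (NaN)
        IC25 are dropped; remaining lines are inner-joined with the
        matrix columns. Genes with missing expression values use
        pairwise-complete observations, subject to ``min_pairs``.
    """
    from rospanel.expression import ExpressionMatrix  # local: avoid cycle

    if isinstance(matrix, ExpressionMatrix):
        if not matrix.annotation_filtered:
            logger.warning("screen called on a matrix without annotation filtering")
        values = matrix.values
    else:
        values = matrix
    ic25 = pd.Series(ic25_by_line, dtype=float).dropna()
    shared = [c for c in values.columns if c in ic25.index]
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 cell lines shared between matrix and IC25 table, got {len(shared)}"
        )
    sub = values[shared]
    y = ic25[shared].to_numpy()
    if np.ptp(y) == 0:
        raise ValidationError("IC25 vector is constant: screen undefined")

    genes = sub.index.to_numpy()
    x = sub.to_numpy(dtype=float)
    dropped: dict[str, str] = {}

    complete = np.isfinite(x).all(axis=1)
    const = np.zeros(len(genes), dtype=bool)
    const[complete] = np.ptp(x[complete], axis=1) == 0

    rows: list[dict] = []
    # fast path: fully observed, non-constant genes, vectorized rank-then-Pearson
    fast = complete & ~const
    if fast.any():
        rx = _rank(x[fast])
        ry = _rank(y)[None, :]
        r_fast = _pearson_of_ranks(rx, np.broadcast_to(ry, rx.shape))
        if p_method == "t_approx":
            p_fast, bound_fast = _t_approx_p(r_fast, len(shared))
        else:
            p_fast = np.array(
                [spearman(xi, y, method=p_method).p for xi in x[fast]]
            )
            bound_fast = np.zeros(len(p_fast), dtype=bool)
        for g, r_, p_, b_ in zip(genes[fast], r_fast, p_fast, bound_fast):
            rows.append(
                {"gene": g, "r": float(r_), "p": float(p_), "n": len(shared),
                 "p_at_bound": bool(b_)}
            )
    for g in genes[const]:
        dropped[g] = "constant expression across lines"
    # slow path: genes with missing values -> pairwise-complete
    for g, xi in zip(genes[~complete], x[~complete]):
        mask = np.isfinite(xi)
        if mask.sum() < min_pairs:
            dropped[g] = f"only {int(mask.sum())} paired observations (< {min_pairs})"
            continue
        try:
            res = spearman(xi[mask], y[mask], method=p_method)
        except ValidationError as exc:
            dropped[g] = str(exc)
            continue
        rows.append(
            {"gene": g, "r": res.r, "p": res.p, "n": res.n, "p_at_bound": res.p_at_bound}
        )

    if dropped:
        logger.info(
            "screen[%s]: dropped %d genes (%s...)",
            treatment, len(dropped), next(iter(dropped.values())),
        )
    records = pd.DataFrame(rows, columns=["gene", "r", "p", "n", "p_at_bound"])
    if not records.empty:
        records["sign"] = np.where(records["r"] > 0, "+", np.where(records["r"] < 0, "-", ""))
        records["q"] = multipletests(records["p"].to_numpy(), method="fdr_bh")[1]
        records = _sorted_candidates(records).reset_index(drop=True)
    else:
        records["sign"] = pd.Series(dtype=str)
        records["q"] = pd.Series(dtype=float)
    return ScreenResult(treatment=treatment, records=records, alpha=alpha, dropped=dropped)


def select_top(result: ScreenResult, k: int, which: str) -> list[str]:
    """Top-k gene list from a screen, restricted to significant records.

    ``which`` is ``"positive"``, ``"negative"`` or ``"overall"``. Sorting
    is by p ascending, ties broken by |r| descending then gene id. If
    fewer than k significant genes are available the list is shorter
    (logged).
    """
    if which not in ("positive", "negative", "overall"):
        raise ValidationError(f"which must be positive/negative/overall, got {which!r}")
    cand = result.significant
    if which == "positive":
        cand = cand[cand["sign"] == "+"]
    elif which == "negative":
        cand = cand[cand["sign"] == "-"]
    cand = _sorted_candidates(cand)
    if len(cand) < k:
        logger.info(
            "select_top[%s/%s]: only %d significant genes available for k=%d",
            result.treatment, which, len(cand), k,
        )
    return cand["gene"].head(k).tolist()


def correlate_metabolism(baseline_by_line, ranks) -> SpearmanResult:
    """Spearman correlation of baseline metabolic activity vs sensitivity ranks.

    ``baseline_by_line`` is the per-line mean untreated-control
    fluorescence; ``ranks`` the per-line sensitivity ranks of one
    treatment. Lines are inner-joined; a constant baseline raises
    :class:`ValidationError` (degenerate, no record).
    """
    b = pd.Series(baseline_by_line, dtype=float).dropna()
    r = pd.Series(ranks, dtype=float).dropna()
    shared = b.index.intersection(r.index)
    if len(shared) < 3:
        raise ValidationError("need >= 3 shared cell lines")
    return spearman(b[shared].to_numpy(), r[shared].to_numpy())
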