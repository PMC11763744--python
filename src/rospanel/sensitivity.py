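"""Sensitivity ranking and cross-treatment comparison statistics.

Convention: rank 1 = most sensitive = lowest IC25; ties receive average
ranks, so each treatment's ranks sum to N(N+1)/2. Cross-treatment
agreement is measured by Spearman correlation of the IC25 vectors
(identical on ranks, by monotone invariance); per-line rank ratios and
rank sums summarize which lines are generally sensitive or resistant to
oxidant challenge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import rankdata

from rospanel.dose_response import dynamic_range
from rospanel.errors import ValidationError
from rospanel.screen import SpearmanResult, spearman

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-treatment IC25 vector with derived ranks and dynamic range."""

    treatment: str
    ic25_by_line: pd.Series
    ranks: pd.Series
    dynamic_range: float


def rank_sensitivity(ic25_by_line) -> pd.Series:
    """Ascending average-tie ranks of IC25 (1 = most sensitive).

    Missing values are dropped before ranking; at least two lines with
    finite IC25 are required.
    """
    vals = pd.Series(ic25_by_line, dtype=float).dropna()
    if len(vals) < 2:
        raise ValidationError("ranking needs >= 2 lines with non-missing IC25")
    ranks = pd.Series(rankdata(vals.to_numpy(), method="average"), index=vals.index)
    ranks.name = "rank"
    return ranks


def make_profile(treatment: str, ic25_by_line) -> SensitivityProfile:
    vals = pd.Series(ic25_by_line, dtype=float)
    return SensitivityProfile(
        treatment=treatment,
        ic25_by_line=vals,
        ranks=rank_sensitivity(vals),
        dynamic_range=dynamic_range(vals),
    )


def cross_treatment_correlation(
    profile1: SensitivityProfile, profile2: SensitivityProfile
) -> SpearmanResult:
    """Spearman r and two-sided p between two treatments' IC25 vectors.

    Lines are inner-joined; missing lines are dropped pairwise. At least
    3 shared lines are required.
    """
    a = profile1.ic25_by_line.dropna()
    b = profile2.ic25_by_line.dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared lines between {profile1.treatment} and "
            f"{profile2.treatment}, got {len(shared)}"
        )
    return spearman(a[shared].to_numpy(), b[shared].to_numpy())


def rank_ratio(profile1: SensitivityProfile, profile2: SensitivityProfile) -> pd.Series:
    """Per-line ratio rank(profile1) / rank(profile2), over shared lines."""
    shared = profile1.ranks.index.intersection(profile2.ranks.index)
    if shared.empty:
        raise ValidationError("no shared lines between profiles")
    out = profile1.ranks[shared] / profile2.ranks[shared]
    out.name = f"rank_{profile1.treatment}/rank_{profile2.treatment}"
    return out


def rank_sum(profiles: list[SensitivityProfile]) -> pd.Series:
    """Per-line sum of sensitivity ranks across treatments.

    Lines missing from any treatment's ranking are excluded (logged);
    a low sum marks a generally oxidant-sensitive line.
    """
    if len(profiles) < 2:
        raise ValidationError("rank_sum needs >= 2 profiles")
    shared = profiles[0].ranks.index
    union = profiles[0].ranks.index
    for p in profiles[1:]:
        shared = shared.intersection(p.ranks.index)
        union = union.union(p.ranks.index)
    excluded = union.difference(shared)
    if not excluded.empty:
        logger.info("rank_sum: excluded %d lines missing from some treatment", len(excluded))
    out = sum(p.ranks[shared] for p in profiles)
    out.name = "rank_sum"
    return out
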