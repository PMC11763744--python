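"""Overlap analysis of per-treatment top-k gene lists.

Gene identity for overlaps is the annotation symbol, upper-cased, by
exact string match (no alias resolution). Overlap significance uses the
upper-tail hypergeometric test against a shared universe — the number
of genes that survived the annotation filter in the screen, i.e. the
lists' true sampling frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from scipy.stats import hypergeom

from rospanel.errors import ValidationError


@dataclass(frozen=True)
class GeneSet:
    """A labelled gene list, e.g. one treatment's top-20 positives."""

    label: str
    members: frozenset[str]

    @classmethod
    def from_iterable(cls, label: str, genes) -> "GeneSet":
        return cls(label=label, members=frozenset(str(g).upper() for g in genes))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise/triple intersections and Venn region counts of gene sets."""

    universe_size: int | None
    #: (label1, label2) -> (intersection size, sorted members, hypergeometric p or None)
    pairwise: dict[tuple[str, str], tuple[int, list[str], float | None]]
    #: sorted members of the intersection of all sets
    full_intersection: list[str]
    #: for exactly 3 sets: region id ('100', '110', ..., '111') -> exclusive count
    venn_regions: dict[str, int] | None

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "pairwise": {
                f"{a} & {b}": {"size": k, "members": m, "p_hypergeom": p}
                for (a, b), (k, m, p) in self.pairwise.items()
            },
            "full_intersection": self.full_intersection,
            "venn_regions": self.venn_regions,
        }


def intersect(sets: list[GeneSet]) -> OverlapReport:
    """All pairwise intersections plus the full intersection (no p-values)."""
    return overlap_report(sets, universe_size=None)


def venn_counts(set1: GeneSet, set2: GeneSet, set3: GeneSet) -> dict[str, int]:
    """Exclusive counts of the 7 regions of a 3-set Venn diagram.

    Region ids are membership masks in set order: '100' = only set1,
    '110' = set1 and set2 but not set3, '111' = all three, etc. The
    counts sum to the size of the union.
    """
    a, b, c = set1.members, set2.members, set3.members
    regions = {
        "100": a - b - c,
        "010": b - a - c,
        "001": c - a - b,
        "110": (a & b) - c,
        "101": (a & c) - b,
        "011": (b & c) - a,
        "111": a & b & c,
    }
    return {k: len(v) for k, v in regions.items()}


def overlap_significance(k: int, m1: int, m2: int, universe: int) -> float:
    """Upper-tail hypergeometric p for an observed overlap.

    P(X >= k) where X is the overlap of a random m1-set and a fixed
    m2-set drawn without replacement from ``universe`` genes.
    Symmetric in (m1, m2).
    """
    if not (0 <= k <= min(m1, m2)):
        raise ValidationError(f"overlap k={k} inconsistent with set sizes {m1}, {m2}")
    if m1 > universe or m2 > universe:
        raise ValidationError(
            f"set sizes ({m1}, {m2}) exceed universe size {universe}"
        )
    return float(hypergeom.sf(k - 1, universe, m1, m2))


def overlap_report(sets: list[GeneSet], universe_size: int | None) -> OverlapReport:
    """Compare >= 2 gene sets: intersections, Venn regions, significance.

    With a ``universe_size``, each pairwise overlap gets an upper-tail
    hypergeometric p; Venn region counts are reported when exactly three
    sets are given.
    """
    if len(sets) < 2:
        raise ValidationError("overlap analysis needs >= 2 gene sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate set labels: {labels}")
    pairwise = {}
    for s1, s2 in combinations(sets, 2):
        inter = sorted(s1.members & s2.members)
        p = (
            overlap_significance(len(inter), len(s1), len(s2), universe_size)
            if universe_size is not None
            else None
        )
        pairwise[(s1.label, s2.label)] = (len(inter), inter, p)
    full = set(sets[0].members)
    for s in sets[1:]:
        full &= s.members
    venn = venn_counts(*sets) if len(sets) == 3 else None
    return OverlapReport(
        universe_size=universe_size,
        pairwise=pairwise,
        full_intersection=sorted(full),
        venn_regions=venn,
    )
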