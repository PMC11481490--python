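"""Four-taxon topology counts and the multispecies-coalescent null test.

With the outgroup fixed, every unordered triple of ingroup taxa defines a
quartet.  Each gene tree restricted to those four taxa supports exactly one
of three unrooted topologies, identified by which ingroup pair sits opposite
the outgroup.  Under the MSC with no gene flow, the two minor (discordant)
topologies of any quartet are equally probable, so the testable null is
*equal minor frequencies*: with minor counts m1 and m2,

    X^2 = (m1 - m2)^2 / (m1 + m2)  ~  chi-square(1)

(or an exact two-sided binomial test of m1 successes in m1+m2 trials at
p = 1/2).  Rejection at a small alpha flags the quartet as not explainable
by incomplete lineage sorting alone.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .treeio import PhyloTree, bipartitions

__all__ = [
    "QuartetResult",
    "enumerate_quartets",
    "quartet_topology",
    "quartet_counts",
    "msc_test",
    "simplex_coords",
    "evaluate_quartets",
    "quartet_summary",
]

#: equilateral reference triangle: vertices for pair12, pair13, pair23
_V1 = (0.0, 0.0)
_V2 = (1.0, 0.0)
_V3 = (0.5, math.sqrt(3.0) / 2.0)


@dataclass
class QuartetResult:
    """Counts and MSC-test outcome for one four-taxon set.

    ``n1``, ``n2``, ``n3`` count gene trees in which, respectively, the
    (sorted) first+second, first+third, and second+third ingroup taxa are
    sisters relative to the outgroup.
    """

    taxa: tuple[str, str, str]
    outgroup: str
    n1: int
    n2: int
    n3: int
    n_unresolved: int = 0
    n_missing: int = 0
    statistic: float = math.nan
    p_value: float = math.nan
    verdict: str = "undetermined"
    x: float = math.nan
    y: float = math.nan

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2 + self.n3


def enumerate_quartets(taxa, outgroup: str) -> list[tuple[tuple[str, str, str], str]]:
    """All C(n, 3) ingroup triples, each paired with the fixed outgroup,
    in deterministic sorted order."""
    taxa = sorted(taxa)
    if outgroup in taxa:
        raise ValueError(f"outgroup {outgroup!r} must not be an ingroup taxon")
    if len(taxa) < 3:
        raise ValueError("need at least 3 ingroup taxa")
    return [(trip, outgroup) for trip in itertools.combinations(taxa, 3)]


def _tree_splits(tree: PhyloTree) -> tuple[frozenset[str], list[frozenset[str]]]:
    """A tree's leaf set and the canonical sides of its non-trivial splits."""
    return tree.leaf_names(), [bp.side for bp in bipartitions(tree)]


def _split_quartet(
    leaves: frozenset[str],
    sides: list[frozenset[str]],
    trio: tuple[str, str, str],
    outgroup: str,
) -> int | None:
    t1, t2, t3 = trio
    four = frozenset((t1, t2, t3, outgroup))
    for side in sides:
        inside = side & four
        if len(inside) == 2:
            # the sister pair is the side of the induced split away from the outgroup
            pair = inside if outgroup not in inside else four - inside
            if pair == {t1, t2}:
                return 0
            if pair == {t1, t3}:
                return 1
            return 2
    return None


def quartet_topology(
    tree: PhyloTree, trio: tuple[str, str, str], outgroup: str
) -> int | None:
    """Which ingroup pair is sister in ``tree`` restricted to the four taxa.

    Returns 0/1/2 for pair (t1,t2)/(t1,t3)/(t2,t3) with the trio sorted, or
    ``None`` if the restriction is a star (no 2|2 split separates the four).
    """
    leaves, sides = _tree_splits(tree)
    return _split_quartet(leaves, sides, tuple(sorted(trio)), outgroup)


def _count_from_splits(
    splits, trio: tuple[str, str, str], outgroup: str
) -> QuartetResult:
    four = frozenset(trio) | {outgroup}
    counts = [0, 0, 0]
    unresolved = missing = 0
    for leaves, sides in splits:
        if not four <= leaves:
            missing += 1
            continue
        k = _split_quartet(leaves, sides, trio, outgroup)
        if k is None:
            unresolved += 1
        else:
            counts[k] += 1
    return QuartetResult(
        taxa=trio,
        outgroup=outgroup,
        n1=counts[0],
        n2=counts[1],
        n3=counts[2],
        n_unresolved=unresolved,
        n_missing=missing,
    )


def quartet_counts(
    gene_trees, trio: tuple[str, str, str], outgroup: str
) -> QuartetResult:
    """Tally the three quartet topologies over ``gene_trees``.

    Trees lacking any of the four taxa are skipped (``n_missing``); trees
    whose restriction is unresolved support no topology (``n_unresolved``).
    """
    trio = tuple(sorted(trio))  # type: ignore[assignment]
    return _count_from_splits((_tree_splits(t) for t in gene_trees), trio, outgroup)


def msc_test(
    counts: tuple[int, int, int], alpha: float = 1e-4, mode: str = "chi2"
) -> tuple[float, float, str]:
    """Equal-minor-frequencies test of the ILS-only null.

    The largest count is the major topology; the remaining two are compared
    with a chi-square (default) or exact binomial test at p = 1/2.  Zero
    minor counts cannot reject (p = 1).  A tie for the major count is
    resolved conservatively toward the null: every admissible major choice is
    evaluated and the largest p-value reported.  Returns
    ``(statistic, p_value, verdict)``.
    """
    if mode not in ("chi2", "exact"):
        raise ValueError(f"unknown test mode {mode!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n1, n2, n3 = counts
    if min(counts) < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 + n3 == 0:
        return math.nan, math.nan, "undetermined"

    best: tuple[float, float] | None = None
    top = max(counts)
    for major in range(3):
        if counts[major] != top:
            continue
        m1, m2 = (counts[k] for k in range(3) if k != major)
        if m1 + m2 == 0:
            stat, p = 0.0, 1.0
        elif mode == "chi2":
            stat = (m1 - m2) ** 2 / (m1 + m2)
            p = float(stats.chi2.sf(stat, df=1))
        else:
            res = stats.binomtest(m1, m1 + m2, 0.5)
            stat, p = float(m1), float(res.pvalue)
        if best is None or p > best[1]:
            best = (stat, p)
    stat, p = best  # type: ignore[misc]
    verdict = "rejected" if p < alpha else "ILS_consistent"
    return stat, p, verdict


def simplex_coords(counts: tuple[int, int, int]) -> tuple[float, float]:
    """Barycentric placement of the topology proportions in the reference
    equilateral triangle; equal counts map to the centroid."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("cannot place a quartet with zero counted trees")
    w1, w2, w3 = (c / total for c in counts)
    x = w1 * _V1[0] + w2 * _V2[0] + w3 * _V3[0]
    y = w1 * _V1[1] + w2 * _V2[1] + w3 * _V3[1]
    return x, y


def evaluate_quartets(
    gene_trees,
    ingroup_taxa,
    outgroup: str,
    alpha: float = 1e-4,
    mode: str = "chi2",
) -> list[QuartetResult]:
    """Enumerate, count, test, and place every quartet of ``ingroup_taxa``."""
    splits = [_tree_splits(t) for t in gene_trees]  # computed once, reused per quartet
    results = []
    for trio, out in enumerate_quartets(ingroup_taxa, outgroup):
        res = _count_from_splits(splits, trio, out)
        if res.n_total > 0:
            res.statistic, res.p_value, res.verdict = msc_test(
                (res.n1, res.n2, res.n3), alpha=alpha, mode=mode
            )
            res.x, res.y = simplex_coords((res.n1, res.n2, res.n3))
        results.append(res)
    return results


def quartet_summary(results: list[QuartetResult]) -> pd.DataFrame:
    """Fractions of quartets per verdict; fractions sum to 1."""
    if not results:
        raise ValueError("no quartet results to summarize")
    n = len(results)
    rows = []
    for verdict in ("ILS_consistent", "rejected", "undetermined"):
        c = sum(1 for r in results if r.verdict == verdict)
        rows.append({"verdict": verdict, "count": c, "fraction": c / n})
    return pd.DataFrame(rows)


def results_to_frame(results: list[QuartetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon1": r.taxa[0],
            "taxon2": r.taxa[1],
            "taxon3": r.taxa[2],
            "outgroup": r.outgroup,
            "n1": r.n1,
            "n2": r.n2,
            "n3": r.n3,
            "n_unresolved": r.n_unresolved,
            "n_missing": r.n_missing,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "verdict": r.verdict,
            "x": r.x,
            "y": r.y,
        }
        for r in results
    )
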