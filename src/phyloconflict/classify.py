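"""Gene-tree filtering, backbone classification, and branch-length statistics.

Implements the per-gene decision chain used to dissect discordance among
three radiating lineages (L1, L2, L3) rooted by an outgroup:

1. *consistency filter* -- a gene is kept only if two independent inference
   strategies produced the same unrooted topology;
2. *support filter* -- a gene is kept only if its bootstrap-support summary
   (mean by default) reaches a threshold, 80 by default;
3. *classification* -- after rerooting on the outgroup, a gene tree is TREE1
   if L1 and L2 are sisters (the species-tree backbone), TREE2 if L1 and L3
   are, TREE3 if L2 and L3 are, and UNCLASSIFIED whenever any lineage is
   non-monophyletic or the backbone is unresolved;
4. *branch statistics* -- the divergence segment between the ingroup MRCA
   (node1) and the sister-pair MRCA (node2), the cumulative tree length, and
   a per-gene evolutionary rate, compared across classes with Welch t-tests.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import (
    PhyloTree,
    TreeError,
    mean_support,
    mrca,
    reroot_on_leaf,
    rf_distance,
    total_tree_length,
)

__all__ = [
    "LineageMap",
    "TopologyClass",
    "GeneTreeRecord",
    "filter_consistent",
    "filter_support",
    "classify_topology",
    "divergence_branch_length",
    "evolutionary_rate",
    "compare_groups",
    "classification_summary",
    "build_records",
    "records_to_frame",
    "estimate_internal_branch",
]

VALID_LABELS = ("L1", "L2", "L3", "OUT")


class TopologyClass(str, enum.Enum):
    """Backbone class relative to the species tree ((L1,L2),L3)."""

    TREE1 = "TREE1"  # L1 + L2 sisters: concordant with the species tree
    TREE2 = "TREE2"  # L1 + L3 sisters
    TREE3 = "TREE3"  # L2 + L3 sisters
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class LineageMap:
    """Assignment of each taxon to one of L1, L2, L3 or OUT."""

    mapping: dict[str, str]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {t: l for t, l in self.mapping.items() if l not in VALID_LABELS}
        if bad:
            raise ValueError(f"invalid lineage labels: {bad}")
        for lab in ("L1", "L2", "L3"):
            if not self.taxa_for(lab):
                raise ValueError(f"lineage {lab} has no taxa")
        if not self.taxa_for("OUT"):
            raise ValueError("no outgroup taxon")

    def taxa_for(self, label: str) -> frozenset[str]:
        return frozenset(t for t, l in self.mapping.items() if l == label)

    @property
    def outgroup(self) -> frozenset[str]:
        return self.taxa_for("OUT")

    @property
    def ingroup(self) -> frozenset[str]:
        return frozenset(self.mapping) - self.outgroup

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.mapping)

    @classmethod
    def from_tsv(cls, path) -> "LineageMap":
        """Read a two-column ``taxon<TAB>label`` table; ``#`` lines are comments.

        A comment of the form ``# display L1=Arthrobotrys`` sets a display name.
        """
        mapping: dict[str, str] = {}
        display: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("# ").strip()
                    if body.startswith("display ") and "=" in body:
                        key, val = body[len("display "):].split("=", 1)
                        display[key.strip()] = val.strip()
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"expected 'taxon<TAB>label', got: {line!r}")
                taxon, label = parts[0].strip(), parts[1].strip()
                if taxon in mapping:
                    raise ValueError(f"taxon mapped twice: {taxon!r}")
                mapping[taxon] = label
        return cls(mapping, display)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# taxon\tlineage\n")
            for key, val in self.display_names.items():
                fh.write(f"# display {key}={val}\n")
            for taxon, label in sorted(self.mapping.items()):
                fh.write(f"{taxon}\t{label}\n")


@dataclass
class GeneTreeRecord:
    """Per-gene bundle: trees, filter status, class, branch statistics."""

    gene_id: str
    tree_a: PhyloTree
    tree_b: PhyloTree | None = None
    consistent: bool | None = None
    single_strategy: bool = False
    mean_support: float | None = None
    passes_support: bool | None = None
    topology_class: TopologyClass | None = None
    divergence_branch_length: float | None = None
    cumulative_length: float | None = None
    evolutionary_rate: float | None = None


# -- filters ----------------------------------------------------------------


def filter_consistent(tree_a: PhyloTree, tree_b: PhyloTree | None) -> tuple[bool, bool]:
    """``(consistent, single_strategy)``: topologies agree across strategies.

    With only one strategy available the gene passes and is flagged
    ``single_strategy``; branch lengths and supports never enter the
    comparison, only the unrooted topology does.
    """
    if tree_b is None:
        return True, True
    return rf_distance(tree_a, tree_b) == 0, False


def filter_support(
    tree: PhyloTree, threshold: float = 80.0, statistic: str = "mean"
) -> bool:
    """True iff the support summary reaches ``threshold`` (kept at equality)."""
    vals = [
        nd.support
        for nd in tree.internal_nodes(exclude_root=True)
        if nd.support is not None
    ]
    if not vals:
        raise TreeError("tree carries no supports; cannot apply the support filter")
    if statistic == "mean":
        stat = sum(vals) / len(vals)
    elif statistic == "median":
        stat = float(np.median(vals))
    elif statistic == "minimum":
        stat = min(vals)
    else:
        raise ValueError(f"unknown support statistic {statistic!r}")
    return stat >= threshold


# -- classification ----------------------------------------------------------


def _rooted_on_outgroup(tree: PhyloTree, lm: LineageMap) -> PhyloTree | None:
    """Reroot on the outgroup; None if several OUT taxa are non-monophyletic."""
    out = sorted(lm.outgroup)
    rooted = reroot_on_leaf(tree, out[0])
    if len(out) > 1:
        sets = rooted.leaf_sets()
        want = frozenset(out)
        if not any(sets[id(nd)] == want for nd in rooted.postorder()):
            return None
    return rooted


def classify_topology(tree: PhyloTree, lm: LineageMap) -> TopologyClass:
    """Backbone class of a gene tree after rooting on the outgroup.

    UNCLASSIFIED whenever any ingroup lineage is non-monophyletic or the three
    lineage ancestors form an unresolved backbone; otherwise determined by
    which two lineages are sisters relative to the third.  Invariant to child
    order and branch lengths.
    """
    missing = lm.taxa - tree.leaf_names()
    extra = tree.leaf_names() - lm.taxa
    if missing or extra:
        raise TreeError(
            f"tree/lineage-map mismatch; missing from tree: {sorted(missing)}, "
            f"unmapped: {sorted(extra)}"
        )
    rooted = _rooted_on_outgroup(tree, lm)
    if rooted is None:
        return TopologyClass.UNCLASSIFIED
    sets = rooted.leaf_sets()
    clades = {sets[id(nd)] for nd in rooted.postorder()}
    groups = {lab: lm.taxa_for(lab) for lab in ("L1", "L2", "L3")}
    for g in groups.values():
        if len(g) > 1 and g not in clades:
            return TopologyClass.UNCLASSIFIED
    if groups["L1"] | groups["L2"] in clades:
        return TopologyClass.TREE1
    if groups["L1"] | groups["L3"] in clades:
        return TopologyClass.TREE2
    if groups["L2"] | groups["L3"] in clades:
        return TopologyClass.TREE3
    return TopologyClass.UNCLASSIFIED


_SISTERS = {
    TopologyClass.TREE1: ("L1", "L2"),
    TopologyClass.TREE2: ("L1", "L3"),
    TopologyClass.TREE3: ("L2", "L3"),
}


def divergence_branch_length(tree: PhyloTree, lm: LineageMap) -> float:
    """Path length from the ingroup MRCA (node1) to the sister-pair MRCA (node2).

    Equals the single internal backbone branch on a binary tree; on trees with
    intermediate nodes it is the node1-to-node2 path sum.  Raises on
    UNCLASSIFIED trees, where no sister pair exists.
    """
    cls = classify_topology(tree, lm)
    if cls is TopologyClass.UNCLASSIFIED:
        raise TreeError("divergence branch length undefined for UNCLASSIFIED trees")
    rooted = _rooted_on_outgroup(tree, lm)
    assert rooted is not None
    la, lb = _SISTERS[cls]
    node1 = mrca(rooted, lm.ingroup)
    node2 = mrca(rooted, lm.taxa_for(la) | lm.taxa_for(lb))
    total = 0.0
    nd = node2
    while nd is not node1:
        if nd.length is None:
            raise TreeError("branch length missing on the divergence path")
        total += nd.length
        nd = nd.parent
        if nd is None:  # pragma: no cover - node1 is an ancestor by construction
            raise TreeError("node1 is not an ancestor of node2")
    return total


def evolutionary_rate(tree: PhyloTree, method: str = "total_per_leaf") -> float:
    """Per-gene rate proxy: total tree length, optionally per leaf (default)."""
    total = total_tree_length(tree)
    if method == "total_per_leaf":
        return total / tree.n_leaves
    if method == "total":
        return total
    raise ValueError(f"unknown rate method {method!r}")


# -- group statistics and summaries ------------------------------------------


def compare_groups(values: dict[str, list[float]], conf: float = 0.95) -> pd.DataFrame:
    """Welch two-sided t-test for every pair of groups with n >= 2.

    Returns one row per pair with the statistic, p-value, group means and
    confidence intervals; pairs with an undersized group are skipped and
    reported with NaN statistics.
    """
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(values.items(), 2):
        row: dict = {"group_a": na, "group_b": nb, "n_a": len(va), "n_b": len(vb)}
        for tag, v in (("a", va), ("b", vb)):
            if len(v) >= 2:
                m = float(np.mean(v))
                half = stats.t.ppf((1 + conf) / 2, len(v) - 1) * stats.sem(v)
                row[f"mean_{tag}"] = m
                row[f"ci_low_{tag}"], row[f"ci_high_{tag}"] = m - half, m + half
            else:
                row[f"mean_{tag}"] = float(np.mean(v)) if v else math.nan
                row[f"ci_low_{tag}"] = row[f"ci_high_{tag}"] = math.nan
        if len(va) >= 2 and len(vb) >= 2:
            if np.var(va) == 0 and np.var(vb) == 0 and np.mean(va) == np.mean(vb):
                row["statistic"], row["p_value"] = 0.0, 1.0
            else:
                res = stats.ttest_ind(va, vb, equal_var=False)
                row["statistic"], row["p_value"] = float(res.statistic), float(res.pvalue)
        else:
            row["statistic"] = row["p_value"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_records(
    genes: list[tuple[str, PhyloTree, PhyloTree | None]],
    lm: LineageMap,
    support_threshold: float = 80.0,
    support_statistic: str = "mean",
    rate_method: str = "total_per_leaf",
) -> list[GeneTreeRecord]:
    """Run the full filter/classify/measure chain over ``(id, tree_a, tree_b)``.

    Classification and branch statistics are computed only for genes passing
    both filters, mirroring the staged accounting of the analysis.
    """
    records = []
    for gene_id, tree_a, tree_b in genes:
        rec = GeneTreeRecord(gene_id, tree_a, tree_b)
        rec.consistent, rec.single_strategy = filter_consistent(tree_a, tree_b)
        try:
            rec.mean_support = mean_support(tree_a)
            rec.passes_support = filter_support(
                tree_a, support_threshold, support_statistic
            )
        except TreeError:
            rec.mean_support = None
            rec.passes_support = None
        if not rec.consistent or rec.passes_support is False:
            records.append(rec)
            continue
        rec.topology_class = classify_topology(tree_a, lm)
        try:  # length statistics are undefined for trees without branch lengths
            rec.cumulative_length = total_tree_length(tree_a)
            rec.evolutionary_rate = evolutionary_rate(tree_a, rate_method)
            if rec.topology_class is not TopologyClass.UNCLASSIFIED:
                rec.divergence_branch_length = divergence_branch_length(tree_a, lm)
        except TreeError:
            pass
        records.append(rec)
    return records


def records_to_frame(records: list[GeneTreeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": r.gene_id,
            "consistent": r.consistent,
            "mean_support": r.mean_support,
            "passes_support": r.passes_support,
            "class": str(r.topology_class) if r.topology_class else None,
            "divergence_branch_length": r.divergence_branch_length,
            "cumulative_length": r.cumulative_length,
            "evolutionary_rate": r.evolutionary_rate,
        }
        for r in records
    )


def classification_summary(records: list[GeneTreeRecord]) -> pd.DataFrame:
    """Counts and proportions per class plus per-filter removal counts.

    Proportions are over classified (filter-passing) records and sum to 1.
    """
    if not records:
        raise ValueError("no records to summarize")
    removed_inconsistent = sum(1 for r in records if not r.consistent)
    removed_support = sum(
        1 for r in records if r.consistent and r.passes_support is False
    )
    classified = [r for r in records if r.topology_class is not None]
    rows = [
        {"category": "input", "count": len(records), "proportion": math.nan},
        {"category": "removed_inconsistent", "count": removed_inconsistent, "proportion": math.nan},
        {"category": "removed_low_support", "count": removed_support, "proportion": math.nan},
        {"category": "retained", "count": len(classified), "proportion": math.nan},
    ]
    n = len(classified)
    for cls in TopologyClass:
        c = sum(1 for r in classified if r.topology_class is cls)
        rows.append(
            {"category": str(cls), "count": c, "proportion": c / n if n else math.nan}
        )
    return pd.DataFrame(rows)


def estimate_internal_branch(discordant_fraction: float) -> float:
    """Invert the MSC discordance probability: t = -log(1.5 * p_discordant).

    ``p_discordant`` is the combined frequency of the two minor backbone
    classes, whose MSC expectation is (2/3)e^(-t).
    """
    if not 0 < discordant_fraction <= 2 / 3:
        raise ValueError("discordant fraction must lie in (0, 2/3]")
    return -math.log(1.5 * discordant_fraction)
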