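"""Multispecies-coalescent simulation on a three-lineage + outgroup species tree.

The generative model matches the null hypothesis tested by the analysis
modules: three ingroup lineages L1-L3 with backbone ((L1,L2),L3) plus an
outgroup, gene genealogies drawn under the standard multispecies coalescent
(within each species-tree branch, k lineages coalesce pairwise at rate
k(k-1)/2 per coalescent-time unit, truncated at the branch end), and an
optional introgression *pulse*: with probability ``gamma`` per gene, the
recipient lineage's ancestral lineages are relocated into the donor
population, emulating a hybrid edge of inheritance weight gamma.

Two simulators are provided:

* :func:`simulate_gene_trees` -- per-gene genealogies with coalescent-unit
  branch lengths, simulated bootstrap-like supports, and a truth table
  (backbone class, pulse indicator, internal-segment times) recorded from the
  coalescent merge events themselves, independently of the tree-classification
  code it is used to test.
* :func:`simulate_site_patterns` -- fully vectorised per-site four-taxon
  genealogies with exactly one mutation placed uniformly along the genealogy,
  yielding the biallelic columns the ABBA-BABA test consumes.

All randomness flows through one :class:`numpy.random.Generator` derived from
the config seed; identical config + seed gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .treeio import Node, PhyloTree

__all__ = [
    "MSCSimConfig",
    "SiteSimConfig",
    "simulate_gene_trees",
    "simulate_strategy_pair",
    "simulate_site_patterns",
    "random_nni",
    "species_tree_for",
    "expected_backbone_freqs",
    "make_fixture",
    "FIXTURE_PRESETS",
]

LINEAGES = ("L1", "L2", "L3")


def expected_backbone_freqs(t: float) -> tuple[float, float, float]:
    """MSC quartet/backbone topology probabilities for internal branch ``t``
    (coalescent units): (major, minor, minor) = (1-(2/3)e^-t, e^-t/3, e^-t/3)."""
    minor = math.exp(-t) / 3.0
    return (1.0 - 2.0 * minor, minor, minor)


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSCSimConfig:
    """Study conditions for gene-tree simulation.

    Times are in coalescent units, measured from the tips (time 0) rootward.
    ``lineage_depth`` is the L1/L2 split depth; the L3 split sits
    ``internal_t`` above it (this is the ILS-controlling internal branch);
    the root (outgroup join) sits ``outgroup_extra`` above that.
    """

    n1: int = 1
    n2: int = 1
    n3: int = 1
    n_genes: int = 100
    internal_t: float = 1.0
    lineage_depth: float = 3.0
    outgroup_extra: float = 2.0
    introgression: tuple[str, str, float] | None = None  # (donor, recipient, gamma)
    pulse_time: float = 0.0
    # supports: logistic in subtending branch length, plus Gaussian noise
    support_midpoint: float = 0.10
    support_scale: float = 0.05
    support_sd: float = 8.0
    # strategy-B perturbation: fraction of genes receiving one random NNI
    nni_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if min(self.n1, self.n2, self.n3) < 1:
            raise ValueError("each lineage needs >= 1 taxon")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("internal_t", "lineage_depth", "outgroup_extra", "pulse_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.introgression is not None:
            donor, recip, gamma = self.introgression
            if donor not in LINEAGES or recip not in LINEAGES or donor == recip:
                raise ValueError("introgression needs two distinct lineages among L1/L2/L3")
            if not 0.0 <= gamma <= 1.0:
                raise ValueError("gamma must lie in [0, 1]")
            ends = self.population_ends()
            if self.pulse_time >= min(ends[donor], ends[recip]):
                raise ValueError("pulse_time must precede both populations' end times")

    def population_ends(self) -> dict[str, float]:
        s12 = self.lineage_depth
        return {"L1": s12, "L2": s12, "L3": s12 + self.internal_t}

    @property
    def root_time(self) -> float:
        return self.lineage_depth + self.internal_t + self.outgroup_extra

    def taxa(self) -> dict[str, list[str]]:
        return {
            "L1": [f"L1_{i + 1}" for i in range(self.n1)],
            "L2": [f"L2_{i + 1}" for i in range(self.n2)],
            "L3": [f"L3_{i + 1}" for i in range(self.n3)],
            "OUT": ["OUT"],
        }


class _Lin:
    """One extant coalescent lineage: its subtree node, node time, tip set."""

    __slots__ = ("node", "time", "tips")

    def __init__(self, node: Node, time: float, tips: frozenset[str]):
        self.node = node
        self.time = time
        self.tips = tips


def _kingman(
    lins: list[_Lin],
    t0: float,
    t1: float,
    rng: np.random.Generator,
    merges: list[tuple[frozenset[str], float]],
) -> list[_Lin]:
    """Bounded pairwise coalescence among ``lins`` over [t0, t1)."""
    t = t0
    while len(lins) >= 2:
        k = len(lins)
        t += rng.exponential(2.0 / (k * (k - 1)))
        if t >= t1:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lins[i], lins[j]
        a.node.length = t - a.time
        b.node.length = t - b.time
        merged = _Lin(Node(children=[a.node, b.node]), t, a.tips | b.tips)
        merges.append((merged.tips, t))
        lins[min(i, j)] = merged
        lins.pop(max(i, j))
    return lins


def _truth_from_merges(
    merges: list[tuple[frozenset[str], float]],
    taxa: dict[str, list[str]],
) -> tuple[str, float, float]:
    """Backbone class and (pair-MRCA time, ingroup-MRCA time) from merge events.

    Clades of the genealogy *after* rerooting on the outgroup are exactly the
    merge tip-sets not containing the outgroup, plus complements of those that
    do.  This re-derives the classification from simulator bookkeeping alone.
    """
    tips1, tips2, tips3 = (frozenset(taxa[lab]) for lab in LINEAGES)
    out_tip = taxa["OUT"][0]
    all_tips = tips1 | tips2 | tips3 | {out_tip}
    ingroup = all_tips - {out_tip}

    clades: dict[frozenset[str], float] = {}
    for tips, t in merges:
        side = (all_tips - tips) if out_tip in tips else tips
        clades.setdefault(side, t)

    def mono(ts: frozenset[str]) -> bool:
        return len(ts) == 1 or ts in clades

    t_ing = clades.get(ingroup, math.nan)
    if not (mono(tips1) and mono(tips2) and mono(tips3)):
        return "UNCLASSIFIED", math.nan, t_ing
    for cls, pair in (("TREE1", tips1 | tips2), ("TREE2", tips1 | tips3), ("TREE3", tips2 | tips3)):
        if pair in clades:
            return cls, clades[pair], t_ing
    return "UNCLASSIFIED", math.nan, t_ing


def _simulate_one(
    cfg: MSCSimConfig, rng: np.random.Generator
) -> tuple[PhyloTree, str, bool, float, float]:
    taxa = cfg.taxa()
    ends = cfg.population_ends()
    merges: list[tuple[frozenset[str], float]] = []
    pops: dict[str, list[_Lin]] = {
        lab: [_Lin(Node(name=nm), 0.0, frozenset((nm,))) for nm in taxa[lab]]
        for lab in LINEAGES
    }
    starts = {lab: 0.0 for lab in LINEAGES}

    pulsed = False
    if cfg.introgression is not None:
        donor, recip, gamma = cfg.introgression
        if rng.random() < gamma:
            pulsed = True
            tm = cfg.pulse_time
            pops[donor] = _kingman(pops[donor], 0.0, tm, rng, merges)
            pops[recip] = _kingman(pops[recip], 0.0, tm, rng, merges)
            pops[donor] += pops[recip]
            pops[recip] = []
            starts[donor] = tm

    for lab in LINEAGES:
        pops[lab] = _kingman(pops[lab], starts[lab], ends[lab], rng, merges)

    s12 = cfg.lineage_depth
    s123 = s12 + cfg.internal_t
    anc12 = _kingman(pops["L1"] + pops["L2"], s12, s123, rng, merges)
    anc123 = _kingman(anc12 + pops["L3"], s123, cfg.root_time, rng, merges)
    out_lin = _Lin(Node(name=taxa["OUT"][0]), 0.0, frozenset(taxa["OUT"]))
    final = _kingman(anc123 + [out_lin], cfg.root_time, math.inf, rng, merges)
    assert len(final) == 1
    root = final[0].node

    tree = PhyloTree(root, unit="coalescent")
    # simulated supports: high for long subtending branches, diffuse for short
    for nd in tree.internal_nodes(exclude_root=True):
        p = 1.0 / (1.0 + math.exp(-((nd.length or 0.0) - cfg.support_midpoint) / cfg.support_scale))
        nd.support = float(min(100.0, max(0.0, 100.0 * p + rng.normal(0.0, cfg.support_sd))))

    cls, t_pair, t_ing = _truth_from_merges(merges, taxa)
    return tree, cls, pulsed, t_pair, t_ing


def simulate_gene_trees(cfg: MSCSimConfig, rng: np.random.Generator | None = None):
    """Simulate ``cfg.n_genes`` gene trees; returns ``(trees, truth)``.

    ``trees`` is a list of ``(gene_id, PhyloTree)``; ``truth`` is a
    :class:`pandas.DataFrame` with the per-gene backbone class as established
    by coalescent-event bookkeeping, whether the introgression pulse fired,
    the sister-pair and ingroup MRCA times, the true internal segment
    (``t_ingroup - t_pair``), and the total tree length.
    """
    import pandas as pd

    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trees = []
    rows = []
    for g in range(cfg.n_genes):
        gene_id = f"g{g + 1:05d}"
        tree, cls, pulsed, t_pair, t_ing = _simulate_one(cfg, rng)
        total = sum(nd.length for nd in tree.postorder() if nd is not tree.root)
        trees.append((gene_id, tree))
        rows.append(
            {
                "gene_id": gene_id,
                "true_class": cls,
                "introgressed": pulsed,
                "t_pair": t_pair,
                "t_ingroup": t_ing,
                "true_divergence": t_ing - t_pair if cls != "UNCLASSIFIED" else math.nan,
                "tree_length": total,
            }
        )
    return trees, pd.DataFrame(rows)


def random_nni(tree: PhyloTree, rng: np.random.Generator) -> PhyloTree:
    """Apply one nearest-neighbour interchange at a random internal edge.

    Moves are enumerated on internal edges of the *unrooted* topology, so the
    result always differs from the input as an unrooted tree.  A two-child
    root is not an unrooted node: the edge between its children is treated as
    one edge, exchanging a grandchild from each side.
    """
    t = tree.copy()
    moves: list[tuple[Node, Node]] = []
    for v in t.postorder():
        if v.is_leaf or v.parent is None:
            continue
        p = v.parent
        if p is t.root and len(t.root.children) == 2:
            sib = next(c for c in p.children if c is not v)
            if not sib.is_leaf and id(v) < id(sib):  # count the root edge once
                moves.extend((c, w) for c in v.children for w in sib.children)
        else:
            siblings = [c for c in p.children if c is not v]
            moves.extend((c, w) for c in v.children for w in siblings)
    if not moves:
        raise ValueError("tree has no internal edge to rearrange")
    x, y = moves[rng.integers(len(moves))]
    px, py = x.parent, y.parent
    px.children[px.children.index(x)] = y
    py.children[py.children.index(y)] = x
    return PhyloTree(t.root, unit=t.unit)


def simulate_strategy_pair(cfg: MSCSimConfig, rng: np.random.Generator | None = None):
    """Simulate gene trees plus a second-strategy copy with NNI noise.

    Strategy-B trees are copies of strategy-A trees; a fraction
    ``cfg.nni_fraction`` of genes receives one random NNI, emulating
    alignment/trimming-dependent inference error.  The truth table gains a
    ``perturbed`` column.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trees_a, truth = simulate_gene_trees(cfg, rng)
    perturbed = rng.random(len(trees_a)) < cfg.nni_fraction
    trees_b = []
    for (gene_id, tree), hit in zip(trees_a, perturbed):
        trees_b.append((gene_id, random_nni(tree, rng) if hit else tree.copy()))
    truth = truth.assign(perturbed=perturbed)
    return trees_a, trees_b, truth


def species_tree_for(cfg: MSCSimConfig) -> PhyloTree:
    """The species tree implied by the simulation config: backbone
    (((L1,L2),L3),OUT) with pectinate within-lineage clades."""

    def clade(names: list[str], stem: float) -> Node:
        nd = Node(name=names[0], length=0.1)
        for nm in names[1:]:
            nd = Node(children=[nd, Node(name=nm, length=0.1)], length=0.1, support=100.0)
        nd.length = stem
        return nd

    taxa = cfg.taxa()
    s12 = cfg.lineage_depth
    c12 = Node(
        children=[clade(taxa["L1"], s12), clade(taxa["L2"], s12)],
        length=cfg.internal_t,
        support=100.0,
    )
    ing = Node(
        children=[c12, clade(taxa["L3"], s12 + cfg.internal_t)],
        length=cfg.outgroup_extra,
        support=100.0,
    )
    root = Node(children=[ing, Node(name=taxa["OUT"][0], length=cfg.root_time)])
    return PhyloTree(root, unit="coalescent")


# ---------------------------------------------------------------------------
# site-pattern simulation (vectorised four-taxon genealogies)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteSimConfig:
    """Study conditions for biallelic site-pattern simulation.

    One haploid sequence per population P1, P2, P3, O on the species tree
    (((P1,P2):t2-t1, P3):t3-t2, O); times in coalescent units from the tips.
    With probability ``gamma`` per site the recipient lineage (direction
    ``"P3->P2"`` or ``"P3->P1"``) is relocated into P3 at ``pulse_time``.
    Each site's genealogy receives exactly one mutation placed uniformly
    along its total branch length.
    """

    n_sites: int = 50_000
    t1: float = 1.0
    t2: float = 2.0
    t3: float = 3.0
    gamma: float = 0.0
    direction: str = "P3->P2"
    pulse_time: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0.0 < self.t1 < self.t2 < self.t3:
            raise ValueError("need 0 < t1 < t2 < t3")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.direction not in ("P3->P2", "P3->P1"):
            raise ValueError("direction must be 'P3->P2' or 'P3->P1'")
        if not 0.0 <= self.pulse_time < min(self.t1, self.t2):
            raise ValueError("pulse_time must precede t1")


_A, _B, _C, _D = 1, 2, 4, 8
# pair lookup ordered so the first C(k,2) entries use indices < k
_PAIRS_I = np.array([0, 0, 1, 0, 1, 2])
_PAIRS_J = np.array([1, 2, 2, 3, 3, 3])


def _kingman_epoch(C, k, t, t_end, rng, ev_mask, ev_time, ev_n):
    n = C.shape[0]
    for _ in range(3):
        act = (k >= 2) & (t < t_end)
        if not act.any():
            break
        rate = k * (k - 1) / 2.0
        tau = t + rng.exponential(size=n) / np.maximum(rate, 1.0)
        fire = act & (tau < t_end)
        t = np.where(act, np.minimum(tau, t_end), t)
        rows = np.where(fire)[0]
        if rows.size == 0:
            continue
        npairs = (k[rows] * (k[rows] - 1)) // 2
        r = (rng.random(rows.size) * npairs).astype(np.int64)
        i, j = _PAIRS_I[r], _PAIRS_J[r]
        merged = C[rows, i] | C[rows, j]
        C[rows, i] = merged
        last = k[rows] - 1
        C[rows, j] = C[rows, last]
        C[rows, last] = 0
        k[rows] -= 1
        slot = ev_n[rows]
        ev_mask[rows, slot] = merged
        ev_time[rows, slot] = tau[rows]
        ev_n[rows] += 1
    return t


def simulate_site_patterns(cfg: SiteSimConfig, rng: np.random.Generator | None = None):
    """Simulate biallelic columns for P1, P2, P3, O; returns a GroupedAlignment."""
    from .dstat import GroupedAlignment

    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    recip_bit = _B if cfg.direction == "P3->P2" else _A
    other_bit = _A if recip_bit == _B else _B

    ev_mask = np.zeros((n, 3), dtype=np.uint8)
    ev_time = np.zeros((n, 3), dtype=np.float64)
    ev_n = np.zeros(n, dtype=np.int64)

    pulsed = rng.random(n) < cfg.gamma
    # pre-ingroup epochs: at most one coalescence is possible per site --
    # (recipient, P3) inside the donor population for pulsed sites over
    # [pulse_time, t2), or (P1, P2) over [t1, t2) otherwise.
    start = np.where(pulsed, cfg.pulse_time, cfg.t1)
    tau = start + rng.exponential(size=n)
    joined = tau < cfg.t2
    pre_mask = np.where(pulsed, recip_bit | _C, _A | _B).astype(np.uint8)
    rows = np.where(joined)[0]
    ev_mask[rows, 0] = pre_mask[rows]
    ev_time[rows, 0] = tau[rows]
    ev_n[rows] = 1

    C = np.zeros((n, 4), dtype=np.uint8)
    k = np.empty(n, dtype=np.int64)
    C[joined, 0] = pre_mask[joined]
    # the un-joined member of the ingroup trio
    C[joined, 1] = np.where(pulsed[joined], other_bit, _C)
    k[joined] = 2
    nj = ~joined
    C[nj, 0], C[nj, 1], C[nj, 2] = _A, _B, _C
    k[nj] = 3

    t = np.full(n, cfg.t2)
    t = _kingman_epoch(C, k, t, np.float64(cfg.t3), rng, ev_mask, ev_time, ev_n)

    C[np.arange(n), k] = _D
    k += 1
    t = np.maximum(t, cfg.t3)
    _kingman_epoch(C, k, t, np.inf, rng, ev_mask, ev_time, ev_n)
    assert (ev_n == 3).all()

    # branch lengths: four tip branches plus the two non-root internal branches
    tips = np.array([_A, _B, _C, _D], dtype=np.uint8)
    contains = (ev_mask[:, None, :] & tips[None, :, None]) != 0  # (n, 4, 3)
    first = contains.argmax(axis=2)  # events are time-ordered
    tip_len = np.take_along_axis(ev_time, first, axis=1)  # parent time; tips start at 0
    in01 = (ev_mask[:, 1] & ev_mask[:, 0]) == ev_mask[:, 0]
    ev0_len = np.where(in01, ev_time[:, 1], ev_time[:, 2]) - ev_time[:, 0]
    ev1_len = ev_time[:, 2] - ev_time[:, 1]

    b_mask = np.concatenate(
        [np.broadcast_to(tips, (n, 4)), ev_mask[:, :2]], axis=1
    )
    b_len = np.concatenate([tip_len, ev0_len[:, None], ev1_len[:, None]], axis=1)
    total = b_len.sum(axis=1)
    u = rng.random(n) * total
    choice = (np.cumsum(b_len, axis=1) < u[:, None]).sum(axis=1)
    derived_mask = b_mask[np.arange(n), np.minimum(choice, 5)]

    anc = rng.integers(0, 4, size=n)
    der = (anc + rng.integers(1, 4, size=n)) % 4
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {}
    for name, bit in zip(("P1", "P2", "P3", "O"), (_A, _B, _C, _D)):
        code = np.where((derived_mask & bit) != 0, der, anc)
        seqs[name] = bases[code].tobytes().decode("ascii")
    populations = {"P1": "P1", "P2": "P2", "P3": "P3", "O": "O"}
    return GroupedAlignment(sequences=seqs, populations=populations)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

FIXTURE_PRESETS: dict[str, dict] = {
    # small heterogeneous community: enough genes to run every stage fast
    "mini-ntf": dict(
        msc=MSCSimConfig(n1=3, n2=3, n3=2, n_genes=200, internal_t=0.5, nni_fraction=0.03),
        sites=SiteSimConfig(n_sites=20_000, gamma=0.0),
    ),
    # pure-ILS null at a moderately short internal branch
    "null-ils": dict(
        msc=MSCSimConfig(n1=1, n2=1, n3=1, n_genes=300, internal_t=0.5, nni_fraction=0.0),
        sites=SiteSimConfig(n_sites=20_000, gamma=0.0),
    ),
    # L3 -> L2 pulse of weight 0.3
    "introgression": dict(
        msc=MSCSimConfig(
            n1=1, n2=1, n3=1, n_genes=300, internal_t=0.5,
            introgression=("L3", "L2", 0.3), nni_fraction=0.0,
        ),
        sites=SiteSimConfig(n_sites=20_000, gamma=0.3, direction="P3->P2"),
    ),
}


def make_fixture(name: str, outdir, seed: int | None = None) -> dict[str, str]:
    """Write a self-contained fixture bundle; returns a map of role -> path.

    Bundle contents: two strategy gene-tree files, the species tree, a
    lineage map, a biallelic alignment with population map, the truth table,
    and a YAML echo of the configuration.
    """
    import os

    import pandas as pd
    import yaml

    from .dstat import write_popmap
    from .treeio import write_newick, write_tree_file

    if name not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(FIXTURE_PRESETS)}")
    preset = FIXTURE_PRESETS[name]
    msc: MSCSimConfig = preset["msc"]
    sites: SiteSimConfig = preset["sites"]
    if seed is not None:
        msc = replace(msc, seed=seed)
        sites = replace(sites, seed=seed + 1)

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "trees_a": "genetrees_a.nwk",
        "trees_b": "genetrees_b.nwk",
        "species_tree": "species.nwk",
        "lineage_map": "lineage_map.tsv",
        "alignment": "alignment.fasta",
        "popmap": "popmap.tsv",
        "truth": "truth.tsv",
        "config": "config.yaml",
    }.items()}

    trees_a, trees_b, truth = simulate_strategy_pair(msc)
    write_tree_file(paths["trees_a"], trees_a)
    write_tree_file(paths["trees_b"], trees_b)
    with open(paths["species_tree"], "w") as fh:
        fh.write(write_newick(species_tree_for(msc)) + "\n")
    taxa = msc.taxa()
    with open(paths["lineage_map"], "w") as fh:
        fh.write("# taxon\tlineage\n")
        for lab in ("L1", "L2", "L3", "OUT"):
            for nm in taxa[lab]:
                fh.write(f"{nm}\t{lab}\n")
    aln = simulate_site_patterns(sites)
    aln.to_fasta(paths["alignment"])
    write_popmap(paths["popmap"], aln.populations)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                "preset": name,
                "gene_trees": {**msc.__dict__, "introgression": list(msc.introgression) if msc.introgression else None},
                "sites": dict(sites.__dict__),
            },
            fh,
            sort_keys=False,
        )
    return paths
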