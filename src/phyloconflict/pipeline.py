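"""End-to-end orchestration: filters -> classification -> concordance ->
RF/MDS -> quartet MSC tests -> D-statistic -> branch-length comparisons.

Every stage writes its own TSV before the next starts, so any stage can be
re-run in isolation from the CLI and reproduced byte-for-byte; the combined
:class:`RunReport` keeps the filter accounting identity

    input = removed_inconsistent + removed_low_support + retained.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    GeneTreeRecord,
    LineageMap,
    TopologyClass,
    build_records,
    classification_summary,
    compare_groups,
    records_to_frame,
)
from .concordance import (
    annotate_species_tree_gcf,
    classical_mds,
    gene_concordance_factors,
    rf_matrix,
)
from .dstat import DStatResult, GroupedAlignment, abba_baba, read_popmap
from .quartets import evaluate_quartets, quartet_summary, results_to_frame
from .treeio import PhyloTree, parse_newick, read_tree_file, write_newick

logger = logging.getLogger("phyloconflict")

__all__ = ["PipelineConfig", "RunReport", "validate_inputs", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and knobs for one full analysis run."""

    gene_trees_a: str
    species_tree: str
    lineage_map: str
    gene_trees_b: str | None = None
    alignment: str | None = None
    popmap: str | None = None
    outdir: str = "phyloconflict_out"
    support_threshold: float = 80.0
    support_statistic: str = "mean"
    quartet_alpha: float = 1e-4
    quartet_trees: str = "discordant"  # "discordant" | "all"
    quartet_mode: str = "chi2"  # "chi2" | "exact"
    jackknife_blocks: int = 50
    mds_dimensions: int = 2
    gcf_highlight: float = 60.0
    rate_method: str = "total_per_leaf"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.quartet_alpha < 1:
            raise ValueError("quartet_alpha must lie in (0, 1)")
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must lie in [0, 100]")
        if self.quartet_trees not in ("discordant", "all"):
            raise ValueError("quartet_trees must be 'discordant' or 'all'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Combined accounting of one pipeline run."""

    n_input: int
    n_removed_inconsistent: int
    n_removed_low_support: int
    n_retained: int
    classification: pd.DataFrame
    gcf: pd.DataFrame | None = None
    quartets: pd.DataFrame | None = None
    quartet_fractions: pd.DataFrame | None = None
    dstat: DStatResult | None = None
    branch_tests: pd.DataFrame | None = None
    version: str = __version__
    config: dict = field(default_factory=dict)

    def check_accounting(self) -> None:
        total = (
            self.n_removed_inconsistent + self.n_removed_low_support + self.n_retained
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter accounting broken: {self.n_input} != "
                f"{self.n_removed_inconsistent} + {self.n_removed_low_support} + {self.n_retained}"
            )


def _load_gene_trees(cfg: PipelineConfig):
    trees_a = read_tree_file(cfg.gene_trees_a)
    trees_b = dict(read_tree_file(cfg.gene_trees_b)) if cfg.gene_trees_b else {}
    genes = []
    for name, tree in trees_a:
        genes.append((name, tree, trees_b.get(name)))
    return genes


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """All detectable problems, returned (not raised) without running analysis."""
    issues: list[str] = []
    for label, path in (
        ("gene trees (strategy A)", cfg.gene_trees_a),
        ("species tree", cfg.species_tree),
        ("lineage map", cfg.lineage_map),
        ("gene trees (strategy B)", cfg.gene_trees_b),
        ("alignment", cfg.alignment),
        ("population map", cfg.popmap),
    ):
        if path is not None and not os.path.exists(path):
            issues.append(f"{label} file not found: {path}")
    if issues:
        return issues

    try:
        lm = LineageMap.from_tsv(cfg.lineage_map)
    except Exception as exc:
        return issues + [f"lineage map unreadable: {exc}"]
    try:
        with open(cfg.species_tree) as fh:
            sp = parse_newick(fh.read())
    except Exception as exc:
        return issues + [f"species tree unreadable: {exc}"]
    if sp.leaf_names() != lm.taxa:
        missing = lm.taxa - sp.leaf_names()
        extra = sp.leaf_names() - lm.taxa
        issues.append(
            f"species tree vs lineage map: missing {sorted(missing)}, unmapped {sorted(extra)}"
        )
    try:
        trees_a = read_tree_file(cfg.gene_trees_a)
    except Exception as exc:
        return issues + [f"gene trees (A) unreadable: {exc}"]
    if not trees_a:
        issues.append("gene tree file (strategy A) holds no trees")
    for name, tree in trees_a:
        diff = tree.leaf_names() ^ lm.taxa
        if diff:
            issues.append(f"gene {name}: leaf set differs from lineage map by {sorted(diff)}")
            break  # one representative issue is enough
    if cfg.gene_trees_b:
        try:
            trees_b = read_tree_file(cfg.gene_trees_b)
        except Exception as exc:
            return issues + [f"gene trees (B) unreadable: {exc}"]
        if len(trees_b) != len(trees_a):
            issues.append(
                f"strategy files differ in gene count: A has {len(trees_a)}, B has {len(trees_b)}"
            )
        unmatched = {n for n, _ in trees_b} - {n for n, _ in trees_a}
        if unmatched:
            issues.append(f"strategy-B genes without a strategy-A partner: {sorted(unmatched)[:5]}")
    if (cfg.alignment is None) != (cfg.popmap is None):
        issues.append("alignment and population map must be given together")
    if cfg.alignment and cfg.popmap:
        try:
            GroupedAlignment.from_fasta(cfg.alignment, read_popmap(cfg.popmap))
        except Exception as exc:
            issues.append(f"alignment/popmap invalid: {exc}")
    return issues


def _write_tsv(df: pd.DataFrame, path: str, float_format="%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order, writing outputs under ``cfg.outdir``."""
    logging.basicConfig(level=cfg.log_level)
    os.makedirs(cfg.outdir, exist_ok=True)
    t0 = time.time()

    issues = validate_inputs(cfg)
    if issues:
        raise ValueError("invalid inputs:\n" + "\n".join(f"- {s}" for s in issues))

    lm = LineageMap.from_tsv(cfg.lineage_map)
    with open(cfg.species_tree) as fh:
        species = parse_newick(fh.read())
    genes = _load_gene_trees(cfg)
    logger.info("loaded %d genes (%.1fs)", len(genes), time.time() - t0)

    # stage 1+2: filters and classification
    records = build_records(
        genes, lm, cfg.support_threshold, cfg.support_statistic, cfg.rate_method
    )
    frame = records_to_frame(records)
    _write_tsv(frame, os.path.join(cfg.outdir, "genes.tsv"))
    summary = classification_summary(records)
    _write_tsv(summary, os.path.join(cfg.outdir, "classification_summary.tsv"))
    retained = [r for r in records if r.topology_class is not None]
    logger.info("classified %d retained genes (%.1fs)", len(retained), time.time() - t0)

    # stage 3: gene concordance factors on the species tree
    gcfs = gene_concordance_factors(
        species, [r.tree_a for r in retained], cfg.gcf_highlight
    )
    gcf_frame = pd.DataFrame(
        {
            "branch": "|".join(sorted(c.branch.side)),
            "n_decisive": c.n_decisive,
            "n_concordant": c.n_concordant,
            "gcf": c.gcf,
            "highlight": c.highlight,
        }
        for c in gcfs
    )
    _write_tsv(gcf_frame, os.path.join(cfg.outdir, "gcf.tsv"))
    with open(os.path.join(cfg.outdir, "species_gcf.nwk"), "w") as fh:
        fh.write(write_newick(annotate_species_tree_gcf(species, gcfs)) + "\n")

    # stage 4: RF matrix (species tree first) and classical MDS
    all_trees = [species] + [r.tree_a for r in retained]
    labels = ["species_tree"] + [r.gene_id for r in retained]
    mat = rf_matrix(all_trees)
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        os.path.join(cfg.outdir, "rf_matrix.tsv"), sep="\t"
    )
    mds = classical_mds(mat, k=cfg.mds_dimensions)
    mds_frame = mds.to_frame()
    mds_frame.index = labels
    mds_frame["is_species_tree"] = [lab == "species_tree" for lab in labels]
    mds_frame.to_csv(os.path.join(cfg.outdir, "mds.tsv"), sep="\t", float_format="%.6g")
    logger.info("gCF + RF/MDS done (%.1fs)", time.time() - t0)

    # stage 5: quartet MSC tests
    if cfg.quartet_trees == "discordant":
        pool = [r for r in retained if r.topology_class is not TopologyClass.TREE1]
    else:
        pool = retained
    outgroup = sorted(lm.outgroup)[0]
    qresults = evaluate_quartets(
        [r.tree_a for r in pool],
        sorted(lm.ingroup),
        outgroup,
        alpha=cfg.quartet_alpha,
        mode=cfg.quartet_mode,
    )
    _write_tsv(results_to_frame(qresults), os.path.join(cfg.outdir, "quartets.tsv"))
    qsummary = quartet_summary(qresults)
    _write_tsv(qsummary, os.path.join(cfg.outdir, "quartet_summary.tsv"))
    logger.info("quartets done: %d sets (%.1fs)", len(qresults), time.time() - t0)

    # stage 6 (optional): D-statistic
    dresult = None
    if cfg.alignment and cfg.popmap:
        aln = GroupedAlignment.from_fasta(cfg.alignment, read_popmap(cfg.popmap))
        dresult = abba_baba(aln, n_blocks=cfg.jackknife_blocks)
        drow = pd.DataFrame(
            [
                {
                    "abba_sum": dresult.abba_sum,
                    "baba_sum": dresult.baba_sum,
                    "D": dresult.d if dresult.d_defined else math.nan,
                    "n_informative_sites": dresult.n_informative_sites,
                    "n_blocks": dresult.n_blocks,
                    "jackknife_se": dresult.jackknife_se,
                    "Z": dresult.z if dresult.z_defined else math.nan,
                }
            ]
        )
        _write_tsv(drow, os.path.join(cfg.outdir, "dstat.tsv"))
    else:
        logger.info("no alignment given; skipping the D-statistic stage")

    # stage 7: branch-length statistics per class
    groups: dict[str, list[float]] = {}
    for which, attr in (
        ("divergence", "divergence_branch_length"),
        ("cumulative", "cumulative_length"),
        ("rate", "evolutionary_rate"),
    ):
        for r in retained:
            val = getattr(r, attr)
            if val is not None and r.topology_class is not None:
                groups.setdefault(f"{which}:{r.topology_class}", []).append(val)
    tests = []
    for which in ("divergence", "cumulative", "rate"):
        sub = {
            k.split(":", 1)[1]: v for k, v in groups.items() if k.startswith(which + ":")
        }
        if len(sub) >= 2:
            t = compare_groups(sub)
            t.insert(0, "quantity", which)
            tests.append(t)
    branch_tests = pd.concat(tests, ignore_index=True) if tests else None
    if branch_tests is not None:
        _write_tsv(branch_tests, os.path.join(cfg.outdir, "branch_tests.tsv"))

    report = RunReport(
        n_input=len(records),
        n_removed_inconsistent=sum(1 for r in records if not r.consistent),
        n_removed_low_support=sum(
            1 for r in records if r.consistent and r.passes_support is False
        ),
        n_retained=len(retained),
        classification=summary,
        gcf=gcf_frame,
        quartets=results_to_frame(qresults),
        quartet_fractions=qsummary,
        dstat=dresult,
        branch_tests=branch_tests,
        config=cfg.echo(),
    )
    report.check_accounting()
    with open(os.path.join(cfg.outdir, "report.json"), "w") as fh:
        json.dump(
            {
                "version": report.version,
                "config": report.config,
                "filters": {
                    "input": report.n_input,
                    "removed_inconsistent": report.n_removed_inconsistent,
                    "removed_low_support": report.n_removed_low_support,
                    "retained": report.n_retained,
                },
                "classification": summary.to_dict(orient="records"),
                "quartet_fractions": qsummary.to_dict(orient="records"),
                "dstat": None
                if dresult is None
                else {
                    "D": dresult.d,
                    "Z": dresult.z,
                    "n_informative_sites": dresult.n_informative_sites,
                },
            },
            fh,
            indent=2,
        )
    logger.info("run complete (%.1fs)", time.time() - t0)
    return report
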