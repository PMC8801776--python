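"""End-to-end orchestration: identification → classification → homeology →
duplication → evolution → expression, with a consistency-checked report.

All randomness flows from one master seed.  In synthetic mode the genome
comes from :mod:`polymads.synthetic`; in real mode the same stages run on
user-supplied FASTA/TSV inputs and profile seed alignments.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import duplication as dup
from . import evolution as evo
from . import expression as expr
from . import homeology as hom
from . import identify as ident
from . import phylo
from . import synthetic as syn

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    mode: str = "synthetic"
    seed: int = 0
    identity_threshold: float = 90.0
    min_coverage: float = 0.5
    support_threshold: float = 90.0
    expression_threshold: float = 0.0
    rate: float = evo.DEFAULT_RATE
    bootstrap_replicates: int = 100
    clustering: expr.ClusteringConfig = field(default_factory=expr.ClusteringConfig)
    outdir: Optional[str] = None
    # real-mode inputs
    proteins_fasta: Optional[str] = None
    cds_fasta: Optional[str] = None
    annotation_tsv: Optional[str] = None
    segments_tsv: Optional[str] = None
    expression_tsv: Optional[str] = None
    references_fasta: Optional[str] = None
    mads_seed_fasta: Optional[str] = None
    kbox_seed_fasta: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0 <= self.identity_threshold <= 100:
            raise ConfigurationError("identity threshold must be in [0, 100]")
        if not 0 <= self.support_threshold <= 100:
            raise ConfigurationError("support threshold must be in [0, 100]")
        if not 0 <= self.min_coverage <= 1:
            raise ConfigurationError("min coverage must be in [0, 1]")
        if self.rate <= 0:
            raise ConfigurationError("substitution rate must be positive")
        self.clustering.validate()
        if self.mode == "real":
            required = [
                self.proteins_fasta, self.cds_fasta, self.annotation_tsv,
                self.references_fasta, self.mads_seed_fasta, self.kbox_seed_fasta,
            ]
            for path in required:
                if path is None or not Path(path).exists():
                    raise ConfigurationError(f"missing required input file: {path}")


@dataclass
class Report:
    total_genes: int = 0
    pooled_candidates: int = 0
    union_candidates: int = 0
    superclade_counts: Dict[str, int] = field(default_factory=dict)
    subfamily_counts: Dict[str, int] = field(default_factory=dict)
    architecture_counts: Dict[str, int] = field(default_factory=dict)
    chromosome_counts: Dict[str, int] = field(default_factory=dict)
    chromosome_density: Dict[str, float] = field(default_factory=dict)
    balance_rows: List[dict] = field(default_factory=list)
    n_duplicate_pairs: int = 0
    n_duplicated_genes: int = 0
    dup_type_counts: Dict[str, int] = field(default_factory=dict)
    location_counts: Dict[str, int] = field(default_factory=dict)
    tandem_by_chromosome: Dict[str, int] = field(default_factory=dict)
    evolution_summary: Dict[str, dict] = field(default_factory=dict)
    expressed_count: int = 0
    not_expressed_count: int = 0
    expressed_fraction: float = 0.0
    superclade_nonexpressed_share: Dict[str, float] = field(default_factory=dict)
    cluster_sizes: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def consistency_check(report: Report) -> List[str]:
    """Partition identities over a report; returns the violated ones.

    Checks only sections that are populated, so it applies equally to a
    pipeline run and to externally tabulated counts.
    """
    violations: List[str] = []

    def check(name: str, total: int, parts: Sequence[int]) -> None:
        if total != sum(parts):
            violations.append(f"{name}: {total} != sum{tuple(parts)} = {sum(parts)}")

    if report.superclade_counts:
        check("superclades vs total", report.total_genes,
              list(report.superclade_counts.values()))
    if report.subfamily_counts:
        check("subfamilies vs total", report.total_genes,
              list(report.subfamily_counts.values()))
        m_subs = [v for k, v in report.subfamily_counts.items()
                  if k in phylo.M_SUBFAMILIES]
        mikc_subs = [v for k, v in report.subfamily_counts.items()
                     if k not in phylo.M_SUBFAMILIES]
        if report.superclade_counts.get("M") is not None and m_subs:
            check("M subfamilies vs M superclade",
                  report.superclade_counts["M"], m_subs)
        if report.superclade_counts.get("MIKC") is not None and mikc_subs:
            check("MIKC subfamilies vs MIKC superclade",
                  report.superclade_counts["MIKC"], mikc_subs)
    if report.architecture_counts:
        check("architectures vs total", report.total_genes,
              list(report.architecture_counts.values()))
    if report.chromosome_counts:
        check("chromosome counts vs total", report.total_genes,
              list(report.chromosome_counts.values()))
    for row in report.balance_rows:
        check(
            f"balance row {row['subfamily']}",
            row["total"],
            [row["balanced"], row["unbalanced"]],
        )
    if report.balance_rows:
        grand = sum(r["total"] + r.get("undetermined", 0) for r in report.balance_rows)
        if report.total_genes and grand != report.total_genes:
            violations.append(
                f"balance table covers {grand} genes, expected {report.total_genes}"
            )
    if report.dup_type_counts:
        check("dup types vs pair total", report.n_duplicate_pairs,
              list(report.dup_type_counts.values()))
    if report.location_counts:
        placed = sum(
            v for k, v in report.dup_type_counts.items() if k != "unplaced"
        ) if report.dup_type_counts else report.n_duplicate_pairs
        check("location categories vs placed pairs", placed,
              list(report.location_counts.values()))
    for clade, summary in report.evolution_summary.items():
        fracs = [summary.get("positive_pct"), summary.get("purifying_pct"),
                 summary.get("neutral_pct")]
        if all(f is not None for f in fracs) and abs(sum(fracs) - 100.0) > 1e-6:
            violations.append(f"selection fractions for {clade} do not sum to 100")
    if report.expressed_count or report.not_expressed_count:
        check("expression flags vs total", report.total_genes,
              [report.expressed_count, report.not_expressed_count])
    return violations


@dataclass
class PipelineResult:
    report: Report
    genome: Optional[syn.SyntheticGenome]
    assignments: Dict[str, phylo.SubfamilyAssignment]
    trees: Dict[str, phylo.Node]
    groups: List[hom.HomeologGroup]
    undetermined: List[str]
    balance: hom.BalanceReport
    calls: dup.DuplicationCalls
    estimates: Dict[Tuple[str, str], evo.EvolutionEstimate]
    expressed: expr.ExpressedReport
    clusters: expr.KMeansResult
    architectures: Dict[str, str]


def run_pipeline(config: PipelineConfig,
                 genome: Optional[syn.SyntheticGenome] = None) -> PipelineResult:
    """Run every stage and return the report plus all stage artifacts."""
    config.validate()
    t0 = time.time()
    if config.mode == "synthetic":
        if genome is None:
            spec = syn.default_spec(master_seed=config.seed)
            genome = syn.generate_genome(spec)
        annotation = genome.annotation
        proteins = genome.proteins
        cds = genome.cds
        references = genome.references
        mads_seed = genome.mads_seed_alignment
        kbox_seed = genome.kbox_seed_alignment
        segmap = dup.SegmentMap(
            dict(genome.spec.segment_breakpoints), dict(genome.spec.chromosome_lengths)
        )
        expression = genome.expression
    else:
        from .io import read_fasta, read_references

        proteins = read_fasta(config.proteins_fasta)
        cds = read_fasta(config.cds_fasta)
        annotation = pd.read_csv(config.annotation_tsv, sep="\t")
        references = read_references(config.references_fasta)
        mads_seed = list(read_fasta(config.mads_seed_fasta).values())
        kbox_seed = list(read_fasta(config.kbox_seed_fasta).values())
        segmap = dup.SegmentMap.from_tsv(config.segments_tsv) if config.segments_tsv else None
        expression = (
            pd.read_csv(config.expression_tsv, sep="\t", index_col=0)
            if config.expression_tsv else None
        )
    logger.info("inputs ready (%.1fs)", time.time() - t0)

    # --- stage 1: identification -----------------------------------------
    t0 = time.time()
    mads_profile = ident.build_pssm("MADS", ident.MADS_PFAM, mads_seed)
    kbox_profile = ident.build_pssm("KBOX", ident.KBOX_PFAM, kbox_seed)
    mads_profile.threshold = ident.calibrate_threshold_max(mads_profile, seed=config.seed)
    kbox_profile.threshold = ident.calibrate_threshold_max(kbox_profile, seed=config.seed + 1)

    scans: Dict[str, Dict[str, ident.DomainScan]] = {}
    for gid, prot in proteins.items():
        scans[gid] = {
            "MADS": ident.scan_domain(gid, prot, mads_profile),
            "KBOX": ident.scan_domain(gid, prot, kbox_profile),
        }
    mads_hits = sorted(g for g, s in scans.items() if s["MADS"].passed)
    kbox_hits = sorted(g for g, s in scans.items() if s["KBOX"].passed)
    descriptions = dict(zip(annotation["gene_id"], annotation.get("description", "")))
    keyword_hits = ident.keyword_search(descriptions)
    pool = ident.merge_candidates(
        {"MADS": mads_hits, "KBOX": kbox_hits}, keyword_hits
    )
    confidence = dict(zip(annotation["gene_id"], annotation["confidence"]))
    retained, _ = ident.filter_nonredundant(pool, confidence)
    architectures = {
        g: ident.classify_architecture(scans[g]["MADS"], scans[g]["KBOX"])
        for g in retained
    }
    logger.info("identification: %d retained of %d pooled (%.1fs)",
                len(retained), pool.pooled_total, time.time() - t0)

    # --- stage 2: classification ------------------------------------------
    # M-type and MIKC-type genes are aligned and built into separate trees;
    # their architectures differ enough that a joint alignment only blurs
    # the within-superclade signal the homeolog scan depends on.
    t0 = time.time()
    assignments = {
        g: phylo.assign_subfamily(g, proteins[g], references) for g in retained
    }
    trees: Dict[str, phylo.Node] = {}
    for clade_idx, clade in enumerate(sorted({a.superclade for a in assignments.values()})):
        members = [g for g in retained if assignments[g].superclade == clade]
        if len(members) < 3:
            trees[clade] = phylo.Node(
                children=[phylo.Node(name=g) for g in members]
            )
            continue
        msa = phylo.progressive_msa({g: proteins[g] for g in members})
        trees[clade] = phylo.bootstrap_support(
            msa, replicates=config.bootstrap_replicates,
            seed=config.seed + clade_idx,
        )
    logger.info("classification: %d trees over %d genes (%.1fs)", len(trees),
                len(retained), time.time() - t0)

    # --- stage 3 & 4: homeology + duplication ------------------------------
    t0 = time.time()
    anno_idx = annotation.set_index("gene_id")
    subgenome_of = {g: str(anno_idx.at[g, "subgenome"]) for g in retained}
    chromosome_of = {g: str(anno_idx.at[g, "chromosome"]) for g in retained}
    subfamily_of = {g: assignments[g].subfamily for g in retained}
    superclade_of = {g: assignments[g].superclade for g in retained}

    matrix = dup.identity_matrix({g: cds[g] for g in retained})
    prelim = dup.same_subgenome_duplicates(
        matrix, subgenome_of, config.identity_threshold, config.min_coverage
    )
    groups: List[hom.HomeologGroup] = []
    undetermined: List[str] = []
    for clade_tree in trees.values():
        clade_groups, clade_undet = hom.detect_homeolog_groups(
            clade_tree, subfamily_of, subgenome_of,
            support_threshold=config.support_threshold,
            duplicate_pairs=prelim,
        )
        groups.extend(clade_groups)
        undetermined.extend(clade_undet)
    undetermined.sort()
    calls = dup.call_duplicates(
        matrix, groups, subgenome_of,
        threshold=config.identity_threshold, min_coverage=config.min_coverage,
    )
    coords = {
        g: (chromosome_of[g], int(anno_idx.at[g, "start"]), int(anno_idx.at[g, "end"]))
        for g in retained
    }
    calls = dup.annotate_pairs(calls, chromosome_of, coords, segmap)
    pair_ids = [p.genes for p in calls.pairs]
    balance = hom.balance_report(groups, undetermined, subfamily_of, pair_ids)
    logger.info("homeology/duplication: %d groups, %d pairs (%.1fs)",
                len(groups), calls.n_pairs, time.time() - t0)

    # --- stage 5: evolution -------------------------------------------------
    t0 = time.time()
    estimates: Dict[Tuple[str, str], evo.EvolutionEstimate] = {}
    for p in calls.pairs:
        estimates[p.genes] = evo.estimate_pair(
            cds[p.gene_a], cds[p.gene_b], rate=config.rate
        )
    evolution_summary = evo.summarize_by_superclade(estimates, superclade_of)
    logger.info("evolution: %d estimates (%.1fs)", len(estimates), time.time() - t0)

    # --- stage 6: expression -------------------------------------------------
    t0 = time.time()
    if expression is None:
        raise ConfigurationError("no expression matrix available")
    expression = expression.loc[[g for g in expression.index if g in set(retained)]]
    expressed = expr.mark_expressed(expression, config.expression_threshold)
    clustering = expr.ClusteringConfig(
        k=min(config.clustering.k, expression.shape[0]),
        iterations=config.clustering.iterations,
        runs=config.clustering.runs,
        seed=config.seed,
    )
    clusters = expr.kmeans_cluster(expression, clustering)
    summary = expr.subfamily_expression_summary(
        expression, subfamily_of, superclade_of, expressed.flags, clusters.labels
    )
    logger.info("expression: %.0f%% expressed (%.1fs)",
                100 * expressed.expressed_fraction, time.time() - t0)

    # --- report ---------------------------------------------------------------
    report = Report(total_genes=len(retained))
    report.pooled_candidates = pool.pooled_total
    report.union_candidates = len(pool.union)
    for g in retained:
        report.superclade_counts[superclade_of[g]] = (
            report.superclade_counts.get(superclade_of[g], 0) + 1
        )
        report.subfamily_counts[subfamily_of[g]] = (
            report.subfamily_counts.get(subfamily_of[g], 0) + 1
        )
        report.architecture_counts[architectures[g]] = (
            report.architecture_counts.get(architectures[g], 0) + 1
        )
    retained_anno = annotation[annotation["gene_id"].isin(retained)]
    lengths = (dict(genome.spec.chromosome_lengths) if genome is not None
               else (segmap.lengths if segmap else {}))
    density = dup.chromosome_density(retained_anno, lengths) if lengths else None
    if density is not None:
        report.chromosome_counts = {
            r.chromosome: int(r.n_genes) for r in density.itertuples()
        }
        report.chromosome_density = {
            r.chromosome: float(r.genes_per_mbp) for r in density.itertuples()
        }
    report.balance_rows = [
        {
            "subfamily": r.subfamily, "total": r.total, "balanced": r.balanced,
            "unbalanced": r.unbalanced, "undetermined": r.undetermined,
            "duplications": r.duplications, "exception": r.exception,
        }
        for r in balance.rows
    ]
    report.n_duplicate_pairs = calls.n_pairs
    report.n_duplicated_genes = len(calls.nonredundant_genes)
    for p in calls.pairs:
        report.dup_type_counts[p.dup_type] = report.dup_type_counts.get(p.dup_type, 0) + 1
        if p.location_category:
            report.location_counts[p.location_category] = (
                report.location_counts.get(p.location_category, 0) + 1
            )
        if p.dup_type == "tandem":
            chrom = chromosome_of.get(p.gene_a, "U")
            report.tandem_by_chromosome[chrom] = (
                report.tandem_by_chromosome.get(chrom, 0) + 1
            )
    report.evolution_summary = evolution_summary
    n_expr = sum(1 for f in expressed.flags.values() if f)
    report.expressed_count = n_expr
    report.not_expressed_count = len(expressed.flags) - n_expr
    report.expressed_fraction = expressed.expressed_fraction
    report.superclade_nonexpressed_share = summary.superclade_nonexpressed_share
    for lab in clusters.labels.values():
        key = f"cluster_{lab}"
        report.cluster_sizes[key] = report.cluster_sizes.get(key, 0) + 1

    violations = consistency_check(report)
    if violations:
        logger.warning("report inconsistencies: %s", violations)

    result = PipelineResult(
        report=report, genome=genome, assignments=assignments, trees=trees,
        groups=groups, undetermined=undetermined, balance=balance, calls=calls,
        estimates=estimates, expressed=expressed, clusters=clusters,
        architectures=architectures,
    )
    if config.outdir:
        write_artifacts(result, config.outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.genome is not None:
        result.genome.write_outputs(outdir / "genome")
    with open(outdir / "report.json", "w") as fh:
        fh.write(result.report.to_json() + "\n")
    for clade, tree in result.trees.items():
        with open(outdir / f"tree_{clade}.nwk", "w") as fh:
            fh.write(tree.to_newick() + "\n")
    pd.DataFrame(
        [
            {
                "gene_id": a.gene_id, "superclade": a.superclade,
                "subfamily": a.subfamily, "nearest_reference": a.nearest_reference,
                "score": a.score,
                "ambiguous_with": ",".join(a.ambiguous_with),
            }
            for a in result.assignments.values()
        ]
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    pd.DataFrame(result.report.balance_rows).to_csv(
        outdir / "balance.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "gene_a": p.gene_a, "gene_b": p.gene_b, "identity": p.identity,
                "coverage": p.coverage, "dup_type": p.dup_type,
                "location_category": p.location_category or "",
                "boundary": p.boundary,
            }
            for p in result.calls.pairs
        ]
    ).to_csv(outdir / "duplicates.tsv", sep="\t", index=False)
    rows = []
    for (a, b), est in result.estimates.items():
        rows.append(
            {
                "gene_a": a, "gene_b": b, "S": est.S, "N": est.N,
                "Sd": est.Sd, "Nd": est.Nd, "Ka": est.ka, "Ks": est.ks,
                "omega": est.omega, "T_MYA": est.t_mya,
                "selection": est.selection_class,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "evolution.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "cluster": c} for g, c in sorted(result.clusters.labels.items())]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
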