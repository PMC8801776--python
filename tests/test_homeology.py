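"""Triad detection from supported clades and balance classification."""

import numpy as np
import pytest

from polymads import homeology as hom
from polymads import phylo


def make_group(members, support=98.0, subfamily="SEP"):
    return hom.HomeologGroup(
        subfamily=subfamily,
        members=[(g, sg) for g, sg in members],
        support=support,
    )


@pytest.mark.parametrize(
    "subgenomes,expected",
    [
        (("A", "B", "D"), "balanced"),
        (("A", "B"), "unbalanced"),
        (("A",), "unbalanced"),
        (("A", "B", "D", "A"), "balanced"),  # extra duplicate copy
        (("U", "U"), "undetermined"),
    ],
)
def test_balance_rules(subgenomes, expected):
    group = make_group([(f"g{i}", sg) for i, sg in enumerate(subgenomes)])
    assert hom.classify_balance(group) == expected


def _triad_tree(support=98.0):
    """((gA,gB),gD) with the inner edges carrying the given support."""
    ga, gb, gd = (phylo.Node(name=n, length=0.1) for n in ("gA", "gB", "gD"))
    inner = phylo.Node(children=[ga, gb], length=0.5, support=support)
    other = [phylo.Node(name=f"x{i}", length=2.0) for i in range(2)]
    triad = phylo.Node(children=[inner, gd], length=3.0, support=support)
    return phylo.Node(children=[triad, *other])


SUBFAM = {"gA": "SEP", "gB": "SEP", "gD": "SEP", "x0": "SVP", "x1": "SVP"}
SUBGEN = {"gA": "A", "gB": "B", "gD": "D", "x0": "A", "x1": "B"}


def test_supported_triad_detected_and_balanced():
    groups, undet = hom.detect_homeolog_groups(
        _triad_tree(support=98.0), SUBFAM, SUBGEN, reroot=False
    )
    sep = [g for g in groups if g.subfamily == "SEP"]
    assert len(sep) == 1
    assert sorted(sep[0].gene_ids) == ["gA", "gB", "gD"]
    assert sep[0].status == "balanced"


def test_low_support_members_undetermined():
    groups, undet = hom.detect_homeolog_groups(
        _triad_tree(support=85.0), SUBFAM, SUBGEN, reroot=False
    )
    assert not [g for g in groups if g.subfamily == "SEP"]
    assert {"gA", "gB", "gD"} <= set(undet)


def test_support_exactly_at_threshold_not_enough():
    groups, _ = hom.detect_homeolog_groups(
        _triad_tree(support=90.0), SUBFAM, SUBGEN, reroot=False
    )
    assert not [g for g in groups if g.subfamily == "SEP"]


def test_missing_subgenome_label_raises():
    with pytest.raises(hom.DataError):
        hom.detect_homeolog_groups(_triad_tree(), SUBFAM, {"gA": "A"}, reroot=False)


def test_threshold_monotone_never_resolves_more_genes():
    tree = _triad_tree(support=95.0)
    determined = []
    for thr in (80.0, 90.0, 94.0, 96.0, 99.0):
        groups, undet = hom.detect_homeolog_groups(
            tree, SUBFAM, SUBGEN, support_threshold=thr, reroot=False
        )
        determined.append({g for grp in groups for g in grp.gene_ids})
    for lo, hi in zip(determined[1:], determined):
        assert lo <= hi


def test_same_subgenome_duplicate_absorbed_via_exemption():
    # triad plus a tandem copy on subgenome A: one group of four
    ga, gb, gd, dup = (phylo.Node(name=n, length=0.1)
                       for n in ("gA", "gB", "gD", "gA2"))
    cherry = phylo.Node(children=[ga, dup], length=0.2, support=99.0)
    inner = phylo.Node(children=[cherry, gb], length=0.3, support=99.0)
    triad = phylo.Node(children=[inner, gd], length=3.0, support=99.0)
    root = phylo.Node(children=[triad, phylo.Node(name="x0", length=2.0)])
    subfam = {"gA": "SEP", "gA2": "SEP", "gB": "SEP", "gD": "SEP", "x0": "SVP"}
    subgen = {"gA": "A", "gA2": "A", "gB": "B", "gD": "D", "x0": "A"}
    groups, _ = hom.detect_homeolog_groups(
        root, subfam, subgen, duplicate_pairs=[("gA", "gA2")], reroot=False
    )
    sep = [g for g in groups if g.subfamily == "SEP"]
    assert len(sep) == 1 and len(sep[0].members) == 4
    assert sep[0].status == "balanced"
    # without the exemption the clade splits and the pair group survives
    groups2, undet2 = hom.detect_homeolog_groups(
        root, subfam, subgen, reroot=False
    )
    assert all(len(g.members) < 4 for g in groups2 if g.subfamily == "SEP")


def test_balance_report_table_semantics():
    groups = [
        make_group([("a1", "A"), ("b1", "B"), ("d1", "D")], subfamily="Malpha"),
        make_group([("a2", "A"), ("b2", "B")], subfamily="Malpha"),
        make_group([("a3", "A"), ("b3", "B"), ("d3", "D")], subfamily="AP3"),
    ]
    for g in groups:
        g.status = hom.classify_balance(g)
    subfam = {g: "Malpha" for g in ("a1", "b1", "d1", "a2", "b2", "u1")}
    subfam.update({g: "AP3" for g in ("a3", "b3", "d3")})
    report = hom.balance_report(
        groups, ["u1"], subfam, duplicate_pairs=[("a3", "b3")]
    )
    rows = {r.subfamily: r for r in report.rows}
    assert rows["Malpha"].total == 5
    assert rows["Malpha"].balanced == 3
    assert rows["Malpha"].unbalanced == 2
    assert rows["Malpha"].undetermined == 1
    assert rows["Malpha"].duplications == "Absent"
    # duplications despite fully balanced homeologs -> exception flag
    assert rows["AP3"].duplications == "Present" and rows["AP3"].exception


def test_table_one_style_pattern_totals():
    """A subfamily built like the survey's Malpha row: 33 members in
    balanced triads plus 20 members in unbalanced pairs -> 53/33/20."""
    from polymads import synthetic as syn

    spec = syn.GenomeSpec(
        subfamilies=("Malpha",),
        triad_configs=[["ABD"] * 11 + ["AB"] * 10],
        chromosome_lengths=syn.default_chromosomes(n_groups=2, length=30_000_000),
        master_seed=5,
        n_decoys_low=0, n_decoys_high=0, fraction_silent=0.0, k_true=3,
    )
    genome = syn.generate_genome(spec)
    assert len(genome.cds) == 53
    subfam = genome.truth.subfamily
    subgen = dict(zip(genome.annotation.gene_id, genome.annotation.subgenome))
    msa = phylo.progressive_msa(genome.proteins)
    tree = phylo.bootstrap_support(msa, replicates=100, seed=5)
    groups, undet = hom.detect_homeolog_groups(tree, subfam, subgen)
    report = hom.balance_report(groups, undet, subfam)
    (row,) = report.rows
    assert (row.total, row.balanced, row.unbalanced) == (53, 33, 20)
    assert row.undetermined == 0


def test_status_partition_on_pipeline_run(pipeline_result):
    groups = pipeline_result.groups
    undet = set(pipeline_result.undetermined)
    in_groups = [g for grp in groups for g in grp.gene_ids]
    assert len(in_groups) == len(set(in_groups))  # no gene in two groups
    assert not (set(in_groups) & undet)
    assert len(in_groups) + len(undet) == pipeline_result.report.total_genes
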