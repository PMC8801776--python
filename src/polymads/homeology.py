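"""Homeolog-group (triad) detection and balance classification.

A homeolog group is operationalized as the largest bootstrap-supported clade
whose leaves all carry one subfamily label and which holds at most one gene
per subgenome — genes linked by known same-subgenome duplicate pairs merge
into one count, so a triad carrying a tandem duplicate still forms a single
group.  Genes falling in no supported clade are undetermined, as are
groups whose members all sit on unplaced (U) chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .phylo import Node, midpoint_root

SUBGENOMES = ("A", "B", "D")


class DataError(ValueError):
    pass


@dataclass
class HomeologGroup:
    subfamily: str
    members: List[Tuple[str, str]]  # (gene_id, subgenome)
    support: float
    status: str = "undetermined"

    @property
    def gene_ids(self) -> List[str]:
        return [g for g, _ in self.members]

    @property
    def subgenomes(self) -> Set[str]:
        return {sg for _, sg in self.members if sg in SUBGENOMES}


def classify_balance(group: HomeologGroup) -> str:
    """balanced iff all of A, B, D are present; all-unplaced → undetermined."""
    if not group.members:
        raise DataError("empty homeolog group")
    present = group.subgenomes
    if not present:
        return "undetermined"
    return "balanced" if set(SUBGENOMES) <= present else "unbalanced"


def _pair_key(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def detect_homeolog_groups(
    tree: Node,
    subfamily_of: Mapping[str, str],
    subgenome_of: Mapping[str, str],
    support_threshold: float = 90.0,
    duplicate_pairs: Iterable[Tuple[str, str]] = (),
    reroot: bool = True,
) -> Tuple[List[HomeologGroup], List[str]]:
    """Scan a supported tree for homeolog groups.

    Returns ``(groups, undetermined gene ids)``.  The whole-tree clade
    counts as trivially supported (support 100); singleton leaves never form
    groups on their own.  ``duplicate_pairs`` lists known duplicate gene
    pairs whose same-subgenome members collapse into one homeolog count.
    """
    for leaf in tree.leaves():
        if leaf.name not in subgenome_of:
            raise DataError(f"leaf {leaf.name} has no subgenome label")
        if leaf.name not in subfamily_of:
            raise DataError(f"leaf {leaf.name} has no subfamily label")

    dup_edges: Dict[str, Set[str]] = {}
    for a, b in duplicate_pairs:
        dup_edges.setdefault(a, set()).add(b)
        dup_edges.setdefault(b, set()).add(a)

    root = midpoint_root(tree) if reroot else tree
    root.support = 100.0

    def subgenome_counts_ok(genes: Sequence[str]) -> bool:
        for sg in SUBGENOMES:
            here = [g for g in genes if subgenome_of[g] == sg]
            if len(here) <= 1:
                continue
            # merge genes connected by known duplicate pairs; count components
            remaining = set(here)
            components = 0
            while remaining:
                stack = [remaining.pop()]
                components += 1
                while stack:
                    g = stack.pop()
                    for nb in dup_edges.get(g, ()):
                        if nb in remaining:
                            remaining.remove(nb)
                            stack.append(nb)
            if components > 1:
                return False
        return True

    groups: List[HomeologGroup] = []
    undetermined: List[str] = []

    def walk(node: Node) -> None:
        genes = node.leaf_names()
        if node.is_leaf:
            undetermined.append(node.name)
            return
        subfams = {subfamily_of[g] for g in genes}
        supported = node.support is not None and node.support > support_threshold
        if supported and len(subfams) == 1 and subgenome_counts_ok(genes):
            group = HomeologGroup(
                subfamily=next(iter(subfams)),
                members=sorted((g, subgenome_of[g]) for g in genes),
                support=float(node.support),
            )
            group.status = classify_balance(group)
            groups.append(group)
            return
        for child in node.children:
            walk(child)

    walk(root)
    return groups, sorted(undetermined)


@dataclass
class BalanceRow:
    subfamily: str
    total: int
    balanced: int
    unbalanced: int
    undetermined: int
    duplications: str  # "Present" | "Absent"
    exception: bool = False


@dataclass
class BalanceReport:
    rows: List[BalanceRow] = field(default_factory=list)

    @property
    def totals(self) -> Tuple[int, int, int, int]:
        return (
            sum(r.total for r in self.rows),
            sum(r.balanced for r in self.rows),
            sum(r.unbalanced for r in self.rows),
            sum(r.undetermined for r in self.rows),
        )


def balance_report(
    groups: Sequence[HomeologGroup],
    undetermined_genes: Sequence[str],
    subfamily_of: Mapping[str, str],
    duplicate_pairs: Iterable[Tuple[str, str]] = (),
) -> BalanceReport:
    """Per-subfamily member counts plus duplication presence.

    ``total`` counts genes in balanced or unbalanced groups (the homeolog
    complement); undetermined members are tracked separately so that
    balanced + unbalanced + undetermined covers every assigned gene.  A
    subfamily with duplicate pairs but no unbalanced members gets the
    exception flag (duplications despite fully balanced homeologs).
    """
    dup_subfams: Set[str] = set()
    for a, b in duplicate_pairs:
        sa, sb = subfamily_of.get(a), subfamily_of.get(b)
        if sa is not None and sa == sb:
            dup_subfams.add(sa)

    counts: Dict[str, Dict[str, int]] = {}
    for subfam in sorted(set(subfamily_of.values())):
        counts[subfam] = {"balanced": 0, "unbalanced": 0, "undetermined": 0}
    for group in groups:
        bucket = group.status if group.status in ("balanced", "unbalanced") else "undetermined"
        counts[group.subfamily][bucket] += len(group.members)
    for gid in undetermined_genes:
        subfam = subfamily_of.get(gid)
        if subfam is not None:
            counts[subfam]["undetermined"] += 1

    report = BalanceReport()
    for subfam, c in counts.items():
        has_dups = subfam in dup_subfams
        report.rows.append(
            BalanceRow(
                subfamily=subfam,
                total=c["balanced"] + c["unbalanced"],
                balanced=c["balanced"],
                unbalanced=c["unbalanced"],
                undetermined=c["undetermined"],
                duplications="Present" if has_dups else "Absent",
                exception=has_dups and c["unbalanced"] == 0,
            )
        )
    return report
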