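"""Synthetic allohexaploid genome generator with known ground truth.

Emulates the inputs of a wheat-style MADS-box family survey: an annotation
table over A/B/D subgenome chromosomes, CDS and protein sequences whose
members carry a 58–60 residue MADS domain (MIKC-type genes add a K-box),
homeolog triads with configurable subgenome-presence patterns, planted
tandem/segmental duplications at target Ks and omega, a chromosome segment
map (R1/R2a/C/R2b/R3) and a log2-TPM expression matrix with planted cluster
structure plus an all-negative "silent" fraction.

Everything is driven by one master seed and is byte-reproducible.  The
codon mutation model draws from precomputed synonymous/nonsynonymous
single-nucleotide mutant sets, giving direct control over the realized
Ks and omega of each planted pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
SEGMENTS = ("R1", "R2a", "C", "R2b", "R3")

CANONICAL_SUBFAMILIES = (
    "Malpha", "Mbeta", "Mgamma",
    "AP1", "AP3", "PI", "AG_STK", "SEP", "AGL6", "AGL12", "AGL17",
    "Bsister", "MIKCstar", "OsMADS32", "SOC1", "SVP",
)
M_TYPE = frozenset({"Malpha", "Mbeta", "Mgamma"})


class ConfigurationError(ValueError):
    pass


class SequenceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# local codon tables (kept independent of the estimation code they exercise)

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = "*"


def _aa(codon: str) -> str:
    return _FORWARD[codon]


_SYN_MUTANTS: Dict[str, List[str]] = {}
_NONSYN_MUTANTS: Dict[str, List[str]] = {}
_SYN_SITES: Dict[str, float] = {}
for _codon, _a in _FORWARD.items():
    if _a == "*":
        continue
    syn, nonsyn = [], []
    s = 0.0
    for _pos in range(3):
        syn_here = 0
        nonstop_here = 0
        for _b in NUCLEOTIDES:
            if _b == _codon[_pos]:
                continue
            _m = _codon[:_pos] + _b + _codon[_pos + 1 :]
            if _aa(_m) == "*":
                continue
            nonstop_here += 1
            if _aa(_m) == _a:
                syn.append(_m)
                syn_here += 1
            else:
                nonsyn.append(_m)
        if nonstop_here:
            s += syn_here / nonstop_here
    _SYN_MUTANTS[_codon] = syn
    _NONSYN_MUTANTS[_codon] = nonsyn
    _SYN_SITES[_codon] = s

_CODONS_FOR_AA: Dict[str, List[str]] = {}
for _codon, _a in sorted(_FORWARD.items()):
    if _a != "*":
        _CODONS_FOR_AA.setdefault(_a, []).append(_codon)


# ---------------------------------------------------------------------------
# spec


@dataclass
class DuplicationEvent:
    subfamily: str
    mode: str  # "tandem" | "segmental"
    target_ks: float
    target_omega: float

    def validate(self) -> None:
        if self.mode not in ("tandem", "segmental"):
            raise ConfigurationError(f"unknown duplication mode {self.mode!r}")
        if self.target_ks < 0 or self.target_omega < 0:
            raise ConfigurationError("target_Ks and target_omega must be >= 0")


def default_chromosomes(n_groups: int = 7, length: int = 8_000_000) -> Dict[str, int]:
    return {
        f"{g}{sg}": length for g in range(1, n_groups + 1) for sg in "ABD"
    }


def default_breakpoints(lengths: Mapping[str, int]) -> Dict[str, Tuple[int, int, int, int]]:
    """R1|R2a|C|R2b|R3 boundaries at 25/40/60/75% of each chromosome."""
    return {
        chrom: tuple(int(round(f * ln)) for f in (0.25, 0.40, 0.60, 0.75))
        for chrom, ln in lengths.items()
    }


@dataclass
class GenomeSpec:
    """Configuration of one synthetic genome; defaults give the study
    conditions used throughout the test-suite: 16 canonical subfamilies,
    20 triad units (13 balanced, 7 missing one subgenome), 10 tandem and
    10 segmental duplications at Ks 0.04–0.05."""

    subfamilies: Sequence[str] = CANONICAL_SUBFAMILIES
    triad_configs: Sequence[Sequence[str]] = ()  # per subfamily: unit patterns
    duplication_events: Sequence[DuplicationEvent] = ()
    chromosome_lengths: Mapping[str, int] = field(default_factory=default_chromosomes)
    segment_breakpoints: Optional[Mapping[str, Tuple[int, int, int, int]]] = None
    master_seed: int = 0
    # divergence knobs (substitutions per synonymous site)
    triad_ks: float = 0.03
    triad_omega: float = 0.3
    unit_ks: float = 0.5
    unit_omega: float = 0.2
    subfamily_divergence: float = 0.18  # aa substitution rate vs domain consensus
    # decoys for the identification filters
    n_decoys_low: int = 4
    n_decoys_high: int = 2
    # expression
    n_conditions: int = 16
    k_true: int = 10
    fraction_silent: float = 0.43
    noise_sd: float = 0.3
    cluster_separation: float = 2.5

    def __post_init__(self) -> None:
        if not self.triad_configs:
            self.triad_configs = default_triad_configs(len(self.subfamilies))
        if self.segment_breakpoints is None:
            self.segment_breakpoints = default_breakpoints(self.chromosome_lengths)

    def validate(self) -> None:
        if not self.chromosome_lengths:
            raise ConfigurationError("at least one chromosome is required")
        if len(self.triad_configs) != len(self.subfamilies):
            raise ConfigurationError("triad_configs must match subfamilies")
        for patterns in self.triad_configs:
            for pat in patterns:
                if not pat or any(sg not in "ABD" for sg in pat):
                    raise ConfigurationError(f"invalid triad pattern {pat!r}")
        for chrom, bps in self.segment_breakpoints.items():
            ln = self.chromosome_lengths.get(chrom)
            if ln is None:
                raise ConfigurationError(f"breakpoints for unknown chromosome {chrom}")
            if len(bps) != 4 or list(bps) != sorted(bps) or len(set(bps)) != 4:
                raise ConfigurationError(f"{chrom}: breakpoints must be 4 strictly increasing")
            if bps[0] <= 0 or bps[-1] >= ln:
                raise ConfigurationError(f"{chrom}: breakpoints outside chromosome")
        names = set(self.subfamilies)
        for ev in self.duplication_events:
            ev.validate()
            if ev.subfamily not in names:
                raise ConfigurationError(f"duplication in unknown subfamily {ev.subfamily}")


def default_triad_configs(n_subfamilies: int) -> List[List[str]]:
    """20 homeolog units over 16 subfamilies: 13 balanced ABD triads plus 7
    unbalanced two-subgenome units concentrated in the expanded subfamilies."""
    base: List[List[str]] = [["ABD"] for _ in range(n_subfamilies)]
    # two-unit hosts: Malpha, Mgamma, AGL17, SEP
    for host, pat in zip((0, 2, 10, 7), ("AB", "AD", "BD", "AB")):
        if host < n_subfamilies:
            base[host].append(pat)
    # unbalanced-only subfamilies: Mbeta, Bsister, MIKCstar
    for host, pat in zip((1, 11, 12), ("AD", "BD", "AB")):
        if host < n_subfamilies:
            base[host] = [pat]
    return base


def default_duplication_events(subfamilies: Sequence[str] = CANONICAL_SUBFAMILIES) -> List[DuplicationEvent]:
    """10 tandem + 10 segmental planted duplications, Ks <= 0.05.

    Tandem events favour M-type subfamilies and segmental events MIKC-type
    expanded subfamilies, echoing the duplication landscape the pipeline is
    meant to resolve; a few pairs evolve under positive selection (omega 1.5).
    """
    tandem_hosts = ["Malpha", "Malpha", "Mbeta", "Mgamma", "Mgamma",
                    "AGL17", "MIKCstar", "SEP", "Bsister", "SOC1"]
    segmental_hosts = ["Malpha", "Mbeta", "Mgamma", "AGL17", "AGL17",
                       "MIKCstar", "SEP", "Bsister", "SOC1", "AP3"]
    omegas_t = [0.3, 1.5, 0.2, 0.5, 1.5, 0.3, 0.2, 0.3, 0.5, 0.2]
    omegas_s = [0.5, 0.3, 1.5, 0.2, 0.3, 0.5, 0.2, 0.3, 0.2, 0.5]
    events = [
        DuplicationEvent(sf, "tandem", 0.04, om)
        for sf, om in zip(tandem_hosts, omegas_t) if sf in subfamilies
    ]
    events += [
        DuplicationEvent(sf, "segmental", 0.05, om)
        for sf, om in zip(segmental_hosts, omegas_s) if sf in subfamilies
    ]
    return events


def default_spec(master_seed: int = 0, with_duplications: bool = True) -> GenomeSpec:
    spec = GenomeSpec(master_seed=master_seed)
    if with_duplications:
        spec.duplication_events = default_duplication_events(spec.subfamilies)
    return spec


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class TriadUnit:
    subfamily: str
    unit_id: str
    pattern: str
    members: Dict[str, List[str]]  # subgenome -> gene ids

    @property
    def gene_ids(self) -> List[str]:
        return [g for sg in sorted(self.members) for g in self.members[sg]]

    @property
    def balance(self) -> str:
        return "balanced" if set("ABD") <= set(self.members) else "unbalanced"


@dataclass
class PlantedDuplicate:
    source: str
    copy: str
    subfamily: str
    mode: str
    target_ks: float
    target_omega: float


@dataclass
class GroundTruth:
    subfamily: Dict[str, str]
    superclade: Dict[str, str]
    triads: List[TriadUnit]
    duplicates: List[PlantedDuplicate]
    segment: Dict[str, str]
    expression_labels: Dict[str, int]  # -1 marks silent genes
    decoys: List[str]

    def validate(self) -> None:
        family = set(self.subfamily)
        in_triads = {g for t in self.triads for g in t.gene_ids}
        dup_copies = {d.copy for d in self.duplicates}
        missing = family - in_triads - dup_copies
        if missing:
            raise AssertionError(f"genes outside triads and duplicates: {missing}")
        if in_triads & dup_copies:
            raise AssertionError("duplicate copies must not sit inside triads")


@dataclass
class SyntheticGenome:
    spec: GenomeSpec
    annotation: pd.DataFrame
    cds: Dict[str, str]
    proteins: Dict[str, str]
    truth: GroundTruth
    references: Dict[str, Tuple[str, str]]  # ref id -> (subfamily, protein)
    mads_seed_alignment: List[str]
    kbox_seed_alignment: List[str]
    expression: pd.DataFrame

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, outdir / "proteins.faa")
        write_fasta(self.cds, outdir / "cds.fna")
        write_fasta(
            {rid: seq for rid, (_, seq) in self.references.items()},
            outdir / "references_synthetic.faa",
        )
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        seg_rows = [
            {"chromosome": c, "b1": b[0], "b2": b[1], "b3": b[2], "b4": b[3],
             "length": self.spec.chromosome_lengths[c]}
            for c, b in sorted(self.spec.segment_breakpoints.items())
        ]
        pd.DataFrame(seg_rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        truth_rows = []
        for gid in sorted(self.truth.subfamily):
            truth_rows.append(
                {
                    "gene_id": gid,
                    "subfamily": self.truth.subfamily[gid],
                    "superclade": self.truth.superclade[gid],
                    "segment": self.truth.segment.get(gid, ""),
                    "expression_cluster": self.truth.expression_labels.get(gid, ""),
                }
            )
        pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# sequence machinery


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = []
    for aa in protein:
        if rng.random() < rate:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def reverse_translate(rng: np.random.Generator, protein: str, stop: bool = True) -> str:
    codons = [
        _CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))] for aa in protein
    ]
    return "".join(codons) + ("TAA" if stop else "")


def translate_cds(cds: str) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    aas = [_aa(c) for c in codons]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    if "*" in aas:
        raise SequenceError("internal stop codon")
    return "".join(aas)


def mutate_cds(
    cds: str,
    target_ks: float,
    target_omega: float,
    seed: int | np.random.Generator,
) -> str:
    """Mutate a CDS so NG86 estimates approach (target_Ks, target_omega).

    The expected synonymous and nonsynonymous difference counts are the
    Jukes–Cantor inverses of the targets times the sequence's synonymous and
    nonsynonymous site totals; actual counts are Poisson draws applied as
    categorical choices from each codon's precomputed synonymous or
    nonsynonymous (never stop-creating) single-nucleotide mutant sets.  A
    terminal stop codon is left untouched; the reading frame is preserved.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(cds) % 3:
        raise SequenceError("CDS length not divisible by 3")
    if target_ks < 0 or target_omega < 0:
        raise ConfigurationError("targets must be >= 0")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    terminal_stop = ""
    if codons and _aa(codons[-1]) == "*":
        terminal_stop = codons[-1]
        codons = codons[:-1]
    if any(_aa(c) == "*" for c in codons):
        raise SequenceError("internal stop codon in CDS")
    if not codons:
        return cds

    S = sum(_SYN_SITES[c] for c in codons)
    N = 3.0 * len(codons) - S
    p_syn = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ks))
    target_ka = target_omega * target_ks
    p_non = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ka))
    n_syn = int(rng.poisson(p_syn * S)) if target_ks > 0 else 0
    n_non = int(rng.poisson(p_non * N)) if target_ka > 0 else 0

    for kind, count in (("syn", n_syn), ("non", n_non)):
        table = _SYN_MUTANTS if kind == "syn" else _NONSYN_MUTANTS
        applied = 0
        attempts = 0
        while applied < count and attempts < 50 * (count + 1):
            attempts += 1
            idx = int(rng.integers(len(codons)))
            options = table[codons[idx]]
            if not options:
                continue
            codons[idx] = options[int(rng.integers(len(options)))]
            applied += 1
    return "".join(codons) + terminal_stop


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    genes: Sequence[str],
    k_true: int,
    seed: int | np.random.Generator,
    n_conditions: int = 16,
    fraction_silent: float = 0.0,
    noise_sd: float = 0.3,
    separation: float = 2.5,
    silent_weight: Optional[Mapping[str, float]] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Log2-TPM matrix with planted cluster structure.

    ``round(fraction_silent * n)`` genes are all-negative on the log2 scale
    (label −1); the rest belong to one of ``k_true`` clusters whose condition
    profiles sit on well-separated base levels (spacing ``separation``) with
    additive Gaussian noise, clipped into the expressed range [0.2, 7.89].
    ``silent_weight`` optionally biases which genes go silent.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = list(genes)
    if k_true < 1:
        raise ConfigurationError("k_true must be >= 1")
    if k_true > len(genes):
        raise ConfigurationError("k_true exceeds the number of genes")
    n_silent = int(round(fraction_silent * len(genes)))
    if silent_weight:
        w = np.array([silent_weight.get(g, 1.0) for g in genes], dtype=float)
        w = w / w.sum()
        silent_idx = rng.choice(len(genes), size=n_silent, replace=False, p=w)
    else:
        silent_idx = rng.choice(len(genes), size=n_silent, replace=False)
    silent = {genes[i] for i in silent_idx}

    conditions = [f"cond{c + 1:02d}" for c in range(n_conditions)]
    lo, hi = 0.2, 7.89
    base_levels = np.linspace(1.0, 1.0 + separation * max(k_true - 1, 1), k_true)
    centroids = np.clip(
        base_levels[:, None] + rng.uniform(-0.6, 0.6, size=(k_true, n_conditions)),
        lo + 0.2, hi - 0.2,
    )
    labels: Dict[str, int] = {}
    rows = np.empty((len(genes), n_conditions))
    cluster_cycle = 0
    for i, gene in enumerate(genes):
        if gene in silent:
            labels[gene] = -1
            rows[i] = rng.uniform(-4.0, -0.5, size=n_conditions)
        else:
            k = cluster_cycle % k_true
            cluster_cycle += 1
            labels[gene] = k
            noise = rng.normal(0.0, noise_sd, size=n_conditions) if noise_sd > 0 else 0.0
            rows[i] = np.clip(centroids[k] + noise, lo, hi)
    matrix = pd.DataFrame(rows, index=genes, columns=conditions)
    matrix.index.name = "gene_id"
    return matrix, labels


# ---------------------------------------------------------------------------
# genome generation


def _chrom_group(chrom: str) -> str:
    return chrom[:-1]


def _chrom_subgenome(chrom: str) -> str:
    return chrom[-1]


class _Placer:
    """Sequential, non-overlapping slot allocation inside segments."""

    def __init__(self, lengths: Mapping[str, int],
                 breakpoints: Mapping[str, Tuple[int, int, int, int]],
                 spacing: int = 12_000) -> None:
        self.lengths = lengths
        self.breakpoints = breakpoints
        self.spacing = spacing
        self.cursor: Dict[Tuple[str, str], int] = {}

    def bounds(self, chrom: str, segment: str) -> Tuple[int, int]:
        b = self.breakpoints[chrom]
        edges = [0, *b, self.lengths[chrom]]
        i = SEGMENTS.index(segment)
        return edges[i] + 1, edges[i + 1]

    def place(self, chrom: str, segment: str, gene_len: int) -> Tuple[int, int]:
        lo, hi = self.bounds(chrom, segment)
        key = (chrom, segment)
        start = self.cursor.get(key, lo)
        end = start + gene_len - 1
        if end > hi:
            raise ConfigurationError(
                f"segment {segment} of {chrom} overflowed; enlarge the chromosome"
            )
        self.cursor[key] = start + max(gene_len, 1) + self.spacing
        return start, end


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate the full synthetic genome bundle for a validated spec."""
    spec.validate()
    rng = np.random.default_rng(spec.master_seed)

    mads_consensus = random_protein(rng, 59)
    kbox_consensus = random_protein(rng, 70)
    mads_seed = [mutate_protein(rng, mads_consensus, 0.10) for _ in range(8)]
    kbox_seed = [mutate_protein(rng, kbox_consensus, 0.10) for _ in range(8)]

    groups = sorted({_chrom_group(c) for c in spec.chromosome_lengths if c != "U"})
    if not groups:
        raise ConfigurationError("no placed chromosomes")
    placer = _Placer(spec.chromosome_lengths, spec.segment_breakpoints)

    annotation_rows: List[dict] = []
    cds: Dict[str, str] = {}
    proteins: Dict[str, str] = {}
    subfamily_of: Dict[str, str] = {}
    superclade_of: Dict[str, str] = {}
    segment_of: Dict[str, str] = {}
    triads: List[TriadUnit] = []
    references: Dict[str, Tuple[str, str]] = {}
    ancestors: Dict[str, str] = {}  # subfamily -> ancestor CDS
    unit_sources: Dict[str, List[str]] = {}  # subfamily -> candidate dup sources

    gene_counter = 0

    def new_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"TaSYN{gene_counter:04d}"

    def register(gid: str, chrom: str, segment: str, cds_seq: str,
                 subfam: str, desc: str, confidence: str = "high") -> None:
        prot = translate_cds(cds_seq)
        start, end = placer.place(chrom, segment, len(cds_seq))
        strand = "+" if rng.random() < 0.5 else "-"
        annotation_rows.append(
            {
                "gene_id": gid,
                "chromosome": chrom,
                "subgenome": _chrom_subgenome(chrom) if chrom != "U" else "U",
                "start": start,
                "end": end,
                "strand": strand,
                "confidence": confidence,
                "description": desc,
            }
        )
        cds[gid] = cds_seq
        proteins[gid] = prot
        if subfam:
            subfamily_of[gid] = subfam
            superclade_of[gid] = "M" if subfam in M_TYPE else "MIKC"
        segment_of[gid] = segment

    # superclade ancestors: every subfamily diverges from one of these two,
    # so full-length alignments stay informative across subfamilies
    m_ancestor = mutate_protein(rng, mads_consensus, 0.05) + random_protein(rng, 130)
    mikc_ancestor = (
        mutate_protein(rng, mads_consensus, 0.05)
        + random_protein(rng, 25)  # intervening region
        + mutate_protein(rng, kbox_consensus, 0.05)
        + random_protein(rng, 70)  # C-terminal region
    )

    for sf_idx, subfam in enumerate(spec.subfamilies):
        is_m = subfam in M_TYPE
        base = m_ancestor if is_m else mikc_ancestor
        ancestor_prot = mutate_protein(rng, base, spec.subfamily_divergence)
        ancestor_cds = reverse_translate(rng, ancestor_prot)
        ancestors[subfam] = ancestor_cds
        references[f"REF_{subfam}"] = (subfam, ancestor_prot)

        group = groups[sf_idx % len(groups)]
        for unit_idx, pattern in enumerate(spec.triad_configs[sf_idx]):
            unit_cds = mutate_cds(ancestor_cds, spec.unit_ks, spec.unit_omega, rng)
            segment = SEGMENTS[(sf_idx + unit_idx) % len(SEGMENTS)]
            members: Dict[str, List[str]] = {}
            first_gid: Optional[str] = None
            for sg in sorted(set(pattern)):
                member_cds = mutate_cds(unit_cds, spec.triad_ks, spec.triad_omega, rng)
                gid = new_gene_id()
                register(
                    gid, f"{group}{sg}", segment, member_cds, subfam,
                    f"MADS-box transcription factor {subfam} homeolog",
                )
                members.setdefault(sg, []).append(gid)
                if first_gid is None:
                    first_gid = gid
            triads.append(
                TriadUnit(subfam, f"{subfam}.u{unit_idx + 1}", pattern, members)
            )
            if unit_idx == 0 and first_gid is not None:
                unit_sources.setdefault(subfam, []).append(first_gid)

    chrom_of = {row["gene_id"]: row["chromosome"] for row in annotation_rows}
    duplicates: List[PlantedDuplicate] = []
    for ev_idx, ev in enumerate(spec.duplication_events):
        sources = unit_sources.get(ev.subfamily)
        if not sources:
            raise ConfigurationError(f"no source gene in subfamily {ev.subfamily}")
        source = sources[ev_idx % len(sources)]
        dup_cds = mutate_cds(cds[source], ev.target_ks, ev.target_omega, rng)
        gid = new_gene_id()
        src_chrom = chrom_of[source]
        if ev.mode == "tandem":
            chrom = src_chrom
            segment = segment_of[source]
        else:
            if len(groups) < 2:
                raise ConfigurationError("segmental duplications need >= 2 chromosome groups")
            src_group = _chrom_group(src_chrom)
            other = [g for g in groups if g != src_group]
            chrom = f"{other[ev_idx % len(other)]}{_chrom_subgenome(src_chrom)}"
            segment = SEGMENTS[ev_idx % len(SEGMENTS)]
        register(
            gid, chrom, segment, dup_cds, ev.subfamily,
            f"MADS-box transcription factor {ev.subfamily} duplicate",
        )
        chrom_of[gid] = chrom
        duplicates.append(
            PlantedDuplicate(source, gid, ev.subfamily, ev.mode, ev.target_ks, ev.target_omega)
        )

    decoys: List[str] = []
    for i in range(spec.n_decoys_low):
        domain = mutate_protein(rng, mads_consensus, 0.12)
        prot = domain + random_protein(rng, 40)
        gid = new_gene_id()
        chrom = f"{groups[i % len(groups)]}A"
        register(gid, chrom, "C", reverse_translate(rng, prot), "",
                 "MADS-box protein fragment (low confidence)", confidence="low")
        decoys.append(gid)
    for i in range(spec.n_decoys_high):
        prot = random_protein(rng, 150)
        gid = new_gene_id()
        chrom = f"{groups[i % len(groups)]}B"
        register(gid, chrom, "R2b", reverse_translate(rng, prot), "",
                 "hypothetical protein", confidence="high")
        decoys.append(gid)

    family_genes = sorted(subfamily_of)
    weights = {g: (3.0 if superclade_of[g] == "M" else 1.0) for g in family_genes}
    k_true = min(spec.k_true, max(1, len(family_genes) - int(round(spec.fraction_silent * len(family_genes)))))
    expression, labels = generate_expression(
        family_genes,
        k_true=k_true,
        seed=rng,
        n_conditions=spec.n_conditions,
        fraction_silent=spec.fraction_silent,
        noise_sd=spec.noise_sd,
        separation=spec.cluster_separation,
        silent_weight=weights,
    )

    annotation = pd.DataFrame(annotation_rows)
    truth = GroundTruth(
        subfamily=subfamily_of,
        superclade=superclade_of,
        triads=triads,
        duplicates=duplicates,
        segment=segment_of,
        expression_labels=labels,
        decoys=decoys,
    )
    truth.validate()
    return SyntheticGenome(
        spec=spec,
        annotation=annotation,
        cds=cds,
        proteins=proteins,
        truth=truth,
        references=references,
        mads_seed_alignment=mads_seed,
        kbox_seed_alignment=kbox_seed,
        expression=expression,
    )
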