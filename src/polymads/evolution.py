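"""Nei–Gojobori (1986) pathway Ka/Ks estimation and duplication dating.

Implements the classic codon-level counting method: per-codon synonymous and
nonsynonymous site fractions, pathway-averaged difference counts between codon
pairs (minimal mutational pathways, equal weighting, stop-codon intermediates
excluded), Jukes–Cantor multiple-hit correction, the molecular-clock dating
T = Ks / 2r, and selection-regime classification from omega = Ka/Ks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"

#: substitutions / synonymous site / year used for dating wheat duplications
DEFAULT_RATE = 6.5e-9

_FORWARD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _FORWARD[_stop] = "*"

SENSE_CODONS: Tuple[str, ...] = tuple(
    sorted(c for c, aa in _FORWARD.items() if aa != "*")
)


def translate_codon(codon: str) -> str:
    """Amino acid (one letter) for a codon; ``*`` for stop."""
    try:
        return _FORWARD[codon.upper()]
    except KeyError as exc:
        raise ValueError(f"not a standard codon: {codon!r}") from exc


def is_stop(codon: str) -> bool:
    return translate_codon(codon) == "*"


class SequenceError(ValueError):
    """Raised for frame violations or translation mismatches."""


@dataclass
class CodonAlignment:
    """Gap-masked codon alignment of two coding sequences.

    Only codon columns with no gap in either sequence are retained; the
    number of dropped columns is kept for reporting.
    """

    codons_a: List[str]
    codons_b: List[str]
    dropped_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise SequenceError("codon alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.codons_a)


@dataclass
class EvolutionEstimate:
    """NG86 estimate for one gene pair.

    ``ks``/``ka`` are None when the Jukes–Cantor argument saturates
    (1 − 4/3·p ≤ 0); ``omega`` is None when Ks is 0 or undefined.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: Optional[float]
    ka: Optional[float]
    omega: Optional[float]
    t_mya: Optional[float] = None
    selection_class: str = "undefined"
    saturated: bool = False
    notes: List[str] = field(default_factory=list)


@lru_cache(maxsize=None)
def ng_sites(codon: str) -> Tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one sense codon.

    At each of the three positions the synonymous fraction is the number of
    synonymous single-nucleotide mutants divided by the number of non-stop
    mutants at that position (mutations to stop codons are excluded from the
    denominator).  Returns ``(s, n)`` with ``n = 3 − s``.
    """
    codon = codon.upper()
    aa = translate_codon(codon)
    if aa == "*":
        raise SequenceError(f"stop codon has no site counts: {codon}")
    s = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            maa = translate_codon(mutant)
            if maa == "*":
                continue
            nonstop += 1
            if maa == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


@lru_cache(maxsize=None)
def ng_differences(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences.

    All minimal mutational pathways between the two codons are enumerated;
    each single-nucleotide step is synonymous iff it preserves the amino
    acid.  Pathways passing through a stop codon are excluded.  If every
    pathway is blocked by a stop, all pathways are used with stop-entering
    steps counted as nonsynonymous (degenerate fallback).
    """
    a, b = codon_a.upper(), codon_b.upper()
    if translate_codon(a) == "*" or translate_codon(b) == "*":
        raise SequenceError("stop codons are not comparable")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> Optional[Tuple[float, float]]:
        cur = a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            nxt_aa = translate_codon(nxt)
            if nxt_aa == "*" and not allow_stops:
                return None
            if nxt_aa == translate_codon(cur) and nxt_aa != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff_positions) if (r := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in permutations(diff_positions)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _check_cds(cds: str, label: str) -> str:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise SequenceError(f"{label}: length {len(cds)} not divisible by 3")
    return cds


def split_codons(cds: str, drop_terminal_stop: bool = True) -> List[str]:
    """Split a CDS into codons, optionally dropping one trailing stop."""
    cds = _check_cds(cds, "cds")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if drop_terminal_stop and codons and is_stop(codons[-1]):
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if is_stop(c):
            raise SequenceError(f"internal stop codon {c} at codon {i + 1}")
    return codons


def backtranslate_and_mask(
    protein_alignment: Tuple[str, str], cds_a: str, cds_b: str
) -> CodonAlignment:
    """Map a gapped protein alignment onto codons and drop gapped columns.

    Every residue column with a gap in either row is discarded together with
    its codon.  Raises :class:`SequenceError` naming the offending codon if a
    CDS does not translate to its aligned protein.
    """
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise SequenceError("protein alignment rows differ in length")
    codons_a = split_codons(cds_a)
    codons_b = split_codons(cds_b)
    for row, codons, name in ((row_a, codons_a, "a"), (row_b, codons_b, "b")):
        residues = row.replace("-", "")
        if len(residues) != len(codons):
            raise SequenceError(
                f"sequence {name}: {len(codons)} codons vs {len(residues)} residues"
            )
        for i, (aa, codon) in enumerate(zip(residues, codons)):
            if translate_codon(codon) != aa.upper():
                raise SequenceError(
                    f"sequence {name}: codon {i + 1} ({codon}) does not encode {aa}"
                )
    kept_a: List[str] = []
    kept_b: List[str] = []
    dropped = 0
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            kept_a.append(codons_a[ia])
            kept_b.append(codons_b[ib])
        else:
            dropped += 1
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return CodonAlignment(kept_a, kept_b, dropped_columns=dropped)


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 correction −(3/4)·ln(1 − 4/3·p); None when saturated."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg)


def compute_kaks(aln: CodonAlignment) -> EvolutionEstimate:
    """NG86 Ka/Ks for a gap-masked codon alignment.

    Site counts are averaged between the two sequences (S = (S1+S2)/2);
    proportions are Jukes–Cantor corrected; omega = Ka/Ks when Ks > 0.
    """
    if len(aln) < 1:
        raise SequenceError("no retained codons")
    s1 = sum(ng_sites(c)[0] for c in aln.codons_a)
    s2 = sum(ng_sites(c)[0] for c in aln.codons_b)
    S = (s1 + s2) / 2.0
    N = 3.0 * len(aln) - S
    Sd = Nd = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        sd, nd = ng_differences(ca, cb)
        Sd += sd
        Nd += nd
    notes: List[str] = []
    if S <= 0:
        raise SequenceError("no synonymous sites")
    if N <= 0:
        raise SequenceError("no nonsynonymous sites")
    ps = Sd / S
    pn = Nd / N
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated = ks is None or ka is None
    if saturated:
        notes.append("saturated: Jukes-Cantor argument <= 0")
    omega: Optional[float] = None
    if ks is not None and ka is not None and ks > 0:
        omega = ka / ks
    est = EvolutionEstimate(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        ks=ks, ka=ka, omega=omega, saturated=saturated, notes=notes,
    )
    est.selection_class = classify_selection(est)
    return est


def divergence_time(ks: Optional[float], rate: float = DEFAULT_RATE) -> Optional[float]:
    """Divergence time T = Ks / (2r), reported in MYA; None if Ks undefined."""
    if ks is None:
        return None
    if rate <= 0:
        raise ValueError("rate must be positive")
    return ks / (2.0 * rate) * 1e-6


def classify_selection(estimate: EvolutionEstimate) -> str:
    """positive (omega>1) / purifying (omega<1) / neutral (omega=1) / undefined."""
    omega = estimate.omega
    if omega is None:
        return "undefined"
    if omega > 1:
        return "positive"
    if omega < 1:
        return "purifying"
    return "neutral"


def estimate_pair(
    cds_a: str,
    cds_b: str,
    protein_alignment: Optional[Tuple[str, str]] = None,
    rate: float = DEFAULT_RATE,
) -> EvolutionEstimate:
    """Full per-pair workflow: backtranslate, mask, NG86, date, classify.

    When no protein alignment is supplied the two CDS are aligned via their
    translations (global alignment, see :mod:`polymads.phylo`).
    """
    if protein_alignment is None:
        from .phylo import align_global

        prot_a = "".join(translate_codon(c) for c in split_codons(cds_a))
        prot_b = "".join(translate_codon(c) for c in split_codons(cds_b))
        pair = align_global(prot_a, prot_b)
        protein_alignment = (pair.aligned_a, pair.aligned_b)
    aln = backtranslate_and_mask(protein_alignment, cds_a, cds_b)
    est = compute_kaks(aln)
    est.t_mya = divergence_time(est.ks, rate)
    return est


def summarize_by_superclade(
    estimates: Mapping[Tuple[str, str], EvolutionEstimate],
    superclade_of: Mapping[str, str],
) -> Dict[str, Dict[str, object]]:
    """Per-superclade quartiles of Ks, omega, T plus selection fractions.

    A pair contributes to a superclade when both genes belong to it; pairs
    with undefined omega are excluded from the omega quartiles and reported
    separately.  Empty superclades are omitted.
    """
    grouped: Dict[str, List[EvolutionEstimate]] = {}
    for (ga, gb), est in estimates.items():
        ca = superclade_of.get(ga)
        cb = superclade_of.get(gb)
        if ca is not None and ca == cb:
            grouped.setdefault(ca, []).append(est)

    def quartiles(values: Iterable[float]) -> Optional[Dict[str, float]]:
        vals = [v for v in values if v is not None]
        if not vals:
            return None
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3)}

    summary: Dict[str, Dict[str, object]] = {}
    for clade, ests in grouped.items():
        defined = [e for e in ests if e.omega is not None]
        n_pos = sum(1 for e in defined if e.omega > 1)
        n_pur = sum(1 for e in defined if e.omega < 1)
        n_neu = len(defined) - n_pos - n_pur
        summary[clade] = {
            "n_pairs": len(ests),
            "n_defined_omega": len(defined),
            "ks": quartiles(e.ks for e in ests),
            "omega": quartiles(e.omega for e in defined),
            "t_mya": quartiles(e.t_mya for e in ests),
            "positive_pct": 100.0 * n_pos / len(defined) if defined else None,
            "purifying_pct": 100.0 * n_pur / len(defined) if defined else None,
            "neutral_pct": 100.0 * n_neu / len(defined) if defined else None,
        }
    return summary
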