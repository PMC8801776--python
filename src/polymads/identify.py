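"""Candidate identification for MADS-box family surveys.

Domain detection is an ungapped position-specific scoring matrix (PSSM) scan
built from a seed alignment of MADS (PF00319-like) or K-box (PF01486-like)
domains, with hit thresholds calibrated on shuffled-sequence null scores.
Candidate bookkeeping mirrors the survey workflow: pooled totals from the
separate searches, a distinct-id union, a high-confidence/non-redundant
filter, domain-architecture classification, and per-protein statistics
(length, average-mass molecular weight in kDa, isoelectric point).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

MADS_PFAM = "PF00319"
KBOX_PFAM = "PF01486"

ARCHITECTURES = ("MADS_ONLY", "MADS_K", "K_ONLY", "NONE")


@dataclass
class DomainProfile:
    """Log2-odds PSSM over the 20 standard residues.

    Background frequencies 1/20 with pseudocount 1.  Unknown residues (X)
    contribute a score of 0 at any column.
    """

    name: str
    pfam_id: str
    matrix: np.ndarray  # (length, 20)
    threshold: float

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())


@dataclass
class DomainScan:
    """Result of scanning one protein with one profile."""

    gene_id: str
    domain: str
    score: float
    start: int  # 1-based window start on the protein; 0 if too short
    passed: bool
    too_short: bool = False


def build_pssm(
    name: str,
    pfam_id: str,
    seed_alignment: Sequence[str],
    pseudocount: float = 1.0,
    threshold: float = 0.0,
) -> DomainProfile:
    """Build a log2-odds PSSM from equal-length ungapped seed sequences."""
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    length = len(seed_alignment[0])
    if any(len(s) != length for s in seed_alignment):
        raise ValueError("seed sequences must have equal length")
    counts = np.full((length, 20), pseudocount, dtype=float)
    for seq in seed_alignment:
        for col, aa in enumerate(seq.upper()):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                counts[col, idx] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    matrix = np.log2(freqs / 0.05)
    return DomainProfile(name=name, pfam_id=pfam_id, matrix=matrix, threshold=threshold)


def _encode(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, -1) for aa in protein.upper()], dtype=np.int64)


def scan_domain(gene_id: str, protein: str, profile: DomainProfile) -> DomainScan:
    """Best ungapped window score of a protein against a profile.

    Returns the maximum-scoring window; ``passed`` is True iff the score
    reaches the profile threshold.  Proteins shorter than the profile get a
    too-short no-hit.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    seq = _encode(protein)
    L = profile.length
    if len(seq) < L:
        return DomainScan(gene_id, profile.name, -math.inf, 0, False, too_short=True)
    # append a zero column so unknown residues (index -1) score 0
    padded = np.hstack([profile.matrix, np.zeros((L, 1))])
    n_windows = len(seq) - L + 1
    scores = np.empty(n_windows)
    cols = np.arange(L)
    for i in range(n_windows):
        scores[i] = padded[cols, seq[i : i + L]].sum()
    best = int(scores.argmax())
    score = float(scores[best])
    return DomainScan(gene_id, profile.name, score, best + 1, score >= profile.threshold)


def calibrate_threshold(
    profile: DomainProfile,
    background: Optional[str] = None,
    n_shuffles: int = 1000,
    quantile: float = 0.99,
    seed: int = 0,
) -> float:
    """Score quantile of shuffled sequences: an empirical null threshold.

    ``background`` defaults to the profile consensus; it is shuffled
    ``n_shuffles`` times and scanned, and the requested quantile of the null
    score distribution is returned.
    """
    rng = np.random.default_rng(seed)
    base = (background or profile.consensus()).upper()
    chars = np.array(list(base))
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        rng.shuffle(chars)
        scan = scan_domain("null", "".join(chars), profile)
        scores[i] = scan.score
    return float(np.quantile(scores, quantile))


def calibrate_threshold_max(profile: DomainProfile, seed: int = 0,
                            tiles: int = 5, n_shuffles: int = 1000) -> float:
    """Null maximum over shuffles of a tiled consensus.

    Tiling makes each shuffled null sequence multi-window, so the null
    distribution includes the max-over-windows effect a real protein scan
    sees; the maximum over 1,000 such nulls gives a conservative threshold
    that long random proteins essentially never reach while genuine domain
    instances exceed it severalfold.
    """
    return calibrate_threshold(
        profile, background=profile.consensus() * tiles,
        n_shuffles=n_shuffles, quantile=1.0, seed=seed,
    )


@dataclass
class CandidatePool:
    """Merged candidate lists with per-source provenance.

    ``pooled_total`` is the sum of the individual list sizes (the survey's
    bookkeeping total); ``union`` is the set of distinct ids.
    """

    pooled_total: int
    union: Set[str]
    provenance: Dict[str, List[str]] = field(default_factory=dict)


def merge_candidates(
    domain_lists: Mapping[str, Iterable[str]],
    keyword_list: Iterable[str] = (),
) -> CandidatePool:
    """Merge domain-search id lists with a keyword-search id list."""
    sources: Dict[str, List[str]] = {k: list(v) for k, v in domain_lists.items()}
    sources["keyword"] = list(keyword_list)
    pooled_total = sum(len(v) for v in sources.values())
    union: Set[str] = set()
    provenance: Dict[str, List[str]] = {}
    for source, ids in sources.items():
        for gid in ids:
            union.add(gid)
            provenance.setdefault(gid, [])
            if source not in provenance[gid]:
                provenance[gid].append(source)
    return CandidatePool(pooled_total=pooled_total, union=union, provenance=provenance)


def keyword_search(descriptions: Mapping[str, str], keyword: str = "MADS") -> List[str]:
    """Case-insensitive literal substring match over annotation descriptions."""
    needle = keyword.lower()
    return sorted(gid for gid, desc in descriptions.items() if needle in (desc or "").lower())


def filter_nonredundant(
    pool: CandidatePool,
    confidence: Mapping[str, str],
) -> Tuple[List[str], List[str]]:
    """Keep high-confidence candidates, one record per distinct id.

    Returns (retained ids sorted, excluded ids sorted).  Candidates missing
    from the annotation are excluded with a logged warning.
    """
    retained: List[str] = []
    excluded: List[str] = []
    for gid in sorted(pool.union):
        conf = confidence.get(gid)
        if conf is None:
            logger.warning("candidate %s absent from annotation; excluded", gid)
            excluded.append(gid)
        elif conf.lower() == "high":
            retained.append(gid)
        else:
            excluded.append(gid)
    return retained, excluded


def classify_architecture(
    mads: Optional[DomainScan], kbox: Optional[DomainScan]
) -> str:
    """Domain architecture from the pair of profile scans."""
    m = bool(mads and mads.passed)
    k = bool(kbox and kbox.passed)
    if m and k:
        return "MADS_K"
    if m:
        return "MADS_ONLY"
    if k:
        return "K_ONLY"
    return "NONE"


# ---------------------------------------------------------------------------
# protein statistics

# EMBOSS pKa set (iep): side chains + termini
_PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6


@dataclass
class ProteinStats:
    length: int
    molecular_weight_kda: float
    isoelectric_point: float


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    seq = protein.upper()
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa in seq:
        if aa in _PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE[aa]))
        elif aa in _PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, found by bisection to |charge| < tol."""
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(protein, mid)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def compute_protein_stats(protein: str) -> ProteinStats:
    """Length, average-mass MW (kDa) and pI of a protein.

    Residues outside the 20 standard amino acids are excluded from the MW
    and charge calculations with a warning.
    """
    seq = protein.upper().rstrip("*")
    clean = "".join(aa for aa in seq if aa in _AA_INDEX)
    if len(clean) != len(seq):
        logger.warning(
            "%d non-standard residues excluded from MW/pI", len(seq) - len(clean)
        )
    if not clean:
        raise ValueError("no standard residues in protein")
    mw_da = ProteinAnalysis(clean).molecular_weight()
    return ProteinStats(
        length=len(seq),
        molecular_weight_kda=mw_da / 1000.0,
        isoelectric_point=isoelectric_point(clean),
    )
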