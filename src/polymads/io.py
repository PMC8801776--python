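"""FASTA/TSV readers shared by the CLI and the real-mode pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Tuple

from Bio import SeqIO


def read_fasta(path: str | Path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_references(path: str | Path) -> Dict[str, Tuple[str, str]]:
    """Reference exemplars: headers ``>id subfamily`` or ``>REF_<subfamily>``."""
    refs: Dict[str, Tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        if len(parts) > 1:
            subfamily = parts[1]
        elif rec.id.startswith("REF_"):
            subfamily = rec.id[4:]
        else:
            raise ValueError(f"reference {rec.id} carries no subfamily label")
        refs[rec.id] = (subfamily, str(rec.seq))
    return refs
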