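"""Small sequence helpers (standard genetic code, plastid bacterial-style)."""

from __future__ import annotations

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the last is a stop codon."""
    n = len(cds) - len(cds) % 3
    return any(is_stop(cds[i:i + 3]) for i in range(0, n - 3, 3))


def ends_at_stop(cds: str) -> bool:
    return len(cds) >= 3 and len(cds) % 3 == 0 and is_stop(cds[-3:])
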