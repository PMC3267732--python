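"""Genetic-code constants and codon extraction.

The composition signature used throughout this package is the usage of the
61 sense codons of the standard bacterial genetic code.  The three stop
triplets (TAA, TAG, TGA) carry no amino acid and are excluded, which fixes
the dimensionality of every codon-usage vector at 61.  Only *internal*
codons of a CDS are counted: the positional start codon (whatever its
identity -- ATG, GTG or TTG all occur in bacteria) and a terminal stop are
removed before counting.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from itertools import product

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "N_SENSE_CODONS",
    "reverse_complement",
    "codons_of",
    "extract_internal_codons",
    "gc_content",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

#: The 61 sense codons in fixed lexicographic order (AAA ... TTT minus stops).
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOP_CODONS
)
N_SENSE_CODONS = len(SENSE_CODONS)  # 61

#: codon string -> dimension index in every codon-usage vector.
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(seq: str, skip_ambiguous: bool = True) -> list[str]:
    """Split an in-frame nucleotide string into codons.

    A trailing partial codon (length not a multiple of 3) is discarded with
    a warning.  Codons containing characters outside A/C/G/T are skipped
    when ``skip_ambiguous`` is set (never imputed).
    """
    seq = seq.strip().upper()
    if len(seq) % 3:
        warnings.warn(
            f"sequence length {len(seq)} not a multiple of 3; "
            "trailing partial codon discarded",
            stacklevel=2,
        )
        seq = seq[: len(seq) - len(seq) % 3]
    out = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if skip_ambiguous:
        acgt = set("ACGT")
        out = [c for c in out if set(c) <= acgt]
    return out


def extract_internal_codons(cds: str, strand: str = "+") -> list[str]:
    """Internal codons of a CDS: everything but the start and the stop.

    The first codon is removed positionally (regardless of ATG/GTG/TTG
    identity); a terminal stop codon is removed by identity.  Minus-strand
    input is reverse-complemented first, so callers may pass the plus-strand
    genomic substring of a minus-strand feature directly.

    Fewer than two complete codons yield an empty list, never an exception.
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        cds = reverse_complement(cds)
    cds = cds.strip().upper()
    if len(cds) < 6:
        return []
    # Trim the trailing partial codon before identifying the terminal stop.
    full = codons_of(cds, skip_ambiguous=False)
    if len(full) < 2:
        return []
    internal = full[1:]
    if internal and internal[-1] in STOP_CODONS:
        internal = internal[:-1]
    acgt = set("ACGT")
    return [c for c in internal if set(c) <= acgt]


def gc_content(seq: str, digits: int | None = 1) -> float:
    """G+C percentage of a nucleotide sequence.

    Characters outside A/C/G/T are excluded from both numerator and
    denominator.  Reported to one decimal by default, rounding half up,
    matching the convention of genome summary tables; pass ``digits=None``
    for the unrounded value.
    """
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T characters")
    pct = 100.0 * (counts["G"] + counts["C"]) / denom
    if digits is None:
        return pct
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(pct)).quantize(q, rounding=ROUND_HALF_UP))
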