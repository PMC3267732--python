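"""Clone/contig/end-read records: an id plus its in-frame coding sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CloneRecord"]

_KINDS = ("clone", "contig", "end_read")


@dataclass
class CloneRecord:
    """A sequenced unit of the library and its coding content.

    ``cds_sequences`` hold in-frame nucleotide strings: full CDSs
    (start..stop) for clones and contigs, or the in-frame coding fragment
    of a ~600 bp end read.  ``mate_id`` links the two end reads of one
    fosmid so they can be pooled during classification.
    """

    clone_id: str
    cds_sequences: list[str] = field(default_factory=list)
    kind: str = "clone"
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        for s in self.cds_sequences:
            if self.kind != "end_read" and len(s) < 6:
                raise ValueError(
                    f"CDS of {self.clone_id!r} shorter than 6 nt before trimming"
                )
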