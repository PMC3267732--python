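"""Readers/writers for the pipeline's on-disk formats and genome summaries.

Formats: FASTA (Biopython), GFF3 CDS annotations (gffutils, in-memory db),
TSV reports ('#'-prefixed header, tab-separated, no quoting), Newick
dendrograms.  Internal coordinates are 0-based half-open; the single GFF3
boundary conversion (1-based inclusive -> python slice) lives in
:func:`read_cds` only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import SENSE_CODONS, gc_content, reverse_complement
from .profile import CodonUsageVector
from .records import CloneRecord

logger = logging.getLogger("codonbin")

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_gff3",
    "read_cds",
    "read_fragments",
    "write_profile_table",
    "read_profile_table",
    "write_tsv",
    "read_tsv",
    "summarize_contigs",
    "log_provenance",
]


# -- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; descriptions kept separately by callers
    that need them (see :func:`read_fragments`)."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = []
    for header, seq in seqs.items():
        name, _, desc = header.partition(" ")
        records.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(records, str(path), "fasta")


# -- GFF3 -----------------------------------------------------------------

def write_gff3(features: Mapping[str, list[tuple[str, int, int, str]]], path: str | Path) -> None:
    """Write CDS features; values are (cds_id, start_1based, end_inclusive, strand)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, feats in features.items():
            for cds_id, start, end, strand in feats:
                fh.write(
                    f"{seqid}\tcodonbin\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={cds_id}\n"
                )


def read_cds(fasta_path: str | Path, gff3_path: str | Path) -> list[CloneRecord]:
    """Strand-corrected in-frame CDS strings grouped per FASTA record.

    GFF3 coordinates are 1-based inclusive; minus-strand features are
    reverse-complemented so every returned string starts with its start
    codon.  Out-of-bounds features raise with the offending feature named.
    """
    import gffutils

    seqs = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_clone: dict[str, list[str]] = {sid: [] for sid in seqs}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in seqs:
            raise ValueError(f"GFF3 feature {feat.id!r} references unknown sequence {feat.seqid!r}")
        seq = seqs[feat.seqid]
        if feat.start < 1 or feat.end > len(seq):
            raise ValueError(
                f"feature {feat.id!r} ({feat.seqid}:{feat.start}-{feat.end}) "
                f"out of bounds for sequence of length {len(seq)}"
            )
        sub = seq[feat.start - 1 : feat.end]  # the one 1-based -> slice conversion
        if feat.strand == "-":
            sub = reverse_complement(sub)
        by_clone[feat.seqid].append(sub)
    return [
        CloneRecord(clone_id=sid, cds_sequences=cds, kind="clone")
        for sid, cds in by_clone.items()
        if cds
    ]


def read_fragments(path: str | Path) -> list[CloneRecord]:
    """End-read FASTA -> end_read records; an optional ``mate=<id>`` tag in
    the description links mate pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        mate = None
        for tok in rec.description.split():
            if tok.startswith("mate="):
                mate = tok[5:]
        out.append(
            CloneRecord(clone_id=rec.id, cds_sequences=[str(rec.seq).upper()],
                        kind="end_read", mate_id=mate)
        )
    if not out:
        raise ValueError(f"no fragments in {path}")
    return out


# -- TSV ------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated, UTF-8, '#'-prefixed header, no quoting."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header")
        cols = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=cols)


def write_profile_table(profiles: list[CodonUsageVector], path: str | Path) -> None:
    """One row per source: 61 frequency columns + total_codons."""
    rows = []
    for p in profiles:
        row = {"source_id": p.source_id}
        row.update({c: f for c, f in zip(SENSE_CODONS, p.frequencies)})
        row["total_codons"] = p.total_codons
        rows.append(row)
    write_tsv(pd.DataFrame(rows), path)


def read_profile_table(path: str | Path) -> list[CodonUsageVector]:
    df = read_tsv(path)
    out = []
    for _, row in df.iterrows():
        freqs = row[list(SENSE_CODONS)].to_numpy(dtype=float)
        out.append(
            CodonUsageVector.from_frequencies(
                freqs, int(row["total_codons"]), source_id=str(row["source_id"])
            )
        )
    return out


# -- genome summary (Table-2-style) ---------------------------------------

def summarize_contigs(fasta_path: str | Path, gff3_path: str | Path | None = None) -> pd.DataFrame:
    """Per-contig length and GC%, a TOTAL row, and annotation counts when a
    GFF3 is supplied (feature types CDS, rRNA, tRNA)."""
    seqs = read_fasta(fasta_path)
    rows = []
    counts: dict[str, dict[str, int]] = {}
    if gff3_path is not None:
        import gffutils

        db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                                merge_strategy="create_unique")
        for ftype, col in (("CDS", "protein_coding"), ("rRNA", "rRNA"), ("tRNA", "tRNA")):
            for feat in db.features_of_type(ftype):
                counts.setdefault(feat.seqid, {}).setdefault(col, 0)
                counts[feat.seqid][col] += 1
    for sid, seq in seqs.items():
        row = {"contig_id": sid, "length_bp": len(seq), "gc_percent": gc_content(seq)}
        if gff3_path is not None:
            for col in ("protein_coding", "rRNA", "tRNA"):
                row[col] = counts.get(sid, {}).get(col, 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"contig_id": "TOTAL", "length_bp": int(df["length_bp"].sum()),
             "gc_percent": gc_content("".join(seqs.values()))}
    if gff3_path is not None:
        for col in ("protein_coding", "rRNA", "tRNA"):
            total[col] = int(df[col].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# -- provenance -----------------------------------------------------------

def log_provenance(config: dict, seed: int | None = None) -> str:
    """Log tool version, a stable hash of the run configuration, and the
    seed; returns the config hash for embedding in outputs."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    digest = hashlib.sha256(payload).hexdigest()[:12]
    logger.info("codonbin %s | config sha256:%s | seed=%s", __version__, digest, seed)
    return digest
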