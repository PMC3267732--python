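"""Synthetic multi-species fosmid library generator.

Emulates the structure of a mixed-community fosmid library so every
pipeline stage can be exercised with known ground truth: tens of species
with controlled pairwise codon-usage distances, a skewed clone-abundance
profile (one dominant group, as in real libraries where a single phylotype
can contribute ~34 of ~151 clones), clones carrying ~1,700-14,300 internal
codons split across CDSs, and two ~200-codon in-frame end reads per clone.

Species codon-usage profiles are Dirichlet draws over the 61 sense codons.
The symmetric concentration ``a`` controls how far two species sit apart:
E||p - q||^2 = 2 * sum_i m_i(1-m_i) / (61 a + 1) with m = 1/61, so a target
typical distance d maps to a = ((2 * 60/61) / d^2 - 1) / 61.  A distance
window is enforced by sequential rejection sampling.

What this generator deliberately does not emulate: sequencing error,
strand-composition bias, horizontally transferred genes with alien codon
usage, rRNA operons, or amelioration gradients within a genome -- real
clones of one species scatter slightly more than the pure multinomial
sampling noise simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import N_SENSE_CODONS, SENSE_CODONS, STOP_CODONS, reverse_complement
from .profile import CodonUsageVector
from .records import CloneRecord

__all__ = [
    "CommunitySpec",
    "concentration_for_distance",
    "sample_species_profiles",
    "geometric_abundance",
    "SyntheticLibrary",
    "generate_library",
    "generate_gc_temperature_points",
]

_CODON_ARR = np.array(SENSE_CODONS)


def concentration_for_distance(d: float) -> float:
    """Symmetric Dirichlet concentration giving expected pairwise distance ~d."""
    if not 0 < d < 1.4:
        raise ValueError("target distance must be in (0, 1.4)")
    m = 1.0 / N_SENSE_CODONS
    s = N_SENSE_CODONS * m * (1.0 - m)  # = 60/61
    return max((2.0 * s / d**2 - 1.0) / N_SENSE_CODONS, 1e-3)


def geometric_abundance(n_species: int, largest: int = 34, ratio: float = 0.78) -> list[int]:
    """Geometrically decaying clones-per-species with a dominant first group."""
    if n_species < 1 or largest < 1 or not 0 < ratio < 1:
        raise ValueError("invalid abundance parameters")
    return [max(1, round(largest * ratio**k)) for k in range(n_species)]


@dataclass
class CommunitySpec:
    """Design of a synthetic fosmid library.

    Defaults mirror the real library's conditions: 20 species with a
    geometric clone-abundance skew (largest group 34 clones), clone coding
    content uniform in 1,700-14,300 internal codons, 200-codon end reads,
    and species profiles kept at pairwise distances in [0.08, 0.25] --
    comfortably above the 0.04 same-species cutoff, as real genome pairs
    usually are.
    """

    n_species: int = 20
    clones_per_species: Sequence[int] | None = None
    codons_per_clone: tuple[int, int] = (1_700, 14_300)
    end_read_codons: int = 200
    dirichlet_concentration: float | None = None
    target_distance_window: tuple[float, float] | None = (0.08, 0.25)
    spacer_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        lo, hi = self.codons_per_clone
        if lo < 1 or hi < lo or self.end_read_codons < 1 or self.spacer_length < 0:
            raise ValueError("invalid size parameters")
        if self.clones_per_species is None:
            self.clones_per_species = geometric_abundance(self.n_species)
        if len(self.clones_per_species) != self.n_species:
            raise ValueError("clones_per_species length must equal n_species")

    @property
    def concentration(self) -> float:
        if self.dirichlet_concentration is not None:
            return self.dirichlet_concentration
        if self.target_distance_window is not None:
            lo, hi = self.target_distance_window
            return concentration_for_distance((lo + hi) / 2.0)
        return 1.5


def sample_species_profiles(
    spec: CommunitySpec, rng: np.random.Generator | None = None, max_tries: int = 20_000
) -> list[CodonUsageVector]:
    """Dirichlet-sample species frequency vectors, rejection-enforcing the
    pairwise distance window when one is set.

    Candidates are accepted sequentially when their distance to every
    already-accepted profile lies in the window; an unsatisfiable window
    exhausts ``max_tries`` and raises with diagnostics.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    a = np.full(N_SENSE_CODONS, spec.concentration)
    window = spec.target_distance_window
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < spec.n_species:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place species {len(accepted) + 1}/{spec.n_species} in "
                f"distance window {window} after {max_tries} tries "
                f"(concentration={spec.concentration:.3g}); widen the window or "
                "change the concentration"
            )
        cand = rng.dirichlet(a)
        tries += 1
        if window is not None and accepted:
            d = np.sqrt(((np.vstack(accepted) - cand) ** 2).sum(axis=1))
            if d.min() < window[0] or d.max() > window[1]:
                continue
        accepted.append(cand)
    # exact-integer counts representation: scale to a large denominator
    denom = 10_000_000
    out = []
    for k, p in enumerate(accepted, start=1):
        counts = np.rint(p * denom).astype(np.int64)
        out.append(CodonUsageVector(source_id=f"S{k:03d}", counts=counts))
    return out


@dataclass
class SyntheticLibrary:
    """In-memory synthetic library plus writers for its on-disk formats."""

    spec: CommunitySpec
    species_profiles: list[CodonUsageVector]
    clone_sequences: dict[str, str]
    clone_features: dict[str, list[tuple[str, int, int, str]]]  # cds_id, start(1-based), end, strand
    clone_records: list[CloneRecord]
    end_reads: list[CloneRecord]
    truth: pd.DataFrame  # columns: id, kind, species

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clones_fasta": outdir / "clones.fasta",
            "clones_gff3": outdir / "clones.gff3",
            "end_reads_fasta": outdir / "end_reads.fasta",
            "truth_tsv": outdir / "truth.tsv",
        }
        cio.write_fasta(self.clone_sequences, paths["clones_fasta"])
        cio.write_gff3(self.clone_features, paths["clones_gff3"])
        reads = {}
        for r in self.end_reads:
            header = f"{r.clone_id} mate={r.mate_id}" if r.mate_id else r.clone_id
            reads[header] = r.cds_sequences[0]
        cio.write_fasta(reads, paths["end_reads_fasta"])
        cio.write_tsv(self.truth, paths["truth_tsv"])
        return paths


def _draw_codon_run(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(N_SENSE_CODONS, size=n, p=p)


def _split_cds_lengths(total: int, rng: np.random.Generator, lo: int = 150, hi: int = 450) -> list[int]:
    """Partition a clone's internal-codon budget into CDS-sized chunks."""
    lengths: list[int] = []
    left = total
    while left > 0:
        n = int(rng.integers(lo, hi + 1))
        if left - n < lo // 3:
            n = left
        lengths.append(min(n, left))
        left -= lengths[-1]
    return lengths


def generate_library(
    spec: CommunitySpec, profiles: list[CodonUsageVector] | None = None
) -> SyntheticLibrary:
    """Generate a synthetic fosmid library with full ground truth.

    Every CDS is a start codon + i.i.d. sense codons from the species
    profile + a stop codon, so generated CDSs contain no in-frame internal
    stops by construction.  CDSs are packed into the clone sequence with
    fixed-length N spacers (accidental ORFs in spacers are impossible) and
    roughly half are placed on the minus strand.  Two in-frame end reads
    per clone are taken as the first and last ``end_read_codons`` codons of
    the clone's codon stream, mimicking reads off both insert ends.
    """
    rng = np.random.default_rng(spec.seed)
    if profiles is None:
        profiles = sample_species_profiles(spec, rng)
    if len(profiles) != spec.n_species:
        raise ValueError("profiles length must equal n_species")

    lo, hi = spec.codons_per_clone
    spacer = "N" * spec.spacer_length
    clone_sequences: dict[str, str] = {}
    clone_features: dict[str, list[tuple[str, int, int, str]]] = {}
    clone_records: list[CloneRecord] = []
    end_reads: list[CloneRecord] = []
    truth_rows: list[dict] = []

    clone_no = 0
    for sp, prof, n_clones in zip(range(spec.n_species), profiles, spec.clones_per_species):
        p = prof.frequencies
        for _ in range(n_clones):
            clone_no += 1
            clone_id = f"C{clone_no:04d}"
            total = int(rng.integers(lo, hi + 1))
            cds_seqs: list[str] = []
            codon_stream: list[str] = []
            for n_codons in _split_cds_lengths(total, rng):
                idx = _draw_codon_run(p, n_codons, rng)
                internal = _CODON_ARR[idx]
                codon_stream.extend(internal.tolist())
                stop = STOP_CODONS[int(rng.integers(0, 3))]
                cds_seqs.append("ATG" + "".join(internal) + stop)
            # pack into the clone with spacers; alternate strands randomly
            parts: list[str] = []
            feats: list[tuple[str, int, int, str]] = []
            pos = 0
            for i, cds in enumerate(cds_seqs, start=1):
                if parts:
                    parts.append(spacer)
                    pos += len(spacer)
                strand = "+" if rng.random() < 0.5 else "-"
                block = cds if strand == "+" else reverse_complement(cds)
                start = pos + 1  # 1-based inclusive
                parts.append(block)
                pos += len(block)
                feats.append((f"{clone_id}|cds{i}", start, pos, strand))
            clone_sequences[clone_id] = "".join(parts)
            clone_features[clone_id] = feats
            clone_records.append(CloneRecord(clone_id=clone_id, cds_sequences=cds_seqs, kind="clone"))
            truth_rows.append({"id": clone_id, "kind": "clone", "species": prof.source_id})

            n_end = min(spec.end_read_codons, len(codon_stream))
            r5, r3 = f"{clone_id}_end5", f"{clone_id}_end3"
            end_reads.append(
                CloneRecord(r5, ["".join(codon_stream[:n_end])], kind="end_read", mate_id=r3)
            )
            end_reads.append(
                CloneRecord(r3, ["".join(codon_stream[-n_end:])], kind="end_read", mate_id=r5)
            )
            truth_rows.append({"id": r5, "kind": "end_read", "species": prof.source_id})
            truth_rows.append({"id": r3, "kind": "end_read", "species": prof.source_id})

    truth = pd.DataFrame(truth_rows, columns=["id", "kind", "species"])
    return SyntheticLibrary(
        spec=spec,
        species_profiles=profiles,
        clone_sequences=clone_sequences,
        clone_features=clone_features,
        clone_records=clone_records,
        end_reads=end_reads,
        truth=truth,
    )


def generate_gc_temperature_points(
    n: int = 10,
    slope: float = 3.0,
    intercept: float = -101.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    gc_range: tuple[float, float] = (52.0, 65.0),
) -> pd.DataFrame:
    """Synthetic (16S GC%, max growth temperature) calibration points.

    Points lie on t = slope * gc + intercept with Gaussian noise.  The
    default line passes through (61.9% GC, 84.7 degC), a published anchor
    for a thermophilic deeply branching bacterium; the GC range spans
    typical mesophile-to-hyperthermophile 16S compositions.
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    rng = np.random.default_rng(seed)
    gc = np.sort(rng.uniform(*gc_range, size=n))
    t = slope * gc + intercept + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {"species": [f"sp{i + 1:02d}" for i in range(n)], "gc_percent": gc, "t_max_celsius": t}
    )
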