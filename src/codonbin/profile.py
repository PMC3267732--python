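"""Codon-usage vectors: construction, comparison, and a sklearn transformer.

A clone, contig or species group is summarised by its counts over the 61
sense codons; the frequency vector (counts / total) is the point compared
under Euclidean distance.  With N internal codons the sampling error of the
frequency estimate is E||p_hat - p|| ~ sqrt(sum_i p_i (1 - p_i) / N), which
is what makes whole fosmids (~8,000 codons, error ~0.011) clusterable at a
0.04 cutoff while ~200-codon end reads (error ~0.07) need a likelihood
classifier instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .codons import CODON_INDEX, N_SENSE_CODONS, SENSE_CODONS, codons_of, extract_internal_codons
from .records import CloneRecord

__all__ = [
    "CodonUsageVector",
    "EmptyProfileError",
    "count_codons",
    "build_profile",
    "euclidean_distance",
    "expected_sampling_distance",
    "CodonUsageVectorizer",
]


class EmptyProfileError(ValueError):
    """Raised when a profile would be built from zero internal codons."""


@dataclass(frozen=True)
class CodonUsageVector:
    """61-dimensional codon count/frequency vector for one source.

    Parameters
    ----------
    source_id :
        Identifier of the clone, contig or species group.
    counts :
        Integer counts per sense codon, in the canonical lexicographic
        codon order.
    """

    source_id: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_SENSE_CODONS,):
            raise ValueError(
                f"counts must have shape ({N_SENSE_CODONS},), got {counts.shape}"
            )
        if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total_codons(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        n = self.total_codons
        if n == 0:
            raise EmptyProfileError(f"profile {self.source_id!r} has zero codons")
        return self.counts / n

    @classmethod
    def from_codons(cls, codons: Iterable[str], source_id: str) -> "CodonUsageVector":
        return cls(source_id=source_id, counts=count_codons(codons))

    @classmethod
    def from_frequencies(
        cls, frequencies: np.ndarray, total_codons: int, source_id: str
    ) -> "CodonUsageVector":
        """Reconstruct integer counts from a frequency row (e.g. a TSV row)."""
        counts = np.rint(np.asarray(frequencies, dtype=float) * total_codons)
        return cls(source_id=source_id, counts=counts)

    def to_series(self):
        import pandas as pd

        return pd.Series(self.counts, index=list(SENSE_CODONS), name=self.source_id)


def count_codons(codons: Iterable[str]) -> np.ndarray:
    """Count sense codons into the canonical 61-vector; non-sense triplets
    (stops, ambiguous) are ignored."""
    counts = np.zeros(N_SENSE_CODONS, dtype=np.int64)
    for c in codons:
        i = CODON_INDEX.get(c)
        if i is not None:
            counts[i] += 1
    return counts


def _codons_from_source(source) -> list[str]:
    if isinstance(source, CloneRecord):
        out: list[str] = []
        for cds in source.cds_sequences:
            if source.kind == "end_read":
                out.extend(codons_of(cds))
            else:
                out.extend(extract_internal_codons(cds))
        return out
    if isinstance(source, str):
        return extract_internal_codons(source)
    # assume an iterable of codon strings
    return list(source)


def build_profile(
    records, source_id: str | None = None
) -> CodonUsageVector:
    """Aggregate internal codons over CDSs/records into one profile.

    ``records`` may be a single :class:`CloneRecord`, a list of records
    (a species group), a list of CDS nucleotide strings, or a list of codon
    lists.  Zero internal codons in the union is an error naming the source.
    """
    if isinstance(records, (CloneRecord, str)):
        records = [records]
    records = list(records)
    if source_id is None:
        ids = [r.clone_id for r in records if isinstance(r, CloneRecord)]
        source_id = ids[0] if len(ids) == 1 else "+".join(ids) or "profile"
    counts = np.zeros(N_SENSE_CODONS, dtype=np.int64)
    for rec in records:
        counts += count_codons(_codons_from_source(rec))
    if counts.sum() == 0:
        raise EmptyProfileError(f"no internal codons for source {source_id!r}")
    return CodonUsageVector(source_id=source_id, counts=counts)


def euclidean_distance(a: CodonUsageVector, b: CodonUsageVector) -> float:
    """Euclidean (L2) distance between two codon-usage frequency vectors."""
    return float(np.linalg.norm(a.frequencies - b.frequencies))


def expected_sampling_distance(p: np.ndarray, n_codons: int, paired: bool = True) -> float:
    """First-order expected distance between frequency estimates.

    For a single estimate of ``p`` from ``n_codons`` draws the RMS error is
    sqrt(sum p(1-p)/N); between two independent estimates of the same ``p``
    (``paired=True``, the artificial-fosmid calibration setting) the factor
    doubles under the square root.
    """
    p = np.asarray(p, dtype=float)
    v = float(np.sum(p * (1.0 - p))) / n_codons
    return float(np.sqrt(2.0 * v if paired else v))


class CodonUsageVectorizer(TransformerMixin, BaseEstimator):
    """Turn clones (sets of in-frame CDSs) into a (n, 61) codon matrix.

    Stateless in the sklearn sense; ``fit`` only validates parameters.

    Parameters
    ----------
    output : {"counts", "frequencies"}
        Whether :meth:`transform` returns integer counts or rows normalised
        to sum to 1.
    min_internal_codons : int
        Rows with fewer internal codons raise (frequencies) -- clones this
        shallow should be reported "unclustered" upstream, not silently
        included.  Set 0 to disable.  The default of 100 is far below the
        shallowest real fosmid (1,685 internal codons), so no sequenced
        clone is excluded by default.
    """

    def __init__(self, output: str = "frequencies", min_internal_codons: int = 0):
        self.output = output
        self.min_internal_codons = min_internal_codons

    def fit(self, X=None, y=None):
        if self.output not in {"counts", "frequencies"}:
            raise ValueError(f"unknown output mode {self.output!r}")
        self.n_features_in_ = N_SENSE_CODONS
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        self.fit()
        rows = []
        for item in X:
            if isinstance(item, CodonUsageVector):
                counts = item.counts
            else:
                counts = count_codons(_codons_from_source(item))
            rows.append(counts)
        M = np.asarray(rows, dtype=np.int64)
        if self.output == "counts":
            return M
        totals = M.sum(axis=1)
        low = totals < max(self.min_internal_codons, 1)
        if np.any(low):
            raise EmptyProfileError(
                f"{int(low.sum())} source(s) below min_internal_codons="
                f"{self.min_internal_codons} (or empty)"
            )
        return M / totals[:, None]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(SENSE_CODONS, dtype=object)
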