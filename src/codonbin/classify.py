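"""Multinomial classification of short coding fragments into species groups.

A ~600 bp clone-end read carries only ~200 codons, so its frequency vector
is far too noisy for distance-based binning.  Instead, the codon counts
n_1..n_61 of a fragment are modelled as a multinomial draw from each
candidate species' codon frequencies p_ik:

    P(fragment | species k) = N! / prod_i n_i!  *  prod_i p_ik^{n_i}

and the fragment is attributed to the species maximising this probability
(uniform prior over groups by default).  Group frequencies are smoothed
with an additive pseudocount so unseen codons never yield -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .codons import N_SENSE_CODONS, codons_of
from .profile import CodonUsageVector, count_codons
from .records import CloneRecord

__all__ = [
    "FragmentCounts",
    "log_multinomial_prob",
    "MultinomialCodonClassifier",
    "classify",
    "pool_paired",
]

DEFAULT_ALPHA = 0.5


@dataclass(frozen=True)
class FragmentCounts:
    """Codon counts of one fragment (or pooled mate pair)."""

    read_id: str
    counts: np.ndarray = field(repr=False)
    mate_id: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a non-negative 1-d integer vector")
        if counts.sum() < 1:
            raise ValueError(f"empty fragment {self.read_id!r}")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_sequence(cls, seq: str, read_id: str, mate_id: str | None = None) -> "FragmentCounts":
        """Counts from an in-frame coding fragment (no start/stop trimming)."""
        return cls(read_id=read_id, counts=count_codons(codons_of(seq)), mate_id=mate_id)


def log_multinomial_prob(counts: np.ndarray, p: np.ndarray) -> float:
    """log P(counts | p) under the multinomial, via log-gamma.

    Finite for every strictly positive ``p``; supports toy alphabets of any
    size (counts and p just need matching lengths).
    """
    n = np.asarray(counts, dtype=float)
    p = np.asarray(p, dtype=float)
    if n.shape != p.shape:
        raise ValueError("counts and p must have the same shape")
    N = n.sum()
    if N < 1:
        raise ValueError("empty fragment")
    if np.any(p <= 0):
        raise ValueError("profile must be strictly positive (apply smoothing)")
    coeff = gammaln(N + 1.0) - gammaln(n + 1.0).sum()
    return float(coeff + np.dot(n, np.log(p)))


def pool_paired(fragments: Sequence[FragmentCounts]) -> list[FragmentCounts]:
    """Sum the counts of mate pairs; unpaired fragments pass through.

    Pooling by summation is the maximum-likelihood treatment of two reads
    assumed drawn independently from the same species.
    """
    by_id = {f.read_id: f for f in fragments}
    done: set[str] = set()
    out: list[FragmentCounts] = []
    for f in fragments:
        if f.read_id in done:
            continue
        mate = by_id.get(f.mate_id) if f.mate_id else None
        if mate is not None and mate.read_id != f.read_id:
            out.append(
                FragmentCounts(
                    read_id=f"{f.read_id}+{mate.read_id}",
                    counts=f.counts + mate.counts,
                )
            )
            done.update({f.read_id, mate.read_id})
        else:
            out.append(f)
            done.add(f.read_id)
    return out


class MultinomialCodonClassifier(ClassifierMixin, BaseEstimator):
    """Maximum-multinomial-probability species assignment for fragments.

    Fit on codon *count* rows labelled by species group; the per-group
    frequencies are estimated from the pooled counts with an additive
    pseudocount:

        p_ik = (c_ik + alpha) / (C_k + alpha * n_codons)

    Parameters
    ----------
    alpha : float
        Additive pseudocount per codon (default 0.5).  Strictly positive
        so every p_ik > 0.
    priors : mapping group -> probability, optional
        Group prior; uniform when omitted.

    Attributes
    ----------
    classes_ : ndarray
        Lexicographically sorted group labels.
    feature_log_prob_ : ndarray (n_groups, n_codons)
        log p_ik.
    group_counts_ : ndarray (n_groups, n_codons)
        Raw pooled counts per group.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, priors: Mapping[str, float] | None = None):
        self.alpha = alpha
        self.priors = priors

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        X = self._as_count_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[0] == 0:
            raise ValueError("empty model: no training rows")
        self.classes_ = np.unique(y)
        k, d = len(self.classes_), X.shape[1]
        self.n_features_in_ = d
        self.group_counts_ = np.zeros((k, d), dtype=np.int64)
        for i, g in enumerate(self.classes_):
            self.group_counts_[i] = X[y == g].sum(axis=0)
        smoothed = self.group_counts_ + self.alpha
        self.feature_log_prob_ = np.log(smoothed / smoothed.sum(axis=1, keepdims=True))
        if self.priors is None:
            self.class_log_prior_ = np.full(k, -np.log(k))
        else:
            pr = np.array([self.priors[g] for g in self.classes_], dtype=float)
            if abs(pr.sum() - 1.0) > 1e-9 or np.any(pr <= 0):
                raise ValueError("priors must be positive and sum to 1")
            self.class_log_prior_ = np.log(pr)
        return self

    @classmethod
    def from_grouping(
        cls,
        grouping,
        profiles: Sequence[CodonUsageVector],
        alpha: float = DEFAULT_ALPHA,
        priors: Mapping[str, float] | None = None,
    ) -> "MultinomialCodonClassifier":
        """Build the species model from a SpeciesGrouping over clone profiles."""
        X = np.vstack([p.counts for p in profiles])
        y = np.array([grouping.assignment[p.source_id] for p in profiles])
        return cls(alpha=alpha, priors=priors).fit(X, y)

    # -- scoring -----------------------------------------------------------
    @staticmethod
    def _as_count_matrix(X) -> np.ndarray:
        if isinstance(X, FragmentCounts):
            X = [X]
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], (FragmentCounts, CodonUsageVector)):
            X = np.vstack([f.counts for f in X])
        X = np.asarray(X)
        if X.ndim == 1:
            X = X[None, :]
        return X.astype(np.int64)

    def joint_log_prob(self, X) -> np.ndarray:
        """(n_fragments, n_groups) matrix of log prior + log P(frag | group),
        including the multinomial coefficient (constant per row)."""
        check_is_fitted(self, "feature_log_prob_")
        X = self._as_count_matrix(X)
        N = X.sum(axis=1)
        if np.any(N < 1):
            raise ValueError("empty fragment in X")
        coeff = gammaln(N + 1.0) - gammaln(X + 1.0).sum(axis=1)
        return coeff[:, None] + X @ self.feature_log_prob_.T + self.class_log_prior_

    def predict(self, X) -> np.ndarray:
        jlp = self.joint_log_prob(X)
        return self.classes_[np.argmax(jlp, axis=1)]

    def classify_fragments(self, fragments: Sequence[FragmentCounts], paired: bool = False,
                           min_margin: float | None = None) -> pd.DataFrame:
        """Score fragments; returns one row per (pooled) fragment.

        Columns: read_id, assigned_group, log_prob_best, margin, tie_flag
        (and 'ambiguous' assignment when ``min_margin`` is set and unmet).
        Ties are broken toward the lexicographically smallest group id and
        flagged.  With a single-group model the margin is +inf.
        """
        check_is_fitted(self, "feature_log_prob_")
        if paired:
            fragments = pool_paired(list(fragments))
        rows = []
        jlp = self.joint_log_prob(fragments)
        for frag, scores in zip(fragments, jlp):
            order = np.argsort(scores)[::-1]
            best = int(order[0])
            tie = bool(len(scores) > 1 and np.isclose(scores[order[0]], scores[order[1]], rtol=0, atol=1e-12))
            if tie:
                tied = np.flatnonzero(np.isclose(scores, scores[best], rtol=0, atol=1e-12))
                tied_labels = [str(self.classes_[i]) for i in tied]
                best = int(tied[tied_labels.index(min(tied_labels))])
            margin = float(scores[order[0]] - scores[order[1]]) if len(scores) > 1 else float("inf")
            assigned = str(self.classes_[best])
            if min_margin is not None and margin < min_margin:
                assigned = "ambiguous"
            rows.append(
                {
                    "read_id": frag.read_id,
                    "assigned_group": assigned,
                    "log_prob_best": float(scores[order[0]]),
                    "margin": margin,
                    "tie_flag": tie,
                }
            )
        return pd.DataFrame(rows, columns=["read_id", "assigned_group", "log_prob_best", "margin", "tie_flag"])


def classify(frag, model: MultinomialCodonClassifier):
    """Score one fragment (or a mate pair) against the model.

    Returns (best_group, per-group log-probabilities as a dict, margin).
    """
    frags = list(frag) if isinstance(frag, (list, tuple)) else [frag]
    pooled = pool_paired(frags)[0] if len(frags) > 1 else frags[0]
    df = model.classify_fragments([pooled])
    scores = model.joint_log_prob([pooled])[0]
    per_group = {str(g): float(s) for g, s in zip(model.classes_, scores)}
    return df.loc[0, "assigned_group"], per_group, float(df.loc[0, "margin"])
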