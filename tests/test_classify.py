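"""Multinomial fragment classification: probabilities, ties, pairing."""

import itertools
import math

import numpy as np
import pytest

from codonbin import (
    FragmentCounts,
    MultinomialCodonClassifier,
    classify,
    log_multinomial_prob,
    pool_paired,
)


def test_toy_probabilities_match_closed_form():
    # 2!/(1!1!) * 0.5*0.5 = 0.5 ; 2!/2! * 0.25 = 0.25
    assert log_multinomial_prob(np.array([1, 1]), np.array([0.5, 0.5])) == pytest.approx(
        math.log(0.5), abs=1e-12
    )
    assert log_multinomial_prob(np.array([2, 0]), np.array([0.5, 0.5])) == pytest.approx(
        math.log(0.25), abs=1e-12
    )


def test_empty_fragment_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        log_multinomial_prob(np.zeros(3), np.full(3, 1 / 3))
    with pytest.raises(ValueError, match="empty"):
        FragmentCounts("r", np.zeros(61, dtype=int))


@pytest.mark.parametrize("n_total", [1, 2, 3, 4, 5])
def test_multinomial_normalises_by_enumeration(n_total):
    """Over a toy 3-codon alphabet, summing P(counts) over every possible
    count vector of size N must give exactly 1; each count-vector
    probability must equal the sum over the distinct sequences realising it."""
    rng = np.random.default_rng(n_total)
    p = rng.dirichlet([2.0, 2.0, 2.0])
    total = 0.0
    for counts in itertools.product(range(n_total + 1), repeat=3):
        if sum(counts) != n_total:
            continue
        lp = log_multinomial_prob(np.array(counts), p)
        total += math.exp(lp)
        # sequence-enumeration oracle for this count vector
        seq_prob = sum(
            math.prod(p[s] for s in seq)
            for seq in itertools.product(range(3), repeat=n_total)
            if tuple(seq.count(i) for i in range(3)) == counts
        )
        assert math.exp(lp) == pytest.approx(seq_prob, abs=1e-12)
    assert total == pytest.approx(1.0, abs=1e-9)


def _toy_model(alpha=0.5):
    # group A trained on uniform counts, group B concentrated on codon 0
    X = np.vstack([np.full(61, 10), np.r_[900, np.ones(60, dtype=int)]])
    return MultinomialCodonClassifier(alpha=alpha).fit(X, np.array(["A", "B"]))


def test_likelihood_dominance_assigns_concentrated_fragment():
    model = _toy_model()
    frag = FragmentCounts("f", np.r_[10, np.zeros(60, dtype=int)])
    best, per_group, margin = classify(frag, model)
    assert best == "B" and margin > 0
    assert set(per_group) == {"A", "B"}


def test_single_group_model_margin_is_infinite():
    X = np.full((1, 61), 5)
    model = MultinomialCodonClassifier().fit(X, np.array(["only"]))
    best, _, margin = classify(FragmentCounts("f", np.full(61, 1)), model)
    assert best == "only" and margin == float("inf")


def test_identical_groups_tie_flagged_and_smallest_id_wins():
    X = np.vstack([np.full(61, 10), np.full(61, 10)])
    model = MultinomialCodonClassifier().fit(X, np.array(["zeta", "alpha"]))
    df = model.classify_fragments([FragmentCounts("f", np.full(61, 2))])
    assert bool(df.loc[0, "tie_flag"])
    assert df.loc[0, "assigned_group"] == "alpha"


def test_paired_mates_are_pooled_by_count_summation():
    f1 = FragmentCounts("r1", np.r_[3, np.zeros(60, dtype=int)], mate_id="r2")
    f2 = FragmentCounts("r2", np.r_[1, 2, np.zeros(59, dtype=int)], mate_id="r1")
    pooled = pool_paired([f1, f2])
    assert len(pooled) == 1
    assert pooled[0].total == 6
    assert pooled[0].counts[0] == 4 and pooled[0].counts[1] == 2


def test_argmax_stable_under_count_duplication():
    """Doubling every count rescales log-probabilities but not the winner."""
    model = _toy_model()
    rng = np.random.default_rng(4)
    counts = rng.multinomial(50, np.full(61, 1 / 61), size=20)
    a = model.predict(counts)
    b = model.predict(counts * 2)
    assert np.array_equal(a, b)


def test_smoothing_keeps_unseen_codons_finite():
    X = np.vstack([np.r_[100, np.zeros(60, dtype=int)]])
    model = MultinomialCodonClassifier(alpha=0.5).fit(X, np.array(["g"]))
    frag = np.zeros(61, dtype=int)
    frag[60] = 5  # codon never seen in training
    assert np.isfinite(model.joint_log_prob(frag)).all()


def test_agrees_with_sklearn_multinomial_nb_argmax():
    """Independent oracle: sklearn's multinomial naive Bayes shares the
    smoothed-likelihood argmax (it omits only the count-permutation
    coefficient, constant per fragment)."""
    from sklearn.naive_bayes import MultinomialNB

    rng = np.random.default_rng(11)
    P = [rng.dirichlet(np.full(61, 3.0)) for _ in range(8)]
    X = np.vstack([rng.multinomial(8000, p) for p in P])
    y = np.array([f"G{i}" for i in range(8)])
    mine = MultinomialCodonClassifier(alpha=0.5).fit(X, y)
    ref = MultinomialNB(alpha=0.5, fit_prior=False).fit(X, y)
    frags = np.vstack([rng.multinomial(150, p, size=25) for p in P])
    assert np.array_equal(mine.predict(frags), ref.predict(frags))


def test_accuracy_non_decreasing_in_fragment_length():
    rng = np.random.default_rng(21)
    P = [rng.dirichlet(np.full(61, 9.0)) for _ in range(10)]
    X = np.vstack([rng.multinomial(8000, p) for p in P])
    y = np.array([f"S{i}" for i in range(10)])
    model = MultinomialCodonClassifier().fit(X, y)
    accs = []
    for L in (100, 200, 400):
        frags = np.vstack([rng.multinomial(L, p, size=60) for p in P])
        truth = np.repeat(y, 60)
        accs.append(float((model.predict(frags) == truth).mean()))
    assert accs[0] <= accs[1] + 0.02 and accs[1] <= accs[2] + 0.02


def test_min_margin_marks_ambiguous_reads():
    model = _toy_model()
    frag = FragmentCounts("f", np.full(61, 1))
    df = model.classify_fragments([frag], min_margin=1e9)
    assert df.loc[0, "assigned_group"] == "ambiguous"
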