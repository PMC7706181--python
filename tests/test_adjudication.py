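"""Consensus voting rule: worked examples, brute-force oracle, properties."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdval import (
    AdjudicationPolicy,
    Assignment,
    Label,
    RaterSource,
    TrueRule,
    VoteSet,
    adjudicate,
    adjudicate_corpus,
    merge_rater,
)
from crowdval.errors import ConfigurationError, ValidationError

from conftest import make_corpus

POLICY = AdjudicationPolicy()


def oracle(n_true: int, n_false: int, n_exclude: int) -> Label:
    """Independent restatement of the consensus rule in exact arithmetic:
    exclude at >= half exclude-votes, else true on absolute majority, else false."""
    m = n_true + n_false + n_exclude
    if Fraction(n_exclude, m) >= Fraction(1, 2):
        return Label.EXCLUDE
    if Fraction(n_true, m) > Fraction(1, 2):
        return Label.TRUE
    return Label.FALSE


def votes_from_counts(n_true, n_false, n_exclude):
    return [Label.TRUE] * n_true + [Label.FALSE] * n_false + [Label.EXCLUDE] * n_exclude


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 0, 5), Label.EXCLUDE),  # 5 of 8 say exclude
            ((3, 2, 3), Label.FALSE),  # kept, but no agreement on true
            ((4, 2, 1), Label.TRUE),  # clear majority true among 7
            ((4, 0, 4), Label.EXCLUDE),  # exactly half is "at least half"
            ((3, 4, 0), Label.FALSE),
            ((1, 0, 0), Label.TRUE),  # single-vote passthrough
            ((0, 1, 0), Label.FALSE),
            ((0, 0, 1), Label.EXCLUDE),
        ],
    )
    def test_examples(self, counts, expected):
        result = adjudicate(votes_from_counts(*counts), POLICY)
        assert result.label is expected
        assert result.vote_counts == counts

    def test_empty_votes_error(self):
        with pytest.raises(ValidationError):
            adjudicate([], POLICY)

    def test_exclusion_threshold_arithmetic(self):
        # 4 of 7 excludes, 3 of 7 does not
        assert adjudicate(votes_from_counts(3, 0, 4), POLICY).label is Label.EXCLUDE
        assert adjudicate(votes_from_counts(4, 0, 3), POLICY).label is Label.TRUE

    def test_plurality_variant(self):
        plurality = AdjudicationPolicy(true_rule=TrueRule.PLURALITY_OVER_FALSE)
        # 3 true vs 2 false among 8: plurality says true, the default rule false
        votes = votes_from_counts(3, 2, 3)
        assert adjudicate(votes, plurality).label is Label.TRUE
        assert adjudicate(votes, POLICY).label is Label.FALSE


class TestOracleEquivalence:
    def test_all_count_triples_up_to_nine_votes(self):
        for m in range(1, 10):
            for n_true in range(m + 1):
                for n_false in range(m - n_true + 1):
                    n_exclude = m - n_true - n_false
                    got = adjudicate(votes_from_counts(n_true, n_false, n_exclude), POLICY)
                    assert got.label is oracle(n_true, n_false, n_exclude), (
                        n_true,
                        n_false,
                        n_exclude,
                    )


@st.composite
def count_triples(draw, max_votes=12):
    m = draw(st.integers(1, max_votes))
    n_true = draw(st.integers(0, m))
    n_false = draw(st.integers(0, m - n_true))
    return n_true, n_false, m - n_true - n_false


class TestProperties:
    @given(counts=count_triples())
    @settings(max_examples=200, deadline=None)
    def test_exclusion_monotone(self, counts):
        """Turning any non-exclude vote into exclude never rescues a relation."""
        n_true, n_false, n_exclude = counts
        before = adjudicate(votes_from_counts(*counts), POLICY).label
        for d_true, d_false in ((1, 0), (0, 1)):
            if n_true >= d_true and n_false >= d_false:
                after = adjudicate(
                    votes_from_counts(n_true - d_true, n_false - d_false, n_exclude + 1),
                    POLICY,
                ).label
                if before is Label.EXCLUDE:
                    assert after is Label.EXCLUDE

    @given(counts=count_triples())
    @settings(max_examples=200, deadline=None)
    def test_default_false_on_tie(self, counts):
        n_true, n_false, n_exclude = counts
        if n_true == n_false and 2 * n_exclude < sum(counts):
            got = adjudicate(votes_from_counts(*counts), POLICY).label
            assert got is Label.FALSE

    @given(counts=count_triples())
    @settings(max_examples=100, deadline=None)
    def test_counts_partition_votes(self, counts):
        result = adjudicate(votes_from_counts(*counts), POLICY)
        assert result.n_votes == sum(counts)


def _voteset_for(corpus, labels_per_relation):
    votes = VoteSet()
    for inst, labels in zip(corpus, labels_per_relation):
        for w, lab in enumerate(labels):
            votes.add(inst.relation_id, Assignment(f"h-{inst.relation_id}", f"W{w}", lab))
    return votes


class TestAdjudicateCorpus:
    def test_labels_match_per_item_rule(self):
        corpus = make_corpus(9)
        patterns = [
            votes_from_counts(t, f, e)
            for t, f, e in [(7, 0, 0), (0, 7, 0), (0, 0, 7), (4, 2, 1), (3, 2, 2),
                            (2, 2, 3), (1, 2, 4), (3, 3, 1), (5, 1, 1)]
        ]
        votes = _voteset_for(corpus, patterns)
        labeled, exclusions = adjudicate_corpus(corpus, votes, POLICY)
        for inst, pattern in zip(labeled, patterns):
            t = sum(1 for v in pattern if v is Label.TRUE)
            f = sum(1 for v in pattern if v is Label.FALSE)
            e = len(pattern) - t - f
            assert inst.revised_label is oracle(t, f, e)
        assert len(exclusions) == sum(
            1 for inst in labeled if inst.revised_label is Label.EXCLUDE
        )

    def test_unanimous_true(self):
        corpus = make_corpus(4)
        votes = _voteset_for(corpus, [[Label.TRUE] * 7] * 4)
        labeled, exclusions = adjudicate_corpus(corpus, votes)
        assert all(i.revised_label is Label.TRUE for i in labeled)
        assert exclusions == []

    def test_all_exclude(self):
        corpus = make_corpus(4)
        votes = _voteset_for(corpus, [[Label.EXCLUDE] * 7] * 4)
        labeled, exclusions = adjudicate_corpus(corpus, votes)
        assert all(i.revised_label is Label.EXCLUDE for i in labeled)
        assert len(exclusions) == 4

    def test_unvoted_relation_listed(self):
        corpus = make_corpus(3)
        votes = _voteset_for(corpus, [[Label.TRUE]] * 2 + [[]])
        with pytest.raises(ValidationError, match="no votes"):
            adjudicate_corpus(corpus, votes)


class TestMergeRater:
    def _crowd_votes(self, corpus, n=7):
        return _voteset_for(corpus, [[Label.TRUE] * n] * len(corpus))

    def test_adds_exactly_one_vote_per_relation(self):
        corpus = make_corpus(3)
        votes = self._crowd_votes(corpus)
        extra = pd.DataFrame(
            {"relation_id": corpus.relation_ids, "answer": ["FALSE"] * 3}
        )
        merged = merge_rater(votes, extra, RaterSource.EXTRA_RATER)
        assert all(len(merged[r]) == 8 for r in corpus.relation_ids)
        assert all(len(votes[r]) == 7 for r in corpus.relation_ids)  # input untouched

    def test_empty_extra_is_identity(self):
        corpus = make_corpus(2)
        votes = self._crowd_votes(corpus)
        merged = merge_rater(
            votes, pd.DataFrame({"relation_id": [], "answer": []}), RaterSource.EXPERT
        )
        assert merged == votes

    def test_unknown_relation_rejected(self):
        corpus = make_corpus(2)
        votes = self._crowd_votes(corpus)
        extra = pd.DataFrame({"relation_id": ["ghost"], "answer": ["TRUE"]})
        with pytest.raises(ValidationError, match="unknown relation"):
            merge_rater(votes, extra, RaterSource.EXTRA_RATER)

    def test_duplicate_extra_rating_rejected(self):
        corpus = make_corpus(1)
        votes = self._crowd_votes(corpus)
        extra = pd.DataFrame(
            {"relation_id": [corpus.relation_ids[0]] * 2, "answer": ["TRUE", "FALSE"]}
        )
        with pytest.raises(ValidationError, match="duplicate extra rating"):
            merge_rater(votes, extra, RaterSource.EXTRA_RATER)


def test_invalid_threshold_rejected():
    with pytest.raises(ConfigurationError):
        AdjudicationPolicy(exclusion_threshold=0.0)
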