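"""Majority-consensus adjudication of crowd votes.

The rule, applied per relation to its multiset of m votes over
{TRUE, FALSE, EXCLUDE}:

1. **Exclusion**: if at least half the votes say exclude
   (``n_exclude >= threshold * m``, threshold 1/2 by default), the relation is
   dropped as a pre-annotation error.
2. **True**: otherwise the relation is kept, and labeled TRUE only if the true
   votes reach an absolute majority (``n_true > m / 2``) — the raters *agreed*
   the relation holds.
3. **Default false**: any remaining case — a kept relation with no agreement on
   true — is FALSE, on the argument that false relations are the harder call and
   a false negative costs downstream training less than a false positive.

A single-vote relation degenerates to a passthrough of that vote, so the one
rule serves both the single-assignment and the seven-assignment task designs.
A ``PLURALITY_OVER_FALSE`` variant (TRUE merely needs more true than false
votes; exclude votes count toward m but sit out the contest) is kept as a
policy switch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corpus import Corpus, Label
from .errors import ConfigurationError, ValidationError
from .hits import Assignment, RaterSource, VoteSet

__all__ = [
    "TrueRule",
    "AdjudicationPolicy",
    "AdjudicationResult",
    "adjudicate",
    "merge_rater",
    "adjudicate_corpus",
]


class TrueRule(str, Enum):
    PLURALITY_OVER_FALSE = "PLURALITY_OVER_FALSE"
    ABSOLUTE_MAJORITY = "ABSOLUTE_MAJORITY"


@dataclass(frozen=True)
class AdjudicationPolicy:
    """Parameters of the consensus rule.

    exclusion_threshold
        Fraction of total votes that must say exclude for the relation to be
        dropped; compared as ``n_exclude >= threshold * m`` in exact arithmetic,
        so 4 of 8 and 4 of 7 exclude, 3 of 7 does not.
    default_label
        Label used when neither the exclusion nor the true rule fires.
    true_rule
        ABSOLUTE_MAJORITY (default): TRUE iff n_true > m / 2.
        PLURALITY_OVER_FALSE: TRUE iff n_true > n_false.
    """

    exclusion_threshold: float = 0.5
    default_label: Label = Label.FALSE
    true_rule: TrueRule = TrueRule.ABSOLUTE_MAJORITY

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_threshold <= 1.0:
            raise ConfigurationError(
                f"exclusion_threshold must be in (0, 1], got {self.exclusion_threshold}"
            )


@dataclass(frozen=True)
class AdjudicationResult:
    relation_id: str
    label: Label
    vote_counts: tuple[int, int, int]  # (n_true, n_false, n_exclude)
    rule_fired: str

    @property
    def n_votes(self) -> int:
        return sum(self.vote_counts)


def _count(votes: Iterable[Label]) -> tuple[int, int, int]:
    n_true = n_false = n_exclude = 0
    for v in votes:
        if v is Label.TRUE:
            n_true += 1
        elif v is Label.FALSE:
            n_false += 1
        else:
            n_exclude += 1
    return n_true, n_false, n_exclude


def adjudicate(
    votes: Sequence[Label],
    policy: AdjudicationPolicy = AdjudicationPolicy(),
    relation_id: str = "?",
) -> AdjudicationResult:
    """Apply the consensus rule to one relation's votes."""
    if len(votes) == 0:
        raise ValidationError(f"relation {relation_id}: cannot adjudicate zero votes")
    n_true, n_false, n_exclude = _count(votes)
    m = n_true + n_false + n_exclude
    counts = (n_true, n_false, n_exclude)

    if n_exclude >= policy.exclusion_threshold * m:
        return AdjudicationResult(relation_id, Label.EXCLUDE, counts, "exclusion_majority")
    if policy.true_rule is TrueRule.PLURALITY_OVER_FALSE:
        if n_true > n_false:
            return AdjudicationResult(relation_id, Label.TRUE, counts, "true_plurality")
    else:
        if 2 * n_true > m:
            return AdjudicationResult(relation_id, Label.TRUE, counts, "true_majority")
    return AdjudicationResult(relation_id, policy.default_label, counts, "default")


def merge_rater(
    votes: VoteSet,
    extra: pd.DataFrame | str | Path,
    source_tag: RaterSource,
    worker_id: Optional[str] = None,
) -> VoteSet:
    """Add one extra rating per covered relation (e.g. the on-site rater's pass).

    ``extra`` is a long-format table with columns ``relation_id`` and ``answer``
    (or a CSV/TSV path to one).  Every rated relation must already be in the vote
    set, and may gain at most one rating from this rater.
    """
    if isinstance(extra, (str, Path)):
        sep = "\t" if str(extra).endswith((".tsv", ".tab")) else ","
        extra = pd.read_csv(extra, dtype=str, sep=sep, keep_default_na=False)
    merged = VoteSet({rel: list(assignments) for rel, assignments in votes.items()})
    seen: set[str] = set()
    for _, row in extra.iterrows():
        rel_id = row["relation_id"]
        if rel_id not in merged:
            raise ValidationError(
                f"extra rating for unknown relation {rel_id!r}: not in the vote set"
            )
        if rel_id in seen:
            raise ValidationError(
                f"duplicate extra rating for relation {rel_id!r} from one rater"
            )
        seen.add(rel_id)
        merged.add(
            rel_id,
            Assignment(
                hit_id=f"{source_tag.value.lower()}-{rel_id}",
                worker_id=worker_id or source_tag.value.lower(),
                answer=Label(row["answer"]),
                work_time=float(row["work_time"]) if "work_time" in row else 0.0,
                rater_source=source_tag,
            ),
        )
    return merged


def adjudicate_corpus(
    corpus: Corpus,
    votes: VoteSet,
    policy: AdjudicationPolicy = AdjudicationPolicy(),
) -> tuple[Corpus, list[AdjudicationResult]]:
    """Adjudicate every relation of a corpus; returns the labeled corpus and the
    exclusion list.

    The returned corpus carries the consensus label on every instance (EXCLUDE
    included — dropping excluded relations is the release builder's job).
    """
    unvoted = [inst.relation_id for inst in corpus if inst.relation_id not in votes]
    if unvoted:
        raise ValidationError(
            f"{len(unvoted)} relation(s) have no votes, e.g. {unvoted[:5]}"
        )
    labeled = []
    exclusions: list[AdjudicationResult] = []
    for inst in corpus:
        result = adjudicate(votes.labels(inst.relation_id), policy, inst.relation_id)
        labeled.append(replace(inst, revised_label=result.label))
        if result.label is Label.EXCLUDE:
            exclusions.append(result)
    meta = dict(corpus.metadata, adjudicated=True)
    return Corpus(labeled, meta), exclusions
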