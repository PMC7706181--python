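"""HIT batch generation and crowd-results ingestion.

One HIT (human intelligence task) shows a worker a single sentence with the
phenotype and gene mentions emphasised, and asks for one of three answers:
true relation, false relation, or wrongly labeled (exclude).  A batch input
file has one CSV row per HIT; the results file comes back in the MTurk batch
export dialect (``HITId``, ``WorkerId``, ``WorkTimeInSeconds``, ``Answer.*``)
with one row per assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .corpus import Corpus, Label, RelationInstance
from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "RaterSource",
    "Hit",
    "Assignment",
    "VoteSet",
    "AnomalyReport",
    "ANSWER_ALIASES",
    "render_hit",
    "unwrap_rendered",
    "generate_hit_batch",
    "parse_results",
    "filter_by_time",
]


class RaterSource(str, Enum):
    CROWD = "CROWD"
    EXTRA_RATER = "EXTRA_RATER"
    EXPERT = "EXPERT"


#: Fixed on-screen option order: true relation / false relation / wrongly labeled.
HIT_OPTIONS = ("true relation", "false relation", "wrongly labeled")

#: Normalisation from answer strings (on-screen texts and internal codes) to labels.
#: Extendable: parse_results accepts an extra mapping for custom templates.
ANSWER_ALIASES: dict[str, Label] = {
    "true relation": Label.TRUE,
    "false relation": Label.FALSE,
    "wrongly labeled": Label.EXCLUDE,
    "true": Label.TRUE,
    "false": Label.FALSE,
    "exclude": Label.EXCLUDE,
    "TRUE": Label.TRUE,
    "FALSE": Label.FALSE,
    "EXCLUDE": Label.EXCLUDE,
}

_DIALECTS = {
    "double-asterisk": ("**", "**"),
    "html-bold": ("<b>", "</b>"),
}


@dataclass(frozen=True)
class Hit:
    """One crowd task: a rendered sentence plus the fixed three-option answer set."""

    hit_id: str
    relation_id: str
    rendered_sentence: str
    options: tuple[str, str, str] = HIT_OPTIONS


@dataclass(frozen=True)
class Assignment:
    """One worker's (or on-site rater's / expert's) answer to one HIT."""

    hit_id: str
    worker_id: Optional[str]
    answer: Label
    work_time: float = 0.0
    rater_source: RaterSource = RaterSource.CROWD

    def __post_init__(self) -> None:
        if self.work_time < 0:
            raise ValidationError(f"hit {self.hit_id}: negative work_time {self.work_time}")


class VoteSet:
    """Mapping relation_id -> multiset of assignments.

    Within one relation, a crowd worker id may appear at most once (the platform
    guarantees distinct workers across a HIT's assignments).
    """

    def __init__(self, votes: Optional[Mapping[str, Iterable[Assignment]]] = None):
        self._votes: dict[str, list[Assignment]] = {}
        if votes:
            for rel_id, assignments in votes.items():
                for a in assignments:
                    self.add(rel_id, a)

    def add(self, relation_id: str, assignment: Assignment) -> None:
        bucket = self._votes.setdefault(relation_id, [])
        if (
            assignment.rater_source is RaterSource.CROWD
            and assignment.worker_id is not None
        ):
            seen = {
                a.worker_id
                for a in bucket
                if a.rater_source is RaterSource.CROWD and a.worker_id is not None
            }
            if assignment.worker_id in seen:
                raise ValidationError(
                    f"relation {relation_id}: crowd worker {assignment.worker_id} "
                    "already voted on this relation"
                )
        bucket.append(assignment)

    def __getitem__(self, relation_id: str) -> list[Assignment]:
        return self._votes[relation_id]

    def __contains__(self, relation_id: str) -> bool:
        return relation_id in self._votes

    def __len__(self) -> int:
        return len(self._votes)

    def __iter__(self):
        return iter(self._votes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoteSet):
            return NotImplemented
        if set(self._votes) != set(other._votes):
            return False
        return all(
            sorted(self._votes[k], key=_assignment_key)
            == sorted(other._votes[k], key=_assignment_key)
            for k in self._votes
        )

    def items(self):
        return self._votes.items()

    def labels(self, relation_id: str) -> list[Label]:
        return [a.answer for a in self._votes[relation_id]]

    @property
    def n_assignments(self) -> int:
        return sum(len(v) for v in self._votes.values())

    def assignments(self) -> Iterable[tuple[str, Assignment]]:
        for rel_id, bucket in self._votes.items():
            for a in bucket:
                yield rel_id, a


def _assignment_key(a: Assignment):
    return (a.worker_id or "", a.answer.value, a.work_time, a.rater_source.value)


@dataclass
class AnomalyReport:
    """Ingestion anomalies: unattributed rows and invariant breaches."""

    n_missing_worker_id: int = 0
    duplicate_votes: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return self.n_missing_worker_id == 0 and not self.duplicate_votes


def render_hit(
    instance: RelationInstance,
    dialect: str = "double-asterisk",
    hit_id: Optional[str] = None,
) -> Hit:
    """Render a relation as a HIT: both entity spans wrapped in emphasis markers."""
    try:
        open_m, close_m = _DIALECTS[dialect]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        ) from None
    spans = sorted(
        [instance.phenotype, instance.gene], key=lambda m: m.start, reverse=True
    )
    text = instance.sentence
    for mention in spans:
        text = (
            text[: mention.start]
            + open_m
            + text[mention.start : mention.end]
            + close_m
            + text[mention.end :]
        )
    return Hit(
        hit_id=hit_id or f"hit-{instance.relation_id}",
        relation_id=instance.relation_id,
        rendered_sentence=text,
    )


def unwrap_rendered(rendered: str, dialect: str = "double-asterisk") -> str:
    """Strip the two emphasis wrappers, recovering the original sentence."""
    open_m, close_m = _DIALECTS[dialect]
    out = rendered
    for marker in (open_m, close_m) if open_m != close_m else (open_m,):
        out = out.replace(marker, "", 4 if open_m == close_m else 2)
    return out


def generate_hit_batch(
    corpus: Corpus,
    assignments_per_hit: int,
    path: str | Path,
    dialect: str = "double-asterisk",
) -> pd.DataFrame:
    """Write the batch input CSV (one row per relation) and return it as a frame.

    The declared assignment count is recorded in a metadata comment-free side
    channel: the returned frame's ``attrs`` and the expected-assignment arithmetic
    used by batch audits.
    """
    if assignments_per_hit < 1:
        raise ConfigurationError("assignments_per_hit must be >= 1")
    rows = []
    for inst in corpus:
        hit = render_hit(inst, dialect=dialect)
        rows.append(
            {
                "hit_id": hit.hit_id,
                "relation_id": hit.relation_id,
                "rendered_sentence": hit.rendered_sentence,
            }
        )
    frame = pd.DataFrame(rows, columns=["hit_id", "relation_id", "rendered_sentence"])
    frame.attrs["assignments_per_hit"] = assignments_per_hit
    frame.attrs["expected_assignments"] = assignments_per_hit * len(frame)
    frame.to_csv(path, index=False)
    return frame


_RESULT_COLUMN_SYNONYMS = {
    "hit_id": ("HITId", "hit_id"),
    "worker_id": ("WorkerId", "worker_id"),
    "work_time": ("WorkTimeInSeconds", "work_time"),
    "relation_id": ("Input.relation_id", "relation_id"),
}


def _pick_column(columns: Iterable[str], synonyms: tuple[str, ...]) -> Optional[str]:
    for name in synonyms:
        if name in columns:
            return name
    return None


def parse_results(
    path: str | Path,
    rater_source: RaterSource = RaterSource.CROWD,
    answer_aliases: Optional[Mapping[str, Label]] = None,
) -> tuple[VoteSet, AnomalyReport]:
    """Ingest an MTurk batch-results CSV (or the internal simplified dialect).

    Rows with an empty WorkerId are kept (their votes still count) but tallied in
    the anomaly report.  A duplicate (relation, worker) pair is an invariant
    breach: it is dropped from the vote set and listed in the report.
    """
    aliases = dict(ANSWER_ALIASES)
    if answer_aliases:
        aliases.update(answer_aliases)
    report = AnomalyReport()
    votes = VoteSet()
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return votes, report
    if frame.empty:
        return votes, report

    cols = list(frame.columns)
    hit_col = _pick_column(cols, _RESULT_COLUMN_SYNONYMS["hit_id"])
    worker_col = _pick_column(cols, _RESULT_COLUMN_SYNONYMS["worker_id"])
    time_col = _pick_column(cols, _RESULT_COLUMN_SYNONYMS["work_time"])
    rel_col = _pick_column(cols, _RESULT_COLUMN_SYNONYMS["relation_id"])
    answer_col = next(
        (c for c in cols if c.startswith("Answer.") or c == "answer"), None
    )
    missing = [
        name
        for name, col in [
            ("HITId", hit_col),
            ("WorkerId", worker_col),
            ("WorkTimeInSeconds", time_col),
            ("Answer.*", answer_col),
        ]
        if col is None
    ]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {missing}")

    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(cols, row))
        raw_answer = rec[answer_col].strip()
        label = aliases.get(raw_answer) or aliases.get(raw_answer.lower())
        if label is None:
            raise ParseError(
                f"{path}: line {row_no}: unknown answer string {raw_answer!r}"
            )
        worker = rec[worker_col].strip() or None
        if worker is None:
            report.n_missing_worker_id += 1
        relation_id = rec[rel_col] if rel_col else rec[hit_col]
        assignment = Assignment(
            hit_id=rec[hit_col],
            worker_id=worker,
            answer=label,
            work_time=float(rec[time_col] or 0.0),
            rater_source=rater_source,
        )
        try:
            votes.add(relation_id, assignment)
        except ValidationError:
            report.duplicate_votes.append((relation_id, worker or ""))
    return votes, report


def filter_by_time(votes: VoteSet, cutoff: float) -> VoteSet:
    """Keep only assignments with work_time <= cutoff (for statistics, not adjudication).

    A cutoff of 50 keeps times up to and including 50 s, i.e. the assignments
    completed in under 51 seconds.
    """
    if not cutoff > 0:
        raise ConfigurationError(f"cutoff must be positive, got {cutoff}")
    filtered = VoteSet()
    for rel_id, a in votes.assignments():
        if a.work_time <= cutoff or math.isinf(cutoff):
            filtered.add(rel_id, a)
    return filtered
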