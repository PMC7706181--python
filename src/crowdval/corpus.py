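"""Relation-corpus data model, TSV reader/writer, label mapping and task partition.

A corpus holds one phenotype-gene relation instance per row: a sentence from a
PubMed abstract, the two entity mentions with character offsets, their ontology /
gene identifiers, and a label.  Distant supervision assigns the *original* label
(``KNOWN`` if the pair is in the phenotype-ontology knowledge base, ``UNKNOWN``
otherwise); crowd or expert review assigns the *revised* label
(``TRUE`` / ``FALSE`` / ``EXCLUDE``).

The on-disk format is a plain UTF-8 TSV with a fixed header (see
:data:`CORPUS_COLUMNS`).  Literal tabs or newlines inside sentences are rejected
so the file stays line-per-record and diff-able.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "EntityKind",
    "OriginalLabel",
    "Label",
    "EntityMention",
    "RelationInstance",
    "Corpus",
    "CORPUS_COLUMNS",
    "read_corpus",
    "write_corpus",
    "map_original_labels",
    "partition_corpus",
]


class EntityKind(str, Enum):
    PHENOTYPE = "PHENOTYPE"
    GENE = "GENE"


class OriginalLabel(str, Enum):
    """Distant-supervision label: present in the knowledge base or not."""

    KNOWN = "KNOWN"
    UNKNOWN = "UNKNOWN"


class Label(str, Enum):
    """Revised three-way label used by raters and adjudication."""

    TRUE = "TRUE"
    FALSE = "FALSE"
    EXCLUDE = "EXCLUDE"


@dataclass(frozen=True)
class EntityMention:
    """One entity span inside a sentence.

    Offsets are 0-based, half-open: ``sentence[start:end] == surface_text``.
    """

    surface_text: str
    start: int
    end: int
    entity_kind: EntityKind
    external_id: Optional[str] = None

    def validate_against(self, sentence: str, relation_id: str = "?") -> None:
        if not (0 <= self.start < self.end <= len(sentence)):
            raise ValidationError(
                f"relation {relation_id}: mention offsets [{self.start}, {self.end}) "
                f"out of range for sentence of length {len(sentence)}"
            )
        actual = sentence[self.start : self.end]
        if actual != self.surface_text:
            raise ValidationError(
                f"relation {relation_id}: surface text {self.surface_text!r} does not "
                f"match sentence substring {actual!r} at [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class RelationInstance:
    """One candidate phenotype-gene relation: a sentence plus its two mentions."""

    relation_id: str
    pmid: str
    sentence: str
    phenotype: EntityMention
    gene: EntityMention
    original_label: OriginalLabel
    revised_label: Optional[Label] = None

    def __post_init__(self) -> None:
        self.phenotype.validate_against(self.sentence, self.relation_id)
        self.gene.validate_against(self.sentence, self.relation_id)
        if self.phenotype.start < self.gene.end and self.gene.start < self.phenotype.end:
            raise ValidationError(
                f"relation {self.relation_id}: phenotype span "
                f"[{self.phenotype.start}, {self.phenotype.end}) overlaps gene span "
                f"[{self.gene.start}, {self.gene.end})"
            )


@dataclass
class Corpus:
    """An ordered collection of relation instances with free-form metadata."""

    instances: list[RelationInstance] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [inst.relation_id for inst in self.instances]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValidationError(f"duplicate relation_ids in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[RelationInstance]:
        return iter(self.instances)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.instances == other.instances

    @property
    def relation_ids(self) -> list[str]:
        return [inst.relation_id for inst in self.instances]

    def original_label_counts(self) -> dict[OriginalLabel, int]:
        counts = {lab: 0 for lab in OriginalLabel}
        for inst in self.instances:
            counts[inst.original_label] += 1
        return counts

    def revised_label_counts(self) -> dict[Label, int]:
        counts = {lab: 0 for lab in Label}
        for inst in self.instances:
            if inst.revised_label is not None:
                counts[inst.revised_label] += 1
        return counts


CORPUS_COLUMNS = (
    "relation_id",
    "pmid",
    "sentence",
    "phen_text",
    "phen_start",
    "phen_end",
    "phen_id",
    "gene_text",
    "gene_start",
    "gene_end",
    "gene_id",
    "original_label",
    "revised_label",
)

_NONE = ""  # empty field encodes a missing optional value


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as the fixed-schema TSV.

    Sentences containing literal tabs or newlines are rejected: they would break
    the one-line-per-record contract.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        writer.writerow(CORPUS_COLUMNS)
        for inst in corpus.instances:
            if "\t" in inst.sentence or "\n" in inst.sentence:
                raise ValidationError(
                    f"relation {inst.relation_id}: sentence contains a literal tab or "
                    "newline, which the TSV format forbids"
                )
            writer.writerow(
                [
                    inst.relation_id,
                    inst.pmid,
                    inst.sentence,
                    inst.phenotype.surface_text,
                    inst.phenotype.start,
                    inst.phenotype.end,
                    inst.phenotype.external_id or _NONE,
                    inst.gene.surface_text,
                    inst.gene.start,
                    inst.gene.end,
                    inst.gene.external_id or _NONE,
                    inst.original_label.value,
                    inst.revised_label.value if inst.revised_label else _NONE,
                ]
            )


def read_corpus(path: str | Path, metadata: Optional[dict] = None) -> Corpus:
    """Read a corpus TSV, validating offsets against each sentence.

    Raises :class:`ParseError` (naming the line) on malformed rows and
    :class:`ValidationError` (naming the relation) on offset/surface mismatches.
    """
    path = Path(path)
    instances: list[RelationInstance] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected header row") from None
        if tuple(header) != CORPUS_COLUMNS:
            raise ParseError(f"{path}: line 1: header {header!r} does not match schema")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(CORPUS_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(CORPUS_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            rec = dict(zip(CORPUS_COLUMNS, row))
            try:
                phen = EntityMention(
                    surface_text=rec["phen_text"],
                    start=int(rec["phen_start"]),
                    end=int(rec["phen_end"]),
                    entity_kind=EntityKind.PHENOTYPE,
                    external_id=rec["phen_id"] or None,
                )
                gene = EntityMention(
                    surface_text=rec["gene_text"],
                    start=int(rec["gene_start"]),
                    end=int(rec["gene_end"]),
                    entity_kind=EntityKind.GENE,
                    external_id=rec["gene_id"] or None,
                )
                original = OriginalLabel(rec["original_label"])
                revised = Label(rec["revised_label"]) if rec["revised_label"] else None
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            instances.append(
                RelationInstance(
                    relation_id=rec["relation_id"],
                    pmid=rec["pmid"],
                    sentence=rec["sentence"],
                    phenotype=phen,
                    gene=gene,
                    original_label=original,
                    revised_label=revised,
                )
            )
    return Corpus(instances=instances, metadata=metadata or {"source": str(path)})


def map_original_labels(corpus: Corpus) -> Corpus:
    """Seed revised labels from the distant-supervision originals.

    KNOWN becomes the baseline TRUE, UNKNOWN the baseline FALSE.  Refuses to
    overwrite instances that already carry a revised label.
    """
    already = [i.relation_id for i in corpus if i.revised_label is not None]
    if already:
        raise ValidationError(
            f"{len(already)} instance(s) already adjudicated (e.g. {already[:3]}); "
            "refusing to overwrite revised labels"
        )
    mapped = [
        replace(
            inst,
            revised_label=Label.TRUE
            if inst.original_label is OriginalLabel.KNOWN
            else Label.FALSE,
        )
        for inst in corpus
    ]
    return Corpus(instances=mapped, metadata=dict(corpus.metadata))


def partition_corpus(
    corpus: Corpus,
    fraction: float,
    seed: int,
    stratified: bool = False,
) -> tuple[Corpus, Corpus]:
    """Split a corpus into two disjoint partitions of floor(fraction*N) and the rest.

    The split is a uniform shuffle under ``seed``; with ``stratified`` the
    original-label proportions are preserved within one instance per stratum
    (largest-remainder apportionment of the floor(fraction*N) total).
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1), got {fraction}")
    if len(corpus) == 0:
        raise ConfigurationError("cannot partition an empty corpus")
    rng = np.random.default_rng(seed)
    n1 = math.floor(fraction * len(corpus))

    if not stratified:
        order = rng.permutation(len(corpus))
        take = set(order[:n1].tolist())
    else:
        strata: dict[OriginalLabel, list[int]] = {}
        for idx, inst in enumerate(corpus):
            strata.setdefault(inst.original_label, []).append(idx)
        # largest-remainder apportionment of n1 across strata
        keys = sorted(strata, key=lambda k: k.value)
        quotas = {k: fraction * len(strata[k]) for k in keys}
        floors = {k: math.floor(quotas[k]) for k in keys}
        remainder = n1 - sum(floors.values())
        by_frac = sorted(keys, key=lambda k: quotas[k] - floors[k], reverse=True)
        for k in by_frac[: max(remainder, 0)]:
            floors[k] += 1
        take = set()
        for k in keys:
            idxs = np.asarray(strata[k])
            order = rng.permutation(len(idxs))
            take.update(idxs[order[: floors[k]]].tolist())

    part1 = [inst for i, inst in enumerate(corpus) if i in take]
    part2 = [inst for i, inst in enumerate(corpus) if i not in take]
    meta1 = dict(corpus.metadata, partition="task1", fraction=fraction, seed=seed)
    meta2 = dict(corpus.metadata, partition="task2", fraction=fraction, seed=seed)
    return Corpus(part1, meta1), Corpus(part2, meta2)
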