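"""Merge adjudicated task partitions into a new corpus release and export
train/test splits for downstream relation-extraction systems.

A release keeps the TRUE/FALSE relations of both partitions and drops the
excluded ones.  Abstract and annotation counts are recomputed from the kept
relations only: an abstract counts if at least one kept relation cites its
PMID, and an entity annotation counts if it participates in a kept relation
(distinct by PMID + span + identifier).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .corpus import Corpus, EntityMention, Label, RelationInstance
from .errors import ConfigurationError, ValidationError
from .stats import class_weight_multiplier

__all__ = ["ReleaseManifest", "build_release", "export_splits"]


@dataclass
class ReleaseManifest:
    """Provenance and recomputed counts of a merged release."""

    release_tag: str
    sources: dict[str, str]
    n_abstracts: int
    n_phenotype_annotations: int
    n_gene_annotations: int
    n_true: int
    n_false: int
    n_total: int
    n_excluded: int
    exclusion_rate_pct: float
    built_at: str = ""
    seed: Optional[int] = None
    notes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.__dict__)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _annotation_key(pmid: str, mention: EntityMention) -> tuple:
    return (pmid, mention.start, mention.end, mention.surface_text, mention.external_id)


def _recount(corpus: Corpus) -> tuple[int, int, int]:
    abstracts = {inst.pmid for inst in corpus}
    phen = {_annotation_key(i.pmid, i.phenotype) for i in corpus}
    gene = {_annotation_key(i.pmid, i.gene) for i in corpus}
    return len(abstracts), len(phen), len(gene)


def build_release(
    task1: Corpus,
    task2: Corpus,
    release_tag: str = "release-3",
    task1_source: str = "worker",
    task2_source: str = "expert",
    seed: Optional[int] = None,
) -> tuple[Corpus, ReleaseManifest]:
    """Merge two adjudicated, disjoint partitions into one release.

    EXCLUDE-labeled instances are dropped; TRUE/FALSE instances are kept with
    their revised labels.  The manifest reports recomputed abstract/annotation/
    relation counts and the overall exclusion rate.
    """
    overlap = set(task1.relation_ids) & set(task2.relation_ids)
    if overlap:
        raise ValidationError(f"partitions overlap on {len(overlap)} relation_id(s)")
    for name, part in (("task1", task1), ("task2", task2)):
        unlabeled = [i.relation_id for i in part if i.revised_label is None]
        if unlabeled:
            raise ValidationError(f"{name}: {len(unlabeled)} unlabeled instance(s)")

    kept = [
        inst
        for part in (task1, task2)
        for inst in part
        if inst.revised_label is not Label.EXCLUDE
    ]
    n_excluded = len(task1) + len(task2) - len(kept)
    merged = Corpus(
        instances=kept,
        metadata={
            "release_tag": release_tag,
            "task1_source": task1_source,
            "task2_source": task2_source,
        },
    )
    n_true = sum(1 for i in kept if i.revised_label is Label.TRUE)
    n_false = len(kept) - n_true
    n_abs, n_phen, n_gene = _recount(merged)
    original_total = len(task1) + len(task2)
    rate = round(100.0 * n_excluded / original_total, 2) if original_total else 0.0
    manifest = ReleaseManifest(
        release_tag=release_tag,
        sources={"task1": task1_source, "task2": task2_source},
        n_abstracts=n_abs,
        n_phenotype_annotations=n_phen,
        n_gene_annotations=n_gene,
        n_true=n_true,
        n_false=n_false,
        n_total=len(kept),
        n_excluded=n_excluded,
        exclusion_rate_pct=rate,
        built_at=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        seed=seed,
        notes=[
            "annotation counts cover only mentions participating in kept relations",
            "exclusion rate recomputed from partition totals",
        ],
    )
    return merged, manifest


def _placeholder_sentence(inst: RelationInstance) -> str:
    """Replace the two entity mentions by typed placeholders."""
    spans = sorted(
        [
            (inst.phenotype.start, inst.phenotype.end, "PHENOTYPE"),
            (inst.gene.start, inst.gene.end, "GENE"),
        ],
        reverse=True,
    )
    text = inst.sentence
    for start, end, kind in spans:
        text = text[:start] + f"@{kind}$" + text[end:]
    return text


def export_splits(
    release: Corpus,
    test_source: Corpus,
    train_path: str | Path,
    test_path: str | Path,
    class_weight: float = 5.0,
    fmt: str = "placeholder-tsv",
) -> dict:
    """Export train/test TSVs with typed entity placeholders, plus weighting metadata.

    Each row carries the placeholder sentence and a TRUE/FALSE label.  The
    returned metadata records the full class-imbalance multiplier of the
    training set and the (smaller) class weight chosen for the loss function.
    """
    if fmt != "placeholder-tsv":
        raise ConfigurationError(f"unknown export format {fmt!r}")
    if len(test_source) == 0:
        raise ConfigurationError("refusing to export an empty test set")
    overlap = set(release.relation_ids) & set(test_source.relation_ids)
    if overlap:
        raise ValidationError(
            f"train and test share {len(overlap)} relation_id(s); splits must be disjoint"
        )

    def _frame(corpus: Corpus) -> pd.DataFrame:
        rows = []
        for inst in corpus:
            if inst.revised_label is Label.EXCLUDE or inst.revised_label is None:
                raise ValidationError(
                    f"relation {inst.relation_id}: export requires a TRUE/FALSE label"
                )
            rows.append(
                {
                    "relation_id": inst.relation_id,
                    "pmid": inst.pmid,
                    "sentence": _placeholder_sentence(inst),
                    "label": inst.revised_label.value,
                }
            )
        return pd.DataFrame(rows, columns=["relation_id", "pmid", "sentence", "label"])

    train = _frame(release)
    test = _frame(test_source)
    train.to_csv(train_path, sep="\t", index=False)
    test.to_csv(test_path, sep="\t", index=False)
    n_true = int((train["label"] == "TRUE").sum())
    n_false = int((train["label"] == "FALSE").sum())
    meta = {
        "n_train": len(train),
        "n_test": len(test),
        "train_true": n_true,
        "train_false": n_false,
        "full_multiplier": class_weight_multiplier(n_true, n_false),
        "class_weight": class_weight,
        "format": fmt,
    }
    return meta
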