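"""Shared fixtures: tiny in-memory corpora and simulated vote sets."""

from __future__ import annotations

import pytest

from crowdval import (
    Corpus,
    EntityKind,
    EntityMention,
    Label,
    OriginalLabel,
    RelationInstance,
)


def make_instance(
    rel_id: str,
    phen: str = "short stature",
    gene: str = "GH1",
    original: OriginalLabel = OriginalLabel.UNKNOWN,
    revised: Label | None = None,
    pmid: str = "12345678",
) -> RelationInstance:
    """A valid instance with computed offsets: '<phen> is linked to <gene>.'"""
    sentence = f"{phen} is linked to {gene}."
    g_start = len(phen) + len(" is linked to ")
    return RelationInstance(
        relation_id=rel_id,
        pmid=pmid,
        sentence=sentence,
        phenotype=EntityMention(phen, 0, len(phen), EntityKind.PHENOTYPE, "HP:0004322"),
        gene=EntityMention(gene, g_start, g_start + len(gene), EntityKind.GENE, "2688"),
        original_label=original,
        revised_label=revised,
    )


def make_corpus(n: int, n_known: int = 0, **kwargs) -> Corpus:
    """n instances, the first n_known labeled KNOWN, the rest UNKNOWN."""
    return Corpus(
        instances=[
            make_instance(
                f"r{i:04d}",
                original=OriginalLabel.KNOWN if i < n_known else OriginalLabel.UNKNOWN,
                pmid=f"{10000000 + i}",
                **kwargs,
            )
            for i in range(n)
        ]
    )


@pytest.fixture
def tiny_corpus() -> Corpus:
    return make_corpus(3, n_known=1)


@pytest.fixture
def mixed_corpus() -> Corpus:
    return make_corpus(10, n_known=4)
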