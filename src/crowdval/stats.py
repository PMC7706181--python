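"""Descriptive layers of a crowdsourcing campaign.

Covers the label distributions of the adjudicated partitions, the campaign cost
model (reward + platform fee per assignment, with the platform's round-up-to-
the-cent behaviour), worker/work-time summaries under a break cutoff, the class
imbalance multiplier used to weight downstream training, and the aggregation of
benchmark F-measures against a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import Corpus, Label
from .errors import ConfigurationError, ValidationError
from .hits import VoteSet, filter_by_time

__all__ = [
    "LabelDistribution",
    "CostConfig",
    "WorkerSummary",
    "label_distribution",
    "cost_total",
    "worker_summary",
    "class_weight_multiplier",
    "fmeasure_aggregation",
    "BENCHMARK_FMEASURES",
]


def _round_half_up(x: float | Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, total: int) -> float:
    return _round_half_up(Decimal(100 * count) / Decimal(total), 2)


@dataclass(frozen=True)
class LabelDistribution:
    """Counts and percentages of one task's adjudicated labels.

    Percentages refer to the *original* task total, and ``total_kept`` is the
    sum of true and false relations (the excluded ones leave the corpus).
    """

    n_true: int
    n_false: int
    n_excluded: int
    original_total: int
    pct_true: float
    pct_false: float
    pct_excluded: float
    total_kept: int
    pct_kept: float


def label_distribution(
    adjudicated: Corpus | dict[Label, int],
    original_total: Optional[int] = None,
) -> LabelDistribution:
    """Tabulate adjudicated labels against the original task total.

    Accepts either a fully labeled corpus or a pre-tabulated count mapping.
    Percentages are rounded half-up to 2 decimals.
    """
    if isinstance(adjudicated, Corpus):
        unlabeled = [i.relation_id for i in adjudicated if i.revised_label is None]
        if unlabeled:
            raise ValidationError(
                f"{len(unlabeled)} unlabeled instance(s), e.g. {unlabeled[:5]}"
            )
        counts = adjudicated.revised_label_counts()
    else:
        counts = {lab: int(adjudicated.get(lab, 0)) for lab in Label}
    n_true, n_false, n_excl = counts[Label.TRUE], counts[Label.FALSE], counts[Label.EXCLUDE]
    total = original_total if original_total is not None else n_true + n_false + n_excl
    if n_true + n_false + n_excl > total:
        raise ValidationError(
            f"label counts ({n_true + n_false + n_excl}) exceed original total ({total})"
        )
    kept = n_true + n_false
    return LabelDistribution(
        n_true=n_true,
        n_false=n_false,
        n_excluded=n_excl,
        original_total=total,
        pct_true=_pct(n_true, total),
        pct_false=_pct(n_false, total),
        pct_excluded=_pct(n_excl, total),
        total_kept=kept,
        pct_kept=_pct(kept, total),
    )


@dataclass(frozen=True)
class CostConfig:
    """Cost model of one task: per-assignment reward plus platform fee.

    The platform charges the fee rounded **up** to the cent; a sub-cent
    surcharge (e.g. for requiring high-performing "Masters" workers) is
    therefore absorbed whenever the base fee already sits at a cent boundary.
    """

    n_tasks: int
    assignments_per_task: int
    reward: Decimal = Decimal("0.02")
    base_fee: Decimal = Decimal("0.01")
    masters_surcharge: Decimal = Decimal("0.001")

    def __post_init__(self) -> None:
        object.__setattr__(self, "reward", Decimal(str(self.reward)))
        object.__setattr__(self, "base_fee", Decimal(str(self.base_fee)))
        object.__setattr__(self, "masters_surcharge", Decimal(str(self.masters_surcharge)))
        if min(self.reward, self.base_fee, self.masters_surcharge) < 0:
            raise ConfigurationError("monetary amounts must be non-negative")
        if self.n_tasks < 0 or self.assignments_per_task < 0:
            raise ConfigurationError("task and assignment counts must be non-negative")

    @property
    def rounded_fee(self) -> Decimal:
        """Platform fee per assignment after the round-up-to-cent rule.

        The base fee is taken as the platform's already-rounded per-assignment
        fee; the surcharge only raises it if it pushes past the next cent
        boundary from an unrounded base.
        """
        if self.base_fee == self.base_fee.quantize(Decimal("0.01")):
            return self.base_fee  # already at a cent boundary: surcharge absorbed
        return (self.base_fee + self.masters_surcharge).quantize(
            Decimal("0.01"), rounding=ROUND_CEILING
        )


def cost_total(config: CostConfig) -> Decimal:
    """Total campaign cost in USD, exact cent arithmetic:
    n_tasks x assignments x (reward + rounded fee)."""
    per_assignment = config.reward + config.rounded_fee
    total = config.n_tasks * config.assignments_per_task * per_assignment
    return total.quantize(Decimal("0.01"))


@dataclass(frozen=True)
class WorkerSummary:
    """Worker and work-time statistics for a campaign under a break cutoff."""

    n_workers: int
    n_assignments: int
    assignments_per_worker: int  # rounded half-up
    n_missing_worker_id: int
    cutoff: float
    n_under_cutoff: int
    time_mean: float
    time_median: float
    time_sd: float
    histogram_counts: np.ndarray = field(repr=False, default=None)
    histogram_edges: np.ndarray = field(repr=False, default=None)


def worker_summary(votes: VoteSet, cutoff: float = 50.0) -> WorkerSummary:
    """Summarise workers and work times.

    Time statistics (mean/median/sd and the 1-second histogram) cover only
    assignments completed within ``cutoff`` seconds — longer times are treated
    as mid-task breaks, not rating effort.  Worker and assignment counts cover
    everything.
    """
    if len(votes) == 0:
        raise ValidationError("empty vote set")
    workers = set()
    times = []
    n_assignments = 0
    n_missing = 0
    for _, a in votes.assignments():
        n_assignments += 1
        if a.worker_id is None:
            n_missing += 1
        else:
            workers.add(a.worker_id)
        times.append(a.work_time)
    if not workers:
        raise ValidationError("no attributed workers in the vote set")
    kept = filter_by_time(votes, cutoff)
    kept_times = np.array([a.work_time for _, a in kept.assignments()], dtype=float)
    edges = np.arange(0.0, np.floor(cutoff) + 2.0)
    hist, _ = np.histogram(kept_times, bins=edges)
    per_worker = int(_round_half_up(Decimal(n_assignments) / Decimal(len(workers)), 0))
    return WorkerSummary(
        n_workers=len(workers),
        n_assignments=n_assignments,
        assignments_per_worker=per_worker,
        n_missing_worker_id=n_missing,
        cutoff=cutoff,
        n_under_cutoff=len(kept_times),
        time_mean=float(kept_times.mean()) if kept_times.size else float("nan"),
        time_median=float(np.median(kept_times)) if kept_times.size else float("nan"),
        time_sd=float(kept_times.std(ddof=1)) if kept_times.size > 1 else 0.0,
        histogram_counts=hist,
        histogram_edges=edges,
    )


def class_weight_multiplier(n_true: int, n_false: int) -> float:
    """Full class-imbalance multiplier: majority/minority count ratio
    (equivalently the ratio of their percentages), rounded to 1 decimal."""
    if n_false <= 0:
        raise ConfigurationError("n_false must be positive to form the ratio")
    return _round_half_up(Decimal(n_true) / Decimal(n_false), 1)


#: Published benchmark F-measures of two relation-extraction systems (a
#: bidirectional-LSTM ontology model and a biomedical BERT) on the original
#: distantly supervised corpus and on its crowd-revised releases.  Inputs to
#: :func:`fmeasure_aggregation`; the ``"PGR original"`` rows are the baseline.
BENCHMARK_FMEASURES: tuple[tuple[str, str, float], ...] = (
    ("BiOnt", "PGR original", 0.4459),
    ("BiOnt", "Amazon Task 1 (train) + PGR original (test)", 0.8175),
    ("BiOnt", "Amazon Task 1 (train) + Amazon/extra-rater consensus Task 2 (test)", 0.7992),
    ("BiOnt", "Amazon Task 1 (train) + Expert Task 2 (test)", 0.8861),
    ("BiOnt", "Amazon/extra-rater consensus Task 2 (train) + PGR original (test)", 0.7608),
    ("BiOnt", "Expert Task 2 (train) + PGR original (test)", 0.8072),
    ("BioBERT", "PGR original", 0.4910),
    ("BioBERT", "Amazon Task 1 (train) + PGR original (test)", 0.8000),
    ("BioBERT", "Amazon Task 1 (train) + Amazon/extra-rater consensus Task 2 (test)", 0.7946),
    ("BioBERT", "Amazon Task 1 (train) + Expert (test)", 0.8915),
    ("BioBERT", "Amazon/extra-rater consensus Task 2 (train) + PGR original (test)", 0.8134),
    ("BioBERT", "Expert Task 2 (train) + PGR original (test)", 0.8082),
)


def fmeasure_aggregation(
    rows: Iterable[tuple[str, str, float]],
    baseline_tag: str = "PGR original",
) -> tuple[float, float, float]:
    """Average the non-baseline and baseline F-measures and their difference.

    A row is a (method, experiment, F-measure) triple; a row belongs to the
    baseline when its experiment tag equals ``baseline_tag`` exactly.  Returns
    (avg_other, avg_baseline, delta), each rounded half-up to 4 decimals with
    the delta computed on the unrounded means.
    """
    baseline = [Decimal(str(f)) for _, exp, f in rows if exp == baseline_tag]
    other = [Decimal(str(f)) for _, exp, f in rows if exp != baseline_tag]
    if not baseline or not other:
        raise ValidationError(
            f"need at least one baseline and one non-baseline row "
            f"(got {len(baseline)} baseline, {len(other)} other)"
        )
    avg_base = sum(baseline) / len(baseline)
    avg_other = sum(other) / len(other)
    delta = avg_other - avg_base
    return (
        _round_half_up(avg_other, 4),
        _round_half_up(avg_base, 4),
        _round_half_up(delta, 4),
    )
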