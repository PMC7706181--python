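"""Synthetic crowdsourcing campaigns with known ground truth.

The generative model mirrors a redundant-annotation campaign on a
microtask platform:

* each item carries a latent label in {TRUE, FALSE, EXCLUDE} (EXCLUDE standing
  for a pre-annotation error a competent rater should flag);
* each item is assigned to ``a`` *distinct* workers sampled uniformly from a
  small pool of ``W`` workers (the platform guarantees unique workers per item
  but nothing else — the same worker may rate many items);
* a worker's answer is drawn from the row of their 3x3 confusion matrix for the
  item's latent label; a *malicious* worker answers uniformly at random;
* work times are a mixture of a lognormal "genuine effort" component (mode in
  the low teens of seconds) and a rare long-break component (exponential tail
  reaching tens of thousands of seconds).

Everything is reproducible from one master seed via per-item spawned substreams.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adjudication import AdjudicationPolicy, adjudicate
from .agreement import build_ratings_table, fleiss_kappa, krippendorff_alpha_nominal
from .corpus import Label
from .errors import ConfigurationError
from .hits import Assignment, RaterSource, VoteSet

__all__ = [
    "TimeModel",
    "WorkerProfile",
    "CampaignConfig",
    "default_worker_pool",
    "confusion_from_accuracy",
    "sample_campaign",
    "expected_consensus_accuracy",
    "recover_parameters_check",
    "RecoveryReport",
]

CATEGORIES = (Label.TRUE, Label.FALSE, Label.EXCLUDE)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class TimeModel:
    """Work-time distribution: lognormal effort plus a rare long-break tail.

    Defaults (mu=2.4, sigma=0.6) give a genuine-effort mean of ~13 s; the break
    component (probability 0.005, exponential mean 3000 s) reproduces the
    occasional multi-hour completion time a requester observes.
    """

    mu: float = 2.4
    sigma: float = 0.6
    break_probability: float = 0.005
    break_scale: float = 3000.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        times = rng.lognormal(self.mu, self.sigma, size)
        breaks = rng.random(size) < self.break_probability
        times = times + breaks * rng.exponential(self.break_scale, size)
        return times

    def truncated_mean(self, cutoff: float, grid: int = 200_001) -> float:
        """Mean of the genuine-effort lognormal conditional on t <= cutoff,
        by numerical integration (the break tail is above any sane cutoff)."""
        from scipy import stats

        dist = stats.lognorm(s=self.sigma, scale=np.exp(self.mu))
        t = np.linspace(1e-9, cutoff, grid)
        pdf = dist.pdf(t)
        return float(np.trapezoid(t * pdf, t) / np.trapezoid(pdf, t))


def confusion_from_accuracy(theta: float, binary: bool = False) -> np.ndarray:
    """Row-stochastic confusion matrix for a worker of accuracy ``theta``.

    Errors split evenly over the two wrong categories; with ``binary`` the mass
    stays within {TRUE, FALSE} (latent EXCLUDE still maps to EXCLUDE w.p. theta).
    """
    if not 0.0 <= theta <= 1.0:
        raise ConfigurationError(f"accuracy must be in [0, 1], got {theta}")
    k = len(CATEGORIES)
    mat = np.full((k, k), (1.0 - theta) / (k - 1))
    np.fill_diagonal(mat, theta)
    if binary:
        # confine true/false errors to the other binary label
        mat = np.full((k, k), 0.0)
        np.fill_diagonal(mat, theta)
        mat[0, 1] = 1.0 - theta  # latent TRUE -> FALSE
        mat[1, 0] = 1.0 - theta  # latent FALSE -> TRUE
        mat[2, 0] = mat[2, 1] = (1.0 - theta) / 2.0  # latent EXCLUDE errs to T/F
    return mat


@dataclass(frozen=True)
class WorkerProfile:
    """One simulated worker: reliability (confusion matrix) and time behaviour."""

    worker_id: str
    confusion: np.ndarray = field(default_factory=lambda: confusion_from_accuracy(0.8))
    malicious: bool = False
    time_model: TimeModel = TimeModel()

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if self.malicious:
            conf = np.full((3, 3), 1.0 / 3.0)
        if conf.shape != (3, 3) or (conf < 0).any():
            raise ConfigurationError(
                f"worker {self.worker_id}: confusion must be a non-negative 3x3 matrix"
            )
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError(
                f"worker {self.worker_id}: confusion rows must sum to 1"
            )
        object.__setattr__(self, "confusion", conf)


@dataclass(frozen=True)
class CampaignConfig:
    """Design of a simulated campaign.

    Defaults follow the redundant-annotation task design this package models:
    7 assignments per item from a pool of 33 workers, with the latent label
    mix set to the expert-reviewed composition of such a corpus (roughly 54%
    true, 14% false, 32% exclude-worthy).
    """

    n_items: int
    n_workers: int = 33
    assignments_per_item: int = 7
    latent_distribution: tuple[float, float, float] = (0.5362, 0.1436, 0.3202)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigurationError("n_items must be >= 1")
        if self.n_workers < self.assignments_per_item:
            raise ConfigurationError(
                f"need at least as many workers ({self.n_workers}) as assignments "
                f"per item ({self.assignments_per_item}) for distinct workers"
            )
        pi = np.asarray(self.latent_distribution, dtype=float)
        if pi.shape != (3,) or (pi < 0).any() or not np.isclose(pi.sum(), 1.0):
            raise ConfigurationError("latent_distribution must be 3 non-negative shares summing to 1")


def default_worker_pool(
    n_workers: int = 33,
    accuracies: Sequence[float] = (0.6, 0.8, 0.95),
    malicious_fraction: float = 0.05,
    binary: bool = False,
) -> list[WorkerProfile]:
    """A heterogeneous pool: accuracy tiers cycled over the pool plus a small
    malicious (uniform-random) contingent.  The tier values are plausible
    placeholders, not estimates fitted to any campaign."""
    n_malicious = int(round(malicious_fraction * n_workers))
    profiles = []
    tiers = itertools.cycle(accuracies)
    for w in range(n_workers):
        if w < n_malicious:
            profiles.append(WorkerProfile(worker_id=f"W{w:03d}", malicious=True))
        else:
            profiles.append(
                WorkerProfile(
                    worker_id=f"W{w:03d}",
                    confusion=confusion_from_accuracy(next(tiers), binary=binary),
                )
            )
    return profiles


def sample_campaign(
    config: CampaignConfig,
    profiles: Optional[Sequence[WorkerProfile]] = None,
    seed: Optional[int] = None,
) -> tuple[dict[str, Label], VoteSet]:
    """Simulate a campaign: returns (latent truth map, vote set).

    Every item gets exactly ``assignments_per_item`` votes from distinct
    workers.  One master seed drives a spawned substream per item, so any
    prefix of the campaign is reproducible on its own.
    """
    profiles = list(profiles) if profiles is not None else default_worker_pool(config.n_workers)
    if len(profiles) != config.n_workers:
        raise ConfigurationError(
            f"expected {config.n_workers} worker profiles, got {len(profiles)}"
        )
    master = np.random.SeedSequence(seed if seed is not None else config.seed)
    latent_seq, *item_seqs = master.spawn(config.n_items + 1)
    latent_rng = np.random.default_rng(latent_seq)
    pi = np.asarray(config.latent_distribution)
    latent_idx = latent_rng.choice(3, size=config.n_items, p=pi)

    truth: dict[str, Label] = {}
    votes = VoteSet()
    for i, item_seq in enumerate(item_seqs):
        rng = np.random.default_rng(item_seq)
        rel_id = f"rel-{i:06d}"
        latent = CATEGORIES[latent_idx[i]]
        truth[rel_id] = latent
        chosen = rng.choice(config.n_workers, size=config.assignments_per_item, replace=False)
        for w in chosen:
            profile = profiles[w]
            row = profile.confusion[_CAT_INDEX[latent]]
            answer = CATEGORIES[rng.choice(3, p=row)]
            work_time = float(profile.time_model.sample(rng, 1)[0])
            votes.add(
                rel_id,
                Assignment(
                    hit_id=f"hit-{rel_id}",
                    worker_id=profile.worker_id,
                    answer=answer,
                    work_time=work_time,
                    rater_source=RaterSource.CROWD,
                ),
            )
    return truth, votes


def expected_consensus_accuracy(
    policy: AdjudicationPolicy,
    theta: float,
    a: int,
) -> float:
    """Exact probability that consensus over ``a`` votes recovers the latent
    label, for homogeneous binary workers of accuracy ``theta`` and balanced
    (TRUE/FALSE) truth.

    Enumerates every binomial vote outcome and applies the adjudication policy;
    an even ``a`` is refused because ties change the rule's semantics.
    """
    from scipy import stats

    if a < 1 or a % 2 == 0:
        raise ConfigurationError(f"assignment count must be a positive odd integer, got {a}")
    if not 0.0 <= theta <= 1.0:
        raise ConfigurationError(f"accuracy must be in [0, 1], got {theta}")
    total = 0.0
    for latent in (Label.TRUE, Label.FALSE):
        wrong = Label.FALSE if latent is Label.TRUE else Label.TRUE
        acc = 0.0
        for k in range(a + 1):  # k votes for the latent label
            votes = [latent] * k + [wrong] * (a - k)
            result = adjudicate(votes, policy)
            if result.label is latent:
                acc += float(stats.binom.pmf(k, a, theta))
        total += 0.5 * acc
    return total


@dataclass
class RecoveryReport:
    """End-to-end check of a simulated campaign against its generative model."""

    n_items: int
    empirical_accuracy: float
    expected_accuracy: Optional[float]
    accuracy_ci95: Optional[tuple[float, float]]
    accuracy_within_ci: Optional[bool]
    fleiss_kappa: Optional[float]
    krippendorff_alpha: Optional[float]
    reference_kappa: Optional[float]
    reference_alpha: Optional[float]
    notes: str = ""


def recover_parameters_check(
    config: CampaignConfig,
    profiles: Optional[Sequence[WorkerProfile]] = None,
    seed: Optional[int] = None,
    policy: AdjudicationPolicy = AdjudicationPolicy(),
    binary_theta: Optional[float] = None,
    reference_factor: int = 10,
) -> RecoveryReport:
    """Simulate, adjudicate, and compare against the model's predictions.

    * consensus accuracy vs the enumeration oracle (when ``binary_theta`` names
      the homogeneous binary accuracy), with a 95% normal-approximation
      binomial interval around the oracle value;
    * empirical kappa/alpha vs reference values from an independent
      re-simulation with ``reference_factor`` x items (different substreams).
    """
    from scipy import stats as _stats

    truth, votes = sample_campaign(config, profiles, seed)
    correct = 0
    for rel_id, latent in truth.items():
        result = adjudicate(votes.labels(rel_id), policy, rel_id)
        if result.label is latent:
            correct += 1
    emp_acc = correct / config.n_items

    expected = ci = within = None
    if binary_theta is not None:
        expected = expected_consensus_accuracy(policy, binary_theta, config.assignments_per_item)
        half = 1.959964 * float(np.sqrt(expected * (1 - expected) / config.n_items))
        ci = (expected - half, expected + half)
        within = ci[0] <= emp_acc <= ci[1]

    def _metrics(vs: VoteSet) -> tuple[Optional[float], Optional[float]]:
        table = build_ratings_table(vs)
        try:
            k = fleiss_kappa(table)
        except Exception:
            k = None
        try:
            al = krippendorff_alpha_nominal(table)
        except Exception:
            al = None
        return k, al

    kappa, alpha = _metrics(votes)
    ref_config = CampaignConfig(
        n_items=config.n_items * reference_factor,
        n_workers=config.n_workers,
        assignments_per_item=config.assignments_per_item,
        latent_distribution=config.latent_distribution,
        seed=config.seed + 1,
    )
    ref_kappa, ref_alpha = _metrics(sample_campaign(ref_config, profiles)[1])
    return RecoveryReport(
        n_items=config.n_items,
        empirical_accuracy=emp_acc,
        expected_accuracy=expected,
        accuracy_ci95=ci,
        accuracy_within_ci=within,
        fleiss_kappa=kappa,
        krippendorff_alpha=alpha,
        reference_kappa=ref_kappa,
        reference_alpha=ref_alpha,
    )
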