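"""Inter-rater agreement: Fleiss' kappa and Krippendorff's alpha (nominal).

Both coefficients correct raw agreement for chance.  Fleiss' kappa

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e)

assumes a complete design: every item is rated by the same number n >= 2 of
raters, with per-item agreement ``P_i = (sum_j n_ij^2 - n) / (n (n - 1))`` and
chance agreement ``P_bar_e = sum_j p_j^2`` from the marginal category shares
``p_j``.  Krippendorff's alpha (nominal metric) tolerates missing ratings:
it is computed from the coincidence matrix over all pairable values,

    alpha = 1 - D_o / D_e,

with observed disagreement ``D_o`` the off-diagonal coincidence mass and
expected disagreement ``D_e`` from the value marginals.  Items with fewer than
two ratings contribute no pairable values and are ignored.

When every rating falls in a single category, chance agreement is 1 and both
coefficients are undefined; this is signalled with
:class:`~crowdval.errors.UndefinedAgreementError` rather than a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .corpus import Label
from .errors import UndefinedAgreementError, ValidationError
from .hits import RaterSource, VoteSet

__all__ = [
    "RatingsTable",
    "AgreementReport",
    "build_ratings_table",
    "fleiss_kappa",
    "krippendorff_alpha_nominal",
    "qualitative_label",
    "agreement_report",
    "STANDARD_GROUPS",
]

CATEGORIES = (Label.TRUE, Label.FALSE, Label.EXCLUDE)


@dataclass
class RatingsTable:
    """Items x categories count matrix.

    ``counts[i, j]`` is the number of raters assigning category ``j`` to item
    ``i``.  For Fleiss' kappa every row must sum to the same rater count n >= 2;
    Krippendorff's alpha accepts ragged row sums.
    """

    counts: np.ndarray
    categories: tuple = CATEGORIES
    item_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("ratings table must be 2-D (items x categories)")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or (self.counts < 0).any():
                raise ValidationError("ratings table entries must be non-negative integers")
            self.counts = self.counts.astype(int)

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def fixed_rater_count(self) -> int:
        """Raters per item for a complete design; error if the design is ragged."""
        sums = self.row_sums
        if len(set(sums.tolist())) != 1:
            offenders = _offending_items(self, sums)
            raise ValidationError(
                "unequal rater counts per item: a Fleiss' kappa table needs a "
                f"complete design (offending items: {offenders[:5]})"
            )
        return int(sums[0])


def _offending_items(table: RatingsTable, sums: np.ndarray) -> list[str]:
    mode = np.bincount(sums).argmax()
    bad = np.nonzero(sums != mode)[0]
    if table.item_ids:
        return [table.item_ids[i] for i in bad]
    return [str(i) for i in bad]


def build_ratings_table(
    votes: VoteSet,
    sources: Optional[Iterable[RaterSource]] = None,
    categories: tuple = CATEGORIES,
) -> RatingsTable:
    """Tabulate a vote set into an items x categories count matrix.

    ``sources`` restricts the table to particular rater groups (e.g. crowd only,
    crowd plus on-site rater, on-site rater plus expert); ``None`` keeps all.
    """
    wanted = set(sources) if sources is not None else None
    index = {cat: j for j, cat in enumerate(categories)}
    item_ids = sorted(votes)
    rows = np.zeros((len(item_ids), len(categories)), dtype=int)
    for i, rel_id in enumerate(item_ids):
        for a in votes[rel_id]:
            if wanted is None or a.rater_source in wanted:
                rows[i, index[a.answer]] += 1
    keep = rows.sum(axis=1) > 0
    return RatingsTable(
        counts=rows[keep],
        categories=categories,
        item_ids=[r for r, k in zip(item_ids, keep) if k],
    )


def fleiss_kappa(table: RatingsTable) -> float:
    """Fleiss' kappa for a complete nominal design.

    Raises :class:`UndefinedAgreementError` when all ratings fall in a single
    category (chance agreement is 1, the coefficient is 0/0).
    """
    n = table.fixed_rater_count()
    if n < 2:
        raise ValidationError(f"Fleiss' kappa needs >= 2 raters per item, got n={n}")
    counts = table.counts
    N = table.n_items
    p_j = counts.sum(axis=0) / (N * n)
    p_bar_e = float(np.sum(p_j**2))
    if p_bar_e >= 1.0:
        raise UndefinedAgreementError(
            "all ratings fall in a single category; Fleiss' kappa is undefined"
        )
    p_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    p_bar = float(np.mean(p_i))
    return (p_bar - p_bar_e) / (1.0 - p_bar_e)


def krippendorff_alpha_nominal(
    ratings: Sequence[Sequence] | RatingsTable,
) -> float:
    """Krippendorff's alpha with the nominal difference function.

    Accepts either per-item rating lists (possibly ragged) or a
    :class:`RatingsTable`.  Items with fewer than two ratings are ignored.
    """
    if isinstance(ratings, RatingsTable):
        counts = ratings.counts
    else:
        values = sorted({v for unit in ratings for v in unit}, key=str)
        index = {v: j for j, v in enumerate(values)}
        counts = np.zeros((len(ratings), len(values)), dtype=int)
        for i, unit in enumerate(ratings):
            for v in unit:
                counts[i, index[v]] += 1

    m = counts.sum(axis=1)
    pairable = m >= 2
    counts = counts[pairable]
    m = m[pairable]
    if counts.size == 0 or counts.sum() == 0:
        raise UndefinedAgreementError("no pairable values; alpha is undefined")

    # coincidence matrix: o[c, k] = sum_u n_uc (n_uk - delta_ck) / (m_u - 1)
    K = counts.shape[1]
    o = np.zeros((K, K))
    for row, m_u in zip(counts, m):
        outer = np.outer(row, row) - np.diag(row)
        o += outer / (m_u - 1)
    n_c = o.sum(axis=1)
    n_total = n_c.sum()
    d_o = (o.sum() - np.trace(o)) / n_total
    d_e = (n_total**2 - np.sum(n_c**2)) / (n_total * (n_total - 1))
    if d_e == 0:
        raise UndefinedAgreementError(
            "all pairable ratings fall in a single category; alpha is undefined"
        )
    return float(1.0 - d_o / d_e)


#: Landis-Koch qualitative bands for chance-corrected agreement.
_LANDIS_KOCH = (
    (0.00, "slight"),
    (0.20, "fair"),
    (0.40, "moderate"),
    (0.60, "substantial"),
    (0.80, "almost perfect"),
)

#: Values this close to a band boundary are reported with the adjacent band too.
BOUNDARY_SLACK = 0.005


def qualitative_label(kappa: float) -> str:
    """Landis-Koch band for a coefficient in [-1, 1].

    <0 poor; [0, 0.20] slight; (0.20, 0.40] fair; (0.40, 0.60] moderate;
    (0.60, 0.80] substantial; >0.80 almost perfect.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValidationError(f"agreement coefficient out of [-1, 1]: {kappa}")
    if kappa < 0:
        return "poor"
    label = "slight"
    for lower, name in _LANDIS_KOCH:
        if kappa > lower:
            label = name
    return label


def qualitative_label_hedged(kappa: float) -> str:
    """Band label, hedged with the adjacent band when within 0.005 of a boundary."""
    label = qualitative_label(kappa)
    for lower, name in _LANDIS_KOCH[1:]:
        if abs(kappa - lower) <= BOUNDARY_SLACK:
            below = qualitative_label(lower - 1e-9)
            above = qualitative_label(lower + 1e-9)
            if below != above:
                return f"{below} to {above}"
    return label


@dataclass
class AgreementReport:
    """Both coefficients for one rater group, with design diagnostics."""

    group_name: str
    n_items: int
    raters_description: str
    fleiss_kappa: Optional[float]
    krippendorff_alpha: Optional[float]
    qualitative: Optional[str]
    deviation: Optional[float]
    n_distinct_raters: int
    ratings_per_rater_mean: float
    notes: str = ""


#: The three rater groupings used when a campaign has crowd, on-site and expert passes.
STANDARD_GROUPS = {
    "workers": (RaterSource.CROWD,),
    "workers+extra": (RaterSource.CROWD, RaterSource.EXTRA_RATER),
    "extra+expert": (RaterSource.EXTRA_RATER, RaterSource.EXPERT),
}


def agreement_report(
    votes: VoteSet,
    groups: Optional[dict[str, tuple[RaterSource, ...]]] = None,
) -> list[AgreementReport]:
    """One report per rater group: kappa, alpha, their absolute deviation
    (a low deviation supports an unbiased estimate), the qualitative band, and
    rater-overlap diagnostics (distinct raters, mean ratings per rater) that
    flag how far the design is from either coefficient's ideal assumptions.
    """
    groups = groups if groups is not None else STANDARD_GROUPS
    reports = []
    for name, sources in groups.items():
        table = build_ratings_table(votes, sources=sources)
        raters = [
            a.worker_id
            for _, a in votes.assignments()
            if a.rater_source in set(sources) and a.worker_id is not None
        ]
        n_distinct = len(set(raters))
        per_rater = len(raters) / n_distinct if n_distinct else float("nan")
        notes = []
        kappa: Optional[float] = None
        alpha: Optional[float] = None
        try:
            kappa = fleiss_kappa(table)
        except (UndefinedAgreementError, ValidationError) as exc:
            notes.append(f"kappa: {exc}")
        try:
            alpha = krippendorff_alpha_nominal(table)
        except UndefinedAgreementError as exc:
            notes.append(f"alpha: {exc}")
        deviation = abs(alpha - kappa) if kappa is not None and alpha is not None else None
        row_sums = sorted(set(table.row_sums.tolist()))
        reports.append(
            AgreementReport(
                group_name=name,
                n_items=table.n_items,
                raters_description=f"ratings per item: {row_sums}",
                fleiss_kappa=kappa,
                krippendorff_alpha=alpha,
                qualitative=qualitative_label_hedged(kappa) if kappa is not None else None,
                deviation=deviation,
                n_distinct_raters=n_distinct,
                ratings_per_rater_mean=per_rater,
                notes="; ".join(notes),
            )
        )
    return reports
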