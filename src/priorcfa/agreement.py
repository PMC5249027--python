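"""Item-factor classification and inter-rater agreement statistics.

Implements the three analysis steps applied to the expert sorting study:

* majority (strict plurality) classification of items to factors, with
  exclusion of tied or predominantly rejected items;
* Gwet's AC1 chance-corrected agreement coefficient for multiple raters on
  nominal categories;
* average shared ratings (ASR): the per-factor percentage of expert votes
  cast for factors other than an item's majority factor, a measure of how
  distinctive the items of each factor are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .votes import FACTORS, REJECT, VoteMatrix

NO_SINGLE_MAJORITY = "no_single_majority"
PREDOMINANTLY_REJECTED = "predominantly_rejected"


@dataclass(frozen=True)
class ItemClassification:
    """Partition of the item pool into factor assignments and exclusions.

    ``assignments`` maps retained item ids to their factor label;
    ``exclusions`` maps dropped item ids to the reason they were dropped
    (``no_single_majority`` or ``predominantly_rejected``).
    """

    assignments: dict[int, str]
    exclusions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.assignments) & set(self.exclusions)
        if overlap:
            raise ValueError(f"items both assigned and excluded: {sorted(overlap)}")
        bad = {f for f in self.assignments.values() if f not in FACTORS}
        if bad:
            raise ValueError(f"unknown factor labels: {sorted(bad)}")
        bad_r = {r for r in self.exclusions.values()
                 if r not in (NO_SINGLE_MAJORITY, PREDOMINANTLY_REJECTED)}
        if bad_r:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad_r)}")

    @property
    def item_ids(self) -> list[int]:
        return sorted(set(self.assignments) | set(self.exclusions))

    @property
    def factors(self) -> list[str]:
        present = set(self.assignments.values())
        return [f for f in FACTORS if f in present]

    def items_on(self, factor: str) -> list[int]:
        return sorted(i for i, f in self.assignments.items() if f == factor)

    @property
    def n_assigned(self) -> int:
        return len(self.assignments)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement summary: AC1, per-factor ASR (%), factor x factor sharing."""

    ac1: float
    asr_by_factor: dict[str, float]
    shared_rating_matrix: pd.DataFrame
    n_raters: int
    n_items: int

    def to_dict(self) -> dict:
        return {
            "ac1": self.ac1,
            "asr_by_factor": self.asr_by_factor,
            "shared_rating_matrix": {
                f: {g: float(self.shared_rating_matrix.at[f, g])
                    for g in self.shared_rating_matrix.columns}
                for f in self.shared_rating_matrix.index
            },
            "n_raters": self.n_raters,
            "n_items": self.n_items,
        }


def classify_items(votes: VoteMatrix) -> ItemClassification:
    """Assign each item to its strict-plurality category, or exclude it.

    An item is retained when a single substantive factor received strictly
    more votes than every other category. Items whose modal category is the
    rejection category (possibly tied) are excluded as predominantly
    rejected; other ties for the maximum are excluded for lack of a single
    majority.
    """
    assignments: dict[int, str] = {}
    exclusions: dict[int, str] = {}
    counts = votes.counts
    arr = counts.to_numpy()
    cats = list(counts.columns)
    reject_col = cats.index(REJECT)
    for row, item in zip(arr, counts.index):
        top = row.max()
        winners = np.flatnonzero(row == top)
        if row[reject_col] == top:
            exclusions[int(item)] = PREDOMINANTLY_REJECTED
        elif len(winners) > 1:
            exclusions[int(item)] = NO_SINGLE_MAJORITY
        else:
            assignments[int(item)] = cats[int(winners[0])]
    return ItemClassification(assignments, exclusions)


def gwet_ac1(votes: VoteMatrix) -> float:
    """Gwet's AC1 chance-corrected agreement coefficient.

    With r raters, q categories and r_ik votes for category k on item i,

        Pa = mean_i  sum_k r_ik (r_ik - 1) / (r (r - 1))
        Pe = 1/(q-1) sum_k pi_k (1 - pi_k),   pi_k = mean_i r_ik / r
        AC1 = (Pa - Pe) / (1 - Pe)

    AC1 equals 1 exactly under perfect agreement and is near 0 when votes
    are at chance level. All q categories offered to the raters, including
    rejection, enter the chance term.
    """
    r = votes.n_raters
    if r < 2:
        raise ValueError("AC1 is undefined for a single rater")
    counts = votes.counts.to_numpy(dtype=float)
    q = counts.shape[1]
    if q < 2:
        raise ValueError("AC1 requires at least two categories")
    pa = float((counts * (counts - 1)).sum(axis=1).mean() / (r * (r - 1)))
    pi = counts.mean(axis=0) / r
    pe = float((pi * (1 - pi)).sum() / (q - 1))
    return (pa - pe) / (1 - pe)


def shared_ratings(
    votes: VoteMatrix,
    classification: ItemClassification,
    include_reject: bool = False,
) -> AgreementReport:
    """Average shared ratings per factor plus the full agreement report.

    For each assigned item, the shared-rating fraction is the share of its
    votes cast for factors other than its assigned one. By default rejection
    votes are dropped from both numerator and denominator, so ASR measures
    confusion among substantive factors only; ``include_reject=True`` keeps
    them in the denominator (rejection votes then count as shared).
    The factor x factor matrix entry (f, g) is the mean, over items assigned
    to f, of the percentage of votes received by category g; its off-diagonal
    row sums reproduce the per-factor ASR.
    """
    missing = set(classification.assignments) - set(votes.counts.index)
    if missing:
        raise ValueError(f"classified items absent from votes: {sorted(missing)}")

    factors = classification.factors
    cols = list(FACTORS) + ([REJECT] if include_reject else [])
    frac_rows: dict[str, list[np.ndarray]] = {f: [] for f in factors}
    for item, f in classification.assignments.items():
        row = votes.counts.loc[item, cols].to_numpy(dtype=float)
        denom = row.sum()
        if denom == 0:  # only rejection votes and include_reject=False
            continue
        frac_rows[f].append(row / denom)

    mat = pd.DataFrame(0.0, index=factors, columns=cols)
    asr: dict[str, float] = {}
    for f in factors:
        rows = frac_rows[f]
        if not rows:
            raise ValueError(f"factor {f} has no items with countable votes")
        mean_frac = np.mean(rows, axis=0) * 100.0
        mat.loc[f] = mean_frac
        own = cols.index(f)
        asr[f] = float(mean_frac.sum() - mean_frac[own])

    return AgreementReport(
        ac1=gwet_ac1(votes),
        asr_by_factor=asr,
        shared_rating_matrix=mat,
        n_raters=votes.n_raters,
        n_items=votes.n_items,
    )
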