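"""Expert vote matrices from item-sorting studies.

Each of a panel of raters assigns every questionnaire item to exactly one
category: one of the seven substantive factors of the prosthesis-satisfaction
model (SAT, FoS, BSI, SUP, SOC, MOB, OUT) or a rejection category meaning the
item should be dropped from the pool. A :class:`VoteMatrix` stores the
resulting per-item vote counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven substantive latent factors, in canonical order:
#: satisfaction, feeling of security, body schema integration, support,
#: socket, mobility, outer appearance.
FACTORS: tuple[str, ...] = ("SAT", "FoS", "BSI", "SUP", "SOC", "MOB", "OUT")

#: Label of the rejection category (item should leave the pool).
REJECT: str = "REJECT"

#: All rating categories offered to the experts.
CATEGORIES: tuple[str, ...] = FACTORS + (REJECT,)


class VoteMatrixError(ValueError):
    """Raised when vote counts violate the vote-matrix contract."""


@dataclass(frozen=True)
class VoteMatrix:
    """Per-item expert vote counts over rating categories.

    Parameters
    ----------
    counts
        Integer DataFrame, one row per item (index = item ids), one column
        per category. Every row must sum to ``n_raters``.
    n_raters
        Number of experts; each expert casts exactly one vote per item.
    """

    counts: pd.DataFrame
    n_raters: int
    categories: tuple[str, ...] = field(default=CATEGORIES)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.shape[0] == 0:
            raise VoteMatrixError("vote matrix has no items")
        if self.n_raters < 1:
            raise VoteMatrixError("n_raters must be positive")
        if len(set(counts.columns)) != len(counts.columns):
            raise VoteMatrixError("duplicate category labels")
        if list(counts.columns) != list(self.categories):
            raise VoteMatrixError(
                f"categories must be exactly {list(self.categories)} in order, "
                f"got {list(counts.columns)}"
            )
        if sum(c == REJECT for c in counts.columns) != 1:
            raise VoteMatrixError(f"{REJECT!r} category must appear exactly once")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise VoteMatrixError("vote counts must be integers")
            arr = arr.astype(np.int64)
            object.__setattr__(self, "counts", pd.DataFrame(
                arr, index=counts.index, columns=counts.columns))
        if (arr < 0).any():
            raise VoteMatrixError("vote counts must be non-negative")
        bad = counts.index[arr.sum(axis=1) != self.n_raters]
        if len(bad):
            raise VoteMatrixError(
                f"rows {list(bad)} do not sum to n_raters={self.n_raters}")
        if counts.index.has_duplicates:
            raise VoteMatrixError("duplicate item ids")

    @property
    def item_ids(self) -> list[int]:
        return list(self.counts.index)

    @property
    def n_items(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    def votes_for(self, item_id: int, category: str) -> int:
        return int(self.counts.at[item_id, category])


def vote_matrix_from_dicts(
    rows: dict[int, dict[str, int]], n_raters: int
) -> VoteMatrix:
    """Build a :class:`VoteMatrix` from ``{item_id: {category: count}}``.

    Categories absent from an item's dict get zero votes.
    """
    df = pd.DataFrame(
        [[int(rows[i].get(c, 0)) for c in CATEGORIES] for i in rows],
        index=pd.Index(list(rows), name="item_id"),
        columns=list(CATEGORIES),
        dtype=np.int64,
    )
    return VoteMatrix(df, n_raters)
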