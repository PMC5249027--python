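"""Synthetic expert votes and Likert response data.

Two generators make every pipeline stage testable without the (unpublished)
study data:

* :func:`simulate_votes` draws expert vote matrices from a
  Dirichlet-multinomial model with a single consensus knob. Each item's
  category probabilities come from a Dirichlet whose true factor carries
  ``concentration`` times the weight of each competing factor, so
  ``concentration >> 1`` approaches unanimity (AC1 -> 1) and
  ``concentration = 1`` is chance-level sorting (AC1 ~ 0). A fixed
  precision constant keeps the per-item probabilities close to their mean;
  without it the Dirichlet overdispersion itself would read as agreement.
* :func:`simulate_responses` draws respondent data from the same linear
  factor model the CFA fits, discretized onto the 5-point Likert scale
  through fixed thresholds, with independent random omissions emulating
  respondents' option to skip items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import ItemClassification
from .votes import CATEGORIES, FACTORS, REJECT, VoteMatrix

#: Default cut points dividing a standard-normal-scale response into the
#: five Likert categories; symmetric and unit-spaced so the middle
#: categories are balanced.
DEFAULT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: Dirichlet weight per competing factor. Controls how tightly each item's
#: probability vector concentrates around its mean: at the symmetric
#: setting (consensus knob = 1) the induced chance-corrected agreement stays
#: within Monte-Carlo error of zero rather than reflecting overdispersion.
DIRICHLET_PRECISION = 50.0


@dataclass(frozen=True)
class VoteSimConfig:
    """Configuration of the Dirichlet-multinomial vote simulator.

    ``concentration`` is the ratio of the Dirichlet weight on each item's
    true factor to the weight on every competing factor;
    ``rejection_prob`` is the expected share of rejection votes.
    """

    n_items: int
    true_assignment: dict[int, str]
    n_raters: int = 22
    concentration: float = 10.0
    rejection_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if self.n_raters < 1:
            raise ValueError("n_raters must be positive")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")
        if not 0.0 <= self.rejection_prob < 1.0:
            raise ValueError("rejection_prob must lie in [0, 1)")
        if len(self.true_assignment) != self.n_items:
            raise ValueError("true_assignment must cover every item")
        bad = set(self.true_assignment.values()) - set(FACTORS)
        if bad:
            raise ValueError(f"unknown factors in true_assignment: {sorted(bad)}")


def round_robin_assignment(n_items: int) -> dict[int, str]:
    """Items 1..n assigned to the seven factors in rotation."""
    return {i: FACTORS[(i - 1) % len(FACTORS)] for i in range(1, n_items + 1)}


def simulate_votes(config: VoteSimConfig) -> VoteMatrix:
    """Draw a :class:`VoteMatrix` under the Dirichlet-multinomial model."""
    if config.seed is None:
        raise ValueError("a seed is required")
    rng = np.random.default_rng(config.seed)
    items = sorted(config.true_assignment)
    q = len(CATEGORIES)
    counts = np.zeros((len(items), q), dtype=np.int64)
    sub_idx = {f: i for i, f in enumerate(FACTORS)}
    rej_col = CATEGORIES.index(REJECT)
    for r, item in enumerate(items):
        alpha_sub = np.full(len(FACTORS), DIRICHLET_PRECISION)
        alpha_sub[sub_idx[config.true_assignment[item]]] *= config.concentration
        p = np.zeros(q)
        if config.rejection_prob > 0:
            # expected rejection mass rejection_prob; Dirichlet over the rest
            alpha_rej = config.rejection_prob / (1 - config.rejection_prob) \
                * alpha_sub.sum()
            full = np.concatenate([alpha_sub, [alpha_rej]])
            draw = rng.dirichlet(full)
            p[: len(FACTORS)] = draw[:-1]
            p[rej_col] = draw[-1]
        else:
            p[: len(FACTORS)] = rng.dirichlet(alpha_sub)
        counts[r] = rng.multinomial(config.n_raters, p)
    df = pd.DataFrame(counts, index=pd.Index(items, name="item_id"),
                      columns=list(CATEGORIES))
    return VoteMatrix(df, config.n_raters)


@dataclass(frozen=True)
class ResponseSimConfig:
    """Configuration of the Likert response simulator.

    ``true_loadings`` maps item id -> loading; intercepts default to 0 and
    error sds to 1 for items not listed. ``thresholds`` are the four
    increasing cut points mapping the continuous response to categories
    1..5; ``factor_correlations`` (factors x factors, optional) induces
    correlated latent traits.
    """

    n_respondents: int
    true_loadings: dict[int, float]
    true_intercepts: dict[int, float] = field(default_factory=dict)
    error_sds: dict[int, float] = field(default_factory=dict)
    thresholds: tuple[float, float, float, float] = DEFAULT_THRESHOLDS
    omission_prob: float = 0.0
    factor_correlations: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be positive")
        t = np.asarray(self.thresholds, dtype=float)
        if t.size != 4 or not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be 4 strictly increasing reals")
        if not 0.0 <= self.omission_prob < 1.0:
            raise ValueError("omission_prob must lie in [0, 1)")
        if any(s <= 0 for s in self.error_sds.values()):
            raise ValueError("error_sds must be > 0")
        if self.factor_correlations is not None:
            R = np.asarray(self.factor_correlations, dtype=float)
            if R.ndim != 2 or R.shape[0] != R.shape[1] or \
                    not np.allclose(R, R.T):
                raise ValueError("factor_correlations must be symmetric square")
            if np.linalg.eigvalsh(R).min() <= 0:
                raise ValueError("factor_correlations must be positive definite")


def simulate_responses(
    classification: ItemClassification,
    config: ResponseSimConfig,
    return_latent: bool = False,
):
    """Draw a respondents x items Likert table from the linear factor model.

    Latent traits are standard normal (optionally correlated across
    factors); the continuous response ``nu + lambda * eta + eps`` is cut at
    the thresholds into categories 1..5; cells are then omitted (NaN)
    independently with ``omission_prob``. With ``return_latent`` the
    generating latent scores (n_respondents x factors) are also returned.
    """
    if config.seed is None:
        raise ValueError("a seed is required")
    items = sorted(classification.assignments)
    missing = [j for j in items if j not in config.true_loadings]
    if missing:
        raise ValueError(f"true_loadings missing for assigned items {missing}")
    factors = classification.factors
    F = len(factors)
    if config.factor_correlations is not None and \
            np.asarray(config.factor_correlations).shape[0] != F:
        raise ValueError("factor_correlations size must match factor count")

    rng = np.random.default_rng(config.seed)
    N = config.n_respondents
    R = (np.eye(F) if config.factor_correlations is None
         else np.asarray(config.factor_correlations, dtype=float))
    eta = rng.multivariate_normal(np.zeros(F), R, size=N,
                                  method="cholesky")
    fmap = {f: i for i, f in enumerate(factors)}
    lam = np.array([config.true_loadings[j] for j in items])
    nu = np.array([config.true_intercepts.get(j, 0.0) for j in items])
    sd = np.array([config.error_sds.get(j, 1.0) for j in items])
    fidx = np.array([fmap[classification.assignments[j]] for j in items])

    ystar = nu + eta[:, fidx] * lam + rng.standard_normal((N, len(items))) * sd
    y = np.searchsorted(np.asarray(config.thresholds), ystar) + 1.0
    if config.omission_prob > 0:
        omit = rng.random((N, len(items))) < config.omission_prob
        y = np.where(omit, np.nan, y)
    df = pd.DataFrame(y, columns=[f"item_{j}" for j in items],
                      index=pd.RangeIndex(N, name="respondent_id"))
    if return_latent:
        return df, pd.DataFrame(eta, columns=factors,
                                index=df.index)
    return df


def reconstructed_study_votes():
    """Vote matrix consistent with the published elicitation table.

    Raw study votes were never published; this synthetic stand-in places
    each retained item's majority count (reconstructed from the printed
    prior means as round(M * 22)) on its assigned factor and spreads the
    remaining votes as evenly as possible over the six other substantive
    factors, so the assigned factor always keeps a strict plurality — only
    the majority count affects prior elicitation. The unanimously sorted
    item keeps all 22 votes on its factor.
    """
    from .datasets import load_published_loading_priors

    t3 = load_published_loading_priors()
    rows = np.zeros((len(t3), len(CATEGORIES)), dtype=np.int64)
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    for r, (item, rec) in enumerate(t3.iterrows()):
        f = rec["factor"]
        k = int(rec["majority_votes"])
        rows[r, cat_idx[f]] = k
        others = [g for g in FACTORS if g != f]
        rest = 22 - k
        base, extra = divmod(rest, len(others))
        for i, g in enumerate(others):
            rows[r, cat_idx[g]] = base + (1 if i < extra else 0)
    df = pd.DataFrame(rows, index=pd.Index(t3.index, name="item_id"),
                      columns=list(CATEGORIES))
    return VoteMatrix(df, 22)
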