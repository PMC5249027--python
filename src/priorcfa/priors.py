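"""Elicitation of informed priors from expert agreement.

The expert study is turned into prior distributions for the measurement
model as follows. An item assigned to its factor by k of r experts gets a
Normal prior on its factor loading with

    mean M = k / r        and        sd = (1 - M) / 2,

so that more unanimously sorted items carry larger prior loadings with less
prior uncertainty. A unanimously sorted item (k = r) would yield the
degenerate prior N(1, 0), which is replaced by a prior resembling the mean
of the other loading priors on the same factor. All remaining measurement
parameters are left uninformed: intercepts ~ N(0, 100), measurement error
variances ~ inverse-Gamma(0.01, 0.01) and latent factor values ~ N(0, 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .agreement import ItemClassification
from .votes import VoteMatrix

LOADING = "loading"
INTERCEPT = "intercept"
ERROR_VARIANCE = "error_variance"
LATENT = "latent"
ROLES = (LOADING, INTERCEPT, ERROR_VARIANCE, LATENT)

#: Scale (standard deviation) of the vague Normal priors on intercepts and
#: latent factor values.
UNINFORMED_SD = 100.0
#: Shape and scale of the inverse-Gamma prior on error variances.
ERROR_PRIOR = (0.01, 0.01)


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior distribution.

    ``family`` is ``"normal"`` (params = mean, sd) or ``"inverse_gamma"``
    (params = shape, scale). ``informed`` marks expert-elicited priors and
    may only be true for loadings; ``replaced`` marks a loading prior that
    came from the unanimity-replacement rule rather than direct elicitation.
    """

    role: str
    family: str
    params: tuple[float, ...]
    item_id: int | None = None
    factor: str | None = None
    informed: bool = False
    replaced: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.family == "normal":
            mean, sd = self.params
            if not sd > 0:
                raise ValueError(f"normal sd must be > 0, got {sd}")
        elif self.family == "inverse_gamma":
            shape, scale = self.params
            if not (shape > 0 and scale > 0):
                raise ValueError("inverse_gamma shape and scale must be > 0")
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if self.informed:
            if self.role != LOADING:
                raise ValueError("only loading priors may be informed")
            if not 0 < self.params[0] < 1:
                raise ValueError(
                    f"informed loading prior mean must lie in (0, 1), "
                    f"got {self.params[0]}")

    @property
    def name(self) -> str:
        if self.role == LATENT:
            return f"{LATENT}[{self.factor}]"
        return f"{self.role}[{self.item_id}]"

    @property
    def mean(self) -> float:
        if self.family != "normal":
            raise AttributeError("mean is defined for normal priors only")
        return self.params[0]

    @property
    def sd(self) -> float:
        if self.family != "normal":
            raise AttributeError("sd is defined for normal priors only")
        return self.params[1]


@dataclass(frozen=True)
class PriorLedger:
    """Bookkeeping of the prior set: 3 parameters per item + 1 per factor."""

    n_total: int
    n_informed: int
    n_uninformed: int
    by_role: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total != self.n_informed + self.n_uninformed:
            raise ValueError("ledger does not add up")


class UnanimityError(ValueError):
    """All raters agreed: the elicitation rule would give sd = 0."""


def elicit_loading_prior(
    majority_votes: int,
    n_raters: int,
    item_id: int | None = None,
    factor: str | None = None,
) -> PriorSpec:
    """Normal loading prior N(k/r, (1 - k/r)/2) from k-of-r expert agreement.

    Unanimity (k = r) is rejected here; callers must apply
    :func:`unanimity_replacement` instead.
    """
    if majority_votes >= n_raters:
        if majority_votes == n_raters:
            raise UnanimityError(
                "unanimous item yields the degenerate prior N(1, 0); "
                "use unanimity_replacement")
        raise ValueError("majority_votes cannot exceed n_raters")
    if majority_votes <= 0:
        raise ValueError("majority_votes must be positive")
    mean = majority_votes / n_raters
    return PriorSpec(LOADING, "normal", (mean, (1.0 - mean) / 2.0),
                     item_id=item_id, factor=factor, informed=True)


def unanimity_replacement(
    factor: str,
    peer_priors: list[PriorSpec],
    item_id: int | None = None,
) -> PriorSpec:
    """Replacement prior for a unanimously sorted item.

    The mean is the arithmetic mean of the peer loading-prior means on the
    same factor (at full precision) and the sd follows the usual rule
    (1 - mean)/2.
    """
    if not peer_priors:
        raise ValueError(
            f"no non-unanimous peers on factor {factor}; replacement impossible")
    for p in peer_priors:
        if p.family != "normal" or p.role != LOADING:
            raise ValueError("peer priors must be normal loading priors")
        if p.factor is not None and p.factor != factor:
            raise ValueError(f"peer prior {p.name} is not on factor {factor}")
    mean = sum(p.mean for p in peer_priors) / len(peer_priors)
    return PriorSpec(LOADING, "normal", (mean, (1.0 - mean) / 2.0),
                     item_id=item_id, factor=factor, informed=True,
                     replaced=True)


def build_prior_set(
    classification: ItemClassification, votes: VoteMatrix
) -> list[PriorSpec]:
    """Full prior set for the measurement model implied by a classification.

    Per assigned item: one informed loading prior (elicited from the item's
    majority vote count, or replaced if unanimous), one uninformed intercept
    prior N(0, 100) and one inverse-Gamma(0.01, 0.01) error-variance prior.
    Per factor with assigned items: one uninformed latent prior N(0, 100).
    Excluded items contribute nothing. Ordering is deterministic: items
    ascending with loading/intercept/error-variance triples, then factors.
    """
    missing = set(classification.assignments) - set(votes.counts.index)
    if missing:
        raise ValueError(f"assigned items absent from votes: {sorted(missing)}")

    loadings: dict[int, PriorSpec] = {}
    unanimous: list[tuple[int, str]] = []
    for item in sorted(classification.assignments):
        f = classification.assignments[item]
        k = votes.votes_for(item, f)
        if k == votes.n_raters:
            unanimous.append((item, f))
        else:
            loadings[item] = elicit_loading_prior(
                k, votes.n_raters, item_id=item, factor=f)
    for item, f in unanimous:
        peers = [p for p in loadings.values() if p.factor == f]
        loadings[item] = unanimity_replacement(f, peers, item_id=item)

    priors: list[PriorSpec] = []
    for item in sorted(classification.assignments):
        f = classification.assignments[item]
        priors.append(loadings[item])
        priors.append(PriorSpec(INTERCEPT, "normal", (0.0, UNINFORMED_SD),
                                item_id=item, factor=f))
        priors.append(PriorSpec(ERROR_VARIANCE, "inverse_gamma", ERROR_PRIOR,
                                item_id=item, factor=f))
    for f in classification.factors:
        priors.append(PriorSpec(LATENT, "normal", (0.0, UNINFORMED_SD),
                                factor=f))
    return priors


def ledger(priors: list[PriorSpec]) -> PriorLedger:
    """Count parameters by role and informedness."""
    names = [p.name for p in priors]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate parameter names: {dupes}")
    by_role = {r: sum(p.role == r for p in priors) for r in ROLES}
    n_informed = sum(p.informed for p in priors)
    return PriorLedger(
        n_total=len(priors),
        n_informed=n_informed,
        n_uninformed=len(priors) - n_informed,
        by_role=by_role,
    )


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.025 -> 0.03 at two decimals)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def report_priors(
    priors: list[PriorSpec],
    decimals: int = 2,
    sd_from_rounded_mean: bool = True,
) -> pd.DataFrame:
    """Render loading priors as an ``M (SD)`` table.

    Full-precision values are retained in the frame; the rendered columns
    are presentation-only. With ``sd_from_rounded_mean`` (default) the
    displayed SD is (1 - rounded M)/2, itself rounded — the convention under
    which a 17-of-22 item reads M = 0.77, SD = (1 - 0.77)/2 = 0.115 -> 0.12.
    Otherwise the full-precision sd is rounded directly.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    q = Decimal(1).scaleb(-decimals)
    rows = []
    for p in priors:
        if p.role != LOADING:
            continue
        m_dec = Decimal(repr(p.mean)).quantize(q, rounding=ROUND_HALF_UP)
        if sd_from_rounded_mean:
            # derive in decimal arithmetic: (1 - 0.91)/2 must read 0.045,
            # not the float 0.04499...
            s_dec = ((1 - m_dec) / 2).quantize(q, rounding=ROUND_HALF_UP)
        else:
            s_dec = Decimal(repr(p.sd)).quantize(q, rounding=ROUND_HALF_UP)
        m_disp, s_disp = float(m_dec), float(s_dec)
        rows.append({
            "item_id": p.item_id, "factor": p.factor,
            "mean": p.mean, "sd": p.sd,
            "mean_rendered": m_disp, "sd_rendered": s_disp,
            "label": f"{m_disp:.{decimals}f} ({s_disp:.{decimals}f})",
            "replaced": p.replaced,
        })
    return pd.DataFrame(rows).set_index("item_id").sort_index()


def loading_prior(priors: list[PriorSpec], item_id: int) -> PriorSpec:
    """The loading prior for one item (convenience lookup)."""
    for p in priors:
        if p.role == LOADING and p.item_id == item_id:
            return p
    raise KeyError(f"no loading prior for item {item_id}")
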