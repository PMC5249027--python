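"""Seven-factor Bayesian confirmatory factor analysis by Gibbs sampling.

The measurement model is a simple-structure linear factor model: respondent
i's answer to item j, measured on a 5-point Likert scale and treated as
continuous,

    y_ij = nu_j + lambda_j * eta_{i, f(j)} + eps_ij,
    eps_ij ~ N(0, sigma_j^2),

where f(j) is the single factor item j loads on. Priors come from
:mod:`priorcfa.priors`: informed Normal priors on loadings, vague Normals
on intercepts, inverse-Gamma(0.01, 0.01) on error variances, and Normals on
latent factor values. All full conditionals are conjugate (Normal for
loadings, intercepts and latent scores; inverse-Gamma for error variances),
so the posterior is explored by a plain Gibbs sampler.

Identification: a factor model is invariant under jointly flipping the sign
of a factor's loadings and scores, and with a vague latent prior the latent
scale itself is unidentified. The default ``standardized_latent`` mode fixes
the latent variance at 1; ``vague_latent`` keeps the printed N(0, 100)
latent prior. In both modes the item with the highest prior loading mean on
each factor anchors the sign: whenever its loading draw is negative, the
factor's loadings and scores are jointly reflected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .agreement import ItemClassification
from .priors import (
    ERROR_VARIANCE,
    INTERCEPT,
    LATENT,
    LOADING,
    PriorSpec,
    ledger,
)
from .votes import FACTORS

STANDARDIZED_LATENT = "standardized_latent"
VAGUE_LATENT = "vague_latent"
IDENTIFICATION_MODES = (STANDARDIZED_LATENT, VAGUE_LATENT)


class ModelSpecificationError(ValueError):
    """Loading pattern and prior set are inconsistent."""


@dataclass(frozen=True)
class MeasurementModel:
    """Loading pattern plus full prior set for the CFA.

    ``loading_pattern`` maps item id -> factor label (simple structure:
    each item loads on exactly one factor). ``priors`` must cover exactly
    the parameters the pattern implies: one loading, intercept and error
    variance per item, one latent prior per factor.
    """

    loading_pattern: dict[int, str]
    priors: tuple[PriorSpec, ...]
    identification: str = STANDARDIZED_LATENT

    def __post_init__(self) -> None:
        if self.identification not in IDENTIFICATION_MODES:
            raise ValueError(f"unknown identification {self.identification!r}")
        if not self.loading_pattern:
            raise ModelSpecificationError("empty loading pattern")
        object.__setattr__(self, "priors", tuple(self.priors))
        expected = set()
        for item, f in self.loading_pattern.items():
            expected |= {f"{LOADING}[{item}]", f"{INTERCEPT}[{item}]",
                         f"{ERROR_VARIANCE}[{item}]"}
        for f in self.factors:
            expected.add(f"{LATENT}[{f}]")
        got = {p.name for p in self.priors}
        if got != expected:
            raise ModelSpecificationError(
                f"prior set does not match pattern; missing={sorted(expected - got)} "
                f"extra={sorted(got - expected)}")
        ledger(list(self.priors))  # rejects duplicates

    @property
    def item_ids(self) -> list[int]:
        return sorted(self.loading_pattern)

    @property
    def factors(self) -> list[str]:
        present = set(self.loading_pattern.values())
        ordered = [f for f in FACTORS if f in present]
        return ordered + sorted(present - set(FACTORS))

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def prior(self, role: str, key) -> PriorSpec:
        name = f"{role}[{key}]"
        for p in self.priors:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def latent_sd(self) -> float:
        """Prior sd of latent scores under the identification mode."""
        if self.identification == STANDARDIZED_LATENT:
            return 1.0
        return self.prior(LATENT, self.factors[0]).sd


def assemble_model(
    classification: ItemClassification,
    priors: list[PriorSpec],
    identification: str = STANDARDIZED_LATENT,
) -> MeasurementModel:
    """Build a :class:`MeasurementModel` from a classification and prior set."""
    return MeasurementModel(dict(classification.assignments), tuple(priors),
                            identification)


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted draws.

    For a unimodal posterior this estimates the highest density interval.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("hdi requires at least 2 draws")
    if not np.all(np.isfinite(x)):
        raise ValueError("hdi requires finite draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(x)
    n = x.size
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


@dataclass
class PosteriorSamples:
    """MCMC draws for every measurement parameter, plus latent scores.

    Arrays are shaped ``(chains, retained_draws, ...)``. ``latent`` is
    ``(chains, draws, n_respondents, n_factors)`` and may be None when
    latent storage was disabled to save memory.
    """

    item_ids: list[int]
    factors: list[str]
    loadings: np.ndarray
    intercepts: np.ndarray
    error_variances: np.ndarray
    latent: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_draws(self) -> int:
        return self.loadings.shape[1]

    def parameter_draws(self, name: str) -> np.ndarray:
        """Draws (chains x iterations) for one named parameter."""
        role, _, key = name.partition("[")
        key = key.rstrip("]")
        arrays = {LOADING: self.loadings, INTERCEPT: self.intercepts,
                  ERROR_VARIANCE: self.error_variances}
        if role in arrays:
            return arrays[role][:, :, self.item_ids.index(int(key))]
        raise KeyError(name)

    def parameter_names(self) -> list[str]:
        names = [f"{r}[{j}]" for j in self.item_ids
                 for r in (LOADING, INTERCEPT, ERROR_VARIANCE)]
        return names

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd, HDI and convergence diagnostics per parameter."""
        import arviz as az

        rows = []
        diag = {}
        data = {LOADING: self.loadings, INTERCEPT: self.intercepts,
                ERROR_VARIANCE: self.error_variances}
        if self.n_chains >= 2 and self.n_draws >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = az.convert_to_dataset(
                    {k: v for k, v in data.items()})
                rhat = az.rhat(ds)
                ess = az.ess(ds)
            diag = {k: (np.asarray(rhat[k]), np.asarray(ess[k])) for k in data}
        for role, arr in data.items():
            for idx, item in enumerate(self.item_ids):
                d = arr[:, :, idx].ravel()
                lo, hi = hdi(d, mass)
                row = {
                    "parameter": f"{role}[{item}]", "role": role, "item_id": item,
                    "mean": float(d.mean()), "sd": float(d.std(ddof=1)),
                    "hdi_low": lo, "hdi_high": hi,
                    "rhat": float(diag[role][0][idx]) if diag else np.nan,
                    "ess": float(diag[role][1][idx]) if diag else np.nan,
                }
                rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")

    def draws_long(self) -> pd.DataFrame:
        """All measurement-parameter draws in long (chain, iteration) format."""
        frames = []
        for name in self.parameter_names():
            d = self.parameter_draws(name)
            c, t = np.meshgrid(np.arange(d.shape[0]), np.arange(d.shape[1]),
                               indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "iteration": t.ravel(),
                "parameter": name, "value": d.ravel()}))
        return pd.concat(frames, ignore_index=True)


def _as_response_array(
    data, item_ids: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Coerce responses to (Y, mask) with columns ordered like item_ids."""
    if isinstance(data, pd.DataFrame):
        cols = {}
        for c in data.columns:
            s = str(c)
            key = int(s.split("_")[-1]) if s.startswith("item_") else None
            if key is None:
                try:
                    key = int(s)
                except ValueError as exc:
                    raise ValueError(f"unrecognized item column {c!r}") from exc
            cols[key] = c
        missing = [j for j in item_ids if j not in cols]
        if missing:
            raise ValueError(f"data lacks columns for items {missing}")
        Y = data[[cols[j] for j in item_ids]].to_numpy(dtype=float)
    else:
        Y = np.asarray(data, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != len(item_ids):
            raise ValueError(
                f"expected a 2-d array with {len(item_ids)} item columns")
    if Y.shape[0] == 0:
        raise ValueError("no respondents: empty data provides no likelihood")
    mask = np.isfinite(Y)
    vals = Y[mask]
    if vals.size and (np.any(vals < 1) or np.any(vals > 5)
                      or np.any(vals != np.floor(vals))):
        raise ValueError("observed responses must be integers in 1..5")
    return Y, mask


def _gibbs_chain(
    Y: np.ndarray,
    W: np.ndarray,
    fidx: np.ndarray,
    factor_items: list[np.ndarray],
    prior_m: np.ndarray,
    prior_s2: np.ndarray,
    nu_m: np.ndarray,
    nu_s2: np.ndarray,
    ig_a: np.ndarray,
    ig_b: np.ndarray,
    eta_var: float,
    anchors: np.ndarray,
    iterations: int,
    burn_in: int,
    rng: np.random.Generator,
    save_latent: bool,
):
    """One Gibbs chain over the conjugate full conditionals."""
    N, J = Y.shape
    F = len(factor_items)
    Y0 = np.where(W, Y, 0.0)
    nobs = W.sum(axis=0)

    lam = prior_m.copy()
    nu = np.where(nobs > 0, Y0.sum(axis=0) / np.maximum(nobs, 1), nu_m)
    sig2 = np.ones(J)
    eta = np.zeros((N, F))

    keep = iterations - burn_in
    out_lam = np.empty((keep, J))
    out_nu = np.empty((keep, J))
    out_sig2 = np.empty((keep, J))
    out_eta = np.empty((keep, N, F)) if save_latent else None

    for t in range(iterations):
        # latent scores, factor by factor (independent given simple structure)
        inv_s2 = 1.0 / sig2
        lam_w = lam * inv_s2
        Z = Y0 - np.where(W, nu, 0.0)
        for f in range(F):
            cols = factor_items[f]
            prec = 1.0 / eta_var + W[:, cols] @ (lam[cols] * lam_w[cols])
            b = Z[:, cols] @ lam_w[cols]
            eta[:, f] = b / prec + rng.standard_normal(N) / np.sqrt(prec)

        E = eta[:, fidx]  # N x J latent score relevant to each item
        WE = np.where(W, E, 0.0)

        # loadings
        prec = 1.0 / prior_s2 + (WE * E).sum(axis=0) * inv_s2
        b = prior_m / prior_s2 + (WE * (Y0 - np.where(W, nu, 0.0))).sum(axis=0) * inv_s2
        lam = b / prec + rng.standard_normal(J) / np.sqrt(prec)

        # sign anchoring: reflect a factor when its anchor loading goes negative
        flip = lam[anchors] < 0
        if flip.any():
            for f in np.flatnonzero(flip):
                lam[factor_items[f]] *= -1.0
                eta[:, f] *= -1.0
            E = eta[:, fidx]
            WE = np.where(W, E, 0.0)

        # intercepts
        prec = 1.0 / nu_s2 + nobs * inv_s2
        b = nu_m / nu_s2 + (np.where(W, Y0 - lam * E, 0.0)).sum(axis=0) * inv_s2
        nu = b / prec + rng.standard_normal(J) / np.sqrt(prec)

        # error variances
        R = np.where(W, Y0 - nu - lam * E, 0.0)
        shape = ig_a + nobs / 2.0
        scale = ig_b + 0.5 * (R * R).sum(axis=0)
        g = rng.gamma(shape)
        sig2 = scale / np.maximum(g, 1e-300)
        if not np.all(sig2 > 0):
            raise FloatingPointError("non-positive error-variance draw")

        if t >= burn_in:
            k = t - burn_in
            out_lam[k] = lam
            out_nu[k] = nu
            out_sig2[k] = sig2
            if save_latent:
                out_eta[k] = eta

    return out_lam, out_nu, out_sig2, out_eta


def fit_gibbs(
    model: MeasurementModel,
    data,
    chains: int = 4,
    iterations: int = 2000,
    burn_in: int = 1000,
    seed: int | None = None,
    save_latent: bool = True,
) -> PosteriorSamples:
    """Sample the CFA posterior with a conjugate Gibbs sampler.

    ``data`` is a respondents x items table (DataFrame with ``item_<j>`` or
    integer columns, or an array with columns in ascending item-id order);
    missing answers are NaN and contribute nothing to the likelihood.
    Identical inputs and seed give bit-identical draws.
    """
    if chains < 1:
        raise ValueError("chains must be >= 1")
    if not iterations > burn_in >= 0:
        raise ValueError("need iterations > burn_in >= 0")
    if seed is None:
        raise ValueError("a seed is required for reproducible sampling")

    item_ids = model.item_ids
    factors = model.factors
    for f in factors:
        n_ind = sum(1 for j in item_ids if model.loading_pattern[j] == f)
        if n_ind < 2:
            raise ModelSpecificationError(
                f"factor {f} has a single indicator: one item cannot "
                "identify a latent trait")

    Y, W = _as_response_array(data, item_ids)
    fmap = {f: i for i, f in enumerate(factors)}
    fidx = np.array([fmap[model.loading_pattern[j]] for j in item_ids])
    factor_items = [np.flatnonzero(fidx == i) for i in range(len(factors))]

    prior_m = np.array([model.prior(LOADING, j).mean for j in item_ids])
    prior_s2 = np.array([model.prior(LOADING, j).sd ** 2 for j in item_ids])
    nu_m = np.array([model.prior(INTERCEPT, j).mean for j in item_ids])
    nu_s2 = np.array([model.prior(INTERCEPT, j).sd ** 2 for j in item_ids])
    ig_a = np.array([model.prior(ERROR_VARIANCE, j).params[0] for j in item_ids])
    ig_b = np.array([model.prior(ERROR_VARIANCE, j).params[1] for j in item_ids])
    eta_var = model.latent_sd ** 2
    # sign anchor per factor: highest prior loading mean, lowest id tie-break
    anchors = np.array([
        cols[int(np.argmax(prior_m[cols]))] for cols in factor_items])

    ss = np.random.SeedSequence(seed)
    results = []
    for child in ss.spawn(chains):
        rng = np.random.default_rng(child)
        results.append(_gibbs_chain(
            Y, W, fidx, factor_items, prior_m, prior_s2, nu_m, nu_s2,
            ig_a, ig_b, eta_var, anchors, iterations, burn_in, rng,
            save_latent))

    samples = PosteriorSamples(
        item_ids=item_ids,
        factors=factors,
        loadings=np.stack([r[0] for r in results]),
        intercepts=np.stack([r[1] for r in results]),
        error_variances=np.stack([r[2] for r in results]),
        latent=np.stack([r[3] for r in results]) if save_latent else None,
        meta={
            "seed": seed, "chains": chains, "iterations": iterations,
            "burn_in": burn_in, "identification": model.identification,
            "n_respondents": Y.shape[0],
            "prior_means": {f"{LOADING}[{j}]": float(m)
                            for j, m in zip(item_ids, prior_m)},
        },
    )
    return samples


class BayesianCFA(BaseEstimator):
    """Bayesian confirmatory factor analysis with expert-informed priors.

    scikit-learn style estimator around :func:`fit_gibbs`. Construct with a
    loading pattern (item id -> factor label) and the matching prior set,
    then call :meth:`fit` on a respondents x items Likert table (NaN =
    omitted answer).

    Parameters
    ----------
    loading_pattern : dict[int, str]
        Simple-structure assignment of items to factors.
    priors : sequence of PriorSpec
        Full prior set as produced by :func:`priorcfa.priors.build_prior_set`.
    identification : str
        ``"standardized_latent"`` (latent variance fixed at 1, default) or
        ``"vague_latent"`` (vague N(0, 100) latent prior).
    chains, n_iter, burn_in : int
        Sampler schedule; retained draws per chain = ``n_iter - burn_in``.
    random_state : int
        Seed; required at fit time.
    save_latent : bool
        Whether to store per-respondent latent score draws.

    Attributes
    ----------
    model_ : MeasurementModel
    samples_ : PosteriorSamples
    summary_ : pandas.DataFrame
        Posterior mean, sd, 95% HDI, split-Rhat and effective sample size
        per measurement parameter.
    """

    def __init__(
        self,
        loading_pattern: dict[int, str] | None = None,
        priors=None,
        identification: str = STANDARDIZED_LATENT,
        chains: int = 4,
        n_iter: int = 2000,
        burn_in: int = 1000,
        random_state: int | None = None,
        save_latent: bool = True,
    ):
        self.loading_pattern = loading_pattern
        self.priors = priors
        self.identification = identification
        self.chains = chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.random_state = random_state
        self.save_latent = save_latent

    def fit(self, X, y=None):
        if self.loading_pattern is None or self.priors is None:
            raise ValueError("loading_pattern and priors are required")
        self.model_ = MeasurementModel(
            dict(self.loading_pattern), tuple(self.priors),
            self.identification)
        self.samples_ = fit_gibbs(
            self.model_, X, chains=self.chains, iterations=self.n_iter,
            burn_in=self.burn_in, seed=self.random_state,
            save_latent=self.save_latent)
        self.summary_ = self.samples_.summary()
        self.item_ids_ = self.samples_.item_ids
        self.factors_ = self.samples_.factors
        self.n_respondents_ = self.samples_.meta["n_respondents"]
        bad = self.summary_["rhat"].dropna()
        bad = bad[bad > 1.05]
        if len(bad):
            warnings.warn(
                f"{len(bad)} parameters have split-Rhat > 1.05; "
                "consider more iterations", RuntimeWarning)
        return self

    def transform(self, X=None):
        """Posterior-mean latent scores of the fitted respondents (N x F)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "samples_")
        if self.samples_.latent is None:
            raise ValueError("latent draws were not stored (save_latent=False)")
        return self.samples_.latent.mean(axis=(0, 1))
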