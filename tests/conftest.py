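import numpy as np
import pandas as pd
import pytest

import priorcfa as pc
from priorcfa.model import assemble_model


@pytest.fixture(scope="session")
def published_cls():
    return pc.load_published_classification()


@pytest.fixture(scope="session")
def fixture_votes():
    return pc.reconstructed_study_votes()


@pytest.fixture(scope="session")
def published_priors(published_cls, fixture_votes):
    return pc.build_prior_set(published_cls, fixture_votes)


@pytest.fixture(scope="session")
def published_model(published_cls, published_priors):
    return assemble_model(published_cls, published_priors)


@pytest.fixture(scope="session")
def small_cls():
    """Two factors with three items each."""
    return pc.ItemClassification(
        {1: "SAT", 2: "SAT", 3: "SAT", 4: "FoS", 5: "FoS", 6: "FoS"})


@pytest.fixture(scope="session")
def small_votes(small_cls):
    rows = {}
    for i, f in small_cls.assignments.items():
        other = "OUT" if f != "OUT" else "SAT"
        rows[i] = {f: 16, other: 6}
    return pc.vote_matrix_from_dicts(rows, 22)


@pytest.fixture(scope="session")
def small_model(small_cls, small_votes):
    return assemble_model(small_cls, pc.build_prior_set(small_cls, small_votes))


@pytest.fixture(scope="session")
def small_data(small_cls, small_model):
    true = {j: small_model.prior("loading", j).mean
            for j in small_model.item_ids}
    return pc.simulate_responses(small_cls, pc.ResponseSimConfig(
        n_respondents=200, true_loadings=true, omission_prob=0.05, seed=11))


def all_missing_frame(item_ids, n=8):
    return pd.DataFrame(
        np.nan, index=range(n), columns=[f"item_{j}" for j in item_ids])


# --- independent grid-integration oracle for the two-item pinned model ---
#
# One factor, two items, intercepts pinned near 3 and error variances near 1
# by very tight priors, so the loadings are the only free parameters. The
# latent scores integrate out analytically: y_i ~ N(nu, LL' + diag(sigma^2)),
# leaving a 2-d posterior evaluated exactly on a dense grid. Sign anchoring
# is mirrored by folding the density through the origin onto the anchor's
# positive half. Built from the closed-form bivariate normal likelihood,
# independent of the Gibbs code path.

ORACLE_DATA = np.array([[3, 3], [4, 4], [2, 2], [4, 3], [3, 2]], float)


def pinned_two_item_model():
    from priorcfa.model import MeasurementModel
    from priorcfa.priors import PriorSpec

    priors = [
        PriorSpec("loading", "normal", (0.7, 0.2), item_id=1,
                  factor="SAT", informed=True),
        PriorSpec("intercept", "normal", (3.0, 1e-4), item_id=1, factor="SAT"),
        PriorSpec("error_variance", "inverse_gamma", (1e6, 1e6),
                  item_id=1, factor="SAT"),
        PriorSpec("loading", "normal", (0.5, 0.25), item_id=2,
                  factor="SAT", informed=True),
        PriorSpec("intercept", "normal", (3.0, 1e-4), item_id=2, factor="SAT"),
        PriorSpec("error_variance", "inverse_gamma", (1e6, 1e6),
                  item_id=2, factor="SAT"),
        PriorSpec("latent", "normal", (0.0, 100.0), factor="SAT"),
    ]
    return MeasurementModel({1: "SAT", 2: "SAT"}, tuple(priors))


def grid_loading_marginal(Y, grid):
    from scipy.stats import norm

    def log_post(l1, l2):
        C = np.array([[l1 * l1 + 1.0, l1 * l2], [l1 * l2, l2 * l2 + 1.0]])
        det = C[0, 0] * C[1, 1] - C[0, 1] ** 2
        Ci = np.array([[C[1, 1], -C[0, 1]], [-C[0, 1], C[0, 0]]]) / det
        R = Y - 3.0
        q = np.einsum("ni,ij,nj->n", R, Ci, R)
        return (-0.5 * (q.sum() + len(Y) * np.log(det))
                + norm.logpdf(l1, 0.7, 0.2) + norm.logpdf(l2, 0.5, 0.25))

    logp = np.array([[log_post(a, b) for b in grid] for a in grid])
    p = np.exp(logp - logp.max())
    folded = p + p[::-1, ::-1]      # sign reflection (l1,l2) -> (-l1,-l2)
    folded[grid < 0, :] = 0.0       # anchor loading kept positive
    marg = folded.sum(axis=1)
    return marg / marg.sum()


def gibbs_vs_grid_total_variation(seed=5):
    """TV distance between Gibbs draws and the grid marginal of loading 1."""
    from priorcfa.model import fit_gibbs

    model = pinned_two_item_model()
    grid = np.linspace(-3, 3, 241)
    marg = grid_loading_marginal(ORACLE_DATA, grid)
    s = fit_gibbs(model, ORACLE_DATA, chains=4, iterations=12000,
                  burn_in=2000, seed=seed, save_latent=False)
    draws = s.loadings[:, :, 0].ravel()
    edges = np.linspace(-3, 3, 41)
    hist, _ = np.histogram(draws, bins=edges)
    hist = hist / hist.sum()
    grid_binned = np.zeros(len(edges) - 1)
    idx = np.clip(np.digitize(grid, edges) - 1, 0, len(edges) - 2)
    for k, m in zip(idx, marg):
        grid_binned[k] += m
    return 0.5 * np.abs(hist - grid_binned).sum()
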