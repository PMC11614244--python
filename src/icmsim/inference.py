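"""Multi-round simulation-based posterior estimation for the free parameters.

The workflow mirrors sequential neural posterior estimation (SNPE): draw
parameter vectors from a proposal (round 1: the uniform prior), simulate the
model and reduce each run to the joint pattern-score feature vector over the
last-12-hour scoring window, train a conditional density estimator on the
(theta, x) pairs, condition it on the all-ones target observation, and use
the resulting posterior as the next round's proposal (truncated to the prior
box).  Several estimators are trained per round with different seeds; the
candidate whose MAP estimate attains the highest meta score on a fresh
validation ensemble is selected.

The density-estimation backend is a pluggable train/condition/sample/MAP
contract.  The default backend models the joint distribution of (theta, x)
as a Gaussian mixture and conditions it analytically on the observed
features, which yields a closed-form Gaussian-mixture posterior that can be
sampled, optimized and further conditioned (for the parameter-correlation
analysis) without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .params import (
    FREE_PARAM_BOUNDS,
    FREE_PARAM_NAMES,
    RTM_FREE_PARAM_NAMES,
    ParameterSet,
)
from .scoring import build_target_observation

__all__ = [
    "PriorSpec",
    "build_prior",
    "GaussianMixturePosterior",
    "GaussianMixtureConditionalEstimator",
    "PosteriorCandidate",
    "make_training_pairs",
    "run_round",
    "select_posterior",
    "run_inference",
    "conditional_correlations",
    "credible_region_contains",
    "LinearGaussianToy",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent multivariate-uniform prior over free parameters."""

    names: tuple[str, ...]
    lows: np.ndarray
    highs: np.ndarray

    @property
    def dim(self) -> int:
        return len(self.names)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lows, self.highs, size=(n, self.dim))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lows) & (theta <= self.highs), axis=1)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(theta, self.lows, self.highs)


def build_prior(variant: str = "ITWT") -> PriorSpec:
    """19-dimensional prior for the wild type; 4 core-GRN dimensions for the
    signaling-free reinferred mutant."""
    if variant == "ITWT":
        names = FREE_PARAM_NAMES
    elif variant == "RTM":
        names = RTM_FREE_PARAM_NAMES
    else:
        raise ValueError(f"unknown variant {variant!r}")
    lows = np.array([FREE_PARAM_BOUNDS[n][0] for n in names])
    highs = np.array([FREE_PARAM_BOUNDS[n][1] for n in names])
    return PriorSpec(tuple(names), lows, highs)


# ---------------------------------------------------------------------------
# Gaussian-mixture conditional density estimation
# ---------------------------------------------------------------------------

from scipy.special import logsumexp as _logsumexp  # noqa: E402


def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.shape[0]
    L = np.linalg.cholesky(cov)
    diff = np.atleast_2d(x) - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


@dataclass
class GaussianMixturePosterior:
    """A Gaussian-mixture density over parameter space.

    Supports sampling (optionally truncated to a prior box), log-density
    evaluation, analytic conditioning on a subset of dimensions, moments and
    MAP extraction — everything the inference loop needs from a posterior.
    """

    weights: np.ndarray    # (K,)
    means: np.ndarray      # (K, D)
    covs: np.ndarray       # (K, D, D)
    bounds: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        parts = np.stack([
            np.log(self.weights[k] + 1e-300)
            + _gauss_logpdf(theta, self.means[k], self.covs[k])
            for k in range(len(self.weights))
        ])
        return _logsumexp(parts, axis=0)

    def sample(self, n: int, rng: np.random.Generator,
               max_tries: int = 200) -> np.ndarray:
        """Draw samples; when bounds are set, rejection-sample into the box."""
        out = np.empty((0, self.dim))
        tries = 0
        need = n
        while need > 0 and tries < max_tries:
            comp = rng.choice(len(self.weights), size=need, p=self.weights)
            draws = np.empty((need, self.dim))
            for k in np.unique(comp):
                idx = comp == k
                draws[idx] = rng.multivariate_normal(
                    self.means[k], self.covs[k], size=int(idx.sum()))
            if self.bounds is not None:
                lo, hi = self.bounds
                ok = np.all((draws >= lo) & (draws <= hi), axis=1)
                draws = draws[ok]
            out = np.vstack([out, draws])
            need = n - out.shape[0]
            tries += 1
        if out.shape[0] < n:
            # pathologically little mass in the box: clip instead of looping
            extra = self.means[np.argmax(self.weights)][None, :].repeat(need, 0)
            if self.bounds is not None:
                extra = np.clip(extra, self.bounds[0], self.bounds[1])
            out = np.vstack([out, extra])
        return out[:n]

    def mean(self) -> np.ndarray:
        return np.einsum("k,kd->d", self.weights, self.means)

    def covariance(self) -> np.ndarray:
        mu = self.mean()
        cov = np.zeros((self.dim, self.dim))
        for k, w in enumerate(self.weights):
            d = self.means[k] - mu
            cov += w * (self.covs[k] + np.outer(d, d))
        return cov

    def correlation(self) -> np.ndarray:
        cov = self.covariance()
        sd = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            return cov / np.outer(sd, sd)

    def condition(self, idx: Sequence[int], values: np.ndarray
                  ) -> "GaussianMixturePosterior":
        """Condition the mixture on ``theta[idx] = values`` analytically."""
        idx = np.asarray(idx, dtype=int)
        keep = np.array([i for i in range(self.dim) if i not in set(idx.tolist())])
        if keep.size == 0:
            raise ValueError("cannot condition on every dimension")
        K = len(self.weights)
        new_means = np.zeros((K, keep.size))
        new_covs = np.zeros((K, keep.size, keep.size))
        logw = np.zeros(K)
        for k in range(K):
            mu, cov = self.means[k], self.covs[k]
            Saa = cov[np.ix_(keep, keep)]
            Sab = cov[np.ix_(keep, idx)]
            Sbb = cov[np.ix_(idx, idx)]
            sol = np.linalg.solve(Sbb, (values - mu[idx]))
            new_means[k] = mu[keep] + Sab @ sol
            new_covs[k] = Saa - Sab @ np.linalg.solve(Sbb, Sab.T)
            logw[k] = (np.log(self.weights[k] + 1e-300)
                       + _gauss_logpdf(values, mu[idx], Sbb)[0])
        logw -= _logsumexp(logw)
        bounds = None
        if self.bounds is not None:
            bounds = (self.bounds[0][keep], self.bounds[1][keep])
        # symmetrize for numerical hygiene
        new_covs = 0.5 * (new_covs + np.transpose(new_covs, (0, 2, 1)))
        return GaussianMixturePosterior(np.exp(logw), new_means, new_covs, bounds)

    def map_estimate(self, rng: np.random.Generator,
                     n_starts: int = 8, n_presamples: int = 256) -> np.ndarray:
        """Gradient-free multi-start maximization of the log density within
        the prior box."""
        cands = self.sample(n_presamples, rng)
        cands = np.vstack([cands, self.means])
        if self.bounds is not None:
            cands = np.clip(cands, self.bounds[0], self.bounds[1])
        lp = self.log_prob(cands)
        starts = cands[np.argsort(lp)[::-1][:n_starts]]
        lo, hi = (self.bounds if self.bounds is not None
                  else (None, None))

        def neg(theta):
            if lo is not None:
                theta = np.clip(theta, lo, hi)
            return -float(self.log_prob(theta[None, :])[0])

        best, best_val = starts[0], neg(starts[0])
        for s in starts:
            res = optimize.minimize(neg, s, method="Nelder-Mead",
                                    options={"maxiter": 400, "xatol": 1e-6,
                                             "fatol": 1e-9})
            x = np.clip(res.x, lo, hi) if lo is not None else res.x
            v = neg(x)
            if v < best_val:
                best, best_val = x, v
        return best


class GaussianMixtureConditionalEstimator:
    """Joint Gaussian-mixture conditional density estimator.

    Fits a full-covariance Gaussian mixture to the stacked (theta, x)
    training pairs; conditioning on an observed feature vector x_o then
    gives the posterior over theta in closed form.
    """

    def __init__(self, n_components: int = 2, reg_covar: float = 1e-4,
                 seed: int = 0):
        self.n_components = n_components
        self.reg_covar = reg_covar
        self.seed = seed
        self._gm: Optional[GaussianMixture] = None
        self._dim_theta: Optional[int] = None

    def fit(self, theta: np.ndarray, x: np.ndarray
            ) -> "GaussianMixtureConditionalEstimator":
        theta = np.atleast_2d(theta)
        x = np.atleast_2d(x)
        if theta.shape[0] != x.shape[0]:
            raise ValueError("theta and x must have matching row counts")
        joint = np.hstack([theta, x])
        k = min(self.n_components, max(1, theta.shape[0] // (joint.shape[1] + 2)))
        self._gm = GaussianMixture(
            n_components=k, covariance_type="full",
            reg_covar=self.reg_covar, random_state=self.seed, n_init=1,
            max_iter=200)
        self._gm.fit(joint)
        self._dim_theta = theta.shape[1]
        return self

    def condition(self, x_obs: np.ndarray,
                  bounds: Optional[tuple[np.ndarray, np.ndarray]] = None
                  ) -> GaussianMixturePosterior:
        if self._gm is None:
            raise RuntimeError("estimator is not fitted")
        D = self._dim_theta
        joint = GaussianMixturePosterior(
            self._gm.weights_.copy(), self._gm.means_.copy(),
            self._gm.covariances_.copy())
        x_obs = np.asarray(x_obs, dtype=float).ravel()
        idx = np.arange(D, D + x_obs.size)
        post = joint.condition(idx, x_obs)
        return replace(post, bounds=bounds)


# ---------------------------------------------------------------------------
# Rounds, selection, correlations
# ---------------------------------------------------------------------------

@dataclass
class PosteriorCandidate:
    """A trained estimator conditioned on the target, with its MAP point."""

    estimator: GaussianMixtureConditionalEstimator
    posterior: GaussianMixturePosterior
    theta_map: np.ndarray
    round_index: int
    train_seed: int
    meta: Optional[float] = None


def make_training_pairs(theta_batch: np.ndarray,
                        feature_batch: Sequence[Optional[np.ndarray]]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Pair parameter vectors with their score-feature vectors, dropping
    failed simulations (``None`` features)."""
    thetas, xs = [], []
    for theta, x in zip(theta_batch, feature_batch):
        if x is None:
            continue
        thetas.append(np.asarray(theta, dtype=float))
        xs.append(np.asarray(x, dtype=float).ravel())
    if not thetas:
        raise ValueError("no usable training pairs")
    return np.stack(thetas), np.stack(xs)


def run_round(
    proposal,
    prior: PriorSpec,
    simulator: Callable[[np.ndarray, int], Optional[np.ndarray]],
    budget: int,
    round_index: int,
    seed: int,
    n_candidates: int = 3,
    x_target: Optional[np.ndarray] = None,
    backend_factory: Callable[[int], GaussianMixtureConditionalEstimator]
        = lambda s: GaussianMixtureConditionalEstimator(seed=s),
) -> tuple[list[PosteriorCandidate], np.ndarray, np.ndarray]:
    """One inference round: simulate a budget of parameter draws from the
    proposal, train ``n_candidates`` estimators on the same dataset with
    different seeds, and condition each on the target observation.

    Returns the candidates and the training pairs (theta, x).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if proposal is None:
        thetas = prior.sample(budget, rng)
    else:
        thetas = proposal.sample(budget, rng)
        thetas = prior.clip(thetas)
    sim_seeds = rng.integers(0, 2 ** 31, size=budget)
    feats = [simulator(thetas[i], int(sim_seeds[i])) for i in range(budget)]
    theta_tr, x_tr = make_training_pairs(thetas, feats)
    if x_target is None:
        x_target = np.ones(x_tr.shape[1])
    candidates = []
    for c in range(n_candidates):
        train_seed = int(rng.integers(0, 2 ** 31))
        est = backend_factory(train_seed).fit(theta_tr, x_tr)
        post = est.condition(x_target, bounds=(prior.lows, prior.highs))
        theta_map = post.map_estimate(np.random.default_rng(train_seed))
        candidates.append(PosteriorCandidate(est, post, theta_map,
                                             round_index, train_seed))
    return candidates, theta_tr, x_tr


def select_posterior(
    candidates: Sequence[PosteriorCandidate],
    simulator: Callable[[np.ndarray, int], Optional[np.ndarray]],
    n_validation: int,
    seed: int,
) -> PosteriorCandidate:
    """Score every candidate's MAP with a fresh validation ensemble and
    return the one with the highest meta score (ties broken by round then
    training seed)."""
    from .scoring import meta_score

    if not candidates:
        raise ValueError("empty candidate set")
    rng = np.random.default_rng(seed)
    for cand in candidates:
        series = []
        for _ in range(n_validation):
            x = simulator(cand.theta_map, int(rng.integers(0, 2 ** 31)))
            if x is not None:
                series.append(np.asarray(x, dtype=float).ravel())
        cand.meta = meta_score(series) if series else 0.0
    return max(candidates,
               key=lambda c: (c.meta, -c.round_index, -c.train_seed))


def run_inference(
    prior: PriorSpec,
    simulator: Callable[[np.ndarray, int], Optional[np.ndarray]],
    rounds: int = 3,
    budget: int = 1000,
    n_candidates: int = 3,
    n_validation: int = 10,
    seed: int = 0,
    x_target: Optional[np.ndarray] = None,
) -> dict:
    """Multi-round loop: each round's proposal is the previous round's
    selected posterior (truncated to the prior box)."""
    proposal = None
    history = []
    best = None
    for r in range(rounds):
        candidates, theta_tr, x_tr = run_round(
            proposal, prior, simulator, budget, r, seed + 7919 * r,
            n_candidates, x_target)
        best = select_posterior(candidates, simulator, n_validation,
                                seed + 104729 * r)
        history.append({"round": r, "candidates": candidates, "best": best,
                        "n_pairs": theta_tr.shape[0]})
        proposal = best.posterior
    return {"posterior": best.posterior, "theta_map": best.theta_map,
            "meta": best.meta, "history": history}


def conditional_correlations(posterior: GaussianMixturePosterior,
                             theta_map: np.ndarray) -> np.ndarray:
    """Pairwise Pearson coefficients of the posterior conditioned, for each
    parameter pair, on the MAP values of all remaining parameters.

    Returns a symmetric matrix with unit diagonal; NaN where a conditional
    variance degenerates.
    """
    D = posterior.dim
    out = np.eye(D)
    for i in range(D):
        for j in range(i + 1, D):
            others = [k for k in range(D) if k not in (i, j)]
            if others:
                cond = posterior.condition(others, theta_map[others])
            else:
                cond = posterior
            # conditioning keeps the two free dims in original relative order
            r = cond.correlation()[0, 1]
            out[i, j] = out[j, i] = r
    return out


def credible_region_contains(posterior: GaussianMixturePosterior,
                             theta: np.ndarray, level: float,
                             rng: np.random.Generator,
                             n_samples: int = 4000) -> bool:
    """Highest-density-region membership test: theta lies inside the
    ``level`` credible region when at most ``level`` of the posterior mass
    has higher density."""
    samples = posterior.sample(n_samples, rng)
    lp_theta = float(posterior.log_prob(theta[None, :])[0])
    frac_higher = float(np.mean(posterior.log_prob(samples) > lp_theta))
    return frac_higher <= level


def tissue_feature_simulator(
    base_params: ParameterSet,
    variant: str = "ITWT",
    n_cells: int = 25,
    t_end_h: float = 48.0,
    window_h: float = 12.0,
):
    """Bind the tissue model into a ``simulator(theta, seed) -> x`` callable.

    For the wild type each parameter vector is simulated twice on the
    inference lattice — once with functional cell-cell signaling (40-60-0
    EPI-PRE-UND target) and once with signaling inactivated (100-0-0
    target) — and the joint score over the scoring window is the feature
    vector.  The signaling-free mutant uses its single 40-60-0 configuration
    score directly.
    """
    from .engine import run_batch
    from .experiments import icd_sampler
    from .lattice import lattice_for_size
    from .observables import fate_counts
    from .scoring import (TARGETS_ITWT_OFF, TARGETS_ITWT_ON, TargetSpec,
                          joint_score, score_time_series, window_indices)

    lat = lattice_for_size(n_cells)
    prior = build_prior(variant)
    t_end = t_end_h * 3600.0

    def simulator(theta: np.ndarray, seed: int) -> Optional[np.ndarray]:
        values = dict(zip(prior.names, np.asarray(theta, dtype=float)))
        try:
            p_on = base_params.with_free(values)
        except ValueError:
            return None
        try:
            if variant == "ITWT":
                tgt_on = TargetSpec.from_proportions(0, n_cells, TARGETS_ITWT_ON)
                tgt_off = TargetSpec.from_proportions(1, n_cells, TARGETS_ITWT_OFF)
                ens_on = run_batch(p_on, lat, "ITWT",
                                   icd_sampler(p_on, n_cells), 1, seed, t_end)
                ens_off = run_batch(p_on, lat, "TM-APM",
                                    icd_sampler(p_on, n_cells), 1, seed + 1,
                                    t_end)
                c_on = fate_counts(ens_on[0])
                c_off = fate_counts(ens_off[0])
                idx = window_indices(ens_on[0].times_h, t_end_h, window_h)
                s0 = score_time_series(c_on[idx], tgt_on)
                s1 = score_time_series(c_off[idx], tgt_off)
                return np.array([joint_score(a, b) for a, b in zip(s0, s1)])
            tgt = TargetSpec.from_proportions(0, n_cells, TARGETS_ITWT_ON)
            ens = run_batch(p_on, lat, "RTM", icd_sampler(p_on, n_cells),
                            1, seed, t_end)
            counts = fate_counts(ens[0])
            idx = window_indices(ens[0].times_h, t_end_h, window_h)
            return score_time_series(counts[idx], tgt)
        except RuntimeError:
            return None

    return simulator


# ---------------------------------------------------------------------------
# Analytically tractable toy model (oracle for the inference machinery)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearGaussianToy:
    """Identifiable linear-Gaussian simulator with a known posterior.

    Features are ``x = A @ theta + b + noise`` with isotropic Gaussian noise;
    under a flat prior the posterior given one observation is the Gaussian
    ``N((A'A)^-1 A'(x - b), sigma^2 (A'A)^-1)``, which serves as the
    independent oracle for the inference loop.
    """

    A: np.ndarray
    b: np.ndarray
    sigma: float

    @staticmethod
    def make(dim_theta: int = 2, dim_x: int = 8, sigma: float = 0.05,
             seed: int = 0) -> "LinearGaussianToy":
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(dim_x, dim_theta)) / np.sqrt(dim_theta)
        b = rng.normal(size=dim_x) * 0.1
        return LinearGaussianToy(A, b, sigma)

    def simulate(self, theta: np.ndarray, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return self.A @ np.asarray(theta, float) + self.b \
            + self.sigma * rng.normal(size=self.A.shape[0])

    def analytic_posterior(self, x_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        AtA = self.A.T @ self.A
        mean = np.linalg.solve(AtA, self.A.T @ (x_obs - self.b))
        cov = self.sigma ** 2 * np.linalg.inv(AtA)
        return mean, cov
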