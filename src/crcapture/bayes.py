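"""Bayesian closed-population models M0/Mt/Mh/Mth with model averaging.

Capture probabilities follow the logistic model

    logit(p_it) = mu + alpha_t + gamma_i,        gamma_i ~ N(0, sigma_gamma^2)

where mu is the mean capture rate on the logit scale, alpha_t a per-episode
(time/source) effect under a sum-to-zero constraint, and gamma_i an individual
random effect.  Switching the alpha and gamma terms off yields the four
classical closed-population models M0, Mt, Mh and Mth.  The data likelihood
for a population of unknown size N with n observed capture histories x is

    f(x | theta, gamma)  proportional to
        N!/(N-n)! * prod_t prod_i p_it^x_it (1-p_it)^(1-x_it)

with x_it = 0 for the N - n never-captured individuals.

Inference is by MCMC over the joint posterior of (model, parameters, N):
random-walk Metropolis within a model, reversible-jump toggles of the time
and heterogeneity effects between models (parameters of a toggled-on effect
are proposed from their priors, so the Jacobian is 1), an exact Gibbs draw of
N, and posterior summaries averaged over models weighted by their posterior
probabilities (Bayesian model averaging).  Individual random effects are
integrated out of the likelihood by Gauss-Hermite quadrature, which makes the
between-model moves low-dimensional and is what lets the chain actually visit
the heterogeneity models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import arviz as az
import numpy as np
from scipy import stats
from scipy.special import expit, gammaln, log_expit, logsumexp

from .capture_data import CaptureDataError, CaptureHistory, CellCounts, to_capture_history

__all__ = [
    "ModelSpec",
    "MthParams",
    "SamplerConfig",
    "PosteriorDraws",
    "BMAEstimate",
    "MODEL_LABELS",
    "capture_prob",
    "log_likelihood",
    "run_mcmc",
    "bma_summarize",
    "grid_posterior_oracle",
]

MODEL_LABELS = ("M0", "Mt", "Mh", "Mth")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the closed-population model family.

    The label is determined by the two effect flags; the prior probability is
    the product of independent per-effect priors (0.5 each by default, giving
    the uniform 1/4 over the four models).
    """

    time_effect: bool
    heterogeneity: bool
    prior_prob: float = 0.25

    @property
    def label(self) -> str:
        suffix = ("t" if self.time_effect else "") + ("h" if self.heterogeneity else "")
        return "M" + (suffix or "0")

    @classmethod
    def from_label(cls, label: str, prior_prob: float = 0.25) -> "ModelSpec":
        if label not in MODEL_LABELS:
            raise CaptureDataError(f"unknown model label {label!r}; have {MODEL_LABELS}")
        return cls("t" in label, "h" in label, prior_prob)


@dataclass
class MthParams:
    """Full parameter state theta = {mu, alpha, sigma^2_gamma, N} (+ latent gamma)."""

    mu: float
    alpha: np.ndarray | None  # length T, sums to zero; None when time effect off
    sigma2_gamma: float
    N: int
    gamma: np.ndarray | None = None  # length N latent effects; None when marginalized

    def validate(self, m: ModelSpec, n: int, T: int) -> None:
        if self.N < n:
            raise CaptureDataError(f"N = {self.N} below the observed count n = {n}")
        if m.time_effect:
            a = np.asarray(self.alpha, float)
            if a.shape != (T,) or abs(a.sum()) > 1e-8:
                raise CaptureDataError("alpha must have length T and sum to zero")
        elif self.alpha is not None and np.any(np.asarray(self.alpha) != 0):
            raise CaptureDataError("alpha must be identically zero when the time effect is off")
        if not m.heterogeneity:
            if self.sigma2_gamma != 0:
                raise CaptureDataError("sigma2_gamma must be 0 when heterogeneity is off")
            if self.gamma is not None and np.any(np.asarray(self.gamma) != 0):
                raise CaptureDataError("gamma must be identically zero when heterogeneity is off")


def capture_prob(mu: float, alpha_tau: float = 0.0, gamma_i: float = 0.0) -> float:
    """Capture probability expit(mu + alpha_tau + gamma_i); saturates smoothly."""
    return float(expit(mu + alpha_tau + gamma_i))


def log_likelihood(h: CaptureHistory, p: MthParams, m: ModelSpec) -> float:
    """Log of the capture-history likelihood with explicit random effects.

    Computes log N!/(N-n)! + sum_it [x_it log p_it + (1-x_it) log(1-p_it)]
    over all N individuals, the x rows of never-captured individuals being
    zero.  ``p.gamma`` must supply an effect for every one of the N
    individuals when the model includes heterogeneity (observed first).
    """
    p.validate(m, h.n, h.T)
    n, T, N = h.n, h.T, int(p.N)
    alpha = np.zeros(T) if p.alpha is None else np.asarray(p.alpha, float)
    if m.heterogeneity:
        gamma = np.asarray(p.gamma, float)
        if gamma.shape != (N,):
            raise CaptureDataError("gamma must supply an effect for all N individuals")
    else:
        gamma = np.zeros(N)
    x = np.zeros((N, T))
    x[:n] = h.matrix
    eta = p.mu + alpha[None, :] + gamma[:, None]
    ll = x * log_expit(eta) + (1 - x) * log_expit(-eta)
    return float(gammaln(N + 1) - gammaln(N - n + 1) + ll.sum())


# ---------------------------------------------------------------------------
# marginalized pattern likelihood
# ---------------------------------------------------------------------------

def _pattern_data(h: CaptureHistory) -> tuple[np.ndarray, np.ndarray]:
    pats, counts = np.unique(h.matrix, axis=0, return_counts=True)
    return pats.astype(float), counts.astype(float)


def _pattern_loglik(
    pats: np.ndarray,
    mu: float,
    alpha: np.ndarray,
    sigma: float,
    quad: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float]:
    """Per-pattern marginal log-probabilities and the all-zero pattern's.

    Individual effects are integrated out with Gauss-Hermite quadrature
    (exact in the sigma = 0 limit, where the single effective node is 0).
    """
    eta0 = mu + alpha  # (T,)
    if sigma <= 0:
        lp1, lp0 = log_expit(eta0), log_expit(-eta0)
        pat_lp = pats @ lp1 + (1 - pats) @ lp0
        return pat_lp, float(lp0.sum())
    nodes, logw = quad
    eta = eta0[None, :] + np.sqrt(2.0) * sigma * nodes[:, None]  # (K, T)
    lp1, lp0 = log_expit(eta), log_expit(-eta)
    per_node = pats @ lp1.T + (1 - pats) @ lp0.T  # (U, K)
    pat_lp = logsumexp(per_node + logw[None, :], axis=1)
    zero_lp = float(logsumexp(lp0.sum(axis=1) + logw))
    return pat_lp, zero_lp


def _expand_alpha(free: np.ndarray | None, T: int) -> np.ndarray:
    if free is None:
        return np.zeros(T)
    return np.concatenate([free, [-np.sum(free)]])


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Tunable settings of the reversible-jump sampler.

    ``iterations`` counts *kept* draws after ``burn_in`` discarded ones.
    ``m_aug`` is the data-augmentation ceiling for N (default
    max(5n, n + 200)); the induced prior on N is uniform on [0, m_aug].
    Priors are diffuse by default: mu and the T-1 free alpha components are
    Normal(0, sd 10), sigma_gamma is Uniform(0, 10).
    """

    iterations: int = 25_000
    burn_in: int = 5_000
    m_aug: int | None = None
    models: tuple[str, ...] = MODEL_LABELS
    mu_prior_sd: float = 10.0
    alpha_prior_sd: float = 10.0
    sigma_prior_max: float = 10.0
    quad_nodes: int = 31
    mu_scale: float = 0.1
    alpha_scale: float = 0.15
    log_sigma_scale: float = 0.4
    adapt: bool = True
    adapt_interval: int = 50

    def __post_init__(self):
        self.models = tuple(self.models)
        unknown = set(self.models) - set(MODEL_LABELS)
        if unknown:
            raise CaptureDataError(f"unknown model labels {sorted(unknown)}")
        if not self.models:
            raise CaptureDataError("empty model space")
        if self.iterations < 1 or self.burn_in < 0:
            raise CaptureDataError("need iterations >= 1 and burn_in >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d


@dataclass
class PosteriorDraws:
    """Kept MCMC draws over (model, N, mu, alpha, sigma_gamma)."""

    model: np.ndarray  # int codes into MODEL_LABELS
    N: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray  # (kept, T), zeros when time effect off
    sigma_gamma: np.ndarray
    burn_in: int
    kept_iterations: int
    seed: int
    n: int
    T: int
    m_aug: int
    config: dict
    acceptance: dict
    warnings: tuple[str, ...] = ()

    def model_labels(self) -> np.ndarray:
        return np.asarray(MODEL_LABELS)[self.model]


@dataclass(frozen=True)
class BMAEstimate:
    """Model-averaged posterior summary of the population size."""

    model_posteriors: dict[str, float]
    N_mean: float
    N_sd: float
    N_median: float
    hpdi: tuple[float, float]
    level: float
    mc_se_mean: float
    per_model_summaries: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "model_posteriors": self.model_posteriors,
            "N_mean": self.N_mean,
            "N_sd": self.N_sd,
            "N_median": self.N_median,
            "hpdi": list(self.hpdi),
            "level": self.level,
            "mc_se_mean": self.mc_se_mean,
            "per_model_summaries": self.per_model_summaries,
        }


def _model_code(time_on: bool, het_on: bool) -> int:
    return MODEL_LABELS.index("M" + (("t" if time_on else "") + ("h" if het_on else "") or "0"))


class _Adaptive:
    """Robbins-Monro-style scale adaptation toward 20-50% acceptance."""

    def __init__(self, scale: float, enabled: bool, interval: int):
        self.scale, self.enabled, self.interval = scale, enabled, interval
        self.tried = 0
        self.accepted = 0

    def record(self, accepted: bool, adapting: bool):
        if not (self.enabled and adapting):
            return
        self.tried += 1
        self.accepted += accepted
        if self.tried >= self.interval:
            rate = self.accepted / self.tried
            if rate > 0.5:
                self.scale *= np.exp(0.15)
            elif rate < 0.2:
                self.scale *= np.exp(-0.15)
            self.tried = self.accepted = 0


def run_mcmc(
    data: CaptureHistory | CellCounts,
    config: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the joint posterior over (model, mu, alpha, sigma_gamma, N).

    Within-model moves are random-walk Metropolis on mu, on each free alpha
    component and on log sigma_gamma; N is redrawn exactly each sweep
    (N - n | rest ~ NegBin(n+1, 1-p0) truncated at the augmentation ceiling,
    the conditional implied by the uniform induced prior on N); one time
    toggle and one heterogeneity toggle per sweep move between models, with
    the toggled-on parameters proposed from their priors.  Deterministic
    replay under an identical seed, input and configuration.
    """
    if isinstance(data, CellCounts):
        data = to_capture_history(data)
    cfg = config or SamplerConfig()
    rng = np.random.default_rng(seed)
    pats, counts = _pattern_data(data)
    n, T = data.n, data.T
    m_aug = cfg.m_aug if cfg.m_aug is not None else max(5 * n, n + 200)
    if m_aug < n:
        raise CaptureDataError("augmentation ceiling below the observed count")
    gh_nodes, gh_w = np.polynomial.hermite.hermgauss(cfg.quad_nodes)
    quad = (gh_nodes, np.log(gh_w) - 0.5 * np.log(np.pi))

    space = [(("t" in lab), ("h" in lab)) for lab in cfg.models]
    # start from the simplest time-effect model available
    for pref in ("Mt", "M0", "Mth", "Mh"):
        if pref in cfg.models:
            time_on, het_on = ("t" in pref), ("h" in pref)
            break

    pbar = counts @ pats.sum(axis=1) / (n * T)
    pbar = float(np.clip(pbar, 1.0 / (n * T + 2), 1.0 - 1.0 / (n * T + 2)))
    mu = float(np.log(pbar / (1 - pbar)))
    a_free = np.zeros(T - 1) if time_on else None
    sigma = 1.0 if het_on else 0.0
    N = min(int(round(n * 1.05)), m_aug)

    def data_ll(mu_, afree_, sig_):
        pat_lp, zero_lp = _pattern_loglik(pats, mu_, _expand_alpha(afree_, T), sig_, quad)
        return counts @ pat_lp, zero_lp

    def full_ll(sum_lp, zero_lp, N_):
        return (
            gammaln(N_ + 1) - gammaln(N_ - n + 1) + sum_lp + (N_ - n) * zero_lp
        )

    def log_prior(mu_, afree_, sig_):
        lp = -0.5 * (mu_ / cfg.mu_prior_sd) ** 2
        if afree_ is not None:
            lp += -0.5 * np.sum((afree_ / cfg.alpha_prior_sd) ** 2)
        # sigma prior is uniform: constant inside (0, max), enforced in moves
        return lp

    sum_lp, zero_lp = data_ll(mu, a_free, sigma)

    total = cfg.burn_in + cfg.iterations
    keep_model = np.empty(cfg.iterations, dtype=np.int8)
    keep_N = np.empty(cfg.iterations, dtype=np.int64)
    keep_mu = np.empty(cfg.iterations)
    keep_alpha = np.zeros((cfg.iterations, T))
    keep_sigma = np.zeros(cfg.iterations)

    ad_mu = _Adaptive(cfg.mu_scale, cfg.adapt, cfg.adapt_interval)
    ad_alpha = _Adaptive(cfg.alpha_scale, cfg.adapt, cfg.adapt_interval)
    ad_lsig = _Adaptive(cfg.log_sigma_scale, cfg.adapt, cfg.adapt_interval)
    acc = {k: 0 for k in ("mu", "alpha", "sigma", "jump_time", "jump_het")}
    tries = {k: 0 for k in acc}
    ceiling_hits = 0

    for it in range(total):
        adapting = it < cfg.burn_in

        # -- mu ------------------------------------------------------------
        prop = mu + ad_mu.scale * rng.standard_normal()
        s_lp, z_lp = data_ll(prop, a_free, sigma)
        logr = (
            full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
            + log_prior(prop, a_free, sigma) - log_prior(mu, a_free, sigma)
        )
        tries["mu"] += 1
        ok = np.log(rng.uniform()) < logr
        if ok:
            mu, sum_lp, zero_lp = prop, s_lp, z_lp
            acc["mu"] += 1
        ad_mu.record(ok, adapting)

        # -- alpha (free components, one at a time) --------------------------
        if time_on:
            for j in range(T - 1):
                prop_a = a_free.copy()
                prop_a[j] += ad_alpha.scale * rng.standard_normal()
                s_lp, z_lp = data_ll(mu, prop_a, sigma)
                logr = (
                    full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                    + log_prior(mu, prop_a, sigma) - log_prior(mu, a_free, sigma)
                )
                tries["alpha"] += 1
                ok = np.log(rng.uniform()) < logr
                if ok:
                    a_free, sum_lp, zero_lp = prop_a, s_lp, z_lp
                    acc["alpha"] += 1
                ad_alpha.record(ok, adapting)

        # -- sigma (random walk on log scale, Jacobian sigma'/sigma) --------
        if het_on:
            lprop = np.log(sigma) + ad_lsig.scale * rng.standard_normal()
            prop_s = float(np.exp(lprop))
            tries["sigma"] += 1
            ok = False
            if prop_s < cfg.sigma_prior_max:
                s_lp, z_lp = data_ll(mu, a_free, prop_s)
                logr = (
                    full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                    + np.log(prop_s) - np.log(sigma)
                )
                ok = np.log(rng.uniform()) < logr
            if ok:
                sigma, sum_lp, zero_lp = prop_s, s_lp, z_lp
                acc["sigma"] += 1
            ad_lsig.record(ok, adapting)

        # -- N: exact conditional draw --------------------------------------
        p0 = float(np.exp(min(zero_lp, -1e-12)))
        r = n + 1
        fmax = stats.nbinom.cdf(m_aug - n, r, 1.0 - p0)
        u = rng.uniform() * fmax
        k = int(stats.nbinom.ppf(max(u, 1e-300), r, 1.0 - p0))
        N = min(n + k, m_aug)
        if N >= m_aug:
            ceiling_hits += not adapting

        # -- reversible jumps ------------------------------------------------
        if ((not time_on), het_on) in space and len(space) > 1:
            tries["jump_time"] += 1
            if time_on:
                s_lp, z_lp = data_ll(mu, None, sigma)
                logr = full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                if np.log(rng.uniform()) < logr:
                    time_on, a_free, sum_lp, zero_lp = False, None, s_lp, z_lp
                    acc["jump_time"] += 1
            else:
                prop_a = rng.normal(0.0, cfg.alpha_prior_sd, size=T - 1)
                s_lp, z_lp = data_ll(mu, prop_a, sigma)
                logr = full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                if np.log(rng.uniform()) < logr:
                    time_on, a_free, sum_lp, zero_lp = True, prop_a, s_lp, z_lp
                    acc["jump_time"] += 1
        # heterogeneity toggle
        if (time_on, (not het_on)) in space and len(space) > 1:
            tries["jump_het"] += 1
            if het_on:
                s_lp, z_lp = data_ll(mu, a_free, 0.0)
                logr = full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                if np.log(rng.uniform()) < logr:
                    het_on, sigma, sum_lp, zero_lp = False, 0.0, s_lp, z_lp
                    acc["jump_het"] += 1
            else:
                prop_s = rng.uniform(0.0, cfg.sigma_prior_max)
                s_lp, z_lp = data_ll(mu, a_free, prop_s)
                logr = full_ll(s_lp, z_lp, N) - full_ll(sum_lp, zero_lp, N)
                if np.log(rng.uniform()) < logr:
                    het_on, sigma, sum_lp, zero_lp = True, prop_s, s_lp, z_lp
                    acc["jump_het"] += 1

        if not adapting:
            j = it - cfg.burn_in
            keep_model[j] = _model_code(time_on, het_on)
            keep_N[j] = N
            keep_mu[j] = mu
            keep_alpha[j] = _expand_alpha(a_free, T) if time_on else 0.0
            keep_sigma[j] = sigma if het_on else 0.0

    warns: list[str] = []
    if ceiling_hits >= 0.01 * cfg.iterations:
        msg = (
            f"posterior mass at the augmentation ceiling ({ceiling_hits} of "
            f"{cfg.iterations} kept draws at N = {m_aug}); increase m_aug"
        )
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    rates = {
        k: (acc[k] / tries[k] if tries[k] else float("nan")) for k in acc
    }
    return PosteriorDraws(
        model=keep_model,
        N=keep_N,
        mu=keep_mu,
        alpha=keep_alpha,
        sigma_gamma=keep_sigma,
        burn_in=cfg.burn_in,
        kept_iterations=cfg.iterations,
        seed=seed,
        n=n,
        T=T,
        m_aug=m_aug,
        config=cfg.to_dict(),
        acceptance=rates,
        warnings=tuple(warns),
    )


def _summary(N: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(N)),
        "sd": float(np.std(N, ddof=1)) if N.size > 1 else 0.0,
        "median": float(np.median(N)),
    }


def _hpdi(N: np.ndarray, level: float) -> tuple[float, float]:
    if np.ptp(N) == 0:
        return float(N[0]), float(N[0])
    lo, hi = az.hdi(np.asarray(N, float), hdi_prob=level)
    return float(lo), float(hi)


def bma_summarize(d: PosteriorDraws, level: float = 0.95) -> BMAEstimate:
    """Model-averaged and per-model posterior summaries of N.

    Model posterior probabilities are the chain's visit frequencies; the
    averaged summaries are computed over *all* kept draws, which is exactly
    the model-averaged posterior; per-model summaries condition on the visited
    subsets.  The HPDI is the shortest interval holding ``level`` mass of the
    empirical N distribution.
    """
    if d.kept_iterations == 0 or d.N.size == 0:
        raise CaptureDataError("no kept draws to summarize")
    K = d.N.size
    post = {lab: float(np.mean(d.model == i)) for i, lab in enumerate(MODEL_LABELS)}
    per_model: dict[str, dict[str, float]] = {}
    for i, lab in enumerate(MODEL_LABELS):
        sub = d.N[d.model == i]
        if sub.size:
            s = _summary(sub)
            lo, hi = _hpdi(sub, level)
            s["hpdi_low"], s["hpdi_high"] = lo, hi
            s["probability"] = post[lab]
            per_model[lab] = s
    overall = _summary(d.N)
    lo, hi = _hpdi(d.N, level)
    if np.ptp(d.N) == 0:
        mcse = 0.0
    else:
        ess = float(az.ess(np.asarray(d.N, float)))
        mcse = overall["sd"] / np.sqrt(max(ess, 1.0))
    return BMAEstimate(
        model_posteriors=post,
        N_mean=overall["mean"],
        N_sd=overall["sd"],
        N_median=overall["median"],
        hpdi=(lo, hi),
        level=level,
        mc_se_mean=mcse,
        per_model_summaries=per_model,
    )


# ---------------------------------------------------------------------------
# independent grid oracle (small instances, no heterogeneity)
# ---------------------------------------------------------------------------

def grid_posterior_oracle(
    h: CaptureHistory,
    m: ModelSpec,
    mu_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    n_max: int = 60,
    mu_prior_sd: float = 10.0,
    alpha_prior_sd: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct numerical posterior of N by brute-force grid summation.

    Sums likelihood x prior over a grid of (mu, free alpha components) and the
    range N = n..n_max, then normalizes; intended as an independent oracle for
    the sampler on toy instances.  Models with heterogeneity are refused (the
    gamma integral is not grid-feasible here).
    """
    if m.heterogeneity:
        raise CaptureDataError("grid oracle supports only models without heterogeneity")
    if h.n > 30 or h.T > 3:
        raise CaptureDataError("grid oracle is restricted to small instances (n<=30, T<=3)")
    if n_max < h.n:
        raise CaptureDataError("n_max below the observed count")
    pats, counts = _pattern_data(h)
    n, T = h.n, h.T
    if mu_grid is None:
        mu_grid = np.linspace(-5, 5, 81)
    grids = [np.asarray(mu_grid, float)]
    prior_sds = [mu_prior_sd]
    if m.time_effect:
        if alpha_grid is None:
            alpha_grid = np.linspace(-4, 4, 41)
        for _ in range(T - 1):
            grids.append(np.asarray(alpha_grid, float))
            prior_sds.append(alpha_prior_sd)
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = np.stack([g.ravel() for g in mesh], axis=1)  # (G, 1+T-1)

    mu_v = flat[:, 0]
    alpha_v = np.zeros((flat.shape[0], T))
    if m.time_effect:
        alpha_v[:, : T - 1] = flat[:, 1:]
        alpha_v[:, T - 1] = -flat[:, 1:].sum(axis=1)
    eta = mu_v[:, None] + alpha_v  # (G, T)
    lp1, lp0 = log_expit(eta), log_expit(-eta)
    sum_lp = (pats @ lp1.T + (1 - pats) @ lp0.T).T @ counts  # (G,)
    zero_lp = lp0.sum(axis=1)  # (G,)
    logprior = np.zeros(flat.shape[0])
    for j, sd in enumerate(prior_sds):
        logprior += -0.5 * (flat[:, j] / sd) ** 2

    Ns = np.arange(n, n_max + 1)
    comb = gammaln(Ns + 1) - gammaln(Ns - n + 1)  # (M,)
    logpost = comb[:, None] + sum_lp[None, :] + np.outer(Ns - n, zero_lp) + logprior[None, :]
    lp_N = logsumexp(logpost, axis=1)
    probs = np.exp(lp_N - logsumexp(lp_N))
    return Ns, probs
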