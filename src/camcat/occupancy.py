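"""Bayesian single-season, single-species occupancy model.

Hierarchy (per site i):

    z_i  ~ Bernoulli(psi_i),          logit(psi_i) = x_i' beta
    y_i  ~ Binomial(n_i, p_i z_i),    logit(p_i)   = w_i' alpha

where z_i is the latent occupancy state, y_i the number of occasions with a
detection, n_i the occasions surveyed, x_i the standardized site covariates
of the space-use model and w_i those of the detection model. Coefficients
carry independent Normal(0, 3.16) priors (precision 0.1, weakly informative
on the logit scale). Inference is adaptive random-walk Metropolis on the
coefficients against the marginal likelihood (z_i summed out per site in
closed form), one univariate step per coefficient with the proposal scale
tuned toward ~0.44 acceptance during an adaptation phase and frozen
afterwards, plus one joint random-walk step per iteration whose proposal
covariance is learned from the pre-burn history (frozen after burn) to cross
the psi–p correlation ridge that weakly identified detection data produce;
the latent z_i are drawn each iteration from their exact Bernoulli full
conditional. Collapsing z out of the coefficient updates
avoids the self-reinforcing all-occupied trap of fully augmented samplers
when detection information is weak, while targeting the same posterior.

A detection at a site forces z_i = 1; a silent site leaves z_i uncertain with

    Pr(z_i = 1 | y_i = 0) = psi_i (1-p_i)^{n_i} / (psi_i (1-p_i)^{n_i} + 1 - psi_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln, log_expit, logsumexp

from .ingest import DetectionHistory, StandardizedDesign

logger = logging.getLogger("camcat")

DEFAULT_PRIOR_SD = 3.16  # ~ precision 0.1 on the logit scale
RHAT_THRESHOLD = 1.1
_TARGET_ACCEPT = 0.44
_ADAPT_BATCH = 50


@dataclass(frozen=True)
class OccupancyModelSpec:
    """Covariate sets for the space-use (psi) and detection (p) regressions."""

    psi_covariates: tuple[str, ...] = (
        "canopycover", "predators", "livestock", "human", "othercat",
    )
    p_covariates: tuple[str, ...] = ("dist_water", "dist_road", "dist_settlement")
    prior_mean: float = 0.0
    prior_sd: float = DEFAULT_PRIOR_SD

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")

    @property
    def psi_names(self) -> list[str]:
        return ["psi_intercept"] + [f"psi_{c}" for c in self.psi_covariates]

    @property
    def p_names(self) -> list[str]:
        return ["p_intercept"] + [f"p_{c}" for c in self.p_covariates]


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 3
    adapt: int = 1000
    burn: int = 1000
    iterations: int = 15000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("chains", "adapt", "burn", "iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PosteriorDraws:
    """Post-burn MCMC samples: (chains, iterations, ...) arrays."""

    beta: np.ndarray        # (C, I, k_psi)
    alpha: np.ndarray       # (C, I, k_p)
    z: np.ndarray           # (C, I, n_sites) uint8
    psi_names: list[str]
    p_names: list[str]
    X_psi: np.ndarray = field(repr=False, default=None)
    X_p: np.ndarray = field(repr=False, default=None)
    sites: list = field(default_factory=list)
    settings: MCMCSettings | None = None
    accept_rate: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    def pooled(self, which: str = "beta") -> np.ndarray:
        arr = getattr(self, which)
        return arr.reshape(-1, arr.shape[-1])


@dataclass(frozen=True)
class SpeciesComparison:
    """Welch two-sample t-test between per-site probability vectors."""

    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def build_design_matrices(
    design: StandardizedDesign, spec: OccupancyModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Intercept-augmented design matrices for the psi and p regressions."""
    for c in (*spec.psi_covariates, *spec.p_covariates):
        if c not in design.frame.columns:
            raise ValueError(f"covariate {c!r} not in the standardized design")
    S = len(design.frame)
    X_psi = np.column_stack(
        [np.ones(S)] + [design.frame[c].to_numpy(float) for c in spec.psi_covariates]
    )
    X_p = np.column_stack(
        [np.ones(S)] + [design.frame[c].to_numpy(float) for c in spec.p_covariates]
    )
    return X_psi, X_p


def joint_log_density(
    beta: np.ndarray,
    alpha: np.ndarray,
    z: np.ndarray,
    history: DetectionHistory,
    design: StandardizedDesign,
    spec: OccupancyModelSpec,
) -> float:
    """Log joint density log p(y, z, beta, alpha) of the occupancy hierarchy.

    Returns −inf when a site has detections (y_total > 0) but z = 0, which
    has probability zero under the model.
    """
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    z = np.asarray(z, float)
    X_psi, X_p = build_design_matrices(design, spec)
    if beta.shape != (X_psi.shape[1],) or alpha.shape != (X_p.shape[1],):
        raise ValueError("coefficient vector does not match the covariate set")
    y, n = history.y_total.astype(float), history.n.astype(float)
    if z.shape != y.shape:
        raise ValueError("z length does not match the number of sites")
    if np.any((z == 0) & (y > 0)):
        return -np.inf
    eta_psi = X_psi @ beta
    eta_p = X_p @ alpha
    ll = float(z @ log_expit(eta_psi) + (1.0 - z) @ log_expit(-eta_psi))
    occ = z == 1
    if occ.any():
        binom_const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        ll += float(
            np.sum(
                (binom_const + y * log_expit(eta_p) + (n - y) * log_expit(-eta_p))[occ]
            )
        )
    prior = stats.norm.logpdf(
        np.concatenate([beta, alpha]), spec.prior_mean, spec.prior_sd
    ).sum()
    return ll + float(prior)


def marginal_log_likelihood_brute(
    beta, alpha, history: DetectionHistory, design: StandardizedDesign,
    spec: OccupancyModelSpec,
) -> float:
    """Exact log likelihood with z summed out, by per-site closed form.

    Sites factorize:  L_i = psi_i Binom(y_i | n_i, p_i) + (1 - psi_i) 1{y_i = 0}.
    Usable as an oracle against logsumexp of :func:`joint_log_density` over
    all z configurations on small problems.
    """
    X_psi, X_p = build_design_matrices(design, spec)
    psi = expit(X_psi @ np.asarray(beta, float))
    p = expit(X_p @ np.asarray(alpha, float))
    y, n = history.y_total, history.n
    lik = psi * stats.binom.pmf(y, n, p) + (1.0 - psi) * (y == 0)
    return float(np.sum(np.log(lik)))


def update_latent_z(
    beta, alpha, history: DetectionHistory, design: StandardizedDesign,
    spec: OccupancyModelSpec, rng: np.random.Generator,
) -> np.ndarray:
    """Draw z from its exact Bernoulli full conditional given the data."""
    X_psi, X_p = build_design_matrices(design, spec)
    psi = expit(X_psi @ np.asarray(beta, float))
    eta_p = X_p @ np.asarray(alpha, float)
    pr = conditional_z_probability(psi, eta_p, history.n)
    z = (rng.random(history.n_sites) < pr).astype(np.int8)
    z[history.y_total > 0] = 1
    return z


def conditional_z_probability(psi, eta_p, n) -> np.ndarray:
    """Pr(z = 1 | y = 0) for silent sites; stable via log1p-expit."""
    psi = np.asarray(psi, float)
    log_miss = np.asarray(n, float) * log_expit(-np.asarray(eta_p, float))
    num = psi * np.exp(log_miss)
    return num / (num + 1.0 - psi)


def _run_chain(y, n, X_psi, X_p, prior_mean, prior_var, settings, seed):
    """One MCMC chain. Returns post-burn (beta, alpha, z) draws + accept rates."""
    rng = np.random.default_rng(seed)
    S, k1 = X_psi.shape
    k2 = X_p.shape[1]
    detected = y > 0
    silent = ~detected
    yf, nf = y.astype(float), n.astype(float)
    yd, nd = yf[detected], nf[detected]
    Xp_det, Xp_sil = X_p[detected], X_p[silent]
    n_sil = nf[silent]

    def marginal_ll(eta_psi, eta_p):
        # per-site likelihood with z summed out:
        #   detected: log psi + y log p + (n-y) log(1-p)
        #   silent:   log( psi (1-p)^n + 1-psi )
        lpsi = log_expit(eta_psi)
        det = np.sum(lpsi[detected]
                     + yd * log_expit(eta_p[detected])
                     + (nd - yd) * log_expit(-eta_p[detected]))
        sil = np.sum(np.logaddexp(
            lpsi[silent] + n_sil * log_expit(-eta_p[silent]),
            log_expit(-eta_psi[silent])))
        return det + sil

    beta = rng.normal(0.0, 1.0, k1)
    alpha = rng.normal(0.0, 1.0, k2)

    eta_psi = X_psi @ beta
    eta_p = X_p @ alpha
    step_b = np.full(k1, 0.3)
    step_a = np.full(k2, 0.3)

    total = settings.adapt + settings.burn + settings.iterations
    keep_from = settings.adapt + settings.burn
    out_beta = np.empty((settings.iterations, k1))
    out_alpha = np.empty((settings.iterations, k2))
    out_z = np.empty((settings.iterations, S), dtype=np.uint8)
    acc = np.zeros(k1 + k2)
    batch_acc = np.zeros(k1 + k2)
    n_kept_updates = 0

    inv2v = 0.5 / prior_var
    cur = marginal_ll(eta_psi, eta_p)

    # joint adaptive-Metropolis state: proposal covariance learned from the
    # pre-burn history, scale tuned to ~0.23 acceptance, frozen after burn
    d_all = k1 + k2
    hist_buf = np.empty((keep_from, d_all))
    joint_chol = np.eye(d_all) * 0.1
    joint_scale = 2.38 / np.sqrt(d_all)
    joint_acc_batch = 0.0

    for t in range(total):
        norm = rng.standard_normal(k1 + k2)
        logu = np.log(rng.random(k1 + k2))
        for j in range(k1):
            prop = beta[j] + step_b[j] * norm[j]
            eta_prop = eta_psi + X_psi[:, j] * (prop - beta[j])
            new = marginal_ll(eta_prop, eta_p)
            dprior = ((beta[j] - prior_mean) ** 2 - (prop - prior_mean) ** 2) * inv2v
            if logu[j] < new - cur + dprior:
                beta[j] = prop
                eta_psi = eta_prop
                cur = new
                batch_acc[j] += 1
                if t >= keep_from:
                    acc[j] += 1

        for j in range(k2):
            prop = alpha[j] + step_a[j] * norm[k1 + j]
            eta_prop = eta_p + X_p[:, j] * (prop - alpha[j])
            new = marginal_ll(eta_psi, eta_prop)
            dprior = ((alpha[j] - prior_mean) ** 2 - (prop - prior_mean) ** 2) * inv2v
            if logu[k1 + j] < new - cur + dprior:
                alpha[j] = prop
                eta_p = eta_prop
                cur = new
                batch_acc[k1 + j] += 1
                if t >= keep_from:
                    acc[k1 + j] += 1

        # --- joint step across the psi-p ridge -------------------------------
        theta = np.concatenate([beta, alpha])
        prop = theta + joint_scale * (joint_chol @ rng.standard_normal(d_all))
        eta_psi_prop = X_psi @ prop[:k1]
        eta_p_prop = X_p @ prop[k1:]
        new = marginal_ll(eta_psi_prop, eta_p_prop)
        dprior = (np.sum((theta - prior_mean) ** 2)
                  - np.sum((prop - prior_mean) ** 2)) * inv2v
        if np.log(rng.random()) < new - cur + dprior:
            beta, alpha = prop[:k1].copy(), prop[k1:].copy()
            eta_psi, eta_p = eta_psi_prop, eta_p_prop
            cur = new
            joint_acc_batch += 1.0

        if t < keep_from:
            hist_buf[t, :k1] = beta
            hist_buf[t, k1:] = alpha
            if t >= settings.adapt // 2 and (t + 1) % 200 == 0:
                cov = np.cov(hist_buf[t // 2: t + 1].T)
                try:
                    joint_chol = np.linalg.cholesky(
                        cov + 1e-8 * np.eye(d_all))
                except np.linalg.LinAlgError:
                    pass
                rate = joint_acc_batch / 200.0
                joint_scale *= np.exp(np.clip(rate - 0.23, -0.5, 0.5))
                joint_acc_batch = 0.0

        # --- latent states: exact Bernoulli full conditional -----------------
        psi = expit(eta_psi)
        num = psi * np.exp(nf * log_expit(-eta_p))
        pr = num / (num + 1.0 - psi)
        z = (rng.random(S) < pr).astype(np.uint8)
        z[detected] = 1

        # --- proposal-scale adaptation (frozen after the adapt phase) ---------
        if t < settings.adapt and (t + 1) % _ADAPT_BATCH == 0:
            rate = batch_acc / _ADAPT_BATCH
            factor = np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            step_b *= factor[:k1]
            step_a *= factor[k1:]
            batch_acc[:] = 0.0

        if t >= keep_from:
            i = t - keep_from
            out_beta[i] = beta
            out_alpha[i] = alpha
            out_z[i] = z
            n_kept_updates += 1

    return out_beta, out_alpha, out_z, acc / max(n_kept_updates, 1)


def run_mcmc(
    history: DetectionHistory,
    design: StandardizedDesign,
    spec: OccupancyModelSpec,
    settings: MCMCSettings = MCMCSettings(),
) -> PosteriorDraws:
    """Fit the occupancy model; chain ``c`` is seeded with ``settings.seed + c``."""
    X_psi, X_p = build_design_matrices(design, spec)
    y, n = history.y_total, history.n
    betas, alphas, zs, rates = [], [], [], []
    for c in range(settings.chains):
        b, a, z, rate = _run_chain(
            y, n, X_psi, X_p, spec.prior_mean, spec.prior_sd ** 2,
            settings, settings.seed + c,
        )
        betas.append(b)
        alphas.append(a)
        zs.append(z)
        rates.append(rate)
    draws = PosteriorDraws(
        beta=np.stack(betas),
        alpha=np.stack(alphas),
        z=np.stack(zs),
        psi_names=spec.psi_names,
        p_names=spec.p_names,
        X_psi=X_psi,
        X_p=X_p,
        sites=list(history.sites),
        settings=settings,
        accept_rate=np.stack(rates),
    )
    logger.info(
        "mcmc %s: %d chains x %d draws, mean acceptance %.2f",
        history.species, settings.chains, settings.iterations,
        float(np.mean(draws.accept_rate)),
    )
    return draws


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    Each chain is halved, giving 2C sequences; Rhat compares between- to
    within-sequence variance. Constant draws return 1 by convention.
    """
    chains = np.asarray(chains, float)
    half = chains.shape[1] // 2
    seqs = chains[:, : 2 * half].reshape(-1, half)
    if np.ptp(seqs) == 0:
        return 1.0
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS from the multi-chain autocorrelation sum (Geyer initial positive
    sequence): pairwise sums of autocorrelations are accumulated until the
    first negative pair."""
    chains = np.asarray(chains, float)
    C, N = chains.shape
    if np.ptp(chains) == 0:
        return float(C * N)
    acov = np.empty((C, N))
    for c in range(C):
        x = chains[c] - chains[c].mean()
        f = np.fft.rfft(x, 2 * N)
        a = np.fft.irfft(f * np.conj(f), 2 * N)[:N].real
        acov[c] = a / N
    W = np.mean([chains[c].var(ddof=1) for c in range(C)])
    B_over_n = chains.mean(axis=1).var(ddof=1) if C > 1 else 0.0
    var_plus = (N - 1) / N * W + B_over_n
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    tau = 1.0
    t = 1
    while t + 1 < N:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        t += 2
    return float(min(C * N / tau, C * N))


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table: mean, sd, 95% equal-tailed interval, Rhat,
    ESS, whether the interval overlaps 0, and f = posterior mass sharing the
    mean's sign."""
    rows = []
    single = draws.n_chains < 2
    if single:
        logger.warning("single chain: Rhat is not defined and reported as NaN")
    for names, arr in ((draws.psi_names, draws.beta), (draws.p_names, draws.alpha)):
        for j, name in enumerate(names):
            chains = arr[:, :, j]
            flat = chains.reshape(-1)
            mean = float(flat.mean())
            lci, uci = np.percentile(flat, [2.5, 97.5])
            share_pos = float((flat > 0).mean())
            share_neg = float((flat < 0).mean())
            if mean > 0:
                f = share_pos
            elif mean < 0:
                f = share_neg
            else:
                f = max(share_pos, share_neg)
            rows.append({
                "parameter": name,
                "mean": mean,
                "sd": float(flat.std(ddof=1)),
                "lci": float(lci),
                "uci": float(uci),
                "rhat": np.nan if single else split_rhat(chains),
                "ess": effective_sample_size(chains),
                "overlap0": int(lci <= 0.0 <= uci),
                "f": f,
            })
    return pd.DataFrame(rows).set_index("parameter")


def converged(summary: pd.DataFrame, threshold: float = RHAT_THRESHOLD) -> bool:
    """All-parameter convergence per the Rhat < threshold rule."""
    rhat = summary["rhat"].dropna()
    return bool((rhat < threshold).all())


def derive_site_probabilities(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and SD of per-site psi_i and p_i over all draws."""
    out = {}
    for tag, X, arr in (("psi", draws.X_psi, draws.beta), ("p", draws.X_p, draws.alpha)):
        flat = arr.reshape(-1, arr.shape[-1])
        vals = expit(flat @ X.T)  # (draws, sites)
        out[f"{tag}_mean"] = vals.mean(axis=0)
        out[f"{tag}_sd"] = vals.std(axis=0, ddof=1)
    idx = pd.Index(draws.sites if draws.sites else range(draws.X_psi.shape[0]),
                   name="site_id")
    return pd.DataFrame(out, index=idx)


def compare_species(psi_a, psi_b) -> SpeciesComparison:
    """Welch unpaired t-test on two per-site probability vectors."""
    a = np.asarray(psi_a, float)
    b = np.asarray(psi_b, float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length (one value per site)")
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    if a.std(ddof=1) <= 1e-14 * scale and b.std(ddof=1) <= 1e-14 * scale:
        if np.allclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return SpeciesComparison(
        t_statistic=float(t), p_value=float(p),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
    )


def logsumexp_over_latents(
    beta, alpha, history: DetectionHistory, design: StandardizedDesign,
    spec: OccupancyModelSpec,
) -> float:
    """logsumexp of the joint density over every latent configuration.

    Exponential in the number of sites; intended for small oracle checks
    against :func:`marginal_log_likelihood_brute`.
    """
    S = history.n_sites
    if S > 16:
        raise ValueError("latent enumeration is exponential; use <= 16 sites")
    vals = []
    for mask in range(2 ** S):
        z = np.array([(mask >> i) & 1 for i in range(S)], dtype=float)
        vals.append(joint_log_density(beta, alpha, z, history, design, spec))
    return float(logsumexp(vals))
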