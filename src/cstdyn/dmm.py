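"""Dirichlet-Multinomial mixture (DMM) community state typing.

Each body site's samples are modeled as a mixture of K Dirichlet
components over OTU proportions, with counts arising from a multinomial
at each sample's library size. Estimation is by EM: the E-step computes
component responsibilities from Dirichlet-Multinomial log-densities,
the M-step updates mixture weights by posterior means and the Dirichlet
parameters by Minka's monotone fixed-point iteration on the weighted
likelihood. Model complexity K is scored by a Laplace approximation of
the negative log model evidence under a flat (improper) parameter
prior, and chosen by repeated subsampling with a standard-error rule.
Fitted components become community state types (CSTs), renumbered so
CST 1 is the most frequent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, polygamma

from .types import CountsTable

_ALPHA_FLOOR = 1e-8


@dataclass
class DMMFit:
    k: int
    alpha: np.ndarray               # K x n_otus, all > 0
    pi: np.ndarray                  # mixture weights, sums to 1
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    otu_ids: list[str] = field(default_factory=list)
    neg_log_evidence: float | None = None

    @property
    def n_free_parameters(self) -> int:
        return self.k * self.alpha.shape[1] + (self.k - 1)


@dataclass
class CSTAssignment:
    """Per-sample CST posteriors and canonical MAP labels.

    Posterior columns and ``map_label`` are in canonical (frequency)
    order: CST 1 is the most frequent. ``canonical_map[j]`` gives the
    canonical label (1-based) of fit-order component j.
    """

    sample_ids: list[str]
    posterior: np.ndarray           # samples x K, canonical column order
    map_label: np.ndarray           # 1..K
    canonical_map: np.ndarray


@dataclass
class KSelection:
    scores: np.ndarray              # reps x k_max neg_log_evidence (NaN = failed)
    k_values: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    chosen_k: int
    rule: str = "one_se"


def _dm_logpmf_matrix(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """n x K matrix of Dirichlet-Multinomial log-densities.

    Includes the multinomial coefficient so values are proper log-pmfs.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.atleast_2d(alpha)
    n_tot = x.sum(axis=1)
    a_tot = alpha.sum(axis=1)
    coef = gammaln(n_tot + 1) - gammaln(x + 1).sum(axis=1)
    core = gammaln(x[:, None, :] + alpha[None, :, :]).sum(axis=2) \
        - gammaln(alpha).sum(axis=1)[None, :]
    norm = gammaln(a_tot)[None, :] - gammaln(n_tot[:, None] + a_tot[None, :])
    return coef[:, None] + norm + core


def _weighted_alpha_update(x: np.ndarray, w: np.ndarray, alpha: np.ndarray,
                           n_inner: int = 20, inner_tol: float = 1e-8
                           ) -> np.ndarray:
    """Minka fixed-point update of one component's alpha under weights w."""
    n_tot = x.sum(axis=1)
    wsum = w.sum()
    if wsum <= 0:
        return alpha
    for _ in range(n_inner):
        a_tot = alpha.sum()
        num = w @ (digamma(x + alpha[None, :]) - digamma(alpha)[None, :])
        den = w @ (digamma(n_tot + a_tot) - digamma(a_tot))
        if den <= 0:
            break
        new = np.maximum(alpha * num / den, _ALPHA_FLOOR)
        delta = np.max(np.abs(new - alpha) / np.maximum(alpha, 1e-12))
        alpha = new
        if delta < inner_tol:
            break
    return alpha


def _init_alpha(x: np.ndarray, k: int, seed: int,
                concentration: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """k-means on relative abundances; cluster means scaled to a fixed
    concentration give the starting Dirichlet parameters."""
    from sklearn.cluster import KMeans

    rel = x / x.sum(axis=1, keepdims=True)
    if k == 1:
        centers = rel.mean(axis=0, keepdims=True)
        sizes = np.array([x.shape[0]])
    else:
        km = KMeans(n_clusters=k, n_init=3, random_state=seed)
        labels = km.fit_predict(rel)
        centers = np.vstack([
            rel[labels == j].mean(axis=0) if np.any(labels == j)
            else rel.mean(axis=0)
            for j in range(k)
        ])
        sizes = np.array([max(np.sum(labels == j), 1) for j in range(k)])
    alpha = np.maximum(centers * concentration, 1e-3)
    pi = sizes / sizes.sum()
    return alpha, pi


def fit_dmm(counts: CountsTable, k: int, seed: int = 0, *,
            n_restarts: int = 3, tol: float = 1e-6,
            max_iter: int = 500) -> DMMFit:
    """Fit a K-component Dirichlet-Multinomial mixture by EM.

    The best of ``n_restarts`` differently-initialized runs is kept.
    The log-likelihood trace is monotone non-decreasing (within 1e-8);
    convergence is declared when the relative change drops below
    ``tol``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > counts.n_samples:
        raise ValueError(f"k={k} exceeds n_samples={counts.n_samples}")
    x = counts.counts.astype(float)
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("every sample must have positive total count")

    best: DMMFit | None = None
    for r in range(n_restarts):
        alpha, pi = _init_alpha(x, k, seed + 1000 * r)
        trace = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logf = _dm_logpmf_matrix(x, alpha) + np.log(pi)[None, :]
            ll = float(logsumexp(logf, axis=1).sum())
            if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
                warnings.warn("EM log-likelihood decreased; keeping last iterate")
                break
            if trace and abs(ll - trace[-1]) <= tol * max(1.0, abs(trace[-1])):
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            resp = np.exp(logf - logsumexp(logf, axis=1, keepdims=True))
            pi = np.maximum(resp.mean(axis=0), 1e-12)
            pi = pi / pi.sum()
            for j in range(k):
                alpha[j] = _weighted_alpha_update(x, resp[:, j], alpha[j])
        fit = DMMFit(
            k=k, alpha=alpha.copy(), pi=pi.copy(), loglik=trace[-1],
            loglik_trace=np.array(trace), n_iter=it, converged=converged,
            otu_ids=list(counts.otu_ids),
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
        if k == 1:
            break  # restarts identical: deterministic init
    assert best is not None
    if not best.converged:
        warnings.warn(f"DMM EM (K={k}) did not converge in {max_iter} iterations")
    return best


def _mixture_hessian(x: np.ndarray, alpha: np.ndarray,
                     pi: np.ndarray) -> np.ndarray:
    """Hessian of the negative observed-data log-likelihood at the fit.

    Parameters are the K*J Dirichlet parameters plus the first K-1
    mixture weights (the last is 1 minus their sum).
    """
    n, j_dim = x.shape
    k = alpha.shape[0]
    n_tot = x.sum(axis=1)
    a_tot = alpha.sum(axis=1)

    logf = _dm_logpmf_matrix(x, alpha)
    logden = logsumexp(logf + np.log(pi)[None, :], axis=1)
    r = np.exp(logf + np.log(pi)[None, :] - logden[:, None])   # n x K

    # per-sample, per-component gradient of log f wrt alpha_k: n x K x J
    g = (digamma(x[:, None, :] + alpha[None, :, :]) - digamma(alpha)[None, :, :]
         + digamma(a_tot)[None, :, None]
         - digamma(n_tot[:, None] + a_tot[None, :])[:, :, None])

    d = k * j_dim + (k - 1)
    h = np.zeros((d, d))

    # alpha-alpha blocks
    for a_idx in range(k):
        sl_a = slice(a_idx * j_dim, (a_idx + 1) * j_dim)
        # within-component curvature of log f: diag + rank-one-in-ones part
        diag_term = polygamma(1, x + alpha[a_idx][None, :]) \
            - polygamma(1, alpha[a_idx])[None, :]
        c_term = polygamma(1, a_tot[a_idx]) - polygamma(1, n_tot + a_tot[a_idx])
        w = r[:, a_idx]
        block = np.diag(w @ diag_term) + float(w @ c_term) * np.ones((j_dim, j_dim))
        gw = g[:, a_idx, :] * (w * (1 - w))[:, None]
        block += gw.T @ g[:, a_idx, :]
        h[sl_a, sl_a] += block
        for b_idx in range(a_idx + 1, k):
            sl_b = slice(b_idx * j_dim, (b_idx + 1) * j_dim)
            cross = -(g[:, a_idx, :] * (r[:, a_idx] * r[:, b_idx])[:, None]).T \
                @ g[:, b_idx, :]
            h[sl_a, sl_b] += cross
            h[sl_b, sl_a] += cross.T

    if k > 1:
        # a_il = d log(den_i) / d pi_l for the K-1 free weights
        a_mat = r[:, :-1] / pi[None, :-1] - (r[:, -1] / pi[-1])[:, None]
        sl_p = slice(k * j_dim, d)
        h[sl_p, sl_p] += -(a_mat.T @ a_mat)
        for a_idx in range(k):
            sl_a = slice(a_idx * j_dim, (a_idx + 1) * j_dim)
            for l_idx in range(k - 1):
                dr = -r[:, a_idx] * a_mat[:, l_idx]
                if a_idx == l_idx:
                    dr = dr + r[:, a_idx] / pi[a_idx]
                if a_idx == k - 1:
                    dr = dr - r[:, a_idx] / pi[a_idx]
                col = dr @ g[:, a_idx, :]
                h[sl_a, k * j_dim + l_idx] += col
                h[k * j_dim + l_idx, sl_a] += col
    return -h  # Hessian of the NEGATIVE log-likelihood


#: rate of the weak exponential prior on each Dirichlet parameter. The
#: Dirichlet-Multinomial likelihood tends to a positive constant as alpha
#: grows (the multinomial limit), so a flat prior gives a divergent
#: evidence integral; a diffuse proper prior keeps it finite while
#: leaving the fit essentially untouched.
ALPHA_PRIOR_RATE = 0.1


def laplace_evidence(fit: DMMFit, counts: CountsTable) -> float:
    """Laplace approximation to the negative log model evidence.

    The evidence integrates likelihood times prior over the
    K*J + (K-1) free parameters: independent Exponential(rate 0.1)
    priors on the Dirichlet parameters and a uniform prior on the
    mixture-weight simplex. The Gaussian approximation is taken in
    log-alpha space (substituting alpha = e^lambda, whose Jacobian
    e^{sum lambda} enters the integrand), where the skewed posterior
    of a positive concentration parameter is far closer to normal:

        -log E = -loglik - log prior - sum(log alpha)
                 - (d/2) log(2 pi) + 1/2 log|H| - 1/2 g' H^{-1} g

    with H the Hessian of the negative log integrand in (lambda, pi)
    and g its gradient at the plug-in maximum-likelihood fit (the last
    term corrects for the small offset from the exact posterior mode).
    Flat or negative-curvature directions (redundant components,
    boundary fits) are floored at the prior curvature scale with a
    warning — without the floor a degenerate extra component would
    claim arbitrarily good evidence.
    """
    from scipy.special import gammaln as _gammaln

    x = counts.counts.astype(float)
    h_alpha = _mixture_hessian(x, fit.alpha, fit.pi)
    d = fit.n_free_parameters
    nu = ALPHA_PRIOR_RATE
    n_alpha = fit.k * fit.alpha.shape[1]
    avec = fit.alpha.ravel()

    log_prior = n_alpha * np.log(nu) - nu * float(avec.sum())
    if fit.k > 1:  # uniform density on the (K-1)-simplex is (K-1)!
        log_prior += float(_gammaln(fit.k))
    log_jacobian = float(np.sum(np.log(avec)))

    # chain rule to lambda = log(alpha); mixture-weight block unchanged
    scale = np.ones(d)
    scale[:n_alpha] = avec
    h = h_alpha * np.outer(scale, scale)
    # second chain-rule term: alpha_i * d(-log integrand)/d alpha_i at the
    # plug-in point, where the likelihood gradient vanishes and the prior
    # contributes +nu (the Jacobian term is linear in lambda)
    h[np.arange(n_alpha), np.arange(n_alpha)] += nu * avec
    g = np.zeros(d)
    g[:n_alpha] = 1.0 - nu * avec  # gradient of the log integrand in lambda

    eigvals, eigvecs = np.linalg.eigh((h + h.T) / 2)
    floor = nu ** 2
    if np.any(eigvals < floor):
        warnings.warn("near-singular Hessian in Laplace evidence; "
                      "ridge-stabilized at the prior curvature scale")
    clipped = np.maximum(eigvals, floor)
    logdet = float(np.sum(np.log(clipped)))
    gv = eigvecs.T @ g
    correction = 0.5 * float(np.sum(gv ** 2 / clipped))
    return float(-fit.loglik - log_prior - log_jacobian
                 - 0.5 * d * np.log(2 * np.pi) + 0.5 * logdet - correction)


def select_k(counts: CountsTable, k_max: int = 10, reps: int = 10,
             frac: float = 0.8, seed: int = 0, *, rule: str = "one_se",
             n_restarts: int = 1, max_iter: int = 300) -> KSelection:
    """Choose the number of Dirichlet components by subsampled evidence.

    For each of ``reps`` random subsamples of ``frac`` of the samples,
    models with K = 1..k_max are fit and scored by the Laplace negative
    log evidence. With ``rule='one_se'`` the chosen K is the smallest
    whose mean score is within one standard error (at the argmin) of
    the best mean; ``rule='min_minus_se'`` picks the argmin of
    mean - SEM.
    """
    n = counts.n_samples
    m = int(np.floor(frac * n))
    if m < k_max:
        raise ValueError(f"subsample size {m} smaller than k_max={k_max}")
    rng = np.random.default_rng(seed)
    scores = np.full((reps, k_max), np.nan)
    for rep in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        sub = counts.select_samples([counts.sample_ids[i] for i in idx])
        for k in range(1, k_max + 1):
            try:
                fit = fit_dmm(sub, k, seed=seed + 97 * rep + k,
                              n_restarts=n_restarts, max_iter=max_iter)
                scores[rep, k - 1] = laplace_evidence(fit, sub)
            except Exception as exc:  # noqa: BLE001 - cell marked missing
                warnings.warn(f"select_k rep={rep} K={k} failed: {exc}")
    valid = np.mean(np.isfinite(scores), axis=0) > 0.5
    mean = np.nanmean(np.where(np.isfinite(scores), scores, np.nan), axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(
            np.sum(np.isfinite(scores), axis=0).clip(min=1))
    mean = np.where(valid, mean, np.inf)
    best = int(np.argmin(mean))
    if rule == "one_se":
        cutoff = mean[best] + (sem[best] if np.isfinite(sem[best]) else 0.0)
        chosen = int(np.argmax(mean <= cutoff)) + 1
    elif rule == "min_minus_se":
        adj = np.where(np.isfinite(mean), mean - np.nan_to_num(sem), np.inf)
        chosen = int(np.argmin(adj)) + 1
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return KSelection(
        scores=scores, k_values=np.arange(1, k_max + 1),
        mean=mean, sem=sem, chosen_k=chosen, rule=rule,
    )


def relabel_by_frequency(labels, k: int | None = None
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Renumber CST labels so occurrence counts are non-increasing.

    Ties keep the original fit order. Returns the canonical labels and
    the permutation ``perm`` with ``perm[j] = canonical label of fit
    component j+1`` (1-based).
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if k is None:
        k = int(labels.max())
    counts = np.bincount(labels, minlength=k + 1)[1:]
    order = np.argsort(-counts, kind="stable")  # stable: ties keep fit order
    perm = np.empty(k, dtype=int)
    perm[order] = np.arange(1, k + 1)
    return perm[labels - 1], perm


def assign_cst(fit: DMMFit, counts: CountsTable) -> CSTAssignment:
    """Posterior CST membership and canonical MAP labels for each sample."""
    if fit.otu_ids and list(counts.otu_ids) != list(fit.otu_ids):
        raise ValueError("count table OTUs do not match the fitted model")
    x = counts.counts.astype(float)
    logf = _dm_logpmf_matrix(x, fit.alpha) + np.log(fit.pi)[None, :]
    post = np.exp(logf - logsumexp(logf, axis=1, keepdims=True))
    # MAP with ties broken toward the lowest component index
    map_fit = np.argmax(np.isclose(post, post.max(axis=1, keepdims=True),
                                   rtol=0, atol=1e-12), axis=1) + 1
    canonical, perm = relabel_by_frequency(map_fit, k=fit.k)
    post_canonical = np.empty_like(post)
    post_canonical[:, perm - 1] = post
    return CSTAssignment(
        sample_ids=list(counts.sample_ids),
        posterior=post_canonical,
        map_label=canonical,
        canonical_map=perm,
    )
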