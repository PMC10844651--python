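"""Minimal MCMC machinery for the hierarchical rating models.

Two samplers are provided, both written directly against the model
structure so that no probabilistic-programming runtime is required:

* :func:`sample_gaussian_mixed` — blocked Gibbs for a Gaussian linear mixed
  model with stratified residual SDs (the "distributional" part): fixed
  effects and random intercepts are conditionally conjugate and drawn
  exactly; scale parameters (residual SDs, random-effect SDs) are updated
  by univariate slice sampling on the log scale.
* :func:`sample_bernoulli_logit_mixed` — logistic mixed model: regression
  coefficients by univariate slice sampling with a cached linear predictor,
  random intercepts by a vectorized per-group adaptive Metropolis step
  (scales tuned toward 44% acceptance during warmup), SD by slice.

Priors: Normal(0, prior_sd) on location coefficients, Exponential(rate) on
every SD.  Draws are returned per chain for split-R-hat / ESS diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def slice_sample(logpdf, x0: float, lp0: float, w: float, rng: np.random.Generator,
                 max_steps: int = 50) -> tuple[float, float]:
    """One update of a univariate stepping-out/shrinkage slice sampler.

    Returns the new point and its log density (Neal 2003).  ``w`` is the
    initial bracket width; the bracket is stepped out at most ``max_steps``
    times per side.
    """
    log_u = lp0 + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logpdf(lo) < log_u:
            break
        lo -= w
    for _ in range(max_steps):
        if logpdf(hi) < log_u:
            break
        hi += w
    while True:
        x1 = lo + (hi - lo) * rng.random()
        lp1 = logpdf(x1)
        if lp1 >= log_u:
            return x1, lp1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


@dataclass
class GroupSpec:
    """A random-intercept grouping factor: per-observation level indices."""

    name: str
    index: np.ndarray  # (n_obs,) int level index
    n_levels: int


def _draw_mvn_coefs(X, resid, weights, prior_prec, rng):
    """Exact draw of regression coefficients given everything else."""
    Xw = X * weights[:, None]
    prec = X.T @ Xw + np.diag(prior_prec)
    mean_rhs = Xw.T @ resid
    chol = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, mean_rhs)
    z = rng.standard_normal(X.shape[1])
    return mean + np.linalg.solve(chol.T, z)


def sample_gaussian_mixed(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[GroupSpec],
    sigma_stratum: np.ndarray,
    n_strata: int,
    *,
    prior_sd_beta: np.ndarray,
    prior_rate_sigma: float = 0.1,
    prior_rate_tau: float = 0.1,
    n_warmup: int = 500,
    n_draws: int = 500,
    n_chains: int = 4,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Blocked Gibbs sampler for ``y ~ N(X b + sum_g u_g[idx_g], sigma[stratum])``.

    Returns draws with shape (n_chains, n_draws, ...): ``beta``,
    ``sigma`` (per stratum), ``tau`` (per grouping factor) and one array per
    grouping factor named ``u_<name>``.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    prior_prec = 1.0 / np.asarray(prior_sd_beta, float) ** 2
    strata_masks = [sigma_stratum == s for s in range(n_strata)]
    strata_n = np.array([m.sum() for m in strata_masks], float)

    out: dict[str, list[np.ndarray]] = {
        "beta": [], "sigma": [], "tau": [],
        **{f"u_{g.name}": [] for g in groups},
    }
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        beta = np.zeros(p)
        u = [np.zeros(g.n_levels) for g in groups]
        tau = np.ones(len(groups))
        sigma = np.full(n_strata, max(np.std(y), 1e-3))
        b_draws = np.empty((n_draws, p))
        s_draws = np.empty((n_draws, n_strata))
        t_draws = np.empty((n_draws, len(groups)))
        u_draws = [np.empty((n_draws, g.n_levels)) for g in groups]

        for it in range(n_warmup + n_draws):
            w_obs = 1.0 / sigma[sigma_stratum] ** 2
            ranef = sum(ug[g.index] for ug, g in zip(u, groups)) if groups else 0.0

            beta = _draw_mvn_coefs(X, y - ranef, w_obs, prior_prec, rng)
            fixed = X @ beta

            for gi, g in enumerate(groups):
                others = sum(u[gj][groups[gj].index] for gj in range(len(groups)) if gj != gi)
                r = y - fixed - others
                sw = np.bincount(g.index, weights=w_obs, minlength=g.n_levels)
                srw = np.bincount(g.index, weights=w_obs * r, minlength=g.n_levels)
                post_prec = sw + 1.0 / tau[gi] ** 2
                post_mean = srw / post_prec
                u[gi] = post_mean + rng.standard_normal(g.n_levels) / np.sqrt(post_prec)

                # tau: slice on log scale; Exponential prior + Jacobian
                ssq = float(u[gi] @ u[gi])
                nl = g.n_levels

                def lp_tau(lt, ssq=ssq, nl=nl):
                    t = np.exp(lt)
                    return -nl * lt - 0.5 * ssq / t**2 - prior_rate_tau * t + lt

                lt = np.log(tau[gi])
                lt, _ = slice_sample(lp_tau, lt, lp_tau(lt), 1.0, rng)
                tau[gi] = np.exp(lt)

                # interweaving (ASIS): re-update tau in the non-centered
                # parameterization to break the funnel when tau is near 0
                if tau[gi] > 0 and np.any(u[gi] != 0):
                    u_tilde = u[gi] / tau[gi]
                    ut_obs = u_tilde[g.index]
                    r0 = r  # y - fixed - other groups

                    def lp_tau_nc(lt, r0=r0, ut_obs=ut_obs, w=w_obs):
                        t = np.exp(lt)
                        resid = r0 - t * ut_obs
                        return -0.5 * float(w @ (resid * resid)) - prior_rate_tau * t + lt

                    lt = np.log(tau[gi])
                    lt, _ = slice_sample(lp_tau_nc, lt, lp_tau_nc(lt), 1.0, rng)
                    tau[gi] = np.exp(lt)
                    u[gi] = u_tilde * tau[gi]

            ranef = sum(ug[g.index] for ug, g in zip(u, groups)) if groups else 0.0
            resid = y - fixed - ranef
            for s, mask in enumerate(strata_masks):
                ssq = float(resid[mask] @ resid[mask])
                ns = strata_n[s]

                def lp_sig(ls, ssq=ssq, ns=ns):
                    sg = np.exp(ls)
                    return -ns * ls - 0.5 * ssq / sg**2 - prior_rate_sigma * sg + ls

                ls = np.log(sigma[s])
                ls, _ = slice_sample(lp_sig, ls, lp_sig(ls), 0.5, rng)
                sigma[s] = np.exp(ls)

            if it >= n_warmup:
                k = it - n_warmup
                b_draws[k] = beta
                s_draws[k] = sigma
                t_draws[k] = tau
                for gi in range(len(groups)):
                    u_draws[gi][k] = u[gi]

        out["beta"].append(b_draws)
        out["sigma"].append(s_draws)
        out["tau"].append(t_draws)
        for gi, g in enumerate(groups):
            out[f"u_{g.name}"].append(u_draws[gi])

    return {k: np.stack(v) for k, v in out.items()}


def sample_bernoulli_logit_mixed(
    z: np.ndarray,
    X: np.ndarray,
    group: GroupSpec | None,
    *,
    prior_sd_gamma: np.ndarray,
    prior_rate_tau: float = 0.1,
    n_warmup: int = 500,
    n_draws: int = 500,
    n_chains: int = 4,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """MCMC for ``z ~ Bernoulli(invlogit(X g + w[idx]))``.

    Coefficients are slice-sampled one at a time against a cached linear
    predictor; random intercepts use a vectorized per-level adaptive
    random-walk Metropolis step.
    """
    z = np.asarray(z, float)
    X = np.asarray(X, float)
    n, p = X.shape
    prior_prec = 1.0 / np.asarray(prior_sd_gamma, float) ** 2

    def bern_loglik(eta):
        # sum z*eta - log(1 + exp(eta)), stable
        return float(z @ eta - np.logaddexp(0.0, eta).sum())

    out: dict[str, list[np.ndarray]] = {"gamma": [], "tau": [], "w": []}
    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain, 7]))
        gamma = np.zeros(p)
        w = np.zeros(group.n_levels) if group else np.zeros(0)
        tau = 1.0
        eta = X @ gamma + (w[group.index] if group else 0.0)
        step = np.full(len(w), 0.5)
        g_draws = np.empty((n_draws, p))
        t_draws = np.empty(n_draws)
        w_draws = np.empty((n_draws, len(w)))

        if group is not None:
            # per-level log-likelihood pieces, vectorized with bincount
            idx = group.index
            nl = group.n_levels

        for it in range(n_warmup + n_draws):
            for j in range(p):
                xj = X[:, j]
                base = eta - xj * gamma[j]

                def lp(gj, xj=xj, base=base, j=j):
                    e = base + xj * gj
                    return (z @ e - np.logaddexp(0.0, e).sum()) - 0.5 * prior_prec[j] * gj * gj

                gamma[j], _ = slice_sample(lp, gamma[j], lp(gamma[j]), 1.0, rng)
                eta = base + xj * gamma[j]

            if group is not None:
                for _ in range(5):  # extra sweeps sharpen tau mixing
                    prop = w + step * rng.standard_normal(nl)
                    eta_prop = eta + (prop - w)[idx]
                    ll_cur = np.bincount(idx, weights=z * eta - np.logaddexp(0.0, eta), minlength=nl)
                    ll_prop = np.bincount(idx, weights=z * eta_prop - np.logaddexp(0.0, eta_prop), minlength=nl)
                    lr = (ll_prop - ll_cur) - 0.5 * (prop**2 - w**2) / tau**2
                    accept = np.log(rng.random(nl)) < lr
                    w = np.where(accept, prop, w)
                    eta = X @ gamma + w[idx]
                    if it < n_warmup:
                        step *= np.exp(np.where(accept, 0.03, -0.0236))
                        step = np.clip(step, 1e-3, 10.0)

                ssq = float(w @ w)

                def lp_tau(lt, ssq=ssq, nl=nl):
                    t = np.exp(lt)
                    return -nl * lt - 0.5 * ssq / t**2 - prior_rate_tau * t + lt

                lt = np.log(tau)
                lt, _ = slice_sample(lp_tau, lt, lp_tau(lt), 1.0, rng)
                tau = np.exp(lt)

                # interweaving (ASIS) on the non-centered scale
                if tau > 0 and np.any(w != 0):
                    w_tilde = w / tau
                    wt_obs = w_tilde[idx]
                    base = X @ gamma

                    def lp_tau_nc(lt, base=base, wt_obs=wt_obs):
                        e = base + np.exp(lt) * wt_obs
                        return (z @ e - np.logaddexp(0.0, e).sum()) - prior_rate_tau * np.exp(lt) + lt

                    lt = np.log(tau)
                    lt, _ = slice_sample(lp_tau_nc, lt, lp_tau_nc(lt), 1.0, rng)
                    tau = np.exp(lt)
                    w = w_tilde * tau
                    eta = base + w[idx]

            if it >= n_warmup:
                k = it - n_warmup
                g_draws[k] = gamma
                t_draws[k] = tau
                w_draws[k] = w

        out["gamma"].append(g_draws)
        out["tau"].append(t_draws)
        out["w"].append(w_draws)

    return {k: np.stack(v) for k, v in out.items()}
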