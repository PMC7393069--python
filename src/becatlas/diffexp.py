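"""Zero-inflated negative binomial (ZINB) differential expression.

Each gene is modelled as a negative binomial with gene-wise dispersion theta
and a gene-wise structural-zero (dropout) probability pi shared across
groups; size factors enter as exposure offsets.  The one-vs-rest test
compares a null fit with a single mean against an alternative with one extra
group mean, by likelihood-ratio test on one degree of freedom.

Fitting is by generalized EM, vectorized across genes: the E-step assigns
each observed zero a posterior probability of being structural; the M-step
takes damped Newton steps on the group log-means and log-dispersion and
updates pi in closed form.  Step halving on the EM surrogate keeps the
observed log-likelihood non-decreasing at every iteration.  Genes whose
observed zero fraction does not exceed the NB-implied zero fraction fall
back to a plain NB fit (pi = 0), which is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import BecatlasError, get_logger

log = get_logger("diffexp")

__all__ = [
    "ZinbFit",
    "DEResult",
    "zinb_fit",
    "de_all",
    "signatures",
    "rule_of_three_ci",
]

MAX_ITER = 100
LL_TOL = 1e-5
_M_FLOOR = 1e-10
_THETA_BOUNDS = (1e-3, 1e4)
ALPHA = 0.001
TOP_N = 50


# ---------------------------------------------------------------------------
# vectorized ZINB core (genes in parallel)
# ---------------------------------------------------------------------------


@dataclass
class _FitState:
    """Per-gene parameter arrays for a (possibly grouped) ZINB fit."""

    log_m: np.ndarray  # genes x n_groups
    log_theta: np.ndarray  # genes
    pi: np.ndarray  # genes; fixed at 0 for NB-only genes
    use_zinb: np.ndarray  # genes, bool
    loglik: np.ndarray  # genes
    converged: np.ndarray  # genes, bool
    trace: list = field(default_factory=list)  # total loglik per iteration


def _nb_logpmf(y, mu, theta):
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def _loglik(Y, mu, theta, pi, lgam=None):
    """Observed ZINB log-likelihood per gene (rows).

    ``lgam`` optionally carries the precomputed mu-independent term
    gammaln(y+theta) - gammaln(theta) - gammaln(y+1) (valid while theta is
    held fixed), which removes the gammaln cost from inner loops.
    """
    theta = theta[:, None]
    pi = pi[:, None]
    p0 = np.exp(theta * np.log(theta / (theta + mu)))
    zero = Y == 0
    ll_zero = np.log(pi + (1.0 - pi) * p0)
    if lgam is None:
        lgam = (
            special.gammaln(Y + theta)
            - special.gammaln(theta)
            - special.gammaln(np.maximum(Y, 1) + 1)
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_pos = (
            np.log1p(-pi)
            + lgam
            + theta * np.log(theta / (theta + mu))
            + Y * np.log(np.maximum(mu, 1e-300) / (theta + mu))
        )
    return np.where(zero, ll_zero, ll_pos).sum(axis=1)


def _lgam_term(Y, theta):
    """The mu-independent part of the NB log-pmf, per observation."""
    th = theta[:, None]
    return (
        special.gammaln(Y + th)
        - special.gammaln(th)
        - special.gammaln(np.maximum(Y, 1) + 1)
    )


def _fit_means(
    Y: np.ndarray,
    sf: np.ndarray,
    group: np.ndarray,
    log_theta: np.ndarray,
    pi: np.ndarray,
    init_log_m: np.ndarray,
    max_iter: int = MAX_ITER,
):
    """Group-mean-only ZINB fit with dispersion and dropout held fixed.

    Used for the alternative model of the one-vs-rest test: theta and pi are
    the null estimates (shared across groups), and only the two group
    log-means are optimized, by the same EM/Newton scheme with step halving.
    Returns (log_m, loglik, converged, trace).
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    gidx = np.asarray(group, dtype=int)
    theta = np.exp(log_theta)
    lgam = _lgam_term(Y, theta)
    cols = [np.flatnonzero(gidx == g) for g in range(2)]
    log_m = init_log_m.copy()
    zero_mask = Y == 0
    all_zero = zero_mask.all(axis=1)
    ll = _loglik(Y, np.exp(log_m[:, gidx]) * sf[None, :], theta, pi, lgam)
    trace = [ll.copy()]
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        act = np.flatnonzero(~converged & ~all_zero)
        if len(act) == 0:
            break
        th = theta[act][:, None]
        pia = pi[act][:, None]
        lm = log_m[act]
        mu = np.exp(lm[:, gidx]) * sf[None, :]
        p0 = np.exp(th * np.log(th / (th + mu)))
        w = np.where(zero_mask[act], pia / np.maximum(pia + (1 - pia) * p0, 1e-300), 0.0)
        v = 1.0 - w
        new_lm = lm.copy()
        for g in (0, 1):
            yg, vg, sfg = Y[np.ix_(act, cols[g])], v[:, cols[g]], sf[cols[g]]
            for _inner in range(2):
                mug = np.exp(new_lm[:, [g]]) * sfg[None, :]
                grad = (vg * (yg - mug) * th / (th + mug)).sum(1)
                curv = -(vg * th * mug * (th + yg) / (th + mug) ** 2).sum(1)
                step = np.where(curv < -1e-12, -grad / curv, 0.0)
                new_lm[:, g] = new_lm[:, g] + np.clip(step, -2.0, 2.0)
        old_ll = ll[act]
        for _half in range(8):
            ll_c = _loglik(Y[act], np.exp(new_lm[:, gidx]) * sf[None, :],
                           theta[act], pi[act], lgam[act])
            worse = ll_c < old_ll - 1e-9
            if not worse.any():
                break
            new_lm[worse] = (new_lm[worse] + lm[worse]) / 2
        ll_c = _loglik(Y[act], np.exp(new_lm[:, gidx]) * sf[None, :],
                       theta[act], pi[act], lgam[act])
        still_worse = ll_c < old_ll - 1e-9
        new_lm[still_worse] = lm[still_worse]
        ll_c = np.where(still_worse, old_ll, ll_c)
        log_m[act] = new_lm
        ll[act] = ll_c
        newly = (np.abs(ll_c - old_ll) < LL_TOL) | still_worse
        converged[act[newly]] = True
        trace.append(ll.copy())
    converged = converged | all_zero
    return log_m, ll, converged, trace


def _mu_from(state: _FitState, sf: np.ndarray, group: np.ndarray | None):
    m = np.exp(state.log_m)
    if group is None or state.log_m.shape[1] == 1:
        return m[:, [0]] * sf[None, :]
    return m[:, group] * sf[None, :]


def _fit_many(
    Y: np.ndarray,
    sf: np.ndarray,
    group: np.ndarray | None,
    force_nb: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    polish: bool = True,
) -> _FitState:
    """Fit every row of Y; ``group`` (0/1 per cell) adds a second mean.

    ``force_nb`` pins pi = 0 for the flagged genes (the NB fallback); when
    None, the fallback rule is decided here from a moment comparison of the
    observed and NB-implied zero fractions.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    sf = np.asarray(sf, dtype=float)
    n_groups = 1 if group is None else 2
    gidx = None if group is None else np.asarray(group, dtype=int)

    # moment initialization on size-factor-scaled counts
    log_m = np.empty((G, n_groups))
    for g in range(n_groups):
        cols = slice(None) if gidx is None else np.flatnonzero(gidx == g)
        ysub = Y[:, cols]
        sfsub = sf[cols]
        log_m[:, g] = np.log(np.maximum(ysub.sum(axis=1) / sfsub.sum(), _M_FLOOR))
    scaled = Y / sf[None, :]
    mbar = scaled.mean(axis=1)
    var = scaled.var(axis=1)
    theta0 = np.where(var > mbar, mbar**2 / np.maximum(var - mbar, 1e-8), 50.0)
    log_theta = np.log(np.clip(theta0, *_THETA_BOUNDS))

    if force_nb is None:
        mu0 = np.exp(log_m[:, [0]] if gidx is None else log_m[:, gidx]) * sf[None, :]
        p0 = np.exp(np.exp(log_theta)[:, None] * np.log(
            np.exp(log_theta)[:, None] / (np.exp(log_theta)[:, None] + mu0)))
        implied_zero = p0.mean(axis=1)
        observed_zero = (Y == 0).mean(axis=1)
        force_nb = observed_zero <= implied_zero + 1e-12
        if force_nb.any():
            log.info("zinb: %d/%d gene(s) fall back to NB (no excess zeros)",
                     int(force_nb.sum()), G)
    use_zinb = ~np.asarray(force_nb, dtype=bool)
    pi = np.where(use_zinb, 0.05, 0.0)

    state = _FitState(log_m, log_theta, pi, use_zinb,
                      np.full(G, -np.inf), np.zeros(G, dtype=bool))
    zero_mask = Y == 0
    all_zero = zero_mask.all(axis=1)

    mu = _mu_from(state, sf, gidx)
    state.loglik = _loglik(Y, mu, np.exp(state.log_theta), state.pi)
    state.trace.append(state.loglik.copy())

    group_cols = (
        [slice(None)] if gidx is None
        else [np.flatnonzero(gidx == g) for g in range(n_groups)]
    )
    for _ in range(max_iter):
        act = np.flatnonzero(~state.converged & ~all_zero)
        if len(act) == 0:
            break
        # work on the active gene subset only
        Ya = Y[act]
        za = zero_mask[act]
        theta = np.exp(state.log_theta[act])
        lm = state.log_m[act]
        pi = state.pi[act]
        mu = np.exp(lm[:, [0]] if gidx is None else lm[:, gidx]) * sf[None, :]
        th = theta[:, None]
        # E-step: posterior structural-zero weight for observed zeros
        p0 = np.exp(th * np.log(th / (th + mu)))
        w = np.where(
            za,
            pi[:, None] / np.maximum(pi[:, None] + (1 - pi[:, None]) * p0,
                                     1e-300),
            0.0,
        )
        v = 1.0 - w  # weight of the NB component per observation

        # M-step 1: pi in closed form
        new_pi = np.where(state.use_zinb[act], w.mean(axis=1), 0.0)
        new_pi = np.clip(new_pi, 0.0, 1.0 - 1e-9)

        # M-step 2: damped Newton on each group log-mean (two inner steps)
        new_lm = lm.copy()
        for g, cols in enumerate(group_cols):
            yg, vg, sfg = Ya[:, cols], v[:, cols], sf[cols]
            for _inner in range(2):
                mug = np.exp(new_lm[:, [g]]) * sfg[None, :]
                grad = (vg * (yg - mug) * th / (th + mug)).sum(1)
                curv = -(vg * th * mug * (th + yg) / (th + mug) ** 2).sum(1)
                step = np.where(curv < -1e-12, -grad / curv, 0.0)
                new_lm[:, g] = new_lm[:, g] + np.clip(step, -2.0, 2.0)

        # M-step 3: damped Newton on log-dispersion (secant curvature)
        mu2 = np.exp(new_lm[:, [0]] if gidx is None else new_lm[:, gidx]) \
            * sf[None, :]
        dtheta = (
            special.digamma(Ya + th) - special.digamma(th)
            + np.log(th / (th + mu2)) + 1.0 - (Ya + th) / (th + mu2)
        )
        grad_t = (v * dtheta).sum(axis=1) * theta  # d/d log theta
        eps = 1e-4
        th_e = th * np.exp(eps)
        dtheta_e = (
            special.digamma(Ya + th_e) - special.digamma(th_e)
            + np.log(th_e / (th_e + mu2)) + 1.0 - (Ya + th_e) / (th_e + mu2)
        )
        grad_t_e = (v * dtheta_e).sum(axis=1) * theta * np.exp(eps)
        curv_t = (grad_t_e - grad_t) / eps
        step_t = np.where(curv_t < -1e-12, -grad_t / curv_t,
                          np.sign(grad_t) * 0.1)
        new_lt = np.clip(
            state.log_theta[act] + np.clip(step_t, -1.0, 1.0),
            np.log(_THETA_BOUNDS[0]), np.log(_THETA_BOUNDS[1]),
        )

        # accept with per-gene step halving on the observed log-likelihood
        old_ll = state.loglik[act]
        for _half in range(8):
            mu_c = np.exp(new_lm[:, [0]] if gidx is None
                          else new_lm[:, gidx]) * sf[None, :]
            ll_c = _loglik(Ya, mu_c, np.exp(new_lt), new_pi)
            worse = ll_c < old_ll - 1e-9
            if not worse.any():
                break
            new_lm[worse] = (new_lm[worse] + lm[worse]) / 2
            new_lt[worse] = (new_lt[worse] + state.log_theta[act][worse]) / 2
            new_pi[worse] = (new_pi[worse] + pi[worse]) / 2
        mu_c = np.exp(new_lm[:, [0]] if gidx is None else new_lm[:, gidx]) \
            * sf[None, :]
        ll_c = _loglik(Ya, mu_c, np.exp(new_lt), new_pi)
        still_worse = ll_c < old_ll - 1e-9
        # genes that cannot improve keep their old parameters and stop
        new_lm[still_worse] = lm[still_worse]
        new_lt[still_worse] = state.log_theta[act][still_worse]
        new_pi[still_worse] = pi[still_worse]
        ll_c = np.where(still_worse, old_ll, ll_c)
        state.log_m[act] = new_lm
        state.log_theta[act] = new_lt
        state.pi[act] = new_pi
        state.loglik[act] = ll_c
        newly = (np.abs(ll_c - old_ll) < LL_TOL) | still_worse
        state.converged[act[newly]] = True
        state.trace.append(state.loglik.copy())

    state.converged = state.converged | all_zero
    if polish:
        _polish(Y, sf, gidx, state, all_zero)
    # genes that used all iterations without meeting the tolerance are flagged
    return state


def _polish(Y, sf, gidx, state: _FitState, all_zero: np.ndarray) -> None:
    """Quasi-Newton finish for genes the EM left unconverged.

    EM on the ZINB dropout/dispersion ridge can take thousands of
    iterations; the handful of genes still open after the EM budget are
    completed per gene by L-BFGS-B from the current parameters.  The
    objective is the same observed log-likelihood, so the ascent stays
    monotone.
    """
    from scipy.optimize import minimize

    open_genes = np.flatnonzero(~state.converged & ~all_zero)
    if len(open_genes) == 0:
        return
    n_groups = state.log_m.shape[1]
    lo_t, hi_t = np.log(_THETA_BOUNDS[0]), np.log(_THETA_BOUNDS[1])
    for g in open_genes:
        y = Y[[g]]
        zinb = bool(state.use_zinb[g])

        def nll(x):
            lm = x[:n_groups]
            lt = x[n_groups]
            pi = 1.0 / (1.0 + np.exp(-x[n_groups + 1])) if zinb else 0.0
            mu = np.exp(lm[[0]] if gidx is None else lm[gidx])[None, :] \
                * sf[None, :]
            return -_loglik(y, mu, np.exp([lt]), np.array([pi]))[0]

        pi0 = np.clip(state.pi[g], 1e-6, 1 - 1e-6)
        x0 = np.concatenate(
            [state.log_m[g], [state.log_theta[g]], [np.log(pi0 / (1 - pi0))]]
        )
        bounds = [(-30.0, 30.0)] * n_groups + [(lo_t, hi_t), (-13.0, 13.0)]
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if -res.fun >= state.loglik[g] - 1e-9:
            state.log_m[g] = res.x[:n_groups]
            state.log_theta[g] = res.x[n_groups]
            state.pi[g] = (
                1.0 / (1.0 + np.exp(-res.x[n_groups + 1])) if zinb else 0.0
            )
            state.loglik[g] = -res.fun
            state.converged[g] = True
    still = int((~state.converged & ~all_zero).sum())
    log.info("zinb polish: %d gene(s) finished by quasi-Newton, %d still open",
             len(open_genes) - still, still)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass
class ZinbFit:
    """Null and alternative fits plus the likelihood-ratio test, one gene."""

    null_log_mean: float
    alt_log_means: tuple
    log_theta: float
    pi: float
    used_zinb: bool
    lrt_stat: float
    p: float
    converged: bool
    loglik_trace_null: np.ndarray
    loglik_trace_alt: np.ndarray


def zinb_fit(y: np.ndarray, size_factors: np.ndarray, group: np.ndarray) -> ZinbFit:
    """Fit one gene's counts under shared-mean and group-mean models.

    ``group`` is a 0/1 indicator (1 = subset of interest).  Both groups must
    have at least 3 cells.  Non-convergence yields ``p = nan`` with
    ``converged = False``.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group, dtype=int)
    if min((group == 0).sum(), (group == 1).sum()) < 3:
        raise BecatlasError("each group needs at least 3 cells")
    Y = y[None, :]
    if np.all(y == 0):
        return ZinbFit(np.log(_M_FLOOR), (np.log(_M_FLOOR),) * 2, 0.0, 0.0,
                       False, 0.0, 1.0, True,
                       np.zeros(1), np.zeros(1))
    sf = np.asarray(size_factors, dtype=float)
    null = _fit_many(Y, sf, None)
    # alternative: group means only, starting from the null mean so the
    # ascent (and hence the LRT statistic) is non-negative by construction
    init = np.repeat(null.log_m[:, [0]], 2, axis=1)
    alt_lm, alt_ll, alt_conv, alt_trace = _fit_means(
        Y, sf, group, null.log_theta, null.pi, init)
    stat = float(max(2.0 * (alt_ll[0] - null.loglik[0]), 0.0))
    conv = bool(null.converged[0] and alt_conv[0])
    p = float(stats.chi2.sf(stat, df=1)) if conv else float("nan")
    return ZinbFit(
        float(null.log_m[0, 0]),
        tuple(alt_lm[0]),
        float(null.log_theta[0]),
        float(null.pi[0]),
        bool(null.use_zinb[0]),
        stat,
        p,
        conv,
        np.array([t[0] for t in null.trace]),
        np.array([t[0] for t in alt_trace]),
    )


@dataclass
class DEResult:
    """One-vs-rest ZINB test results for every (gene, subset) pair."""

    table: pd.DataFrame
    alpha: float


def de_all(counts, size_factors: np.ndarray, labels: pd.Series,
           alpha: float = ALPHA, genes=None) -> DEResult:
    """ZINB one-vs-rest LRT for every gene in every subset.

    ``counts`` is a CountMatrix; ``size_factors`` come from normalization
    and enter as exposure offsets.  BH adjustment is applied jointly across
    all gene x subset tests.  The specificity score of (gene, subset) is the
    gene's log-mean in the subset minus the log of the maximum of all other
    subsets' means.
    """
    labels = pd.Series(labels).reindex(counts.cell_ids)
    subsets = sorted(labels.dropna().unique())
    usable = [s for s in subsets if (labels == s).sum() >= 3]
    for s in subsets:
        if s not in usable:
            log.warning("de_all: subset %s has <3 cells, skipped", s)
    if len(usable) < 2:
        raise BecatlasError("de_all needs at least 2 usable subsets")
    gene_mask = (
        np.ones(counts.n_genes, dtype=bool)
        if genes is None
        else np.isin(counts.gene_ids, list(genes))
    )
    Y = np.asarray(counts.X[gene_mask].todense(), dtype=float)
    gene_ids = counts.gene_ids[gene_mask]
    sf = np.asarray(size_factors, dtype=float)

    # the null (nuisance) fit is shared by all subset tests; quasi-Newton
    # polish completes any gene the EM budget leaves open
    null = _fit_many(Y, sf, None, max_iter=150)
    init = np.repeat(null.log_m[:, [0]], 2, axis=1)
    all_zero = (Y == 0).all(axis=1)
    recs = []
    subset_log_means = {}
    for s in usable:
        z = (labels == s).to_numpy().astype(int)
        alt_lm, alt_ll, alt_conv, _ = _fit_means(
            Y, sf, z, null.log_theta, null.pi, init)
        stat = np.maximum(2.0 * (alt_ll - null.loglik), 0.0)
        conv = null.converged & alt_conv
        p = np.where(conv, stats.chi2.sf(stat, df=1), np.nan)
        lfc = alt_lm[:, 1] - alt_lm[:, 0]
        stat[all_zero] = 0.0
        p[all_zero] = 1.0
        subset_log_means[s] = alt_lm[:, 1]
        recs.append(pd.DataFrame({
            "gene": gene_ids, "subset": s, "lfc": lfc, "lrt": stat, "p": p,
            "converged": conv | all_zero,
        }))
        log.info("de_all: subset %s fitted (%d genes)", s, len(gene_ids))
    tab = pd.concat(recs, ignore_index=True)
    mean_mat = np.column_stack([subset_log_means[s] for s in usable])
    spec = {}
    for j, s in enumerate(usable):
        others = np.delete(mean_mat, j, axis=1)
        spec[s] = mean_mat[:, j] - others.max(axis=1)
    tab["specificity"] = np.concatenate([spec[s] for s in usable])
    ok = tab["p"].notna()
    p_adj = np.full(len(tab), np.nan)
    _, p_adj[ok.to_numpy()], _, _ = multipletests(tab.loc[ok, "p"],
                                                  method="fdr_bh")
    tab["p_adj"] = p_adj
    tab["significant"] = tab["p_adj"] < alpha
    return DEResult(tab, alpha)


@dataclass
class SignatureTable:
    signatures: dict  # subset -> ordered gene list


def signatures(de: DEResult, n: int = TOP_N) -> SignatureTable:
    """Per-subset top-n differentially *and* specifically expressed genes:
    significant, positive fold change, positive specificity, ordered by
    specificity score."""
    out = {}
    for s, sub in de.table.groupby("subset"):
        good = sub[(sub["significant"]) & (sub["lfc"] > 0)
                   & (sub["specificity"] > 0)]
        good = good.sort_values(["specificity", "gene"],
                                ascending=[False, True])
        out[s] = good["gene"].head(n).tolist()
    return SignatureTable(out)


def rule_of_three_ci(events: int, n: int):
    """Upper 95% confidence bound for a proportion with zero observed events.

    With 0 events in n trials the bound is 3/n (lower bound 0).  For any
    non-zero event count an exact binomial interval is required instead.
    """
    if n < 1:
        raise BecatlasError("n must be at least 1")
    if events != 0:
        raise BecatlasError(
            "rule of three applies only to zero events; use an exact "
            "binomial interval"
        )
    return 0.0, min(3.0 / n, 1.0)
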