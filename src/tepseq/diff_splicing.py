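"""Negative-binomial differential-splicing analysis.

Per-gene counts are modeled as NB(mean mu, dispersion phi) with
``var = mu + phi * mu**2`` and a log link, ``log mu = X beta + offset``
where the offset is the log effective library size.  Differential splicing
between two clinical groups is tested with a likelihood-ratio test of the
group coefficient (chi-square, 1 df), after estimating common, trended and
tagwise dispersions:

* **common** -- one phi maximizing the profile likelihood summed over genes;
* **trend** -- a local (lowess) regression of per-gene dispersion against
  average logCPM;
* **tagwise** -- per-gene estimates shrunk toward the trend on the log
  scale with a fixed prior weight (empirical-Bayes moderation).

Multiple testing is controlled with Benjamini-Hochberg FDR; genes below
3 logCPM are dropped from result lists, and FDR < 0.01 is the default
significance bar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

_MIN_PHI = 1e-6
_MAX_PHI = 20.0


# ---------------------------------------------------------------------------
# Vectorized NB GLM (shared design across genes)
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; Poisson limit for phi ~ 0.

    ``y`` and ``mu`` are genes x samples, ``phi`` is per-gene (or scalar).
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],))
    out = np.empty(y.shape[0])
    tiny = phi < 1e-8
    if tiny.any():
        yt, mt = y[tiny], mu[tiny]
        out[tiny] = (yt * np.log(mt) - mt - gammaln(yt + 1.0)).sum(axis=1)
    if (~tiny).any():
        yn, mn = y[~tiny], mu[~tiny]
        r = (1.0 / phi[~tiny])[:, None]
        out[~tiny] = (
            gammaln(yn + r)
            - gammaln(r)
            - gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        ).sum(axis=1)
    return out


def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offsets: np.ndarray,
    phi: np.ndarray | float,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of an NB GLM with a design shared by all genes.

    ``Y`` is genes x samples, ``X`` samples x p, ``offsets`` log effective
    library sizes.  Returns (beta, loglik, converged) with beta genes x p.
    The iteration is vectorized over genes: each step solves one small
    weighted least-squares system per gene via batched linear solves.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()

    eta0 = np.log(Y + 0.5) - offsets  # working response at start
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ eta0.T).T  # genes x p

    converged = np.zeros(G, dtype=bool)
    ll_old = np.full(G, -np.inf)
    ridge = 1e-8 * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T + offsets, -50.0, 50.0)
        mu = np.exp(eta)
        ll = nb_loglik(Y, mu, phi_vec)
        done = np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
        converged |= done
        if converged.all():
            break
        ll_old = ll
        W = mu / (1.0 + phi_vec[:, None] * mu)
        z = (eta - offsets) + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + ridge
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(XtWX, XtWz)]
            )
        bad = ~np.isfinite(beta_new).all(axis=1)
        beta_new[bad] = beta[bad]
        beta = beta_new
    eta = np.clip(beta @ X.T + offsets, -50.0, 50.0)
    ll = nb_loglik(Y, np.exp(eta), phi_vec)
    converged |= np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
    return beta, ll, converged


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionModel:
    """Common / trended / tagwise NB dispersions for one dataset."""

    common: float
    trend_x: np.ndarray  # average logCPM knots (sorted)
    trend_y: np.ndarray  # trended dispersion at the knots
    tagwise: pd.Series  # per-gene moderated dispersion
    ave_logcpm: pd.Series
    prior_weight: float

    def trend(self, ave_logcpm: np.ndarray | float) -> np.ndarray:
        """Trended dispersion at the given average abundance."""
        return np.interp(ave_logcpm, self.trend_x, self.trend_y)


def average_logcpm(Y: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Per-gene average abundance on the log2 CPM scale."""
    lib = np.exp(offsets)
    return np.log2(((Y + 0.5) / (lib + 1.0)).mean(axis=1) * 1e6)


def _profile_ll(Y, X, offsets, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene.

    The adjustment ``-0.5 log det(X' W X)`` accounts for the degrees of
    freedom spent estimating the per-gene coefficients; without it the
    dispersion maximizer is biased downward and downstream tests run
    liberal.
    """
    beta, ll, _ = fit_nb_glm(Y, X, offsets, phi)
    eta = np.clip(beta @ X.T + offsets, -50.0, 50.0)
    mu = np.exp(eta)
    phi_vec = np.broadcast_to(np.asarray(phi, dtype=float), (Y.shape[0],))
    W = mu / (1.0 + phi_vec[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    sign, logdet = np.linalg.slogdet(XtWX)
    return ll - 0.5 * np.where(sign > 0, logdet, 0.0)


def estimate_common_dispersion(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray
) -> float:
    """Single dispersion maximizing the profile likelihood summed over genes."""
    from scipy.optimize import minimize_scalar

    def neg(log_phi: float) -> float:
        return -float(_profile_ll(Y, X, offsets, np.exp(log_phi)).sum())

    res = minimize_scalar(
        neg,
        bounds=(np.log(_MIN_PHI), np.log(_MAX_PHI)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def estimate_dispersions(
    counts: pd.DataFrame,
    group: pd.Series,
    offsets: pd.Series,
    prior_weight: float = 10.0,
    n_grid: int = 15,
) -> DispersionModel:
    """Common, trended, and tagwise dispersions for a two-group design.

    Per-gene profile likelihoods are evaluated on a log-spaced phi grid
    (betas re-fit at every grid point), the per-gene maximizer feeds a
    lowess trend against average logCPM, and tagwise values shrink the
    per-gene estimate toward the trend on the log scale:
    ``log phi_tag = (n * log phi_g + w * log phi_trend) / (n + w)`` with
    ``n`` the residual degrees of freedom and ``w`` the fixed prior weight
    (an infinite prior collapses tagwise onto the trend).
    """
    X, _ = _design(group)
    keep = counts.sum(axis=1) > 0
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} all-zero genes excluded from dispersion "
            "estimation"
        )
    Y = counts.loc[keep].to_numpy(dtype=float)
    off = np.log(offsets.loc[counts.columns].to_numpy(dtype=float))

    common = estimate_common_dispersion(Y, X, off)

    grid = np.exp(
        np.linspace(np.log(_MIN_PHI * 10), np.log(_MAX_PHI / 2), n_grid)
    )
    ll_grid = np.stack([_profile_ll(Y, X, off, g) for g in grid], axis=1)
    best = ll_grid.argmax(axis=1)
    phi_gene = grid[best]

    ave = average_logcpm(Y, off)
    order = np.argsort(ave)
    sm = lowess(
        np.log(phi_gene)[order], ave[order], frac=0.5, it=1, return_sorted=False
    )
    trend_x, trend_y = ave[order], np.exp(sm)
    # enforce a usable interpolation table (strictly increasing x)
    ux, ui = np.unique(trend_x, return_index=True)
    trend_x, trend_y = ux, trend_y[ui]
    trend_at_gene = np.interp(ave, trend_x, trend_y)

    df_resid = max(Y.shape[1] - X.shape[1], 1)
    log_tag = (
        df_resid * np.log(phi_gene) + prior_weight * np.log(trend_at_gene)
    ) / (df_resid + prior_weight)
    phi_tag = np.clip(np.exp(log_tag), _MIN_PHI, _MAX_PHI)

    tagwise = pd.Series(common, index=counts.index, dtype=float)
    tagwise.loc[keep] = phi_tag
    ave_all = pd.Series(np.nan, index=counts.index, dtype=float)
    ave_all.loc[keep] = ave
    return DispersionModel(
        common=common,
        trend_x=trend_x,
        trend_y=trend_y,
        tagwise=tagwise,
        ave_logcpm=ave_all,
        prior_weight=prior_weight,
    )


# ---------------------------------------------------------------------------
# LRT
# ---------------------------------------------------------------------------


def _design(group: pd.Series, ref_level=None) -> tuple[np.ndarray, list]:
    # levels sorted lexicographically (factor convention) unless a
    # reference level is named: logFC reports the second level against
    # the first, so swapping the labels negates logFC while leaving LR
    # and p untouched
    levels = sorted(pd.unique(group.dropna()))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    if ref_level is not None:
        if ref_level not in levels:
            raise ValueError(f"ref_level {ref_level!r} not among {levels}")
        levels = [ref_level] + [l for l in levels if l != ref_level]
    x = (group == levels[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(group)), x])
    return X, levels


def glm_lrt(
    counts: pd.DataFrame,
    group: pd.Series,
    offsets: pd.Series,
    dispersion: DispersionModel | float,
    ref_level=None,
) -> pd.DataFrame:
    """Likelihood-ratio test of the group coefficient, gene by gene.

    Fits the NB GLM under the full design (intercept + group) and the
    reduced design (intercept only); ``LR = 2 (ll_full - ll_reduced)`` is
    referred to chi-square with one degree of freedom.  ``logFC`` is the
    group-2-vs-group-1 coefficient on the log2 scale.  Non-convergent fits
    are flagged, get ``p = NaN``, and are excluded from the BH-FDR
    denominator.
    """
    group = group.loc[counts.columns]
    X_full, levels = _design(group, ref_level)
    X_red = X_full[:, :1]
    Y = counts.to_numpy(dtype=float)
    off = np.log(offsets.loc[counts.columns].to_numpy(dtype=float))
    phi = (
        dispersion.tagwise.loc[counts.index].to_numpy()
        if isinstance(dispersion, DispersionModel)
        else float(dispersion)
    )
    beta_f, ll_f, conv_f = fit_nb_glm(Y, X_full, off, phi)
    _, ll_r, conv_r = fit_nb_glm(Y, X_red, off, phi)
    LR = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    ok = conv_f & conv_r & np.isfinite(LR)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} genes failed to converge; reported with p=NaN"
        )
    p = np.where(ok, stats.chi2.sf(LR, df=1), np.nan)
    table = pd.DataFrame(
        {
            "logFC": beta_f[:, 1] / np.log(2.0),
            "logCPM": average_logcpm(Y, off),
            "LR": LR,
            "p": p,
            "converged": ok,
        },
        index=counts.index,
    )
    table["FDR"] = np.nan
    table.loc[ok, "FDR"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table.attrs["levels"] = levels
    return table


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-equivariant)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def filter_results(
    table: pd.DataFrame, min_logcpm: float = 3.0, max_fdr: float = 0.01
) -> pd.DataFrame:
    """Keep abundant significant genes; record up/down counts in ``attrs``.

    A gene survives with ``logCPM >= min_logcpm`` and ``FDR < max_fdr``.
    """
    keep = (table["logCPM"] >= min_logcpm) & (table["FDR"] < max_fdr)
    out = table.loc[keep.fillna(False)]
    out.attrs["n_up"] = int((out["logFC"] > 0).sum())
    out.attrs["n_down"] = int((out["logFC"] < 0).sum())
    return out


def cluster_and_partition_test(
    log_mat: pd.DataFrame, group: pd.Series, n_clusters: int = 2
) -> tuple[np.ndarray, pd.Series, float]:
    """Ward clustering on 1 - Pearson distances, with a Fisher exact test.

    Samples are clustered on the selected genes' logCPM, cut into
    ``n_clusters``, and the cluster-by-group 2x2 table tested for
    non-random partitioning (two-sided Fisher's exact test).
    """
    group = group.loc[log_mat.columns]
    if group.value_counts().min() < 2:
        raise ValueError("need >= 2 samples per group for the partition test")
    corr = np.corrcoef(log_mat.to_numpy().T)
    dist = 1.0 - corr
    iu = np.triu_indices_from(dist, k=1)
    Z = linkage(dist[iu], method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    assign = pd.Series(labels, index=log_mat.columns)
    tab = pd.crosstab(assign, group)
    if tab.shape != (2, 2):
        warnings.warn("degenerate clustering (empty cluster); p set to 1")
        return Z, assign, 1.0
    _, p = stats.fisher_exact(tab.to_numpy(), alternative="two-sided")
    return Z, assign, float(p)


def differential_splicing(
    counts: pd.DataFrame,
    group: pd.Series,
    offsets: pd.Series,
    min_logcpm: float = 3.0,
    max_fdr: float = 0.01,
    prior_weight: float = 10.0,
    ref_level=None,
) -> tuple[pd.DataFrame, pd.DataFrame, DispersionModel]:
    """Dispersion estimation + LRT + abundance/FDR filtering in one call."""
    disp = estimate_dispersions(counts, group, offsets, prior_weight)
    table = glm_lrt(counts, group, offsets, disp, ref_level=ref_level)
    selected = filter_results(table, min_logcpm, max_fdr)
    return table, selected, disp
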