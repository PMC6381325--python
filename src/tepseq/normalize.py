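"""TMM normalization and iterative RUV-based confounder correction.

The correction module works in four steps, all locked to the training
cohort so that held-out samples never leak information into the model:

1. **Stable genes.** Genes whose raw counts track the intron-spanning
   library size (Pearson r toward 1) and are independent of the donor's
   age are designated negative-control ("stable") genes: after
   counts-per-million scaling they carry the least confounder-driven
   variability.
2. **Latent factors.** Singular value decomposition of the centered
   log-counts of the stable genes yields k latent factors per sample
   (the RUVg construction, k = 3 by default).
3. **Factor triage.** Each factor is kept or removed by two rules: it must
   NOT separate the clinical groups (two-sided t-test p > 1e-5 protects
   signal) AND it must match a named confounder (library size or age,
   correlation-test p < 0.01).  Matched factors are regressed out of the
   log counts gene by gene and the counts back-transformed.
4. **TMM/logCPM.** A reference sample is selected among training
   candidates and locked; trimmed-mean-of-M-values factors scale the
   corrected library sizes, and expression is reported as
   log2 counts-per-million against that effective library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountMatrix, SampleAnnotation, save_model, load_model


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationModel:
    """Frozen state of the normalization pipeline (training-derived only).

    ``loadings`` (stable-genes x k) and ``control_means`` let held-out
    samples be projected onto the training factor directions;
    ``correction_beta`` holds the per-gene regression coefficients on the
    removed factors, estimated on the training cohort.
    """

    ref_sample: str
    tmm_factors: pd.Series
    stable_genes: list[str]
    k: int
    W: pd.DataFrame  # samples x k latent-factor scores
    removed_factors: list[int]  # 0-based column indices into W
    factor_matches: dict[int, list[str]]
    corrected_lib_size: pd.Series
    ref_counts: np.ndarray | None = None  # corrected reference column, locked
    tmm_rescale: float = 1.0  # geometric-mean constant from training
    control_means: pd.Series | None = None
    loadings: pd.DataFrame | None = None
    correction_beta: pd.DataFrame | None = None  # genes x removed factors
    gene_ids: list[str] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def save(self, path) -> None:
        save_model(self.__dict__ | {
            "W": self.W,
            "factor_matches": {str(k): v for k, v in self.factor_matches.items()},
        }, path, kind="normalization")

    @classmethod
    def load(cls, path) -> "NormalizationModel":
        p = load_model(path, kind="normalization")
        p["factor_matches"] = {int(k): v for k, v in p["factor_matches"].items()}
        model = cls(**p)
        # JSON stringifies factor-index columns; restore integer keys
        for attr in ("W", "loadings", "correction_beta"):
            frame = getattr(model, attr)
            if frame is not None and len(frame.columns):
                frame.columns = [int(c) for c in frame.columns]
        if model.ref_counts is not None:
            model.ref_counts = np.asarray(model.ref_counts, dtype=float)
        model.removed_factors = [int(x) for x in model.removed_factors]
        return model


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _quantile_cpm(counts: np.ndarray, q: float = 0.75) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    lib = np.where(lib == 0, 1.0, lib)
    return np.quantile(counts / lib * 1e6, q, axis=0)


def select_tmm_reference(m: CountMatrix, candidates: list[str]) -> str:
    """Pick the candidate whose upper-quartile CPM is most typical.

    The reference is the sample whose 75th-percentile CPM sits closest to
    the candidate-mean 75th-percentile CPM; the first sample in input
    order wins ties.  Once chosen it is locked for the life of the model.
    """
    if not candidates:
        raise NormalizationError("empty TMM reference candidate set")
    sub = m.counts[list(candidates)].to_numpy(dtype=float)
    q75 = _quantile_cpm(sub)
    idx = int(np.argmin(np.abs(q75 - q75.mean())))
    return list(candidates)[idx]


def tmm_factor(
    sample: np.ndarray,
    ref: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Trimmed mean of M-values scaling factor of ``sample`` against ``ref``.

    M- and A-values are computed over genes observed in both columns, the
    top and bottom 30% by M and 5% by A are trimmed, and the factor is
    2**(weighted mean M) with inverse asymptotic-variance weights.  The
    caller rescales all factors to geometric mean one.
    """
    y_s = np.asarray(sample, dtype=float)
    y_r = np.asarray(ref, dtype=float)
    n_s, n_r = y_s.sum(), y_r.sum()
    if n_s <= 0 or n_r <= 0:
        raise NormalizationError("TMM requires positive library sizes")
    both = (y_s > 0) & (y_r > 0)
    ys, yr = y_s[both], y_r[both]
    ps, pr = ys / n_s, yr / n_r
    M = np.log2(ps / pr)
    A = 0.5 * np.log2(ps * pr)
    if np.allclose(M, 0):
        return 1.0
    n = M.size
    # rank-based double trim, matching the trimmed-mean convention
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    w = 1.0 / ((1 - ps[keep]) / ys[keep] + (1 - pr[keep]) / yr[keep])
    f = 2 ** (np.sum(w * M[keep]) / np.sum(w))
    if not np.isfinite(f) or f <= 0:
        warnings.warn("degenerate TMM factor; falling back to 1")
        return 1.0
    return float(f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str,
    rescale_over: list[str] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample TMM factors against a locked reference.

    Factors are rescaled so their geometric mean over ``rescale_over``
    (default: all columns) is one; restricting the rescaling set to the
    training cohort keeps training factors independent of held-out
    samples.  Returns the factors and the rescaling constant.
    """
    ref = counts[ref_sample].to_numpy(dtype=float)
    raw = pd.Series(
        [tmm_factor(counts[s].to_numpy(dtype=float), ref) for s in counts.columns],
        index=counts.columns,
    )
    basis = raw if rescale_over is None else raw.loc[list(rescale_over)]
    geo = float(np.exp(np.mean(np.log(basis))))
    return raw / geo, geo


def logcpm(
    counts: pd.DataFrame,
    eff_lib: pd.Series,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million against effective library sizes.

    ``logCPM[g, s] = log2(1e6 * (counts[g, s] + 0.5) / (eff_lib[s] + 1))``
    where the effective library size is the (corrected) library size times
    the sample's TMM factor.  Monotone in counts by construction.
    """
    lib = eff_lib.loc[counts.columns].to_numpy(dtype=float)
    vals = np.log2(1e6 * (counts.to_numpy(dtype=float) + prior_count) / (lib + 1.0))
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# Stable genes + RUV
# ---------------------------------------------------------------------------


def _rowwise_pearson(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with vector y (NaN if degenerate)."""
    y = y.astype(float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = Xc @ yc / denom
    return r


def stable_gene_selection(
    m: CountMatrix,
    age: pd.Series,
    libsize_threshold: float = 0.8,
    age_threshold: float = 0.2,
) -> tuple[list[str], pd.Series, pd.Series]:
    """Select negative-control genes: track library size, ignore age.

    A gene is stable when the Pearson correlation of its raw counts with
    the intron-spanning library size is at least ``libsize_threshold``
    (a gene proportional to sequencing depth shows the least biological
    variability after CPM scaling) AND the absolute correlation with donor
    age is at most ``age_threshold``.  Samples with missing age are
    skipped in the age correlation only.
    """
    if not (0 < libsize_threshold < 1):
        raise NormalizationError(
            f"libsize_threshold must be in (0,1), got {libsize_threshold}"
        )
    X = m.counts.to_numpy(dtype=float)
    lib = m.lib_size.to_numpy(dtype=float)
    r_lib = _rowwise_pearson(X, lib)

    age = age.loc[m.sample_ids]
    have_age = age.notna().to_numpy()
    if have_age.sum() >= 3:
        r_age = _rowwise_pearson(X[:, have_age], age.to_numpy()[have_age])
    else:
        r_age = np.zeros(m.n_genes)

    degenerate = np.isnan(r_lib) | np.isnan(r_age)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes excluded from the "
            "stable set"
        )
    stable = (
        ~degenerate
        & (r_lib >= libsize_threshold)
        & (np.abs(r_age) <= age_threshold)
    )
    return (
        list(m.gene_ids[stable]),
        pd.Series(r_lib, index=m.gene_ids),
        pd.Series(r_age, index=m.gene_ids),
    )


def ruv_estimate(
    m: CountMatrix, controls: list[str], k: int
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Latent unwanted-variation scores via SVD of control-gene log counts.

    Returns the sample-by-k score matrix W (columns ordered by singular
    value), plus the per-gene means and gene loadings needed to project
    held-out samples onto the same directions.
    """
    if k < 1:
        raise NormalizationError(f"k must be >= 1, got {k}")
    if len(controls) < k:
        raise NormalizationError(
            f"need at least k={k} control genes, got {len(controls)}"
        )
    Y = np.log(m.counts.loc[controls].to_numpy(dtype=float) + 1.0).T  # samples x controls
    mu = Y.mean(axis=0)
    Yc = Y - mu
    if np.allclose(Yc, 0):
        raise NormalizationError(
            "control genes are constant across samples; factors undefined"
        )
    U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
    if k > np.sum(S > 1e-12):
        raise NormalizationError(f"k={k} exceeds the rank of the control matrix")
    W = U[:, :k] * S[:k]
    loadings = Vt[:k].T  # controls x k, orthonormal columns
    return (
        pd.DataFrame(W, index=m.sample_ids, columns=range(k)),
        pd.Series(mu, index=controls),
        pd.DataFrame(loadings, index=controls, columns=range(k)),
    )


def project_factors(
    m: CountMatrix, control_means: pd.Series, loadings: pd.DataFrame
) -> pd.DataFrame:
    """Score samples on locked factor directions (for held-out cohorts)."""
    controls = list(control_means.index)
    Y = np.log(m.counts.loc[controls].to_numpy(dtype=float) + 1.0).T
    W = (Y - control_means.to_numpy()) @ loadings.to_numpy()
    return pd.DataFrame(W, index=m.sample_ids, columns=loadings.columns)


def assign_factors(
    W: pd.DataFrame,
    group: pd.Series,
    confounders: dict[str, pd.Series],
    p_group_floor: float = 1e-5,
    p_confounder_ceiling: float = 0.01,
) -> tuple[list[int], dict[int, list[str]]]:
    """Decide which latent factors carry unwanted variation.

    A factor is flagged for removal only when (a) it does not separate the
    clinical groups -- t-test p must exceed ``p_group_floor``, protecting
    genuine signal -- and (b) it significantly correlates with at least one
    named confounder (correlation-test p below ``p_confounder_ceiling``).
    """
    group = group.loc[W.index]
    levels = group.dropna().unique()
    if len(levels) != 2:
        raise NormalizationError(
            f"group must have exactly 2 levels, got {list(levels)}"
        )
    removed: list[int] = []
    matches: dict[int, list[str]] = {}
    for j in W.columns:
        w = W[j]
        a = w[group == levels[0]]
        b = w[group == levels[1]]
        p_group = stats.ttest_ind(a, b).pvalue
        matched = []
        for name, conf in confounders.items():
            conf = conf.loc[W.index]
            ok = conf.notna()
            if ok.sum() < int(len(conf)):
                warnings.warn(
                    f"confounder {name!r} has missing values; using "
                    "pairwise-complete correlation"
                )
            if ok.sum() < 3:
                continue
            r, p_conf = stats.pearsonr(w[ok], conf[ok])
            if p_conf < p_confounder_ceiling:
                matched.append(name)
        if p_group > p_group_floor and matched:
            removed.append(int(j))
            matches[int(j)] = matched
    return removed, matches


def ruv_regression(
    counts: pd.DataFrame, W_removed: np.ndarray
) -> np.ndarray:
    """Per-gene OLS coefficients of log(counts+1) on removed factor scores."""
    Y = np.log(counts.to_numpy(dtype=float) + 1.0)  # genes x samples
    X = np.column_stack([np.ones(W_removed.shape[0]), W_removed])
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (1+r) x genes
    return beta[1:].T  # genes x r


def ruv_correct(
    m: CountMatrix,
    W: pd.DataFrame,
    removed_factors: list[int],
    beta: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Regress removed factors out of log counts and back-transform.

    With no removed factors this is the identity.  ``beta`` may be supplied
    (training-derived) so held-out samples are corrected with locked
    coefficients; otherwise it is estimated on the given cohort.  Corrected
    values are ``exp(log(y+1) - W_r @ beta) - 1`` clipped at zero, and the
    corrected library size is the per-sample sum of corrected values.
    """
    if not removed_factors:
        vals = m.counts.astype(float)
        return vals, vals.sum(axis=0), np.zeros((m.n_genes, 0))
    Wr = W.loc[m.sample_ids, list(removed_factors)].to_numpy()
    if beta is None:
        beta = ruv_regression(m.counts, Wr)
    Y = np.log(m.counts.to_numpy(dtype=float) + 1.0)
    corrected = np.exp(Y - beta @ Wr.T) - 1.0
    corrected = np.clip(corrected, 0.0, None)
    frame = pd.DataFrame(corrected, index=m.gene_ids, columns=m.sample_ids)
    return frame, frame.sum(axis=0), beta


# ---------------------------------------------------------------------------
# Composition + diagnostics
# ---------------------------------------------------------------------------


def iterative_correction(
    m: CountMatrix,
    ann: SampleAnnotation,
    training: list[str],
    k: int = 3,
    libsize_threshold: float = 0.8,
    age_threshold: float = 0.2,
    p_group_floor: float = 1e-5,
    p_confounder_ceiling: float = 0.01,
) -> tuple[NormalizationModel, pd.DataFrame, pd.DataFrame]:
    """Full training-locked normalization: stable genes -> RUV -> TMM -> logCPM.

    Stable genes, factor directions, regression coefficients, and the TMM
    reference are all derived from the training cohort only, then applied
    to every sample; the procedure is agnostic to non-training labels.
    With ``k = 0`` the correction degenerates to TMM-logCPM.

    Returns the frozen model, the corrected counts (reals), and the logCPM
    matrix for all samples.
    """
    training = [s for s in training if s in set(m.sample_ids)]
    if not training:
        raise NormalizationError("training set shares no samples with the matrix")
    m_train = m.subset_samples(training)
    age = ann.age(m.sample_ids)

    if k > 0:
        stable, _, _ = stable_gene_selection(
            m_train, age.loc[training], libsize_threshold, age_threshold
        )
        if len(stable) < k:
            raise NormalizationError(
                f"only {len(stable)} stable genes at threshold "
                f"{libsize_threshold}; cannot estimate k={k} factors"
            )
        W_train, mu, loadings = ruv_estimate(m_train, stable, k)
        removed, matched = assign_factors(
            W_train,
            ann.group(training),
            {"lib_size": m_train.lib_size.astype(float), "age": age.loc[training]},
            p_group_floor,
            p_confounder_ceiling,
        )
        W_all = project_factors(m, mu, loadings)
        W_all.loc[training] = W_train.to_numpy()
        if removed:
            beta = ruv_regression(m_train.counts, W_train[removed].to_numpy())
        else:
            beta = np.zeros((m.n_genes, 0))
        corrected, corr_lib, _ = ruv_correct(m, W_all, removed, beta=beta)
    else:
        stable, removed, matched = [], [], {}
        mu, loadings = None, None
        W_all = pd.DataFrame(index=m.sample_ids)
        beta = np.zeros((m.n_genes, 0))
        corrected = m.counts.astype(float)
        corr_lib = corrected.sum(axis=0)

    # TMM reference chosen among training candidates on the corrected values
    sub = corrected[training].to_numpy(dtype=float)
    q75 = _quantile_cpm(sub)
    ref = training[int(np.argmin(np.abs(q75 - q75.mean())))]
    factors, tmm_rescale = tmm_factors(corrected, ref, rescale_over=training)
    eff_lib = corr_lib * factors
    log_mat = logcpm(corrected, eff_lib)

    model = NormalizationModel(
        ref_sample=ref,
        tmm_factors=factors,
        stable_genes=stable,
        k=k,
        W=W_all,
        removed_factors=removed,
        factor_matches=matched,
        corrected_lib_size=corr_lib,
        ref_counts=corrected[ref].to_numpy(),
        tmm_rescale=tmm_rescale,
        control_means=mu,
        loadings=loadings,
        correction_beta=pd.DataFrame(
            beta, index=m.gene_ids, columns=list(removed)
        ),
        gene_ids=list(m.gene_ids),
        thresholds={
            "libsize_corr_threshold": libsize_threshold,
            "age_corr_threshold": age_threshold,
            "p_group_floor": p_group_floor,
            "p_confounder_ceiling": p_confounder_ceiling,
        },
    )
    return model, corrected, log_mat


def apply_correction(
    m: CountMatrix, model: NormalizationModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct and logCPM-transform new samples with a locked model.

    Only training-derived parameters are used: factor directions and
    regression coefficients are fixed, each new sample's scores come from
    projecting its own counts, and TMM factors are computed against the
    locked reference profile stored at training time.
    """
    m = m.subset_genes(model.gene_ids)
    if model.removed_factors:
        W = project_factors(m, model.control_means, model.loadings)
        beta = model.correction_beta[model.removed_factors].to_numpy()
        corrected, corr_lib, _ = ruv_correct(
            m, W, model.removed_factors, beta=beta
        )
    else:
        corrected = m.counts.astype(float)
        corr_lib = corrected.sum(axis=0)
    factors = pd.Series(
        [
            tmm_factor(corrected[s].to_numpy(), model.ref_counts)
            for s in corrected.columns
        ],
        index=corrected.columns,
    ) / model.tmm_rescale
    eff_lib = corr_lib * factors
    return corrected, logcpm(corrected, eff_lib)


def rle_matrix(log_mat: pd.DataFrame) -> pd.DataFrame:
    """Relative log expression: per-gene deviation from the across-sample median."""
    med = log_mat.median(axis=1)
    return log_mat.sub(med, axis=0)


def rle_stats(
    log_before: pd.DataFrame, log_after: pd.DataFrame
) -> tuple[pd.Series, pd.Series, float]:
    """Per-sample |median RLE - overall median| before/after, with paired t-test p.

    A drop in the statistic after correction means the samples' expression
    distributions are better aligned; the p-value is a two-sided paired
    Student's t comparison of the per-sample deviations.
    """
    if log_before.shape != log_after.shape:
        raise NormalizationError("RLE inputs must have the same shape")

    def deviation(log_mat: pd.DataFrame) -> pd.Series:
        rle = rle_matrix(log_mat)
        med = rle.median(axis=0)
        return (med - med.median()).abs()

    d_before, d_after = deviation(log_before), deviation(log_after)
    if np.allclose(d_before, d_after):
        return d_before, d_after, 1.0
    p = float(stats.ttest_rel(d_before, d_after).pvalue)
    return d_before, d_after, p
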