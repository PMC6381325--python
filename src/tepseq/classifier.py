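"""Swarm-optimized SVM classifier for platelet spliced-RNA profiles.

Training composes, on the training cohort only:

1. training-locked normalization (stable genes, latent-factor correction,
   TMM reference);
2. initial gene-panel selection by the NB likelihood-ratio test (ANOVA
   step), ranked by LR statistic;
3. removal of highly inter-correlated panel genes (they add noise to SVM
   models without adding information);
4. recursive feature elimination (RFE) with a linear-kernel SVM, dropping
   the 10% of genes with the smallest squared weights per round;
5. RBF-SVM cost/gamma selection on a powers-of-two grid with 2-fold
   internal cross-validation, refined by a small particle swarm around
   the grid optimum;
6. a final RBF SVM fit on all training samples, locked together with
   per-gene training median counts for validation-time imputation and a
   Platt-style score calibration.

Four upstream thresholds -- the stable-gene library-size correlation, the
ANOVA FDR cut, the correlation-filter cutoff, and the RFE panel size --
are themselves tuned by an outer particle swarm that minimizes 1 - AUC on
a held-out evaluation cohort.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import diff_splicing, normalize, performance
from .core_io import CountMatrix, SampleAnnotation
from .pso import PSOConfig, minimize_pso


class TrainingError(RuntimeError):
    """A pipeline stage produced an unusable state (e.g. empty panel)."""


DEFAULT_THETA_BOUNDS = (
    (0.5, 0.95),   # stable-gene library-size correlation threshold
    (1e-4, 0.2),   # ANOVA FDR threshold
    (0.5, 1.0),    # correlation-filter cutoff
    (10, 1000),    # RFE panel size (rounded to integer at evaluation)
)


@dataclass
class GenePanel:
    genes: list[str]
    scores: pd.Series  # ranking statistic per gene (LR or RFE weight)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise TrainingError("gene panel contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SVMConfig:
    C: float
    gamma: float
    cv_folds: int = 2
    cv_auc: float = float("nan")


@dataclass
class ClassifierModel:
    """Frozen classifier: prediction uses only what is stored here."""

    norm_model: normalize.NormalizationModel
    panel: GenePanel
    svm_config: SVMConfig
    labels_order: list  # [negative level, positive level]
    theta: tuple
    imputation_medians: pd.Series
    impute_trigger: int
    feature_means: pd.Series
    feature_stds: pd.Series
    platt_a: float
    platt_b: float
    call_threshold: float = 0.5
    _svm: SVC | None = None
    _train_features: pd.DataFrame | None = None
    _train_y: np.ndarray | None = None

    def serialized_bytes(self) -> bytes:
        """Deterministic byte serialization of the locked state."""
        payload = {
            "panel": self.panel.genes,
            "theta": list(self.theta),
            "svm": [self.svm_config.C, self.svm_config.gamma],
            "labels": [str(x) for x in self.labels_order],
            "medians": self.imputation_medians.to_numpy().tolist(),
            "trigger": self.impute_trigger,
            "means": self.feature_means.to_numpy().tolist(),
            "stds": self.feature_stds.to_numpy().tolist(),
            "platt": [self.platt_a, self.platt_b],
            "ref": self.norm_model.ref_sample,
            "tmm_rescale": self.norm_model.tmm_rescale,
            "stable_genes": self.norm_model.stable_genes,
            "removed_factors": self.norm_model.removed_factors,
            "beta": (
                self.norm_model.correction_beta.to_numpy().tolist()
                if self.norm_model.correction_beta is not None
                else None
            ),
            "support": self._svm.support_vectors_.tolist() if self._svm else None,
            "dual_coef": self._svm.dual_coef_.tolist() if self._svm else None,
            "intercept": self._svm.intercept_.tolist() if self._svm else None,
        }
        return json.dumps(payload, sort_keys=True).encode()

    def digest(self) -> str:
        return hashlib.sha256(self.serialized_bytes()).hexdigest()

    def save(self, path) -> None:
        """Full single-archive serialization (training features included).

        The RBF SVM itself is reconstructed on load by refitting on the
        stored training features with the locked (C, gamma) -- a
        deterministic operation -- so the archive stays a plain versioned
        JSON file.
        """
        from .core_io import save_model

        nm = self.norm_model
        payload = {
            "norm": {
                "ref_sample": nm.ref_sample,
                "tmm_factors": nm.tmm_factors,
                "stable_genes": nm.stable_genes,
                "k": nm.k,
                "W": nm.W,
                "removed_factors": nm.removed_factors,
                "factor_matches": {str(k): v for k, v in nm.factor_matches.items()},
                "corrected_lib_size": nm.corrected_lib_size,
                "ref_counts": nm.ref_counts,
                "tmm_rescale": nm.tmm_rescale,
                "control_means": nm.control_means,
                "loadings": nm.loadings,
                "correction_beta": nm.correction_beta,
                "gene_ids": nm.gene_ids,
                "thresholds": nm.thresholds,
            },
            "panel_genes": self.panel.genes,
            "panel_scores": self.panel.scores,
            "panel_provenance": self.panel.provenance,
            "svm": {"C": self.svm_config.C, "gamma": self.svm_config.gamma,
                    "cv_folds": self.svm_config.cv_folds,
                    "cv_auc": self.svm_config.cv_auc},
            "labels_order": [str(x) for x in self.labels_order],
            "theta": list(self.theta),
            "imputation_medians": self.imputation_medians,
            "impute_trigger": self.impute_trigger,
            "feature_means": self.feature_means,
            "feature_stds": self.feature_stds,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "call_threshold": self.call_threshold,
            "train_features": self._train_features,
            "train_y": np.asarray(self._train_y),
        }
        save_model(payload, path, kind="classifier")

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        from .core_io import load_model

        p = load_model(path, kind="classifier")
        nm = p["norm"]
        norm_model = normalize.NormalizationModel(
            ref_sample=nm["ref_sample"],
            tmm_factors=nm["tmm_factors"],
            stable_genes=list(nm["stable_genes"]),
            k=int(nm["k"]),
            W=nm["W"],
            removed_factors=[int(x) for x in nm["removed_factors"]],
            factor_matches={int(k): v for k, v in nm["factor_matches"].items()},
            corrected_lib_size=nm["corrected_lib_size"],
            ref_counts=np.asarray(nm["ref_counts"]),
            tmm_rescale=float(nm["tmm_rescale"]),
            control_means=nm["control_means"],
            loadings=nm["loadings"],
            correction_beta=nm["correction_beta"],
            gene_ids=list(nm["gene_ids"]),
            thresholds=nm["thresholds"],
        )
        # JSON stringifies the factor-index columns; restore integer keys
        if norm_model.correction_beta is not None:
            norm_model.correction_beta.columns = [
                int(c) for c in norm_model.correction_beta.columns
            ]
        if norm_model.loadings is not None:
            norm_model.loadings.columns = [int(c) for c in norm_model.loadings.columns]
        if norm_model.W is not None and len(norm_model.W.columns):
            norm_model.W.columns = [int(c) for c in norm_model.W.columns]
        cfg = SVMConfig(**p["svm"])
        features = p["train_features"]
        y = np.asarray(p["train_y"], dtype=int)
        svm = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)
        Z = (
            features.sub(p["feature_means"], axis=0)
            .div(p["feature_stds"], axis=0)
            .to_numpy()
            .T
        )
        svm.fit(Z, y)
        return cls(
            norm_model=norm_model,
            panel=GenePanel(
                genes=list(p["panel_genes"]),
                scores=p["panel_scores"],
                provenance=p["panel_provenance"],
            ),
            svm_config=cfg,
            labels_order=p["labels_order"],
            theta=tuple(p["theta"]),
            imputation_medians=p["imputation_medians"],
            impute_trigger=int(p["impute_trigger"]),
            feature_means=p["feature_means"],
            feature_stds=p["feature_stds"],
            platt_a=float(p["platt_a"]),
            platt_b=float(p["platt_b"]),
            call_threshold=float(p["call_threshold"]),
            _svm=svm,
            _train_features=features,
            _train_y=y,
        )


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def rank_genes_anova(
    counts: pd.DataFrame,
    group: pd.Series,
    offsets: pd.Series,
    fdr_threshold: float,
    prior_weight: float = 10.0,
    dispersion: float | None = None,
) -> GenePanel:
    """Initial panel: NB likelihood-ratio (ANOVA) test, FDR cut, LR ordering.

    ``dispersion`` may pin a fixed dispersion (skipping estimation) for
    speed inside swarm evaluations; by default the full common/trend/
    tagwise moderation runs on the training counts.
    """
    if dispersion is None:
        disp = diff_splicing.estimate_dispersions(
            counts, group, offsets, prior_weight
        )
    else:
        disp = float(dispersion)
    table = diff_splicing.glm_lrt(counts, group, offsets, disp)
    hits = table[table["FDR"] < fdr_threshold].sort_values(
        "LR", ascending=False, kind="mergesort"
    )
    if hits.empty:
        raise TrainingError(
            f"no genes pass the ANOVA filter at FDR < {fdr_threshold}; "
            "raise the threshold"
        )
    return GenePanel(
        genes=list(hits.index),
        scores=hits["LR"],
        provenance={"fdr_threshold": fdr_threshold},
    )


def remove_correlated_genes(
    features: pd.DataFrame, panel: GenePanel, cutoff: float
) -> GenePanel:
    """Greedy pruning of highly inter-correlated panel genes.

    While any pair of panel genes exceeds ``cutoff`` in absolute Pearson
    correlation, the member of the worst pair with the larger mean
    absolute correlation to the rest of the panel is removed (ties break
    toward the later panel position).  The survivors satisfy
    ``max |r| <= cutoff`` by construction.
    """
    if not (0 < cutoff <= 1):
        raise TrainingError(f"correlation cutoff must be in (0, 1], got {cutoff}")
    genes = list(panel.genes)
    X = features.loc[genes].to_numpy()
    with np.errstate(invalid="ignore"):
        R = np.abs(np.corrcoef(X))
    R = np.nan_to_num(R, nan=0.0)
    np.fill_diagonal(R, 0.0)
    alive = np.ones(len(genes), dtype=bool)
    while True:
        Rv = np.where(np.outer(alive, alive), R, 0.0)
        worst = np.unravel_index(np.argmax(Rv), Rv.shape)
        if Rv[worst] <= cutoff:
            break
        i, j = worst
        mean_i = Rv[i, alive].mean()
        mean_j = Rv[j, alive].mean()
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # later panel position
        alive[drop] = False
        if alive.sum() <= 1:
            break
    kept = [g for g, a in zip(genes, alive) if a]
    return GenePanel(
        genes=kept,
        scores=panel.scores.loc[kept],
        provenance=panel.provenance | {"corr_cutoff": cutoff},
    )


def _standardize(features: pd.DataFrame) -> tuple[np.ndarray, pd.Series, pd.Series]:
    mu = features.mean(axis=1)
    sd = features.std(axis=1).replace(0.0, 1.0)
    Z = features.sub(mu, axis=0).div(sd, axis=0)
    return Z.to_numpy().T, mu, sd  # samples x genes


def svm_rfe(
    features: pd.DataFrame,
    y: np.ndarray,
    panel: GenePanel,
    target_size: int,
) -> GenePanel:
    """Recursive feature elimination by squared linear-SVM weights.

    Each round fits a linear-kernel SVM on the surviving genes, ranks them
    by w**2, and drops the lowest 10% (at least one) until ``target_size``
    remain; the final panel is ordered by the last round's ranking.  A
    linear kernel is used here even though the classifier is RBF: the RFE
    criterion needs explicit weights.
    """
    genes = list(panel.genes)
    if target_size > len(genes):
        raise TrainingError(
            f"RFE target {target_size} exceeds panel size {len(genes)}"
        )
    if target_size < 1:
        raise TrainingError("RFE target must be >= 1")
    w2 = None
    while True:
        Z, _, _ = _standardize(features.loc[genes])
        svm = SVC(kernel="linear", C=1.0)
        svm.fit(Z, y)
        w2 = np.asarray(svm.coef_).ravel() ** 2
        if len(genes) <= target_size:
            break
        n_drop = min(max(1, int(np.floor(0.1 * len(genes)))), len(genes) - target_size)
        order = np.argsort(w2, kind="mergesort")  # ascending: weakest first
        drop = set(order[:n_drop])
        genes = [g for i, g in enumerate(genes) if i not in drop]
    final_order = np.argsort(-w2, kind="mergesort")
    ordered = [genes[i] for i in final_order]
    return GenePanel(
        genes=ordered,
        scores=pd.Series(w2[final_order], index=ordered),
        provenance=panel.provenance | {"rfe_target": target_size},
    )


def _cv_auc(
    Z: np.ndarray, y: np.ndarray, C: float, gamma: float, folds: int, seed: int
) -> float:
    """Mean stratified-CV AUC of an RBF SVM, re-folding on degenerate splits."""
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        aucs = []
        try:
            for tr, te in skf.split(Z, y):
                if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                    raise ValueError("single-class fold")
                svm = SVC(kernel="rbf", C=C, gamma=gamma)
                svm.fit(Z[tr], y[tr])
                aucs.append(performance.roc_auc(svm.decision_function(Z[te]), y[te]))
            return float(np.mean(aucs))
        except ValueError:
            continue
    raise TrainingError("could not build two-class CV folds in 5 attempts")


def grid_search_svm(
    features: pd.DataFrame,
    y: np.ndarray,
    folds: int = 2,
    seed: int = 0,
    log2_c_grid: np.ndarray | None = None,
    log2_gamma_grid: np.ndarray | None = None,
) -> SVMConfig:
    """Powers-of-two (gamma, C) grid search with internal cross-validation.

    The default grid is C in 2**(0..20) and gamma in 2**(-20..0), scored
    by mean 2-fold stratified CV AUC with a fixed fold seed; ties break
    toward smaller C, then larger gamma.
    """
    if log2_c_grid is None:
        log2_c_grid = np.arange(0, 21)
    if log2_gamma_grid is None:
        log2_gamma_grid = np.arange(-20, 1)
    Z, _, _ = _standardize(features)
    best = None
    for lc in sorted(log2_c_grid):
        for lg in sorted(log2_gamma_grid, reverse=True):
            auc = _cv_auc(Z, y, 2.0 ** lc, 2.0 ** lg, folds, seed)
            if best is None or auc > best[0]:
                best = (auc, lc, lg)
    return SVMConfig(C=2.0 ** best[1], gamma=2.0 ** best[2], cv_folds=folds,
                     cv_auc=best[0])


def pso_refine_svm(
    features: pd.DataFrame,
    y: np.ndarray,
    grid_opt: SVMConfig,
    half_width: float = 2.0,
    folds: int = 2,
    seed: int = 0,
    n_particles: int = 10,
    n_iterations: int = 8,
) -> SVMConfig:
    """Continuous swarm refinement of (log2 gamma, log2 C) near the grid optimum.

    The grid point is seeded as one particle, so the refined configuration
    is never worse (in CV AUC) than the grid search result.
    """
    Z, _, _ = _standardize(features)
    c0, g0 = np.log2(grid_opt.C), np.log2(grid_opt.gamma)
    bounds = [(c0 - half_width, c0 + half_width), (g0 - half_width, g0 + half_width)]

    def objective(x: np.ndarray) -> float:
        return -_cv_auc(Z, y, 2.0 ** x[0], 2.0 ** x[1], folds, seed)

    res = minimize_pso(
        objective,
        bounds,
        PSOConfig(n_particles=n_particles, n_iterations=n_iterations, seed=seed),
        seeds=[np.array([c0, g0])],
    )
    return SVMConfig(
        C=2.0 ** res.best_x[0],
        gamma=2.0 ** res.best_x[1],
        cv_folds=folds,
        cv_auc=-res.best_f,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt-style sigmoid P(y=1|d) = expit(a*d + b), fit by Newton steps.

    The score is monotone increasing in the decision value when a > 0
    (the usual case; a could only come out negative if the SVM decision
    anti-correlated with the positive class).  Targets are smoothed with
    Platt's prior counts so perfectly separated decision values stay
    numerically stable, and the step size is damped to keep the
    iteration from overshooting on near-separable data.
    """
    from scipy.special import expit

    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    a, b = 1.0, float(np.log((n_pos + 1.0) / (n_neg + 1.0)))
    for _ in range(200):
        p = expit(a * decision + b)
        g = np.maximum(p * (1 - p), 1e-12)
        grad_a = np.sum(decision * (p - t))
        grad_b = np.sum(p - t)
        h11 = np.sum(decision * decision * g) + 1e-10
        h22 = np.sum(g) + 1e-10
        h12 = np.sum(decision * g)
        det = h11 * h22 - h12 * h12
        if abs(det) < 1e-24:
            break
        da = -(h22 * grad_a - h12 * grad_b) / det
        db = -(-h12 * grad_a + h11 * grad_b) / det
        step = min(1.0, 10.0 / max(abs(da), abs(db), 1e-12))
        a, b = a + step * da, b + step * db
        if max(abs(da), abs(db)) < 1e-10:
            break
    return float(a), float(b)


def _platt_score(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    from scipy.special import expit

    return expit(a * np.asarray(decision, dtype=float) + b)


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def _encode_labels(group: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(group.dropna()))
    if len(levels) != 2:
        raise TrainingError(f"need exactly 2 classes, got {levels}")
    y = (group == levels[1]).to_numpy(dtype=int)
    return y, levels


def train_classifier(
    m: CountMatrix,
    ann: SampleAnnotation,
    theta: tuple[float, float, float, int],
    k: int = 3,
    impute_trigger: int = 12,
    seed: int = 0,
    anova_dispersion: float | None = None,
    grid_step: int = 1,
) -> ClassifierModel:
    """Train and lock the full pipeline on a training cohort.

    ``theta = (libsize_thr, fdr_thr, corr_cutoff, rfe_size)`` are the four
    swarm-tunable hyperparameters.  Panel selection runs on the raw
    (uncorrected) counts for reproducibility of classification, while the
    SVM consumes normalization-corrected logCPM features.  ``grid_step``
    thins the powers-of-two grid (step 1 = the full 21 x 21 grid).
    """
    libsize_thr, fdr_thr, corr_cutoff, rfe_size = theta
    rfe_size = int(round(rfe_size))
    group = ann.group(m.sample_ids)
    y, levels = _encode_labels(group)

    norm_model, corrected, log_all = normalize.iterative_correction(
        m, ann, training=list(m.sample_ids), k=k, libsize_threshold=libsize_thr
    )

    try:
        panel = rank_genes_anova(
            m.counts,
            group,
            m.lib_size.astype(float),
            fdr_thr,
            dispersion=anova_dispersion,
        )
    except TrainingError as exc:
        raise TrainingError(f"anova stage: {exc}") from exc

    panel = remove_correlated_genes(log_all, panel, corr_cutoff)
    if len(panel) == 0:
        raise TrainingError("correlation-filter stage: panel shrank to zero")

    rfe_size = min(rfe_size, len(panel))
    panel = svm_rfe(log_all, y, panel, rfe_size)
    if len(panel) == 0:
        raise TrainingError("rfe stage: panel shrank to zero")

    features = log_all.loc[panel.genes]
    grid = np.arange(0, 21, grid_step)
    cfg = grid_search_svm(
        features, y, seed=seed,
        log2_c_grid=grid, log2_gamma_grid=-grid,
    )
    cfg = pso_refine_svm(features, y, cfg, seed=seed)

    Z, mu, sd = _standardize(features)
    svm = SVC(kernel="rbf", C=cfg.C, gamma=cfg.gamma)
    svm.fit(Z, y)
    decision = svm.decision_function(Z)
    a, b = _fit_platt(decision, y)

    medians = m.counts.loc[panel.genes].median(axis=1)
    return ClassifierModel(
        norm_model=norm_model,
        panel=panel,
        svm_config=cfg,
        labels_order=levels,
        theta=(libsize_thr, fdr_thr, corr_cutoff, rfe_size),
        imputation_medians=medians,
        impute_trigger=impute_trigger,
        feature_means=mu,
        feature_stds=sd,
        platt_a=a,
        platt_b=b,
        _svm=svm,
        _train_features=features,
        _train_y=y,
    )


def impute_undetected_genes(
    counts: pd.DataFrame, model: ClassifierModel, trigger: int | None = None
) -> pd.DataFrame:
    """Replace low validation counts of panel genes by training medians.

    Undetected or barely detected genes (count between 0 and the trigger,
    inclusive on both ends) in a validation sample would distort
    normalization, so they take the training cohort's median count for
    that gene.  Panel genes absent from the validation table count as
    zero (and are therefore imputed) with a warning.
    """
    if trigger is None:
        trigger = model.impute_trigger
    if trigger < 0:
        raise ValueError("imputation trigger must be >= 0")
    out = counts.astype(float)
    missing = [g for g in model.panel.genes if g not in out.index]
    if missing:
        warnings.warn(
            f"{len(missing)} panel genes absent from the validation table; "
            "treated as zero counts and imputed"
        )
        filler = pd.DataFrame(0.0, index=missing, columns=out.columns)
        out = pd.concat([out, filler])
    sub = out.loc[model.panel.genes]
    med = model.imputation_medians.loc[model.panel.genes].to_numpy(dtype=float)
    mask = (sub >= 0) & (sub <= trigger)
    sub = sub.where(~mask, np.tile(med[:, None], (1, sub.shape[1])))
    out.loc[model.panel.genes] = sub
    return out


def predict(
    m: CountMatrix, model: ClassifierModel
) -> pd.DataFrame:
    """Score samples with a locked model: per-sample score in [0, 1] + call.

    Applies imputation, the locked normalization, panel restriction and
    feature standardization, then maps SVM decision values through the
    training-fitted Platt sigmoid.  The class call is made at the model's
    threshold (default 0.5).
    """
    counts = m.counts.copy()
    absent = [g for g in model.norm_model.gene_ids if g not in counts.index]
    if absent:
        counts = pd.concat(
            [counts, pd.DataFrame(0, index=absent, columns=counts.columns)]
        )
    counts = impute_undetected_genes(counts, model)
    adjusted = CountMatrix(counts.loc[model.norm_model.gene_ids].round().astype(np.int64))
    _, log_mat = normalize.apply_correction(adjusted, model.norm_model)
    features = log_mat.loc[model.panel.genes]
    Z = (
        features.sub(model.feature_means, axis=0)
        .div(model.feature_stds, axis=0)
        .to_numpy()
        .T
    )
    decision = model._svm.decision_function(Z)
    score = _platt_score(decision, model.platt_a, model.platt_b)
    calls = np.where(
        score >= model.call_threshold, model.labels_order[1], model.labels_order[0]
    )
    return pd.DataFrame(
        {"score": score, "call": calls, "decision": decision},
        index=m.sample_ids,
    )


def svm_fit_predict_factory(model: ClassifierModel):
    """``fit_predict(Xtr, ytr, Xte)`` closure refitting only the SVM.

    Used by LOOCV / permutation / resampling procedures: the gene panel,
    normalization and (C, gamma) stay locked; support vectors are refit
    on the given training features.
    """

    def fit_predict(Xtr: pd.DataFrame, ytr: pd.Series, Xte: pd.DataFrame):
        mu = Xtr.mean(axis=1)
        sd = Xtr.std(axis=1).replace(0.0, 1.0)
        Ztr = Xtr.sub(mu, axis=0).div(sd, axis=0).to_numpy().T
        Zte = Xte.sub(mu, axis=0).div(sd, axis=0).to_numpy().T
        yarr = np.asarray(ytr)
        if len(np.unique(yarr)) < 2:
            return np.full(Zte.shape[0], 0.5)
        svm = SVC(kernel="rbf", C=model.svm_config.C, gamma=model.svm_config.gamma)
        svm.fit(Ztr, yarr)
        return svm.decision_function(Zte)

    return fit_predict


def outer_pso_optimize(
    m: CountMatrix,
    ann: SampleAnnotation,
    training: list[str],
    evaluation: list[str],
    config: PSOConfig,
    bounds=DEFAULT_THETA_BOUNDS,
    k: int = 3,
    impute_trigger: int = 12,
    anova_dispersion: float | None = None,
    grid_step: int = 1,
) -> tuple[tuple, ClassifierModel, list[float]]:
    """Outer swarm over the four pipeline thresholds.

    Each particle position is a full hyperparameter vector theta; its
    fitness is ``1 - AUC`` of the theta-trained classifier on the held-out
    evaluation cohort (panel optimization cohort).  Any stage failure for
    a particle scores 1.  Returns the global best theta, its (re-trained)
    locked model, and the per-iteration global-best trace.
    """
    if set(training) & set(evaluation):
        raise TrainingError("training and evaluation cohorts must be disjoint")
    m_train = m.subset_samples(training)
    m_eval = m.subset_samples(evaluation)
    ann_train = ann.subset(training)
    y_eval, levels = _encode_labels(ann.group(evaluation))

    def objective(x: np.ndarray) -> float:
        theta = (x[0], x[1], x[2], int(round(x[3])))
        try:
            model = train_classifier(
                m_train, ann_train, theta, k=k,
                impute_trigger=impute_trigger, seed=config.seed,
                anova_dispersion=anova_dispersion, grid_step=grid_step,
            )
            preds = predict(m_eval, model)
            auc = performance.roc_auc(preds["score"].to_numpy(), y_eval)
        except (TrainingError, normalize.NormalizationError):
            return 1.0
        return 1.0 - auc

    res = minimize_pso(objective, list(bounds), config)
    best_theta = (
        float(res.best_x[0]),
        float(res.best_x[1]),
        float(res.best_x[2]),
        int(round(res.best_x[3])),
    )
    best_model = train_classifier(
        m_train, ann_train, best_theta, k=k, impute_trigger=impute_trigger,
        seed=config.seed, anova_dispersion=anova_dispersion, grid_step=grid_step,
    )
    return best_theta, best_model, res.trace
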