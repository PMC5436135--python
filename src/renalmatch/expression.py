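"""Expression-based ccA/ccB subtype classification.

The classifier pipeline has three stages:

1. **Batch correction** — parametric empirical-Bayes location/scale
   adjustment. Each gene is standardized against its batch-free fit; batch
   location effects get a normal prior and batch scale effects an
   inverse-gamma prior, with method-of-moments hyperparameters; conditional
   posterior estimates are iterated to convergence and the data
   back-transformed.
2. **Nearest shrunken centroids** — per-gene standardized class-centroid
   contrasts ``d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s0))`` soft-thresholded at
   Δ: ``d'_kj = sign(d_kj)(|d_kj| − Δ)₊``, giving shrunken centroids
   ``x̄'_kj = x̄_j + m_k (s_j + s0) d'_kj``. Genes with all-zero shrunken
   contrasts drop out; Δ is chosen by stratified 10-fold cross-validation
   (ties toward larger Δ, i.e. fewer genes).
3. **Margin calling** — each sample is Spearman-correlated with the two
   shrunken class centroids over the surviving genes; it is called for a
   class only when that correlation exceeds the other by at least the
   margin (default 0.05), otherwise it stays unclassified.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .harmonize import GeneMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Empirical-Bayes batch correction


@dataclass
class BatchAdjustModel:
    """Fitted location/scale batch-effect model."""

    batches: list[str]
    grand_mean: pd.Series
    pooled_var: pd.Series
    gamma_hat: pd.DataFrame        # batch x gene, raw location effects
    delta_hat: pd.DataFrame        # batch x gene, raw scale effects
    gamma_star: pd.DataFrame       # EB-shrunken location effects
    delta_star: pd.DataFrame       # EB-shrunken scale effects
    hyper: dict = field(default_factory=dict)
    adjusted_genes: list[str] = field(default_factory=list)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_adjust(matrix: GeneMatrix, batch_labels: pd.Series,
                  parametric: bool = True, tol: float = 1e-6,
                  max_iter: int = 500) -> tuple[GeneMatrix, BatchAdjustModel | None]:
    """Parametric empirical-Bayes batch correction of an expression matrix.

    With a single batch the input is returned unchanged (warning). A fully
    constant gene is left unadjusted (warning). A gene whose within-batch
    residual variance is zero but whose batch means differ (the noiseless
    limit) has nothing to shrink against: it receives the exact
    maximum-likelihood location adjustment, so pure location-scale batch
    effects on noiseless input are removed exactly — adjusted per-gene
    batch means then agree across batches to numerical tolerance.
    """
    if not parametric:
        raise NotImplementedError("only the parametric prior family is implemented")
    values = matrix.values
    batch = batch_labels.reindex(values.columns)
    if batch.isna().any():
        raise InvalidArgumentError("batch label missing for some samples")
    batches = sorted(batch.unique())
    if len(batches) < 2:
        warnings.warn("single batch: returning data unadjusted", stacklevel=2)
        return matrix, None
    sizes = batch.value_counts()
    if (sizes < 2).any():
        raise InvalidArgumentError("every batch needs at least 2 samples")

    X = values.to_numpy(dtype=float)         # genes x samples
    n_genes, n = X.shape
    design = np.stack([(batch == b).to_numpy(dtype=float) for b in batches])  # B x n
    n_b = design.sum(axis=1)

    batch_means = (X @ design.T) / n_b       # genes x B
    grand_mean = batch_means @ (n_b / n)     # size-weighted grand mean
    resid = X - batch_means @ design
    pooled_var = (resid**2).sum(axis=1) / n

    scale = np.maximum(np.abs(X).max(axis=1), 1.0)
    degenerate = pooled_var <= (1e-14 * scale) ** 2   # no within-batch variation
    spread = np.abs(batch_means - grand_mean[:, None]).max(axis=1)
    constant = degenerate & (spread <= 1e-14 * scale)
    exact_fix = degenerate & ~constant
    usable = ~degenerate
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes left unadjusted",
                      stacklevel=2)

    Xu = X[usable]
    gm = grand_mean[usable]
    pv = pooled_var[usable]
    Z = (Xu - gm[:, None]) / np.sqrt(pv)[:, None]

    gamma_hat = (Z @ design.T) / n_b         # genes x B
    delta_hat = np.empty_like(gamma_hat)
    for bi in range(len(batches)):
        cols = design[bi] == 1
        delta_hat[:, bi] = Z[:, cols].var(axis=1, ddof=1)

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    hyper = {}
    for bi, b in enumerate(batches) if Xu.shape[0] else ():
        g_hat = gamma_hat[:, bi]
        d_hat = delta_hat[:, bi]
        gamma_bar, tau2 = g_hat.mean(), g_hat.var(ddof=1)
        if tau2 == 0 or d_hat.var(ddof=1) == 0:
            # degenerate across-gene spread: nothing to shrink toward
            hyper[b] = {"gamma_bar": float(gamma_bar), "tau2": float(tau2),
                        "a_prior": math.nan, "b_prior": math.nan}
            continue
        a_pr, b_pr = _aprior(d_hat), _bprior(d_hat)
        hyper[b] = {"gamma_bar": float(gamma_bar), "tau2": float(tau2),
                    "a_prior": float(a_pr), "b_prior": float(b_pr)}
        cols = design[bi] == 1
        nb = float(n_b[bi])
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_old, d_old = g_new, d_new
            g_new = (nb * tau2 * g_hat + d_old * gamma_bar) / (nb * tau2 + d_old)
            sse = ((Z[:, cols] - g_new[:, None])**2).sum(axis=1)
            d_new = (0.5 * sse + b_pr) / (nb / 2.0 + a_pr - 1.0)
            change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
            if change < tol:
                break
        gamma_star[:, bi] = g_new
        delta_star[:, bi] = d_new

    Z_adj = (Z - gamma_star @ design) / np.sqrt(delta_star @ design)
    X_adj = X.copy()
    X_adj[usable] = Z_adj * np.sqrt(pv)[:, None] + gm[:, None]
    if exact_fix.any():
        # noiseless limit: subtract the batch mean, restore the grand mean
        shift = (batch_means[exact_fix] - grand_mean[exact_fix, None]) @ design
        X_adj[exact_fix] = X[exact_fix] - shift

    genes = values.index
    model = BatchAdjustModel(
        batches=[str(b) for b in batches],
        grand_mean=pd.Series(grand_mean, index=genes),
        pooled_var=pd.Series(pooled_var, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat.T, index=batches, columns=genes[usable]),
        delta_hat=pd.DataFrame(delta_hat.T, index=batches, columns=genes[usable]),
        gamma_star=pd.DataFrame(gamma_star.T, index=batches, columns=genes[usable]),
        delta_star=pd.DataFrame(delta_star.T, index=batches, columns=genes[usable]),
        hyper=hyper,
        adjusted_genes=list(genes[usable]),
    )
    adjusted = GeneMatrix(pd.DataFrame(X_adj, index=genes, columns=values.columns),
                          kind="expression")
    return adjusted, model


# ---------------------------------------------------------------------------
# Nearest shrunken centroids


@dataclass
class ShrunkenCentroidModel:
    """Nearest-shrunken-centroid model at one shrinkage threshold Δ."""

    classes: list[str]
    genes: list[str]                  # all training genes
    centroids: pd.DataFrame           # gene x class, unshrunken x̄_kj
    overall: pd.Series                # x̄_j
    s: pd.Series                      # pooled within-class sd s_j
    s0: float
    m: dict[str, float]               # class-size normalizers m_k
    delta: float
    priors: dict[str, float]
    shrunken: pd.DataFrame = field(init=False)    # gene x class, x̄'_kj
    surviving_genes: list[str] = field(init=False)

    def __post_init__(self) -> None:
        denom = (self.s + self.s0)
        d = pd.DataFrame({k: (self.centroids[k] - self.overall) / (self.m[k] * denom)
                          for k in self.classes})
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
        self.shrunken = pd.DataFrame(
            {k: self.overall + self.m[k] * denom * d_shrunk[k] for k in self.classes})
        self.surviving_genes = list(d_shrunk.index[(d_shrunk != 0).any(axis=1)])

    def discriminant(self, sample_matrix: GeneMatrix) -> pd.DataFrame:
        """Per-class discriminant score (smaller is closer) for each sample.

        ``δ_k(x) = Σ_j (x_j − x̄'_kj)² / (s_j + s0)² − 2 log π_k`` over the
        surviving genes; with no surviving genes the score reduces to the
        prior term.
        """
        X = sample_matrix.values.reindex(self.genes)
        genes = self.surviving_genes
        scores = {}
        for k in self.classes:
            prior_term = -2.0 * np.log(self.priors[k])
            if genes:
                denom = (self.s.loc[genes] + self.s0) ** 2
                diff = X.loc[genes].sub(self.shrunken.loc[genes, k], axis=0)
                scores[k] = (diff**2).div(denom, axis=0).sum(axis=0, skipna=True) + prior_term
            else:
                scores[k] = pd.Series(prior_term, index=X.columns)
        return pd.DataFrame(scores)

    def predict(self, sample_matrix: GeneMatrix) -> pd.Series:
        scores = self.discriminant(sample_matrix)
        return scores.idxmin(axis=1).rename("prediction")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "classes": self.classes,
            "delta": self.delta,
            "s0": self.s0,
            "m": self.m,
            "priors": self.priors,
            "genes": self.genes,
            "overall": self.overall.tolist(),
            "s": self.s.tolist(),
            "centroids": {k: self.centroids[k].tolist() for k in self.classes},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ShrunkenCentroidModel":
        obj = json.loads(Path(path).read_text())
        genes = obj["genes"]
        return cls(
            classes=obj["classes"],
            genes=genes,
            centroids=pd.DataFrame({k: pd.Series(v, index=genes)
                                    for k, v in obj["centroids"].items()}),
            overall=pd.Series(obj["overall"], index=genes),
            s=pd.Series(obj["s"], index=genes),
            s0=obj["s0"],
            m=obj["m"],
            delta=obj["delta"],
            priors=obj["priors"],
        )


@dataclass
class SubtypeCall:
    sample_id: str
    corr_ccA: float
    corr_ccB: float
    call: str          # ccA | ccB | unclassified
    margin: float


def _fit_centroids(values: pd.DataFrame, labels: pd.Series, delta: float,
                   m_variant: str = "minus", priors: dict | None = None) -> ShrunkenCentroidModel:
    classes = sorted(labels.unique())
    n = values.shape[1]
    overall = values.mean(axis=1)
    centroids = {}
    within_ss = pd.Series(0.0, index=values.index)
    for k in classes:
        cols = labels.index[labels == k]
        sub = values[cols]
        centroids[k] = sub.mean(axis=1)
        within_ss += ((sub.sub(centroids[k], axis=0))**2).sum(axis=1)
    s = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(s.median())
    m = {}
    for k in classes:
        n_k = int((labels == k).sum())
        if m_variant == "minus":
            m[k] = float(np.sqrt(max(1.0 / n_k - 1.0 / n, 0.0)))
        else:
            m[k] = float(np.sqrt(1.0 / n_k + 1.0 / n))
    if priors is None:
        priors = {k: 1.0 / len(classes) for k in classes}
    return ShrunkenCentroidModel(
        classes=classes, genes=list(values.index),
        centroids=pd.DataFrame(centroids), overall=overall, s=s, s0=s0,
        m=m, delta=delta, priors=priors)


def _stratified_folds(labels: pd.Series, folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns per-fold boolean masks."""
    assignment = pd.Series(-1, index=labels.index)
    for k in sorted(labels.unique()):
        idx = labels.index[labels == k].to_numpy()
        rng.shuffle(idx)
        for i, sid in enumerate(idx):
            assignment[sid] = i % folds
    return [(assignment == f).to_numpy() for f in range(folds)]


def train_nsc(matrix: GeneMatrix, labels: pd.Series,
              threshold_grid: np.ndarray | list[float] | None = None,
              folds: int = 10, seed: int = 0,
              m_variant: str = "minus", cv_rule: str = "margin",
              margin: float = 0.05) -> tuple[ShrunkenCentroidModel, pd.DataFrame]:
    """Fit the shrunken-centroid model and a cross-validated error table.

    ``threshold_grid`` defaults to 30 values spanning [0, max |d|]. The
    returned model is refit on all data at the CV-selected Δ. The error
    table has one row per Δ with per-class CV error, mean error and the
    surviving-gene count of the full-data fit at that Δ.

    ``cv_rule`` selects the prediction rule scored in cross-validation:
    ``"margin"`` (default) scores the deployed decision rule — Spearman
    correlation with the shrunken centroids and the margin cut, with an
    unclassified sample counting as an error — so over-shrinking, which
    collapses the margins, is penalized and the selected Δ keeps the
    informative genes; ``"discriminant"`` scores the standardized-distance
    rule instead.
    """
    if cv_rule not in ("margin", "discriminant"):
        raise InvalidArgumentError(f"unknown cv_rule {cv_rule!r}")
    values = matrix.values
    labels = labels.reindex(values.columns)
    if labels.isna().any():
        raise InvalidArgumentError("class label missing for some samples")
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise InvalidArgumentError("need at least 2 classes")
    for k in classes:
        if (labels == k).sum() < folds:
            raise InvalidArgumentError(f"class {k!r} smaller than fold count {folds}")

    base = _fit_centroids(values, labels, delta=0.0, m_variant=m_variant)
    if threshold_grid is None:
        denom = base.s + base.s0
        dmax = max(float((np.abs(base.centroids[k] - base.overall)
                          / (base.m[k] * denom)).max()) for k in classes)
        threshold_grid = np.linspace(0.0, dmax, 30)
    grid = [float(d) for d in threshold_grid]
    if not grid:
        raise InvalidArgumentError("empty threshold grid")

    rng = np.random.default_rng(seed)
    fold_masks = _stratified_folds(labels, folds, rng)

    errors = {d: {k: [0, 0] for k in classes} for d in grid}  # class -> [wrong, total]
    for mask in fold_masks:
        train_cols = values.columns[~mask]
        test_cols = values.columns[mask]
        if len(test_cols) == 0:
            continue
        test = GeneMatrix(values[test_cols], kind=matrix.kind)
        for d in grid:
            model = _fit_centroids(values[train_cols], labels[train_cols], d,
                                   m_variant=m_variant)
            if cv_rule == "margin":
                fold_calls = classify_margin(model, test, margin=margin)
                pred = pd.Series({c.sample_id: c.call for c in fold_calls})
            else:
                pred = model.predict(test)
            for sid in test_cols:
                truth = labels[sid]
                errors[d][truth][1] += 1
                if pred[sid] != truth:
                    errors[d][truth][0] += 1

    rows = []
    for d in grid:
        per_class = {k: errors[d][k][0] / errors[d][k][1] for k in classes}
        full = _fit_centroids(values, labels, d, m_variant=m_variant)
        rows.append({"delta": d, **{f"cv_error_{k}": per_class[k] for k in classes},
                     "mean_cv_error": float(np.mean(list(per_class.values()))),
                     "n_genes": len(full.surviving_genes)})
    cv_table = pd.DataFrame(rows)

    best = select_threshold(cv_table)
    model = _fit_centroids(values, labels, best, m_variant=m_variant)
    logger.info("NSC: selected delta=%.3f with %d surviving genes",
                best, len(model.surviving_genes))
    return model, cv_table


def select_threshold(cv_table: pd.DataFrame) -> float:
    """Δ minimizing mean per-class CV error; ties resolved toward larger Δ
    (fewer genes)."""
    if len(cv_table) == 0:
        raise InvalidArgumentError("empty CV table")
    best_err = cv_table["mean_cv_error"].min()
    candidates = cv_table.loc[cv_table["mean_cv_error"] == best_err, "delta"]
    return float(candidates.max())


def classify_margin(model: ShrunkenCentroidModel, sample_matrix: GeneMatrix,
                    margin: float = 0.05, use_shrunken: bool = True,
                    max_missing: float = 0.10) -> list[SubtypeCall]:
    """Margin-based class calls by Spearman correlation with class centroids.

    Correlations run over the surviving genes present in the sample matrix
    (at most ``max_missing`` of them may be absent); a sample is called for
    the class whose correlation exceeds the other's by at least ``margin``
    (inclusive), otherwise it is unclassified. ``use_shrunken=False``
    correlates against the raw class means over the surviving genes instead.
    """
    genes = model.surviving_genes
    centroids = model.shrunken if use_shrunken else model.centroids
    present = [g for g in genes if g in sample_matrix.values.index]
    if genes and len(present) < (1.0 - max_missing) * len(genes):
        raise InvalidArgumentError(
            f"sample matrix covers {len(present)}/{len(genes)} surviving genes; "
            f"more than {max_missing:.0%} missing")
    k_a, k_b = model.classes[0], model.classes[1]
    calls = []
    for sid in sample_matrix.values.columns:
        x = sample_matrix.values.loc[present, sid]
        usable = x.notna()
        if int(usable.sum()) < 3:
            calls.append(SubtypeCall(sid, np.nan, np.nan, "unclassified", np.nan))
            continue
        xv = x[usable]
        ca = float(stats.spearmanr(xv, centroids.loc[xv.index, k_a]).statistic)
        cb = float(stats.spearmanr(xv, centroids.loc[xv.index, k_b]).statistic)
        gap = abs(ca - cb)
        # inclusive boundary, robust to float representation of the gap
        if gap >= margin - 1e-12:
            call = k_a if ca > cb else k_b
        else:
            call = "unclassified"
        calls.append(SubtypeCall(sid, ca, cb, call, gap))
    return calls


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.sample_id, c.corr_ccA, c.corr_ccB, c.call, c.margin) for c in calls],
        columns=["sample_id", "corr_ccA", "corr_ccB", "call", "margin"])
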