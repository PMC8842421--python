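"""Multivariate analyses of the rating data.

PCA of per-image mean ratings, per-observer PCA on polychoric correlations,
per-observer 3-fold cross-validated logistic prediction of the observer's
own binary labels (with Wald-test attribute significance), significant-
attribute counting across folds, and seeded t-SNE embedding.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import multivariate_normal, norm
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold

from .core_data import ATTRIBUTES, DomainError, ParameterError, ResponsePanel


class DegeneracyError(ValueError):
    """Input is constant along a dimension that the analysis must scale."""


@dataclasses.dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame            # attribute x component
    scores: pd.DataFrame              # item x component
    explained_variance_ratio: np.ndarray
    standardized: bool = True
    psd_repaired: bool = False
    excluded_attributes: tuple = ()


@dataclasses.dataclass(frozen=True)
class PredictionResult:
    observer_id: str
    condition: str
    fold_accuracies: tuple
    significant_attributes_per_fold: tuple   # 3 frozensets of attribute names
    coefficients: tuple                      # 3 pandas Series (const + attrs)
    wald_reliable: tuple                     # per-fold bool
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclasses.dataclass(frozen=True)
class EmbeddingResult:
    coordinates: pd.DataFrame
    perplexity: float
    seed: int


def _fix_component_signs(loadings: np.ndarray, scores: Optional[np.ndarray]) -> tuple:
    """Flip each component so its largest-magnitude loading is positive."""
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
            if scores is not None:
                scores[:, k] = -scores[:, k]
    return loadings, scores


def pca_mean_ratings(mean_ratings: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of the image x attribute mean-rating table.

    With ``standardize`` the columns are z-scored first (the attributes share
    a 1-6 scale but standardizing keeps loadings comparable).  Components are
    sign-fixed deterministically.
    """
    attrs = [a for a in ATTRIBUTES if a in mean_ratings.columns]
    if len(attrs) != len(ATTRIBUTES):
        raise DomainError("mean ratings table must contain all 5 attributes")
    if len(mean_ratings) < len(attrs):
        raise DomainError("need at least 5 images")
    if mean_ratings[attrs].isna().any().any():
        raise DomainError("mean ratings table has missing cells")
    data = mean_ratings[attrs].to_numpy(float)
    if standardize:
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = attrs[int(np.argmax(sd == 0))]
            raise DegeneracyError(f"attribute {bad!r} has zero variance")
        data = (data - data.mean(axis=0)) / sd
    model = PCA(n_components=len(attrs))
    scores = model.fit_transform(data)
    loadings = model.components_.T.copy()
    loadings, scores = _fix_component_signs(loadings, scores)
    comp_names = [f"PC{k + 1}" for k in range(len(attrs))]
    return PCAResult(
        pd.DataFrame(loadings, index=attrs, columns=comp_names),
        pd.DataFrame(scores, index=mean_ratings.index, columns=comp_names),
        model.explained_variance_ratio_.copy(),
        standardized=standardize,
    )


# ---------------------------------------------------------------------------
# Polychoric correlation


def _thresholds(values: np.ndarray) -> np.ndarray:
    """Probit thresholds from the empirical marginal of an ordinal column."""
    levels, counts = np.unique(values, return_counts=True)
    cum = np.cumsum(counts)[:-1] / values.size
    return norm.ppf(cum)


def _bivariate_rect_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of a discretized bivariate normal with corr rho."""
    ax = np.concatenate([[-np.inf], tx, [np.inf]])
    ay = np.concatenate([[-np.inf], ty, [np.inf]])
    nx, ny = ax.size, ay.size
    cdf = np.zeros((nx, ny))
    # grid CDF with infinity edges handled via marginals
    cdf[-1, :] = norm.cdf(ay)
    cdf[:, -1] = norm.cdf(ax)
    cdf[-1, -1] = 1.0
    interior_x, interior_y = ax[1:-1], ay[1:-1]
    if interior_x.size and interior_y.size:
        gx, gy = np.meshgrid(interior_x, interior_y, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        cdf[1:-1, 1:-1] = mvn.cdf(pts).reshape(gx.shape)
    probs = (
        cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    )
    return np.clip(probs, 1e-12, None)


def polychoric_correlation(x, y) -> float:
    """Two-step ML polychoric correlation between two ordinal variables.

    Thresholds come from the empirical marginals; the latent correlation is
    then the pairwise maximum-likelihood estimate.  Perfectly concordant
    (discordant) pairs return +1 (-1) exactly.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size:
        raise DomainError("columns must have equal length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegeneracyError("each column needs at least 2 distinct levels")
    tau, _ = stats.kendalltau(x, y)
    if tau == 1.0:
        return 1.0
    if tau == -1.0:
        return -1.0
    tx, ty = _thresholds(x), _thresholds(y)
    xi = np.searchsorted(np.unique(x), x)
    yi = np.searchsorted(np.unique(y), y)
    table = np.zeros((np.unique(x).size, np.unique(y).size))
    np.add.at(table, (xi, yi), 1)

    def nll(rho: float) -> float:
        probs = _bivariate_rect_probs(tx, ty, rho)
        return -float(np.sum(table * np.log(probs)))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, tuple]:
    """Pairwise polychoric correlation matrix; single-level columns excluded."""
    usable, excluded = [], []
    for col in table.columns:
        (usable if np.unique(table[col]).size >= 2 else excluded).append(col)
    if excluded:
        warnings.warn(f"excluding single-level attributes: {excluded}")
    k = len(usable)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            corr[i, j] = corr[j, i] = polychoric_correlation(
                table[usable[i]].to_numpy(), table[usable[j]].to_numpy()
            )
    idx = pd.Index(usable)
    return pd.DataFrame(corr, idx, idx), tuple(excluded)


def polychoric_pca(observer_ratings: pd.DataFrame) -> PCAResult:
    """PCA eigendecomposition of the polychoric correlation matrix.

    Pairwise assembly can be indefinite; negative eigenvalues are clipped to
    zero and the repair is flagged.  Scores project the z-scored ordinal data
    onto the eigenvectors.
    """
    if len(observer_ratings) < 3:
        raise DomainError("need at least 3 images")
    corr, excluded = polychoric_matrix(observer_ratings)
    eigvals, eigvecs = np.linalg.eigh(corr.to_numpy())
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    repaired = bool(np.any(eigvals < -1e-10))
    eigvals = np.clip(eigvals, 0.0, None)
    data = observer_ratings[corr.index].to_numpy(float)
    sd = data.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (data - data.mean(axis=0)) / sd
    scores = z @ eigvecs
    loadings, scores = _fix_component_signs(eigvecs.copy(), scores)
    comp_names = [f"PC{k + 1}" for k in range(len(corr.index))]
    return PCAResult(
        pd.DataFrame(loadings, index=corr.index, columns=comp_names),
        pd.DataFrame(scores, index=observer_ratings.index, columns=comp_names),
        eigvals / eigvals.sum(),
        standardized=True,
        psd_repaired=repaired,
        excluded_attributes=excluded,
    )


# ---------------------------------------------------------------------------
# Logistic prediction of the observer's own binary labels


def _logistic_irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Newton/IRLS logistic fit; returns (beta, standard errors, converged).

    ``ridge`` adds an L2 penalty on the non-intercept coefficients, used as
    the fallback under (quasi-)separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    penalty = np.full(p, ridge)
    penalty[0] = 0.0  # intercept unpenalized
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - penalty * beta
        hess = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    hess = (X.T * w) @ X + np.diag(penalty)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return beta, se, converged


_SEPARATION_COEF = 30.0
_RIDGE_FALLBACK = 1.0


def predict_binary_from_ratings(
    ratings: pd.DataFrame,
    labels: pd.Series,
    observer_id: str = "",
    condition: str = "color",
    seed: int = 0,
    n_folds: int = 3,
    alpha: float = 0.05,
) -> PredictionResult:
    """3-fold stratified CV logistic prediction of one observer's labels.

    The model is unpenalized maximum likelihood on the five ratings with an
    intercept; per-fold Wald tests at ``alpha`` pick the significant
    attributes from the training-fold fit.  Detected separation (huge or
    non-converged coefficients) triggers a small-ridge refit and marks that
    fold's Wald tests unreliable.
    """
    attrs = list(ATTRIBUTES)
    ratings = ratings[attrs]
    labels = labels.loc[ratings.index]
    y = labels.to_numpy(float)
    if len(ratings) < 30:
        raise DomainError(f"observer {observer_id!r}: needs >= 30 rated+labeled images")
    if np.unique(y).size < 2:
        raise DegeneracyError(f"observer {observer_id!r}: single-class labels")
    X = np.column_stack([np.ones(len(ratings)), ratings.to_numpy(float)])
    names = ["const"] + attrs

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracies, sig_sets, coefs, reliable = [], [], [], []
    for train, test in skf.split(X, y):
        beta, se, converged = _logistic_irls(X[train], y[train], ridge=0.0)
        ok = converged and np.max(np.abs(beta)) < _SEPARATION_COEF and np.isfinite(se).all()
        if not ok:
            beta, se, _ = _logistic_irls(X[train], y[train], ridge=_RIDGE_FALLBACK)
        with np.errstate(divide="ignore", invalid="ignore"):
            zvals = beta / se
        pvals = 2 * norm.sf(np.abs(zvals))
        sig = frozenset(a for a, p in zip(names[1:], pvals[1:]) if p < alpha)
        pred = (X[test] @ beta) > 0
        accuracies.append(float(np.mean(pred == (y[test] > 0.5))))
        sig_sets.append(sig)
        coefs.append(pd.Series(beta, index=names))
        reliable.append(bool(ok))
    return PredictionResult(
        observer_id,
        condition,
        tuple(accuracies),
        tuple(sig_sets),
        tuple(coefs),
        tuple(reliable),
        seed,
    )


def predict_all_observers(panel: ResponsePanel, seed: int = 0) -> tuple[list, list]:
    """Run the per-observer prediction for every observer with rating data.

    Returns (results, skipped) where ``skipped`` lists (observer, reason)
    for single-class or under-sampled observers.
    """
    results, skipped = [], []
    rated = sorted(set(panel.ratings["observer_id"]))
    for obs in rated:
        table, labels = panel.observer_slice(obs)
        try:
            results.append(
                predict_binary_from_ratings(table, labels, obs, panel.condition, seed)
            )
        except (DegeneracyError, DomainError) as exc:
            skipped.append((obs, str(exc)))
    return results, skipped


def significant_attribute_counts(results: Sequence[PredictionResult]) -> dict:
    """Per attribute: observer counts per fold, their median, and max-min."""
    if not results:
        raise DomainError("need at least one prediction result")
    n_folds = len(results[0].significant_attributes_per_fold)
    summary = {}
    for attr in ATTRIBUTES:
        per_fold = [
            sum(attr in r.significant_attributes_per_fold[k] for r in results)
            for k in range(n_folds)
        ]
        summary[attr] = {
            "per_fold": per_fold,
            "median": float(np.median(per_fold)),
            "range": int(max(per_fold) - min(per_fold)),
        }
    return summary


def tsne_embed(features: pd.DataFrame, perplexity: float = 15.0, seed: int = 0) -> EmbeddingResult:
    """Seeded 2-D t-SNE of an item x feature table."""
    if len(features) < 3 * perplexity:
        raise ParameterError(
            f"need at least {int(3 * perplexity)} rows for perplexity {perplexity}"
        )
    model = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    coords = model.fit_transform(features.to_numpy(float))
    return EmbeddingResult(
        pd.DataFrame(coords, index=features.index, columns=["dim1", "dim2"]),
        perplexity,
        seed,
    )
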