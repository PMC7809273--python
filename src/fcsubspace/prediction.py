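"""Connectome-based prediction of clinical scores with elastic net.

The predictive procedure per training fold is: (1) nuisance-regress the
score on demographic covariates (coefficients estimated on the training
fold only and applied to the test fold), (2) select the fraction of edges
whose Fisher-z values correlate most strongly (positively or negatively)
with the residualized score, (3) standardize the selected features with
training statistics, (4) tune the elastic-net mixing alpha and penalty
lambda by inner leave-one-out cross-validation on a per-fold grid, and
(5) fit the final model. Evaluation designs: outer leave-one-out over a
cohort, the leave-one-out bootstrap (out-of-bag scoring over B resampled
training sets), and cross-group designs that train on one cohort's
bootstrap draw and test on subjects sampled without replacement from the
other cohort.

The elastic-net objective is (1/2n)||y - b0 - Xb||^2 +
lambda [alpha ||b||_1 + (1-alpha)/2 ||b||_2^2], which maps onto
scikit-learn's ElasticNet with ``alpha=lambda`` and ``l1_ratio=alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path
from statsmodels.stats.multitest import multipletests

from .connectivity import EdgeVector

__all__ = [
    "PredictionSpec",
    "PredictionResult",
    "BootstrapPredictionResult",
    "JaccardResult",
    "ConnectomePredictor",
    "nuisance_regress",
    "select_features",
    "fit_elastic_net",
    "tune_hyperparameters",
    "loo_predict",
    "loo_bootstrap",
    "cross_group_predict",
    "compare_accuracy_distributions",
    "compare_accuracy_battery",
    "jaccard_overlap",
    "overlap_with_reference",
]


@dataclass
class PredictionSpec:
    """Settings for the nested elastic-net procedure.

    ``feature_fraction`` keeps the top fraction of edges by |r| with the
    residualized score (default 0.5). The mixing grid spans 0.1..1.0 and the
    penalty grid is ``n_lambdas`` values log-spaced from the per-fold
    lasso threshold lambda_max = max|X^T(y - ybar)|/n down to
    ``lambda_min_ratio * lambda_max``.
    """

    feature_fraction: float = 0.5
    alpha_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    n_lambdas: int = 50
    lambda_min_ratio: float = 1e-3
    nuisance_covariates: tuple[str, ...] = ("age", "sex", "education")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.feature_fraction <= 1):
            raise ValueError("feature_fraction must be in (0, 1]")
        if not self.alpha_grid or any(not (0 <= a <= 1) for a in self.alpha_grid):
            raise ValueError("alpha_grid values must lie in [0, 1]")
        if self.n_lambdas < 1:
            raise ValueError("n_lambdas must be >= 1")


@dataclass
class PredictionResult:
    predicted: np.ndarray
    observed: np.ndarray  # residualized observed scores, per held-out subject
    accuracy: float  # Pearson r(predicted, observed)
    prediction_r2: float  # 1 - SSE/SST, SST about the mean observed residual


@dataclass
class BootstrapPredictionResult:
    """B replicate accuracies/R^2 plus per-edge selection counts.

    ``edge_weights[e]`` counts the replicates in which edge e was both
    selected and assigned a nonzero elastic-net coefficient; weights are
    integers bounded by the number of replicates.
    """

    B: int
    accuracies: np.ndarray
    r2s: np.ndarray
    edge_weights: np.ndarray


@dataclass
class JaccardResult:
    threshold_fraction: float
    set_a: frozenset
    set_b: frozenset
    overlap: int
    union: int
    index: float


# ---------------------------------------------------------------------------
# fold-level operations


def nuisance_regress(train_scores, train_covariates, test_scores=None, test_covariates=None):
    """Residualize scores on (intercept + covariates), train-fit only.

    Returns (train_residuals, test_residuals, coefficients); test residuals
    use the training-fold coefficients, never test statistics.
    """
    y = np.asarray(train_scores, dtype=float)
    c = np.atleast_2d(np.asarray(train_covariates, dtype=float))
    if c.shape[0] != y.size:
        c = c.T
    # constant columns carry no information beyond the intercept; keep the
    # design full rank without rejecting e.g. an all-zero placeholder column
    informative = np.ptp(c, axis=0) > 0
    design = np.column_stack([np.ones(y.size), c[:, informative]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"covariate design is rank deficient (rank {rank} < {design.shape[1]} columns)"
        )
    beta_kept, *_ = np.linalg.lstsq(design, y, rcond=None)
    # full-length coefficients (zeros for dropped columns) so the same vector
    # applies to any test design with the original column layout
    beta = np.zeros(1 + c.shape[1])
    beta[0] = beta_kept[0]
    beta[1:][informative] = beta_kept[1:]
    res_train = y - np.column_stack([np.ones(y.size), c]) @ beta
    res_test = None
    if test_scores is not None:
        yt = np.atleast_1d(np.asarray(test_scores, dtype=float))
        ct = np.atleast_2d(np.asarray(test_covariates, dtype=float))
        if ct.shape[0] != yt.size:
            ct = ct.T
        res_test = yt - np.column_stack([np.ones(yt.size), ct]) @ beta
    return res_train, res_test, beta


def select_features(train_edges: np.ndarray, train_scores: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the top ceil(fraction*E) edges by |Pearson r| with the score.

    Ties break toward the lower edge index. ``train_edges`` is subjects x E.
    """
    x = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training subjects for feature ranking")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * math.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    n_keep = int(np.ceil(fraction * x.shape[1]))
    # stable sort on -|r| keeps lower indices first among ties
    order = np.argsort(-np.abs(r), kind="stable")
    return np.sort(order[:n_keep])


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_elastic_net(x: np.ndarray, y: np.ndarray, alpha: float, lam: float):
    """Elastic net at one (alpha, lambda); X standardized with train stats.

    Returns (coef on the standardized scale, intercept, (mu, sd)) so
    predictions are ``(x_new - mu)/sd @ coef + intercept``.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mu, sd = _standardize_fit(x)
    xs = (x - mu) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=5000)
        model.fit(xs, y)
    return model.coef_.copy(), float(model.intercept_), (mu, sd)


def _lambda_grid(xs: np.ndarray, y: np.ndarray, spec: PredictionSpec) -> np.ndarray:
    n = xs.shape[0]
    lam_max = np.max(np.abs(xs.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, spec.lambda_min_ratio * lam_max, spec.n_lambdas)


def tune_hyperparameters(
    train_edges: np.ndarray, train_scores: np.ndarray, spec: PredictionSpec
) -> tuple[float, float]:
    """Grid search minimizing inner leave-one-out MSE.

    The lambda grid is built once from the full training fold; each inner
    fold re-standardizes with its own statistics. Ties prefer smaller alpha,
    then larger lambda (the sparser model).
    """
    x = np.asarray(train_edges, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 training subjects for inner-loop tuning")
    mu, sd = _standardize_fit(x)
    lam_grid = _lambda_grid((x - mu) / sd, y, spec)
    alphas = sorted(spec.alpha_grid)
    sq_err = np.zeros((len(alphas), len(lam_grid)))
    for i in range(n):
        tr = np.arange(n) != i
        xt, yt = x[tr], y[tr]
        mu_i, sd_i = _standardize_fit(xt)
        xs = (xt - mu_i) / sd_i
        yc = yt - yt.mean()
        xv = (x[i] - mu_i) / sd_i
        for ai, a in enumerate(alphas):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    xs, yc, l1_ratio=max(a, 1e-3), alphas=lam_grid, max_iter=2000
                )
            preds = xv @ coefs + yt.mean()
            sq_err[ai] += (preds - y[i]) ** 2
    mse = sq_err / n
    # preference order: lower MSE, then smaller alpha, then larger lambda.
    # lam_grid is descending, so plain argmin over the flattened row-major
    # array realizes the tie-break exactly.
    ai, li = np.unravel_index(np.argmin(mse), mse.shape)
    return float(alphas[ai]), float(lam_grid[li])


class ConnectomePredictor(RegressorMixin, BaseEstimator):
    """Elastic-net connectome model for one training fold.

    ``fit(X, y, covariates=...)`` runs the full training-side procedure
    (nuisance regression, feature selection, standardization, inner-LOO
    tuning, final elastic-net fit) using the training data only.
    ``predict(X)`` returns predicted residualized scores;
    ``residualize(y, covariates)`` applies the stored nuisance coefficients
    so held-out observations can be scored on the same scale.
    """

    def __init__(self, spec: PredictionSpec | None = None):
        self.spec = spec

    def fit(self, X, y, covariates=None):
        spec = self.spec if self.spec is not None else PredictionSpec()
        x = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if np.ptp(yv) == 0:
            raise ValueError("training scores are constant; prediction undefined")
        if covariates is not None:
            y_res, _, beta = nuisance_regress(yv, covariates)
        else:
            y_res, beta = yv - yv.mean(), np.array([yv.mean()])
        self.nuisance_coef_ = beta
        self.selected_ = select_features(x, y_res, spec.feature_fraction)
        xs = x[:, self.selected_]
        self.alpha_, self.lambda_ = tune_hyperparameters(xs, y_res, spec)
        self.coef_, self.intercept_, (self.mu_, self.sd_) = fit_elastic_net(
            xs, y_res, self.alpha_, self.lambda_
        )
        self.n_features_in_ = x.shape[1]
        return self

    def predict(self, X):
        x = np.atleast_2d(np.asarray(X, dtype=float))
        xs = (x[:, self.selected_] - self.mu_) / self.sd_
        return xs @ self.coef_ + self.intercept_

    def residualize(self, y, covariates=None):
        yv = np.atleast_1d(np.asarray(y, dtype=float))
        if covariates is None or self.nuisance_coef_.size == 1:
            return yv - self.nuisance_coef_[0] if self.nuisance_coef_.size == 1 else yv
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != yv.size:
            c = c.T
        return yv - np.column_stack([np.ones(yv.size), c]) @ self.nuisance_coef_

    def active_edges(self) -> np.ndarray:
        """Edge indices selected AND carrying a nonzero coefficient."""
        return self.selected_[self.coef_ != 0]


# ---------------------------------------------------------------------------
# evaluation drivers


def _edges_matrix(edges) -> np.ndarray:
    if isinstance(edges, np.ndarray):
        return edges
    return np.vstack([e.values if isinstance(e, EdgeVector) else np.asarray(e) for e in edges])


def _score(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    if np.std(pred) == 0 or np.std(obs) == 0:
        acc = 0.0
    else:
        acc = float(np.corrcoef(pred, obs)[0, 1])
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else -np.inf
    return acc, r2


def loo_predict(cohort_edges, scores, covariates=None, spec: PredictionSpec | None = None) -> PredictionResult:
    """Outer leave-one-out nested cross-validation over one cohort."""
    spec = spec or PredictionSpec()
    x = _edges_matrix(cohort_edges)
    y = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects for leave-one-out evaluation")
    if np.ptp(y) == 0:
        raise ValueError("scores are constant; nothing to predict")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    preds = np.empty(n)
    obs = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        try:
            model = ConnectomePredictor(spec).fit(
                x[tr], y[tr], covariates=None if cov is None else cov[tr]
            )
        except Exception as exc:  # noqa: BLE001 - annotate fold, re-raise
            raise RuntimeError(f"training failed in fold {i}: {exc}") from exc
        preds[i] = model.predict(x[i][None, :])[0]
        obs[i] = model.residualize(y[i], None if cov is None else cov[i][None, :])[0]
    acc, r2 = _score(preds, obs)
    return PredictionResult(predicted=preds, observed=obs, accuracy=acc, prediction_r2=r2)


def loo_bootstrap(
    cohort_edges,
    scores,
    covariates=None,
    spec: PredictionSpec | None = None,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> BootstrapPredictionResult:
    """Leave-one-out bootstrap: out-of-bag scoring over B resampled draws.

    Each replicate draws n subjects with replacement, trains the full nested
    procedure on the unique members of the draw, and scores the out-of-bag
    subjects (replicates with fewer than 3 OOB subjects are redrawn).
    """
    spec = spec or PredictionSpec()
    if B < 100:
        raise ValueError("B must be at least 100")
    x = _edges_matrix(cohort_edges)
    y = np.asarray(scores, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(B)
    r2s = np.empty(B)
    weights = np.zeros(x.shape[1], dtype=int)
    max_draws = 50 * B
    drawn = 0
    for b in range(B):
        while True:
            if drawn >= max_draws:
                raise RuntimeError("bootstrap redraw budget exhausted; n too small")
            drawn += 1
            draw = rng.integers(0, n, size=n)
            train_idx = np.unique(draw)
            oob = np.setdiff1d(np.arange(n), train_idx)
            if oob.size >= 3 and train_idx.size >= 4 and np.ptp(y[train_idx]) > 0:
                break
        model = ConnectomePredictor(spec).fit(
            x[train_idx], y[train_idx], covariates=None if cov is None else cov[train_idx]
        )
        preds = model.predict(x[oob])
        obs = model.residualize(y[oob], None if cov is None else cov[oob])
        accs[b], r2s[b] = _score(preds, obs)
        weights[model.active_edges()] += 1
    return BootstrapPredictionResult(B=B, accuracies=accs, r2s=r2s, edge_weights=weights)


def cross_group_predict(
    train_edges,
    train_scores,
    test_edges,
    test_scores,
    train_covariates=None,
    test_covariates=None,
    spec: PredictionSpec | None = None,
    B: int = 1000,
    m: int | None = None,
    seed: int | np.random.Generator = 0,
) -> BootstrapPredictionResult:
    """Train on bootstrap draws of one cohort, test on the other cohort.

    Per replicate, m test subjects are sampled without replacement from the
    test cohort (default m = max(3, ceil(n_test/3))) and scored against
    predictions from the replicate's trained model. Test scores are
    residualized with the training fold's nuisance coefficients.
    """
    spec = spec or PredictionSpec()
    xt = _edges_matrix(train_edges)
    yt = np.asarray(train_scores, dtype=float)
    xs = _edges_matrix(test_edges)
    ys = np.asarray(test_scores, dtype=float)
    if xt.shape[0] == 0 or xs.shape[0] == 0:
        raise ValueError("both cohorts must be nonempty")
    n_tr, n_te = xt.shape[0], xs.shape[0]
    if m is None:
        m = max(3, int(np.ceil(n_te / 3)))
    if m > n_te:
        raise ValueError(f"m={m} exceeds test cohort size {n_te}")
    ctr = None if train_covariates is None else np.asarray(train_covariates, dtype=float)
    cte = None if test_covariates is None else np.asarray(test_covariates, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    accs = np.empty(B)
    r2s = np.empty(B)
    weights = np.zeros(xt.shape[1], dtype=int)
    for b in range(B):
        while True:
            draw = np.unique(rng.integers(0, n_tr, size=n_tr))
            if draw.size >= 4 and np.ptp(yt[draw]) > 0:
                break
        model = ConnectomePredictor(spec).fit(
            xt[draw], yt[draw], covariates=None if ctr is None else ctr[draw]
        )
        test_idx = rng.choice(n_te, size=m, replace=False)
        preds = model.predict(xs[test_idx])
        obs = model.residualize(ys[test_idx], None if cte is None else cte[test_idx])
        accs[b], r2s[b] = _score(preds, obs)
        weights[model.active_edges()] += 1
    return BootstrapPredictionResult(B=B, accuracies=accs, r2s=r2s, edge_weights=weights)


# ---------------------------------------------------------------------------
# distribution comparison and overlap


def compare_accuracy_distributions(d1, d2, sided: str = "two-sided") -> dict:
    """Welch t-test between two accuracy distributions plus one-sample tests.

    Bootstrap replicates are dependent, so these p-values are
    anti-conservative; they replicate the evaluation protocol rather than
    claiming exact calibration.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size < 2 or d2.size < 2:
        raise ValueError("need at least 2 values per distribution")
    t, p = stats.ttest_ind(d1, d2, equal_var=False, alternative=sided)
    t1, p1 = stats.ttest_1samp(d1, 0.0)
    t2, p2 = stats.ttest_1samp(d2, 0.0)
    return {
        "t": float(t),
        "p": float(p),
        "mean_diff": float(d1.mean() - d2.mean()),
        "one_sample": {"d1": (float(t1), float(p1)), "d2": (float(t2), float(p2))},
    }


def compare_accuracy_battery(named_pairs: dict, sided: str = "two-sided") -> dict:
    """Run a battery of comparisons with BH-FDR across their p-values."""
    results = {name: compare_accuracy_distributions(a, b, sided) for name, (a, b) in named_pairs.items()}
    names = list(results)
    _, q, _, _ = multipletests([results[n]["p"] for n in names], method="fdr_bh")
    for name, qv in zip(names, q):
        results[name]["q"] = float(qv)
    return results


def _top_weighted(weights: np.ndarray, fraction: float) -> frozenset:
    pos = np.flatnonzero(weights > 0)
    if pos.size == 0:
        return frozenset()
    n_keep = int(np.ceil(fraction * pos.size))
    order = pos[np.argsort(-weights[pos], kind="stable")]
    return frozenset(order[:n_keep].tolist())


def jaccard_overlap(weights_a, weights_b, threshold_fraction: float) -> JaccardResult:
    """Jaccard index of the top-weighted edge sets of two groups.

    Within each group, positive-weight edges are ranked by weight (ties
    toward the lower edge index) and the top ``threshold_fraction`` kept;
    at fraction 1.0 all positive-weight edges enter. JI = |A∩B| / |A∪B|.
    """
    wa = np.asarray(weights_a, dtype=float)
    wb = np.asarray(weights_b, dtype=float)
    if wa.size != wb.size:
        raise ValueError("edge counts differ")
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    sa = _top_weighted(wa, threshold_fraction)
    sb = _top_weighted(wb, threshold_fraction)
    union = len(sa | sb)
    overlap = len(sa & sb)
    if union == 0:
        warnings.warn("both edge sets empty; Jaccard index defined as 0")
        ji = 0.0
    else:
        ji = overlap / union
    return JaccardResult(
        threshold_fraction=threshold_fraction,
        set_a=sa,
        set_b=sb,
        overlap=overlap,
        union=union,
        index=ji,
    )


def overlap_with_reference(selected_set, reference_set) -> float:
    """|selected ∩ reference| / |reference| as a percentage."""
    ref = set(reference_set)
    if not ref:
        raise ValueError("reference set is empty")
    return 100.0 * len(set(selected_set) & ref) / len(ref)
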