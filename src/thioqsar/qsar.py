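"""MLR fitting, GA descriptor selection and the model-validation battery.

The workflow mirrors standard small-n QSAR practice: split compounds ~80/20
into training and prediction sets, search descriptor subsets of fixed size
with a genetic algorithm whose fitness is the leave-one-out cross-validated
determination coefficient Q^2_LOO = 1 - PRESS/SS_tot, then report internal
(R^2, Q^2_cv, CCC, AIC/BIC, y-scrambling) and external (Q^2_F1/F2/F3, CCC_ex,
origin slopes k/k', r^2_m) validation statistics for the selected model.

LOO residuals are computed with the hat-matrix identity e_i/(1-h_ii), which
is algebraically exact for OLS and equal to n explicit refits (tested as
such against a brute-force oracle).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np


class FitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Ordinary least squares
# ---------------------------------------------------------------------------


@dataclass
class RegressionModel:
    """Linear model: intercept + sum(coefficients * named descriptors)."""

    descriptor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    n_train: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "n_train": self.n_train,
        }


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def fit_mlr(
    X: np.ndarray, y: np.ndarray, names: Optional[Sequence[str]] = None
) -> RegressionModel:
    """Least-squares fit of y on X with intercept.

    Raises on rank deficiency, naming the collinear columns.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise FitError(f"need n > p + 1 rows (got n={n}, p={p})")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    variances = X.var(axis=0)
    zero_var = [names[j] for j in np.nonzero(variances == 0)[0]]
    if zero_var:
        raise FitError(f"zero-variance columns: {zero_var}")
    A = _design(X)
    if np.linalg.matrix_rank(A) < p + 1:
        # identify an offending column via pairwise correlation
        C = np.corrcoef(X, rowvar=False)
        bad = [
            (names[i], names[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(C[i, j]) > 1 - 1e-10
        ]
        raise FitError(f"design matrix is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return RegressionModel(
        descriptor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        n_train=n,
    )


def coefficient_standard_errors(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS standard errors of the slope coefficients (intercept excluded)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    A = _design(X)
    n, k = A.shape
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(A.T @ A)
    return np.sqrt(np.diag(cov))[1:]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _loo_press(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    A = _design(X)
    n, k = A.shape
    if n < k + 1:
        raise FitError(f"LOO needs n >= p + 2 (got n={n}, p={k - 1})")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # hat diagonal via solves (cheap at QSAR scale)
    AtA_inv = np.linalg.pinv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", A, AtA_inv, A)
    h = np.clip(h, None, 1 - 1e-12)
    press_resid = resid / (1.0 - h)
    return float(press_resid @ press_resid), press_resid


def loo_q2(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out Q^2 = 1 - PRESS/SS_tot."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitError("y has zero variance; Q^2 undefined")
    press, _ = _loo_press(np.asarray(X, dtype=float), y)
    return 1.0 - press / ss_tot


# ---------------------------------------------------------------------------
# External validation metrics
# ---------------------------------------------------------------------------


def concordance_ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    vy, vh = y.var(), yhat.var()
    if vy == 0 and vh == 0:
        raise FitError("CCC undefined: both vectors are constant")
    cov = ((y - y.mean()) * (yhat - yhat.mean())).mean()
    return float(2 * cov / (vy + vh + (y.mean() - yhat.mean()) ** 2))


def external_metrics(
    model: RegressionModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    y_train: np.ndarray,
) -> dict[str, float]:
    """External predictivity battery on a held-out set.

    Q^2_F1 normalizes squared prediction error by deviation from the training
    mean, Q^2_F2 by the test mean, Q^2_F3 by per-observation training
    variance. k and k' are the through-origin regression slopes of yhat on y
    and of y on yhat; R2_ext is the squared Pearson correlation.
    """
    y_test = np.asarray(y_test, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    if len(y_test) == 0:
        raise FitError("empty test set")
    yhat = model.predict(X_test)
    press = float(((y_test - yhat) ** 2).sum())
    n_ext, n_tr = len(y_test), len(y_train)
    ss_train_mean = float(((y_test - y_train.mean()) ** 2).sum())
    ss_test_mean = float(((y_test - y_test.mean()) ** 2).sum())
    ss_tr = float(((y_train - y_train.mean()) ** 2).sum())
    if ss_test_mean == 0:
        raise FitError("test responses have zero variance; Q^2_F2/CCC undefined")
    denom_y2 = float((y_test**2).sum())
    denom_yhat2 = float((yhat**2).sum())
    cross = float((y_test * yhat).sum())
    r = np.corrcoef(y_test, yhat)[0, 1] if yhat.var() > 0 else float("nan")
    return {
        "Q2F1": 1.0 - press / ss_train_mean,
        "Q2F2": 1.0 - press / ss_test_mean,
        "Q2F3": 1.0 - (press / n_ext) / (ss_tr / n_tr),
        "CCC_ex": concordance_ccc(y_test, yhat),
        "RMSE_ex": math.sqrt(press / n_ext),
        "MSE_ex": press / n_ext,
        "MAE_ex": float(np.abs(y_test - yhat).mean()),
        "PRESS_ex": press,
        "k": cross / denom_y2 if denom_y2 > 0 else float("nan"),
        "k_prime": cross / denom_yhat2 if denom_yhat2 > 0 else float("nan"),
        "R2_ext": float(r**2),
    }


def rm2_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Roy's modified-r^2 pair: r^2_m = r^2 (1 - sqrt(r^2 - r^2_0)).

    Computed in both regression directions (observed~predicted and the
    reverse), where r^2_0 is the through-origin determination coefficient.
    A numerically negative r^2 - r^2_0 is clamped at zero.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) < 3:
        raise FitError("r^2_m needs at least 3 points")

    def one_direction(y: np.ndarray, x: np.ndarray) -> float:
        r2 = float(np.corrcoef(y, x)[0, 1] ** 2)
        k = float((x * y).sum() / (x * x).sum())
        ss_res0 = float(((y - k * x) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2_0 = 1.0 - ss_res0 / ss_tot
        return r2 * (1.0 - math.sqrt(max(r2 - r2_0, 0.0)))

    rm2_fwd = one_direction(y_obs, y_pred)
    rm2_rev = one_direction(y_pred, y_obs)
    return {
        "r2m_fwd": rm2_fwd,
        "r2m_rev": rm2_rev,
        "r2m_avg": 0.5 * (rm2_fwd + rm2_rev),
        "r2m_delta": abs(rm2_fwd - rm2_rev),
    }


def y_scrambling(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int,
    seed: int = 0,
    identity_first: bool = False,
) -> float:
    """Mean training R^2 over refits to permuted responses.

    Under the null (no structure) the expectation is ~ p/(n-1). With
    ``identity_first`` the first "permutation" is the identity, a diagnostic
    hook that reduces to the unscrambled R^2 at n_permutations=1.
    """
    if n_permutations < 1:
        raise FitError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    r2s = []
    for i in range(n_permutations):
        yp = y if (identity_first and i == 0) else rng.permutation(y)
        m = fit_mlr(X, yp)
        resid = yp - m.predict(X)
        ss_tot = ((yp - yp.mean()) ** 2).sum()
        r2s.append(1.0 - (resid @ resid) / ss_tot)
    return float(np.mean(r2s))


# ---------------------------------------------------------------------------
# Train/test split and descriptor pre-filtering
# ---------------------------------------------------------------------------


def split_train_test(
    n: int, train_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint exhaustive split; train size = round(fraction * n)."""
    if not (0 < train_fraction < 1):
        raise FitError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise FitError(f"degenerate split: {n_train}/{n - n_train}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def prefilter_descriptors(
    X: np.ndarray, corr_threshold: float = 0.95
) -> np.ndarray:
    """Indices of columns kept after dropping zero-variance columns and one
    of each pair with |r| > threshold (the earlier column is kept)."""
    X = np.asarray(X, dtype=float)
    keep = np.nonzero(X.var(axis=0) > 0)[0]
    if len(keep) < 2:
        return keep
    C = np.corrcoef(X[:, keep], rowvar=False)
    selected: list[int] = []
    for pos, col in enumerate(keep):
        if all(abs(C[pos, q]) <= corr_threshold for q in range(len(keep))
               if keep[q] in selected):
            selected.append(col)
    return np.array(selected, dtype=int)


# ---------------------------------------------------------------------------
# Genetic algorithm subset selection
# ---------------------------------------------------------------------------


@dataclass
class GAParams:
    population: int = 50
    generations: int = 200
    tournament: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    elitism: int = 2
    #: steepest-ascent single-column refinement of the final best subset,
    #: iterated to a local optimum (memetic finishing step; deterministic)
    local_search: bool = True


def loo_q2_batch(X: np.ndarray, y: np.ndarray, subsets: Sequence[tuple[int, ...]]
                 ) -> np.ndarray:
    """Vectorized LOO Q^2 for many equal-size column subsets at once.

    Same hat-matrix identity as :func:`loo_q2`, solved as one batched linear
    system; ill-conditioned subsets come back as -inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    k = len(subsets[0])
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitError("y has zero variance; Q^2 undefined")
    idx = np.asarray(subsets, dtype=int)  # (m, k)
    A = np.empty((len(idx), n, k + 1))
    A[:, :, 0] = 1.0
    A[:, :, 1:] = X[:, idx].transpose(1, 0, 2)
    At = A.transpose(0, 2, 1)
    AtA = At @ A
    AtA_inv = np.linalg.pinv(AtA, hermitian=True)
    beta = AtA_inv @ (At @ y[None, :, None])
    resid = y[None, :] - (A @ beta)[:, :, 0]
    h = np.einsum("bnk,bkl,bnl->bn", A, AtA_inv, A)
    ill = h.max(axis=1) > 1 - 1e-9
    h = np.clip(h, None, 1 - 1e-12)
    press = ((resid / (1.0 - h)) ** 2).sum(axis=1)
    q2 = 1.0 - press / ss_tot
    q2[ill | ~np.isfinite(q2)] = -np.inf
    return q2


def _eval_subsets(X: np.ndarray, y: np.ndarray,
                  subsets: Sequence[tuple[int, ...]], cache: dict) -> np.ndarray:
    """Cached batch fitness evaluation."""
    fresh = [s for s in set(subsets) if s not in cache]
    if fresh:
        for s, q2 in zip(fresh, loo_q2_batch(X, y, fresh)):
            cache[s] = float(q2)
    return np.array([cache[s] for s in subsets])


def _n_subsets(pool_size: int, k: int) -> int:
    return math.comb(pool_size, k)


def _repair(genes: np.ndarray, pool: np.ndarray, rng) -> tuple[int, ...]:
    """Make genes distinct, filling duplicates from the pool."""
    uniq = list(dict.fromkeys(int(g) for g in genes))
    while len(uniq) < len(genes):
        cand = int(rng.choice(pool))
        if cand not in uniq:
            uniq.append(cand)
    return tuple(sorted(uniq))


def ga_select(
    X: np.ndarray,
    y: np.ndarray,
    model_size: int,
    ga: Optional[GAParams] = None,
    seed: int = 0,
    names: Optional[Sequence[str]] = None,
    prefilter: bool = True,
    corr_threshold: float = 0.95,
) -> tuple[tuple[int, ...], RegressionModel, float]:
    """GA search for the descriptor subset maximizing Q^2_LOO.

    Returns (column indices into the original X, fitted model, Q^2). Subsets
    are fixed-size index tuples; selection is tournament, crossover is
    one-point with duplicate repair, mutation replaces genes with random
    unused columns, and the elite carry over unchanged. Deterministic per
    seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if model_size >= n - 2:
        raise FitError(f"model_size {model_size} too large for n={n}")
    pool = prefilter_descriptors(X, corr_threshold) if prefilter else np.arange(p)
    if len(pool) < model_size:
        raise FitError(
            f"only {len(pool)} candidate descriptors for model_size {model_size}"
        )
    ga = ga or GAParams()
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, ...], float] = {}

    def random_individual() -> tuple[int, ...]:
        return tuple(sorted(int(i) for i in rng.choice(pool, model_size, replace=False)))

    popn: list[tuple[int, ...]] = []
    seen_init: set[tuple[int, ...]] = set()
    while len(popn) < ga.population:
        ind = random_individual()
        if ind not in seen_init or len(seen_init) >= _n_subsets(len(pool), model_size):
            popn.append(ind)
            seen_init.add(ind)
    fits = _eval_subsets(X, y, popn, cache)

    for _ in range(ga.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [popn[i] for i in order[: ga.elitism]]
        members = set(new_pop)
        while len(new_pop) < ga.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(popn), ga.tournament)
                parents.append(popn[contenders[np.argmax(fits[contenders])]])
            a, b = (np.array(parents[0]), np.array(parents[1]))
            if rng.random() < ga.crossover_rate and model_size > 1:
                cut = int(rng.integers(1, model_size))
                child = np.concatenate([a[:cut], b[cut:]])
            else:
                child = a.copy()
            mutate = rng.random(model_size) < ga.mutation_rate
            for gpos in np.nonzero(mutate)[0]:
                child[gpos] = int(rng.choice(pool))
            ind = _repair(child, pool, rng)
            # keep the population a set of distinct subsets: duplicates waste
            # evaluations and collapse diversity at this tiny scale
            for _ in range(20):
                if ind not in members:
                    break
                gpos = int(rng.integers(model_size))
                replaced = np.array(ind)
                replaced[gpos] = int(rng.choice(pool))
                ind = _repair(replaced, pool, rng)
            members.add(ind)
            new_pop.append(ind)
        popn = new_pop
        fits = _eval_subsets(X, y, popn, cache)

    best = popn[int(np.argmax(fits))]
    best_q2 = float(np.max(fits))

    if ga.local_search:
        # steepest-ascent single-column refinement from the distinct top
        # individuals; each sweep is one batched evaluation
        order = np.argsort(fits)[::-1]
        starts = list(dict.fromkeys(popn[i] for i in order))
        for start in starts:
            cur, cur_q2 = start, cache[start]
            improved = True
            while improved:
                neighborhood = [
                    tuple(sorted(set(cur) - {g}) + [int(c)])
                    for g in cur
                    for c in pool
                    if int(c) not in cur
                ]
                neighborhood = [tuple(sorted(s)) for s in neighborhood]
                if not neighborhood:
                    break
                q2s = _eval_subsets(X, y, neighborhood, cache)
                j = int(np.argmax(q2s))
                improved = q2s[j] > cur_q2 + 1e-12
                if improved:
                    cur, cur_q2 = neighborhood[j], float(q2s[j])
            if cur_q2 > best_q2:
                best, best_q2 = cur, cur_q2
    subset_names = [names[j] for j in best] if names is not None else None
    model = fit_mlr(X[:, best], y, names=subset_names)
    return best, model, best_q2


def exhaustive_select(
    X: np.ndarray, y: np.ndarray, model_size: int
) -> tuple[tuple[int, ...], float]:
    """Brute-force best Q^2_LOO subset (for small pools)."""
    from itertools import combinations

    X = np.asarray(X, dtype=float)
    best, best_q2 = None, -np.inf
    for subset in combinations(range(X.shape[1]), model_size):
        try:
            q2 = loo_q2(X[:, subset], y)
        except (FitError, np.linalg.LinAlgError):
            continue
        if q2 > best_q2:
            best, best_q2 = subset, q2
    if best is None:
        raise FitError("no feasible subset")
    return best, float(best_q2)


# ---------------------------------------------------------------------------
# Full validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """The internal + external statistic battery for one fitted model."""

    r2_tr: float
    adj_r2: float
    F: float
    RSS_tr: float
    MSE_tr: float
    RMSE_tr: float
    MAE_tr: float
    s: float
    AIC: float
    BIC: float
    CCC_tr: float
    Q2_cv: float
    RMSE_cv: float
    MSE_cv: float
    PRESS_cv: float
    MAE_cv: float
    R2_Yscr: float
    MSE_ex: float = float("nan")
    RMSE_ex: float = float("nan")
    PRESS_ex: float = float("nan")
    Q2F1: float = float("nan")
    Q2F2: float = float("nan")
    Q2F3: float = float("nan")
    MAE_ex: float = float("nan")
    k: float = float("nan")
    k_prime: float = float("nan")
    R2_ext: float = float("nan")
    CCC_ex: float = float("nan")
    r2m_avg: float = float("nan")
    r2m_delta: float = float("nan")

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in asdict(self).items()}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ValidationReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def validation_report(
    model: RegressionModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: Optional[np.ndarray] = None,
    y_test: Optional[np.ndarray] = None,
    seed: int = 0,
    n_scrambles: int = 100,
) -> ValidationReport:
    """Populate the full statistic battery for a fitted model.

    AIC/BIC use the Gaussian-likelihood small-sample form n*ln(RSS/n) plus a
    penalty on p + 2 parameters (coefficients, intercept, error variance); F
    is the overall regression F statistic and s the residual standard error.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    n, p = X_train.shape if X_train.ndim == 2 else (len(X_train), 1)
    yhat = model.predict(X_train)
    resid = y_train - yhat
    rss = float(resid @ resid)
    ss_tot = float(((y_train - y_train.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    F = (ss_tot - rss) / p / (rss / (n - p - 1)) if rss > 0 else float("inf")
    k_params = p + 2
    aic = n * math.log(rss / n) + 2 * k_params if rss > 0 else -float("inf")
    bic = n * math.log(rss / n) + k_params * math.log(n) if rss > 0 else -float("inf")

    press, press_resid = _loo_press(X_train, y_train)
    q2 = 1.0 - press / ss_tot
    mse_cv = press / n

    report = ValidationReport(
        r2_tr=r2,
        adj_r2=adj_r2,
        F=float(F),
        RSS_tr=rss,
        MSE_tr=rss / n,
        RMSE_tr=math.sqrt(rss / n),
        MAE_tr=float(np.abs(resid).mean()),
        s=math.sqrt(rss / (n - p - 1)),
        AIC=aic,
        BIC=bic,
        CCC_tr=concordance_ccc(y_train, yhat),
        Q2_cv=q2,
        RMSE_cv=math.sqrt(mse_cv),
        MSE_cv=mse_cv,
        PRESS_cv=press,
        MAE_cv=float(np.abs(press_resid).mean()),
        R2_Yscr=y_scrambling(X_train, y_train, n_scrambles, seed=seed),
    )

    if X_test is not None and y_test is not None and len(np.atleast_1d(y_test)) > 0:
        ext = external_metrics(model, X_test, y_test, y_train)
        rm2 = rm2_metrics(np.asarray(y_test, float), model.predict(X_test))
        for key in ("MSE_ex", "RMSE_ex", "PRESS_ex", "Q2F1", "Q2F2", "Q2F3",
                    "MAE_ex", "k", "k_prime", "R2_ext", "CCC_ex"):
            setattr(report, key, ext[key])
        report.r2m_avg = rm2["r2m_avg"]
        report.r2m_delta = rm2["r2m_delta"]
    return report
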