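"""Sparse binary linear classifiers and their one-vs-rest multiclass wrapper.

A binary classifier predicts ``sign(w . x + b)``.  Training minimizes

    F(w, b) = loss(w, b) + penalty(w)

where the loss is the mean over samples of one of

* least-square:  (w.x_i + b - y_i)^2
* logistic:      log(1 + exp(-y_i (w.x_i + b)))
* hinge:         max(0, 1 - y_i (w.x_i + b))

and the penalty is one of

* ``l2``            (lambda2 / 2) ||w||_2^2                  (ridge / SVM)
* ``l1``            lambda1 ||w||_1                          (lasso)
* ``group_l1l2``    lambda2 * sum_g ||w_g||_2                (group lasso)
* ``sparse_group``  lambda1 ||w||_1 + lambda2 sum_g ||w_g||_2

The group penalties zero out whole feature groups -- with the texture
features of :mod:`flystage.gabor`, whole image regions -- while the l1 term
additionally zeroes individual features inside surviving groups.

Smooth losses are solved by monotone accelerated proximal gradient (FISTA
with backtracking line search and a monotonicity safeguard); the hinge loss
is ridge-penalized only and solved exactly by dual coordinate descent, the
standard algorithm for linear SVMs.  The intercept is never penalized by
the sparsity terms; the hinge solver carries it as an augmented (and hence
weakly ridge-penalized) constant feature, which is recorded in the model
metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .gabor import GroupStructure

LOSSES = ("least_square", "logistic", "hinge")
REGULARIZERS = ("l2", "l1", "group_l1l2", "sparse_group")


@dataclass(frozen=True)
class SolverConfig:
    """Optimizer settings shared by all training routines."""

    max_iter: int = 1000
    tol: float = 1e-6
    step_init: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class LinearModel:
    """A trained binary linear classifier with its training provenance."""

    weights: np.ndarray
    intercept: float
    loss_name: str
    regularizer_name: str
    lambda1: float = 0.0
    lambda2: float = 0.0
    groups: GroupStructure | None = None
    n_iter: int = 0
    converged: bool = True
    objective: float = np.nan
    solver: str = ""
    objective_history: tuple = ()

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted labels in {-1, +1}; a zero decision value maps to +1."""
        return np.where(self.decision_values(X) >= 0, 1, -1)


# --------------------------------------------------------------------------
# losses


def _check_binary_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("binary labels must be in {-1, +1}")
    return y


def loss_value_and_gradient(
    loss_name: str,
    weights: np.ndarray,
    intercept: float,
    X: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean loss and its exact gradient w.r.t. (w, b).

    Returns the scalar loss and a gradient vector of length d + 1 whose last
    entry is the intercept derivative.  The non-smooth hinge loss is handled
    by its dedicated solver, not here.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary_labels(y)
    n = X.shape[0]
    z = X @ weights + intercept
    if loss_name == "least_square":
        resid = z - y
        value = float(resid @ resid) / n
        gz = 2.0 * resid / n
    elif loss_name == "logistic":
        margin = y * z
        value = float(np.mean(np.logaddexp(0.0, -margin)))
        gz = -y * expit(-margin) / n
    else:
        raise ValueError(f"unknown smooth loss {loss_name!r}")
    grad = np.empty(weights.size + 1)
    grad[:-1] = X.T @ gz
    grad[-1] = gz.sum()
    return value, grad


def _loss_value(loss_name: str, weights, intercept, X, y) -> float:
    """Loss value without the gradient (one matvec instead of two)."""
    z = X @ weights + intercept
    if loss_name == "least_square":
        resid = z - y
        return float(resid @ resid) / X.shape[0]
    if loss_name == "logistic":
        return float(np.mean(np.logaddexp(0.0, -y * z)))
    raise ValueError(f"unknown smooth loss {loss_name!r}")


def hinge_loss_value(weights: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray) -> float:
    y = _check_binary_labels(y)
    margins = y * (np.asarray(X, dtype=float) @ weights + intercept)
    return float(np.mean(np.maximum(0.0, 1.0 - margins)))


# --------------------------------------------------------------------------
# proximal operators


def prox_l1(v: np.ndarray, t: float) -> np.ndarray:
    """Soft threshold: argmin_u 1/2 ||u - v||^2 + t ||u||_1 (componentwise)."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def prox_group(v: np.ndarray, t: float, groups: GroupStructure) -> np.ndarray:
    """Block soft threshold: argmin_u 1/2 ||u - v||^2 + t sum_g ||u_g||_2.

    Each group is scaled by max(1 - t/||v_g||, 0); groups with norm <= t are
    zeroed entirely.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    v = np.asarray(v, dtype=float)
    if groups.n_features != v.size:
        raise ValueError(
            f"group structure covers {groups.n_features} features, vector has {v.size}"
        )
    out = np.empty_like(v)
    ids = groups.group_ids
    norms_sq = np.zeros(groups.n_groups)
    np.add.at(norms_sq, ids, v**2)
    norms = np.sqrt(norms_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(norms > t, 1.0 - t / np.where(norms > 0, norms, 1.0), 0.0)
    out = v * scale[ids]
    return out


def prox_sparse_group(
    v: np.ndarray, t1: float, t2: float, groups: GroupStructure
) -> np.ndarray:
    """Prox of ``t1 ||.||_1 + t2 sum_g ||._g||_2``.

    For this penalty pair the exact prox is the composition: soft-threshold
    first, then block soft-threshold.
    """
    return prox_group(prox_l1(v, t1), t2, groups)


def penalty_value(
    regularizer_name: str,
    weights: np.ndarray,
    lambda1: float,
    lambda2: float,
    groups: GroupStructure | None,
) -> float:
    """Evaluate the (non-smooth or ridge) penalty at a weight vector."""
    w = np.asarray(weights, dtype=float)
    if regularizer_name == "l2":
        return 0.5 * lambda2 * float(w @ w)
    if regularizer_name == "l1":
        return lambda1 * float(np.abs(w).sum())
    if regularizer_name in ("group_l1l2", "sparse_group"):
        if groups is None:
            raise ValueError(f"{regularizer_name} requires a GroupStructure")
        gnorm = sum(float(np.linalg.norm(w[g])) for g in groups.groups)
        if regularizer_name == "group_l1l2":
            return lambda2 * gnorm
        return lambda1 * float(np.abs(w).sum()) + lambda2 * gnorm
    raise ValueError(f"unknown regularizer {regularizer_name!r}")


def objective_value(
    model_or_weights,
    intercept: float | None = None,
    *,
    X: np.ndarray,
    y: np.ndarray,
    loss_name: str | None = None,
    regularizer_name: str | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    groups: GroupStructure | None = None,
) -> float:
    """Full training objective loss + penalty for a model or raw (w, b)."""
    if isinstance(model_or_weights, LinearModel):
        m = model_or_weights
        w, b = m.weights, m.intercept
        loss_name, regularizer_name = m.loss_name, m.regularizer_name
        lambda1, lambda2, groups = m.lambda1, m.lambda2, m.groups
    else:
        w, b = np.asarray(model_or_weights, dtype=float), float(intercept)
    if loss_name == "hinge":
        # intercept is ridge-penalized in the hinge formulation (augmentation)
        loss = hinge_loss_value(w, b, X, y)
        return loss + 0.5 * lambda2 * (float(w @ w) + b * b)
    loss, _ = loss_value_and_gradient(loss_name, w, b, X, y)
    return loss + penalty_value(regularizer_name, w, lambda1, lambda2, groups)


# --------------------------------------------------------------------------
# regularization path anchor


def lambda_max(
    X: np.ndarray,
    y: np.ndarray,
    loss_name: str = "least_square",
    kind: str = "l1",
    groups: GroupStructure | None = None,
) -> float:
    """Smallest penalty strength at which the all-zero weight vector is optimal.

    Computed from the loss gradient at w = 0 with the intercept at its
    unregularized optimum (mean label for least squares, log-odds for
    logistic).  For ``kind='l1'`` this is the max absolute coordinate of the
    gradient; for ``kind='group'`` the max group-wise Euclidean norm.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary_labels(y)
    if loss_name == "least_square":
        b0 = float(np.mean(y))
    elif loss_name == "logistic":
        p = np.clip(np.mean(y == 1.0), 1e-12, 1 - 1e-12)
        b0 = float(np.log(p / (1 - p)))
    else:
        raise ValueError(f"lambda_max undefined for loss {loss_name!r}")
    _, grad = loss_value_and_gradient(loss_name, np.zeros(X.shape[1]), b0, X, y)
    gw = grad[:-1]
    if kind == "l1":
        return float(np.max(np.abs(gw)))
    if kind == "group":
        if groups is None:
            raise ValueError("group lambda_max requires a GroupStructure")
        return float(max(np.linalg.norm(gw[g]) for g in groups.groups))
    raise ValueError(f"unknown kind {kind!r}")


def default_lambdas(
    X: np.ndarray,
    y: np.ndarray,
    loss_name: str,
    regularizer_name: str,
    groups: GroupStructure | None,
    fraction: float = 0.01,
) -> tuple[float, float]:
    """Default (lambda1, lambda2) = ``fraction`` of the problem's lambda_max.

    The pool is built with fixed relative strengths rather than per-member
    cross-validation so that pool construction is cheap and reproducible.
    For the plain ridge penalty (and the hinge SVM) lambda2 defaults to the
    same fixed fraction, on the scale of a unit-variance problem.
    """
    if regularizer_name == "l2":
        return 0.0, fraction
    if loss_name == "hinge":
        raise ValueError("hinge supports only the l2 regularizer")
    if regularizer_name == "l1":
        return fraction * lambda_max(X, y, loss_name, "l1"), 0.0
    if regularizer_name == "group_l1l2":
        return 0.0, fraction * lambda_max(X, y, loss_name, "group", groups)
    if regularizer_name == "sparse_group":
        l1 = fraction * lambda_max(X, y, loss_name, "l1")
        return l1, l1
    raise ValueError(f"unknown regularizer {regularizer_name!r}")


# --------------------------------------------------------------------------
# solvers


def _make_prox(regularizer_name, lambda1, lambda2, groups):
    if regularizer_name == "l2":
        return lambda w, step: w / (1.0 + step * lambda2)
    if regularizer_name == "l1":
        return lambda w, step: prox_l1(w, step * lambda1)
    if regularizer_name == "group_l1l2":
        return lambda w, step: prox_group(w, step * lambda2, groups)
    if regularizer_name == "sparse_group":
        return lambda w, step: prox_sparse_group(w, step * lambda1, step * lambda2, groups)
    raise ValueError(f"unknown regularizer {regularizer_name!r}")


def _fista(X, y, loss_name, regularizer_name, lambda1, lambda2, groups, config):
    """Monotone FISTA with backtracking on the smooth loss part.

    The l2 penalty is handled through its (exact) scaling prox like the
    others, so the smooth part is always just the data loss.  The returned
    objective sequence is non-increasing: each accepted iterate is the
    better of the accelerated candidate and the previous point's plain
    proximal step.
    """
    n, d = X.shape
    prox = _make_prox(regularizer_name, lambda1, lambda2, groups)

    def pen(w):
        return penalty_value(regularizer_name, w, lambda1, lambda2, groups)

    def smooth(w, b):
        return loss_value_and_gradient(loss_name, w, b, X, y)

    def backtracked_step(wv, bv, L):
        """One proximal-gradient step from (wv, bv), doubling L until the
        quadratic majorization of the smooth part holds at the candidate."""
        f_v, grad = smooth(wv, bv)
        for _ in range(80):
            step = 1.0 / L
            cand_w = prox(wv - step * grad[:-1], step)
            cand_b = bv - step * grad[-1]  # intercept un-penalized
            dw = cand_w - wv
            db = cand_b - bv
            f_c = _loss_value(loss_name, cand_w, cand_b, X, y)
            quad = f_v + grad[:-1] @ dw + grad[-1] * db + 0.5 * L * (dw @ dw + db * db)
            if f_c <= quad + 1e-12 * max(1.0, abs(f_v)):
                break
            L *= 2.0
        return cand_w, cand_b, f_c + pen(cand_w), L

    w = np.zeros(d)
    b = 0.0 if loss_name == "logistic" else float(np.mean(y))
    f_x, _ = smooth(w, b)
    F_x = f_x + pen(w)
    yw, yb = w.copy(), b
    t_momentum = 1.0
    L = 1.0 / config.step_init
    n_iter = 0
    converged = False
    history = [F_x]

    for n_iter in range(1, config.max_iter + 1):
        cand_w, cand_b, F_c, L = backtracked_step(yw, yb, L)
        if F_c <= F_x:
            new_w, new_b, F_new = cand_w, cand_b, F_c
        else:
            # monotonicity safeguard: majorized prox step from the best point;
            # guarantees F_new <= F_x, with momentum restarted
            new_w, new_b, F_new, L = backtracked_step(w, b, L)
            t_momentum = 1.0
            cand_w, cand_b = new_w, new_b
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2))
        yw = new_w + (t_momentum / t_next) * (cand_w - new_w) \
            + ((t_momentum - 1.0) / t_next) * (new_w - w)
        yb = new_b + (t_momentum / t_next) * (cand_b - new_b) \
            + ((t_momentum - 1.0) / t_next) * (new_b - b)
        t_momentum = t_next
        delta = F_x - F_new
        w, b, F_x = new_w, new_b, F_new
        history.append(F_x)
        L = max(L * 0.5, 1e-12)  # allow the step to grow again
        if delta <= config.tol * max(1.0, abs(F_x)):
            converged = True
            break
    return w, b, n_iter, converged, F_x, tuple(history)


def _fit_hinge_dual_cd(X, y, lambda2, config):
    """Dual coordinate descent for the l2-regularized linear SVM.

    Solves min_u 1/2 ||u||^2 + C sum_i max(0, 1 - y_i u.x~_i) with
    C = 1 / (n * lambda2) and x~ the bias-augmented sample, which is the
    primal objective lambda2/2 (||w||^2 + b^2) + mean hinge.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary_labels(y)
    n, d = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    C = 1.0 / (n * lambda2)
    q = np.einsum("ij,ij->i", Xa, Xa)
    q[q == 0] = 1.0
    alpha = np.zeros(n)
    u = np.zeros(d + 1)
    rng = np.random.default_rng(config.seed)
    converged = False
    epoch = 0
    for epoch in range(1, config.max_iter + 1):
        for i in rng.permutation(n):
            g = y[i] * (u @ Xa[i]) - 1.0
            # projected gradient for the box constraint [0, C]
            if alpha[i] <= 0:
                pg = min(g, 0.0)
            elif alpha[i] >= C:
                pg = max(g, 0.0)
            else:
                pg = g
            if pg != 0.0:
                new_alpha = min(max(alpha[i] - g / q[i], 0.0), C)
                u += (new_alpha - alpha[i]) * y[i] * Xa[i]
                alpha[i] = new_alpha
        # duality gap is a direct certificate of primal suboptimality:
        # primal = 1/2||u||^2 + C sum hinge, dual = sum(alpha) - 1/2||u||^2
        uu = float(u @ u)
        hinge_sum = float(np.maximum(0.0, 1.0 - y * (Xa @ u)).sum())
        gap = (0.5 * uu + C * hinge_sum) - (float(alpha.sum()) - 0.5 * uu)
        # compare on the scale of the reported objective (scaled by lambda2)
        if gap * lambda2 <= config.tol * max(1.0, lambda2 * (0.5 * uu + C * hinge_sum)):
            converged = True
            break
    return u[:d], float(u[d]), epoch, converged


def fit_binary(
    X: np.ndarray,
    y: np.ndarray,
    loss_name: str,
    regularizer_name: str,
    lambda1: float | None = None,
    lambda2: float | None = None,
    groups: GroupStructure | None = None,
    config: SolverConfig = SolverConfig(),
) -> LinearModel:
    """Train one binary classifier for a (loss, regularizer) configuration.

    ``lambda1``/``lambda2`` default to 1% of the problem's ``lambda_max``
    (see :func:`default_lambdas`).  Non-convergence within ``max_iter``
    flags the model but does not raise.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary_labels(np.asarray(y))
    if len(np.unique(y)) < 2:
        warnings.warn("binary training set contains a single class", stacklevel=2)
    if loss_name not in LOSSES:
        raise ValueError(f"unknown loss {loss_name!r}")
    if regularizer_name not in REGULARIZERS:
        raise ValueError(f"unknown regularizer {regularizer_name!r}")
    if regularizer_name in ("group_l1l2", "sparse_group"):
        if groups is None or groups.n_features != X.shape[1]:
            raise ValueError("group regularizers need a GroupStructure covering all features")
    if lambda1 is None or lambda2 is None:
        d1, d2 = default_lambdas(X, y, loss_name, regularizer_name, groups)
        lambda1 = d1 if lambda1 is None else lambda1
        lambda2 = d2 if lambda2 is None else lambda2
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("regularization strengths must be non-negative")

    if loss_name == "hinge":
        if regularizer_name != "l2":
            raise ValueError("the hinge loss is implemented with the l2 regularizer only")
        w, b, n_iter, converged = _fit_hinge_dual_cd(X, y, lambda2, config)
        model = LinearModel(
            weights=w,
            intercept=b,
            loss_name=loss_name,
            regularizer_name=regularizer_name,
            lambda1=0.0,
            lambda2=lambda2,
            n_iter=n_iter,
            converged=converged,
            solver="dual_coordinate_descent(bias_augmented)",
        )
        obj = objective_value(model, X=X, y=y)
        return replace(model, objective=obj)

    w, b, n_iter, converged, obj, history = _fista(
        X, y, loss_name, regularizer_name, lambda1, lambda2, groups, config
    )
    return LinearModel(
        weights=w,
        intercept=b,
        loss_name=loss_name,
        regularizer_name=regularizer_name,
        lambda1=lambda1,
        lambda2=lambda2,
        groups=groups,
        n_iter=n_iter,
        converged=converged,
        objective=obj,
        solver="monotone_fista_backtracking",
        objective_history=history,
    )


# --------------------------------------------------------------------------
# one-vs-rest multiclass wrapper


@dataclass(frozen=True)
class OneVsRestModel:
    """One binary model per class; prediction takes the largest decision value.

    ``classes`` is sorted ascending, and ties in the decision values resolve
    to the smallest class (``argmax`` returns the first maximum).
    """

    classes: np.ndarray
    models: tuple[LinearModel, ...] = field(repr=False)

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.decision_values(X) for m in self.models])

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_matrix(X)
        return self.classes[np.argmax(scores, axis=1)]


def fit_one_vs_rest(
    X: np.ndarray,
    y: np.ndarray,
    loss_name: str,
    regularizer_name: str,
    lambda1: float | None = None,
    lambda2: float | None = None,
    groups: GroupStructure | None = None,
    config: SolverConfig = SolverConfig(),
    classes: np.ndarray | None = None,
) -> OneVsRestModel:
    """Train one binary model per class (that class vs. the rest).

    ``classes`` fixes the class alphabet (e.g. all 15 stages) even if some
    classes are absent from this particular training split; absent or
    singleton classes produce a warning but are trained anyway.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    found = np.unique(y)
    if classes is None:
        classes = found
    classes = np.sort(np.asarray(classes))
    if found.size < 2:
        raise ValueError("one-vs-rest needs at least two classes present")
    models = []
    for c in classes:
        n_pos = int(np.sum(y == c))
        if n_pos < 2:
            warnings.warn(
                f"class {c} has {n_pos} training sample(s); model trained anyway",
                stacklevel=2,
            )
        yc = np.where(y == c, 1.0, -1.0)
        models.append(
            fit_binary(X, yc, loss_name, regularizer_name, lambda1, lambda2, groups, config)
        )
    return OneVsRestModel(classes=classes, models=tuple(models))
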