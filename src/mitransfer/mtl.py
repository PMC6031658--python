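"""l1- and l2,1-regularized (multi-task) logistic regression.

Each training subject is one task.  All tasks share the feature space; a
weight matrix W (features x tasks) and per-task intercepts c minimize

    sum_i sum_j log(1 + exp(-y_ij (x_ij' W[:, i] + c_i)))  +  rho * P(W)

where P is either the l2,1 norm (sum of row-wise Euclidean norms, inducing
a feature support shared across subjects) or the elementwise l1 norm.  The
pooled single-task l1 model is the one-task special case on the
concatenated data.

The solver is a monotone accelerated proximal-gradient method (FISTA with
backtracking line search and a monotonicity safeguard), deterministic from
zero initialization; intercepts are unpenalized.  The unseen test subject
is scored by the average of the task models (mean weight column and mean
intercept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

log = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 2000


@dataclass
class Task:
    X: np.ndarray  # samples x features
    y: np.ndarray  # labels in {+1, -1}
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("label count must match sample count")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1 / -1")


@dataclass
class TaskSet:
    tasks: list

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("need at least one task")
        ps = {t.X.shape[1] for t in self.tasks}
        if len(ps) != 1:
            raise ValueError("all tasks must share the feature dimension")

    @property
    def p(self) -> int:
        return self.tasks[0].X.shape[1]

    @property
    def t(self) -> int:
        return len(self.tasks)

    @property
    def n_i(self) -> list[int]:
        return [len(task.y) for task in self.tasks]


@dataclass
class MTLModel:
    W: np.ndarray  # features x tasks
    c: np.ndarray  # per-task intercepts
    rho: float
    penalty: str  # "l21" or "l1"
    solver_trace: list = field(default_factory=list)
    converged: bool = True


def l21_norm(W: np.ndarray) -> float:
    """Sum over feature rows of the Euclidean norm across tasks."""
    return float(np.sum(np.linalg.norm(np.atleast_2d(W), axis=1)))


def _penalty_value(W: np.ndarray, penalty: str) -> float:
    if penalty == "l21":
        return l21_norm(W)
    if penalty == "l1":
        return float(np.abs(W).sum())
    raise ValueError(f"unknown penalty {penalty!r}")


def _smooth_loss_grad(W, c, tasks, want_grad=True):
    """Summed logistic loss and its gradient w.r.t. W and c."""
    loss = 0.0
    gW = np.zeros_like(W) if want_grad else None
    gc = np.zeros_like(c) if want_grad else None
    for i, task in enumerate(tasks.tasks):
        z = task.X @ W[:, i] + c[i]
        m = task.y * z
        loss += float(np.logaddexp(0.0, -m).sum())
        if want_grad:
            s = -task.y * expit(-m)
            gW[:, i] = task.X.T @ s
            gc[i] = s.sum()
    return (loss, gW, gc) if want_grad else loss


def mtl_objective(model: MTLModel, tasks: TaskSet) -> float:
    """Total objective: summed logistic loss plus rho * penalty(W)."""
    return _smooth_loss_grad(model.W, model.c, tasks, want_grad=False) \
        + model.rho * _penalty_value(model.W, model.penalty)


def prox_step(W: np.ndarray, step: float, rho: float, penalty: str) -> np.ndarray:
    """Proximal operator of step * rho * penalty.

    l2,1: each feature row is scaled by max(0, 1 - step*rho/||row||);
    l1: elementwise soft threshold at step*rho."""
    if step <= 0:
        raise ValueError("step must be positive")
    thr = step * rho
    if thr == 0:
        return W.copy()
    if penalty == "l1":
        return np.sign(W) * np.maximum(np.abs(W) - thr, 0.0)
    if penalty == "l21":
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        scale = np.maximum(0.0, 1.0 - thr / np.maximum(norms, 1e-300))
        return W * scale
    raise ValueError(f"unknown penalty {penalty!r}")


def fit_mtl(tasks: TaskSet, rho: float, penalty: str = "l21",
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER) -> MTLModel:
    """Monotone FISTA with backtracking; zero initialization, no randomness."""
    if rho < 0:
        raise ValueError("rho must be non-negative")
    p, t = tasks.p, tasks.t

    def F(W, c):
        return _smooth_loss_grad(W, c, tasks, want_grad=False) \
            + rho * _penalty_value(W, penalty)

    W = np.zeros((p, t))
    c = np.zeros(t)
    Wy, cy = W.copy(), c.copy()  # extrapolation point
    obj = F(W, c)
    trace = [obj]
    L = 1.0
    tk = 1.0
    converged = False
    for _ in range(max_iter):
        f_y, gW, gc = _smooth_loss_grad(Wy, cy, tasks)
        # backtracking on the smooth majorizer
        while True:
            Wz = prox_step(Wy - gW / L, 1.0 / L, rho, penalty)
            cz = cy - gc / L
            dW, dc = Wz - Wy, cz - cy
            f_z = _smooth_loss_grad(Wz, cz, tasks, want_grad=False)
            quad = f_y + np.sum(gW * dW) + np.sum(gc * dc) \
                + 0.5 * L * (np.sum(dW ** 2) + np.sum(dc ** 2))
            if f_z <= quad + 1e-12 * max(1.0, abs(f_y)):
                break
            L *= 2.0
        obj_z = f_z + rho * _penalty_value(Wz, penalty)
        if obj_z > obj + 1e-12 * max(1.0, abs(obj)):
            # momentum overshoot: restart acceleration at the incumbent.
            # A proximal step taken *at* the incumbent can never increase
            # the objective (backtracking majorizer), so progress resumes.
            tk = 1.0
            Wy, cy = W.copy(), c.copy()
            continue
        improvement = obj - obj_z
        W_prev, c_prev = W, c
        W, c, obj = Wz, cz, obj_z
        tk_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk ** 2))
        Wy = W + ((tk - 1.0) / tk_next) * (W - W_prev)
        cy = c + ((tk - 1.0) / tk_next) * (c - c_prev)
        tk = tk_next
        trace.append(obj)
        if improvement <= tol * max(1.0, abs(obj)):
            converged = True
            break
    if not converged:
        log.warning("MTL solver did not reach tol=%g in %d iterations "
                    "(last objective %.6g)", tol, max_iter, obj)
    return MTLModel(W=W, c=c, rho=rho, penalty=penalty,
                    solver_trace=trace, converged=converged)


def fit_pooled_l1(X: np.ndarray, y: np.ndarray, rho: float,
                  subject_id: int | None = None, **opts) -> MTLModel:
    """Pooled single-task l1-logistic regression (one task holding the
    concatenation of all training subjects' samples)."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes required")
    tasks = TaskSet([Task(X=X, y=y, subject_id=subject_id)])
    return fit_mtl(tasks, rho=rho, penalty="l1", **opts)


def predict_unseen(model: MTLModel, X_test: np.ndarray,
                   return_prob: bool = False):
    """Score an unseen subject with the average task model: mean weight
    column and mean intercept; label +1 iff the logistic probability
    strictly exceeds 0.5 (ties resolve to -1)."""
    w = model.W.mean(axis=1)
    b = model.c.mean()
    s = np.asarray(X_test, float) @ w + b
    labels = np.where(s > 0, 1, -1)
    if return_prob:
        return labels, expit(s)
    return labels


def select_rho(tasks: TaskSet, candidates, penalty: str = "l21",
               **fit_opts) -> float:
    """Inner leave-one-task-out selection of the regularization weight.

    For each candidate, each training task is held out in turn, the model is
    fitted on the remaining tasks, and the held-out task is scored with the
    unseen-subject rule.  Returns the candidate with the best mean accuracy;
    ties resolve toward the larger (sparser) value."""
    cands = sorted(float(r) for r in candidates)
    if len(cands) == 1:
        return cands[0]
    if tasks.t < 3:
        raise ValueError("rho selection needs at least 3 tasks")
    best_rho, best_acc = cands[0], -np.inf
    for rho in cands:
        accs = []
        for i in range(tasks.t):
            inner = TaskSet([t for j, t in enumerate(tasks.tasks) if j != i])
            model = fit_mtl(inner, rho=rho, penalty=penalty, **fit_opts)
            pred = predict_unseen(model, tasks.tasks[i].X)
            accs.append(np.mean(pred == tasks.tasks[i].y))
        acc = float(np.mean(accs))
        if acc >= best_acc:  # ascending grid, >= : larger rho wins ties
            best_rho, best_acc = rho, acc
    return best_rho


class Standardizer:
    """Per-feature z-scoring with statistics frozen on the training data."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, float)
        self.mean = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.sd
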