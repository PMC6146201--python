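"""From-equation binary classifiers: Fisher LDA, L1-regularized logistic
regression, and a soft-margin RBF-kernel SVM.

The three models share a statsmodels-flavoured contract: a model object is
constructed from data, ``fit()`` returns a results object carrying the
estimated parameters and convergence diagnostics, and the results object
provides ``decision_score`` (continuous, larger = more positive-class),
``predict`` (sign-thresholded scores in {+1, -1}) and ``summary``.

* :class:`FisherLDA` — closed-form Fisher discriminant
  ``w ∝ S_w^{-1}(m_+ - m_-)`` with optional Ledoit-Wolf-style shrinkage of
  the pooled within-class scatter toward a scaled identity, and the
  threshold at the projected midpoint of the class means.
* :class:`L1Logit` — minimizes the average logistic loss plus an L1 penalty
  on the weights (intercept unpenalized) by monotone accelerated proximal
  gradient (MFISTA with soft-thresholding); the recorded objective trace is
  non-increasing and the all-zero-weight solution is returned exactly for
  penalties at or above ``lambda_max``.
* :class:`RBFSVM` — solves the soft-margin dual with Gaussian kernel
  ``K(x, x') = exp(-gamma ||x - x'||^2)`` by SMO-style pairwise updates with
  maximal-violating-pair working-set selection; the decision function is
  ``sign(sum_i beta_i y_i K(x, x_i) + b)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FisherLDA", "L1Logit", "RBFSVM",
    "LDAResults", "L1LogitResults", "RBFSVMResults",
    "DegenerateModelError", "ConvergenceError", "fit_classifier",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("lda", "l1lr", "rbfsvm")


class DegenerateModelError(ValueError):
    """The training data admit no usable model (e.g. identical class means
    or a singular scatter matrix with no regularization)."""


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach its tolerance within the iteration budget."""

    def __init__(self, message: str, gap: float | None = None):
        super().__init__(message)
        self.gap = gap


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("class labels must be +1 / -1")
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    return y.astype(float)


class _BinaryModel:
    """Shared constructor/validation for the three classifiers."""

    def __init__(self, endog, exog):
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2:
            raise ValueError("exog must be 2-D (trials x features)")
        if not np.isfinite(self.exog).all():
            raise ValueError("exog contains non-finite values")
        self.endog = _check_binary(endog)
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        self.nobs, self.k_features = self.exog.shape


class _BinaryResults:
    """Common results surface: continuous scores, sign predictions, summary."""

    model_name = "binary classifier"

    def decision_score(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        """Class labels in {+1, -1}; scores of exactly 0 go to +1."""
        s = self.decision_score(X)
        return np.where(s >= 0, 1, -1)

    def _summary_rows(self) -> list[tuple[str, str]]:
        return []

    def summary(self) -> str:
        rows = self._summary_rows()
        width = max(len(k) for k, _ in rows) + 2
        lines = [self.model_name, "=" * len(self.model_name)]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)


def _as_matrix(X, k_features: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != k_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {k_features}"
        )
    return X


# ---------------------------------------------------------------------------
# Fisher linear discriminant
# ---------------------------------------------------------------------------

class FisherLDA(_BinaryModel):
    """Fisher's linear discriminant for two classes.

    Projects features on ``w = S_w^{-1} (m_+ - m_-)``, the direction that
    maximizes between-class mean separation relative to pooled within-class
    variance; a trial is called positive when ``w^T x`` exceeds the
    projected midpoint of the class means.
    """

    def fit(self, shrinkage: float | str = "auto") -> "LDAResults":
        """Estimate the projection.

        Parameters
        ----------
        shrinkage : float in [0, 1] or "auto"
            Convex shrinkage of the pooled scatter toward
            ``(trace(S_w)/p) I``.  ``"auto"`` uses a Ledoit-Wolf-style
            estimate of the optimal coefficient; 0 uses the raw scatter and
            raises on singularity.
        """
        X, y = self.exog, self.endog
        pos, neg = X[y == 1], X[y == -1]
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError("need >= 2 rows per class")
        m_pos, m_neg = pos.mean(axis=0), neg.mean(axis=0)
        diff = m_pos - m_neg
        if not np.any(diff):
            raise DegenerateModelError("identical class means")
        centered = np.vstack([pos - m_pos, neg - m_neg])
        n = centered.shape[0]
        S = centered.T @ centered / n           # pooled within-class scatter
        p = S.shape[0]
        mu = np.trace(S) / p
        if shrinkage == "auto":
            shrink = _ledoit_wolf_coefficient(centered, S, mu)
        else:
            shrink = float(shrinkage)
            if not 0.0 <= shrink <= 1.0:
                raise ValueError("shrinkage must be in [0, 1]")
        S_reg = (1.0 - shrink) * S + shrink * mu * np.eye(p)
        try:
            w = np.linalg.solve(S_reg, diff)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError(
                "singular within-class scatter; use shrinkage > 0"
            ) from exc
        if shrink == 0.0:
            # np.linalg.solve can silently succeed on barely singular input
            if not np.allclose(S_reg @ w, diff, rtol=1e-6, atol=1e-8):
                raise DegenerateModelError(
                    "singular within-class scatter; use shrinkage > 0"
                )
        threshold = float(w @ (m_pos + m_neg) / 2.0)
        return LDAResults(
            model=self, params=w, threshold=threshold,
            class_means=(m_pos, m_neg), shrinkage=float(shrink),
        )


def _ledoit_wolf_coefficient(centered: np.ndarray, S: np.ndarray,
                             mu: float) -> float:
    """Ledoit-Wolf-style optimal shrinkage toward the scaled identity."""
    n, p = centered.shape
    delta2 = np.sum((S - mu * np.eye(p)) ** 2)
    if delta2 == 0:
        return 0.0
    # E||x x' - S||^2 estimated from the sample
    beta2 = 0.0
    for row in centered:
        beta2 += np.sum((np.outer(row, row) - S) ** 2)
    beta2 /= n * n
    return float(min(1.0, max(0.0, beta2 / delta2)))


@dataclass
class LDAResults(_BinaryResults):
    model: FisherLDA
    params: np.ndarray            # projection weights w
    threshold: float
    class_means: tuple[np.ndarray, np.ndarray]
    shrinkage: float
    model_name = "Fisher linear discriminant"

    def decision_score(self, X) -> np.ndarray:
        X = _as_matrix(X, self.model.k_features)
        return X @ self.params - self.threshold

    def _summary_rows(self):
        return [
            ("n obs", str(self.model.nobs)),
            ("n features", str(self.model.k_features)),
            ("shrinkage", f"{self.shrinkage:.4g}"),
            ("||w||", f"{np.linalg.norm(self.params):.6g}"),
            ("threshold", f"{self.threshold:.6g}"),
        ]

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "weights": self.params.tolist(),
            "threshold": self.threshold,
            "shrinkage": self.shrinkage,
        }


# ---------------------------------------------------------------------------
# L1-regularized logistic regression
# ---------------------------------------------------------------------------

def _logistic_objective(v, w, X, y, lam):
    eta = v + X @ w
    # log(1 + exp(-y*eta)) computed stably
    z = -y * eta
    loss = np.mean(np.logaddexp(0.0, z))
    return loss + lam * np.abs(w).sum()


def _logistic_grad(v, w, X, y):
    eta = v + X @ w
    # d/d eta of log(1+exp(-y eta)) = -y * sigmoid(-y eta)
    s = -y / (1.0 + np.exp(y * eta))
    n = len(y)
    return s.mean(), X.T @ s / n


class L1Logit(_BinaryModel):
    """L1-regularized logistic regression.

    Minimizes ``(1/n) sum_i log(1 + exp(-y_i (v + w^T x_i))) + lam ||w||_1``
    with the intercept ``v`` unpenalized.  The penalty trades average
    logistic loss against weight-vector size, yielding sparse weights for
    large ``lam``.
    """

    def lambda_max(self) -> float:
        """Smallest penalty for which the optimal weight vector is all-zero.

        At the intercept-only optimum ``v* = log(n_+/n_-)`` the KKT
        condition ``|grad_j loss| <= lam`` for every feature j gives
        ``lam_max = max_j |grad_j|``.
        """
        y = self.endog
        v_star = np.log((y == 1).sum() / (y == -1).sum())
        _, gw = _logistic_grad(v_star, np.zeros(self.k_features), self.exog, y)
        return float(np.abs(gw).max())

    def fit(self, lam: float, tol: float = 1e-8,
            max_iter: int = 10000) -> "L1LogitResults":
        """Monotone FISTA with soft-thresholding.

        Iterates until the relative objective change drops below ``tol`` or
        ``max_iter`` proximal steps; the recorded objective trace is
        non-increasing by construction (the accelerated candidate is only
        accepted when it does not increase the objective).
        """
        if lam < 0:
            raise ValueError("lam must be >= 0")
        X, y = self.exog, self.endog
        n = self.nobs
        # KKT shortcut: the intercept-only optimum v* = log(n+/n-) with w = 0
        # is the exact global minimizer whenever every |grad_j loss| <= lam
        v_star = float(np.log((y == 1).sum() / (y == -1).sum()))
        _, g0 = _logistic_grad(v_star, np.zeros(self.k_features), X, y)
        if np.abs(g0).max() <= lam * (1.0 + 1e-12) + 1e-15:
            w0 = np.zeros(self.k_features)
            return L1LogitResults(
                model=self, intercept=v_star, params=w0, lam=float(lam),
                objective_trace=np.array(
                    [_logistic_objective(v_star, w0, X, y, lam)]),
                converged=True,
            )
        # Lipschitz constant of the smooth part: ||[1 X]||_2^2 / (4n)
        A = np.hstack([np.ones((n, 1)), X])
        L = np.linalg.norm(A, 2) ** 2 / (4.0 * n)
        step = 1.0 / L

        v, w = 0.0, np.zeros(self.k_features)
        zv, zw = v, w.copy()
        t = 1.0
        obj = _logistic_objective(v, w, X, y, lam)
        trace = [obj]
        converged = False
        for _ in range(max_iter):
            gv, gw = _logistic_grad(zv, zw, X, y)
            uv = zv - step * gv
            uw = np.sign(zw - step * gw) * np.maximum(
                np.abs(zw - step * gw) - step * lam, 0.0
            )
            obj_u = _logistic_objective(uv, uw, X, y, lam)
            v_prev, w_prev, obj_prev = v, w, obj
            if obj_u <= obj_prev:            # monotone acceptance
                v, w, obj = uv, uw, obj_u
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            zv = v + (t / t_next) * (uv - v) + ((t - 1.0) / t_next) * (v - v_prev)
            zw = w + (t / t_next) * (uw - w) + ((t - 1.0) / t_next) * (w - w_prev)
            t = t_next
            trace.append(obj)
            if abs(obj_prev - obj) <= tol * max(1.0, abs(obj_prev)):
                converged = True
                break
        return L1LogitResults(
            model=self, intercept=float(v), params=w, lam=float(lam),
            objective_trace=np.array(trace), converged=converged,
        )


@dataclass
class L1LogitResults(_BinaryResults):
    model: L1Logit
    intercept: float              # v
    params: np.ndarray            # weights w
    lam: float
    objective_trace: np.ndarray
    converged: bool
    model_name = "L1-regularized logistic regression"

    def linear_predictor(self, X) -> np.ndarray:
        X = _as_matrix(X, self.model.k_features)
        return self.intercept + X @ self.params

    def decision_score(self, X) -> np.ndarray:
        return self.linear_predictor(X)

    def predict_proba(self, X) -> np.ndarray:
        """P(class = +1 | x) = logistic(v + w^T x), in (0, 1)."""
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.params))

    def _summary_rows(self):
        return [
            ("n obs", str(self.model.nobs)),
            ("n features", str(self.model.k_features)),
            ("lambda", f"{self.lam:.4g}"),
            ("nonzero weights", str(self.n_nonzero)),
            ("intercept", f"{self.intercept:.6g}"),
            ("final objective", f"{self.objective_trace[-1]:.8g}"),
            ("iterations", str(len(self.objective_trace) - 1)),
            ("converged", str(self.converged)),
        ]

    def to_dict(self) -> dict:
        return {
            "kind": "l1lr",
            "intercept": self.intercept,
            "weights": self.params.tolist(),
            "lambda": self.lam,
            "converged": self.converged,
            "n_iter": len(self.objective_trace) - 1,
        }


# ---------------------------------------------------------------------------
# RBF-kernel support vector machine
# ---------------------------------------------------------------------------

def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix K[i, j] = exp(-gamma ||a_i - b_j||^2)."""
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


class RBFSVM(_BinaryModel):
    """Soft-margin SVM with Gaussian kernel, trained in the dual.

    Solves ``min_alpha (1/2) alpha' Q alpha - e' alpha`` subject to
    ``y' alpha = 0`` and ``0 <= alpha_i <= C`` (``Q_ij = y_i y_j K_ij``) by
    repeatedly optimizing the maximal-violating pair analytically (SMO).
    The fitted decision function is
    ``f(x) = sign(sum_i beta_i y_i K(x, x_i) + b)`` with ``beta_i`` the
    Lagrange multipliers.
    """

    def fit(self, C: float = 1.0, gamma: float = 1.0, tol: float = 1e-3,
            max_iter: int = 200_000) -> "RBFSVMResults":
        if C <= 0 or gamma <= 0:
            raise ValueError("C and gamma must be positive")
        X, y = self.exog, self.endog
        n = self.nobs
        K = rbf_kernel(X, X, gamma)
        Q = (y[:, None] * y[None, :]) * K
        alpha = np.zeros(n)
        grad = -np.ones(n)                    # Q @ alpha - 1 at alpha = 0
        eps = 1e-12
        it = 0
        while True:
            neg_yg = -y * grad
            up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
            low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
            if not up.any() or not low.any():
                gap = 0.0
                break
            i = np.flatnonzero(up)[np.argmax(neg_yg[up])]
            j = np.flatnonzero(low)[np.argmin(neg_yg[low])]
            gap = neg_yg[i] - neg_yg[j]
            if gap <= tol:
                break
            if it >= max_iter:
                raise ConvergenceError(
                    f"SMO did not converge in {max_iter} iterations "
                    f"(KKT gap {gap:.3e})", gap=float(gap),
                )
            # analytic two-variable update (maximal-violating pair i, j)
            quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
            quad = max(quad, 1e-12)
            delta = gap / quad                # step along (y_i e_i - y_j e_j)
            # box constraints along the feasible direction
            if y[i] > 0:
                delta = min(delta, C - alpha[i])
            else:
                delta = min(delta, alpha[i])
            if y[j] > 0:
                delta = min(delta, alpha[j])
            else:
                delta = min(delta, C - alpha[j])
            alpha[i] += y[i] * delta
            alpha[j] -= y[j] * delta
            grad += delta * (y[i] * Q[:, i] - y[j] * Q[:, j])
            it += 1
        # bias from free support vectors; fallback to the violation midpoint
        free = (alpha > eps) & (alpha < C - eps)
        fx = (alpha * y) @ K                  # sum_i beta_i y_i K(x_i, .)
        if free.any():
            b = float(np.mean(y[free] - fx[free]))
        else:
            neg_yg = -y * grad
            up = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
            low = ((y < 0) & (alpha < C - eps)) | ((y > 0) & (alpha > eps))
            hi = neg_yg[up].max() if up.any() else 0.0
            lo = neg_yg[low].min() if low.any() else 0.0
            b = float((hi + lo) / 2.0)
        dual = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)
        sv = alpha > eps
        return RBFSVMResults(
            model=self, support_coef=(alpha * y)[sv],
            support_vectors=X[sv].copy(), support_index=np.flatnonzero(sv),
            bias=b, C=float(C), gamma=float(gamma),
            dual_objective=dual, kkt_gap=float(gap), n_iter=it,
        )


@dataclass
class RBFSVMResults(_BinaryResults):
    model: RBFSVM
    support_coef: np.ndarray      # beta_i * y_i for support vectors
    support_vectors: np.ndarray
    support_index: np.ndarray
    bias: float
    C: float
    gamma: float
    dual_objective: float
    kkt_gap: float
    n_iter: int
    model_name = "RBF-kernel support vector machine"

    def decision_score(self, X) -> np.ndarray:
        X = _as_matrix(X, self.model.k_features)
        K = rbf_kernel(X, self.support_vectors, self.gamma)
        return K @ self.support_coef + self.bias

    def _summary_rows(self):
        return [
            ("n obs", str(self.model.nobs)),
            ("n features", str(self.model.k_features)),
            ("C", f"{self.C:.4g}"),
            ("gamma", f"{self.gamma:.4g}"),
            ("support vectors", str(len(self.support_coef))),
            ("dual objective", f"{self.dual_objective:.8g}"),
            ("KKT gap", f"{self.kkt_gap:.3e}"),
            ("iterations", str(self.n_iter)),
        ]

    def to_dict(self) -> dict:
        return {
            "kind": "rbfsvm",
            "support_coef": self.support_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "bias": self.bias,
            "C": self.C,
            "gamma": self.gamma,
            "kkt_gap": self.kkt_gap,
        }


# ---------------------------------------------------------------------------
# unified constructor
# ---------------------------------------------------------------------------

def fit_classifier(name: str, X: np.ndarray, y: np.ndarray,
                   **hyper) -> _BinaryResults:
    """Fit one of the three classifiers by name.

    ``lda`` accepts ``shrinkage``; ``l1lr`` accepts ``lam`` (default
    ``0.01 * lambda_max``); ``rbfsvm`` accepts ``C`` (default 10) and
    ``gamma`` (default ``1 / (n_features * var(X))``).
    """
    if name == "lda":
        return FisherLDA(y, X).fit(**hyper)
    if name == "l1lr":
        model = L1Logit(y, X)
        hyper.setdefault("lam", 0.01 * model.lambda_max())
        return model.fit(**hyper)
    if name == "rbfsvm":
        hyper.setdefault("C", 10.0)
        var = np.asarray(X).var()
        hyper.setdefault(
            "gamma", 1.0 / (np.asarray(X).shape[1] * var) if var > 0 else 1.0
        )
        return RBFSVM(y, X).fit(**hyper)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
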