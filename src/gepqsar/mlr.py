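"""Forward-selection multiple linear regression with QSAR validation statistics.

The "heuristic method" stage: descriptors are added one at a time, each
step keeping the candidate that maximizes the fitted model's R².  Every
step records the full statistics panel used to judge QSAR regressions —
R², leave-one-out cross-validated R² (``1 - PRESS/SStot``), the
F-statistic, and the residual variance ``s² = SSres/(n - k - 1)`` — so the
whole trace can be plotted against the descriptor count.  Model size is
chosen by the breaking-point rule: stop growing once the R² gain drops
below a tolerance, and never exceed the sample-size constraint
``n >= 3(k + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gepqsar.dataset import DescriptorTable
from gepqsar.errors import DomainError, NumericalError

__all__ = [
    "LinearModel",
    "SelectionTrace",
    "fit_ols",
    "loo_r2cv",
    "f_statistic",
    "forward_select",
    "breaking_point",
    "max_k_for_n",
    "DEFAULT_BREAKING_TOL",
]

DEFAULT_BREAKING_TOL = 0.02


@dataclass
class LinearModel:
    """An OLS fit on a named descriptor subset, with its statistics panel."""

    descriptors: list[str]
    coefficients: np.ndarray
    intercept: float
    r2: float
    s2: float
    n: int
    r2cv: float | None = None
    f_stat: float | None = None

    @property
    def k(self) -> int:
        return len(self.descriptors)

    def predict(self, table: DescriptorTable) -> np.ndarray:
        X = np.column_stack([table.column(d) for d in self.descriptors])
        return self.intercept + X @ self.coefficients

    def equation(self, digits: int = 4) -> str:
        terms = [f"{self.intercept:+.{digits}f}"]
        terms += [
            f"{c:+.{digits}f}*{d}" for c, d in zip(self.coefficients, self.descriptors)
        ]
        return "y = " + " ".join(terms)


@dataclass
class SelectionTrace:
    """The sequence of best models for k = 1..k_max, plus the chosen size."""

    models: list[LinearModel] = field(default_factory=list)
    chosen_k: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [m.k for m in self.models],
                "added": [
                    m.descriptors[-1] if m.descriptors else "" for m in self.models
                ],
                "r2": [m.r2 for m in self.models],
                "r2cv": [m.r2cv for m in self.models],
                "f_stat": [m.f_stat for m in self.models],
                "s2": [m.s2 for m in self.models],
            }
        )

    @property
    def chosen_model(self) -> LinearModel:
        if self.chosen_k is None:
            raise ValueError("no model size chosen yet; run breaking_point first")
        return self.models[self.chosen_k - 1]


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns (beyond the intercept) that do not increase the design rank."""
    A = np.ones((X.shape[0], 1))
    bad = []
    for j, name in enumerate(names):
        cand = np.column_stack([A, X[:, j]])
        if np.linalg.matrix_rank(cand) == A.shape[1]:
            bad.append(name)
        else:
            A = cand
    return bad


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    descriptor_names: list[str] | None = None,
    with_cv: bool = False,
) -> LinearModel:
    """Ordinary least squares with intercept.

    ``r2 = 1 - SSres/SStot`` and ``s2 = SSres/(n - k - 1)``.  A constant
    response is a degenerate input: r2 is defined as 0 with a warning so
    screening pipelines do not abort.  A rank-deficient design raises
    :class:`NumericalError` naming the collinear columns.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and X.shape[1] > 1 and len(y) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = descriptor_names if descriptor_names is not None else [f"x{j+1}" for j in range(k)]
    if n <= k + 1:
        raise DomainError(f"need n > k + 1 observations, got n={n}, k={k}")
    A = _design(X)
    if np.linalg.matrix_rank(A) < k + 1:
        raise NumericalError(
            f"rank-deficient design; collinear columns: {_name_collinear(X, list(names))}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant response: r2 defined as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    model = LinearModel(
        descriptors=list(names),
        coefficients=beta[1:].copy(),
        intercept=float(beta[0]),
        r2=r2,
        s2=ss_res / (n - k - 1),
        n=n,
    )
    if with_cv:
        model.r2cv = loo_r2cv(X, y)
        model.f_stat = f_statistic(model) if r2 < 1.0 - 1e-12 else float("inf")
    return model


def loo_r2cv(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out cross-validated R², ``1 - PRESS/SStot``.

    Uses the hat-matrix identity ``e_(i) = e_i / (1 - h_ii)`` for the
    deleted residuals; equivalent to n explicit refits (and tested against
    them).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and len(np.asarray(y)) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 2:
        raise DomainError(f"need n > k + 2 for leave-one-out, got n={n}, k={k}")
    A = _design(X)
    if np.linalg.matrix_rank(A) < k + 1:
        raise NumericalError("rank-deficient design in leave-one-out")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    # leverages via the thin QR of the design
    Q, _ = np.linalg.qr(A)
    h = (Q**2).sum(axis=1)
    if np.any(1.0 - h < 1e-12):
        raise NumericalError("a leave-one-out refit is singular (leverage 1 row)")
    press = float(((resid / (1.0 - h)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant response: r2cv defined as 0", stacklevel=2)
        return 0.0
    return 1.0 - press / ss_tot


def f_statistic(model: LinearModel) -> float:
    """F = (R²/k) / ((1 − R²)/(n − k − 1)); a perfect fit has no finite F."""
    if model.r2 >= 1.0 - 1e-12:
        raise NumericalError("perfect fit (r2 = 1): F-statistic undefined")
    k, n = model.k, model.n
    return (model.r2 / k) / ((1.0 - model.r2) / (n - k - 1))


def max_k_for_n(n: int) -> int:
    """Largest model size allowed by the sample-size rule ``n >= 3(k + 1)``."""
    return n // 3 - 1


def forward_select(
    table: DescriptorTable,
    k_max: int | None = None,
    with_cv: bool = True,
) -> SelectionTrace:
    """Greedy forward selection maximizing R² at each augmentation.

    Ties are broken by descriptor-name order.  ``k_max`` is capped by the
    sample-size rule; candidates whose addition makes the design singular
    are skipped, and the trace is truncated (with a warning) if no
    admissible candidate remains.
    """
    n = table.n
    cap = max(1, max_k_for_n(n))
    if k_max is None:
        k_max = cap
    elif k_max > cap:
        warnings.warn(
            f"k_max={k_max} exceeds the n >= 3(k+1) cap for n={n}; using {cap}",
            stacklevel=2,
        )
        k_max = cap
    k_max = min(k_max, table.p)

    y = table.activity
    selected: list[str] = []
    trace = SelectionTrace()
    for _ in range(k_max):
        candidates = sorted(set(table.descriptor_names) - set(selected))
        best_name, best_r2 = None, -np.inf
        for name in candidates:
            cols = selected + [name]
            X = np.column_stack([table.column(c) for c in cols])
            A = _design(X)
            if np.linalg.matrix_rank(A) < len(cols) + 1:
                continue
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
            if r2 > best_r2 + 1e-15:
                best_name, best_r2 = name, r2
        if best_name is None:
            warnings.warn("no admissible descriptor to add; trace truncated", stacklevel=2)
            break
        selected.append(best_name)
        X = np.column_stack([table.column(c) for c in selected])
        trace.models.append(fit_ols(X, y, descriptor_names=list(selected), with_cv=with_cv))
    return trace


def breaking_point(
    trace: SelectionTrace,
    tol: float = DEFAULT_BREAKING_TOL,
    n: int | None = None,
) -> int:
    """Choose the model size at which R² gains become negligible.

    Returns the smallest k with ``r2(k+1) - r2(k) < tol``, further capped
    so that ``n >= 3(k + 1)``; falls back to the last traced k under the
    cap when every gain exceeds the tolerance.  The choice is recorded on
    the trace.
    """
    if not trace.models:
        raise DomainError("empty selection trace")
    if n is None:
        n = trace.models[0].n
    cap = max(1, max_k_for_n(n))
    r2s = [m.r2 for m in trace.models]
    chosen = min(len(r2s), cap)
    for k in range(1, len(r2s)):
        if r2s[k] - r2s[k - 1] < tol:
            chosen = min(k, cap)
            break
    trace.chosen_k = chosen
    return chosen
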