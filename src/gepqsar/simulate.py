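"""Synthetic descriptor tables with planted ground truth.

The generator emulates the statistical structure of a large
quantum-chemical descriptor export for a small compound series: a
compounds × descriptors matrix containing degenerate columns (all-zero or
constant), near-collinear column pairs, irrelevant noise columns, and a
small set of activity-relevant columns through which a known response is
planted — either a linear combination (for validating descriptor
selection) or a {+, −, *, /} expression tree (for validating symbolic
regression) — plus Gaussian noise.  Because the truth is known, every
pipeline stage can be scored for recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from gepqsar.dataset import DescriptorTable
from gepqsar.errors import ConfigError, ValidationError
from gepqsar.gep import ExpressionTree, Node, evaluate_matrix, to_infix

__all__ = ["SyntheticSpec", "GroundTruth", "RecoveryReport", "generate", "score_recovery"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic table.

    The default shape (39 × 551) mirrors a CODESSA-scale export for a
    39-compound series; tests use smaller tables.  ``true_expression`` is
    a nested ``(op, left, right)`` tuple over ``true_support`` labels.
    """

    n_compounds: int = 39
    n_descriptors: int = 551
    n_degenerate: int = 10
    n_collinear_pairs: int = 10
    collinear_r: float = 0.99
    response_kind: str = "linear"  # "linear" | "expression"
    true_support: tuple[str, ...] = ("d001", "d002")
    true_coefficients: tuple[float, ...] = (1.0, 2.0)
    true_expression: Node | None = None
    intercept: float = 0.0
    noise_sd: float = 0.05
    marginal: str = "normal"  # "normal" | "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "true_support", tuple(self.true_support))
        object.__setattr__(self, "true_coefficients", tuple(self.true_coefficients))
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.response_kind not in ("linear", "expression"):
            raise ConfigError(f"unknown response_kind {self.response_kind!r}")
        if self.response_kind == "linear" and len(self.true_coefficients) != len(self.true_support):
            raise ConfigError("true_coefficients must match true_support in length")
        if self.response_kind == "expression" and self.true_expression is None:
            raise ConfigError("expression response requires true_expression")
        if not 0.0 < self.collinear_r < 1.0:
            raise ConfigError("collinear_r must lie in (0, 1)")
        if self.marginal not in ("normal", "lognormal"):
            raise ConfigError(f"unknown marginal {self.marginal!r}")
        budget = self.n_degenerate + 2 * self.n_collinear_pairs + len(self.true_support)
        if budget > self.n_descriptors:
            raise ConfigError(
                f"n_degenerate + 2*n_collinear_pairs + |support| = {budget} "
                f"exceeds n_descriptors = {self.n_descriptors}"
            )


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    spec: SyntheticSpec
    noiseless_response: np.ndarray
    degenerate_names: list[str]
    collinear_pairs: list[tuple[str, str]]

    @property
    def true_support(self) -> tuple[str, ...]:
        return self.spec.true_support


@dataclass
class RecoveryReport:
    """Outcome of a recovery check against the planted truth."""

    support_recovered: bool | None = None
    selected: list[str] = field(default_factory=list)
    coefficient_rmse: float | None = None
    expression_rmse: float | None = None


def _name(i: int, width: int) -> str:
    return f"d{i:0{width}d}"


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw one table. Fully deterministic given ``spec`` (including its seed).

    Base descriptors are i.i.d. standard normal (optionally log-normal);
    each collinear pair satisfies ``x' = r·x + sqrt(1 − r²)·ε``; the
    response is the planted linear combination or expression evaluated on
    the support columns, plus ``N(0, noise_sd²)`` noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    width = max(3, len(str(p)))
    names = [_name(i + 1, width) for i in range(p)]
    support = list(spec.true_support)
    unknown = [s for s in support if s not in set(names)]
    if unknown:
        raise ConfigError(f"true_support labels outside the generated names: {unknown}")

    values = rng.standard_normal((n, p))
    if spec.marginal == "lognormal":
        values = np.exp(0.5 * values)

    # columns not carrying the response, in name order, to repurpose
    free = [i for i, nm in enumerate(names) if nm not in set(support)]
    free_iter = iter(free[::-1])  # consume from the high end, away from the support

    collinear_pairs: list[tuple[str, str]] = []
    for _ in range(spec.n_collinear_pairs):
        i, j = next(free_iter), next(free_iter)
        eps = rng.standard_normal(n)
        base = values[:, i]
        values[:, j] = spec.collinear_r * base + np.sqrt(1 - spec.collinear_r**2) * eps
        collinear_pairs.append((names[i], names[j]))

    degenerate_names: list[str] = []
    for d in range(spec.n_degenerate):
        i = next(free_iter)
        values[:, i] = 0.0 if d % 2 == 0 else 3.2
        degenerate_names.append(names[i])

    cols = {s: values[:, names.index(s)] for s in support}
    if spec.response_kind == "linear":
        X_sup = np.column_stack([cols[s] for s in support]) if support else np.zeros((n, 0))
        noiseless = spec.intercept + X_sup @ np.asarray(spec.true_coefficients)
    else:
        tree = ExpressionTree(gene_trees=(spec.true_expression,), linking_function="+")
        noiseless, invalid = evaluate_matrix(tree, cols)
        if invalid.any():
            raise ValidationError(
                "planted expression evaluates invalid (division guard) on "
                f"{int(invalid.sum())} generated rows; choose another expression or seed"
            )
        noiseless = spec.intercept + noiseless
    activity = noiseless + rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else noiseless.copy()

    table = DescriptorTable(
        compound_ids=[f"c{i+1:03d}" for i in range(n)],
        descriptor_names=names,
        values=values,
        activity=activity,
    )
    truth = GroundTruth(
        spec=spec,
        noiseless_response=noiseless,
        degenerate_names=degenerate_names,
        collinear_pairs=collinear_pairs,
    )
    return table, truth


def score_recovery(
    truth: GroundTruth,
    selected_descriptors: Sequence[str] | None = None,
    fitted_coefficients: Mapping[str, float] | None = None,
    best_tree: ExpressionTree | None = None,
    table: DescriptorTable | None = None,
) -> RecoveryReport:
    """Score a selection or an evolved expression against the planted truth.

    Support recovery means the true support is a subset of the selection.
    For a linear truth, the coefficient RMSE compares fitted coefficients
    on the true support (a descriptor not in the fit counts as 0).  For an
    expression truth, the training RMSE of ``best_tree`` is measured
    against the noiseless response on the generated table.
    """
    report = RecoveryReport()
    if selected_descriptors is not None:
        report.selected = list(selected_descriptors)
        report.support_recovered = set(truth.true_support) <= set(selected_descriptors)
    if fitted_coefficients is not None and truth.spec.response_kind == "linear":
        errs = [
            fitted_coefficients.get(name, 0.0) - coef
            for name, coef in zip(truth.spec.true_support, truth.spec.true_coefficients)
        ]
        report.coefficient_rmse = float(np.sqrt(np.mean(np.square(errs)))) if errs else 0.0
    if best_tree is not None:
        if table is None:
            raise ConfigError("scoring an expression requires the generated table")
        cols = {t: table.column(t) for t in best_tree.terminals()}
        pred, invalid = evaluate_matrix(best_tree, cols)
        if invalid.any():
            report.expression_rmse = float("inf")
        else:
            report.expression_rmse = float(
                np.sqrt(np.mean((pred - truth.noiseless_response) ** 2))
            )
    return report


def describe_truth(truth: GroundTruth) -> dict:
    """JSON-serializable account of the planted ground truth (for sidecar files)."""
    spec = truth.spec
    out: dict = {
        "response_kind": spec.response_kind,
        "true_support": list(spec.true_support),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "degenerate": truth.degenerate_names,
        "collinear_pairs": [list(p) for p in truth.collinear_pairs],
    }
    if spec.response_kind == "linear":
        out["true_coefficients"] = list(spec.true_coefficients)
        out["intercept"] = spec.intercept
    else:
        out["true_expression"] = to_infix(spec.true_expression)
    return out
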