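"""Model-quality statistics and the HM-vs-GEP comparison.

Two r² conventions coexist in QSAR reporting and diverge for nonlinear
models: the OLS-internal ``1 − SSres/SStot`` (kept inside the regression
module) and the squared Pearson correlation between predicted and
observed, which is what this module computes so linear and symbolic
models are compared on the same footing.  MSE here uses divisor n; the
degrees-of-freedom-corrected ``s²`` lives with the linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from gepqsar.dataset import (
    CompoundRecord,
    SplitSpec,
    log_activity,
    records_to_frame,
)
from gepqsar.errors import DomainError, NumericalError

__all__ = ["ModelMetrics", "ComparisonTable", "metrics", "hm_difference", "compare_models"]


@dataclass(frozen=True)
class ModelMetrics:
    """Squared Pearson r², MSE (divisor n), RMSE and signed residuals."""

    r2: float
    mse: float
    rmse: float
    n: int
    residuals: np.ndarray  # predicted − observed, per compound

    def round(self, digits: int = 4) -> "ModelMetrics":
        return ModelMetrics(
            r2=round(self.r2, digits),
            mse=round(self.mse, digits),
            rmse=round(self.rmse, digits),
            n=self.n,
            residuals=self.residuals,
        )


@dataclass
class ComparisonTable:
    """Per-compound predictions and per-split summary metrics for both models."""

    rows: pd.DataFrame
    summary: dict[str, dict[str, ModelMetrics]]  # model → split → metrics
    verdicts: dict[str, str]  # split → "GEP" | "HM" | "tie"

    def summary_frame(self) -> pd.DataFrame:
        recs = []
        for model, per_split in self.summary.items():
            for split, m in per_split.items():
                recs.append((model, split, m.n, m.r2, m.mse, m.rmse))
        return pd.DataFrame(recs, columns=["model", "split", "n", "r2", "mse", "rmse"])


def metrics(predicted: Sequence[float], observed: Sequence[float]) -> ModelMetrics:
    """Squared Pearson correlation and mean squared error of predictions.

    Raises :class:`NumericalError` when either vector has zero variance
    (the correlation is undefined); the MSE is reported in the message.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise DomainError(f"need equal non-empty vectors, got {p.shape} vs {o.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise DomainError("metrics input contains invalid (non-finite) predictions")
    resid = p - o
    mse = float(np.mean(resid**2))
    if p.size < 2 or np.var(p) == 0.0 or np.var(o) == 0.0:
        raise NumericalError(f"zero-variance input: r2 undefined (mse = {mse:.6g})")
    r = float(np.corrcoef(p, o)[0, 1])
    return ModelMetrics(r2=r * r, mse=mse, rmse=float(np.sqrt(mse)), n=p.size, residuals=resid)


def hm_difference(predicted: float, inhibition_pct: float, compound_id: str | None = None) -> float:
    """Signed residual ``predicted − log10(inhibition %)`` (reported to 3 decimals)."""
    return predicted - log_activity(inhibition_pct, compound_id)


def compare_models(
    records: Sequence[CompoundRecord],
    split: SplitSpec | None = None,
    hm_column: str = "hm_predicted",
    gep_column: str = "gep_model",
) -> ComparisonTable:
    """Compare the two prediction columns of the benchmark per split.

    The verdict per split names the model with strictly higher r² and
    strictly lower MSE, or "tie" when neither dominates.  Swapping the two
    columns inverts every verdict.
    """
    df = records_to_frame(records)
    if split is None:
        split = SplitSpec(
            train_ids=tuple(df.loc[~df.is_test, "compound_id"]),
            test_ids=tuple(df.loc[df.is_test, "compound_id"]),
            seed="fixed",
        )
    rows = df[["compound_id", "target_log", hm_column, gep_column]].copy()
    rows.columns = ["compound_id", "observed", "hm", "gep"]
    rows["hm_residual"] = rows.hm - rows.observed
    rows["gep_residual"] = rows.gep - rows.observed
    rows["split"] = np.where(
        rows.compound_id.isin(split.test_ids), "test",
        np.where(rows.compound_id.isin(split.train_ids), "train", "unassigned"),
    )

    summary: dict[str, dict[str, ModelMetrics]] = {"HM": {}, "GEP": {}}
    verdicts: dict[str, str] = {}
    for name, ids in (("train", split.train_ids), ("test", split.test_ids)):
        sub = rows[rows.compound_id.isin(ids)]
        m_hm = metrics(sub.hm.to_numpy(), sub.observed.to_numpy())
        m_gep = metrics(sub.gep.to_numpy(), sub.observed.to_numpy())
        summary["HM"][name] = m_hm
        summary["GEP"][name] = m_gep
        if m_gep.r2 > m_hm.r2 and m_gep.mse < m_hm.mse:
            verdicts[name] = "GEP"
        elif m_hm.r2 > m_gep.r2 and m_hm.mse < m_gep.mse:
            verdicts[name] = "HM"
        else:
            verdicts[name] = "tie"
    return ComparisonTable(rows=rows, summary=summary, verdicts=verdicts)
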