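"""Descriptor pre-selection: the three pruning rules applied before model building.

Large quantum-chemical descriptor exports contain columns that carry no
information (all-zero or constant), columns that duplicate each other
almost exactly, and columns unrelated to the activity.  The screen removes
them in that order:

(a) degenerate columns — zero variance;
(b) inter-correlated pairs — for every pair with ``|Pearson r| > r_max``
    the member less correlated with the activity is dropped;
(c) low-relevance columns — ``|Pearson r(descriptor, activity)| < r_min``.

The thresholds default to conventional QSAR screening values
(``r_max = 0.95``, ``r_min = 0.05``) and are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gepqsar.dataset import DescriptorTable
from gepqsar.errors import ConfigError

__all__ = [
    "ScreeningReport",
    "drop_degenerate",
    "drop_intercorrelated",
    "drop_low_relevance",
    "screen_descriptors",
    "DEFAULT_R_MAX",
    "DEFAULT_R_MIN",
]

DEFAULT_R_MAX = 0.95
DEFAULT_R_MIN = 0.05


@dataclass
class ScreeningReport:
    """Which descriptors each rule removed, and why.

    The three dropped lists plus ``surviving`` always partition the
    original descriptor names.
    """

    dropped_degenerate: list[str] = field(default_factory=list)
    dropped_intercorrelated: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_low_relevance: list[tuple[str, float]] = field(default_factory=list)
    surviving: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            len(self.dropped_degenerate)
            + len(self.dropped_intercorrelated)
            + len(self.dropped_low_relevance)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("degenerate", d, "", "") for d in self.dropped_degenerate]
        rows += [
            ("intercorrelated", dropped, kept, f"{r:.6f}")
            for kept, dropped, r in self.dropped_intercorrelated
        ]
        rows += [
            ("low_relevance", d, "", f"{r:.6f}") for d, r in self.dropped_low_relevance
        ]
        rows += [("surviving", d, "", "") for d in self.surviving]
        return pd.DataFrame(rows, columns=["status", "descriptor", "kept_partner", "correlation"])


def _pearson_to_activity(values: np.ndarray, activity: np.ndarray) -> np.ndarray:
    """|r| of each column with the activity; zero-variance columns get 0."""
    x = values - values.mean(axis=0)
    y = activity - activity.mean()
    sx = np.sqrt((x**2).sum(axis=0))
    sy = np.sqrt((y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ y) / (sx * sy)
    return np.where(np.isfinite(r), r, 0.0)


def drop_degenerate(table: DescriptorTable) -> tuple[DescriptorTable, ScreeningReport]:
    """Rule (a): remove all-zero / constant (zero-variance) columns."""
    # exact constancy (max == min) rather than float variance, which can be
    # a nonzero rounding artifact for a constant column
    keep = np.ptp(table.values, axis=0) > 0.0
    dropped = [n for n, k in zip(table.descriptor_names, keep) if not k]
    survivors = [n for n, k in zip(table.descriptor_names, keep) if k]
    if not survivors:
        warnings.warn("degeneracy screen removed every descriptor", stacklevel=2)
    report = ScreeningReport(dropped_degenerate=dropped, surviving=survivors)
    return table.select_columns(survivors), report


def drop_intercorrelated(
    table: DescriptorTable, r_max: float = DEFAULT_R_MAX
) -> tuple[DescriptorTable, ScreeningReport]:
    """Rule (b): break up descriptor pairs correlated beyond ``r_max``.

    Offending pairs are processed in decreasing |r|; within a pair the
    descriptor with the smaller |correlation to activity| is dropped, with
    exact ties broken by descriptor-name order.  After the pass no
    surviving pair exceeds the threshold.
    """
    if not 0.0 < r_max <= 1.0:
        raise ConfigError(f"r_max must lie in (0, 1], got {r_max}")
    names = table.descriptor_names
    p = len(names)
    if p < 2:
        return table.select_columns(names), ScreeningReport(surviving=list(names))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(table.values, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    rel = np.abs(_pearson_to_activity(table.values, table.activity))

    iu, ju = np.triu_indices(p, k=1)
    mask = np.abs(corr[iu, ju]) > r_max
    pairs = sorted(
        zip(iu[mask], ju[mask]),
        key=lambda ij: (-abs(corr[ij[0], ij[1]]), names[ij[0]], names[ij[1]]),
    )
    alive = np.ones(p, dtype=bool)
    dropped: list[tuple[str, str, float]] = []
    for i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        if rel[i] > rel[j]:
            keep_i, drop_i = i, j
        elif rel[j] > rel[i]:
            keep_i, drop_i = j, i
        else:  # exact tie: keep the alphabetically first name
            keep_i, drop_i = (i, j) if names[i] <= names[j] else (j, i)
        alive[drop_i] = False
        dropped.append((names[keep_i], names[drop_i], float(corr[i, j])))
    survivors = [n for n, a in zip(names, alive) if a]
    report = ScreeningReport(dropped_intercorrelated=dropped, surviving=survivors)
    return table.select_columns(survivors), report


def drop_low_relevance(
    table: DescriptorTable, r_min: float = DEFAULT_R_MIN
) -> tuple[DescriptorTable, ScreeningReport]:
    """Rule (c): remove descriptors with ``|r(descriptor, activity)| < r_min``."""
    if not 0.0 <= r_min < 1.0:
        raise ConfigError(f"r_min must lie in [0, 1), got {r_min}")
    rel = _pearson_to_activity(table.values, table.activity)
    keep = np.abs(rel) >= r_min
    dropped = [
        (n, float(r)) for n, r, k in zip(table.descriptor_names, rel, keep) if not k
    ]
    survivors = [n for n, k in zip(table.descriptor_names, keep) if k]
    if not survivors:
        warnings.warn("relevance screen removed every descriptor", stacklevel=2)
    report = ScreeningReport(dropped_low_relevance=dropped, surviving=survivors)
    return table.select_columns(survivors), report


def screen_descriptors(
    table: DescriptorTable,
    r_max: float = DEFAULT_R_MAX,
    r_min: float = DEFAULT_R_MIN,
) -> tuple[DescriptorTable, ScreeningReport]:
    """Apply the three rules in order (a) → (b) → (c) and merge the reports."""
    t1, rep_a = drop_degenerate(table)
    t2, rep_b = drop_intercorrelated(t1, r_max=r_max)
    t3, rep_c = drop_low_relevance(t2, r_min=r_min)
    report = ScreeningReport(
        dropped_degenerate=rep_a.dropped_degenerate,
        dropped_intercorrelated=rep_b.dropped_intercorrelated,
        dropped_low_relevance=rep_c.dropped_low_relevance,
        surviving=rep_c.surviving,
    )
    return t3, report
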