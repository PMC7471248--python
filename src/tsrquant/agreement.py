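"""Computer-vs-pathologist agreement statistics.

The computer-aided TSR category is compared against the pathologists'
category (the reference standard) on paired cases: 2x2 cross-tabulation,
diagnostic metrics for the high-stromal-component class (sensitivity,
specificity, PPV, NPV and the F1 score ``2PR/(P+R)``), and the weighted
Cohen kappa with either a bootstrap-percentile or an asymptotic
confidence interval.  On two categories the unweighted, linear and
quadratic kappas coincide; the weighted machinery is retained so ordinal
scales cross-tabulate correctly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .labels import CATEGORIES, HIGH_STROMAL, LOW_STROMAL

__all__ = [
    "ConfusionTable",
    "DiagnosticMetrics",
    "KappaResult",
    "confusion_table",
    "diagnostic_metrics",
    "cohen_kappa",
    "kappa_ci",
]

Weighting = Literal["none", "linear", "quadratic"]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tab of computer (rows) vs pathologist (columns) categories.

    The positive class is the high stromal component: ``a`` computer-high &
    pathologist-high, ``b`` computer-high & pathologist-low, ``c``
    computer-low & pathologist-high, ``d`` computer-low & pathologist-low.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("confusion table must contain at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Diagnostic accuracy of the computer path for the high-stromal class.

    Undefined metrics (zero denominator) are NaN; precision/recall alias
    PPV/sensitivity and F1 is their harmonic mean.
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    @property
    def precision(self) -> float:
        return self.ppv

    @property
    def recall(self) -> float:
        return self.sensitivity


@dataclass(frozen=True)
class KappaResult:
    """Chance-corrected agreement ``(po - pe) / (1 - pe)`` with its CI."""

    kappa: float
    po: float
    pe: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    ci_method: str | None = None
    n_boot: int | None = None
    seed: int | None = None


def confusion_table(
    computer_labels: Sequence[str], pathologist_labels: Sequence[str]
) -> ConfusionTable:
    """Cross-tabulate paired categories with the pathologist as reference."""
    comp = list(computer_labels)
    path = list(pathologist_labels)
    if len(comp) != len(path):
        raise ValueError(f"length mismatch: {len(comp)} computer vs {len(path)} pathologist")
    unknown = (set(comp) | set(path)) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}; expected {CATEGORIES}")
    cells = {(HIGH_STROMAL, HIGH_STROMAL): 0, (HIGH_STROMAL, LOW_STROMAL): 0,
             (LOW_STROMAL, HIGH_STROMAL): 0, (LOW_STROMAL, LOW_STROMAL): 0}
    for pair in zip(comp, path):
        cells[pair] += 1
    return ConfusionTable(
        a=cells[(HIGH_STROMAL, HIGH_STROMAL)],
        b=cells[(HIGH_STROMAL, LOW_STROMAL)],
        c=cells[(LOW_STROMAL, HIGH_STROMAL)],
        d=cells[(LOW_STROMAL, LOW_STROMAL)],
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def diagnostic_metrics(t: ConfusionTable) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and F1 for the high-stromal class."""
    sens = _safe_div(t.a, t.a + t.c)
    spec = _safe_div(t.d, t.b + t.d)
    ppv = _safe_div(t.a, t.a + t.b)
    npv = _safe_div(t.d, t.c + t.d)
    f1 = _safe_div(2 * t.a, 2 * t.a + t.b + t.c)  # = 2PR/(P+R)
    return DiagnosticMetrics(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f1=f1)


def _weight_matrix(k: int, weighting: Weighting) -> np.ndarray:
    """Disagreement weights w_ij in [0, 1]; 0 on the diagonal."""
    i, j = np.indices((k, k))
    if weighting == "none":
        return (i != j).astype(float)
    dist = np.abs(i - j) / max(k - 1, 1)
    if weighting == "linear":
        return dist.astype(float)
    if weighting == "quadratic":
        return dist.astype(float) ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


def _kappa_from_counts(table: np.ndarray, weighting: Weighting) -> tuple[float, float, float]:
    n = table.sum()
    p = table / n
    w = _weight_matrix(table.shape[0], weighting)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    qo = float((w * p).sum())   # observed weighted disagreement
    qe = float((w * expected).sum())
    if qe == 0:
        raise ValueError("kappa undefined: degenerate single-category marginals")
    kappa = 1.0 - qo / qe
    # For reporting, express po/pe on the agreement scale (exact for 2x2).
    return kappa, 1.0 - qo, 1.0 - qe


def cohen_kappa(t: ConfusionTable, weighting: Weighting = "none") -> KappaResult:
    """Cohen kappa of a 2x2 table; all weightings coincide on 2 categories."""
    kappa, po, pe = _kappa_from_counts(t.as_array(), weighting)
    return KappaResult(kappa=kappa, po=po, pe=pe)


def kappa_ci(
    t: ConfusionTable,
    method: Literal["bootstrap", "asymptotic"] = "bootstrap",
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    weighting: Weighting = "none",
) -> tuple[float, float]:
    """Confidence interval for kappa.

    ``bootstrap`` resamples the paired cases with replacement and takes
    the percentile interval (degenerate resamples, where one rater uses a
    single category, are skipped and counted; a warning is raised if more
    than 10% are skipped).  ``asymptotic`` uses Cohen's large-sample
    standard error ``sqrt(po(1-po) / (n (1-pe)^2))``.
    """
    if t.n < 2:
        raise ValueError("confidence interval requires n >= 2")
    base = cohen_kappa(t, weighting)
    alpha = 1.0 - level
    if method == "asymptotic":
        se = math.sqrt(base.po * (1.0 - base.po) / (t.n * (1.0 - base.pe) ** 2))
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return (base.kappa - z * se, base.kappa + z * se)
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")

    rng = np.random.default_rng(seed)
    # Case labels: 0..3 = cells (a, b, c, d); resample cases, re-tabulate.
    cases = np.repeat(np.arange(4), [t.a, t.b, t.c, t.d])
    estimates = []
    skipped = 0
    for _ in range(n_boot):
        counts = np.bincount(rng.choice(cases, size=t.n, replace=True), minlength=4)
        table = counts.reshape(2, 2)
        try:
            kappa, _, _ = _kappa_from_counts(table, weighting)
        except ValueError:
            skipped += 1
            continue
        estimates.append(kappa)
    if skipped > 0.10 * n_boot:
        warnings.warn(
            f"{skipped}/{n_boot} bootstrap resamples were degenerate and skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if not estimates:
        raise ValueError("all bootstrap resamples were degenerate")
    lo, hi = np.quantile(estimates, [alpha / 2.0, 1.0 - alpha / 2.0])
    return (float(lo), float(hi))
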