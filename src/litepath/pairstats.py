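"""Paired comparison of classifiers evaluated on the same test set.

Two classifiers scored on identical samples yield a 2x2 concordance table of
per-sample correctness; the discordant cells *b* (reference right, competitor
wrong) and *c* (reference wrong, competitor right) carry all the information
about a difference in error rates. Under the null of equal error rates,
b ~ Binomial(b + c, 1/2), and the exact two-sided McNemar p-value is twice the
smaller tail probability, clamped at 1:

    p = min(1, 2 * P[X <= min(b, c)]),  X ~ Binomial(b + c, 1/2).

The tail is summed with Python integer arithmetic (sum of binomial
coefficients over 2^n), so the result is exact to float rounding — no normal
approximation is ever used. Family-wise error over several comparisons is
controlled with the Holm–Bonferroni step-down adjustment applied to the
unrounded p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PairedOutcome",
    "McNemarResult",
    "StabilitySummary",
    "paired_outcomes",
    "mcnemar_exact",
    "mcnemar_chi2",
    "holm_adjust",
    "compare_to_reference",
    "stability_summary",
]


@dataclass(frozen=True)
class PairedOutcome:
    """Four-cell concordance table of per-sample correctness."""

    n11: int  # both correct
    b: int    # A correct, B wrong
    c: int    # A wrong, B correct
    n00: int  # both wrong

    def __post_init__(self) -> None:
        for name in ("n11", "b", "c", "n00"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.n11 + self.b + self.c + self.n00

    @property
    def n_discordant(self) -> int:
        return self.b + self.c


@dataclass(frozen=True)
class McNemarResult:
    """Exact McNemar test outcome for one pairwise comparison."""

    comparison: str
    b: int
    c: int
    p_exact: float
    p_adjusted: float
    significant: bool | None = None
    n_discordant: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_discordant", self.b + self.c)
        if not (0 < self.p_exact <= 1):
            raise ValueError("p_exact must lie in (0, 1]")
        if self.p_adjusted < self.p_exact - 1e-15:
            raise ValueError("adjusted p-value cannot be below the raw p-value")


def paired_outcomes(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> PairedOutcome:
    """Tabulate per-sample correctness of two classifiers into the 2x2 table."""
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"correctness vectors must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise ValueError("correctness vectors are empty")
    return PairedOutcome(
        n11=int(np.sum(a & b)),
        b=int(np.sum(a & ~b)),
        c=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant counts.

    Doubles the smaller binomial tail at p = 1/2 and clamps at 1; symmetric
    in (b, c). Raises if there are no discordant pairs (test undefined).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        raise ValueError(
            "McNemar test undefined: no discordant pairs (b + c = 0)"
        )
    m = min(b, c)
    # Exact rational tail: sum_{k<=m} C(n,k) / 2^n, evaluated in integers.
    tail_num = sum(math.comb(n, k) for k in range(m + 1))
    p = 2 * tail_num / (1 << n)
    return min(1.0, p)


def mcnemar_chi2(b: int, c: int) -> float:
    """Continuity-corrected chi-square McNemar p-value (labeled alternative;
    the exact binomial form is the default everywhere in this package)."""
    from scipy.stats import chi2

    n = b + c
    if n == 0:
        raise ValueError("McNemar test undefined: no discordant pairs")
    stat = (abs(b - c) - 1) ** 2 / n
    return float(chi2.sf(stat, df=1))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm–Bonferroni step-down adjusted p-values, in the input order.

    adjusted_(k) = max_{j <= k} min(1, (m - j + 1) * p_(j)) over the ascending
    order statistics; monotone, elementwise >= raw and <= Bonferroni.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted_sorted = np.maximum.accumulate(stepped)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def compare_to_reference(
    reference_pred: Sequence[int],
    competitor_preds: Mapping[str, Sequence[int]],
    y_true: Sequence[int],
    alpha: float = 0.05,
    reference_name: str = "reference",
) -> list[McNemarResult]:
    """Exact McNemar test of a reference classifier against each competitor on
    a shared test set, with Holm adjustment across the family.

    ``b`` counts samples the reference gets right and the competitor wrong.
    """
    y = np.asarray(y_true)
    ref = np.asarray(reference_pred)
    if ref.shape != y.shape:
        raise ValueError("reference predictions not aligned with y_true")
    correct_ref = ref == y
    raw: list[tuple[str, PairedOutcome, float]] = []
    for name, pred in competitor_preds.items():
        pred = np.asarray(pred)
        if pred.shape != y.shape:
            raise ValueError(f"predictions for {name!r} not aligned with y_true")
        outcome = paired_outcomes(correct_ref, pred == y)
        raw.append((name, outcome, mcnemar_exact(outcome.b, outcome.c)))
    adjusted = holm_adjust([p for _, _, p in raw])
    return [
        McNemarResult(
            comparison=f"{reference_name} vs {name}",
            b=outcome.b,
            c=outcome.c,
            p_exact=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
        )
        for (name, outcome, p), p_adj in zip(raw, adjusted)
    ]


@dataclass(frozen=True)
class StabilitySummary:
    """Mean and sample standard deviation of metrics over repeated runs."""

    metrics: dict[str, dict[str, float]]
    n_runs: int

    def format(self, metric: str, digits: int = 4) -> str:
        m = self.metrics[metric]
        return f"{m['mean']:.{digits}f} ± {m['sd']:.{digits}f}"

    def to_dict(self) -> dict:
        return {"n_runs": self.n_runs, "metrics": self.metrics}


def stability_summary(metric_values: Mapping[str, Sequence[float]]) -> StabilitySummary:
    """Summarise per-run metric values as mean ± sample sd (n-1 denominator)."""
    out: dict[str, dict[str, float]] = {}
    n_runs = None
    for name, values in metric_values.items():
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError(
                f"stability summary needs at least 2 runs, got {values.size} for {name!r}"
            )
        if n_runs is None:
            n_runs = values.size
        elif values.size != n_runs:
            raise ValueError("all metrics must cover the same runs")
        out[name] = {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)),
            "values": values.tolist(),
        }
    if n_runs is None:
        raise ValueError("no metrics supplied")
    return StabilitySummary(metrics=out, n_runs=n_runs)
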