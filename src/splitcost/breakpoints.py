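"""Breakpoint schemes for categorizing a continuous predictor.

Implements the categorization rules most often seen in the ecological
literature: a median split (two groups), the uneven three-group split
(<25%, 25-75%, >75%), quartiles, fixed-width intervals aligned to multiples
of the width (labels like "60-65"), a "natural break" rule for bimodal
distributions (cut at the widest internal gap), and user-supplied edges.

Categories are half-open ``[low, high)`` with the final interval closed at
the maximum, and a value exactly on an interior edge is assigned to the
higher category.  Quantiles use linear interpolation of order statistics
(the common "type 7" convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CategorizationError

__all__ = ["BreakScheme", "CategorizedPredictor", "compute_edges", "assign"]

KINDS = ("median", "uneven", "quartiles", "interval", "bimodal", "custom")

#: en dash used in interval labels, e.g. "60–65"
_DASH = "–"


@dataclass(frozen=True)
class BreakScheme:
    """A categorization rule.

    kind : one of median / uneven / quartiles / interval / bimodal / custom.
    interval_width : bin width in predictor units (interval kind; default 5).
    custom_edges : strictly increasing interior edges (custom kind).
    bimodal_min_gap : smallest empty gap accepted as a "natural break".
    """

    kind: str
    interval_width: float = 5.0
    custom_edges: Sequence[float] | None = None
    bimodal_min_gap: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CategorizationError(
                f"unknown scheme kind '{self.kind}'; known: {KINDS}"
            )
        if self.kind == "interval" and self.interval_width <= 0:
            raise CategorizationError("interval_width must be > 0")
        if self.kind == "custom":
            if not self.custom_edges:
                raise CategorizationError("custom scheme requires custom_edges")
            e = np.asarray(self.custom_edges, dtype=float)
            if len(e) and np.any(np.diff(e) <= 0):
                raise CategorizationError("custom_edges must be strictly increasing")

    @property
    def name(self) -> str:
        return self.kind

    @classmethod
    def from_dict(cls, mapping: dict) -> "BreakScheme":
        """Build from a config mapping like ``{kind: interval, interval_width: 5}``."""
        return cls(**mapping)


@dataclass(frozen=True)
class CategorizedPredictor:
    """A realized categorization: interior edges, labels and row assignment."""

    edges: tuple[float, ...]
    labels: tuple[str, ...]
    assignment: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise CategorizationError(
                f"{len(self.edges)} edges need {len(self.edges) + 1} labels, "
                f"got {len(self.labels)}"
            )
        if len(self.edges) >= 2 and np.any(np.diff(self.edges) <= 0):
            raise CategorizationError("edges must be strictly increasing")

    @property
    def assigned_labels(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)[self.assignment]


def _quantile_edges(values: np.ndarray, probs: Sequence[float]) -> list[float]:
    edges = [float(np.quantile(values, p)) for p in probs]  # type 7 (linear)
    for lo, hi, plo, phi in zip(edges, edges[1:], probs, probs[1:]):
        if hi <= lo:
            raise CategorizationError(
                f"degenerate quantile edges: Q{int(100 * plo)}={lo} collides "
                f"with Q{int(100 * phi)}={hi}"
            )
    return edges


def _fmt(x: float) -> str:
    return f"{x:g}"


def _interval_grid(values: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(values.min() / width) * width
    hi = np.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    nbins = int(round((hi - lo) / width))
    return lo + width * np.arange(nbins + 1)


def compute_edges(values, scheme: BreakScheme) -> CategorizedPredictor:
    """Apply a breakpoint scheme to observed values.

    Returns interior edges, auto-generated labels, and the per-row category
    index.  Edge conventions: median -> {Q50}; uneven -> {Q25, Q75};
    quartiles -> {Q25, Q50, Q75}; interval -> multiples of ``interval_width``
    spanning the data (floor-aligned, so labels read "55-60", "60-65");
    bimodal -> midpoint of the widest internal gap of at least
    ``bimodal_min_gap``.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise CategorizationError("values contain NaN")
    if len(np.unique(values)) < 2:
        raise CategorizationError("need at least 2 distinct values to categorize")

    kind = scheme.kind
    if kind == "median":
        edges = _quantile_edges(values, [0.5])
        labels = ["early", "late"]
    elif kind == "uneven":
        edges = _quantile_edges(values, [0.25, 0.75])
        labels = ["early", "mid", "late"]
    elif kind == "quartiles":
        edges = _quantile_edges(values, [0.25, 0.5, 0.75])
        labels = ["Q1", "Q2", "Q3", "Q4"]
    elif kind == "interval":
        grid = _interval_grid(values, scheme.interval_width)
        edges = [float(e) for e in grid[1:-1]]
        labels = [f"{_fmt(a)}{_DASH}{_fmt(b)}" for a, b in zip(grid, grid[1:])]
    elif kind == "bimodal":
        uniq = np.unique(values)
        gaps = np.diff(uniq)
        i = int(np.argmax(gaps))
        if gaps[i] < scheme.bimodal_min_gap:
            raise CategorizationError(
                f"no internal gap >= {scheme.bimodal_min_gap} "
                f"(widest is {gaps[i]:g}); distribution has no natural break"
            )
        edges = [float((uniq[i] + uniq[i + 1]) / 2.0)]
        labels = ["lower", "upper"]
    else:  # custom
        edges = [float(e) for e in scheme.custom_edges]
        bounds = [values.min(), *edges, values.max()]
        labels = [f"{_fmt(a)}{_DASH}{_fmt(b)}" for a, b in zip(bounds, bounds[1:])]

    cat = CategorizedPredictor(tuple(edges), tuple(labels), np.empty(0, dtype=int))
    assignment = _assign_indices(values, np.asarray(edges))
    return CategorizedPredictor(tuple(edges), tuple(labels), assignment)


def _assign_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # value == interior edge goes to the higher category (side="right")
    return np.searchsorted(edges, values, side="right")


def assign(values, categorized: CategorizedPredictor) -> np.ndarray:
    """Assign arbitrary values to the categories of a realized categorization.

    Outer bins are open-ended (values beyond the observed range still map to
    the first/last category).  Returns per-row labels.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise CategorizationError("cannot assign NaN values")
    idx = _assign_indices(values, np.asarray(categorized.edges))
    return np.asarray(categorized.labels, dtype=object)[idx]
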