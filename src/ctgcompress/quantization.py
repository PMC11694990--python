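"""Lloyd-Max scalar quantization of heart-rate components.

The compression measures operate on symbol sequences, so each real-valued
component is mapped to a finite alphabet (default 20 letters) with a
locally MSE-optimal scalar quantizer: reconstruction levels are cell
centroids and decision boundaries are midpoints of adjacent levels (the two
Lloyd conditions), iterated to a fixed point.

One quantizer is fitted per (subject, channel, component) on the full
preprocessed series and reused across that subject's segments, so that
between-segment compression comparisons share an alphabet mapping.  Trend
and residual get separate codebooks: their dynamic ranges differ by an order
of magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_ALPHABET = 20


@dataclass
class Quantizer:
    levels: np.ndarray  # L reconstruction values, strictly increasing
    boundaries: np.ndarray  # L-1 thresholds, strictly increasing
    alphabet_size: int
    #: empirical MSE after each Lloyd iteration (non-increasing)
    distortion_history: list = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        return json.dumps({
            "levels": list(map(float, self.levels)),
            "boundaries": list(map(float, self.boundaries)),
            "alphabet_size": int(self.alphabet_size),
        })

    @classmethod
    def from_json(cls, text: str) -> "Quantizer":
        d = json.loads(text)
        return cls(np.asarray(d["levels"], float),
                   np.asarray(d["boundaries"], float),
                   int(d["alphabet_size"]))


@dataclass
class SymbolSequence:
    """Integer codes in [0, alphabet_size) with provenance."""

    symbols: np.ndarray
    alphabet_size: int
    source: tuple = ()

    def __len__(self):
        return int(self.symbols.size)


def _distortion(x, levels, boundaries):
    cells = np.searchsorted(boundaries, x)
    return float(np.mean((x - levels[cells]) ** 2))


def fit_lloyd_max(samples, alphabet_size=DEFAULT_ALPHABET, tol=1e-6,
                  max_iter=500) -> Quantizer:
    """Fit a Lloyd-Max quantizer by alternating the two optimality conditions.

    Levels start at equally spaced empirical quantiles (deterministic and
    robust for skewed heart-rate distributions); a cell that empties during
    iteration has its level re-seeded at the midpoint of its boundaries.

    The per-iteration work is O(L log n) rather than O(n): the samples are
    sorted once and cell sums/counts come from cumulative sums sliced at the
    boundary positions.
    """
    x = np.asarray(samples, dtype=float).ravel()
    L = int(alphabet_size)
    if L < 1:
        raise ValueError("alphabet_size must be >= 1")
    if np.unique(x).size < L:
        raise ValueError("need at least alphabet_size distinct sample values")
    if L == 1:
        q = Quantizer(np.array([x.mean()]), np.array([]), 1)
        q.distortion_history.append(_distortion(x, q.levels, q.boundaries))
        return q

    qs = np.linspace(0, 1, 2 * L + 1)[1::2]  # cell-centred quantiles
    levels = np.quantile(x, qs)
    levels = np.unique(levels)
    while levels.size < L:  # heavy ties: pad within the data range
        extra = np.linspace(x.min(), x.max(), L - levels.size + 2)[1:-1]
        levels = np.unique(np.concatenate([levels, extra]))
    levels = np.sort(levels)[:L]

    xs = np.sort(x)
    n = xs.size
    cum1 = np.concatenate([[0.0], np.cumsum(xs)])
    cum2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def cell_stats(boundaries):
        # side='right' puts a sample equal to a boundary in the lower cell,
        # matching quantize()'s searchsorted(boundaries, x, 'left')
        edges = np.concatenate([[0], np.searchsorted(xs, boundaries, side="right"), [n]])
        counts = np.diff(edges)
        sums = cum1[edges[1:]] - cum1[edges[:-1]]
        sq = cum2[edges[1:]] - cum2[edges[:-1]]
        return counts, sums, sq

    def mse(levels, boundaries):
        counts, sums, sq = cell_stats(boundaries)
        return float(np.sum(sq - 2.0 * levels * sums + counts * levels**2) / n)

    history = []
    for _ in range(max_iter):
        boundaries = 0.5 * (levels[:-1] + levels[1:])
        counts, sums, _ = cell_stats(boundaries)
        new_levels = levels.copy()
        occupied = counts > 0
        new_levels[occupied] = sums[occupied] / counts[occupied]
        if not occupied.all():
            # re-seed empty cells at their boundary midpoints
            lo = np.concatenate([[xs[0]], boundaries])
            hi = np.concatenate([boundaries, [xs[-1]]])
            mid = 0.5 * (lo + hi)
            new_levels[~occupied] = mid[~occupied]
        new_levels = np.sort(new_levels)
        history.append(mse(new_levels, 0.5 * (new_levels[:-1] + new_levels[1:])))
        shift = float(np.max(np.abs(new_levels - levels)))
        levels = new_levels
        if shift < tol:
            break
    boundaries = 0.5 * (levels[:-1] + levels[1:])
    q = Quantizer(levels, boundaries, L)
    q.distortion_history = history
    return q


def quantize(series, q: Quantizer, source=()) -> SymbolSequence:
    """Map each sample to the index of its quantizer cell (length preserved)."""
    x = np.asarray(series, dtype=float).ravel()
    codes = np.searchsorted(q.boundaries, x).astype(np.int64)
    return SymbolSequence(codes, q.alphabet_size, source)
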