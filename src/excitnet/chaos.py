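"""Chaos diagnostics from interspike-interval return maps.

A single neuron's spike train is embedded as the sequence of consecutive-ISI
pairs (s(n), s(n+1)) — a two-dimensional delay embedding of the interval time
series.  Periodic firing collapses onto a single point and a limit cycle
traces a curve of dimension 1; a strange attractor fills a fractal set.  The
Minkowski (box-counting) dimension of the point set is estimated by overlaying
its tight bounding square with a 2^r x 2^r grid, counting occupied cells
N_box(r), and fitting the slope of log2 N_box against r over a range that
precedes the saturation plateau at log2(number of points).

For the drifting neurons of the mixed drifting+synchronized network state this
dimension comes out fractional (about 1.8), signalling chaotic firing without
computing Lyapunov spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttractorEmbedding:
    """Consecutive-ISI return-map points of one neuron.

    ``pairs[n] = (s(n), s(n+1))`` in ms, in spike order; one fewer pair than
    there are intervals.
    """

    pairs: np.ndarray
    neuron: int = -1

    @property
    def n_points(self) -> int:
        return len(self.pairs)


def embed(intervals, neuron: int = -1) -> AttractorEmbedding:
    """Delay-embed an ISI sequence as consecutive pairs (s(n), s(n+1))."""
    s = np.asarray(intervals, float)
    if s.ndim != 1 or len(s) < 2:
        raise ValueError("need at least 2 intervals to form one pair")
    pairs = np.column_stack([s[:-1], s[1:]])
    return AttractorEmbedding(pairs=pairs, neuron=neuron)


def _bounding_square(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and side of the tight bounding square (max extent, centered)."""
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    side = float(np.max(hi - lo))
    center = 0.5 * (lo + hi)
    return center, side


def box_count(embedding, r: int) -> int:
    """Number of cells of a 2^r x 2^r grid holding at least one point.

    The grid spans the tight bounding square of the point set (equal cell
    sizes on both axes).  Degenerate sets (a single point, or all points
    coincident) occupy exactly one cell at every r.
    """
    points = embedding.pairs if isinstance(embedding, AttractorEmbedding) else np.asarray(embedding, float)
    if r < 0 or int(r) != r:
        raise ValueError(f"grid exponent r must be a nonnegative integer, got {r}")
    if len(points) == 0:
        raise ValueError("empty point set")
    center, side = _bounding_square(points)
    if side == 0.0:
        return 1
    n = 1 << int(r)
    origin = center - side / 2.0
    idx = np.floor((points - origin) / side * n).astype(np.int64)
    np.clip(idx, 0, n - 1, out=idx)  # points on the upper edge
    keys = idx[:, 0] * np.int64(n) + idx[:, 1]
    return int(len(np.unique(keys)))


@dataclass
class BoxCountCurve:
    """Box counts across grid refinements and the fitted fractal dimension.

    ``D_F`` is the least-squares slope of log2 N_box versus r over
    ``fit_range`` (inclusive); ``residual`` is the RMS deviation of the fit;
    ``saturation_warning`` flags a fit range touching the N_box ~ N_points
    plateau, where the estimate is biased low.
    """

    r_values: np.ndarray
    N_box: np.ndarray
    D_F: float
    fit_range: tuple[int, int]
    residual: float
    n_points: int
    saturation_warning: bool = False

    @property
    def log2_N_box(self) -> np.ndarray:
        return np.log2(self.N_box)


def default_fit_range(n_points: int) -> tuple[int, int]:
    """Fit-range convention by sample size: r = 2..7 for >= 1e5 points,
    2..5 for >= 2e4, 2..4 below (short series give short linear ranges)."""
    if n_points >= 100_000:
        return (2, 7)
    if n_points >= 20_000:
        return (2, 5)
    return (2, 4)


def fractal_dimension(embedding,
                      fit_range: tuple[int, int] | None = None,
                      r_max: int | None = None) -> BoxCountCurve:
    """Box-counting (Minkowski) dimension of a 2-D point set.

    Counts occupied cells for r = 0..r_max and fits the slope of
    log2 N_box(r) over ``fit_range`` (default chosen from the number of
    points).  The fit range is automatically capped where N_box exceeds half
    the number of points — beyond that the counts bend into the saturation
    plateau at log2(N_points) and no longer reflect the set's geometry; if
    the cap bites, ``saturation_warning`` is set.
    """
    points = embedding.pairs if isinstance(embedding, AttractorEmbedding) else np.asarray(embedding, float)
    n_points = len(points)
    if fit_range is None:
        fit_range = default_fit_range(n_points)
    r_lo, r_hi = int(fit_range[0]), int(fit_range[1])
    if r_max is None:
        r_max = max(r_hi + 2, 10)
    r_values = np.arange(0, r_max + 1)
    N_box = np.array([box_count(points, int(r)) for r in r_values])

    # cap the fit below the saturation plateau
    ok = N_box[r_lo:r_hi + 1] <= 0.5 * n_points
    saturated = not np.all(ok)
    if saturated:
        last_ok = np.nonzero(ok)[0]
        if len(last_ok) < 2:
            raise ValueError(
                f"too few points ({n_points}) for fit range r = {r_lo}..{r_hi}: "
                "box counts saturate immediately"
            )
        r_hi = r_lo + int(last_ok[-1])

    rs = r_values[r_lo:r_hi + 1]
    logN = np.log2(N_box[r_lo:r_hi + 1])
    slope, intercept = np.polyfit(rs, logN, 1)
    resid = float(np.sqrt(np.mean((logN - (slope * rs + intercept)) ** 2)))
    return BoxCountCurve(
        r_values=r_values, N_box=N_box, D_F=float(slope),
        fit_range=(r_lo, r_hi), residual=resid, n_points=n_points,
        saturation_warning=saturated,
    )
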