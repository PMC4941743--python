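"""Box-counting estimation of fractal dimensionality D.

The estimator covers a one-pixel-wide binary border with axis-aligned
grids of boxes of edge length s, counts the occupied boxes N(s) for a
ladder of sizes, and fits an ordinary least-squares line to
log N(s) vs log s.  D is the negated slope: a straight line gives D = 1
and a region-filling curve approaches D = 2.  Enamel-band thickness is
deliberately removed by reducing filled bands to their exterior border
before counting, so thickness does not influence D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .trace_io import RasterTrace

logger = logging.getLogger(__name__)

#: Default box-edge ladder in pixels, spanning the conventional 2-64 px
#: range on a roughly geometric grid.
DEFAULT_SIZES: tuple[int, ...] = (2, 3, 4, 6, 8, 12, 16, 32, 64)

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connected neighborhood
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class BoxCountSeries:
    """Box counts N(s) over a ladder of box sizes s (pixels)."""

    sizes: np.ndarray
    counts: np.ndarray
    grid_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.sizes.shape != self.counts.shape:
            raise ValueError("sizes and counts must have equal length")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("counts must be positive")
        if np.any(np.diff(self.counts) > 0):
            # Guaranteed only on nested (dyadic) grids; warn, don't refuse.
            warnings.warn(
                "box counts are not non-increasing in box size; "
                "non-nested grids can do this on sparse traces",
                stacklevel=2,
            )


@dataclass
class DEstimate:
    """Fitted fractal dimension with its log-log regression diagnostics."""

    D: float
    intercept: float
    fit_r2: float
    series: BoxCountSeries


@dataclass
class BoxCountConfig:
    """Knobs of the D estimator.

    sizes: box-edge ladder (pixels, all >= 2).
    extract_border: reduce the trace to its one-pixel exterior border
        first (default).  Disable only for diagnostics such as the
        D -> 2 limit of a filled region.
    connectivity: 8 (default) or 4, for the border definition.
    n_origins: if > 1, counts are averaged over this many random grid
        origins per size (seeded); default is the single origin (0, 0).
    seed: RNG seed for random origins.
    """

    sizes: Sequence[int] = DEFAULT_SIZES
    extract_border: bool = True
    connectivity: int = 8
    n_origins: int = 1
    seed: int = 0


def extract_border(trace: RasterTrace, connectivity: int = 8) -> RasterTrace:
    """Reduce a trace to foreground pixels that touch the background.

    A pixel is border if it is foreground and at least one neighbor
    (8-neighborhood by default) is background; pixels on the image edge
    count the outside as background.  Filled regions collapse to their
    one-pixel-wide outline; already-thin curves pass through unchanged.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    fg = trace.pixels.astype(bool)
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    interior = ndimage.binary_erosion(fg, structure=struct, border_value=0)
    border = fg & ~interior
    return RasterTrace(border.astype(np.uint8), specimen_id=trace.specimen_id)


def count_boxes(
    trace: RasterTrace, size: int, origin: tuple[int, int] = (0, 0)
) -> int:
    """Count grid cells of edge ``size`` containing >= 1 foreground pixel.

    The grid is anchored at ``origin`` (components in [0, size)); partial
    cells at the image edges count as boxes.  A box larger than the whole
    image yields 1 for any non-empty trace.
    """
    if size < 1:
        raise ValueError("box size must be >= 1")
    orow, ocol = origin
    if not (0 <= orow < size and 0 <= ocol < size):
        raise ValueError(f"origin {origin} not in [0, {size})^2")
    rows, cols = np.nonzero(trace.pixels)
    if rows.size == 0:
        raise ValueError("trace has no foreground pixels")
    # floor division sends pixels left/above the origin to cell index -1,
    # a partial cell of its own
    cr = (rows - orow) // size
    cc = (cols - ocol) // size
    ncols = trace.width // size + 2
    return int(np.unique(cr * ncols + cc).size)


def box_count_series(
    trace: RasterTrace,
    sizes: Sequence[int] = DEFAULT_SIZES,
    n_origins: int = 1,
    seed: int = 0,
) -> BoxCountSeries:
    """Count boxes at each ladder size.

    With ``n_origins > 1`` the count at each size is the mean over that
    many uniformly random origins (rounded to the nearest integer box),
    which reduces grid-placement artifacts on short traces.
    """
    sizes = sorted(int(s) for s in sizes)
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if sizes[0] < 2:
        raise ValueError("box sizes must be >= 2")
    rng = np.random.default_rng(seed)
    counts = []
    for s in sizes:
        if n_origins <= 1:
            counts.append(count_boxes(trace, s))
        else:
            origins = rng.integers(0, s, size=(n_origins, 2))
            c = np.mean([count_boxes(trace, s, (int(a), int(b))) for a, b in origins])
            counts.append(int(round(c)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # monotonicity warning re-checked by caller
        series = BoxCountSeries(np.array(sizes), np.array(counts))
    return series


def fit_dimension(series: BoxCountSeries) -> DEstimate:
    """OLS fit of log N(s) on log s; D is the negated slope.

    The log base is immaterial (the slope is base-invariant); natural
    logs are used.  Requires at least 3 distinct sizes.  A series with
    all counts equal has zero slope and returns D = 0 with a warning.
    """
    if len(series.sizes) < 3:
        raise ValueError("need >= 3 box sizes to fit a dimension")
    x = np.log(series.sizes.astype(float))
    y = np.log(series.counts.astype(float))
    if np.allclose(y, y[0]):
        warnings.warn("all box counts equal; D = 0 (degenerate fit)", stacklevel=2)
        return DEstimate(D=0.0, intercept=float(y[0]), fit_r2=1.0, series=series)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return DEstimate(D=float(-slope), intercept=float(intercept), fit_r2=r2, series=series)


def estimate_D(trace: RasterTrace, config: BoxCountConfig | None = None) -> DEstimate:
    """Full estimator: border extraction -> box counts -> log-log fit.

    Deterministic for a fixed config.  For planar curves D should land in
    [1, 2]; estimates outside [0.9, 2.1] trigger a warning but are
    returned as-is.
    """
    cfg = config or BoxCountConfig()
    work = extract_border(trace, cfg.connectivity) if cfg.extract_border else trace
    if work.n_foreground == 0:
        raise ValueError("trace has no foreground pixels after border extraction")
    series = box_count_series(
        work, sizes=cfg.sizes, n_origins=cfg.n_origins, seed=cfg.seed
    )
    est = fit_dimension(series)
    if not (0.9 <= est.D <= 2.1):
        logger.warning(
            "D estimate %.3f outside the planar-curve range [1, 2] "
            "(specimen %s)", est.D, trace.specimen_id or "<unnamed>"
        )
    return est
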