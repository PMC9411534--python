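"""FLIP quantification: %FL, the Monte-Carlo random-square null, significance
calls, connected-nuclei counts, and photoconversion propagation.

The fluorescence-loss statistic for a region of interest is

    %FL = (I_MEAN(Tstart) - I_MEAN(Tend)) / I_MEAN(Tstart)

where I_MEAN is the arithmetic mean pixel intensity inside the ROI.  Loss in
an unbleached zone is attributed to the photomanipulation only if it exceeds
what imaging decay and acquisition noise alone can produce; that ceiling is
estimated per movie by sampling %FL over many randomly positioned squares
(default ten thousand 10 x 10 um squares) in an unbleached channel and taking
the empirical quantile of the resulting distribution at the chosen confidence
level (default 95%).  A zone is called significant iff its %FL strictly
exceeds the threshold.

Conventions: Tstart defaults to the mean of the pre-bleach frames (robust to
single-frame noise) and Tend to the final frame; %FL is invariant to a global
intensity gain but NOT to a background offset — background subtraction is the
caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage.draw import polygon as _sk_polygon

from .compartment_model import SyntheticMovie

__all__ = [
    "ROI",
    "IntensityTrace",
    "FLIPMeasurement",
    "NullDistribution",
    "SignificanceCall",
    "measure_zone_trace",
    "percent_fluorescence_loss",
    "monte_carlo_null",
    "most_stringent_threshold",
    "classify_loss",
    "count_connected_nuclei",
    "propagation_fraction",
    "converted_signal_detected",
    "zone_roi",
]


@dataclass(frozen=True)
class ROI:
    """A rectangle or polygon on a single Z plane (pixel coordinates, 0-based).

    Rectangles are given by two vertices [(r0, c0), (r1, c1)] and cover the
    half-open box [r0, r1) x [c0, c1); polygons list their vertices in order.
    """

    id: str
    shape: str  # {"rectangle", "polygon"}
    vertices: tuple  # ((row, col), ...)
    plane: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "polygon"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        object.__setattr__(self, "vertices", tuple(tuple(v) for v in self.vertices))
        if self.shape == "rectangle" and len(self.vertices) != 2:
            raise ValueError("rectangle ROI needs exactly two vertices")
        if self.shape == "polygon" and len(self.vertices) < 3:
            raise ValueError("polygon ROI needs at least three vertices")

    def mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        h, w = shape_yx
        m = np.zeros((h, w), dtype=bool)
        if self.shape == "rectangle":
            (r0, c0), (r1, c1) = self.vertices
            r0, r1 = sorted((int(r0), int(r1)))
            c0, c1 = sorted((int(c0), int(c1)))
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"ROI {self.id!r} exceeds image bounds")
            m[r0:r1, c0:c1] = True
        else:
            rr = np.array([v[0] for v in self.vertices], dtype=float)
            cc = np.array([v[1] for v in self.vertices], dtype=float)
            if rr.min() < 0 or cc.min() < 0 or rr.max() > h or cc.max() > w:
                raise ValueError(f"ROI {self.id!r} exceeds image bounds")
            pr, pc = _sk_polygon(rr, cc, shape=(h, w))
            m[pr, pc] = True
        if not m.any():
            raise ValueError(f"ROI {self.id!r} has zero area")
        return m

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "shape": self.shape,
            "vertices": [list(v) for v in self.vertices],
            "plane": self.plane,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ROI":
        return cls(
            id=d["id"], shape=d["shape"], vertices=d["vertices"], plane=d.get("plane", 0)
        )


@dataclass
class IntensityTrace:
    roi_id: str
    channel: str
    values: np.ndarray  # (T,) mean intensity per frame
    times: np.ndarray  # (T,) seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")


@dataclass(frozen=True)
class FLIPMeasurement:
    roi_id: str
    channel: str
    t_start: tuple[int, int]  # half-open frame range averaged for I_MEAN(Tstart)
    t_end: int
    percent_loss: float  # fraction in (-inf, 1]


@dataclass
class NullDistribution:
    """Monte-Carlo %FL null with its empirical-quantile threshold."""

    channel: str
    samples: np.ndarray
    square_size_um: float
    confidence: float
    threshold: float
    n_squares: int

    def coverage(self) -> float:
        """Fraction of null samples at or below the threshold."""
        return float(np.mean(self.samples <= self.threshold))


@dataclass(frozen=True)
class SignificanceCall:
    roi_id: str
    channel: str
    percent_loss: float
    threshold: float
    significant: bool


def measure_zone_trace(
    movie: SyntheticMovie,
    roi: ROI,
    channel: str,
    shift: Optional[tuple[int, tuple[int, int]]] = None,
) -> IntensityTrace:
    """Per-frame arithmetic mean intensity inside the ROI on its plane.

    ``shift`` optionally applies a single integer-pixel ROI displacement
    (from_frame, (dy, dx)) from the given frame onward — the manual
    correction used when restricted tissue drift moves a zone late in a
    movie.  Full drift registration is out of scope.
    """
    c = movie.channel_index(channel)
    t, z, h, w, _ = movie.data.shape
    if not 0 <= roi.plane < z:
        raise ValueError(f"ROI plane {roi.plane} outside stack of depth {z}")
    m = roi.mask((h, w))
    stack = movie.data[:, roi.plane, :, :, c]
    vals = stack[:, m].mean(axis=1)
    if shift is not None:
        from_frame, (dy, dx) = shift
        shifted = ROI(
            id=roi.id,
            shape=roi.shape,
            vertices=tuple((v[0] + dy, v[1] + dx) for v in roi.vertices),
            plane=roi.plane,
        )
        m2 = shifted.mask((h, w))
        vals = vals.copy()
        vals[from_frame:] = stack[from_frame:, m2].mean(axis=1)
    return IntensityTrace(roi_id=roi.id, channel=channel, values=vals, times=movie.times)


def _resolve_start(t_start, n: int) -> tuple[int, int]:
    if isinstance(t_start, (int, np.integer)):
        i = int(t_start) % n
        return (i, i + 1)
    lo, hi = int(t_start[0]), int(t_start[1])
    if not 0 <= lo < hi <= n:
        raise ValueError("t_start range out of bounds")
    return (lo, hi)


def percent_fluorescence_loss(
    trace: IntensityTrace, t_start=0, t_end: int = -1
) -> FLIPMeasurement:
    """%FL = 1 - I_MEAN(Tend) / I_MEAN(Tstart).

    ``t_start`` is a frame index or a half-open (lo, hi) range whose frames
    are averaged; ``t_end`` is a frame index (negative indices allowed).
    """
    n = len(trace.values)
    lo, hi = _resolve_start(t_start, n)
    end = int(t_end) % n
    if end < hi - 1:
        raise ValueError("t_end must not precede t_start")
    i_start = float(trace.values[lo:hi].mean())
    if i_start <= 0:
        raise ValueError("starting intensity must be positive")
    i_end = float(trace.values[end])
    return FLIPMeasurement(
        roi_id=trace.roi_id,
        channel=trace.channel,
        t_start=(lo, hi),
        t_end=end,
        percent_loss=1.0 - i_end / i_start,
    )


def _box_sums(img: np.ndarray, side: int, rows: np.ndarray, cols: np.ndarray):
    """Summed-area-table box sums for squares of given side at (row, col)."""
    sat = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=sat[1:, 1:])
    r1, c1 = rows + side, cols + side
    return sat[r1, c1] - sat[rows, c1] - sat[r1, cols] + sat[rows, cols]


def _nearest_rank_quantile(samples: np.ndarray, level: float) -> float:
    """Empirical quantile by the nearest-rank method (ties resolved upward)."""
    s = np.sort(samples)
    idx = int(np.ceil(level * len(s))) - 1
    return float(s[max(idx, 0)])


def monte_carlo_null(
    movie: SyntheticMovie,
    channel: str,
    n_squares: int = 10_000,
    square_size_um: float = 10.0,
    confidence: float = 0.95,
    seed: int = 0,
    t_start=None,
    t_end: int = -1,
    plane: int = 0,
    exclusion_mask: Optional[np.ndarray] = None,
) -> NullDistribution:
    """Sample %FL over randomly positioned squares and threshold at the
    confidence quantile.

    Squares are placed uniformly at random, fully inside the field, on the
    analysis plane, in the channel named by the caller (normally the
    unbleached fluorophore).  The square side in pixels is the nearest
    integer >= 1 to square_size_um / pixel_size.  %FL uses the same
    Tstart/Tend convention as the test ROI.  An optional boolean exclusion
    mask removes squares overlapping masked pixels.  Deterministic given
    ``seed``.
    """
    if n_squares < 1000:
        raise ValueError("the null needs at least 1000 squares")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    c = movie.channel_index(channel)
    t, z, h, w, _ = movie.data.shape
    side = max(1, int(round(square_size_um / movie.pixel_size)))
    if side > min(h, w):
        raise ValueError(
            f"square of {side} px does not fit inside the {h}x{w} field"
        )
    if t_start is None:
        pre = movie.truth_protocol.pre_frames if movie.truth_protocol else 0
        t_start = (0, pre) if pre > 0 else 0
    lo, hi = _resolve_start(t_start, t)
    end = int(t_end) % t

    stack = movie.data[:, plane, :, :, c]
    start_img = np.asarray(stack[lo:hi].mean(axis=0), dtype=np.float64)
    end_img = np.asarray(stack[end], dtype=np.float64)

    rng = np.random.default_rng(seed)
    rows = np.empty(n_squares, dtype=np.int64)
    cols = np.empty(n_squares, dtype=np.int64)
    filled = 0
    excl_sat = None
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, dtype=np.float64)
        if excl.shape != (h, w):
            raise ValueError("exclusion_mask must match the field shape")
        excl_sat = excl
    attempts = 0
    while filled < n_squares:
        need = n_squares - filled
        r = rng.integers(0, h - side + 1, size=need)
        cc = rng.integers(0, w - side + 1, size=need)
        if excl_sat is not None:
            overlap = _box_sums(excl_sat, side, r, cc) > 0
            r, cc = r[~overlap], cc[~overlap]
        rows[filled : filled + len(r)] = r
        cols[filled : filled + len(r)] = cc
        filled += len(r)
        attempts += 1
        if attempts > 1000:
            raise ValueError("cannot place squares outside the exclusion mask")

    area = float(side * side)
    s_start = _box_sums(start_img, side, rows, cols) / area
    s_end = _box_sums(end_img, side, rows, cols) / area
    if np.any(s_start <= 0):
        raise ValueError("null square with non-positive starting intensity")
    samples = 1.0 - s_end / s_start
    threshold = _nearest_rank_quantile(samples, confidence)
    return NullDistribution(
        channel=channel,
        samples=samples,
        square_size_um=square_size_um,
        confidence=confidence,
        threshold=threshold,
        n_squares=n_squares,
    )


def most_stringent_threshold(nulls: Sequence[NullDistribution]) -> float:
    """Across several movies of one fluorophore, keep the largest threshold."""
    if not nulls:
        raise ValueError("no null distributions given")
    channels = {n.channel for n in nulls}
    if len(channels) > 1:
        raise ValueError("thresholds from different channels cannot be combined")
    return max(n.threshold for n in nulls)


def classify_loss(
    measurement: FLIPMeasurement, null: NullDistribution
) -> SignificanceCall:
    """Significant iff %FL strictly exceeds the null threshold."""
    if measurement.channel != null.channel:
        raise ValueError(
            f"channel mismatch: measurement {measurement.channel!r} vs "
            f"null {null.channel!r}"
        )
    return SignificanceCall(
        roi_id=measurement.roi_id,
        channel=measurement.channel,
        percent_loss=measurement.percent_loss,
        threshold=null.threshold,
        significant=measurement.percent_loss > null.threshold,
    )


def count_connected_nuclei(
    calls: Iterable[SignificanceCall],
    nuclei: Sequence[tuple[str, Optional[str]]],
    bleached_zone: str,
) -> int:
    """Number of nuclei lying in zones with significant loss (bleached zone
    included).  ``nuclei`` lists (nucleus_id, zone) pairs."""
    significant = {c.roi_id for c in calls if c.significant}
    significant.add(bleached_zone)
    n = 0
    for nid, zone in nuclei:
        if zone is None:
            raise ValueError(f"nucleus {nid!r} has no zone assignment")
        if zone in significant:
            n += 1
    return n


def converted_signal_detected(
    trace: IntensityTrace,
    background_frames: tuple[int, int],
    eval_frame: int = -1,
    n_sd: float = 3.0,
) -> bool:
    """Detect converted fluorophore arrival in a distal zone.

    Background statistics come from the trace itself over the pre-conversion
    frame range; the zone counts as reached if the mean intensity at
    ``eval_frame`` exceeds background mean + n_sd * background SD.
    """
    lo, hi = background_frames
    bg = trace.values[lo:hi]
    if len(bg) < 2:
        raise ValueError("need at least two background frames")
    limit = float(bg.mean() + n_sd * bg.std(ddof=1))
    return float(trace.values[int(eval_frame) % len(trace.values)]) > limit


def propagation_fraction(converted_detected: Sequence[bool]) -> float:
    """Percentage of adjacent clones reached by the converted species."""
    if len(converted_detected) == 0:
        raise ValueError("at least one adjacent clone is required")
    return 100.0 * float(np.mean(np.asarray(converted_detected, dtype=bool)))


def zone_roi(movie: SyntheticMovie, node_id: str, plane: int = 0) -> ROI:
    """Rectangle ROI spanning the bounding box of a compartment's label.

    Exact for the tiled fixture geometries, whose zones are rectangles.
    """
    if movie.geometry is None:
        raise ValueError("movie carries no geometry")
    lab = movie.geometry.label_of_node[node_id]
    mask = movie.geometry.label_image[plane] == lab
    if not mask.any():
        raise ValueError(f"node {node_id!r} has no pixels on plane {plane}")
    rows, cols = np.nonzero(mask)
    return ROI(
        id=node_id,
        shape="rectangle",
        vertices=((int(rows.min()), int(cols.min())), (int(rows.max()) + 1, int(cols.max()) + 1)),
        plane=plane,
    )
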