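"""Niche membrane and ensheathing quantification on labelled 3-D volumes.

Two measurements characterise how the glial membrane network serves its
stem cells: (i) membrane-per-NSC — the volume is sampled with a handful of
non-overlapping cubes (default six, 150 x 150 px footprint, depth down to a
stated anatomical boundary), the membrane channel is thresholded by 1-D
k-means on the intensity histogram (k = 2 or 4, kept constant across
conditions) and the segmented pixel count is divided by the number of NSCs
in the cube; (ii) the individual-ensheathing percentage — the fraction of
NSCs housed singly in a membrane chamber, computed from the total NSC count
and the sizes of chambers containing two or more NSCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NicheVolume",
    "CubeSample",
    "EnsheathingResult",
    "sample_cubes",
    "segment_membrane",
    "kmeans_1d",
    "measure_cube",
    "membrane_per_nsc",
    "ensheathing_percentage",
]


@dataclass
class NicheVolume:
    membrane_channel: np.ndarray  # (Z, Y, X) intensity
    nsc_labels: np.ndarray  # (Z, Y, X) integer labels, 0 = background
    pixel_size: float  # um / pixel
    chamber_assignment: Optional[dict[int, int]] = None  # NSC id -> chamber id

    def __post_init__(self) -> None:
        self.membrane_channel = np.asarray(self.membrane_channel)
        self.nsc_labels = np.asarray(self.nsc_labels)
        if self.membrane_channel.shape != self.nsc_labels.shape:
            raise ValueError("membrane and label arrays must be congruent")
        if self.membrane_channel.ndim != 3:
            raise ValueError("volumes must be (Z, Y, X)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class CubeSample:
    """A sampling cube: x/y footprint plus depth to the z boundary."""

    origin: tuple[int, int, int]  # (z, y, x) of the cube corner
    size: tuple[int, int, int]  # (dz, dy, dx)
    membrane_pixel_count: Optional[int] = None
    nsc_count: Optional[int] = None

    @property
    def ratio(self) -> float:
        if self.membrane_pixel_count is None or not self.nsc_count:
            raise ValueError("cube not measured or has zero NSCs")
        return self.membrane_pixel_count / self.nsc_count

    def slices(self) -> tuple[slice, slice, slice]:
        (z, y, x), (dz, dy, dx) = self.origin, self.size
        return (slice(z, z + dz), slice(y, y + dy), slice(x, x + dx))


@dataclass(frozen=True)
class EnsheathingResult:
    total_nsc: int
    individually_ensheathed: int
    percentage: float
    chamber_distribution: tuple[int, ...]  # sizes of multi-NSC chambers


def _overlaps(a: CubeSample, b: CubeSample) -> bool:
    for (oa, sa), (ob, sb) in zip(zip(a.origin, a.size), zip(b.origin, b.size)):
        if oa + sa <= ob or ob + sb <= oa:
            return False
    return True


def sample_cubes(
    volume: NicheVolume,
    n: int = 6,
    xy: int = 150,
    z_limit: Optional[int] = None,
    seed: int = 0,
    exclusion_mask: Optional[np.ndarray] = None,
    max_tries: int = 10_000,
) -> list[CubeSample]:
    """Place ``n`` non-overlapping sampling cubes at seeded random positions.

    Cubes have an xy footprint of ``xy`` pixels and span z from the top of
    the stack down to ``z_limit`` (exclusive; default: the full depth — the
    anatomical boundary becomes an explicit parameter).  Cubes honour an
    optional (Y, X) exclusion mask (e.g. trachea/nerve signal).  Deterministic
    given ``seed``.
    """
    zdim, ydim, xdim = volume.membrane_channel.shape
    depth = zdim if z_limit is None else int(z_limit)
    if not 0 < depth <= zdim:
        raise ValueError("z_limit outside the stack")
    if xy > min(ydim, xdim):
        raise ValueError(f"cube footprint {xy} px does not fit in {ydim}x{xdim}")
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != (ydim, xdim):
            raise ValueError("exclusion_mask must be (Y, X)")
    rng = np.random.default_rng(seed)
    cubes: list[CubeSample] = []
    tries = 0
    while len(cubes) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(f"could not place {n} non-overlapping cubes")
        y = int(rng.integers(0, ydim - xy + 1))
        x = int(rng.integers(0, xdim - xy + 1))
        cand = CubeSample(origin=(0, y, x), size=(depth, xy, xy))
        if exclusion_mask is not None and exclusion_mask[y : y + xy, x : x + xy].any():
            continue
        if any(_overlaps(cand, c) for c in cubes):
            continue
        cubes.append(cand)
    return cubes


def _lloyd_1d(v: np.ndarray, centres: np.ndarray, max_iter: int) -> tuple[np.ndarray, float]:
    centres = np.sort(np.asarray(centres, dtype=float))
    for _ in range(max_iter):
        # assign by nearest centre via midpoint cuts (centres stay sorted)
        cuts = (centres[:-1] + centres[1:]) / 2.0
        labels = np.searchsorted(cuts, v)
        new = centres.copy()
        for j in range(len(centres)):
            sel = v[labels == j]
            if sel.size:
                new[j] = sel.mean()
        new = np.sort(new)
        if np.allclose(new, centres):
            centres = new
            break
        centres = new
    cuts = (centres[:-1] + centres[1:]) / 2.0
    labels = np.searchsorted(cuts, v)
    sse = float(np.sum((v - centres[labels]) ** 2))
    return centres, sse


def kmeans_1d(values: np.ndarray, k: int, max_iter: int = 300) -> np.ndarray:
    """Deterministic 1-D k-means on intensities.

    Lloyd iterations are run from two deterministic initialisations —
    mid-quantile centres and centres spread evenly over the value range —
    and the solution with the lower within-cluster sum of squares is kept.
    Returns the sorted cluster centres.
    """
    v = np.asarray(values, dtype=float).ravel()
    inits = [
        np.quantile(v, (np.arange(k) + 0.5) / k),
        np.linspace(v.min(), v.max(), k + 2)[1:-1],
    ]
    best_centres, best_sse = None, np.inf
    for init in inits:
        centres, sse = _lloyd_1d(v, init, max_iter)
        if sse < best_sse - 1e-12:
            best_centres, best_sse = centres, sse
    return best_centres


def segment_membrane(block: np.ndarray, k: int = 2, top_clusters: int = 1) -> np.ndarray:
    """Threshold a cube's membrane channel by 1-D k-means on the histogram.

    Membrane = pixels assigned to the ``top_clusters`` highest-mean clusters
    (default the single brightest; for k = 4 the caller may keep the top two).
    A constant block yields an empty mask with a warning.
    """
    if k not in (2, 4):
        raise ValueError("k must be 2 or 4")
    if not 1 <= top_clusters < k:
        raise ValueError("top_clusters must be in [1, k)")
    block = np.asarray(block, dtype=float)
    if np.ptp(block) == 0:
        warnings.warn("constant intensity block: returning empty membrane mask")
        return np.zeros(block.shape, dtype=bool)
    centres = kmeans_1d(block, k)
    cuts = (centres[:-1] + centres[1:]) / 2.0
    threshold = cuts[k - top_clusters - 1]
    return block > threshold


def measure_cube(
    volume: NicheVolume, cube: CubeSample, k: int = 2, top_clusters: int = 1
) -> CubeSample:
    """Fill a cube's membrane pixel count and NSC count.

    An NSC is attributed to the cube whose footprint contains its centroid.
    """
    sl = cube.slices()
    block = volume.membrane_channel[sl]
    mask = segment_membrane(block, k=k, top_clusters=top_clusters)
    labels = volume.nsc_labels
    ids = np.unique(labels[labels > 0])
    count = 0
    for nsc in ids:
        zs, ys, xs = np.nonzero(labels == nsc)
        cz, cy, cx = zs.mean(), ys.mean(), xs.mean()
        (oz, oy, ox), (dz, dy, dx) = cube.origin, cube.size
        if oz <= cz < oz + dz and oy <= cy < oy + dy and ox <= cx < ox + dx:
            count += 1
    cube.membrane_pixel_count = int(mask.sum())
    cube.nsc_count = count
    return cube


def membrane_per_nsc(cubes: Sequence[CubeSample], skip_empty: bool = False) -> float:
    """Mean over cubes of membrane pixels / NSC count (one value per brain)."""
    if not cubes:
        raise ValueError("no cubes given")
    ratios = []
    for c in cubes:
        if c.membrane_pixel_count is None or c.nsc_count is None:
            raise ValueError("cube not measured; call measure_cube first")
        if c.nsc_count == 0:
            if skip_empty:
                continue
            raise ValueError(
                "cube contains zero NSCs; pass skip_empty=True to exclude it"
            )
        ratios.append(c.membrane_pixel_count / c.nsc_count)
    if not ratios:
        raise ValueError("all cubes were empty of NSCs")
    return float(np.mean(ratios))


def ensheathing_percentage(
    total_nsc: int, multi_chambers: Sequence[int]
) -> EnsheathingResult:
    """Individual-ensheathing percentage from multi-NSC chamber counts.

    ``multi_chambers`` lists the NSC count of every chamber housing >= 2
    NSCs; all remaining NSCs are individually ensheathed.
    """
    if total_nsc < 0:
        raise ValueError("total_nsc must be >= 0")
    for m in multi_chambers:
        if m < 2:
            raise ValueError("multi-NSC chambers must contain at least 2 NSCs")
    taken = int(sum(multi_chambers))
    if taken > total_nsc:
        raise ValueError("multi-chamber NSCs exceed the total population")
    individually = total_nsc - taken
    pct = 100.0 * individually / total_nsc if total_nsc else 100.0
    return EnsheathingResult(
        total_nsc=total_nsc,
        individually_ensheathed=individually,
        percentage=pct,
        chamber_distribution=tuple(sorted(int(m) for m in multi_chambers)),
    )
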