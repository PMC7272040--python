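"""Structural-complexity metrics from reef elevation cross-sections.

An elevation cross-section is a single-valued function z(x) sampled along a
transect laid over a digital reef reconstruction. From it (plus a benthic
segmentation of the same transect) this module computes the six per-transect
metrics used to characterise reef habitat structure:

* rugosity index RI = L_chain / D_chain (virtual chain-and-tape),
* verticality: mean absolute elevation change per 10 cm planar interval,
* hard coral cover: contour-length fraction under live coral,
* grazing surface area: contour-length fraction under short algal turf (EAM),
* refuge density: crevices (10-20 cm wide, >= 10 cm deep, admitting a 10 cm
  disc) plus near-vertical surfaces > 10 cm high, and
* feeding field-of-view (delegated to :mod:`reefscape.viewshed`).

Profiles are single-valued, so true undercut overhangs are not representable;
near-vertical surfaces act as their proxy, mirroring how cross-sections from
photogrammetric reconstructions are scored in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DataGapError, OutOfBoundsError

GAUGE_DIAMETER = 0.10
"""Diameter (m) of the disc representing a fish cross-section for refuge tests."""

BENTHIC_LABELS = ("hard_coral", "turf_EAM", "macroalgae", "sand", "other")


@dataclass(frozen=True)
class ElevationProfile:
    """Ordered (x, z) samples of one reef cross-section, in metres.

    ``x`` is planar distance from the transect start (strictly increasing);
    ``z`` is elevation relative to an arbitrary vertical datum.
    """

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        if x.ndim != 1 or z.ndim != 1 or x.size != z.size:
            raise ValueError("x and z must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise ValueError("profile coordinates must be finite")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")

    @property
    def length(self) -> float:
        """Planar extent D_chain (m)."""
        return float(self.x[-1] - self.x[0])

    @property
    def resolution(self) -> float:
        """Nominal (median) sample spacing in metres."""
        return float(np.median(np.diff(self.x)))

    def elevation_at(self, xq) -> np.ndarray:
        """Linearly interpolated elevation at planar position(s) ``xq``."""
        xq = np.asarray(xq, dtype=float)
        if np.any(xq < self.x[0] - 1e-12) or np.any(xq > self.x[-1] + 1e-12):
            raise OutOfBoundsError("query position outside profile extent")
        return np.interp(xq, self.x, self.z)


@dataclass(frozen=True)
class BenthicSegmentation:
    """Labelled, non-overlapping intervals ``[start, end)`` along a profile."""

    intervals: tuple
    """Tuple of ``(start_m, end_m, label)`` triples, sorted by start."""

    def __post_init__(self):
        ivs = tuple(sorted((float(a), float(b), str(lab)) for a, b, lab in self.intervals))
        object.__setattr__(self, "intervals", ivs)
        prev_end = -math.inf
        for a, b, _ in ivs:
            if not a < b:
                raise ValueError(f"interval ({a}, {b}) has non-positive length")
            if a < prev_end - 1e-12:
                raise ValueError("segmentation intervals overlap")
            prev_end = b

    @property
    def labels(self) -> set:
        return {lab for _, _, lab in self.intervals}

    @property
    def extent(self) -> tuple:
        return (self.intervals[0][0], self.intervals[-1][1])


@dataclass(frozen=True)
class RefugeSet:
    """Detected refuges: crevices ``(x, width, depth)`` and overhangs ``(x, height)``."""

    crevices: tuple
    overhangs: tuple

    @property
    def count(self) -> int:
        return len(self.crevices) + len(self.overhangs)


@dataclass(frozen=True)
class ComplexityMetrics:
    """Per-transect record of the six structural/nutritional metrics."""

    rugosity: float
    verticality: float
    coral_cover: float
    refuge_count: int
    fov_visible: float
    grazing_area: float
    contour_len: float = field(default=float("nan"))
    planar_len: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        return {
            "rugosity": self.rugosity,
            "verticality": self.verticality,
            "coral_cover": self.coral_cover,
            "refuge_count": self.refuge_count,
            "fov_visible": self.fov_visible,
            "grazing_area": self.grazing_area,
        }


# ---------------------------------------------------------------------------
# chain-and-tape metrics


def contour_length(profile: ElevationProfile, x_range: tuple | None = None) -> float:
    """Contoured (chain) length of the profile over ``x_range``.

    Sum of Euclidean segment lengths sqrt(dx^2 + dz^2) between consecutive
    samples; endpoints of a partial range are obtained by linear
    interpolation, so the measure is additive over any partition of the range.
    """
    if x_range is None:
        x, z = profile.x, profile.z
    else:
        a, b = float(x_range[0]), float(x_range[1])
        if not a < b:
            raise ValueError(f"empty or inverted range ({a}, {b})")
        if a < profile.x[0] - 1e-12 or b > profile.x[-1] + 1e-12:
            raise ValueError("range exceeds profile extent")
        a = max(a, float(profile.x[0]))
        b = min(b, float(profile.x[-1]))
        inside = (profile.x > a) & (profile.x < b)
        x = np.concatenate(([a], profile.x[inside], [b]))
        z = np.concatenate(([profile.elevation_at(a)], profile.z[inside], [profile.elevation_at(b)]))
    return float(np.sum(np.hypot(np.diff(x), np.diff(z))))


def rugosity_index(profile: ElevationProfile) -> float:
    """Rugosity index RI = L_chain / D_chain; 1 for flat terrain, >= 1 always."""
    d = profile.length
    if d <= 0:
        raise ValueError("profile has zero planar span")
    return contour_length(profile) / d


def verticality(profile: ElevationProfile, interval: float = 0.10) -> float:
    """Mean absolute rate of elevation change per planar ``interval`` (default 10 cm).

    The profile is linearly resampled onto a grid anchored at its start;
    each interval contributes |z(b) - z(a)| / interval and a trailing partial
    interval is dropped. 10 cm matches the body size of visually apparent
    reef fishes, the scale at which fishes associate with structure.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    span = profile.length
    if span < interval:
        raise ValueError("profile span shorter than the evaluation interval")
    n = int(math.floor(span / interval + 1e-9))
    grid = profile.x[0] + interval * np.arange(n + 1)
    zg = profile.elevation_at(grid)
    return float(np.mean(np.abs(np.diff(zg)) / interval))


def cover_fraction(profile: ElevationProfile, seg: BenthicSegmentation, labels) -> float:
    """Contour-length fraction of the transect whose benthic label is in ``labels``."""
    if isinstance(labels, str):
        labels = {labels}
    labels = set(labels)
    lo, hi = seg.extent
    if lo < profile.x[0] - 1e-9 or hi > profile.x[-1] + 1e-9:
        raise ValueError("segmentation exceeds profile extent")
    total = contour_length(profile)
    if total <= 0:
        raise ValueError("profile has zero contour length")
    covered = sum(
        contour_length(profile, (a, b)) for a, b, lab in seg.intervals if lab in labels
    )
    return min(1.0, covered / total)


def grazing_area_fraction(profile: ElevationProfile, seg: BenthicSegmentation) -> float:
    """Contour fraction of hard substratum under short (< 2 cm) algal turf.

    Only the epilithic algal matrix counts as grazing surface; macroalgae,
    sand and live coral are excluded because roving herbivores do not
    graze them appreciably.
    """
    return cover_fraction(profile, seg, {"turf_EAM"})


# ---------------------------------------------------------------------------
# refuge detection


def _disc_fits(x, z, roof, i0, i1, radius, dx):
    """True if a disc of ``radius`` fits inside the notch spanning samples i0..i1.

    Candidate centres are gridded over the notch; the disc must sit wholly
    beneath the local ``roof`` surface (the morphological closing of the
    terrain, i.e. the ceiling of enclosed space) and keep all nearby terrain
    samples at distance >= radius.
    """
    lo = max(0, i0 - int(2 * radius / dx) - 2)
    hi = min(x.size, i1 + int(2 * radius / dx) + 3)
    tx, tz = x[lo:hi], z[lo:hi]
    zmin = float(np.min(z[i0 : i1 + 1]))
    cx_cand = x[i0 : i1 + 1]
    roof_cand = roof[i0 : i1 + 1]
    cz_min = zmin + radius
    cz_max = float(np.max(roof_cand)) - radius
    if cz_max < cz_min - 1e-12:
        return False
    n_lvl = max(1, int((cz_max - cz_min) / max(dx, 1e-4)) + 1)
    cz_cand = np.linspace(cz_min, cz_max, min(n_lvl, 25))
    # pairwise distances: centres (grid) x terrain samples
    cxg, czg = np.meshgrid(cx_cand, cz_cand, indexing="ij")
    d2 = (cxg[..., None] - tx) ** 2 + (czg[..., None] - tz) ** 2
    clearance = np.sqrt(d2.min(axis=-1))
    # the centre must lie above the terrain directly beneath it, and the
    # whole disc must stay under the local roof
    z_under = np.interp(cx_cand, tx, tz)
    ok_above = czg >= z_under[:, None] + radius - 1e-9
    ok_below = czg <= roof_cand[:, None] - radius + 1e-9
    return bool(np.any((clearance >= radius - 1e-9) & ok_above & ok_below))


def detect_refuges(
    profile: ElevationProfile,
    gauge: float = GAUGE_DIAMETER,
    crevice_width_bounds: tuple = (0.10, 0.20),
    min_feature: float = 0.10,
    wall_angle_min: float = 80.0,
) -> RefugeSet:
    """Count physical refuges along a cross-section.

    A *crevice* is a concave notch whose rim opening width (measured at the
    shallower rim shoulder) lies within ``crevice_width_bounds``, whose
    vertical depth is at least ``min_feature``, and into which a disc of
    diameter ``gauge`` (a fish cross-section) fits without intersecting the
    terrain. An *overhang* is a maximal near-vertical run (local inclination
    >= ``wall_angle_min`` degrees) of vertical extent > ``min_feature`` that
    is not a wall of a counted crevice; single-valued profiles cannot truly
    overhang, so vertical surfaces act as the proxy.

    Candidate notches closer together than the gauge diameter merge into one
    detection, since a single disc placement cannot distinguish them.
    """
    x, z = profile.x, profile.z
    dx = profile.resolution
    w_lo, w_hi = crevice_width_bounds

    # candidate notches: morphological closing with a flat window just wider
    # than the largest countable crevice fills any narrower concavity to its
    # shoulder level while leaving broader swales (not crevices) mostly open
    se = max(3, (int(round(w_hi / dx)) + 4) | 1)
    closed = ndimage.grey_closing(z, size=se, mode="nearest")
    hole = closed - z > 1e-6
    regions, n_reg = ndimage.label(hole)

    # one candidate per sufficiently deep notch, located at its deepest
    # sample; depth is the fill (closing) level above that sample
    cands = []
    for r in range(1, n_reg + 1):
        idx = np.flatnonzero(regions == r)
        if idx[0] == 0 or idx[-1] == x.size - 1:
            continue  # truncated by the transect edge; cannot measure a rim
        imin = idx[np.argmin(z[idx])]
        depth = float(closed[imin]) - float(z[imin])
        if depth < min_feature - 1e-9:
            continue
        cands.append([idx[0], idx[-1], imin])
    # notches separated by less than the gauge diameter merge: a single disc
    # placement cannot distinguish them
    merged = []
    for c in cands:
        if merged and x[c[0]] - x[merged[-1][1]] < gauge:
            prev = merged[-1]
            prev[1] = max(prev[1], c[1])
            if z[c[2]] < z[prev[2]]:
                prev[2] = c[2]
        else:
            merged.append(c)

    crevices = []
    crevice_walls = []
    for i0, i1, imin in merged:
        zmin = float(z[imin])
        rim_fill = float(closed[imin])
        lo_lim, hi_lim = max(1, i0 - 1), min(x.size - 2, i1 + 1)
        # the opening level is where the walls end.  On uneven terrain the two
        # shoulders differ in height, so scan candidate levels downward from
        # the fill level and measure the opening span at each: the width is
        # taken at the highest level whose span falls within bounds (for a
        # clean notch that is the rim itself).  Spans only narrow as the
        # level drops, so the scan can stop once below the lower bound.
        win = z[lo_lim : hi_lim + 1]
        lvls = np.unique(win[(win <= rim_fill + 1e-9) & (win >= zmin + min_feature - 1e-9)])
        lvls = np.concatenate(([rim_fill], lvls[::-1]))
        hit = None
        for lvl in lvls:
            l = imin
            while l > lo_lim and z[l - 1] < lvl - 1e-9:
                l -= 1
            rgt = imin
            while rgt < hi_lim and z[rgt + 1] < lvl - 1e-9:
                rgt += 1
            width = x[rgt] - x[l] + dx  # opening span; inclusive of samples
            if width < w_lo - 1.5 * dx:
                break
            if width <= w_hi + 1.5 * dx:
                hit = (l, rgt, float(lvl), float(width))
                break
        if hit is None:
            continue
        l, rgt, lvl, width = hit
        if not _disc_fits(x, z, closed, l, rgt, gauge / 2.0, dx):
            continue
        xc = float(0.5 * (x[l] + x[rgt]))
        crevices.append((xc, width, lvl - zmin))
        # exclude walls across the whole merged concavity, not just the
        # accepted opening span: a merged-away neighbour is part of this
        # single detection, so its walls must not double as overhangs
        wa, wb = min(l, i0), max(rgt, i1)
        crevice_walls.append((x[max(0, wa - 2)], x[min(x.size - 1, wb + 2)]))

    # overhang proxy: maximal runs of near-vertical surface
    slope_min = math.tan(math.radians(wall_angle_min))
    seg_slope = np.abs(np.diff(z)) / np.diff(x)
    steep = seg_slope >= slope_min
    runs, n_runs = ndimage.label(steep)
    overhangs = []
    for r in range(1, n_runs + 1):
        idx = np.flatnonzero(runs == r)
        j0, j1 = idx[0], idx[-1] + 1  # sample indices bounding the run
        extent = abs(float(z[j1] - z[j0]))
        if extent <= min_feature + 1e-12:
            continue
        xa, xb = x[j0], x[j1]
        if any(xa <= wb + 1e-9 and xb >= wa - 1e-9 for wa, wb in crevice_walls):
            continue  # wall of a counted crevice
        overhangs.append((float(0.5 * (xa + xb)), extent))

    return RefugeSet(crevices=tuple(crevices), overhangs=tuple(overhangs))


# ---------------------------------------------------------------------------
# aggregation and DEM sampling


def compute_all_metrics(
    profile: ElevationProfile,
    seg: BenthicSegmentation,
    viewshed_params=None,
    refuge_params: dict | None = None,
) -> ComplexityMetrics:
    """One record combining all six metrics for a transect."""
    from .viewshed import ObserverConfig, field_of_view

    cfg = viewshed_params if viewshed_params is not None else ObserverConfig()
    refuges = detect_refuges(profile, **(refuge_params or {}))
    vs = field_of_view(profile, cfg)
    return ComplexityMetrics(
        rugosity=rugosity_index(profile),
        verticality=verticality(profile),
        coral_cover=cover_fraction(profile, seg, {"hard_coral"}),
        refuge_count=refuges.count,
        fov_visible=vs.transect_visible,
        grazing_area=grazing_area_fraction(profile, seg),
        contour_len=contour_length(profile),
        planar_len=profile.length,
    )


def sample_transect_from_dem(
    grid: np.ndarray,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
    endpoints: tuple,
    step: float,
) -> ElevationProfile:
    """Extract an elevation profile from a gridded DEM by bilinear interpolation.

    ``grid`` is elevation indexed as ``grid[iy, ix]`` on the rectilinear axes
    ``x_coords``/``y_coords``. The segment between the two ``(easting,
    northing)`` endpoints is sampled every ``step`` metres.
    """
    from scipy.interpolate import RegularGridInterpolator

    if step <= 0:
        raise ValueError("step must be positive")
    (x0, y0), (x1, y1) = endpoints
    seg_len = math.hypot(x1 - x0, y1 - y0)
    if seg_len <= 0:
        raise ValueError("transect endpoints coincide")
    for (ex, ey) in ((x0, y0), (x1, y1)):
        if not (x_coords[0] <= ex <= x_coords[-1] and y_coords[0] <= ey <= y_coords[-1]):
            raise OutOfBoundsError(f"endpoint ({ex}, {ey}) outside DEM extent")
    n = max(2, int(math.floor(seg_len / step)) + 1)
    s = np.linspace(0.0, seg_len, n)
    ex = x0 + (x1 - x0) * s / seg_len
    ey = y0 + (y1 - y0) * s / seg_len
    interp = RegularGridInterpolator((np.asarray(y_coords), np.asarray(x_coords)), np.asarray(grid, dtype=float))
    zv = interp(np.column_stack([ey, ex]))
    bad = ~np.isfinite(zv)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise DataGapError(f"no-data cell on transect path near ({ex[i]:.3f}, {ey[i]:.3f})")
    return ElevationProfile(x=s, z=zv)
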