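"""Quantify a 1D expression profile from an ISH image and a cell-layer morphology.

The cell layer of the embryo is delimited by two index-paired boundary
polylines (inner and outer).  The layer is decomposed into quadrilateral
segments between consecutive point pairs, pixel intensities are averaged per
segment, obvious artifacts are masked and interpolated over, and the result
is resampled at 100 equidistant arc-length positions and scaled to a maximum
of one.  Positions run from 0 at the animal/oral pole to 1 at the
vegetal/aboral pole along a half-meridian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath

from .domain_model import Stage

__all__ = [
    "BoundaryMorphology",
    "RawProfile",
    "EditMask",
    "StandardizedProfile",
    "GeometryError",
    "ProfileRejected",
    "segment_cell_layer",
    "segment_mean_intensity",
    "edit_profile",
    "standardize_profile",
    "extract_profile",
    "rgb_to_intensity",
    "N_STANDARD_POINTS",
]

N_STANDARD_POINTS = 100


class GeometryError(ValueError):
    """Invalid boundary geometry (degenerate or crossing segments)."""


class ProfileRejected(ValueError):
    """Profile unusable (e.g. all-zero intensity cannot be scaled to unity)."""


def _polyline_cumlen(points: np.ndarray) -> np.ndarray:
    steps = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Arc-length-uniform resampling of an open polyline to n points."""
    cum = _polyline_cumlen(points)
    if cum[-1] <= 0:
        raise GeometryError("polyline has zero length")
    target = np.linspace(0.0, cum[-1], n)
    return np.column_stack(
        [np.interp(target, cum, points[:, 0]), np.interp(target, cum, points[:, 1])]
    )


@dataclass(frozen=True)
class BoundaryMorphology:
    """Paired inner/outer cell-layer boundary polylines (the digital morphology).

    ``inner`` and ``outer`` are (n, 2) arrays of x/y points with equal count;
    point k of the inner boundary corresponds to point k of the outer one.
    ``oral_pole`` says which end of the polylines is the animal/oral pole.
    """

    inner: np.ndarray
    outer: np.ndarray
    oral_pole: str = "start"

    def __post_init__(self) -> None:
        inner = np.asarray(self.inner, dtype=float)
        outer = np.asarray(self.outer, dtype=float)
        object.__setattr__(self, "inner", inner)
        object.__setattr__(self, "outer", outer)
        if inner.ndim != 2 or inner.shape[1] != 2 or inner.shape != outer.shape:
            raise GeometryError("inner and outer must be equal-count (n, 2) arrays")
        if inner.shape[0] < 3:
            raise GeometryError("need at least 3 boundary point pairs")
        if not (np.isfinite(inner).all() and np.isfinite(outer).all()):
            raise GeometryError("non-finite boundary coordinates")
        if self.oral_pole not in ("start", "end"):
            raise GeometryError("oral_pole must be 'start' or 'end'")

    @property
    def n_pairs(self) -> int:
        return self.inner.shape[0]

    def oriented(self) -> "BoundaryMorphology":
        """Copy with the oral pole at index 0."""
        if self.oral_pole == "start":
            return self
        return BoundaryMorphology(self.inner[::-1].copy(), self.outer[::-1].copy())

    def resampled(self, n_pairs: int) -> "BoundaryMorphology":
        """Arc-length-uniform resampling of each polyline independently."""
        return BoundaryMorphology(
            _resample_polyline(self.inner, n_pairs),
            _resample_polyline(self.outer, n_pairs),
            self.oral_pole,
        )

    def midline(self) -> np.ndarray:
        return 0.5 * (self.inner + self.outer)


@dataclass
class RawProfile:
    """Per-segment mean intensities along the cell layer."""

    positions: np.ndarray
    intensities: np.ndarray
    pixel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.pixel_counts = np.asarray(self.pixel_counts, dtype=int)
        if not (len(self.positions) == len(self.intensities) == len(self.pixel_counts)):
            raise ValueError("positions, intensities, pixel_counts lengths differ")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class EditMask:
    """Position intervals [a, b] within [0, 1] whose values are replaced."""

    intervals: tuple

    def __init__(self, intervals: Sequence[tuple]) -> None:
        merged = _normalize_intervals(intervals)
        object.__setattr__(self, "intervals", merged)

    def covers(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=float)
        out = np.zeros(positions.shape, dtype=bool)
        for a, b in self.intervals:
            out |= (positions >= a) & (positions <= b)
        return out


def _normalize_intervals(intervals: Sequence[tuple]) -> tuple:
    cleaned = []
    for a, b in intervals:
        a, b = float(a), float(b)
        if b < a:
            a, b = b, a
        if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
            raise ValueError(f"mask interval [{a}, {b}] outside [0, 1]")
        cleaned.append((a, b))
    cleaned.sort()
    merged: list = []
    for a, b in cleaned:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return tuple(merged)


@dataclass(frozen=True)
class StandardizedProfile:
    """100 equidistant intensity values on [0, 1] arc length, max-scaled to 1."""

    values: np.ndarray
    gene: str = ""
    stage: Optional[Stage] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (N_STANDARD_POINTS,):
            raise ValueError(
                f"standardized profile must have exactly {N_STANDARD_POINTS} values"
            )
        if values.min() < -1e-9:
            raise ValueError("standardized profile values must be nonnegative")
        if abs(values.max() - 1.0) > 1e-9:
            raise ValueError("standardized profile maximum must equal 1")
        if self.stage is not None:
            object.__setattr__(self, "stage", Stage.parse(self.stage))


def segment_cell_layer(
    morphology: BoundaryMorphology, n_segments: Optional[int] = None
) -> list:
    """Decompose the cell layer into quadrilateral segments.

    Segment k is the quad (inner_k, inner_{k+1}, outer_{k+1}, outer_k).  Its
    position is the normalized cumulative arc length of the midline (the
    average of the two polylines) at the segment midpoint, so positions span
    the open interval (0, 1) from oral to aboral pole.

    If ``n_segments`` differs from ``n_pairs - 1`` the morphology is first
    resampled arc-length-uniformly to ``n_segments + 1`` pairs.
    """
    morphology = morphology.oriented()
    if n_segments is None:
        n_segments = morphology.n_pairs - 1
    if n_segments < 1:
        raise GeometryError("need at least one segment")
    if n_segments != morphology.n_pairs - 1:
        morphology = morphology.resampled(n_segments + 1)

    inner, outer = morphology.inner, morphology.outer
    cum = _polyline_cumlen(morphology.midline())
    total = cum[-1]
    if total <= 0:
        raise GeometryError("midline has zero length")
    positions = 0.5 * (cum[:-1] + cum[1:]) / total

    segments = []
    for k in range(n_segments):
        quad = np.array([inner[k], inner[k + 1], outer[k + 1], outer[k]])
        if _shoelace_area(quad) <= 1e-12:
            raise GeometryError(f"segment {k} is degenerate (zero area)")
        segments.append((quad, float(positions[k])))
    return segments


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def rgb_to_intensity(
    image: np.ndarray, invert: bool = True, channel: "str | int" = "luminance"
) -> np.ndarray:
    """Collapse an RGB image to one signal channel.

    ISH signal is typically a dark stain on a light background, so the default
    converts to luminance and inverts (signal-positive output).  ``channel``
    may be ``"luminance"``, ``"mean"`` or an integer channel index.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        gray = image
    elif channel == "luminance":
        from skimage.color import rgb2gray

        gray = rgb2gray(image[..., :3])
    elif channel == "mean":
        gray = image[..., :3].mean(axis=-1)
    else:
        gray = image[..., int(channel)]
    if invert:
        gray = gray.max() - gray
    return gray


def segment_mean_intensity(image: np.ndarray, segments: Sequence[tuple]) -> RawProfile:
    """Average pixel intensity per segment.

    A pixel belongs to a segment when its center (x = column, y = row) falls
    inside the quad (even-odd rule).  Segments capturing no pixel center are
    dropped with a warning; if all segments are empty an error is raised.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image; see rgb_to_intensity")
    h, w = image.shape
    positions, means, counts, dropped = [], [], [], []
    for idx, (quad, pos) in enumerate(segments):
        x0 = max(int(np.floor(quad[:, 0].min())), 0)
        x1 = min(int(np.ceil(quad[:, 0].max())), w - 1)
        y0 = max(int(np.floor(quad[:, 1].min())), 0)
        y1 = min(int(np.ceil(quad[:, 1].max())), h - 1)
        if x1 < x0 or y1 < y0:
            dropped.append(idx)
            continue
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        inside = _MplPath(quad, closed=False).contains_points(pts)
        if not inside.any():
            dropped.append(idx)
            continue
        vals = image[pts[inside, 1], pts[inside, 0]]
        positions.append(pos)
        means.append(vals.mean())
        counts.append(int(inside.sum()))
    if dropped:
        warnings.warn(
            f"{len(dropped)} segment(s) captured no pixel center and were "
            f"dropped (indices {dropped[:5]}{'...' if len(dropped) > 5 else ''})",
            stacklevel=2,
        )
    if not positions:
        raise ValueError("all segments are empty: image and morphology do not overlap")
    return RawProfile(np.array(positions), np.array(means), np.array(counts))


def edit_profile(raw: RawProfile, mask: EditMask) -> RawProfile:
    """Replace intensities in masked position intervals by linear interpolation.

    Masked runs touching either end of the profile take the value of the
    nearest unmasked point.  Pixel counts are carried through unchanged.
    """
    masked = mask.covers(raw.positions)
    if masked.all():
        raise ValueError("edit mask covers the whole profile")
    if not masked.any():
        return RawProfile(
            raw.positions.copy(), raw.intensities.copy(), raw.pixel_counts.copy()
        )
    intens = raw.intensities.copy()
    intens[masked] = np.interp(
        raw.positions[masked], raw.positions[~masked], raw.intensities[~masked]
    )
    return RawProfile(raw.positions.copy(), intens, raw.pixel_counts.copy())


def standardize_profile(
    raw: RawProfile,
    gene: str = "",
    stage: Optional[Stage] = None,
    sample_id: str = "",
) -> StandardizedProfile:
    """Interpolate at 100 equidistant points spanning [0, 1] and scale to unit max.

    The 100 points include both endpoints (step 1/99); positions outside the
    measured range take the nearest measured value.  An all-zero (or
    nonpositive-maximum) profile cannot be scaled and is rejected.
    """
    if len(raw.positions) < 2:
        raise ProfileRejected("need at least two measured points")
    grid = np.linspace(0.0, 1.0, N_STANDARD_POINTS)
    values = np.interp(grid, raw.positions, raw.intensities)
    peak = values.max()
    if peak <= 0:
        raise ProfileRejected("profile maximum is not positive; cannot scale to unity")
    return StandardizedProfile(values / peak, gene=gene, stage=stage, sample_id=sample_id)


def extract_profile(
    image: np.ndarray,
    morphology: BoundaryMorphology,
    n_segments: Optional[int] = None,
    edit_mask: Optional[EditMask] = None,
    invert: bool = False,
    channel: "str | int" = "luminance",
    gene: str = "",
    stage: Optional[Stage] = None,
    sample_id: str = "",
) -> StandardizedProfile:
    """Full quantification pipeline: segment, average, edit, standardize.

    ``invert`` flips intensity polarity (use for dark-stain-on-light images);
    RGB images are collapsed per ``channel`` and inverted by default.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        image = rgb_to_intensity(image, invert=True, channel=channel)
    elif invert:
        image = image.max() - image
    segments = segment_cell_layer(morphology, n_segments)
    raw = segment_mean_intensity(image, segments)
    if edit_mask is not None:
        raw = edit_profile(raw, edit_mask)
    return standardize_profile(raw, gene=gene, stage=stage, sample_id=sample_id)
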