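"""Synthetic embryo images, profile sets and domain tables with ground truth.

Every input the quantification pipeline consumes can be generated here, with
the generating truth recorded alongside, so each downstream stage is testable
against known answers.

Images emulate a cylindrically symmetric embryo: the cell layer is an
elliptical annulus (blastula-like), optionally dented near the oral pole to
mimic the invagination of gastrula-like morphologies; both cases are emitted
as the same inner/outer boundary-polyline type.  Staining intensity inside
the layer is a function of normalized arc-length position along the
oral-aboral half-meridian (0 = animal/oral pole, 1 = vegetal/aboral pole),
given by an archetype's window function; noise is additive Gaussian
truncated at zero, and localized bright or dark blob artifacts can be
injected at recorded positions.  Images are signal-positive (bright stain on
dark background); the extractor's invert flag covers the opposite polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .domain_model import (
    REGION_REPRESENTATIVES,
    REGIONS,
    DomainTable,
    Stage,
    StageRecord,
)
from .profile_extraction import (
    BoundaryMorphology,
    GeometryError,
    N_STANDARD_POINTS,
    StandardizedProfile,
)
from .transition_analysis import CATEGORIES_ALL, TransitionEvent

__all__ = [
    "ArchetypeSpec",
    "ShapeParams",
    "ImageScene",
    "TransitionKernel",
    "generate_embryo_image",
    "generate_profile_set",
    "generate_domain_table",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """A staining archetype: amplitude windows on the [0, 1] arc-length axis.

    ``windows`` is a list of ``(name, start, end)`` intervals with unique
    names; ``amplitudes`` gives the intensity per window (scalar broadcast).
    ``edge_taper`` is the width of the raised-cosine ramp at each window edge
    (0 = sharp box); real expression domains have graded boundaries, so the
    default is gently smoothed.
    """

    windows: tuple
    amplitudes: tuple = ()
    stage: Optional[Stage] = None
    edge_taper: float = 0.05
    name: str = ""

    def __init__(
        self,
        windows: Sequence[tuple],
        amplitudes: "float | Sequence[float]" = 1.0,
        stage: Optional[Stage] = None,
        edge_taper: float = 0.05,
        name: str = "",
    ) -> None:
        windows = tuple((str(n), float(s), float(e)) for n, s, e in windows)
        names = [n for n, _, _ in windows]
        if len(set(names)) != len(names):
            raise ValueError("window names must be unique")
        for n, s, e in windows:
            if not (0.0 <= s < e <= 1.0):
                raise ValueError(f"window {n!r}: need 0 <= start < end <= 1")
        amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(windows),))
        if (amps < 0).any():
            raise ValueError("window amplitudes must be nonnegative")
        if edge_taper < 0:
            raise ValueError("edge_taper must be nonnegative")
        object.__setattr__(self, "windows", windows)
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in amps))
        object.__setattr__(self, "stage", Stage.parse(stage) if stage is not None else None)
        object.__setattr__(self, "edge_taper", float(edge_taper))
        object.__setattr__(
            self, "name", name or "+".join(n for n, _, _ in windows) or "null"
        )

    def window_function(
        self, t: np.ndarray, amplitudes: Optional[Sequence[float]] = None
    ) -> np.ndarray:
        """Summed window intensity at arc positions ``t``."""
        t = np.asarray(t, dtype=float)
        amps = self.amplitudes if amplitudes is None else amplitudes
        out = np.zeros_like(t)
        w = self.edge_taper
        for (name, s, e), amp in zip(self.windows, amps):
            if w <= 0:
                inside = (t >= s) & ((t < e) | ((e >= 1.0 - 1e-12) & (t <= e)))
                out = out + amp * inside
            else:
                u = np.minimum((t - s) / w, (e - t) / w)
                u = np.clip(u, 0.0, 1.0)
                out = out + amp * 0.5 * (1.0 - np.cos(np.pi * u))
        return out


@dataclass(frozen=True)
class ShapeParams:
    """Embryo-geometry parameters (pixel units, angles in radians).

    ``invagination_depth`` > 0 dents both boundaries inward around the oral
    pole (gastrula-like); 0 gives a clean elliptical annulus (blastula-like).
    """

    outer_radius: float = 52.0
    aspect: float = 1.0
    layer_thickness: float = 14.0
    invagination_depth: float = 0.0
    invagination_width: float = 0.45
    center: Optional[tuple] = None
    n_boundary_points: int = 257


@dataclass
class ImageScene:
    """A generated image plus the truth that produced it."""

    image: np.ndarray
    true_morphology: BoundaryMorphology
    true_profile: Callable
    artifact_regions: list
    seed: int
    archetype: ArchetypeSpec
    background: float

    def __post_init__(self) -> None:
        if self.image.ndim != 2 or min(self.image.shape) < 1:
            raise ValueError("image must be a nonempty 2D raster")
        for a, b in self.artifact_regions:
            if not (0.0 <= a <= b <= 1.0):
                raise ValueError("artifact intervals must lie within [0, 1]")

    def true_standardized(self) -> StandardizedProfile:
        grid = np.linspace(0.0, 1.0, N_STANDARD_POINTS)
        values = np.asarray(self.true_profile(grid), dtype=float)
        peak = values.max()
        if peak <= 0:
            raise ValueError("true profile is identically zero")
        return StandardizedProfile(values / peak, gene=self.archetype.name)


_ORAL_ANGLE = -np.pi / 2  # oral pole points "up" (toward row 0)


def _radial_profiles(shape: ShapeParams, phi: np.ndarray) -> tuple:
    """Outer/inner boundary radius as a function of polar angle."""
    rx = shape.outer_radius
    ry = shape.outer_radius * shape.aspect
    ellipse = rx * ry / np.hypot(ry * np.cos(phi), rx * np.sin(phi))
    delta = np.abs(np.angle(np.exp(1j * (phi - _ORAL_ANGLE))))
    dent = shape.invagination_depth * np.exp(
        -0.5 * (delta / shape.invagination_width) ** 2
    )
    r_out = ellipse - dent
    r_in = r_out - shape.layer_thickness
    return r_out, r_in, delta


def _arc_position_map(shape: ShapeParams) -> tuple:
    """Normalized midline arc length t as a function of pole angle delta."""
    delta = np.linspace(0.0, np.pi, 4097)
    phi = _ORAL_ANGLE + delta
    r_out, r_in, _ = _radial_profiles(shape, phi)
    mid = 0.5 * (r_out + r_in)
    pts = np.column_stack([mid * np.cos(phi), mid * np.sin(phi)])
    steps = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return delta, cum / cum[-1]


def generate_embryo_image(
    shape_params: ShapeParams,
    archetype: ArchetypeSpec,
    noise_sd: float = 0.0,
    artifact_spec: Sequence[tuple] = (),
    seed: int = 0,
    background: float = 0.0,
    image_size: tuple = (128, 128),
) -> ImageScene:
    """Render an embryo-like image with recorded ground truth.

    Inside the cell layer the intensity is ``background`` plus the archetype's
    window function of arc-length position; outside it is ``background``.
    ``artifact_spec`` lists ``(center, halfwidth, delta)`` blobs: every layer
    pixel within ``halfwidth`` of arc position ``center`` is offset by
    ``delta`` (positive = bright blob, negative = dark), and the disturbed
    interval is recorded for editing tests.  Gaussian noise of standard
    deviation ``noise_sd`` is added everywhere and the image clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if shape_params.layer_thickness <= 0:
        raise GeometryError("layer thickness must be positive")
    h, w = image_size
    cx, cy = shape_params.center or ((w - 1) / 2.0, (h - 1) / 2.0)

    delta_grid, t_grid = _arc_position_map(shape_params)
    boundary_delta = np.linspace(0.0, np.pi, shape_params.n_boundary_points)
    phi_b = _ORAL_ANGLE + boundary_delta
    r_out_b, r_in_b, _ = _radial_profiles(shape_params, phi_b)
    if r_in_b.min() <= 1.0:
        raise GeometryError(
            "inner boundary is not strictly inside the outer boundary "
            "(thickness/invagination too large for this radius)"
        )
    unit = np.column_stack([np.cos(phi_b), np.sin(phi_b)])
    morphology = BoundaryMorphology(
        inner=np.array([cx, cy]) + r_in_b[:, None] * unit,
        outer=np.array([cx, cy]) + r_out_b[:, None] * unit,
        oral_pole="start",
    )

    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    rho = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    r_out_p, r_in_p, delta_p = _radial_profiles(shape_params, phi)
    inside = (rho >= r_in_p) & (rho <= r_out_p)
    t = np.interp(delta_p, delta_grid, t_grid)

    image = np.full((h, w), float(background))
    image[inside] += archetype.window_function(t[inside])

    artifact_regions = []
    for center, halfwidth, amp in artifact_spec:
        if halfwidth <= 0:
            raise ValueError("artifact halfwidth must be positive")
        sel = inside & (np.abs(t - center) <= halfwidth)
        image[sel] += amp
        artifact_regions.append(
            (max(0.0, center - halfwidth), min(1.0, center + halfwidth))
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, None)

    def true_profile(t_query: np.ndarray) -> np.ndarray:
        return np.clip(archetype.window_function(t_query), 0.0, 1.0)

    return ImageScene(
        image=image,
        true_morphology=morphology,
        true_profile=true_profile,
        artifact_regions=artifact_regions,
        seed=seed,
        archetype=archetype,
        background=float(background),
    )


def generate_profile_set(
    archetypes: Sequence[ArchetypeSpec],
    n_per_archetype: int = 10,
    noise_sd: float = 0.05,
    amplitude_jitter: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Planted-cluster profile fixture.

    Each profile is its archetype's window function sampled at the 100
    standard positions, perturbed by per-window multiplicative amplitude
    jitter and additive truncated Gaussian noise, then max-scaled to one.
    Returns ``(profiles, labels)`` where ``labels[i]`` is the index of the
    generating archetype.
    """
    if n_per_archetype < 1:
        raise ValueError("n_per_archetype must be at least 1")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, N_STANDARD_POINTS)
    profiles, labels = [], []
    for k, arch in enumerate(archetypes):
        base_amps = np.asarray(arch.amplitudes, dtype=float)
        for i in range(n_per_archetype):
            amps = base_amps
            if amplitude_jitter > 0:
                amps = np.clip(
                    base_amps
                    * (1.0 + amplitude_jitter * rng.standard_normal(base_amps.size)),
                    0.0,
                    None,
                )
            values = arch.window_function(grid, amplitudes=amps)
            if noise_sd > 0:
                values = values + rng.normal(0.0, noise_sd, size=values.shape)
            values = np.clip(values, 0.0, None)
            peak = values.max()
            if peak <= 0:
                raise ValueError(
                    f"archetype {arch.name!r} produced an all-zero profile; "
                    "cannot scale to unity"
                )
            profiles.append(
                StandardizedProfile(
                    values / peak,
                    gene=arch.name,
                    stage=arch.stage,
                    sample_id=f"{arch.name}_{i:03d}",
                )
            )
            labels.append(k)
    return profiles, labels


@dataclass(frozen=True)
class TransitionKernel:
    """Per-step transition-category probabilities plus stage availability.

    ``minor``/``major``/``appeared``/``vanished``/``none`` must sum to one;
    at each step the kernel is renormalized over the categories feasible from
    the current state (expressed: minor/major/vanished; silent:
    appeared/none).  ``availability`` is the probability that a gene has an
    image at a stage (scalar or one value per stage).
    """

    minor: float = 1.0
    major: float = 0.0
    appeared: float = 0.0
    vanished: float = 0.0
    none: float = 0.0
    availability: "float | tuple" = 1.0

    def __post_init__(self) -> None:
        probs = self.probabilities()
        if any(p < 0 for p in probs.values()):
            raise ValueError("kernel probabilities must be nonnegative")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("kernel probabilities must sum to 1")
        avail = np.atleast_1d(np.asarray(self.availability, dtype=float))
        if (avail < 0).any() or (avail > 1).any():
            raise ValueError("availability must lie in [0, 1]")

    def probabilities(self) -> dict:
        return {c: float(getattr(self, c)) for c in CATEGORIES_ALL}

    def availability_per_stage(self, n_stages: int) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.availability, dtype=float)), (n_stages,)
        )


_FEASIBLE = {True: ("minor", "major", "vanished"), False: ("appeared", "none")}


def generate_domain_table(
    n_genes: int,
    stages: Optional[Sequence[Stage]] = None,
    kernel: Optional[TransitionKernel] = None,
    region_vocab: Optional[dict] = None,
    seed: int = 0,
) -> tuple:
    """Domain table with known per-transition categories.

    Each gene receives a random subset of available stages (at least two) and
    a major-region state evolving over its consecutive available stages
    according to the kernel; the state is written out as that region's
    representative domain name at the stage.  Returns ``(table, events)``
    where ``events`` lists the true :class:`TransitionEvent` of every
    consecutive pair.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    kernel = kernel or TransitionKernel()
    stages = [Stage.parse(s) for s in (stages or list(Stage))]
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    stages = sorted(stages)
    avail = kernel.availability_per_stage(len(stages))
    if np.sort(avail)[-2] <= 0:  # needs >= 2 stages with any availability
        raise ValueError("availability permits fewer than two stages")
    reps = region_vocab or REGION_REPRESENTATIVES
    probs = kernel.probabilities()
    p_silent_start = probs["appeared"] + probs["none"]

    rng = np.random.default_rng(seed)
    records: dict = {}
    events: list = []
    for g in range(n_genes):
        gene = f"g{g:04d}"
        mask = rng.random(len(stages)) < avail
        while mask.sum() < 2:
            mask = rng.random(len(stages)) < avail
        own_stages = [s for s, m in zip(stages, mask) if m]

        if rng.random() < p_silent_start:
            state: frozenset = frozenset()
        else:
            state = frozenset({rng.choice(REGIONS)})
        recs = [_state_record(own_stages[0], state, reps)]
        for prev, cur in zip(own_stages, own_stages[1:]):
            feasible = _FEASIBLE[bool(state)]
            weights = np.array([probs[c] for c in feasible])
            if weights.sum() <= 0:
                raise ValueError(
                    f"kernel assigns zero probability to every category "
                    f"feasible from state {set(state) or 'silent'}"
                )
            cat = rng.choice(feasible, p=weights / weights.sum())
            state = _apply_category(state, cat, rng)
            recs.append(_state_record(cur, state, reps))
            events.append(TransitionEvent(gene, prev, cur, str(cat)))
        records[gene] = recs
    return DomainTable(records), events


def _state_record(stage: Stage, state: frozenset, reps: dict) -> StageRecord:
    domains = frozenset(reps[stage][r] for r in state)
    return StageRecord(stage=stage, domains=domains)


def _apply_category(state: frozenset, cat: str, rng: np.random.Generator) -> frozenset:
    if cat == "minor":
        return state
    if cat == "major":
        candidates = [r for r in REGIONS if frozenset({r}) != state]
        return frozenset({rng.choice(candidates)})
    if cat == "vanished" or cat == "none":
        return frozenset()
    if cat == "appeared":
        return frozenset({rng.choice(REGIONS)})
    raise ValueError(f"unknown category {cat!r}")  # pragma: no cover
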