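"""Synthetic multi-session two-photon imaging of dendritic segments.

This module generates ground-truth spine timelines with the statistical
structure the downstream analysis assumes — stochastic spine birth at a
per-preexisting-spine daily rate, distinct survival kinetics for newborn and
preexisting spines, occasional single-session disappearance followed by
reappearance at the same location — and renders them as 3D fluorescence
stacks (dendrite tube + spiny protrusions, Gaussian PSF, Poisson shot noise,
small inter-session translation jitter).

Coordinates are physical micrometres, ``(x, y, z)`` with the origin at the
stack corner, x along the segment, z axial.  Voxel arrays are indexed
``(z, y, x)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SimConfig",
    "ImagingParams",
    "DendriteGeometry",
    "SpineTimeline",
    "SimulatedDendrite",
    "ImageStack",
    "sham_config",
    "chi_config",
    "chi_isrib_config",
    "simulate_cohort",
    "simulate_timelines",
    "render_stack",
    "observations_from_timelines",
]


class SpineOutOfBoundsError(ValueError):
    """A spine tip falls outside the rendered volume."""


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative spine-dynamics model.

    Rates are per preexisting spine per day; survival probabilities are per
    day.  ``formation_rate_post_switch`` / ``newborn_survival_post_switch``
    model a treatment that changes the regime from ``rate_switch_day`` on
    (four daily injections starting at day 14 in the emulated study design).
    """

    session_days: tuple[int, ...] = (11, 13, 15, 18, 25)
    n_mice_per_group: int = 12
    dendrites_per_mouse: int = 40
    group: str = "sham"
    segment_length_um: tuple[float, float] = (50.0, 100.0)
    baseline_density_per_um: float = 0.4
    formation_rate_per_spine_per_day: float = 0.1
    formation_rate_post_switch: float | None = None
    newborn_daily_survival_prob: float = 0.94868
    newborn_survival_post_switch: float | None = None
    rate_switch_day: int = 14
    preexisting_daily_survival_prob: float = 0.998
    reappearance_prob: float = 0.05
    min_spacing_um: float = 0.6
    min_spacing_same_side_um: float = 1.2
    spine_length_um: tuple[float, float] = (1.0, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(self.session_days)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("session_days must be strictly increasing, length >= 2")
        lo, hi = self.segment_length_um
        if not (48.0 <= lo <= hi <= 102.0):
            raise ValueError("segment_length_um must lie within [48, 102]")
        if not self.baseline_density_per_um > 0:
            raise ValueError("baseline_density_per_um must be > 0")
        probs = {
            "newborn_daily_survival_prob": self.newborn_daily_survival_prob,
            "preexisting_daily_survival_prob": self.preexisting_daily_survival_prob,
            "reappearance_prob": self.reappearance_prob,
        }
        rates = {
            "formation_rate_per_spine_per_day": self.formation_rate_per_spine_per_day,
        }
        if self.formation_rate_post_switch is not None:
            rates["formation_rate_post_switch"] = self.formation_rate_post_switch
        if self.newborn_survival_post_switch is not None:
            probs["newborn_survival_post_switch"] = self.newborn_survival_post_switch
        for name, v in {**probs, **rates}.items():
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be finite and in [0, 1], got {v!r}")

    def formation_rate_on(self, day: int) -> float:
        if self.formation_rate_post_switch is not None and day >= self.rate_switch_day:
            return self.formation_rate_post_switch
        return self.formation_rate_per_spine_per_day

    def newborn_survival_on(self, day: int) -> float:
        if self.newborn_survival_post_switch is not None and day >= self.rate_switch_day:
            return self.newborn_survival_post_switch
        return self.newborn_daily_survival_prob


def sham_config(**overrides) -> SimConfig:
    """Uninjured-control regime: ~0.2 new spines per preexisting spine over a
    2-day interval, newborn 2-day persistence ~0.9."""
    return SimConfig(
        group="sham",
        formation_rate_per_spine_per_day=0.1,
        newborn_daily_survival_prob=0.94868,
        **overrides,
    )


def chi_config(**overrides) -> SimConfig:
    """Concussive-injury regime: formation ~0.5 over a 2-day interval and
    mostly short-lived newborns (2-day persistence ~0.4)."""
    return SimConfig(
        group="chi",
        formation_rate_per_spine_per_day=0.25,
        newborn_daily_survival_prob=0.63246,
        **overrides,
    )


def chi_isrib_config(**overrides) -> SimConfig:
    """Injury followed by treatment that restores control-like rates from the
    switch day (default 14) onward."""
    return SimConfig(
        group="chi_isrib",
        formation_rate_per_spine_per_day=0.25,
        newborn_daily_survival_prob=0.63246,
        formation_rate_post_switch=0.1,
        newborn_survival_post_switch=0.94868,
        **overrides,
    )


@dataclass(frozen=True)
class ImagingParams:
    """Microscope/rendering parameters (micrometres).

    Voxel geometry defaults to 0.1513 um laterally and 1.0 um z-steps.  The
    dendrite is a bright tube; each spine a thin neck ending in a bulbous
    head whose far edge sits at the spine's length from the backbone
    centerline.  ``gain`` is the fluorescence amplitude in photon counts
    (Poisson noise is applied to blurred intensity + ``background``).
    """

    pixel_size_xy_um: float = 0.1513
    z_step_um: float = 1.0
    tube_radius_um: float = 0.35
    neck_radius_um: float = 0.15
    head_radius_um: float = 0.4
    blur_sigma_lateral_um: float = 0.3
    blur_sigma_axial_um: float = 1.0
    gain: float = 150.0
    background: float = 2.0
    jitter_amplitude_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise: bool = True

    def __post_init__(self) -> None:
        if any(abs(a) > 2.0 for a in self.jitter_amplitude_um):
            raise ValueError("jitter amplitude bounded by 2 um per axis")


@dataclass(frozen=True)
class DendriteGeometry:
    """Physical layout of one rendered segment volume.

    The backbone runs along x from ``margin_x`` to ``margin_x + length_um``
    at the lateral/axial centre of the volume.
    """

    dendrite_id: str
    mouse_id: str
    group: str
    length_um: float
    margin_x_um: float = 2.0
    half_width_um: float = 4.0
    half_depth_um: float = 5.0

    @property
    def y_center_um(self) -> float:
        return self.half_width_um

    @property
    def z_center_um(self) -> float:
        return self.half_depth_um

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return (
            self.length_um + 2 * self.margin_x_um,
            2 * self.half_width_um,
            2 * self.half_depth_um,
        )

    def backbone_polyline(self) -> np.ndarray:
        x0, x1 = self.margin_x_um, self.margin_x_um + self.length_um
        return np.array(
            [[x0, self.y_center_um, self.z_center_um], [x1, self.y_center_um, self.z_center_um]]
        )


# ---------------------------------------------------------------------------
# ground-truth timelines


@dataclass
class SpineTimeline:
    """Ground-truth record of one spine across the session calendar.

    ``position`` is the protrusion tip in volume coordinates (um);
    ``presence`` is the binary per-session vector aligned with
    ``session_days``.
    """

    spine_id: str
    dendrite_id: str
    mouse_id: str
    group: str
    session_days: tuple[int, ...]
    presence: np.ndarray
    position: tuple[float, float, float]
    base_x_um: float
    side: int
    length_um: float
    is_baseline: bool

    @property
    def birth_session(self) -> int:
        return int(np.argmax(self.presence))

    @property
    def death_session(self) -> int | None:
        last = int(np.max(np.nonzero(self.presence)[0]))
        if last == len(self.presence) - 1:
            return None
        return last + 1

    @property
    def reappeared(self) -> bool:
        p = self.presence
        seen_gap = False
        seen_one = False
        for v in p:
            if v and seen_gap:
                return True
            if not v and seen_one:
                seen_gap = True
            if v:
                seen_one = True
        return False


@dataclass
class SimulatedDendrite:
    geometry: DendriteGeometry
    timelines: list[SpineTimeline]


def _allowed_intervals(
    lo: float, hi: float, blocked: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """[lo, hi] minus the union of blocked intervals."""
    events = sorted((max(lo, a), min(hi, b)) for a, b in blocked if b > lo and a < hi)
    out = []
    cur = lo
    for a, b in events:
        if a > cur:
            out.append((cur, a))
        cur = max(cur, b)
    if cur < hi:
        out.append((cur, hi))
    return out


def _place_spine(
    rng: np.random.Generator,
    cfg: SimConfig,
    segment_length_um: float,
    occupied: list[tuple[float, int]],
) -> tuple[float, int] | None:
    """Sample an along-segment position and side respecting minimum spacing.

    ``occupied`` holds (x, side) for every spine ever placed, so a new spine
    never reuses an eliminated spine's location (formation is scored at new
    locations only).  The position is drawn uniformly from the exact set of
    allowed locations (the segment minus the spacing exclusion zones), so a
    birth only fails when the side is truly saturated.
    """
    lo, hi = 1.0, segment_length_um - 1.0
    first = 1 if rng.random() < 0.5 else -1
    for side in (first, -first):
        blocked = []
        for xo, so in occupied:
            r = cfg.min_spacing_same_side_um if so == side else cfg.min_spacing_um
            blocked.append((xo - r, xo + r))
        free = _allowed_intervals(lo, hi, blocked)
        total = sum(b - a for a, b in free)
        if total <= 0:
            continue
        u = rng.uniform(0.0, total)
        for a, b in free:
            if u <= b - a:
                return a + u, side
            u -= b - a
    return None


@dataclass
class _SpineState:
    x: float
    side: int
    length: float
    born_day: int
    is_baseline: bool
    alive: bool = True
    observed: bool = False
    revival_day: int | None = None
    presence: list[int] = field(default_factory=list)


def _simulate_dendrite(
    cfg: SimConfig, rng: np.random.Generator, mouse_id: str, dendrite_id: str
) -> SimulatedDendrite:
    days = cfg.session_days
    length = float(rng.uniform(*cfg.segment_length_um))
    geometry = DendriteGeometry(dendrite_id, mouse_id, cfg.group, length)

    spines: list[_SpineState] = []
    n0 = max(1, int(round(length * cfg.baseline_density_per_um)))
    for _ in range(n0):
        L = float(rng.uniform(*cfg.spine_length_um))
        placed = _place_spine(rng, cfg, length, [(s.x, s.side) for s in spines])
        if placed is None:
            break
        spines.append(_SpineState(placed[0], placed[1], L, days[0], True))

    def snapshot() -> None:
        for s in spines:
            s.presence.append(1 if s.alive else 0)
            if s.alive:
                s.observed = True

    snapshot()  # baseline session

    session_set = set(days)
    for day in range(days[0] + 1, days[-1] + 1):
        # scheduled reappearances become alive again today
        for s in spines:
            if s.revival_day == day:
                s.alive = True
                s.revival_day = None
        # births: each live preexisting spine may spawn one newborn today
        rate = cfg.formation_rate_on(day)
        parents = sum(1 for s in spines if s.alive and s.is_baseline)
        if rate > 0 and parents > 0:
            n_births = int(rng.binomial(parents, rate))
            for _ in range(n_births):
                L = float(rng.uniform(*cfg.spine_length_um))
                placed = _place_spine(rng, cfg, length, [(s.x, s.side) for s in spines])
                if placed is not None:
                    spines.append(_SpineState(placed[0], placed[1], L, day, False))
        # daily survival trials: newborn attrition starts after the spine
        # has been observed at a session (its persistence kinetics are
        # defined from first observation), preexisting spines face a trial
        # every day after baseline
        for s in spines:
            if not s.alive or s.born_day == day:
                continue
            if not s.is_baseline and not s.observed:
                continue
            p = (
                cfg.preexisting_daily_survival_prob
                if s.is_baseline
                else cfg.newborn_survival_on(day)
            )
            if rng.random() >= p:
                s.alive = False
                if rng.random() < cfg.reappearance_prob:
                    upcoming = [d for d in days if d >= day]
                    # absent at the next session, back at the one after
                    if len(upcoming) >= 2:
                        s.revival_day = upcoming[0] + 1
        if day in session_set:
            snapshot()

    timelines: list[SpineTimeline] = []
    counter = 0
    for s in sorted(spines, key=lambda s: (s.born_day, s.x)):
        # spines born mid-simulation missed the earlier snapshots
        pad = len(days) - len(s.presence)
        presence = np.asarray([0] * pad + s.presence, dtype=np.int8)
        if presence.sum() == 0:  # never observed at any session
            continue
        tip = (
            geometry.margin_x_um + s.x,
            geometry.y_center_um + s.side * s.length,
            geometry.z_center_um,
        )
        timelines.append(
            SpineTimeline(
                spine_id=f"{dendrite_id}:G{counter:04d}",
                dendrite_id=dendrite_id,
                mouse_id=mouse_id,
                group=cfg.group,
                session_days=days,
                presence=presence,
                position=tip,
                base_x_um=geometry.margin_x_um + s.x,
                side=s.side,
                length_um=s.length,
                is_baseline=s.is_baseline,
            )
        )
        counter += 1
    return SimulatedDendrite(geometry, timelines)


def simulate_cohort(cfg: SimConfig) -> list[SimulatedDendrite]:
    """Simulate every dendrite of one experimental group.

    Deterministic given ``cfg.seed``; each (mouse, dendrite) gets an
    independent child RNG so the outcome does not depend on iteration order.
    """
    out: list[SimulatedDendrite] = []
    for m in range(cfg.n_mice_per_group):
        mouse_id = f"{cfg.group}_m{m:02d}"
        for d in range(cfg.dendrites_per_mouse):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=(cfg.seed, m, d))
            )
            out.append(_simulate_dendrite(cfg, rng, mouse_id, f"{mouse_id}_d{d:02d}"))
    return out


def simulate_timelines(cfg: SimConfig) -> list[SpineTimeline]:
    """Flat list of ground-truth spine timelines for the whole cohort."""
    return [tl for den in simulate_cohort(cfg) for tl in den.timelines]


# ---------------------------------------------------------------------------
# rendering


@dataclass
class ImageStack:
    """One session's 3D fluorescence volume, indexed (z, y, x)."""

    voxels: np.ndarray
    pixel_size_xy_um: float = 0.1513
    z_step_um: float = 1.0
    session_day: int = 0
    jitter_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if np.min(self.voxels) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def sampling(self) -> tuple[float, float, float]:
        """(z, y, x) voxel sizes in um."""
        return (self.z_step_um, self.pixel_size_xy_um, self.pixel_size_xy_um)

    def voxel_to_um(self, idx: np.ndarray) -> np.ndarray:
        """(z, y, x) voxel indices -> (x, y, z) um positions."""
        idx = np.atleast_2d(idx)
        s = self.sampling
        return np.column_stack([idx[:, 2] * s[2], idx[:, 1] * s[1], idx[:, 0] * s[0]])


def _soft_capsule_2d(
    img: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, pxy: float
) -> None:
    """Accumulate (max) a soft-edged capsule around segment p0-p1 into a 2D
    (y, x) intensity layer.  Points are (x, y) um; the edge rolls off over
    one pixel so sub-pixel positions shift the image smoothly."""
    ny, nx = img.shape
    pad = radius + 2 * pxy
    lo = np.minimum(p0, p1) - pad
    hi = np.maximum(p0, p1) + pad
    ix0 = max(0, int(math.floor(lo[0] / pxy)))
    ix1 = min(nx - 1, int(math.ceil(hi[0] / pxy)))
    iy0 = max(0, int(math.floor(lo[1] / pxy)))
    iy1 = min(ny - 1, int(math.ceil(hi[1] / pxy)))
    if ix1 < ix0 or iy1 < iy0:
        return
    yy, xx = np.meshgrid(
        np.arange(iy0, iy1 + 1) * pxy, np.arange(ix0, ix1 + 1) * pxy, indexing="ij"
    )
    pts = np.stack([xx, yy], axis=-1)
    d = p1 - p0
    dd = float(d @ d)
    if dd == 0:
        closest = p0
    else:
        t = np.clip(((pts - p0) @ d) / dd, 0.0, 1.0)
        closest = p0 + t[..., None] * d
    dist = np.sqrt(np.sum((pts - closest) ** 2, axis=-1))
    val = np.clip((radius - dist) / pxy + 0.5, 0.0, 1.0)
    sub = img[iy0 : iy1 + 1, ix0 : ix1 + 1]
    np.maximum(sub, val, out=sub)


def _axial_profile(
    z_slices: np.ndarray, z0: float, half_thickness: float, sigma: float
) -> np.ndarray:
    """Weight of an in-plane structure (z-extent z0 +/- half_thickness) in
    each z-slice after axial Gaussian blur: a Gaussian-convolved box.  Thin
    structures between slices spread over neighbours instead of vanishing."""
    from math import erf, sqrt

    a = (z_slices - z0 + half_thickness) / (sigma * sqrt(2.0))
    b = (z_slices - z0 - half_thickness) / (sigma * sqrt(2.0))
    return 0.5 * (np.vectorize(erf)(a) - np.vectorize(erf)(b))


def render_stack(
    timelines: list[SpineTimeline],
    geometry: DendriteGeometry,
    session_day: int,
    imaging: ImagingParams = ImagingParams(),
    rng: np.random.Generator | None = None,
    jitter_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Render one session: dendrite tube plus the spines alive that day.

    The whole scene is translated by a random sub-voxel jitter (or the
    explicit ``jitter_um``); the applied offset is recorded in
    ``jitter_offset_um``.  Deterministic given an identically seeded ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if jitter_um is None:
        amp = np.asarray(imaging.jitter_amplitude_um, dtype=float)
        jitter = rng.uniform(-amp, amp)
    else:
        jitter = np.asarray(jitter_um, dtype=float)
    if np.any(np.abs(jitter) > 2.0):
        raise ValueError("jitter bounded by 2 um per axis")

    ex, ey, ez = geometry.extent_um
    pxy, dz = imaging.pixel_size_xy_um, imaging.z_step_um
    shape = (int(round(ez / dz)) + 1, int(round(ey / pxy)) + 1, int(round(ex / pxy)) + 1)

    # the scene is in-plane (backbone and spines share one z); each structure
    # class is drawn as a soft 2D layer, then spread over z-slices by the
    # analytic axial profile of its thickness under the axial PSF
    layers = {
        "tube": (np.zeros(shape[1:], dtype=np.float32), imaging.tube_radius_um),
        "neck": (np.zeros(shape[1:], dtype=np.float32), imaging.neck_radius_um),
        "head": (np.zeros(shape[1:], dtype=np.float32), imaging.head_radius_um),
    }
    j2 = jitter[:2]
    bb = geometry.backbone_polyline()[:, :2] + j2
    for p0, p1 in zip(bb[:-1], bb[1:]):
        _soft_capsule_2d(layers["tube"][0], p0, p1, imaging.tube_radius_um, pxy)

    day_index = list(timelines[0].session_days).index(session_day) if timelines else None
    for tl in timelines:
        if not tl.presence[day_index]:
            continue
        tip = np.asarray(tl.position, dtype=float)
        lims = np.asarray([ex, ey, ez])
        if np.any(tip < 0) or np.any(tip > lims):
            raise SpineOutOfBoundsError(
                f"spine {tl.spine_id} tip {tuple(tip)} outside volume extent {tuple(lims)}"
            )
        base = np.array([tl.base_x_um, geometry.y_center_um, geometry.z_center_um])
        direction = tip - base
        norm = float(np.linalg.norm(direction))
        direction = direction / norm if norm else np.array([0.0, 1.0, 0.0])
        head_center = (tip - direction * imaging.head_radius_um)[:2]
        _soft_capsule_2d(
            layers["neck"][0], base[:2] + j2, head_center + j2, imaging.neck_radius_um, pxy
        )
        _soft_capsule_2d(
            layers["head"][0], head_center + j2, head_center + j2, imaging.head_radius_um, pxy
        )

    z0 = geometry.z_center_um + jitter[2]
    z_slices = np.arange(shape[0]) * dz
    sig2d = imaging.blur_sigma_lateral_um / pxy
    img = np.zeros(shape, dtype=np.float32)
    for layer, half in layers.values():
        if not layer.any():
            continue
        blurred = ndi.gaussian_filter(layer, sig2d)
        w = _axial_profile(z_slices, z0, half, imaging.blur_sigma_axial_um)
        img += imaging.gain * w[:, None, None].astype(np.float32) * blurred[None, :, :]
    img += imaging.background
    if imaging.noise:
        img = rng.poisson(img).astype(np.float32)
    return ImageStack(
        voxels=img,
        pixel_size_xy_um=pxy,
        z_step_um=dz,
        session_day=session_day,
        jitter_offset_um=tuple(float(j) for j in jitter),
    )


def observations_from_timelines(den: SimulatedDendrite):
    """Ground-truth per-session observation lists (tracking-pipeline input).

    Bypasses imaging: each live spine contributes one observation at its true
    tip position.  Used for presence-matrix-level analyses and as the oracle
    against detected observations.
    """
    from .detection import SpineObservation  # local import to avoid a cycle

    days = den.timelines[0].session_days if den.timelines else ()
    out: list[list[SpineObservation]] = [[] for _ in days]
    for tl in den.timelines:
        for i, day in enumerate(days):
            if tl.presence[i]:
                out[i].append(
                    SpineObservation(
                        dendrite_id=tl.dendrite_id,
                        session_day=day,
                        position=tl.position,
                        base_position=(
                            tl.base_x_um,
                            den.geometry.y_center_um,
                            den.geometry.z_center_um,
                        ),
                        length_um=tl.length_um,
                        intensity=1.0,
                    )
                )
    return out
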