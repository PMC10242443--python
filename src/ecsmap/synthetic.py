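"""Synthetic stand-ins for the study's raw imaging data.

Three generators with known ground truth:

* confined 2D Brownian trajectories in parameterized domains (discs,
  rectangles, channels with optional dead-end stubs), sampled at the 30 ms
  frame interval used for quantum-dot tracking, with Gaussian localization
  noise and Bernoulli blinking dropout;
* axial orientation samples from uniform / unimodal / orthogonal-bimodal
  circular-normal laws (sampled on doubled angles, see
  :mod:`ecsmap.orientation`);
* bilevel extracellular-space (ECS) images at 19.53 nm pixel pitch with
  controlled gap widths.

The stepper uses specular reflection about the violated boundary, iterated
until the proposal is interior, which preserves the uniform equilibrium law of
reflected Brownian motion in a bounded domain.  The analytic MSD plateau
(mean squared distance between two independent uniform points) is R^2 for a
disc of radius R and (Lx^2 + Ly^2)/6 for a rectangle; it scales with the
square of the linear domain size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import BinarizedImage, SegmentSet, Trajectory, TrajectorySet
from .geometry import nearest_point_on_polyline, polyline_distances

__all__ = [
    "DomainSpec",
    "SimulationConfig",
    "OrientationLawSpec",
    "ImageSpec",
    "SyntheticEcsImage",
    "simulate_confined_trajectory",
    "simulate_cohort",
    "sample_orientation_segments",
    "generate_ecs_image",
]


# ---------------------------------------------------------------------------
# domain geometry


@dataclass(frozen=True)
class DomainSpec:
    """Bounded 2D domain confining the tracer.

    shape: "disc" (radius, um), "rectangle" (width x height, um) or
    "polyline_channel" (centerline vertices um + channel width um, with
    optional dead-end stub polylines sharing the channel width, emulating the
    dead-ended geometry hypothesized for CA3 neuropil).
    """

    shape: str
    radius: float | None = None
    width: float | None = None
    height: float | None = None
    centerline: tuple[tuple[float, float], ...] | None = None
    channel_width: float | None = None
    dead_ends: tuple[tuple[tuple[float, float], ...], ...] = ()

    def __post_init__(self) -> None:
        if self.shape == "disc":
            if self.radius is None or self.radius <= 0:
                raise ValueError("disc requires radius > 0")
        elif self.shape == "rectangle":
            if not (self.width and self.height and self.width > 0 and self.height > 0):
                raise ValueError("rectangle requires width > 0 and height > 0")
        elif self.shape == "polyline_channel":
            if self.centerline is None or len(self.centerline) < 2:
                raise ValueError("channel centerline needs >= 2 vertices")
            if self.channel_width is None or self.channel_width <= 0:
                raise ValueError("channel requires channel_width > 0")
            for stub in self.dead_ends:
                if len(stub) < 2:
                    raise ValueError("dead-end stub needs >= 2 vertices")
        else:
            raise ValueError(f"unknown domain shape {self.shape!r}")

    # -- derived geometry ---------------------------------------------------

    def scaled(self, s: float) -> "DomainSpec":
        """Multiply every linear dimension by ``s`` (area scales by s^2)."""
        if s <= 0:
            raise ValueError("scale must be positive")
        if self.shape == "disc":
            return replace(self, radius=self.radius * s)
        if self.shape == "rectangle":
            return replace(self, width=self.width * s, height=self.height * s)
        scale_poly = lambda poly: tuple((x * s, y * s) for x, y in poly)
        return replace(
            self,
            centerline=scale_poly(self.centerline),
            channel_width=self.channel_width * s,
            dead_ends=tuple(scale_poly(p) for p in self.dead_ends),
        )

    def min_dimension(self) -> float:
        if self.shape == "disc":
            return 2.0 * self.radius
        if self.shape == "rectangle":
            return min(self.width, self.height)
        return self.channel_width

    def _polylines(self) -> list[np.ndarray]:
        return [np.asarray(self.centerline, dtype=float)] + [
            np.asarray(p, dtype=float) for p in self.dead_ends
        ]

    def contains(self, p: np.ndarray) -> bool:
        p = np.asarray(p, dtype=float)
        if self.shape == "disc":
            return float(np.hypot(p[0], p[1])) <= self.radius
        if self.shape == "rectangle":
            return 0.0 <= p[0] <= self.width and 0.0 <= p[1] <= self.height
        h = self.channel_width / 2.0
        return any(
            nearest_point_on_polyline(p, poly)[1] <= h for poly in self._polylines()
        )

    def contains_many(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self.shape == "disc":
            return np.hypot(pts[:, 0], pts[:, 1]) <= self.radius
        if self.shape == "rectangle":
            return (
                (pts[:, 0] >= 0)
                & (pts[:, 0] <= self.width)
                & (pts[:, 1] >= 0)
                & (pts[:, 1] <= self.height)
            )
        h = self.channel_width / 2.0
        d = np.min(
            np.column_stack([polyline_distances(pts, poly) for poly in self._polylines()]),
            axis=1,
        )
        return d <= h

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        if self.shape == "disc":
            r = self.radius
            return np.array([-r, -r]), np.array([r, r])
        if self.shape == "rectangle":
            return np.zeros(2), np.array([self.width, self.height])
        v = np.vstack(self._polylines())
        h = self.channel_width / 2.0
        return v.min(axis=0) - h, v.max(axis=0) + h

    def sample_interior(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Uniform interior points by rejection from the bounding box."""
        lo, hi = self.bounding_box()
        out = np.empty((size, 2))
        got = 0
        while got < size:
            cand = rng.uniform(lo, hi, size=(max(4 * (size - got), 16), 2))
            good = cand[self.contains_many(cand)]
            take = min(good.shape[0], size - got)
            out[got : got + take] = good[:take]
            got += take
        return out if size > 1 else out[0]

    def analytic_plateau(self) -> float | None:
        """E|r1 - r2|^2 for independent uniform interior points (um^2)."""
        if self.shape == "disc":
            return self.radius**2
        if self.shape == "rectangle":
            return (self.width**2 + self.height**2) / 6.0
        return None


def _reflect_once(domain: DomainSpec, p: np.ndarray) -> np.ndarray:
    """Specular reflection of an exterior proposal about the violated boundary."""
    if domain.shape == "rectangle":
        q = p.copy()
        for i, L in enumerate((domain.width, domain.height)):
            # fold into [0, L]; one fold per call, the caller iterates
            if q[i] < 0:
                q[i] = -q[i]
            elif q[i] > L:
                q[i] = 2 * L - q[i]
        return q
    if domain.shape == "disc":
        r = float(np.hypot(p[0], p[1]))
        return p * ((2 * domain.radius - r) / r)
    h = domain.channel_width / 2.0
    best_q, best_d = None, np.inf
    for poly in domain._polylines():
        q, d = nearest_point_on_polyline(p, poly)
        if d < best_d:
            best_q, best_d = q, d
    u = (p - best_q) / best_d
    return best_q + u * (2 * h - best_d)


def _reflect_into(domain: DomainSpec, p: np.ndarray) -> np.ndarray:
    for _ in range(64):
        if domain.contains(p):
            return p
        p = _reflect_once(domain, p)
    # pathological overshoot: pin just inside the nearest wall
    if domain.shape == "disc":
        return p * (0.999 * domain.radius / np.hypot(p[0], p[1]))
    if domain.shape == "rectangle":
        return np.clip(p, 0, [domain.width, domain.height])
    q, d = nearest_point_on_polyline(p, np.asarray(domain.centerline, dtype=float))
    return q + (p - q) / d * (0.499 * domain.channel_width)


# ---------------------------------------------------------------------------
# trajectory simulation


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and motion parameters for one synthetic recording.

    Defaults follow the tracking protocol emulated here: 30 ms frame interval,
    up to 500 consecutive frames per track, 0.03 um localization precision.
    """

    d_free: float = 0.1  # free diffusion coefficient, um^2/s
    dt: float = 0.03  # frame interval, s
    n_frames: int = 500
    sigma_loc: float = 0.03  # localization noise std per axis, um
    detection_prob: float = 1.0  # Bernoulli per-frame detection (blinking)
    n_substeps: int = 4  # Brownian integration substeps per frame
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d_free < 0:
            raise ValueError("d_free must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must be in (0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be >= 0")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")


def simulate_confined_trajectory(
    domain: DomainSpec,
    cfg: SimulationConfig,
    *,
    track_id: str = "0",
    recording: str = "rec0",
    region: str = "",
    condition: str = "",
    rng: np.random.Generator | None = None,
    start: np.ndarray | None = None,
    return_truth: bool = False,
):
    """Simulate one confined Brownian track with localization noise and blinking.

    The per-frame rms step sqrt(4*D*dt) must not exceed half the smallest
    domain dimension, otherwise the discrete stepper could tunnel through
    walls and a ValueError is raised.

    Returns a :class:`Trajectory`; with ``return_truth=True`` also returns the
    noise-free positions of the detected frames (always inside the domain).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    step_rms = math.sqrt(4.0 * cfg.d_free * cfg.dt)
    if step_rms > 0.5 * domain.min_dimension():
        raise ValueError(
            f"rms step {step_rms:.3g} um exceeds half the smallest domain "
            f"dimension ({domain.min_dimension():.3g} um); reduce d_free or dt"
        )
    n = cfg.n_frames
    pos = np.empty((n, 2))
    pos[0] = domain.sample_interior(rng) if start is None else np.asarray(start, float)
    if not domain.contains(pos[0]):
        raise ValueError("start point lies outside the domain")
    if cfg.d_free > 0 and n > 1:
        # integrate finer than the frame interval to tame reflection-
        # discretization bias near walls; record every n_substeps-th position
        m = cfg.n_substeps
        sub_sd = math.sqrt(2.0 * cfg.d_free * cfg.dt / m)
        steps = rng.normal(0.0, sub_sd, size=((n - 1) * m, 2))
        p = pos[0]
        for i in range(1, n):
            for j in range((i - 1) * m, i * m):
                p = _reflect_into(domain, p + steps[j])
            pos[i] = p
    else:
        pos[1:] = pos[0]
    noise = (
        rng.normal(0.0, cfg.sigma_loc, size=(n, 2)) if cfg.sigma_loc > 0 else np.zeros((n, 2))
    )
    if cfg.detection_prob < 1.0:
        detected = rng.random(n) < cfg.detection_prob
        if not detected.any():
            detected[0] = True
    else:
        detected = np.ones(n, dtype=bool)
    frames = np.flatnonzero(detected)
    obs = pos[detected] + noise[detected]
    traj = Trajectory(
        track_id=str(track_id),
        frames=frames,
        x=obs[:, 0],
        y=obs[:, 1],
        recording=recording,
        region=region,
        condition=condition,
    )
    if return_truth:
        return traj, pos[detected]
    return traj


def simulate_cohort(
    domain: DomainSpec,
    cfg: SimulationConfig,
    n_traj: int,
    scale: float = 1.0,
    *,
    recording: str = "rec0",
    region: str = "",
    condition: str = "",
) -> TrajectorySet:
    """Simulate one recording: ``n_traj`` tracks in a common (scaled) domain.

    ``scale`` multiplies all linear domain dimensions; scale=1 emulates the
    control condition and scale=sqrt(3) emulates the ~3x confinement-area
    increase seen after 4 h of matrix digestion.  Ground-truth domain
    parameters (including the analytic plateau when known) are stored in the
    set's metadata.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    dom = domain.scaled(scale)
    ss = np.random.SeedSequence(cfg.seed)
    trajs = [
        simulate_confined_trajectory(
            dom,
            cfg,
            track_id=str(i),
            recording=recording,
            region=region,
            condition=condition,
            rng=np.random.default_rng(child),
        )
        for i, child in enumerate(ss.spawn(n_traj))
    ]
    return TrajectorySet(
        trajs,
        dt=cfg.dt,
        metadata={
            "domain": dom,
            "scale": scale,
            "analytic_plateau_um2": dom.analytic_plateau(),
            "d_free": cfg.d_free,
            "sigma_loc": cfg.sigma_loc,
            "seed": cfg.seed,
        },
    )


# ---------------------------------------------------------------------------
# orientation samples


@dataclass(frozen=True)
class OrientationLawSpec:
    """Axial orientation law: uniform on [0, pi), unimodal circular normal, or
    a mixture of two circular normals with orthogonal centers.

    mu is the mean orientation in [0, pi); kappa1/kappa2 are concentrations of
    the doubled-angle circular-normal components; weight is the mixture weight
    of the component centered at mu.  Segment lengths are constant or
    lognormal (``length`` is the median, um).
    """

    law: str
    mu: float = 0.0
    kappa1: float = 0.0
    kappa2: float = 0.0
    weight: float = 0.5
    n: int = 100
    length_law: str = "constant"
    length: float = 1.0
    length_sigma: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.law not in ("uniform", "unimodal", "orthogonal_bimodal"):
            raise ValueError(f"unknown orientation law {self.law!r}")
        if self.law == "unimodal" and self.kappa1 <= 0:
            raise ValueError("unimodal law requires kappa1 > 0")
        if self.kappa1 < 0 or self.kappa2 < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.length_law not in ("constant", "lognormal"):
            raise ValueError(f"unknown length law {self.length_law!r}")


def sample_orientation_segments(spec: OrientationLawSpec) -> SegmentSet:
    """Draw (orientation, length) pairs from the specified axial law.

    Unimodal and bimodal sampling happens on doubled angles (phi = 2*theta on
    [0, 2pi)) with the von Mises law, matching the fitting convention; the
    second bimodal component is centred at mu + pi/2 in orientation space.
    """
    rng = np.random.default_rng(spec.seed)
    mu2 = 2.0 * np.mod(spec.mu, np.pi)
    cap = 1e8  # numerical sampler cap only; fitting has its own solver cap
    if spec.law == "uniform":
        theta = rng.uniform(0.0, np.pi, spec.n)
    elif spec.law == "unimodal":
        phi = rng.vonmises(mu2, min(spec.kappa1, cap), spec.n)
        theta = np.mod(phi, 2 * np.pi) / 2.0
    else:
        k2 = spec.kappa2 if spec.kappa2 > 0 else spec.kappa1
        first = rng.random(spec.n) < spec.weight
        phi = np.where(
            first,
            rng.vonmises(mu2, min(spec.kappa1, cap), spec.n),
            rng.vonmises(mu2 + np.pi, min(k2, cap), spec.n),
        )
        theta = np.mod(phi, 2 * np.pi) / 2.0
    if spec.length_law == "constant":
        lengths = np.full(spec.n, spec.length)
    else:
        lengths = rng.lognormal(math.log(spec.length), spec.length_sigma, spec.n)
    return SegmentSet(theta, lengths, owner=f"synthetic:{spec.law}")


# ---------------------------------------------------------------------------
# bilevel ECS images


@dataclass(frozen=True)
class ImageSpec:
    """Bilevel ECS image layout.

    geometry "stripes": vertical cell bands of ``cell_px`` separated by ECS
    gaps; "cell_mosaic": a grid of cell blocks with random sizes in
    ``cell_px_range`` separated by ECS gaps along both axes.  Gap widths are
    constant (``gap_width_nm``) or lognormal (median ``gap_median_nm``,
    log-sigma ``gap_sigma``), realized on the integer pixel grid.
    """

    shape_px: tuple[int, int] = (512, 512)
    pitch_nm: float = 19.53
    geometry: str = "stripes"
    gap_law: str = "constant"
    gap_width_nm: float = 195.3
    gap_median_nm: float = 300.0
    gap_sigma: float = 0.35
    cell_px: int = 30
    cell_px_range: tuple[int, int] = (15, 45)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pitch_nm <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.geometry not in ("stripes", "cell_mosaic"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.gap_law not in ("constant", "lognormal"):
            raise ValueError(f"unknown gap law {self.gap_law!r}")
        if len(self.shape_px) != 2 or min(self.shape_px) < 4:
            raise ValueError("shape_px must be (rows, cols) with >= 4 pixels each")
        if self.cell_px < 0:
            raise ValueError("cell_px must be >= 0")


@dataclass
class SyntheticEcsImage:
    """Generated bilevel image plus the true width (nm) of every drawn gap."""

    image: BinarizedImage
    gap_widths_nm: np.ndarray
    spec: ImageSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _draw_gap_px(spec: ImageSpec, rng: np.random.Generator) -> int:
    if spec.gap_law == "constant":
        px = int(round(spec.gap_width_nm / spec.pitch_nm))
        if px < 1:
            raise ValueError(
                f"requested gap {spec.gap_width_nm} nm is narrower than one pixel "
                f"({spec.pitch_nm} nm)"
            )
        return px
    nm = rng.lognormal(math.log(spec.gap_median_nm), spec.gap_sigma)
    return max(1, int(round(nm / spec.pitch_nm)))


def _band_layout(
    size: int, spec: ImageSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """1D mask of ECS gap bands along one axis, plus realized gap widths (px).

    Only gaps bounded by cell material on both sides are drawn and recorded,
    so that measured and true widths agree exactly.
    """
    mask = np.zeros(size, dtype=bool)
    widths: list[int] = []

    def cell_w() -> int:
        if spec.geometry == "stripes":
            return spec.cell_px
        lo, hi = spec.cell_px_range
        return int(rng.integers(lo, hi + 1))

    x = cell_w()
    if spec.geometry == "stripes" and spec.cell_px == 0:
        mask[:] = True  # degenerate: all-ECS image, no bounded gap
        return mask, widths
    while x < size:
        g = _draw_gap_px(spec, rng)
        if x + g >= size:  # would touch or cross the border: stop
            break
        mask[x : x + g] = True
        widths.append(g)
        x += g + cell_w()
    return mask, widths


def generate_ecs_image(spec: ImageSpec) -> SyntheticEcsImage:
    """Generate a bilevel raster (foreground = ECS) with known gap widths."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape_px
    if spec.geometry == "stripes":
        col_mask, widths = _band_layout(cols, spec, rng)
        img = np.broadcast_to(col_mask, (rows, cols)).copy()
        all_widths = widths
    else:
        col_mask, wx = _band_layout(cols, spec, rng)
        row_mask, wy = _band_layout(rows, spec, rng)
        img = col_mask[None, :] | row_mask[:, None]
        all_widths = wx + wy
    return SyntheticEcsImage(
        image=BinarizedImage(img, pitch_nm=spec.pitch_nm),
        gap_widths_nm=np.asarray(all_widths, dtype=float) * spec.pitch_nm,
        spec=spec,
    )
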