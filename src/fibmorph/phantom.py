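"""Annular bone phantoms with analytic ground truth.

A phantom is a deformed annulus embedded in a muscle-like background:
a hypointense bone wall enclosing hyperintense marrow, surrounded by
intermediate-intensity muscle and dark background. The outer (periosteal)
contour is a harmonically deformed circle,

    r_out(theta) = (D_out / 2) * (1 + sum_k a_k * cos(k*theta + phi_k)),

and the inner (endosteal) contour is offset radially inward by the wall
thickness. Real fibulae have a largely triangular periosteal contour, which
a k = 3 harmonic emulates.

Ground truth (area, mid-wall centerline length, thickness, g-ratio) is
computed from the continuous contours by dense polygonal integration, never
from pixels, so it is resolution-independent. Rendering supersamples each
pixel and block-averages, emulating partial volume — the dominant error
source when pixel size is a sizeable fraction of the wall thickness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .types import RoiMask, SliceImage

__all__ = ["PhantomSpec", "PhantomTruth", "make_annulus_phantom"]

_TRUTH_VERTICES = 7200  # dense polygonal integration of the continuous contours


@dataclass
class PhantomSpec:
    """Geometry, intensities and rendering parameters of one phantom slice.

    Lengths are mm; intensities are dimensionless in [0, 1]. The deformation
    harmonics are ``(order k >= 2, amplitude fraction, phase radians)`` tuples
    applied to the outer contour radius; the inner contour follows at a fixed
    radial wall thickness.
    """

    outer_diameter: float = 10.9
    wall_thickness: float = 2.7
    center_offset: tuple[float, float] = (0.0, 0.0)
    deformation_harmonics: tuple[tuple[int, float, float], ...] = ()
    intensity_bone: float = 0.108
    intensity_marrow: float = 0.90
    intensity_muscle: float = 0.45
    intensity_background: float = 0.05
    noise_sd: float = 0.0
    pixel_spacing: float = 0.7
    grid_size: int | None = None
    supersample_factor: int = 8

    def validate(self) -> None:
        if not self.wall_thickness > 0:
            raise InvalidSpecError("wall_thickness must be positive")
        if not self.wall_thickness < self.outer_diameter / 2:
            raise InvalidSpecError("wall_thickness must be < outer_diameter / 2")
        amp_total = 0.0
        for k, a, _phi in self.deformation_harmonics:
            if int(k) < 2:
                raise InvalidSpecError(f"harmonic order must be >= 2, got {k}")
            if not 0 <= a < 0.3:
                raise InvalidSpecError(f"harmonic amplitude must be in [0, 0.3), got {a}")
            amp_total += a
        # star-shaped, simple contours require r_out > 0 and r_in > 0 everywhere
        r0 = self.outer_diameter / 2
        r_out_min = r0 * (1 - amp_total)
        if r_out_min - self.wall_thickness <= 0:
            raise InvalidSpecError(
                "deformation collapses the inner contour (self-intersection): "
                f"min outer radius {r_out_min:.3f} mm <= wall {self.wall_thickness} mm"
            )
        for v in (
            self.intensity_bone,
            self.intensity_marrow,
            self.intensity_muscle,
            self.intensity_background,
        ):
            if not 0 <= v <= 1:
                raise InvalidSpecError(f"intensities must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel_spacing must be positive")
        if int(self.supersample_factor) < 1:
            raise InvalidSpecError("supersample_factor must be a positive integer")

    # -- continuous geometry -------------------------------------------------

    def outer_radius(self, theta: np.ndarray) -> np.ndarray:
        r = np.full_like(np.asarray(theta, dtype=float), self.outer_diameter / 2)
        for k, a, phi in self.deformation_harmonics:
            r = r * (1 + a * np.cos(int(k) * np.asarray(theta) + phi))
        return r

    def inner_radius(self, theta: np.ndarray) -> np.ndarray:
        return self.outer_radius(theta) - self.wall_thickness

    def max_outer_radius(self) -> float:
        theta = np.linspace(0, 2 * math.pi, _TRUTH_VERTICES, endpoint=False)
        return float(self.outer_radius(theta).max())

    def auto_grid_size(self) -> int:
        """Smallest grid comfortably containing the phantom plus margin."""
        extent = self.max_outer_radius() + max(
            abs(self.center_offset[0]), abs(self.center_offset[1])
        )
        n = int(math.ceil(2 * (extent * 1.25 + 3 * self.pixel_spacing) / self.pixel_spacing))
        # odd, so the ring center falls on a pixel center: a small marrow
        # cavity then lands inside one pixel instead of straddling four,
        # keeping the ring topology at coarse resolution
        return n + 1 - (n % 2)


@dataclass
class PhantomTruth:
    """Resolution-independent ground truth from the continuous contours."""

    true_BA: float
    true_CL: float
    true_BT: float
    true_g: float
    true_BMA: float
    true_MPI_bone: float
    true_D_out: float = field(default=float("nan"))
    true_D_in: float = field(default=float("nan"))


def _polygon_area_perimeter(r: np.ndarray, theta: np.ndarray) -> tuple[float, float]:
    """Shoelace area and perimeter of the polygon with polar vertices (r, theta)."""
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * abs(np.sum(x * y2 - x2 * y))
    perim = float(np.sum(np.hypot(x2 - x, y2 - y)))
    return float(area), perim


def compute_truth(spec: PhantomSpec, n_vertices: int = _TRUTH_VERTICES) -> PhantomTruth:
    """Ground-truth morphometry by dense polygonal integration.

    ``true_BT`` is defined as ``true_BA / true_CL`` — the measurement's own
    definition — which equals the nominal radial wall thickness exactly for
    the undeformed annulus. ``true_g`` follows the ring model on the mid-wall
    centerline: with the centerline diameter ``d = true_CL / pi``,
    ``true_g = (d - BT) / (d + BT) = D_in / D_out``.
    """
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    r_out = spec.outer_radius(theta)
    r_in = r_out - spec.wall_thickness
    r_mid = r_out - spec.wall_thickness / 2

    area_out, _ = _polygon_area_perimeter(r_out, theta)
    area_in, _ = _polygon_area_perimeter(r_in, theta)
    _, cl = _polygon_area_perimeter(r_mid, theta)

    ba = area_out - area_in
    bt = ba / cl
    d_mid = cl / math.pi
    d_out = d_mid + bt
    d_in = d_mid - bt
    g = d_in / d_out
    peak = max(
        spec.intensity_bone,
        spec.intensity_marrow,
        spec.intensity_muscle,
        spec.intensity_background,
    )
    return PhantomTruth(
        true_BA=ba,
        true_CL=cl,
        true_BT=bt,
        true_g=g,
        true_BMA=area_in,
        true_MPI_bone=spec.intensity_bone / peak,
        true_D_out=d_out,
        true_D_in=d_in,
    )


def make_annulus_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[SliceImage, RoiMask, RoiMask, PhantomTruth]:
    """Render one phantom slice and its truth.

    Returns ``(image, bone mask, marrow mask, truth)``. The image is rendered
    at ``supersample_factor`` times the target resolution and block-averaged
    down (partial-volume emulation); masks assign a pixel to a tissue when at
    least half of its subsamples lie in that tissue (majority occupancy, the
    rounding a careful manual tracer would apply). Additive Gaussian noise of
    sd ``noise_sd`` is applied at the target resolution.

    ``rng`` seeds the noise; pass an int or Generator for reproducibility
    (defaults to a fixed seed 0 generator).
    """
    spec.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(0 if rng is None else int(rng))

    n = spec.grid_size or spec.auto_grid_size()
    s = int(spec.supersample_factor)
    dx = spec.pixel_spacing

    half = (n - 1) / 2.0
    # subpixel centers in physical coordinates, relative to the grid center
    sub = (np.arange(n * s) + 0.5) / s - 0.5  # pixel-unit positions
    coords = (sub - half) * dx
    yy = coords[:, None] - spec.center_offset[0]
    xx = coords[None, :] - spec.center_offset[1]
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)

    r_out = spec.outer_radius(theta)
    r_in = r_out - spec.wall_thickness

    extent = spec.max_outer_radius() + max(
        abs(spec.center_offset[0]), abs(spec.center_offset[1])
    )
    if extent > (half - 2) * dx:
        raise InvalidSpecError(
            f"ring (extent {extent:.2f} mm) touches the grid boundary "
            f"(half-field {(half - 2) * dx:.2f} mm); enlarge grid_size"
        )

    marrow_sub = r < r_in
    bone_sub = (r >= r_in) & (r <= r_out)
    muscle_sub = (~marrow_sub) & (~bone_sub) & (r < 1.4 * spec.max_outer_radius())

    intensity = np.full(r.shape, spec.intensity_background, dtype=float)
    intensity[muscle_sub] = spec.intensity_muscle
    intensity[bone_sub] = spec.intensity_bone
    intensity[marrow_sub] = spec.intensity_marrow

    def block_mean(a: np.ndarray) -> np.ndarray:
        return a.reshape(n, s, n, s).mean(axis=(1, 3))

    image_vals = block_mean(intensity)
    if spec.noise_sd > 0:
        image_vals = image_vals + rng.normal(0.0, spec.noise_sd, size=image_vals.shape)

    bone_frac = block_mean(bone_sub.astype(float))
    marrow_frac = block_mean(marrow_sub.astype(float))
    bone_mask = bone_frac >= 0.5
    marrow_mask = (marrow_frac >= 0.5) & ~bone_mask

    image = SliceImage(values=image_vals, pixel_spacing=(dx, dx))
    bone = RoiMask(values=bone_mask, pixel_spacing=(dx, dx), label="bone")
    marrow = RoiMask(values=marrow_mask, pixel_spacing=(dx, dx), label="marrow")
    return image, bone, marrow, compute_truth(spec)
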