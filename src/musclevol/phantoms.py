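"""Synthetic fusiform-muscle phantoms with closed-form ACSA profiles and volumes.

A phantom is a straight, axis-aligned solid whose elliptical cross-sectional
area A(x) is a known function of the relative axial position x (0 = distal end,
1 = proximal end).  Because both the anatomical cross-sectional area (ACSA)
profile and the total volume are available in closed form, voxelized phantoms
provide exact ground truth for testing per-slice area extraction, ACSA_max
localization, and volume estimators against a slice-by-slice reference.

Four shape families are available:

``cylinder``
    constant A(x) = A_max; shape factor exactly 1.
``cone``
    A(x) = A_max * x**2 (apex at the distal end); shape factor exactly 1/3.
``frustum``
    linearly interpolated radius between two end radii.
``beta_spindle``
    a beta-function kernel normalized to peak value A_max at x = x_m:
    A(x) = A_max * (x/x_m)**(a-1) * ((1-x)/(1-x_m))**(b-1) with
    a = 1 + kappa*x_m and b = 1 + kappa*(1-x_m), so the profile mode sits
    exactly at x_m.  This is the fusiform ("spindle") family used to emulate
    thigh muscles, which taper toward both myotendinous junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate
from scipy.special import betaln
from scipy.stats import truncnorm

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "LabelVolume",
    "SHAPE_FAMILIES",
    "analytic_acsa",
    "analytic_volume",
    "quadrature_volume",
    "voxelize",
    "generate_cohort",
    "solve_sharpness_for_shape_factor",
    "DEFAULT_SHARPNESS",
]

SHAPE_FAMILIES = ("cylinder", "cone", "frustum", "beta_spindle")

#: Default spindle sharpness.  Chosen so that the analytic shape factor of a
#: spindle peaking at 61% of muscle length equals 0.62, the value reported for
#: the vastus lateralis in athlete cohorts (see docs/methods.md).
DEFAULT_SHARPNESS = 2.4069927499068053

# Guard against accidentally huge voxel grids (e.g. micron spacing).
MAX_GRID_VOXELS = 200_000_000


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of one synthetic muscle.

    Parameters
    ----------
    shape_family:
        One of :data:`SHAPE_FAMILIES`.
    length_mm:
        Muscle length along the slice axis, mm.
    peak_acsa_mm2:
        Maximal cross-sectional area A_max, mm^2.  For the frustum family it
        is derived from ``end_radii_mm`` and may be omitted (pass ``None``).
    peak_location:
        Relative axial position x_m of A_max in (0, 1), distal end = 0.
        Only meaningful for ``beta_spindle`` (the cone peaks at 1 and the
        cylinder everywhere by construction).
    sharpness:
        Spindle concentration kappa >= 0; larger values taper the ends more
        sharply.  kappa = 0 degenerates to a cylinder.
    aspect_ratio:
        Ratio of the in-plane ellipse semi-axes (muscle cross-sections are
        not circular; 1.5 is a typical eccentricity).  Areas are preserved:
        a = sqrt(A*q/pi), b = sqrt(A/(pi*q)).
    end_radii_mm:
        (distal, proximal) equivalent-circle radii, frustum family only.
    """

    shape_family: str
    length_mm: float
    peak_acsa_mm2: float | None = None
    peak_location: float = 0.5
    sharpness: float = DEFAULT_SHARPNESS
    aspect_ratio: float = 1.5
    end_radii_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if not self.length_mm > 0:
            raise ValueError("length_mm must be positive")
        if self.shape_family == "frustum":
            if self.end_radii_mm is None:
                raise ValueError("frustum requires end_radii_mm")
            r0, r1 = self.end_radii_mm
            if r0 < 0 or r1 < 0 or (r0 == 0 and r1 == 0):
                raise ValueError("end radii must be nonnegative, not both zero")
            derived = math.pi * max(r0, r1) ** 2
            if self.peak_acsa_mm2 is None:
                object.__setattr__(self, "peak_acsa_mm2", derived)
        else:
            if self.peak_acsa_mm2 is None or not self.peak_acsa_mm2 > 0:
                raise ValueError("peak_acsa_mm2 must be positive")
        if not 0.0 < self.peak_location < 1.0:
            raise ValueError("peak_location must lie in (0, 1)")
        if self.sharpness < 0:
            raise ValueError("sharpness must be nonnegative")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def cylinder(cls, length_mm: float, acsa_mm2: float, **kw) -> "PhantomSpec":
        return cls("cylinder", length_mm, acsa_mm2, **kw)

    @classmethod
    def cone(cls, length_mm: float, peak_acsa_mm2: float, **kw) -> "PhantomSpec":
        return cls("cone", length_mm, peak_acsa_mm2, **kw)

    @classmethod
    def frustum(cls, length_mm: float, end_radii_mm: tuple[float, float], **kw) -> "PhantomSpec":
        return cls("frustum", length_mm, end_radii_mm=end_radii_mm, **kw)

    @classmethod
    def beta_spindle(
        cls,
        length_mm: float,
        peak_acsa_mm2: float,
        peak_location: float = 0.5,
        sharpness: float = DEFAULT_SHARPNESS,
        **kw,
    ) -> "PhantomSpec":
        return cls(
            "beta_spindle",
            length_mm,
            peak_acsa_mm2,
            peak_location=peak_location,
            sharpness=sharpness,
            **kw,
        )


@dataclass(frozen=True)
class CohortSpec:
    """Per-subject parameter distributions for a simulated cohort.

    ``length_mm``, ``peak_acsa_mm2`` and ``peak_location`` are (mean, sd)
    pairs of normal distributions; the peak location is truncated to
    ``location_bounds`` to keep the ACSA peak away from the muscle ends.
    The same seed always yields a bit-identical cohort.
    """

    n_subjects: int
    length_mm: tuple[float, float] = (400.0, 25.0)
    peak_acsa_mm2: tuple[float, float] = (4000.0, 500.0)
    peak_location: tuple[float, float] = (0.61, 0.0965)
    location_bounds: tuple[float, float] = (0.05, 0.95)
    voxel_spacing_mm: tuple[float, float, float] = (0.65, 0.65, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("length_mm", "peak_acsa_mm2", "peak_location"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} standard deviation must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        lo, hi = self.location_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("location_bounds must satisfy 0 < lo < hi < 1")


@dataclass
class LabelVolume:
    """3D integer label map with voxel spacing and axis-orientation metadata.

    The slice axis is the third array axis; ``distal_end`` records which end
    of that axis is anatomically distal.  Label 0 is background.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    distal_end: str = "low_index"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all voxel spacings must be positive")
        if self.distal_end not in ("low_index", "high_index"):
            raise ValueError("distal_end must be 'low_index' or 'high_index'")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with the spacing in the header (RAS affine)."""
        import nibabel as nib

        affine = np.diag([*self.spacing_mm, 1.0])
        img = nib.Nifti1Image(self.voxels.astype(np.uint16), affine)
        img.header.set_zooms(self.spacing_mm)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, distal_end: str = "low_index") -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValueError(f"{path}: not an integer label map")
            data = rounded.astype(np.int32)
        zooms = img.header.get_zooms()[:3]
        return cls(data, tuple(float(z) for z in zooms), distal_end)


def _beta_exponents(spec: PhantomSpec) -> tuple[float, float]:
    a = 1.0 + spec.sharpness * spec.peak_location
    b = 1.0 + spec.sharpness * (1.0 - spec.peak_location)
    return a, b


def analytic_acsa(spec: PhantomSpec, x) -> np.ndarray | float:
    """Closed-form ACSA profile A(x) in mm^2 at relative position(s) x in [0, 1]."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > 1):
        raise ValueError("x must lie in [0, 1]")
    fam = spec.shape_family
    if fam == "cylinder":
        out = np.full_like(x_arr, spec.peak_acsa_mm2)
    elif fam == "cone":
        out = spec.peak_acsa_mm2 * x_arr**2
    elif fam == "frustum":
        r0, r1 = spec.end_radii_mm
        r = r0 + (r1 - r0) * x_arr
        out = math.pi * r**2
    else:  # beta_spindle
        a, b = _beta_exponents(spec)
        xm = spec.peak_location
        out = np.zeros_like(x_arr)
        interior = (x_arr > 0) & (x_arr < 1)
        xi = x_arr[interior]
        out[interior] = spec.peak_acsa_mm2 * np.exp(
            (a - 1) * (np.log(xi) - math.log(xm))
            + (b - 1) * (np.log1p(-xi) - math.log1p(-xm))
        )
        if spec.sharpness == 0:  # degenerates to a constant profile
            out = np.full_like(x_arr, spec.peak_acsa_mm2)
    return out if np.ndim(x) else float(out)


def analytic_volume(spec: PhantomSpec) -> float:
    """Closed-form phantom volume in mm^3 (the ground-truth reference)."""
    A, L = spec.peak_acsa_mm2, spec.length_mm
    fam = spec.shape_family
    if fam == "cylinder":
        return A * L
    if fam == "cone":
        return A * L / 3.0
    if fam == "frustum":
        r0, r1 = spec.end_radii_mm
        return math.pi * L / 3.0 * (r0**2 + r0 * r1 + r1**2)
    a, b = _beta_exponents(spec)
    xm = spec.peak_location
    # integral of the peak-normalized beta kernel over [0, 1]
    log_norm = betaln(a, b) - (a - 1) * math.log(xm) - (b - 1) * math.log1p(-xm)
    return A * L * math.exp(log_norm)


def quadrature_volume(spec: PhantomSpec, rtol: float = 1e-10) -> float:
    """Volume by adaptive quadrature of :func:`analytic_acsa`.

    Independent numerical cross-check of the closed forms in
    :func:`analytic_volume`; used by the test suite, not the pipeline.
    """
    val, _ = integrate.quad(
        lambda x: analytic_acsa(spec, x), 0.0, 1.0, epsrel=rtol, limit=200
    )
    return val * spec.length_mm


def _semi_axes(area: np.ndarray, aspect_ratio: float) -> tuple[np.ndarray, np.ndarray]:
    # ellipse with a/b = aspect_ratio and pi*a*b = area
    a = np.sqrt(area * aspect_ratio / math.pi)
    b = np.sqrt(area / (math.pi * aspect_ratio))
    return a, b


def voxelize(
    spec: PhantomSpec,
    spacing_mm: tuple[float, float, float] = (0.65, 0.65, 2.0),
    distal_end: str = "low_index",
    label: int = 1,
    max_grid_voxels: int = MAX_GRID_VOXELS,
) -> LabelVolume:
    """Rasterize a phantom onto an anisotropic voxel grid.

    A voxel is labelled iff its in-plane center lies inside the elliptical
    cross-section evaluated at the axial coordinate of its slice center
    (center-inclusion, no partial-volume weighting — the behavior of binary
    label maps produced by slice-wise segmentation tools).  The labelled
    volume converges to :func:`analytic_volume` as the spacing shrinks.
    """
    dx, dy, dz = spacing_mm
    if min(dx, dy, dz) <= 0:
        raise ValueError("spacings must be positive")
    L = spec.length_mm
    n_z = int(math.ceil(L / dz - 1e-9))
    z_centers = (np.arange(n_z) + 0.5) * dz
    x_rel = z_centers / L
    if distal_end == "high_index":
        x_rel = 1.0 - x_rel
    valid = (x_rel >= 0.0) & (x_rel <= 1.0)
    areas = np.zeros(n_z)
    areas[valid] = np.atleast_1d(analytic_acsa(spec, x_rel[valid]))

    a_semi, b_semi = _semi_axes(areas, spec.aspect_ratio)
    a_max = float(a_semi.max(initial=0.0))
    b_max = float(b_semi.max(initial=0.0))
    n_x = int(math.ceil(2.0 * (a_max + dx) / dx)) + 1
    n_y = int(math.ceil(2.0 * (b_max + dy) / dy)) + 1
    if n_x * n_y * n_z > max_grid_voxels:
        raise ValueError(
            f"voxel grid {n_x}x{n_y}x{n_z} exceeds max_grid_voxels={max_grid_voxels}"
        )

    xc = (np.arange(n_x) - (n_x - 1) / 2.0) * dx
    yc = (np.arange(n_y) - (n_y - 1) / 2.0) * dy
    X2 = (xc**2)[:, None]
    Y2 = (yc**2)[None, :]

    vox = np.zeros((n_x, n_y, n_z), dtype=np.uint16)
    for k in range(n_z):
        if areas[k] <= 0:
            continue
        ak, bk = a_semi[k], b_semi[k]
        vox[:, :, k] = np.where(X2 / ak**2 + Y2 / bk**2 <= 1.0, label, 0)
    return LabelVolume(vox, (dx, dy, dz), distal_end)


def solve_sharpness_for_shape_factor(p_target: float, peak_location: float) -> float:
    """Solve for the spindle kappa whose analytic shape factor equals p_target."""
    from scipy.optimize import brentq

    def p_of(kappa: float) -> float:
        spec = PhantomSpec.beta_spindle(100.0, 100.0, peak_location, kappa)
        return analytic_volume(spec) / (100.0 * 100.0)

    return brentq(lambda k: p_of(k) - p_target, 1e-6, 50.0)


def generate_cohort(
    cohort: CohortSpec,
    spec_template: PhantomSpec | None = None,
    voxelize_subjects: bool = True,
) -> list[dict]:
    """Draw a cohort of phantoms with per-subject parameter variation.

    Each subject record holds the drawn :class:`PhantomSpec`, the analytic
    ground truth (volume, length, peak ACSA, peak location) and — unless
    ``voxelize_subjects`` is False — the rasterized :class:`LabelVolume`.

    Lengths and peak areas are redrawn while nonpositive (relevant only for
    extreme coefficient-of-variation settings); peak locations come from a
    truncated normal on ``cohort.location_bounds``.
    """
    if spec_template is None:
        spec_template = PhantomSpec.beta_spindle(
            cohort.length_mm[0], cohort.peak_acsa_mm2[0], cohort.peak_location[0]
        )
    rng = np.random.default_rng(cohort.rng_seed)

    def draw_positive(mean: float, sd: float, n: int) -> np.ndarray:
        vals = rng.normal(mean, sd, n)
        for _ in range(100):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = rng.normal(mean, sd, bad.sum())
        return vals

    n = cohort.n_subjects
    lengths = draw_positive(*cohort.length_mm, n)
    areas = draw_positive(*cohort.peak_acsa_mm2, n)
    loc_mean, loc_sd = cohort.peak_location
    lo, hi = cohort.location_bounds
    if loc_sd == 0:
        locations = np.full(n, np.clip(loc_mean, lo, hi))
    else:
        a = (lo - loc_mean) / loc_sd
        b = (hi - loc_mean) / loc_sd
        locations = truncnorm.rvs(a, b, loc=loc_mean, scale=loc_sd, size=n, random_state=rng)

    subjects = []
    for i in range(n):
        spec = replace(
            spec_template,
            length_mm=float(lengths[i]),
            peak_acsa_mm2=float(areas[i]),
            peak_location=float(locations[i]),
        )
        rec = {
            "subject_id": f"S{i:03d}",
            "family": spec.shape_family,
            "spec": spec,
            "length_mm": spec.length_mm,
            "peak_acsa_mm2": spec.peak_acsa_mm2,
            "peak_location": spec.peak_location,
            "analytic_volume_mm3": analytic_volume(spec),
            "seed": cohort.rng_seed,
        }
        if voxelize_subjects:
            rec["volume"] = voxelize(spec, cohort.voxel_spacing_mm)
        subjects.append(rec)
    return subjects
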