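"""Digital phantoms and scan emulation for preclinical CBCT radiomics.

Three generators make every downstream stage testable without any scan data:

* a density-calibrated mouse phantom (soft-tissue body, two lungs, spine) on
  the intensity scale a small-animal irradiator's onboard CBCT reports;
* a texture phantom — a plastic block with four cylindrical inserts (air,
  solid water, PVC, acetal) of distinct intensity statistics;
* a two-arm tumour cohort with spherical lesions whose texture differs
  between arms by a configurable effect size.

Intensities follow an affine density→intensity calibration
(``intensity = CALIBRATION_SLOPE · density``) whose slope places soft tissue
(1.01 g/cm³) at 16,844 scanner units — the scale observed on the emulated
scanner — without modelling any X-ray physics.  Each material carries a
frozen, spatially correlated "texture" field (its intrinsic heterogeneity);
scan noise is added separately per acquisition by :func:`simulate_scan_pair`,
so test–retest pairs share the phantom texture and differ only in noise.

Energy (kV) is emulated purely through the protocol parameters: lower kV
means more noise, a stronger slowly varying bias field and a slightly
different contrast scale.  The bias field is a deterministic function of the
energy label, so it is a *systematic* between-protocol difference (it cancels
within a scan–rescan pair but not across energies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import GridSpec, ROIMask, VoxelImage, make_spherical_mask, sphere_radius

# affine density -> intensity calibration (scanner units per g/cm³);
# chosen so soft tissue (1.01 g/cm³) sits at 16,844 units
CALIBRATION_SLOPE = 16677.227722772277
CALIBRATION_OFFSET = 0.0


def density_to_intensity(density: float) -> float:
    return CALIBRATION_SLOPE * density + CALIBRATION_OFFSET


@dataclass(frozen=True)
class MaterialSpec:
    """A phantom material: density, mean intensity and intrinsic texture.

    ``mean_intensity=None`` derives the mean from the density calibration.
    ``texture_sd`` is the standard deviation of the material's frozen texture
    field (scanner units); ``correlation_length`` (mm) sets its spatial scale
    (0 gives white texture).
    """

    label: str
    density: float
    mean_intensity: float | None = None
    texture_sd: float = 0.0
    correlation_length: float = 0.0

    def __post_init__(self) -> None:
        if self.label != "air" and self.density <= 0:
            raise ValueError(f"density must be > 0 for non-air material {self.label!r}")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        if self.mean_intensity is not None and not math.isfinite(self.mean_intensity):
            raise ValueError("mean_intensity must be finite")

    @property
    def intensity(self) -> float:
        if self.mean_intensity is not None:
            return float(self.mean_intensity)
        return density_to_intensity(self.density)


@dataclass(frozen=True)
class ScanProtocol:
    """Emulated acquisition protocol for one imaging energy.

    Only the statistical consequences of the energy are modelled: acquisition
    noise (white Gaussian, ``noise_sd``), a deterministic slowly varying bias
    field (``bias_amplitude``) and a global contrast scale.
    """

    energy_label: int
    noise_sd: float
    contrast_scale: float = 1.0
    bias_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_label not in (40, 50, 60):
            raise ValueError(f"energy_label must be one of 40/50/60 kV, got {self.energy_label}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.contrast_scale <= 0:
            raise ValueError("contrast_scale must be > 0")


# Preset protocols: 40 kV scans are the noisiest and most artefact-prone,
# 60 kV the cleanest (noise_sd strictly decreasing with energy).
DEFAULT_PROTOCOLS: dict[int, ScanProtocol] = {
    40: ScanProtocol(40, noise_sd=350.0, contrast_scale=0.94, bias_amplitude=250.0),
    50: ScanProtocol(50, noise_sd=250.0, contrast_scale=0.97, bias_amplitude=180.0),
    60: ScanProtocol(60, noise_sd=180.0, contrast_scale=1.00, bias_amplitude=120.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """One arm of a synthetic tumour cohort.

    ``effect_size`` shifts this arm's texture mean away from the baseline
    intensity in units of ``texture_sd`` (0 for the reference arm), giving a
    controlled between-arm separation.
    """

    name: str
    n_subjects: int = 9
    tumour_volume: float = 94.25
    mean_intensity: float = 16500.0
    texture_sd: float = 260.0
    correlation_length: float = 0.5
    effect_size: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.tumour_volume <= 0:
            raise ValueError("tumour_volume must be > 0 mm³")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def effective_mean(self) -> float:
        return self.mean_intensity + self.effect_size * self.texture_sd


# --------------------------------------------------------------------------
# material presets
# --------------------------------------------------------------------------

def mouse_materials(texture_sd: float = 250.0, correlation_length: float = 0.4) -> list[MaterialSpec]:
    """Mouse phantom compartments: soft tissue, lung and bone densities."""
    return [
        MaterialSpec("background", 0.0012, mean_intensity=500.0, texture_sd=60.0,
                     correlation_length=correlation_length),
        MaterialSpec("soft_tissue", 1.01, texture_sd=texture_sd,
                     correlation_length=correlation_length),
        MaterialSpec("lung", 0.68, texture_sd=texture_sd,
                     correlation_length=correlation_length),
        MaterialSpec("bone", 1.39, texture_sd=texture_sd,
                     correlation_length=correlation_length),
    ]


def texture_inserts() -> list[MaterialSpec]:
    """Texture phantom inserts at the measured on-scanner mean intensities."""
    return [
        MaterialSpec("air", 0.0012, mean_intensity=1861.0, texture_sd=60.0, correlation_length=0.8),
        MaterialSpec("solid_water", 1.05, mean_intensity=2940.0, texture_sd=100.0, correlation_length=0.8),
        MaterialSpec("pvc", 1.47, mean_intensity=4138.0, texture_sd=160.0, correlation_length=0.8),
        MaterialSpec("acetal", 1.52, mean_intensity=2917.0, texture_sd=110.0, correlation_length=0.8),
    ]


PERSPEX = MaterialSpec("perspex", 1.19, mean_intensity=2600.0, texture_sd=90.0, correlation_length=0.8)


# --------------------------------------------------------------------------
# correlated noise
# --------------------------------------------------------------------------

def _correlated_field(shape, spacing, correlation_length: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with the given correlation length (mm).

    White noise is smoothed with a Gaussian kernel of sigma = correlation
    length and renormalised to unit variance; periodic boundary handling keeps
    the variance stationary across the grid.
    """
    w = rng.standard_normal(shape)
    if correlation_length <= 0:
        return w
    sigma_vox = [correlation_length / s for s in spacing]
    if max(sigma_vox) < 1e-6:
        return w
    c = gaussian_filter(w, sigma=sigma_vox, mode="wrap")
    # exact normalisation: variance of the smoothed field = sum of squared kernel weights
    impulse = np.zeros(shape)
    impulse[tuple(n // 2 for n in shape)] = 1.0
    k = gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    norm = math.sqrt(float(np.sum(k * k)))
    return c / norm


def _paint_materials(
    labels: np.ndarray,
    materials: list[MaterialSpec],
    grid: GridSpec,
    seed: int,
) -> np.ndarray:
    """Fill each labelled compartment with its material's mean + texture field."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(materials))
    values = np.zeros(labels.shape, dtype=np.float64)
    for code, (mat, child) in enumerate(zip(materials, children)):
        region = labels == code
        if not region.any():
            continue
        rng = np.random.default_rng(child)
        field = mat.intensity
        if mat.texture_sd > 0:
            field = field + mat.texture_sd * _correlated_field(
                labels.shape, grid.spacing, mat.correlation_length, rng
            )
            values[region] = field[region]
        else:
            values[region] = field
    return values


# --------------------------------------------------------------------------
# mouse phantom
# --------------------------------------------------------------------------

MOUSE_LABELS = {"background": 0, "soft_tissue": 1, "lung": 2, "bone": 3}


def _ellipsoid(grid: GridSpec, centre, semi_axes) -> np.ndarray:
    coords = [(grid.axis_coordinates(a) - centre[a]) / semi_axes[a] for a in range(3)]
    return (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    ) <= 1.0


def generate_mouse_phantom(
    grid: GridSpec | None = None,
    materials: list[MaterialSpec] | None = None,
    seed: int = 0,
) -> tuple[VoxelImage, np.ndarray, dict[str, int]]:
    """Generate the digital mouse phantom.

    Geometry is a simple anatomy stand-in: an ellipsoid body of soft tissue,
    two ellipsoid lungs in the cranial third, and a cylindrical spine along
    the dorsal side.  The caudal (abdominal) half of the body is free of lung
    and bone so spherical ROIs can be placed in homogeneous soft tissue.

    Returns (image, label map, legend) where legend maps compartment name to
    integer code.  Deterministic given seed.
    """
    if grid is None:
        grid = GridSpec((64, 64, 64))
    if materials is None:
        materials = mouse_materials()
    names = [m.label for m in materials]
    for need in ("soft_tissue", "lung", "bone"):
        if need not in names:
            raise ValueError(f"materials must include a {need!r} compartment")
    ext = grid.extent
    if min(ext) < 8.0:
        raise ValueError(
            f"grid extent {ext} mm is too small to place the mouse geometry (needs >= 8 mm per axis)"
        )
    c = grid.center
    body_semi = tuple(0.47 * e for e in ext)
    body = _ellipsoid(grid, c, body_semi)

    lung_semi = (0.12 * ext[0], 0.11 * ext[1], 0.11 * ext[2])
    lung_c0 = c[0] - 0.28 * ext[0]
    lungs = _ellipsoid(grid, (lung_c0, c[1] - 0.14 * ext[1], c[2]), lung_semi) | _ellipsoid(
        grid, (lung_c0, c[1] + 0.14 * ext[1], c[2]), lung_semi
    )

    # spine: cylinder along axis 0 offset dorsally (axis 2), clipped to the body
    spine_r = 0.05 * min(ext[1], ext[2])
    y = grid.axis_coordinates(1) - c[1]
    z = grid.axis_coordinates(2) - (c[2] + 0.30 * ext[2])
    spine = (y[:, None] ** 2 + z[None, :] ** 2) <= spine_r**2
    spine = np.broadcast_to(spine[None, :, :], grid.shape) & body

    ordered = [
        materials[names.index("background")],
        materials[names.index("soft_tissue")],
        materials[names.index("lung")],
        materials[names.index("bone")],
    ]
    labels = np.zeros(grid.shape, dtype=np.uint8)
    labels[body] = MOUSE_LABELS["soft_tissue"]
    labels[lungs & body] = MOUSE_LABELS["lung"]
    labels[spine] = MOUSE_LABELS["bone"]
    values = _paint_materials(labels, ordered, grid, seed)
    return VoxelImage(values, grid.spacing, grid.origin), labels, dict(MOUSE_LABELS)


# --------------------------------------------------------------------------
# texture phantom
# --------------------------------------------------------------------------

def generate_texture_phantom(
    grid: GridSpec | None = None,
    inserts: list[MaterialSpec] | None = None,
    seed: int = 0,
    insert_radius: float = 10.0,
) -> tuple[VoxelImage, np.ndarray, dict[str, int]]:
    """Generate the block texture phantom with cylindrical inserts.

    A 60 mm plastic (Perspex) block holds full-length cylinders (default
    radius 10 mm, i.e. 20 mm diameter) along axis 0, arranged on a square in
    the cross-sectional plane.  The default grid samples the block at 0.5 mm
    isotropic; insert intensity statistics follow their MaterialSpec.

    Returns (image, label map, legend); label 0 is outside-block air, 1 the
    block, inserts from 2 up.
    """
    if grid is None:
        grid = GridSpec((120, 120, 120), spacing=(0.5, 0.5, 0.5))
    if inserts is None:
        inserts = texture_inserts()
    if len(inserts) < 2:
        raise ValueError("need at least 2 inserts")
    ext = grid.extent
    c = grid.center
    n = len(inserts)
    # cross-section insert centres on a square around the block centre
    offset = 0.25 * min(ext[1], ext[2])
    corner_offsets = [(-offset, -offset), (-offset, offset), (offset, -offset), (offset, offset)]
    if n > len(corner_offsets):
        raise ValueError(f"at most {len(corner_offsets)} inserts supported, got {n}")
    centres = [(c[1] + dy, c[2] + dz) for dy, dz in corner_offsets[:n]]

    for i in range(n):
        for j in range(i + 1, n):
            d = math.hypot(centres[i][0] - centres[j][0], centres[i][1] - centres[j][1])
            if d < 2 * insert_radius:
                raise ValueError(
                    f"inserts {inserts[i].label!r} and {inserts[j].label!r} overlap "
                    f"(centre distance {d:.1f} mm < diameter {2 * insert_radius:.1f} mm)"
                )
    for (cy, cz), ins in zip(centres, inserts):
        if (
            cy - insert_radius < grid.origin[1]
            or cy + insert_radius > grid.origin[1] + ext[1]
            or cz - insert_radius < grid.origin[2]
            or cz + insert_radius > grid.origin[2] + ext[2]
        ):
            raise ValueError(f"insert {ins.label!r} does not fit inside the block cross-section")

    labels = np.ones(grid.shape, dtype=np.uint8)  # block everywhere
    y = grid.axis_coordinates(1)
    z = grid.axis_coordinates(2)
    legend = {"perspex": 1}
    for idx, ((cy, cz), ins) in enumerate(zip(centres, inserts)):
        code = idx + 2
        disc = ((y[:, None] - cy) ** 2 + (z[None, :] - cz) ** 2) <= insert_radius**2
        labels[np.broadcast_to(disc[None, :, :], grid.shape)] = code
        legend[ins.label] = code
    ordered = [replace(PERSPEX, label="air_outside"), PERSPEX, *inserts]
    values = _paint_materials(labels, ordered, grid, seed)
    return VoxelImage(values, grid.spacing, grid.origin), labels, legend


# --------------------------------------------------------------------------
# scan simulation
# --------------------------------------------------------------------------

def _bias_field(shape, spacing, protocol: ScanProtocol) -> np.ndarray:
    """Slowly varying artefact field, deterministic per energy label."""
    if protocol.bias_amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(protocol.energy_label)
    ext = [n * s for n, s in zip(shape, spacing)]
    field = _correlated_field(shape, spacing, 0.25 * min(ext), rng)
    return protocol.bias_amplitude * field


def simulate_scan(phantom: VoxelImage, protocol: ScanProtocol, seed: int) -> VoxelImage:
    """One emulated acquisition of a phantom under a protocol."""
    rng = np.random.default_rng(seed)
    vals = protocol.contrast_scale * phantom.values + _bias_field(
        phantom.values.shape, phantom.spacing, protocol
    )
    if protocol.noise_sd > 0:
        vals = vals + protocol.noise_sd * rng.standard_normal(phantom.values.shape)
    return phantom.copy_with(vals)


def simulate_scan_pair(
    phantom: VoxelImage,
    protocol: ScanProtocol,
    seeds: tuple[int, int],
) -> tuple[VoxelImage, VoxelImage]:
    """Test–retest pair: two acquisitions sharing geometry and expectation.

    The two scans differ only in the noise realisation (the bias field is a
    systematic property of the protocol, identical within the pair), so the
    voxelwise sd of (scan − rescan)/√2 estimates the protocol noise sd.
    """
    return (
        simulate_scan(phantom, protocol, seeds[0]),
        simulate_scan(phantom, protocol, seeds[1]),
    )


# --------------------------------------------------------------------------
# ROI placement
# --------------------------------------------------------------------------

def sample_roi_centres(
    labels: np.ndarray,
    grid: GridSpec,
    volume_mm3: float,
    n: int,
    seed: int,
    target_label: int = 1,
    max_tries: int = 2000,
    margin: float = 1.0,
) -> list[tuple[float, float, float]]:
    """Seeded rejection sampling of sphere centres lying wholly in one compartment.

    Draws candidate centres uniformly over the compartment's bounding region
    and keeps those whose sphere, inflated by ``margin`` mm, stays inside the
    target label — the margin keeps ROIs clear of compartment edges (and of
    the edge responses wavelet filters smear across boundaries).
    Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    r_check = sphere_radius(volume_mm3) + max(0.0, margin)
    check_volume = 4.0 / 3.0 * math.pi * r_check**3
    region = labels == target_label
    if not region.any():
        raise ValueError(f"no voxels with label {target_label}")
    idx = np.argwhere(region)
    lo = [grid.origin[a] + idx[:, a].min() * grid.spacing[a] for a in range(3)]
    hi = [grid.origin[a] + idx[:, a].max() * grid.spacing[a] for a in range(3)]
    centres: list[tuple[float, float, float]] = []
    tries = 0
    while len(centres) < n and tries < max_tries:
        tries += 1
        cand = tuple(rng.uniform(lo[a] + r_check, hi[a] - r_check) for a in range(3))
        probe = make_spherical_mask(grid, cand, check_volume)
        if np.all(region[probe.values]):
            centres.append(cand)
    if len(centres) < n:
        raise ValueError(
            f"could not place {n} spheres of {volume_mm3} mm³ inside label {target_label} "
            f"after {max_tries} tries (placed {len(centres)})"
        )
    return centres


# --------------------------------------------------------------------------
# tumour cohort
# --------------------------------------------------------------------------

def generate_tumour_cohort(
    specA: CohortSpec,
    specB: CohortSpec,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> list[tuple[VoxelImage, ROIMask, str]]:
    """Generate two synthetic tumour cohorts.

    Each subject is a soft-tissue body (ellipsoid) carrying one spherical
    tumour of the arm's requested volume; the tumour compartment has its own
    texture realisation, with the arm's ``effect_size`` shifting its mean.
    Returns ``n_subjects`` (image, mask, cohort-name) triples per arm,
    arm A first.  Deterministic given seed.
    """
    if grid is None:
        grid = GridSpec((48, 48, 48))
    ext = grid.extent
    c = grid.center
    subjects: list[tuple[VoxelImage, ROIMask, str]] = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(specA.n_subjects + specB.n_subjects)
    child_iter = iter(children)
    for spec in (specA, specB):
        r = sphere_radius(spec.tumour_volume)
        if 2 * r >= 0.8 * min(ext):
            raise ValueError(
                f"tumour of {spec.tumour_volume} mm³ (r={r:.2f} mm) does not fit the grid extent {ext}"
            )
        for i in range(spec.n_subjects):
            child = next(child_iter)
            rng = np.random.default_rng(child)
            jitter = rng.uniform(-0.5, 0.5, size=3)
            centre = tuple(c[a] + jitter[a] for a in range(3))
            mask = make_spherical_mask(grid, centre, spec.tumour_volume)
            body = _ellipsoid(grid, c, tuple(0.47 * e for e in ext))

            sub_ss = np.random.SeedSequence(entropy=child.entropy, spawn_key=child.spawn_key + (1,))
            body_rng, tum_rng = (np.random.default_rng(s) for s in sub_ss.spawn(2))
            vals = np.full(grid.shape, 500.0)
            body_tex = 16844.0 + 250.0 * _correlated_field(grid.shape, grid.spacing, 0.4, body_rng)
            vals[body] = body_tex[body]
            tum_tex = spec.effective_mean + spec.texture_sd * _correlated_field(
                grid.shape, grid.spacing, spec.correlation_length, tum_rng
            )
            vals[mask.values] = tum_tex[mask.values]
            subjects.append((VoxelImage(vals, grid.spacing, grid.origin), mask, spec.name))
    return subjects
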