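"""Synthetic two-slice brain phantom: CEST stacks, DWI, masks, B0 fields.

The phantom places bilateral elliptical regions (substantia nigra on the
lower slice; globus pallidus, putamen and caudate on the upper slice) on a
uniform tissue background.  Every voxel carries a 4-pool Bloch-McConnell
parameter set and a ground-truth diffusion tensor; acquisitions are
synthesized by evaluating the region's simulated Z-spectrum at the scheduled
offsets shifted by the voxel's B0 offset, scaling by ``S0`` and adding
seeded Gaussian noise per acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .bloch import PoolParams, SaturationParams, zspectrum_values
from .schedule import OffsetSchedule
from . import defaults
from .dti import tensor_from_eigs

__all__ = [
    "RegionGeometry",
    "B0FieldSpec",
    "PhantomSpec",
    "PhantomData",
    "generate_phantom",
    "region_zspectrum",
    "generate_dwi",
    "eigenvalues_from_fa_md",
    "default_phantom_spec",
    "REGIONS",
]

#: analysis regions, in label order
REGIONS = ("substantia_nigra", "globus_pallidus", "putamen", "caudate")
HEMISPHERES = ("left", "right")


def label_code(region: str, hemisphere: str) -> int:
    """Integer label for a (region, hemisphere) ROI; background is 0."""
    return 2 * REGIONS.index(region) + HEMISPHERES.index(hemisphere) + 1


def label_table() -> dict[int, tuple[str, str]]:
    return {
        label_code(r, h): (r, h) for r in REGIONS for h in HEMISPHERES
    }


@dataclass(frozen=True)
class RegionGeometry:
    """Bilateral ellipse: center/radii as fractions of the in-plane grid.

    ``center`` is the right-hemisphere ellipse center ``(fx, fy)`` with
    ``fx > 0.5``; the left instance mirrors across the midline.
    """

    center: tuple[float, float]
    radii: tuple[float, float]
    slice_index: int

    def masks(self, shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
        nx, ny, nz = shape
        if not (0 <= self.slice_index < nz):
            raise ValueError("region slice outside image bounds")
        cx, cy = self.center[0] * nx, self.center[1] * ny
        rx, ry = self.radii[0] * nx, self.radii[1] * ny
        if cx + rx >= nx or cy + ry >= ny or cy - ry < 0 or (nx - cx) - rx < 0:
            raise ValueError("region ellipse outside image bounds")
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        out = {}
        for hemi, c in (("right", cx), ("left", nx - 1 - cx)):
            plane = ((xs - c) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
            vol = np.zeros(shape, dtype=bool)
            vol[:, :, self.slice_index] = plane
            out[hemi] = vol
        return out


@dataclass(frozen=True)
class B0FieldSpec:
    """Smooth field-offset map: planar tilt plus a Gaussian bump, ppm.

    ``amplitude`` scales the whole map; 0 disables inhomogeneity.  The map
    magnitude stays below ~1.6x amplitude, so keep ``amplitude`` <= 0.5 ppm
    for the default +-1 ppm correction window.
    """

    amplitude: float = 0.10

    def build(self, shape: tuple[int, int, int]) -> np.ndarray:
        nx, ny, nz = shape
        fx = (np.arange(nx) + 0.5) / nx
        fy = (np.arange(ny) + 0.5) / ny
        fz = (np.arange(nz) + 0.5) / max(nz, 1)
        gx, gy, gz = np.meshgrid(fx, fy, fz, indexing="ij")
        tilt = 0.6 * (gx - 0.5) + 0.4 * (gy - 0.5) + 0.2 * (gz - 0.5)
        bump = np.exp(-(((gx - 0.35) ** 2 + (gy - 0.6) ** 2) / 0.08))
        return self.amplitude * (tilt + bump)


@dataclass
class PhantomSpec:
    """Geometry, tissue parameters and corruption model of the phantom."""

    image_shape: tuple[int, int, int] = (64, 64, 2)
    region_geometries: dict[str, RegionGeometry] = field(default_factory=dict)
    region_pools: dict[str, list[PoolParams]] = field(default_factory=dict)
    background_pools: list[PoolParams] = field(default_factory=list)
    b0_field: B0FieldSpec = field(default_factory=B0FieldSpec)
    noise_sigma: float = 0.005
    #: Gaussian intravoxel static-field dispersion (ppm).  Finite pulse
    #: trains leave coherent ripples in the simulated Z-spectrum that no
    #: voxel-scale measurement retains (through-slice field spread over a
    #: 6 mm slice); the phantom convolves each spectrum with this kernel.
    #: Set to 0 for raw, unbroadened simulator output.
    intravoxel_sigma: float = 0.04
    s0_value: float = 1000.0
    dwi_truth: dict[str, np.ndarray] = field(default_factory=dict)
    background_tensor: np.ndarray | None = None

    def label_mask(self) -> np.ndarray:
        labels = np.zeros(self.image_shape, dtype=np.int16)
        for region, geom in self.region_geometries.items():
            for hemi, m in geom.masks(self.image_shape).items():
                if np.any(labels[m] != 0):
                    raise ValueError(f"region {region}/{hemi} overlaps another region")
                labels[m] = label_code(region, hemi)
        return labels

    def pools_for(self, region: str) -> list[PoolParams]:
        if region == "background":
            return self.background_pools
        return self.region_pools[region]

    def tensor_for(self, region: str) -> np.ndarray:
        if region == "background":
            assert self.background_tensor is not None
            return self.background_tensor
        return self.dwi_truth[region]


@dataclass
class PhantomData:
    """One simulated subject acquisition."""

    stack: np.ndarray          # spatial + (n_acquisitions,)
    unsaturated: np.ndarray    # spatial
    labels: np.ndarray         # int16 spatial
    b0_map: np.ndarray         # ppm, spatial
    schedule: OffsetSchedule


def eigenvalues_from_fa_md(fa: float, md: float) -> tuple[float, float, float]:
    """Axially symmetric eigenvalues ``(md+2d, md-d, md-d)`` with the
    anisotropy parameter ``d`` solved from FA in closed form."""
    if not (0 <= fa < 1):
        raise ValueError("fa must be in [0, 1)")
    d = md * fa * np.sqrt(3.0) / np.sqrt(9.0 - 6.0 * fa * fa)
    return (md + 2 * d, md - d, md - d)


#: principal diffusion axis per region (arbitrary but fixed orientations)
_REGION_AXES = {
    "substantia_nigra": (0.2, 0.3, 1.0),
    "globus_pallidus": (1.0, 0.4, 0.2),
    "putamen": (0.3, 1.0, 0.3),
    "caudate": (0.7, 0.7, 0.2),
    "background": (1.0, 0.0, 0.0),
}


def default_phantom_spec(
    image_shape: tuple[int, int, int] = (64, 64, 2),
    amide_fractions: dict[str, float] | None = None,
    b0_amplitude: float = 0.10,
    noise_sigma: float = 0.005,
) -> PhantomSpec:
    """Phantom with default geometry, pools and ground-truth tensors.

    ``amide_fractions`` maps region (and ``"background"``) to the amide
    proton fraction; when omitted, fractions are calibrated so each region's
    baseline APT-weighted value matches
    :data:`pdcest.defaults.REGION_APT_BASELINE`.
    """
    if amide_fractions is None:
        from .cohort import calibrated_amide_fractions

        amide_fractions = calibrated_amide_fractions()
    geoms = {
        "substantia_nigra": RegionGeometry((0.655, 0.62), (0.055, 0.09), 0),
        "globus_pallidus": RegionGeometry((0.645, 0.47), (0.045, 0.07), 1),
        "putamen": RegionGeometry((0.78, 0.50), (0.05, 0.11), 1),
        "caudate": RegionGeometry((0.60, 0.28), (0.045, 0.075), 1),
    }
    tensors = {}
    for region, (fa, md) in defaults.REGION_FA_MD_BASELINE.items():
        eigs = eigenvalues_from_fa_md(fa, md)
        tensors[region] = tensor_from_eigs(eigs, _REGION_AXES[region])
    return PhantomSpec(
        image_shape=image_shape,
        region_geometries=geoms,
        region_pools={
            r: defaults.make_pools(amide_fractions[r]) for r in REGIONS
        },
        background_pools=defaults.make_pools(amide_fractions["background"]),
        b0_field=B0FieldSpec(b0_amplitude),
        noise_sigma=noise_sigma,
        dwi_truth={r: tensors[r] for r in REGIONS},
        background_tensor=tensors["background"],
    )


_DENSE_STEP = 0.02  # ppm, resolves the finite-train ripple before broadening


def _spectrum_spline(
    pools: list[PoolParams],
    sat: SaturationParams,
    scheduled: np.ndarray,
    b0: np.ndarray,
    sigma: float,
) -> CubicSpline:
    """Spline of the region's (optionally broadened) spectrum on a dense
    grid wide enough to evaluate every scheduled offset shifted by b0."""
    pad = float(np.max(np.abs(b0))) + max(0.2, 5.0 * sigma)
    grid = np.arange(
        scheduled[0] - pad, scheduled[-1] + pad + _DENSE_STEP / 2, _DENSE_STEP
    )
    z = zspectrum_values(pools, sat, grid)
    if sigma > 0:
        half = np.arange(0.0, 4.0 * sigma + _DENSE_STEP / 2, _DENSE_STEP)
        kern = np.exp(-0.5 * (np.concatenate([-half[:0:-1], half]) / sigma) ** 2)
        kern /= kern.sum()
        core = np.convolve(z, kern, mode="valid")
        m = (kern.size - 1) // 2
        grid = grid[m:-m]
        z = core
    return CubicSpline(grid, z)


def region_zspectrum(
    spec: PhantomSpec,
    region: str,
    sat: SaturationParams,
    schedule: OffsetSchedule,
) -> np.ndarray:
    """The noiseless spectrum a zero-B0 voxel of ``region`` carries, at the
    sorted scheduled offsets (includes the spec's intravoxel broadening)."""
    offs = np.array(sorted(schedule.offsets))
    pools = spec.pools_for(region)
    if spec.intravoxel_sigma > 0:
        return _spectrum_spline(
            pools, sat, offs, np.zeros(1), spec.intravoxel_sigma
        )(offs)
    return zspectrum_values(pools, sat, offs)


def _region_map(spec: PhantomSpec) -> tuple[np.ndarray, list[str]]:
    """Per-voxel region index into ``names`` (background last)."""
    labels = spec.label_mask()
    names = [r for r in spec.region_geometries] + ["background"]
    idx = np.full(spec.image_shape, len(names) - 1, dtype=np.int8)
    table = label_table()
    for code, (region, _hemi) in table.items():
        if region in spec.region_geometries:
            idx[labels == code] = names.index(region)
    return idx, names


def generate_phantom(
    spec: PhantomSpec,
    sat: SaturationParams,
    schedule: OffsetSchedule,
    seed: int,
) -> PhantomData:
    """Simulate the saturation stack, unsaturated image, masks and B0 map.

    Each voxel's spectrum is its region's Bloch-McConnell spectrum evaluated
    at ``offset - b0`` (the voxel resonates at its local field offset),
    scaled by ``S0``; each repeated acquisition receives independent
    Gaussian noise of ``noise_sigma * S0``.  Voxels with exactly zero B0 use
    the exact simulated value at the scheduled offsets; shifted voxels are
    evaluated with a cubic spline of the spectrum on a dense offset grid.
    Identical seeds give identical arrays.
    """
    rng = np.random.default_rng(seed)
    labels = spec.label_mask()
    region_idx, names = _region_map(spec)
    b0 = spec.b0_field.build(spec.image_shape)

    sorted_offsets = np.array(sorted(schedule.offsets))
    need_dense = bool(np.any(b0 != 0)) or spec.intravoxel_sigma > 0

    # per-region spectra: exact at the scheduled offsets when no corruption
    # applies, otherwise a spline of the (broadened) dense-grid spectrum
    exact: list[np.ndarray] = []
    splines: list[CubicSpline | None] = []
    for name in names:
        pools = spec.pools_for(name)
        if need_dense:
            splines.append(
                _spectrum_spline(pools, sat, sorted_offsets, b0, spec.intravoxel_sigma)
            )
            exact.append(splines[-1](sorted_offsets))
        else:
            splines.append(None)
            exact.append(zspectrum_values(pools, sat, sorted_offsets))

    # noiseless normalized spectra per voxel, indexed by sorted offset
    zvox = np.empty(spec.image_shape + (sorted_offsets.size,))
    for i in range(len(names)):
        in_region = region_idx == i
        if not in_region.any():
            continue
        zero_b0 = in_region & (b0 == 0)
        zvox[zero_b0] = exact[i]
        shifted = in_region & (b0 != 0)
        if shifted.any():
            eval_at = sorted_offsets[None, :] - b0[shifted][:, None]
            zvox[shifted] = splines[i](eval_at)

    acq_offsets = np.array(schedule.acquisition_offsets())
    col = np.searchsorted(sorted_offsets, acq_offsets)
    stack = zvox[..., col] * spec.s0_value
    if spec.noise_sigma > 0:
        stack = stack + rng.normal(
            0.0, spec.noise_sigma * spec.s0_value, size=stack.shape
        )
    unsat = np.full(spec.image_shape, spec.s0_value)
    return PhantomData(stack, unsat, labels, b0, schedule)


def generate_dwi(
    spec: PhantomSpec,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    snr: float,
    seed: int,
) -> np.ndarray:
    """Single-tensor DWI volumes ``S0 * exp(-b g^T D g)`` plus seeded noise.

    Ground-truth tensors are taken per region (1e-3 mm^2/s); ``snr`` is the
    b=0 signal-to-noise ratio (``numpy.inf`` for noiseless data).  Returns
    volumes of shape ``spatial + (n_volumes,)``.
    """
    from .dti import DwiScheme, _tensor_matrix

    scheme = DwiScheme(bvals, bvecs)
    rng = np.random.default_rng(seed)
    region_idx, names = _region_map(spec)
    b, g = scheme.bvals, scheme.bvecs
    sig_per_region = []
    for name in names:
        d6 = np.asarray(spec.tensor_for(name), dtype=float)
        dm = _tensor_matrix(d6) * 1e-3  # back to mm^2/s
        if np.min(np.linalg.eigvalsh(dm)) <= 0:
            raise ValueError(f"ground-truth tensor for {name!r} is not positive definite")
        adc = np.einsum("ni,ij,nj->n", g, dm, g)
        sig_per_region.append(spec.s0_value * np.exp(-b * adc))
    sig = np.stack(sig_per_region)[region_idx]
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        sig = sig + rng.normal(0.0, spec.s0_value / snr, size=sig.shape)
    return sig


def default_dwi_scheme(n_directions: int = 31) -> tuple[np.ndarray, np.ndarray]:
    """1 b=0 volume plus ``n_directions`` roughly uniform unit directions at
    b = 1000 s/mm^2 (deterministic Fibonacci-sphere construction)."""
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (i + 0.5) * 2.0 / n_directions
    r = np.sqrt(1.0 - z * z)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    bvals = np.concatenate([[0.0], np.full(n_directions, 1000.0)])
    return bvals, bvecs
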