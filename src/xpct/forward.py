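"""Propagation-based phase-contrast projection simulation.

The forward model follows the projection approximation: a monochromatic
plane wave crossing the object acquires phase ``phi = -(2*pi/lambda) * int(delta dl)``
and log-amplitude ``B = (2*pi/lambda) * int(beta dl)`` along each ray, giving a
complex transmission ``exp(-B + i*phi)``.  Free-space propagation to the
detector is computed with the Fresnel transfer function
``H(u, v) = exp(-i*pi*lambda*D*(u^2 + v^2))`` (paraxial angular spectrum,
spatial frequencies in cycles per metre), and the detector records
``|field|^2`` times the flat field (modelled as unity) with optional Poisson
photon noise.

Cone-beam (nano) acquisition is mapped to an equivalent parallel geometry by
the Fresnel scaling theorem: magnification ``M = (z1 + z2)/z1``, effective
pixel ``p_det/M`` and effective distance ``D = z1*z2/(z1 + z2)``.

Line integrals are computed by rotating the volume about the z axis
(order-1 spline) and summing; a direct ray-marching oracle lives in the test
suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

HC_KEV_M = 1.23984193e-9  # h*c, keV * m


def wavelength_m(energy_kev: float) -> float:
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_M / energy_kev


@dataclass(frozen=True)
class Geometry:
    """Acquisition geometry for parallel (micro) or cone (nano) mode.

    Distances in metres, pixel sizes in µm.  ``axis_offset_px`` is the
    lateral rotation-axis offset from the detector-frame centre (columns,
    positive rightward); a non-zero offset together with a 360° angle list is
    the half-acquisition (extended field of view) scheme.
    """

    energy_kev: float = 30.0
    mode: str = "parallel"
    distance_m: float = 2.3
    pixel_size_um: float = 3.5
    z1_m: Optional[float] = None
    z2_m: Optional[float] = None
    n_angles: int = 2000
    angular_range_deg: float = 360.0
    axis_offset_px: float = 0.0
    detector_width: Optional[int] = None
    photon_count: float = 5e3

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "cone"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cone":
            if self.z1_m is None or self.z2_m is None:
                raise ValueError("cone mode requires z1 and z2")
            if self.z1_m <= 0 or self.z2_m <= 0:
                raise ValueError("distances must be positive")
        elif self.distance_m < 0:
            raise ValueError("propagation distance must be non-negative")

    # -- derived quantities -------------------------------------------------
    @property
    def wavelength_m(self) -> float:
        return wavelength_m(self.energy_kev)

    @property
    def magnification(self) -> float:
        if self.mode != "cone":
            return 1.0
        return (self.z1_m + self.z2_m) / self.z1_m

    @property
    def effective_distance_m(self) -> float:
        if self.mode != "cone":
            return self.distance_m
        return self.z1_m * self.z2_m / (self.z1_m + self.z2_m)

    @property
    def effective_pixel_um(self) -> float:
        return self.pixel_size_um / self.magnification

    @property
    def angles_deg(self) -> np.ndarray:
        return np.linspace(0.0, self.angular_range_deg, self.n_angles, endpoint=False)

    # -- presets ------------------------------------------------------------
    @classmethod
    def micro_default(cls, n_angles: int = 2000, **kw) -> "Geometry":
        """Parallel 30 keV scan, 2.3 m propagation, 3.5 µm pixel, 360°."""
        return cls(energy_kev=30.0, mode="parallel", distance_m=2.3,
                   pixel_size_um=3.5, n_angles=n_angles, **kw)

    @classmethod
    def nano_default(cls, n_angles: int = 1500, z_total_m: float = 1.2, **kw) -> "Geometry":
        """Cone-beam 17 keV holotomography: 3 µm detector pixel demagnified
        23.08x to a 130 nm effective pixel."""
        M = 3.0 / 0.13
        z1 = z_total_m / M
        return cls(energy_kev=17.0, mode="cone", z1_m=z1, z2_m=z_total_m - z1,
                   pixel_size_um=3.0, n_angles=n_angles, **kw)

    def multi_distances(self, n: int = 4, spacing: float = 1.35) -> list[float]:
        """Effective propagation distances of a holotomography series
        (geometric spacing starting at the base effective distance)."""
        d0 = self.effective_distance_m
        return [d0 * spacing**k for k in range(n)]


@dataclass
class ProjectionSet:
    """Stack of flat-normalized detector frames.

    ``frames`` has shape (n_distances, n_angles, rows, cols); ``distances_m``
    are effective (parallel-equivalent) propagation distances.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    distances_m: np.ndarray
    geometry: Geometry
    noise_seed: Optional[int] = None
    axis_col: Optional[float] = None  # rotation-axis column in the frame

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("frames must be (n_dist, n_angles, rows, cols)")

    def single_distance(self, i: int = 0) -> np.ndarray:
        return self.frames[i]


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def project_transmission(delta: np.ndarray, beta: np.ndarray, angle_deg: float,
                         geometry: Geometry, voxel_size_um: float) -> np.ndarray:
    """Complex transmission exp(-B + i*phi) of the object viewed at one angle.

    The volume (z, y, x) is rotated about z and summed along y, i.e. the
    beam travels along +y at angle 0; detector rows = z, columns = x.
    """
    if delta.shape != beta.shape:
        raise ValueError("delta and beta grids must be co-registered")
    k = 2 * np.pi / geometry.wavelength_m
    dl = voxel_size_um * 1e-6
    proj_d = _rotate_project(delta, angle_deg) * dl
    proj_b = _rotate_project(beta, angle_deg) * dl
    phi = -k * proj_d
    B = k * proj_b
    return np.exp(-B + 1j * phi)


def _rotate_project(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    if angle_deg % 360.0 == 0.0:
        rot = vol
    else:
        rot = ndimage.rotate(vol, -angle_deg, axes=(1, 2), reshape=False,
                             order=1, mode="constant", cval=0.0, prefilter=False)
    return rot.sum(axis=1)


def fresnel_propagate(transmission: np.ndarray, distance_m: float,
                      wavelength_m: float, pixel_size_um: float) -> np.ndarray:
    """Free-space Fresnel propagation; returns the detector intensity.

    Frames are reflect-padded to at least twice their size before the FFT to
    suppress wrap-around, and cropped back afterwards.  D = 0 returns
    |transmission|^2 exactly.
    """
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    t = np.asarray(transmission, dtype=complex)
    if distance_m == 0.0:
        return np.abs(t) ** 2
    p = pixel_size_um * 1e-6
    fresnel_number = p * p / (wavelength_m * distance_m)
    if fresnel_number < 0.1:
        warnings.warn(
            f"per-pixel Fresnel number {fresnel_number:.3g} < 0.1: severe "
            "fringing, the propagated field may be undersampled", stacklevel=2)
    pads = [(_pad_for(n), _pad_for(n)) for n in t.shape[-2:]]
    tp = np.pad(t, [(0, 0)] * (t.ndim - 2) + pads, mode="reflect")
    u = np.fft.fftfreq(tp.shape[-2], d=p)
    v = np.fft.fftfreq(tp.shape[-1], d=p)
    chirp = np.exp(-1j * np.pi * wavelength_m * distance_m *
                   (u[:, None] ** 2 + v[None, :] ** 2))
    out = np.fft.ifft2(np.fft.fft2(tp, axes=(-2, -1)) * chirp, axes=(-2, -1))
    sl = tuple([slice(None)] * (t.ndim - 2) +
               [slice(pads[0][0], pads[0][0] + t.shape[-2]),
                slice(pads[1][0], pads[1][0] + t.shape[-1])])
    return np.abs(out[sl]) ** 2


def _pad_for(n: int) -> int:
    return (n + 1) // 2


def acquire_scan(delta: np.ndarray, beta: np.ndarray, geometry: Geometry,
                 voxel_size_um: Optional[float] = None,
                 distances_m: Optional[Sequence[float]] = None,
                 seed: Optional[int] = None) -> ProjectionSet:
    """Simulate a full tomographic scan.

    For every angle: project -> Fresnel-propagate (per distance) -> flat
    field (unity) -> Poisson noise at ``geometry.photon_count`` photons per
    pixel (noiseless if 0).  In cone mode the simulation runs in the
    Fresnel-scaled parallel frame: the voxel size must equal the effective
    pixel.  With ``detector_width`` set, frames are cropped to a window
    placed so the rotation axis sits at ``axis_offset_px`` columns from the
    window centre (half-acquisition when the offset is large and the scan
    covers 360°).
    """
    if voxel_size_um is None:
        voxel_size_um = geometry.effective_pixel_um
    if abs(voxel_size_um - geometry.effective_pixel_um) > 1e-9 * voxel_size_um:
        raise ValueError("voxel size must match the (effective) detector pixel")
    if distances_m is None:
        distances_m = [geometry.effective_distance_m]
    distances_m = list(distances_m)
    lam = geometry.wavelength_m
    pix = geometry.effective_pixel_um
    angles = geometry.angles_deg
    nz, _, nx = delta.shape
    axis_full = (nx - 1) / 2.0

    if geometry.detector_width is not None:
        W = int(geometry.detector_width)
        axis_col = (W - 1) / 2.0 + geometry.axis_offset_px
        start = axis_full - axis_col
        s0 = int(np.floor(start))
        if s0 != start:
            raise ValueError("axis offset must align the window on whole pixels")
        if s0 < 0 or s0 + W > nx:
            raise ValueError("object extends beyond the extended field of view")
    else:
        W = nx
        s0 = 0
        axis_col = axis_full

    rng = np.random.default_rng(seed)
    frames = np.empty((len(distances_m), len(angles), nz, W))
    for ia, ang in enumerate(angles):
        trans = project_transmission(delta, beta, float(ang), geometry, voxel_size_um)
        for idd, D in enumerate(distances_m):
            I = fresnel_propagate(trans, D, lam, pix)
            frames[idd, ia] = I[:, s0:s0 + W]
    if geometry.photon_count > 0:
        frames = rng.poisson(frames * geometry.photon_count) / geometry.photon_count
    return ProjectionSet(frames=frames, angles_deg=angles,
                         distances_m=np.asarray(distances_m), geometry=geometry,
                         noise_seed=seed, axis_col=axis_col)
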