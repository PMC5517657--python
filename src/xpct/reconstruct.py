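"""Sinogram assembly and filtered back projection.

Half-acquisition (extended field of view) scans rotate over 360° with the
rotation axis offset toward one detector edge; each projection at angle
``theta`` and its mirrored partner at ``theta + 180°`` are stitched into a
double-width projection with the axis exactly centred, halving the angular
range to [0°, 180°).  Stitching resamples both halves onto the common grid
(order-1) and blends them with a linear (optionally cosine) ramp across the
overlap band.

Reconstruction is slice-wise parallel-beam filtered back projection: ramp
(Ram-Lak) filtering in the frequency domain with optional Hann apodization,
then linear-interpolation back projection.  The result is in arbitrary units
proportional to the quantity whose line integrals the sinogram holds
(electron density / refractive-index decrement for retrieved phase maps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .forward import ProjectionSet


@dataclass
class Sinogram:
    """Stack of per-slice sinograms: data is (n_angles, rows, cols); the
    rotation axis sits at ``axis_col`` (sub-pixel, columns)."""

    data: np.ndarray
    angles_deg: np.ndarray
    axis_col: float
    angular_range: str = "180"

    def slice_sinogram(self, i: int) -> np.ndarray:
        return self.data[:, i, :]


@dataclass
class ReconVolume:
    """Reconstructed 3D grid (a.u., proportional to electron density)."""

    data: np.ndarray
    voxel_size_um: float
    provenance: dict = field(default_factory=dict)


def resolution_estimate(pixel_size: float) -> float:
    """Spatial resolution rule of thumb for this imaging chain: twice the
    pixel size, in the units of the argument."""
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    return 2.0 * pixel_size


def sinogram_from_stack(stack: np.ndarray, angles_deg: np.ndarray,
                        axis_col: Optional[float] = None) -> Sinogram:
    """Wrap a [0°, 180°) projection stack (n_angles, rows, cols) directly."""
    stack = np.asarray(stack)
    if axis_col is None:
        axis_col = (stack.shape[-1] - 1) / 2.0
    return Sinogram(stack, np.asarray(angles_deg), float(axis_col))


def stitch_half_acquisition(stack: np.ndarray, angles_deg: np.ndarray,
                            axis_col: float, blend: str = "linear") -> Sinogram:
    """Merge a 360° offset-axis stack into a 180°-equivalent sinogram.

    ``stack`` is (n_angles, rows, cols) with angles uniformly covering
    [0°, 360°); ``axis_col`` is the rotation-axis column (sub-pixel) in the
    frame.  For each angle pair (theta, theta+180°) the mirrored partner is
    aligned on the axis and both are resampled onto a grid whose centre is
    the axis, blended across the overlap.
    """
    stack = np.asarray(stack, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    n = stack.shape[0]
    if n % 2:
        raise ValueError("half-acquisition stitching needs an even number of angles")
    W = stack.shape[-1]
    if not 0 <= axis_col <= W - 1:
        raise ValueError("rotation axis must lie within the frame")
    overlap = 2.0 * min(axis_col, W - 1 - axis_col) + 1.0
    if overlap < 4:
        raise ValueError(f"overlap band of {overlap:.1f} columns (< 4) makes "
                         "the stitch unreliable")
    half = n // 2
    if not np.allclose((angles[half:] - angles[:half]) % 360.0, 180.0, atol=1e-6):
        raise ValueError("angles must come in (theta, theta+180) pairs")
    # output grid on frame A's sample lattice so that no interpolation is
    # needed for A (and none for B either when 2*axis_col is whole)
    m = max(axis_col, W - 1 - axis_col)
    k_lo = int(np.ceil(axis_col - m))
    k_hi = int(np.floor(axis_col + m))
    g = np.arange(k_lo, k_hi + 1) - axis_col  # positions relative to the axis
    pos_a = g + axis_col            # sample positions in frame A (integers)
    pos_b = g + (W - 1 - axis_col)  # sample positions in mirrored frame B
    va = (pos_a >= 0) & (pos_a <= W - 1)
    vb = (pos_b >= 0) & (pos_b <= W - 1)
    both = va & vb
    wa = np.where(va, 1.0, 0.0)
    if np.any(both):
        glo, ghi = g[both][0], g[both][-1]
        span = max(ghi - glo, 1e-9)
        ramp = (ghi - g[both]) / span
        if blend == "cosine":
            ramp = 0.5 * (1.0 - np.cos(np.pi * ramp))
        elif blend != "linear":
            raise ValueError(f"unknown blend {blend!r}")
        wa[both] = ramp
    wb = np.where(vb, 1.0 - wa, 0.0)
    wa = np.where(va, wa, 0.0)
    norm = wa + wb
    norm[norm == 0] = 1.0

    A = stack[:half]
    B = stack[half:][:, :, ::-1]
    out = np.empty((half, stack.shape[1], len(g)))
    for i in range(half):
        fa = _interp_cols(A[i], pos_a)
        fb = _interp_cols(B[i], pos_b)
        out[i] = (fa * wa + fb * wb) / norm
    return Sinogram(out, angles[:half], float(-g[0]))


def _interp_cols(frame: np.ndarray, pos: np.ndarray) -> np.ndarray:
    W = frame.shape[-1]
    idx = np.clip(pos, 0, W - 1)
    i0 = np.minimum(np.floor(idx).astype(int), W - 2)
    frac = idx - i0
    return frame[:, i0] * (1 - frac) + frame[:, i0 + 1] * frac


def sinogram_from_projections(pset: ProjectionSet, stack: Optional[np.ndarray] = None
                              ) -> Sinogram:
    """Build the reconstruction sinogram from an acquired scan (or from a
    retrieved phase-map stack sharing its angles/axis): stitched if the scan
    covers 360°, direct otherwise."""
    data = pset.single_distance(0) if stack is None else np.asarray(stack)
    angles = pset.angles_deg
    span = angles.max() - angles.min() + (angles[1] - angles[0] if len(angles) > 1 else 0)
    if span > 270.0:
        return stitch_half_acquisition(data, angles, pset.axis_col)
    return sinogram_from_stack(data, angles, pset.axis_col)


# --------------------------------------------------------------------------
# filtered back projection
# --------------------------------------------------------------------------

def _ramp_filter(width: int, apodization: Optional[str], cutoff: float) -> np.ndarray:
    # discrete ramp from its real-space kernel (Ram-Lak): unlike a plain |f|
    # profile this carries the correct DC term and avoids cupping
    n = np.concatenate((np.arange(1, width // 2 + 1, 2),
                        np.arange(width // 2 - 1, 0, -2)))
    kernel = np.zeros(width)
    kernel[0] = 0.25
    kernel[1::2] = -1.0 / (np.pi * n) ** 2
    filt = 2.0 * np.real(np.fft.rfft(kernel))
    f = np.fft.rfftfreq(width)
    if apodization is None or apodization == "none":
        return filt
    if apodization == "hann":
        fc = cutoff * 0.5
        win = np.where(np.abs(f) <= fc, 0.5 * (1 + np.cos(np.pi * f / fc)), 0.0)
        return filt * win
    raise ValueError(f"unknown apodization {apodization!r}")


def fbp_reconstruct(sino: Sinogram, filter_name: str = "ram-lak",
                    apodization: Optional[str] = "hann", cutoff: float = 0.9,
                    output_size: Optional[int] = None,
                    voxel_size_um: float = 1.0,
                    ring_correction=None) -> ReconVolume:
    """Slice-wise filtered back projection of a [0°, 180°) sinogram stack.

    ``ring_correction`` is an optional hook ``f(sinogram_data) -> data``
    applied before filtering.  Output voxels are ``output_size`` squared per
    slice (default: stitched width), centred on the rotation axis.
    """
    data = np.asarray(sino.data, dtype=float)
    angles = np.deg2rad(np.asarray(sino.angles_deg, dtype=float))
    n_ang, n_rows, W = data.shape
    if n_ang < 8:
        warnings.warn(f"only {n_ang} angles: expect severe streaking", stacklevel=2)
    if ring_correction is not None:
        data = np.asarray(ring_correction(data))
    N = int(output_size) if output_size else W
    if filter_name not in ("ram-lak", "ramp"):
        raise ValueError(f"unknown filter {filter_name!r}")

    pad = max(64, int(2 ** np.ceil(np.log2(2 * W))))
    filt = _ramp_filter(pad, apodization, cutoff)
    F = np.fft.rfft(data, n=pad, axis=-1) * filt
    fdata = np.fft.irfft(F, n=pad, axis=-1)[..., :W]

    # back projection on a grid centred on the rotation axis
    c = np.arange(N) - (N - 1) / 2.0
    X, Y = np.meshgrid(c, c, indexing="xy")  # X = column, Y = row
    recon = np.zeros((n_rows, N, N))
    cols = np.arange(W, dtype=float)
    for ia, th in enumerate(angles):
        t = X * np.cos(th) - Y * np.sin(th) + sino.axis_col
        i0 = np.clip(np.floor(t).astype(int), 0, W - 2)
        frac = np.clip(t - i0, 0.0, 1.0)
        inside = (t >= 0) & (t <= W - 1)
        sl = fdata[ia]  # (n_rows, W)
        vals = sl[:, i0.ravel()] * (1 - frac.ravel()) + sl[:, i0.ravel() + 1] * frac.ravel()
        vals *= inside.ravel()
        recon += vals.reshape(n_rows, N, N)
    recon *= np.pi / (2.0 * len(angles))
    if voxel_size_um != 1.0:
        recon /= voxel_size_um
    return ReconVolume(recon, voxel_size_um,
                       provenance=dict(filter=filter_name, apodization=apodization,
                                       cutoff=cutoff, n_angles=n_ang,
                                       axis_col=sino.axis_col))
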