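"""Phase retrieval from propagation-based intensity frames.

Two retrieval regimes:

* ``paganin_retrieve`` — single-distance retrieval for a homogeneous object
  (fixed delta/beta): a low-pass Fourier filter
  ``1 / (1 + pi*lambda*D*(delta/beta)*q^2)`` applied to the flat-normalized
  intensity, followed by ``T = -ln(.)/mu`` with ``mu = 4*pi*beta/lambda``,
  yielding the projected thickness.  This is the standard single-distance
  (TIE, near-field) filter used for micro-mode tomography.
* ``ctf_retrieve`` — linearized contrast-transfer-function inversion across
  several propagation distances (holotomography):
  ``I_D(q) = delta_Dirac + 2 sin(chi) phi(q) - 2 cos(chi) B(q)`` with
  ``chi = pi*lambda*D*q^2``, solved in least squares with Tikhonov
  regularization at the transfer-function zeros.  Pure-phase inversion is
  the default; the coupled phase+absorption solve sits behind a flag.

All retrievals act on the trailing two axes, so stacks of frames are
processed in one vectorized call; angle order is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PhaseMap:
    """Retrieved projections: thickness (µm) or phase (radians) per angle."""

    data: np.ndarray  # (..., rows, cols)
    kind: str  # "thickness_um" | "phase_rad"
    method: str
    params: dict

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("retrieved map contains non-finite values")


def _freq_sq(shape, pixel_m):
    u = np.fft.fftfreq(shape[-2], d=pixel_m)
    v = np.fft.rfftfreq(shape[-1], d=pixel_m)
    return u[:, None] ** 2 + v[None, :] ** 2


def _pad_reflect(frames: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Reflect-pad the trailing two axes to twice their size: the retrieval
    filters have long spatial tails, so the result must not depend on the
    detector window edge."""
    pads = [((n + 1) // 2, (n + 1) // 2) for n in frames.shape[-2:]]
    padded = np.pad(frames, [(0, 0)] * (frames.ndim - 2) + pads, mode="reflect")
    sl = tuple([slice(None)] * (frames.ndim - 2) +
               [slice(p0, p0 + n) for (p0, _), n in zip(pads, frames.shape[-2:])])
    return padded, sl


def paganin_retrieve(frames: np.ndarray, distance_m: float, wavelength_m: float,
                     pixel_size_um: float, delta_beta: float,
                     beta: Optional[float] = None, clip_eps: float = 1e-6) -> PhaseMap:
    """Single-distance homogeneous-object phase retrieval.

    Returns projected thickness in µm if ``beta`` is given (through
    ``mu = 4*pi*beta/lambda``), otherwise the dimensionless attenuation map
    ``mu*T``.  At D = 0 the filter is unity and the result reduces to a pure
    absorption inversion ``T = -ln(I)/mu``.  Non-positive filtered
    intensities are clipped at ``clip_eps`` (count logged).
    """
    if delta_beta <= 0:
        raise ValueError("delta/beta must be positive")
    frames = np.asarray(frames, dtype=float)
    p = pixel_size_um * 1e-6
    padded, crop = _pad_reflect(frames)
    q2 = _freq_sq(padded.shape, p)
    denom = 1.0 + np.pi * wavelength_m * distance_m * delta_beta * q2
    filt = np.fft.irfft2(np.fft.rfft2(padded, axes=(-2, -1)) / denom,
                         axes=(-2, -1), s=padded.shape[-2:])[crop]
    n_clip = int(np.count_nonzero(filt <= 0))
    if n_clip:
        logger.warning("paganin_retrieve: clipped %d non-positive pixels", n_clip)
        filt = np.clip(filt, clip_eps, None)
    mu_t = -np.log(filt)
    params = dict(distance_m=distance_m, wavelength_m=wavelength_m,
                  pixel_size_um=pixel_size_um, delta_beta=delta_beta,
                  clipped=n_clip)
    if beta is None:
        return PhaseMap(mu_t, "mu_thickness", "paganin", params)
    mu = 4 * np.pi * beta / wavelength_m  # 1/m
    params["beta"] = beta
    return PhaseMap(mu_t / mu * 1e6, "thickness_um", "paganin", params)


def ctf_retrieve(frames: np.ndarray, distances_m: Sequence[float],
                 wavelength_m: float, pixel_size_um: float,
                 reg_eps: float = 1e-3, with_absorption: bool = False) -> PhaseMap:
    """Multi-distance linearized CTF phase retrieval (weak object).

    ``frames`` has shape (n_distances, ..., rows, cols).  ``reg_eps`` is
    relative to the maximum of the normal-equation diagonal.
    """
    frames = np.asarray(frames, dtype=float)
    distances = np.asarray(list(distances_m), dtype=float)
    if frames.shape[0] != distances.size:
        raise ValueError("first axis of frames must index the distances")
    if len(set(np.round(distances, 12))) != distances.size:
        raise ValueError("propagation distances must be distinct")
    if distances.size == 1 and reg_eps <= 0:
        raise ValueError("single-distance CTF inversion requires regularization "
                         "(reg_eps > 0): the transfer function has zeros")
    p = pixel_size_um * 1e-6
    padded, crop = _pad_reflect(frames - 1.0)
    q2 = _freq_sq(padded.shape, p)
    F = np.fft.rfft2(padded, axes=(-2, -1))
    extra = frames.ndim - 3  # axes between distance axis and rows/cols
    bshape = (distances.size,) + (1,) * extra + q2.shape
    chi = (np.pi * wavelength_m * distances).reshape((-1,) + (1,) * (len(bshape) - 1)) \
        * q2.reshape((1,) * (extra + 1) + q2.shape)
    sin, cos = np.sin(chi), np.cos(chi)
    if not with_absorption:
        num = np.sum(sin * F, axis=0)
        den = 2.0 * np.sum(sin * sin, axis=0)
        phi_hat = num / (den + reg_eps * max(float(den.max()), 1e-30))
    else:
        # least squares in (phi, B): minimize sum_d |F_d - 2 sin chi phi + 2 cos chi B|^2
        a = np.sum(sin * sin, axis=0)
        b = np.sum(sin * cos, axis=0)
        c = np.sum(cos * cos, axis=0)
        det = a * c - b * b
        reg = reg_eps * max(float(det.max()), 1e-30)
        rhs_s = np.sum(sin * F, axis=0)
        rhs_c = np.sum(cos * F, axis=0)
        phi_hat = (c * rhs_s - b * rhs_c) / (2.0 * (det + reg))
    phi = np.fft.irfft2(phi_hat, axes=(-2, -1), s=padded.shape[-2:])[crop[1:]]
    return PhaseMap(phi, "phase_rad", "ctf",
                    dict(distances_m=list(distances), wavelength_m=wavelength_m,
                         pixel_size_um=pixel_size_um, reg_eps=reg_eps,
                         with_absorption=with_absorption))
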