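"""Depth-resolved birefringence from Jones-matrix OCT volumes.

The processing chain mirrors fiber-tissue PS-OCT practice: complex Jones
matrices are moving-averaged (with global-phase alignment) to suppress
speckle, local round-trip matrices are formed from depth pairs at a fixed
pixel separation, their Lu-Chipman retardance is converted to birefringence

    dn = R * lambda0 / (4 pi dz),

a Monte-Carlo bias table corrects the noise-floor bias of the retardance
estimator, and pixels are screened by effective SNR and by the degree of
optic axis uniformity (DOAU) before the volume mean is taken.

Axes convention: volumes are indexed (z, x, y) = (depth, lateral within a
B-scan, frame); depth index 0 is the tissue surface, kernels are 2D within
a B-scan and centred with edge truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .jones import (
    jones_to_mueller,
    lu_chipman_retardance_stack,
    make_linear_retarder,
    fast_axis_stokes_stack,
)

__all__ = [
    "JonesVolume",
    "ScalarMap",
    "PipelineConfig",
    "BiasTable",
    "MaskError",
    "moving_average_jones",
    "local_jones",
    "effective_snr",
    "local_birefringence",
    "build_bias_table",
    "apply_bias_correction",
    "doau_map",
    "mean_birefringence",
    "process_volume",
]


class MaskError(ValueError):
    """Raised when a masking step leaves no valid pixel; carries the
    per-filter survivor counts in ``.counts``."""

    def __init__(self, message, counts=None):
        super().__init__(message)
        self.counts = counts or {}


@dataclass
class JonesVolume:
    """A volume of per-voxel 2x2 complex Jones matrices plus acquisition
    metadata.

    ``data`` is shaped (z, x, y, 2, 2).  ``noise_floor`` is the per-channel
    additive noise variance in linear intensity units (scalar; the four
    detection channels are assumed balanced).  ``valid`` marks voxels whose
    matrix is usable (None means all valid).
    """

    data: np.ndarray
    wavelength_m: float = 1.31e-6
    axial_pitch_m: float = 6.125e-6
    lateral_pitch_m: float = 6.0e-6
    noise_floor: float = 1e-12
    valid: Optional[np.ndarray] = None
    separation_pixels: Optional[int] = None  # set on local volumes

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 5 or self.data.shape[-2:] != (2, 2):
            raise ValueError("data must be shaped (z, x, y, 2, 2)")
        if not (self.wavelength_m > 0 and self.axial_pitch_m > 0):
            raise ValueError("wavelength and axial pitch must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite Jones data")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def separation_depth_m(self) -> Optional[float]:
        if self.separation_pixels is None:
            return None
        return self.separation_pixels * self.axial_pitch_m

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid


@dataclass
class ScalarMap:
    """A per-pixel real-valued image on the volume grid with a validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values/mask shape mismatch")


@dataclass
class PipelineConfig:
    """Tunable parameters of the birefringence pipeline.

    Defaults follow the acquisition geometry of a 1.31 um swept-source
    system with 6.125 um axial pixels: an 8-pixel (49 um) depth separation
    for local matrices, a 10 dB effective-SNR floor and a 0.9 DOAU floor
    for the volume mean.  The DOAU kernel (5, 21) pixels approximates a
    31 x 129 um^2 physical window.
    """

    avg_kernel: Tuple[int, int] = (3, 3)
    separation_pixels: int = 8
    snr_threshold_db: float = 10.0
    doau_kernel: Tuple[int, int] = (5, 21)
    doau_threshold: float = 0.9
    bias_correction: bool = True
    rng_seed: int = 0
    wrap_margin: float = 0.02  # fraction of pi treated as wrapped

    def __post_init__(self):
        if self.separation_pixels < 1:
            raise ValueError("separation_pixels must be >= 1")
        if not 0.0 <= self.doau_threshold <= 1.0:
            raise ValueError("doau_threshold must be in [0, 1]")


def _phase_aligned_window_mean(data, valid, kernel):
    """Mean of Jones matrices over a centred (z, x) window per B-scan.

    Each neighbour is multiplied by the unit phasor that best aligns it to
    the window-centre matrix in the least-squares sense (the phase of the
    Frobenius inner product), then the complex mean is taken.  Edges use
    window truncation; invalid voxels are excluded.
    """
    kz, kx = kernel
    nz, nx = data.shape[0], data.shape[1]
    acc = np.zeros_like(data)
    cnt = np.zeros(data.shape[:3], dtype=float)
    hz, hx = kz // 2, kx // 2
    for dz in range(-hz, hz + 1):
        z0, z1 = max(0, -dz), min(nz, nz - dz)
        for dx in range(-hx, hx + 1):
            x0, x1 = max(0, -dx), min(nx, nx - dx)
            nb = data[z0 + dz : z1 + dz, x0 + dx : x1 + dx]
            ctr = data[z0:z1, x0:x1]
            ok = valid[z0 + dz : z1 + dz, x0 + dx : x1 + dx]
            s = np.einsum("...ij,...ij->...", np.conj(ctr), nb)
            mag = np.abs(s)
            phasor = np.where(mag > 0, np.conj(s) / np.where(mag > 0, mag, 1.0), 1.0)
            acc[z0:z1, x0:x1] += ok[..., None, None] * nb * phasor[..., None, None]
            cnt[z0:z1, x0:x1] += ok
    out_valid = cnt > 0
    cnt_safe = np.where(out_valid, cnt, 1.0)
    return acc / cnt_safe[..., None, None], out_valid


def moving_average_jones(vol: JonesVolume, kernel: Tuple[int, int]) -> JonesVolume:
    """Phase-aligned complex moving average of a Jones volume.

    ``kernel = (axial, lateral)`` pixels, both odd; the window is applied
    per B-scan with truncation at the edges.  The metadata noise floor is
    divided by the kernel area (the incoherent noise-variance reduction of
    an interior pixel; edge pixels see slightly less averaging).
    """
    kz, kx = kernel
    if kz < 1 or kx < 1 or kz % 2 == 0 or kx % 2 == 0:
        raise ValueError("kernel dims must be odd and >= 1")
    nz, nx, _ = vol.shape
    if kz > nz or kx > nx:
        raise ValueError(f"kernel {kernel} larger than image ({nz}, {nx})")
    if kernel == (1, 1):
        return replace(vol)
    out, out_valid = _phase_aligned_window_mean(vol.data, vol.valid_mask(), kernel)
    return JonesVolume(
        data=out,
        wavelength_m=vol.wavelength_m,
        axial_pitch_m=vol.axial_pitch_m,
        lateral_pitch_m=vol.lateral_pitch_m,
        noise_floor=vol.noise_floor / (kz * kx),
        valid=out_valid,
    )


def local_jones(vol: JonesVolume, separation_pixels: int) -> JonesVolume:
    """Local round-trip Jones matrices from depth pairs.

    At output depth z the matrix is ``J(z + s) J(z)^-1`` with s the pixel
    separation; the depth dimension shrinks by s.  Voxels whose cumulative
    matrix is (near-)singular are flagged invalid rather than raising.
    """
    s = int(separation_pixels)
    nz = vol.shape[0]
    if s < 1 or s >= nz:
        raise ValueError("separation must satisfy 1 <= s < depth")
    J1 = vol.data[:-s]
    J2 = vol.data[s:]
    det = np.linalg.det(J1)
    vmask = vol.valid_mask()
    ok = (np.abs(det) > 1e-30) & vmask[:-s] & vmask[s:]
    J1_safe = np.where(ok[..., None, None], J1, np.eye(2, dtype=complex))
    local = J2 @ np.linalg.inv(J1_safe)
    return JonesVolume(
        data=np.where(ok[..., None, None], local, np.eye(2, dtype=complex)),
        wavelength_m=vol.wavelength_m,
        axial_pitch_m=vol.axial_pitch_m,
        lateral_pitch_m=vol.lateral_pitch_m,
        noise_floor=vol.noise_floor,
        valid=ok,
        separation_pixels=s,
    )


def effective_snr(vol: JonesVolume) -> ScalarMap:
    """Effective SNR in dB per pixel.

    ``10 log10( sum_ij |J_ij|^2 / sum_ij sigma_ij^2 )`` — the summed squared
    magnitude of the four Jones elements against the summed per-channel
    noise floor.  Zero-signal pixels return -inf and are masked.
    """
    if not vol.noise_floor > 0:
        raise ValueError("noise_floor must be positive")
    power = np.sum(np.abs(vol.data) ** 2, axis=(-2, -1))
    noise = 4.0 * vol.noise_floor
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(power / noise)
    mask = (power > 0) & vol.valid_mask()
    return ScalarMap(values=np.where(mask, snr, -np.inf), mask=mask)


def _retardance_to_dn(ret, wavelength_m, separation_depth_m):
    return ret * wavelength_m / (4.0 * np.pi * separation_depth_m)


def _dn_to_retardance(dn, wavelength_m, separation_depth_m):
    return dn * 4.0 * np.pi * separation_depth_m / wavelength_m


def local_birefringence(local: JonesVolume, wrap_margin: float = 0.02) -> ScalarMap:
    """Birefringence map from local round-trip matrices.

    Per pixel the Lu-Chipman retardance R of the local Mueller matrix gives
    ``dn = R lambda0 / (4 pi dz)`` with dz the separation depth in tissue.
    Pixels whose retardance is within ``wrap_margin * pi`` of pi are flagged
    (the single-separation estimator wraps at pi and cannot distinguish
    R from 2 pi - R there).
    """
    if local.separation_pixels is None:
        raise ValueError("input must come from local_jones (separation unknown)")
    ret, ok = lu_chipman_retardance_stack(jones_to_mueller(local.data))
    ok = ok & local.valid_mask()
    ok &= ret < np.pi * (1.0 - wrap_margin)
    dn = _retardance_to_dn(ret, local.wavelength_m, local.separation_depth_m)
    return ScalarMap(values=np.where(ok, dn, 0.0), mask=ok)


@dataclass
class BiasTable:
    """Expected measured retardance as a function of (true retardance, SNR).

    Built by Monte-Carlo simulation of the production estimator (noisy
    depth pair -> local matrix -> Lu-Chipman retardance) on a grid; the
    inverse (measured -> true) is taken per SNR slice with monotone cubic
    interpolation and linearly blended between slices.
    """

    retardance_grid: np.ndarray  # (nr,), true retardance in [0, pi]
    snr_grid_db: np.ndarray  # (ns,)
    mean_measured: np.ndarray  # (ns, nr)
    n_draws: int = 0
    rng_seed: int = 0
    _inverses: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.retardance_grid = np.asarray(self.retardance_grid, dtype=float)
        self.snr_grid_db = np.asarray(self.snr_grid_db, dtype=float)
        self.mean_measured = np.asarray(self.mean_measured, dtype=float)
        self._inverses = []
        for k in range(len(self.snr_grid_db)):
            meas = self.mean_measured[k].copy()
            # enforce strict monotonicity for invertibility
            meas = np.maximum.accumulate(meas)
            meas += 1e-12 * np.arange(len(meas))
            self._inverses.append(PchipInterpolator(meas, self.retardance_grid))

    def invert(self, measured: np.ndarray, snr_db: np.ndarray) -> np.ndarray:
        """True retardance for measured values at given SNRs.

        Measured values below the SNR-specific zero-retardance bias floor
        map to 0; values above the table maximum clamp to pi.  SNR outside
        the grid uses the nearest edge slice.
        """
        measured = np.asarray(measured, dtype=float)
        snr = np.clip(np.asarray(snr_db, dtype=float), self.snr_grid_db[0], self.snr_grid_db[-1])
        idx = np.searchsorted(self.snr_grid_db, snr, side="right") - 1
        idx = np.clip(idx, 0, len(self.snr_grid_db) - 2)
        lo, hi = idx, idx + 1
        w = (snr - self.snr_grid_db[lo]) / (self.snr_grid_db[hi] - self.snr_grid_db[lo])
        out = np.zeros_like(measured, dtype=float)
        flat_m = measured.ravel()
        flat_w = np.broadcast_to(w, measured.shape).ravel()
        flat_lo = np.broadcast_to(lo, measured.shape).ravel()
        res = np.empty_like(flat_m)
        for k in np.unique(flat_lo):
            sel = flat_lo == k
            m = flat_m[sel]
            inv_lo = self._eval_slice(int(k), m)
            inv_hi = self._eval_slice(int(k) + 1, m)
            res[sel] = (1.0 - flat_w[sel]) * inv_lo + flat_w[sel] * inv_hi
        out = res.reshape(measured.shape)
        return np.clip(out, 0.0, np.pi)

    def _eval_slice(self, k: int, measured: np.ndarray) -> np.ndarray:
        meas_grid = self._inverses[k].x
        val = self._inverses[k](np.clip(measured, meas_grid[0], meas_grid[-1]))
        val = np.where(measured <= meas_grid[0], 0.0, val)
        val = np.where(measured >= meas_grid[-1], np.pi, val)
        return val


def _simulate_measured_retardance(true_ret, snr_db, n_draws, rng):
    """One grid node of the bias table: mean Lu-Chipman retardance of the
    production local-matrix estimator under additive complex Gaussian noise.

    Signal matrices are unitary (total power 2 over four elements); the
    per-element complex noise variance is set so the four-channel effective
    SNR equals ``snr_db``.
    """
    sigma2 = 0.5 * 10.0 ** (-snr_db / 10.0)
    s = np.sqrt(sigma2 / 2.0)
    J1 = np.broadcast_to(np.eye(2, dtype=complex), (n_draws, 2, 2))
    J2 = np.broadcast_to(make_linear_retarder(true_ret, 0.0), (n_draws, 2, 2))
    n1 = s * (rng.standard_normal((n_draws, 2, 2)) + 1j * rng.standard_normal((n_draws, 2, 2)))
    n2 = s * (rng.standard_normal((n_draws, 2, 2)) + 1j * rng.standard_normal((n_draws, 2, 2)))
    local = (J2 + n2) @ np.linalg.inv(J1 + n1)
    ret, ok = lu_chipman_retardance_stack(jones_to_mueller(local))
    return float(np.mean(ret[ok])) if np.any(ok) else np.nan


def build_bias_table(
    snr_grid_db=None,
    retardance_grid=None,
    n_draws: int = 2000,
    rng_seed: int = 0,
) -> BiasTable:
    """Monte-Carlo table of the retardance estimator's noise bias.

    Defaults: 21 retardance nodes on [0, pi], SNR slices 5..40 dB in 5 dB
    steps, 2000 draws per node.  Deterministic given ``rng_seed``.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable table")
    if snr_grid_db is None:
        snr_grid_db = np.arange(5.0, 41.0, 5.0)
    if retardance_grid is None:
        retardance_grid = np.linspace(0.0, np.pi, 21)
    snr_grid_db = np.asarray(snr_grid_db, dtype=float)
    retardance_grid = np.asarray(retardance_grid, dtype=float)
    rng = np.random.default_rng(rng_seed)
    mean_measured = np.empty((len(snr_grid_db), len(retardance_grid)))
    for i, snr in enumerate(snr_grid_db):
        for k, r in enumerate(retardance_grid):
            mean_measured[i, k] = _simulate_measured_retardance(r, snr, n_draws, rng)
    return BiasTable(
        retardance_grid=retardance_grid,
        snr_grid_db=snr_grid_db,
        mean_measured=mean_measured,
        n_draws=n_draws,
        rng_seed=rng_seed,
    )


def apply_bias_correction(
    dn_map: ScalarMap,
    snr_map: ScalarMap,
    table: BiasTable,
    wavelength_m: float,
    separation_depth_m: float,
) -> ScalarMap:
    """Invert the Monte-Carlo bias table per pixel.

    The pixel's birefringence is converted to retardance, the table inverse
    is evaluated at the pixel's effective SNR, and the result converted
    back.  Values below the SNR-specific bias floor map to 0.
    """
    if dn_map.values.shape != snr_map.values.shape:
        raise ValueError("maps are not co-registered")
    ret = _dn_to_retardance(dn_map.values, wavelength_m, separation_depth_m)
    ok = dn_map.mask & snr_map.mask
    snr = np.where(snr_map.mask, snr_map.values, table.snr_grid_db[0])
    corrected = table.invert(np.where(ok, ret, 0.0), snr)
    dn = _retardance_to_dn(corrected, wavelength_m, separation_depth_m)
    return ScalarMap(values=np.where(ok, dn, 0.0), mask=ok)


def doau_map(local: JonesVolume, kernel: Tuple[int, int]) -> ScalarMap:
    """Degree of optic axis uniformity.

    Each local matrix is diagonalized, the fast-axis eigenvector (selected
    by eigenvalue-phase ordering after removing the matrix's global phase)
    is mapped to a Stokes axis, the (q, u, v) components are averaged over
    the centred (axial, lateral) kernel within the B-scan, and the result
    is the Euclidean norm sqrt(qbar^2 + ubar^2 + vbar^2) in [0, 1]: unity
    for a uniform axis field, ~1/sqrt(N) for N random axes.  Degenerate
    pixels are excluded from the average; a kernel with no usable pixel is
    invalid.
    """
    kz, kx = kernel
    if kz < 1 or kx < 1:
        raise ValueError("kernel dims must be >= 1")
    stokes, ok = fast_axis_stokes_stack(local.data)
    ok = ok & local.valid_mask()
    stokes = np.where(ok[..., None], stokes, 0.0)
    nz, nx, _ = local.shape
    acc = np.zeros_like(stokes)
    cnt = np.zeros(local.shape, dtype=float)
    hz, hx = kz // 2, kx // 2
    for dz in range(-hz, hz + 1):
        z0, z1 = max(0, -dz), min(nz, nz - dz)
        if z1 <= z0:
            continue
        for dx in range(-hx, hx + 1):
            x0, x1 = max(0, -dx), min(nx, nx - dx)
            if x1 <= x0:
                continue
            acc[z0:z1, x0:x1] += stokes[z0 + dz : z1 + dz, x0 + dx : x1 + dx]
            cnt[z0:z1, x0:x1] += ok[z0 + dz : z1 + dz, x0 + dx : x1 + dx]
    valid = cnt > 0
    cnt_safe = np.where(valid, cnt, 1.0)
    doau = np.linalg.norm(acc / cnt_safe[..., None], axis=-1)
    return ScalarMap(values=np.where(valid, np.clip(doau, 0.0, 1.0), 0.0), mask=valid)


def mean_birefringence(
    dn_map: ScalarMap,
    snr_map: ScalarMap,
    doau: ScalarMap,
    config: PipelineConfig,
) -> Tuple[float, int]:
    """Volume-mean birefringence over the screened pixels.

    Pixels must be valid in all three maps, exceed the effective-SNR
    threshold and exceed the DOAU threshold.  Returns (mean, n_valid);
    raises :class:`MaskError` with per-filter survivor counts if nothing
    survives.
    """
    if not (dn_map.values.shape == snr_map.values.shape == doau.values.shape):
        raise ValueError("maps are not co-registered")
    base = dn_map.mask & snr_map.mask & doau.mask
    pass_snr = base & (snr_map.values > config.snr_threshold_db)
    pass_doau = base & (doau.values > config.doau_threshold)
    sel = pass_snr & pass_doau
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise MaskError(
            "no pixel survived the masking",
            counts={
                "valid": int(np.count_nonzero(base)),
                "snr_pass": int(np.count_nonzero(pass_snr)),
                "doau_pass": int(np.count_nonzero(pass_doau)),
            },
        )
    return float(np.mean(dn_map.values[sel])), n


def process_volume(
    vol: JonesVolume,
    config: Optional[PipelineConfig] = None,
    bias_table: Optional[BiasTable] = None,
):
    """Run the full per-volume chain and return a result dict.

    Steps: phase-aligned Jones averaging -> local round-trip matrices ->
    retardance/birefringence -> effective SNR (minimum of the two depths
    entering each local matrix) -> optional bias correction -> DOAU ->
    masked volume mean.  If ``config.bias_correction`` is on and no table
    is supplied, one is built with ``config.rng_seed``.

    Returns a dict with ``mean_birefringence``, ``n_valid`` and the
    intermediate :class:`ScalarMap` objects.
    """
    config = config or PipelineConfig()
    avg = moving_average_jones(vol, config.avg_kernel)
    loc = local_jones(avg, config.separation_pixels)
    dn = local_birefringence(loc, wrap_margin=config.wrap_margin)
    snr_full = effective_snr(avg)
    s = config.separation_pixels
    snr = ScalarMap(
        values=np.minimum(snr_full.values[:-s], snr_full.values[s:]),
        mask=snr_full.mask[:-s] & snr_full.mask[s:],
    )
    if config.bias_correction:
        if bias_table is None:
            bias_table = build_bias_table(rng_seed=config.rng_seed)
        dn = apply_bias_correction(
            dn, snr, bias_table, vol.wavelength_m, loc.separation_depth_m
        )
    doau = doau_map(loc, config.doau_kernel)
    mean, n_valid = mean_birefringence(dn, snr, doau, config)
    return {
        "mean_birefringence": mean,
        "n_valid": n_valid,
        "dn_map": dn,
        "snr_map": snr,
        "doau_map": doau,
        "config": config,
    }
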