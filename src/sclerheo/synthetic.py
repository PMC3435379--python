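"""Ground-truth generators: Jones-matrix phantoms, tensile records, cohorts.

The generators emulate the study conditions the analysis stages are built
for: layered birefringent tissue imaged in round trip by a 1.31 um PS-OCT
(per-A-scan speckle phase, additive complex Gaussian detection noise at a
set effective SNR), a uniaxial tensile protocol (0.04 N pre-load, ten
preconditioning cycles to 6.5% strain at 1.8 mm/min, then a ramp to 18%),
and a cohort in which a latent fiber-organization variable drives both
birefringence and stiffness with a designed Pearson correlation.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .birefringence import JonesVolume
from .jones import make_retarder
from .mechanics import StressStrainRecord

__all__ = [
    "PhantomSpec",
    "MechProtocol",
    "CohortSpec",
    "simulate_jones_volume",
    "simulate_stress_strain",
    "simulate_cohort",
    "random_axes",
    "vmf_axes",
]

AxisSpec = Union[np.ndarray, str, Tuple]


def random_axes(shape, rng) -> np.ndarray:
    """I.i.d. axes uniform on the Poincare sphere, shape ``shape + (3,)``."""
    v = rng.standard_normal(tuple(shape) + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def vmf_axes(shape, mean_axis, kappa, rng) -> np.ndarray:
    """Von-Mises-Fisher distributed axes about ``mean_axis`` on the sphere.

    Uses Wood's inversion for the cosine of the polar angle; ``kappa = 0``
    reduces to the uniform distribution.
    """
    mu = np.asarray(mean_axis, dtype=float)
    mu = mu / np.linalg.norm(mu)
    n = int(np.prod(shape)) if len(shape) else 1
    if kappa <= 0:
        return random_axes(shape, rng)
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal frame around mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    pts = (
        w[:, None] * mu[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )
    return pts.reshape(tuple(shape) + (3,))


@dataclass
class PhantomSpec:
    """Specification of a layered birefringent phantom.

    ``birefringence`` is a scalar or a (z, x, y) array of local dn;
    ``axis`` selects the optic-axis field:

    - a length-3 vector: uniform axis everywhere;
    - a ``(z, x, y, 3)`` array: explicit per-voxel axes;
    - ``"random"``: i.i.d. uniform on the sphere per voxel;
    - ``("vmf", mean_axis, kappa)``: von-Mises-Fisher dispersed;
    - ``("two_domain", axis1, axis2, x_split)``: two lateral domains.

    ``snr_db=None`` produces a noiseless volume (token noise floor so SNR
    maps stay defined).  ``guard_separation_pixels`` is the largest local
    separation the downstream pipeline will use; the generator refuses
    parameter combinations whose round-trip retardance over that span
    reaches pi (the estimator's wrapping limit).
    """

    dims: Tuple[int, int, int] = (64, 64, 4)
    birefringence: Union[float, np.ndarray] = 1.5e-3
    axis: AxisSpec = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    snr_db: Optional[float] = 30.0
    wavelength_m: float = 1.31e-6
    axial_pitch_m: float = 6.125e-6
    lateral_pitch_m: float = 6.0e-6
    guard_separation_pixels: int = 16
    rng_seed: int = 0


def _resolve_axes(spec: PhantomSpec, rng) -> np.ndarray:
    ax = spec.axis
    z, x, y = spec.dims
    if isinstance(ax, str):
        if ax == "random":
            return random_axes((z, x, y), rng)
        raise ValueError(f"unknown axis mode {ax!r}")
    if isinstance(ax, tuple):
        mode = ax[0]
        if mode == "vmf":
            _, mean_axis, kappa = ax
            return vmf_axes((z, x, y), mean_axis, kappa, rng)
        if mode == "two_domain":
            _, a1, a2, x_split = ax
            out = np.empty((z, x, y, 3))
            out[:, :x_split] = np.asarray(a1, dtype=float)
            out[:, x_split:] = np.asarray(a2, dtype=float)
            return out / np.linalg.norm(out, axis=-1, keepdims=True)
        raise ValueError(f"unknown axis mode {mode!r}")
    ax = np.asarray(ax, dtype=float)
    if ax.shape == (3,):
        out = np.broadcast_to(ax / np.linalg.norm(ax), (z, x, y, 3)).copy()
        return out
    if ax.shape == (z, x, y, 3):
        return ax / np.linalg.norm(ax, axis=-1, keepdims=True)
    raise ValueError("axis array must be (3,) or dims + (3,)")


def simulate_jones_volume(spec: PhantomSpec) -> JonesVolume:
    """Forward-model a Jones-matrix OCT volume.

    The cumulative round-trip matrix at depth z is the ordered product of
    per-voxel retarder increments with round-trip retardation
    ``4 pi dn dz_pixel / lambda`` about the local axis, multiplied by a
    random per-A-scan global phasor (speckle-phase surrogate).  Additive
    circular complex Gaussian noise per element realizes the requested
    four-channel effective SNR; the metadata noise floor records the
    per-channel variance.
    """
    rng = np.random.default_rng(spec.rng_seed)
    z, x, y = spec.dims
    dn = np.broadcast_to(np.asarray(spec.birefringence, dtype=float), (z, x, y))
    delta = 4.0 * np.pi * dn * spec.axial_pitch_m / spec.wavelength_m

    # wrap guard: worst-case retardance accumulated over the guard span
    s = min(spec.guard_separation_pixels, z - 1)
    if s >= 1:
        csum = np.cumsum(delta, axis=0)
        span = csum[s:] - csum[:-s] if z > s else csum[-1:]
        worst = float(np.max(span)) if span.size else 0.0
        if worst >= np.pi:
            zbad = int(np.argmax(np.max(span.reshape(span.shape[0], -1), axis=1)))
            raise ValueError(
                f"wrap guard violated: round-trip retardance {worst:.3f} rad >= pi "
                f"over {s} pixels at depth index {zbad}"
            )

    axes = _resolve_axes(spec, rng)
    data = np.empty((z, x, y, 2, 2), dtype=complex)
    J = np.broadcast_to(np.eye(2, dtype=complex), (x, y, 2, 2)).copy()
    for k in range(z):
        inc = make_retarder(delta[k], axes[k])
        J = inc @ J
        data[k] = J

    phase = np.exp(2j * np.pi * rng.uniform(size=(x, y)))
    data = data * phase[None, :, :, None, None]

    if spec.snr_db is not None:
        sigma2 = 0.5 * 10.0 ** (-spec.snr_db / 10.0)
        sd = np.sqrt(sigma2 / 2.0)
        data = data + sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
        noise_floor = sigma2
    else:
        noise_floor = 1e-12
    return JonesVolume(
        data=data,
        wavelength_m=spec.wavelength_m,
        axial_pitch_m=spec.axial_pitch_m,
        lateral_pitch_m=spec.lateral_pitch_m,
        noise_floor=noise_floor,
    )


@dataclass
class MechProtocol:
    """Tensile-test protocol: pre-load, preconditioning, final ramp."""

    prestress_N: float = 0.04
    n_precondition_cycles: int = 10
    precondition_strain: float = 0.065
    hold_s: float = 10.0
    final_strain: float = 0.18
    speed_mm_per_min: float = 1.8
    gauge_length_mm: float = 5.0
    sampling_hz: float = 10.0


def simulate_stress_strain(
    a_mpa: float,
    b: float,
    area_mm2: float = 3.2,
    width_mm: float = 4.0,
    protocol: Optional[MechProtocol] = None,
    noise_frac: float = 0.01,
    rng_seed: int = 0,
) -> StressStrainRecord:
    """Simulate a uniaxial tensile record with exponential tissue response.

    The pseudo-elastic stress developed above the pre-stressed reference
    state follows ``sigma = a (exp(b eps) - 1)``; recorded force is
    ``area * sigma + prestress`` with multiplicative Gaussian noise of
    relative magnitude ``noise_frac``.  The displacement trace covers the
    preconditioning cycles, the hold, and the final ramp to 18% strain at
    the protocol speed.
    """
    if a_mpa <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    p = protocol or MechProtocol()
    rng = np.random.default_rng(rng_seed)
    rate = p.speed_mm_per_min / 60.0 / p.gauge_length_mm  # strain per second
    dt = 1.0 / p.sampling_hz

    seg_t = []
    seg_eps = []
    t0 = 0.0
    cyc_T = p.precondition_strain / rate
    for _ in range(p.n_precondition_cycles):
        tt = np.arange(0.0, 2.0 * cyc_T, dt)
        eps = np.where(tt < cyc_T, rate * tt, p.precondition_strain - rate * (tt - cyc_T))
        seg_t.append(t0 + tt)
        seg_eps.append(np.clip(eps, 0.0, None))
        t0 += 2.0 * cyc_T
    tt = np.arange(0.0, p.hold_s, dt)
    seg_t.append(t0 + tt)
    seg_eps.append(np.zeros_like(tt))
    t0 += p.hold_s
    ramp_T = p.final_strain / rate
    tt = np.arange(0.0, ramp_T + dt / 2, dt)
    seg_t.append(t0 + tt)
    seg_eps.append(np.minimum(rate * tt, p.final_strain))

    time = np.concatenate(seg_t)
    eps = np.concatenate(seg_eps)
    force = area_mm2 * a_mpa * (np.exp(b * eps) - 1.0) + p.prestress_N
    if noise_frac > 0:
        force = force * (1.0 + noise_frac * rng.standard_normal(force.shape))
    return StressStrainRecord(
        time_s=time,
        displacement_mm=eps * p.gauge_length_mm,
        force_N=force,
        gauge_length_mm=p.gauge_length_mm,
        area_mm2=area_mm2,
        width_mm=width_mm,
        speed_mm_per_min=p.speed_mm_per_min,
        prestress_N=p.prestress_N,
    )


REGIONS = ("A", "B", "C", "D")


@dataclass
class CohortSpec:
    """A cohort of eyes with a latent fiber-organization variable per
    sample-region driving both birefringence and stiffness.

    ``target_correlation`` maps region label to the designed population
    Pearson correlation between birefringence and structural stiffness;
    defaults follow the magnitudes a scleral strip study reports near the
    optic nerve head (strong centrally, absent near the equator).  The
    latent construction uses small coefficients of variation so log-scale
    calibration carries to the raw scale.
    """

    n_samples: int = 19
    target_correlation: Dict[str, float] = field(
        default_factory=lambda: {"A": 0.54, "B": 0.82, "C": 0.56, "D": 0.12}
    )
    regions: Sequence[str] = REGIONS
    dn_mean: float = 1.5e-3
    dn_cv: float = 0.12
    e0_mean_mpa: float = 0.8
    e0_cv: float = 0.25
    thickness_mean_mm: float = 0.8
    thickness_cv: float = 0.08
    b_mean: float = 40.0
    b_cv: float = 0.10
    width_mm: float = 4.0
    snr_db: float = 30.0
    volume_dims: Tuple[int, int, int] = (40, 24, 2)
    force_noise_frac: float = 0.01
    rng_seed: int = 0


def _latent_noise_scale(target_r: float, rho: float, ct2: float) -> float:
    """Noise scale s such that corr(dn, E0*t) = target_r in the linearized
    latent model with unit-variance scores z = (L + s e)/sqrt(1+s^2):
    corr = [1/(1+s^2)] / sqrt(1 + rho + ct^2), rho = (c_t/c_E)^2.
    Raises if |target_r| exceeds the feasible bound (s = 0)."""
    r = abs(target_r)
    denom = np.sqrt(1.0 + rho + ct2)
    bound = 1.0 / denom
    if r >= bound:
        raise ValueError(
            f"target correlation {target_r:+.3f} infeasible with thickness noise; "
            f"|r| must be < {bound:.4f}"
        )
    c = r * denom  # required corr(z_dn, z_e0)
    return float(np.sqrt(1.0 / c - 1.0))


def simulate_cohort(spec: CohortSpec):
    """Draw a full cohort: per-sample phantom specs, tensile records,
    cross-section polygons, and the ground-truth table.

    Returns ``(samples, truth)`` where ``samples`` is a list of dicts with
    keys ``sample_id, region, phantom, record, polygon_mm`` and ``truth``
    is a DataFrame with the ground-truth per-row dn, elastic parameters and
    thickness.  The exponential power b is made to decrease with the latent
    organization variable, so its designed correlation with birefringence
    is negative.
    """
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    samples = []
    for region in spec.regions:
        r_target = spec.target_correlation.get(region, 0.0)
        rho = (spec.thickness_cv / spec.e0_cv) ** 2
        for i in range(spec.n_samples):
            L = rng.standard_normal()
            if abs(r_target) < 1e-3:
                z_dn, z_e0 = rng.standard_normal(2)
            else:
                s = _latent_noise_scale(r_target, rho, spec.thickness_cv**2)
                norm = np.sqrt(1.0 + s * s)
                z_dn = (L + s * rng.standard_normal()) / norm
                z_e0 = (L + s * rng.standard_normal()) / norm
                if r_target < 0:
                    z_dn = -z_dn
            dn = spec.dn_mean * (1.0 + spec.dn_cv * z_dn)
            e0 = spec.e0_mean_mpa * (1.0 + spec.e0_cv * z_e0)
            thickness = spec.thickness_mean_mm * (
                1.0 + spec.thickness_cv * rng.standard_normal()
            )
            # exponential power decreases with organization (negative corr)
            z_b = L if abs(r_target) >= 1e-3 else rng.standard_normal()
            b = spec.b_mean * (1.0 - spec.b_cv * z_b)
            dn = float(np.clip(dn, 0.2e-3, 5.5e-3))
            e0 = float(max(e0, 0.05))
            b = float(np.clip(b, 5.0, 120.0))
            thickness = float(max(thickness, 0.2))
            a = e0 / b
            area = thickness * spec.width_mm

            seed_v = int(rng.integers(0, 2**31 - 1))
            seed_m = int(rng.integers(0, 2**31 - 1))
            phantom = PhantomSpec(
                dims=spec.volume_dims,
                birefringence=dn,
                axis=np.array([1.0, 0.0, 0.0]),
                snr_db=spec.snr_db,
                guard_separation_pixels=8,
                rng_seed=seed_v,
            )
            record = simulate_stress_strain(
                a_mpa=a,
                b=b,
                area_mm2=area,
                width_mm=spec.width_mm,
                noise_frac=spec.force_noise_frac,
                rng_seed=seed_m,
            )
            # rectangular strip cross-section: width x thickness
            polygon = np.array(
                [
                    [0.0, 0.0],
                    [spec.width_mm, 0.0],
                    [spec.width_mm, thickness],
                    [0.0, thickness],
                ]
            )
            sid = f"{region}{i:02d}"
            samples.append(
                {
                    "sample_id": sid,
                    "region": region,
                    "phantom": phantom,
                    "record": record,
                    "polygon_mm": polygon,
                }
            )
            rows.append(
                {
                    "sample_id": sid,
                    "region": region,
                    "mean_birefringence": dn,
                    "a_mpa": a,
                    "power_b": b,
                    "tangent_modulus_0": e0,
                    "thickness": thickness,
                    "structural_stiffness": e0 * thickness,
                }
            )
    truth = pd.DataFrame(rows)
    return samples, truth
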