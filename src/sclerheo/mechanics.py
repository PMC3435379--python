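"""Uniaxial stress-strain analysis and exponential elastic parameters.

Engineering strain and stress are computed from a tensile record
(``eps = displacement / gauge length``, ``sigma = force / initial area``),
the loading curve is fitted with the exponential soft-tissue model

    sigma = a (exp(b eps) - 1),

and three elastic parameters are extracted: the tangent modulus at 0%
strain ``E0 = a b`` (the model's derivative at the origin), the structural
stiffness ``E0 * thickness`` (a net load-bearing measure), and the power
``b`` (equivalently the slope of tangent modulus against stress, since
``E = b (sigma + a)``).

The 0.04 N pre-load defines the zero-strain reference state: strain is
measured from the pre-stressed length, and the fit describes the stress
developed above that datum (see ``fit_exponential``'s ``datum``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StressStrainRecord",
    "ElasticParams",
    "FitError",
    "extract_final_ramp",
    "compute_stress_strain",
    "fit_exponential",
    "tangent_modulus",
    "structural_stiffness",
    "exponential_power",
]


class FitError(RuntimeError):
    """Raised when the exponential fit fails to converge; carries the
    initialization in ``.init``."""

    def __init__(self, message, init=None):
        super().__init__(message)
        self.init = init


@dataclass
class StressStrainRecord:
    """A tensile test record: time, crosshead displacement and force,
    plus sample geometry.  Displacement zero is the pre-stressed state."""

    time_s: np.ndarray
    displacement_mm: np.ndarray
    force_N: np.ndarray
    gauge_length_mm: float = 5.0
    area_mm2: float = 1.0
    width_mm: float = 4.0
    speed_mm_per_min: float = 1.8
    prestress_N: float = 0.04

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if not (len(self.time_s) == len(self.displacement_mm) == len(self.force_N)):
            raise ValueError("time/displacement/force lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force_N)):
            raise ValueError("non-finite force values")
        if self.gauge_length_mm <= 0 or self.area_mm2 <= 0:
            raise ValueError("gauge length and area must be positive")


@dataclass
class ElasticParams:
    """Fitted exponential stress-strain parameters.

    ``tangent_modulus_0 = a * b`` by the model identity; structural
    stiffness is filled once a thickness is known.
    """

    a: float  # stress scale, MPa
    b: float  # dimensionless exponential power
    tangent_modulus_0: float  # MPa
    fit_rmse: float  # MPa
    fit_range: Tuple[float, float]
    stress_datum: float = 0.0  # MPa subtracted before fitting
    structural_stiffness: Optional[float] = None  # MPa mm

    def with_thickness(self, thickness_mm: float) -> "ElasticParams":
        return ElasticParams(
            a=self.a,
            b=self.b,
            tangent_modulus_0=self.tangent_modulus_0,
            fit_rmse=self.fit_rmse,
            fit_range=self.fit_range,
            stress_datum=self.stress_datum,
            structural_stiffness=structural_stiffness(self.tangent_modulus_0, thickness_mm),
        )


def extract_final_ramp(rec: StressStrainRecord) -> slice:
    """Index slice of the final loading ramp.

    The protocol ends with a monotone extension after the preconditioning
    cycles; the maximal suffix with non-decreasing displacement is that
    ramp.
    """
    d = rec.displacement_mm
    if len(d) < 2:
        return slice(0, len(d))
    dec = np.nonzero(np.diff(d) < 0)[0]
    start = int(dec[-1]) + 1 if len(dec) else 0
    # skip a hold plateau at the ramp start, keeping one zero-strain point
    while start < len(d) - 2 and d[start + 1] == d[start]:
        start += 1
    return slice(start, len(d))


def compute_stress_strain(
    rec: StressStrainRecord, use_final_ramp: bool = True
) -> Tuple[np.ndarray, np.ndarray]:
    """Engineering strain and stress (MPa) of the analyzed loading segment.

    Strain is ``(L - L0)/L0`` with L0 the pre-stressed gauge length,
    i.e. displacement (re-zeroed to the ramp start) over gauge length;
    stress is force over the initial cross-section area (N/mm^2 = MPa),
    with no pre-load subtraction.
    """
    sl = extract_final_ramp(rec) if use_final_ramp else slice(None)
    disp = rec.displacement_mm[sl]
    strain = (disp - disp[0]) / rec.gauge_length_mm
    stress = rec.force_N[sl] / rec.area_mm2
    return strain, stress


def _initial_guess(strain, stress):
    """Deterministic starting point: b0 from the log-slope of a smoothed
    numerical derivative, a0 from matching the endpoint."""
    w = max(len(strain) // 10, 3)
    kern = np.ones(w) / w
    sm = np.convolve(stress, kern, mode="same")
    with np.errstate(divide="ignore", invalid="ignore"):
        dsde = np.gradient(sm, strain)
    pos = np.isfinite(dsde) & (dsde > 0)
    b0 = 20.0
    if np.count_nonzero(pos) >= 3 and np.ptp(strain[pos]) > 0:
        fit = np.polyfit(strain[pos], np.log(dsde[pos]), 1)[0]
        if np.isfinite(fit):
            b0 = float(fit)
    b0 = float(np.clip(b0, 1e-2, 500.0))
    smax = max(float(stress[-1] - stress[0]), 1e-9)
    a0 = smax / max(np.expm1(b0 * strain[-1]), 1e-9)
    return max(a0, 1e-9), b0


def fit_exponential(
    strain: np.ndarray,
    stress: np.ndarray,
    fit_range: Tuple[float, float] = (0.0, 0.065),
    datum: Union[str, float] = "auto",
) -> ElasticParams:
    """Least-squares fit of ``sigma = a (exp(b eps) - 1)`` over a strain range.

    ``datum`` fixes the stress reference subtracted before fitting:
    ``"auto"`` uses the stress at the smallest strain inside the range (the
    pre-load level, so the model's sigma(0) = 0 describes the stress
    developed above the pre-stressed state), ``"none"`` subtracts nothing,
    and a float subtracts that value (MPa).

    Requires at least 10 samples inside the range.  Deterministic: the
    initialization is a fixed rule (log-slope of the smoothed derivative).
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress, dtype=float)
    sel = (strain >= fit_range[0]) & (strain <= fit_range[1])
    if np.count_nonzero(sel) < 10:
        raise ValueError(
            f"need >= 10 samples in fit range {fit_range}, got {np.count_nonzero(sel)}"
        )
    e = strain[sel]
    order = np.argsort(e, kind="stable")
    e = e[order]
    s = stress[sel][order]
    keep = np.concatenate([[True], np.diff(e) > 0])  # drop duplicate strains
    e, s = e[keep], s[keep]
    if datum == "auto":
        s0 = float(s[0])
    elif datum == "none":
        s0 = 0.0
    else:
        s0 = float(datum)
    y = s - s0

    a0, b0 = _initial_guess(e, y)
    # solve in (E0, b) = (a*b, b): smooth as b -> 0 (linear limit a*b -> k)
    model = lambda eps, e0, b: e0 * np.expm1(b * eps) / b
    try:
        popt, _ = curve_fit(
            model,
            e,
            y,
            p0=(a0 * b0, b0),
            bounds=([1e-12, 1e-8], [np.inf, 1e4]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise FitError(f"exponential fit did not converge: {err}", init=(a0, b0)) from err
    e0, b = float(popt[0]), float(popt[1])
    a = e0 / b
    rmse = float(np.sqrt(np.mean((model(e, e0, b) - y) ** 2)))
    return ElasticParams(
        a=a,
        b=b,
        tangent_modulus_0=a * b,
        fit_rmse=rmse,
        fit_range=(float(fit_range[0]), float(fit_range[1])),
        stress_datum=s0,
    )


def tangent_modulus(params: ElasticParams, at_strain: float = 0.0) -> float:
    """Tangent modulus ``d sigma / d eps = a b exp(b eps)`` in MPa."""
    return params.a * params.b * float(np.exp(params.b * at_strain))


def structural_stiffness(tangent_modulus_0: float, thickness_mm: float) -> float:
    """Structural stiffness = tangent modulus x thickness (MPa mm)."""
    if tangent_modulus_0 <= 0 or thickness_mm <= 0:
        raise ValueError("tangent modulus and thickness must be positive")
    return tangent_modulus_0 * thickness_mm


def exponential_power(params: ElasticParams) -> float:
    """The exponential power b — the slope of tangent modulus against
    stress, by the identity ``E = b (sigma + a)``."""
    return params.b
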