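"""File formats: HDF5 Jones volumes, CSV tensile records, JSON metadata.

The Jones-volume container is HDF5 with datasets ``/jones/real`` and
``/jones/imag`` shaped (z, x, y, 2, 2) and attributes ``wavelength_m``,
``axial_pitch_m``, ``lateral_pitch_m``, ``noise_floor``; a JSON sidecar
mirror (nested lists) is accepted for small fixtures.  Tensile records are
CSV with columns ``time_s, displacement_mm, force_N`` plus a metadata JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd

from .birefringence import JonesVolume, ScalarMap
from .mechanics import StressStrainRecord

__all__ = [
    "write_jones_volume",
    "read_jones_volume",
    "write_jones_volume_json",
    "read_jones_volume_json",
    "write_scalar_map",
    "read_scalar_map",
    "write_stress_strain_csv",
    "read_stress_strain_csv",
    "read_polygon_csv",
    "write_polygon_csv",
]

PathLike = Union[str, Path]


def write_jones_volume(path: PathLike, vol: JonesVolume) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("jones")
        g.create_dataset("real", data=np.real(vol.data))
        g.create_dataset("imag", data=np.imag(vol.data))
        f.attrs["wavelength_m"] = vol.wavelength_m
        f.attrs["axial_pitch_m"] = vol.axial_pitch_m
        f.attrs["lateral_pitch_m"] = vol.lateral_pitch_m
        f.attrs["noise_floor"] = vol.noise_floor


def read_jones_volume(path: PathLike) -> JonesVolume:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["jones/real"]) + 1j * np.asarray(f["jones/imag"])
        return JonesVolume(
            data=data,
            wavelength_m=float(f.attrs["wavelength_m"]),
            axial_pitch_m=float(f.attrs["axial_pitch_m"]),
            lateral_pitch_m=float(f.attrs["lateral_pitch_m"]),
            noise_floor=float(f.attrs["noise_floor"]),
        )


def write_jones_volume_json(path: PathLike, vol: JonesVolume) -> None:
    """Plain-text sidecar mirror for small fixtures."""
    payload = {
        "real": np.real(vol.data).tolist(),
        "imag": np.imag(vol.data).tolist(),
        "wavelength_m": vol.wavelength_m,
        "axial_pitch_m": vol.axial_pitch_m,
        "lateral_pitch_m": vol.lateral_pitch_m,
        "noise_floor": vol.noise_floor,
    }
    Path(path).write_text(json.dumps(payload))


def read_jones_volume_json(path: PathLike) -> JonesVolume:
    payload = json.loads(Path(path).read_text())
    data = np.asarray(payload["real"]) + 1j * np.asarray(payload["imag"])
    return JonesVolume(
        data=data,
        wavelength_m=payload["wavelength_m"],
        axial_pitch_m=payload["axial_pitch_m"],
        lateral_pitch_m=payload["lateral_pitch_m"],
        noise_floor=payload["noise_floor"],
    )


def write_scalar_map(path: PathLike, name: str, sm: ScalarMap, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("values", data=sm.values)
        g.create_dataset("mask", data=sm.mask)


def read_scalar_map(path: PathLike, name: str) -> ScalarMap:
    with h5py.File(path, "r") as f:
        return ScalarMap(
            values=np.asarray(f[f"{name}/values"]),
            mask=np.asarray(f[f"{name}/mask"], dtype=bool),
        )


def write_stress_strain_csv(
    path: PathLike, rec: StressStrainRecord, meta_path: Optional[PathLike] = None
) -> None:
    pd.DataFrame(
        {
            "time_s": rec.time_s,
            "displacement_mm": rec.displacement_mm,
            "force_N": rec.force_N,
        }
    ).to_csv(path, index=False)
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps(
                {
                    "gauge_length_mm": rec.gauge_length_mm,
                    "area_mm2": rec.area_mm2,
                    "width_mm": rec.width_mm,
                    "speed_mm_per_min": rec.speed_mm_per_min,
                    "prestress_N": rec.prestress_N,
                }
            )
        )


def read_stress_strain_csv(
    path: PathLike, meta_path: Optional[PathLike] = None, **overrides
) -> StressStrainRecord:
    """Read a tensile record; metadata comes from the JSON sidecar, with
    keyword overrides taking precedence."""
    df = pd.read_csv(path)
    for col in ("time_s", "displacement_mm", "force_N"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    meta.update(overrides)
    allowed = {
        k: meta[k]
        for k in ("gauge_length_mm", "area_mm2", "width_mm", "speed_mm_per_min", "prestress_N")
        if k in meta
    }
    return StressStrainRecord(
        time_s=df["time_s"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        force_N=df["force_N"].to_numpy(),
        **allowed,
    )


def write_polygon_csv(path: PathLike, polygon_mm: np.ndarray) -> None:
    pd.DataFrame(polygon_mm, columns=["x_mm", "z_mm"]).to_csv(path, index=False)


def read_polygon_csv(path: PathLike) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"x_mm", "z_mm"} <= set(df.columns):
        raise ValueError("polygon CSV needs columns x_mm, z_mm")
    return df[["x_mm", "z_mm"]].to_numpy(dtype=float)
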