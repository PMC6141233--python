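"""Delimited-text input/output for traces, spectra and tables.

Traces travel as two-column tab-separated text (time_s, value) with an
optional YAML sidecar (same path + ``.yaml``) holding drive frequency,
amplitude, solution condition and fiber geometry.  Spectra are TSV with
frequency/elastic/viscous columns.  All writes are lossless round trips
at full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cardiac import CardiacTrace
from .sinusoidal import ComplexModulusSpectrum, FiberGeometry, LengthForceTrace


def _sidecar(path) -> Path:
    return Path(str(path) + ".yaml")


def save_trace(path, trace: LengthForceTrace) -> None:
    """Write strain and stress columns plus a YAML sidecar of metadata."""
    df = pd.DataFrame({"time_s": trace.time, "strain": trace.strain,
                       "stress_kn_m2": trace.stress})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {
        "drive_frequency_hz": float(trace.drive_frequency),
        "amplitude_fraction_ml": float(trace.amplitude),
        "condition": dict(trace.condition),
    }
    geom = trace.metadata.get("geometry")
    if isinstance(geom, FiberGeometry):
        meta["geometry"] = {"length_m": geom.length,
                            "cross_sectional_area_m2": geom.cross_sectional_area}
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def load_trace(path) -> LengthForceTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    metadata = {}
    if "geometry" in meta:
        metadata["geometry"] = FiberGeometry(
            length=meta["geometry"]["length_m"],
            cross_sectional_area=meta["geometry"]["cross_sectional_area_m2"])
    return LengthForceTrace(
        time=df["time_s"].to_numpy(),
        strain=df["strain"].to_numpy(),
        stress=df["stress_kn_m2"].to_numpy(),
        drive_frequency=meta["drive_frequency_hz"],
        amplitude=meta["amplitude_fraction_ml"],
        condition=meta.get("condition", {}),
        metadata=metadata,
    )


def save_spectrum(path, spectrum: ComplexModulusSpectrum) -> None:
    df = pd.DataFrame({
        "frequency_hz": spectrum.frequencies,
        "elastic_kn_m2": spectrum.elastic_modulus,
        "viscous_kn_m2": spectrum.viscous_modulus,
    })
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# amplitude_fraction_ml\t{spectrum.amplitude:.17g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def load_spectrum(path) -> ComplexModulusSpectrum:
    with open(path) as fh:
        first = fh.readline()
        amplitude = float(first.split("\t")[1]) if first.startswith("#") else 0.00125
        if not first.startswith("#"):
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return ComplexModulusSpectrum(
        frequencies=df["frequency_hz"].to_numpy(),
        elastic_modulus=df["elastic_kn_m2"].to_numpy(),
        viscous_modulus=df["viscous_kn_m2"].to_numpy(),
        amplitude=amplitude,
    )


def save_cardiac_trace(path, trace: CardiacTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "diameter_um": trace.diameter}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def load_cardiac_trace(path) -> CardiacTrace:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return CardiacTrace(time=df["time_s"].to_numpy(),
                        diameter=df["diameter_um"].to_numpy())


def load_two_column(path) -> tuple[np.ndarray, np.ndarray]:
    """Generic (time, value) reader for delimited text with a header row."""
    df = pd.read_csv(path, sep=None, engine="python",
                     float_precision="round_trip")
    cols = df.columns
    return df[cols[0]].to_numpy(dtype=float), df[cols[1]].to_numpy(dtype=float)
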