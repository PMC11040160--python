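"""Plain-text I/O: tab-separated tables with ``#`` header lines.

Every writer emits a human-readable header recording what the columns are and
(for analysis products) which settings produced them; readers skip ``#``
lines.  Large intensity traces can optionally be stored in HDF5 via
:func:`write_trace_hdf5` when h5py is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .correlate import CorrelationCurve, IntensityTrace
from .dnase import DnaseTrace
from .fcs import KineticsSeries
from .tirf import SpotTrajectory, SurvivalCurve

__all__ = [
    "write_trace",
    "read_trace",
    "write_series",
    "read_series",
    "write_curve",
    "write_trajectories",
    "read_trajectories",
    "write_survival",
    "write_dnase_trace",
    "read_dnase_trace",
    "write_sidecar",
]


def _write(path, df: pd.DataFrame, header: dict):
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read(path):
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, header


def write_trace(path, trace: IntensityTrace):
    cols = {f"channel_{c}_counts": trace.counts[c] for c in range(trace.n_channels)}
    _write(path, pd.DataFrame(cols),
           {"format": "intensity_trace", "bin_width_s": trace.bin_width,
            "start_time_s": trace.start_time})


def read_trace(path) -> IntensityTrace:
    df, header = _read(path)
    counts = df[[c for c in df.columns if c.startswith("channel_")]].to_numpy().T
    return IntensityTrace(counts, float(header["bin_width_s"]),
                          float(header.get("start_time_s", 0.0)))


def write_trace_hdf5(path, trace: IntensityTrace):
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("counts", data=trace.counts, compression="gzip")
        ds.attrs["bin_width_s"] = trace.bin_width
        ds.attrs["start_time_s"] = trace.start_time


def write_series(path, series: KineticsSeries):
    _write(path, pd.DataFrame({"time": series.times, "value": series.values}),
           {"format": "kinetics_series", "observable": series.observable,
            "window_width": series.window_width, "normalized": series.normalized})


def read_series(path) -> KineticsSeries:
    df, header = _read(path)
    return KineticsSeries(df["time"].to_numpy(), df["value"].to_numpy(),
                          float(header.get("window_width", 60.0)),
                          header.get("observable", ""),
                          header.get("normalized", "False") == "True")


def write_curve(path, curve: CorrelationCurve, note: str = ""):
    df = pd.DataFrame({"lag_s": curve.lags, "G": curve.values})
    if curve.n_samples_per_lag is not None:
        df["n_samples"] = curve.n_samples_per_lag
    _write(path, df, {"format": "correlation_curve",
                      "channel_pair": f"{curve.channel_pair[0]},{curve.channel_pair[1]}",
                      "convention": "G = <FiFj>/(<Fi><Fj>) - 1 (0 at independence)",
                      "note": note})


def write_trajectories(path, trajectories):
    frames = [
        pd.DataFrame({"spot_id": tr.spot_id,
                      "time_s": tr.times,
                      "intensity": tr.intensities})
        for tr in trajectories
    ]
    _write(path, pd.concat(frames, ignore_index=True),
           {"format": "spot_trajectories_long",
            "frame_interval_s": trajectories[0].frame_interval})


def read_trajectories(path):
    df, header = _read(path)
    interval = float(header["frame_interval_s"])
    return [
        SpotTrajectory(int(spot), grp["intensity"].to_numpy(), interval)
        for spot, grp in df.groupby("spot_id")
    ]


def write_survival(path, curve: SurvivalCurve, threshold=0.10, control: str = ""):
    _write(path, pd.DataFrame({"time_s": curve.times,
                               "surviving_fraction": curve.surviving_fraction}),
           {"format": "survival_curve", "n_at_risk": curve.n_at_risk,
            "threshold": threshold, "smoothing": "3-point moving average",
            "corrected": curve.corrected, "control": control,
            "warnings": "; ".join(curve.warnings)})


def write_dnase_trace(path, trace: DnaseTrace):
    _write(path, pd.DataFrame({"time_s": trace.times, "signal": trace.signal}),
           {"format": "dnase_trace", "csm_total_nM": trace.csm_total,
            "rna_total_nM": trace.rna_total, "dna_total_nM": trace.dna_total,
            "rna_type": trace.rna_type, "calibrated": trace.calibrated})


def read_dnase_trace(path) -> DnaseTrace:
    df, header = _read(path)
    return DnaseTrace(df["time_s"].to_numpy(), df["signal"].to_numpy(),
                      csm_total=float(header.get("csm_total_nM", 0.0)),
                      rna_total=float(header.get("rna_total_nM", 0.0)),
                      dna_total=float(header.get("dna_total_nM", 0.0)),
                      rna_type=header.get("rna_type", "none"),
                      calibrated=header.get("calibrated", "False") == "True")


def write_sidecar(path, config):
    """JSON sidecar capturing all generator parameters including the seed."""
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dataclass_fields__"):
            return {f: getattr(obj, f) for f in obj.__dataclass_fields__}
        if isinstance(obj, float) and not np.isfinite(obj):
            return str(obj)
        return str(obj)

    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, default=default)
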