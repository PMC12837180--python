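"""Readers and writers for motion-capture file formats and run config.

TRC (tab-delimited marker trajectories) and MOT/STO (joint-angle time
series) follow the conventions of the common musculoskeletal-modeling
toolchains: TRC headers carry DataRate/NumFrames/Units (mm or m), MOT
headers carry nRows/nColumns/inDegrees.  Positions are stored in meters
internally regardless of file units; angles are always degrees.

All writes are deterministic: stable column ordering and fixed numeric
formatting (6 significant digits in tabular CSV reports; 10 in TRC/MOT
payloads so that write-read round trips are faithful to 1e-9).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .containers import JointAngleSeries, MarkerTrajectorySet, NormalizedCycle
from .deviation import DeviationProfile, NormativeBand

_FMT = "%.6g"          # tabular CSV outputs
_FMT_HI = "%.10g"      # TRC/MOT payloads: round-trip within 1e-9


class FileFormatError(ValueError):
    """Raised on malformed TRC/MOT content; names the offending line."""


# ---------------------------------------------------------------------------
# TRC

def write_trc(path, markers: MarkerTrajectorySet, units: str = "m") -> None:
    """Write a marker trajectory set as a TRC file.

    Invalid (masked) samples are written as blank cells, which
    ``read_trc`` restores into the validity mask.
    """
    if units not in ("m", "mm"):
        raise ValueError("units must be 'm' or 'mm'")
    scale = 1000.0 if units == "mm" else 1.0
    n_frames, n_markers = markers.positions.shape[:2]
    rate = markers.frame_rate
    with open(path, "w", newline="\n") as f:
        f.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        f.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        f.write(f"{_FMT % rate}\t{_FMT % rate}\t{n_frames}\t{n_markers}\t{units}\t"
                f"{_FMT % rate}\t1\t{n_frames}\n")
        f.write("Frame#\tTime\t" + "\t\t\t".join(markers.names) + "\t\t\n")
        f.write("\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, n_markers + 1)) + "\n")
        f.write("\n")
        for i in range(n_frames):
            cells = [str(i + 1), _FMT_HI % (i / rate)]
            for j in range(n_markers):
                if markers.valid[i, j]:
                    cells.extend(_FMT_HI % (markers.positions[i, j, k] * scale)
                                 for k in range(3))
                else:
                    cells.extend(["", "", ""])
            f.write("\t".join(cells) + "\n")


def read_trc(path) -> MarkerTrajectorySet:
    """Read a TRC file, honoring the header DataRate and Units (mm is
    converted to meters); blank cells become invalid-mask entries."""
    with open(path) as f:
        lines = f.read().splitlines()
    if len(lines) < 6:
        raise FileFormatError(f"{path}: truncated TRC header ({len(lines)} lines)")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    if len(vals) < len(keys):
        raise FileFormatError(f"{path}: line 3: header values do not match line 2 keys")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"]
    except (KeyError, ValueError) as e:
        raise FileFormatError(f"{path}: line 2-3: bad TRC header ({e})") from None
    if units not in ("m", "mm"):
        raise FileFormatError(f"{path}: line 3: unsupported Units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0

    name_cells = lines[3].split("\t")[2:]
    names = [c for c in name_cells if c.strip()]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: line 4: found {len(names)} marker names, header says {n_markers}"
        )
    expected_cols = 2 + 3 * n_markers
    positions, valid = [], []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < expected_cols:
            raise FileFormatError(
                f"{path}: line {lineno}: expected {expected_cols} columns, got {len(cells)}"
            )
        row_pos = np.zeros((n_markers, 3))
        row_val = np.ones(n_markers, dtype=bool)
        for j in range(n_markers):
            triple = cells[2 + 3 * j: 5 + 3 * j]
            if any(c.strip() == "" for c in triple):
                row_val[j] = False
            else:
                try:
                    row_pos[j] = [float(c) * scale for c in triple]
                except ValueError:
                    raise FileFormatError(
                        f"{path}: line {lineno}: non-numeric coordinate for marker "
                        f"{names[j]!r}"
                    ) from None
        positions.append(row_pos)
        valid.append(row_val)
    if not positions:
        raise FileFormatError(f"{path}: no data rows")
    return MarkerTrajectorySet(frame_rate=rate, names=names,
                               positions=np.stack(positions), valid=np.stack(valid))


# ---------------------------------------------------------------------------
# MOT / STO

_MOT_JOINT_ORDER = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion")


def write_mot(path, series: JointAngleSeries) -> None:
    """Write a joint-angle series as a MOT/STO file (angles in degrees,
    time column first, stable hip/knee/ankle column order)."""
    joints = [j for j in _MOT_JOINT_ORDER if j in series.angles]
    joints += sorted(set(series.angles) - set(joints))
    cols = ["time"] + [f"{j}_{series.side[0]}" for j in joints]
    n = len(series.time)
    with open(path, "w", newline="\n") as f:
        f.write("joint_angles\nversion=1\n")
        f.write(f"nRows={n}\nnColumns={len(cols)}\ninDegrees=yes\nendheader\n")
        f.write("\t".join(cols) + "\n")
        for i in range(n):
            row = [_FMT_HI % series.time[i]] + [_FMT_HI % series.angles[j][i] for j in joints]
            f.write("\t".join(row) + "\n")


def read_mot(path) -> JointAngleSeries:
    """Read a MOT/STO joint-angle file written by :func:`write_mot`."""
    with open(path) as f:
        lines = f.read().splitlines()
    try:
        end = next(i for i, l in enumerate(lines) if l.strip() == "endheader")
    except StopIteration:
        raise FileFormatError(f"{path}: missing 'endheader' line") from None
    header = dict(l.split("=", 1) for l in lines[1:end] if "=" in l)
    if header.get("inDegrees", "yes").strip() != "yes":
        raise FileFormatError(f"{path}: only inDegrees=yes files are supported")
    cols = lines[end + 1].split("\t")
    if cols[0] != "time":
        raise FileFormatError(f"{path}: line {end + 2}: first column must be 'time'")
    data = []
    for lineno, line in enumerate(lines[end + 2:], start=end + 3):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise FileFormatError(
                f"{path}: line {lineno}: expected {len(cols)} columns, got {len(cells)}"
            )
        data.append([float(c) for c in cells])
    arr = np.array(data)
    time = arr[:, 0]
    side = "right" if any(c.endswith("_r") for c in cols[1:]) else "left"
    angles = {c.rsplit("_", 1)[0]: arr[:, k] for k, c in enumerate(cols) if k > 0}
    frame_rate = 1.0 / float(np.median(np.diff(time)))
    return JointAngleSeries(time=time, angles=angles, frame_rate=frame_rate, side=side)


# ---------------------------------------------------------------------------
# CSV: normalized cycles, normative bands, deviation profiles

def write_cycles_csv(path, cycles: list) -> None:
    """Tidy per-cycle waveforms: station, joint, angle_deg, cycle_id, side."""
    rows = []
    for c in cycles:
        for j in sorted(c.joints):
            for s, v in zip(c.stations, c.angles[j]):
                rows.append((s, j, v, c.cycle_id, c.side))
    df = pd.DataFrame(rows, columns=["station", "joint", "angle_deg", "cycle_id", "side"])
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def read_cycles_csv(path) -> list:
    df = pd.read_csv(path)
    cycles = []
    for (cid, side), g in df.groupby(["cycle_id", "side"], sort=True):
        angles = {}
        for j, gj in g.groupby("joint"):
            gj = gj.sort_values("station")
            angles[j] = gj["angle_deg"].to_numpy()
        n = len(next(iter(angles.values())))
        cycles.append(NormalizedCycle(angles=angles, side=side, cycle_id=str(cid),
                                      n_stations=n))
    return cycles


def write_band_csv(path, band: NormativeBand) -> None:
    """Band file: joint, station, mu_deg, sigma_deg, n_subjects."""
    rows = []
    stations = np.linspace(0.0, 100.0, band.n_stations)
    for j in sorted(band.joints):
        for k, s in enumerate(stations):
            rows.append((j, s, band.mu[j][k], band.sigma[j][k], band.n_subjects))
    df = pd.DataFrame(rows, columns=["joint", "station", "mu_deg", "sigma_deg", "n_subjects"])
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def read_band_csv(path, provenance: str = "file") -> NormativeBand:
    df = pd.read_csv(path)
    mu, sigma = {}, {}
    for j, g in df.groupby("joint"):
        g = g.sort_values("station")
        mu[j] = g["mu_deg"].to_numpy()
        sigma[j] = g["sigma_deg"].to_numpy()
    n_subjects = int(df["n_subjects"].iloc[0])
    n_stations = len(next(iter(mu.values())))
    return NormativeBand(mu=mu, sigma=sigma, n_subjects=n_subjects,
                         n_stations=n_stations, provenance=provenance)


def write_deviation_csv(path, profile: DeviationProfile) -> None:
    """Per-station deviation report: joint, station, z, flagged."""
    if profile.flags is None:
        raise ValueError("flag_deviations must be applied before writing")
    rows = []
    for j in sorted(profile.joints):
        for s, z, fl in zip(profile.stations, profile.z[j], profile.flags[j]):
            rows.append((j, s, z, bool(fl)))
    df = pd.DataFrame(rows, columns=["joint", "station", "z", "flagged"])
    df.to_csv(path, index=False, float_format=_FMT, lineterminator="\n")


def write_regions_json(path, profile: DeviationProfile) -> None:
    """Structured flagged-region report: joint, start_pct, end_pct,
    phase, extreme_z (plus sub-phase labels)."""
    if profile.regions is None:
        raise ValueError("flag_deviations must be applied before writing")
    out = {"threshold": profile.threshold, "regions": []}
    for j in sorted(profile.joints):
        for r in profile.regions[j]:
            out["regions"].append({
                "joint": j, "start_pct": r.start, "end_pct": r.end,
                "phase": r.phase, "extreme_z": r.extreme_z,
                "subphases": list(r.subphases),
            })
    with open(path, "w", newline="\n") as f:
        json.dump(out, f, indent=2, sort_keys=True)
        f.write("\n")


def write_ground_truth_json(path, truth) -> None:
    """Ground-truth sidecar for a synthetic trial."""
    out = {
        "events": {
            "heel_strikes": {s: list(map(float, v)) for s, v in truth.events.heel_strikes.items()},
            "toe_offs": {s: list(map(float, v)) for s, v in truth.events.toe_offs.items()},
        },
        "spatiotemporal": {k: float(v) for k, v in truth.spatiotemporal.items()},
        "stance_fraction_pct": float(truth.stance_fraction),
    }
    with open(path, "w", newline="\n") as f:
        json.dump(out, f, indent=2, sort_keys=True)
        f.write("\n")


# ---------------------------------------------------------------------------
# Run configuration

_CONFIG_DEFAULTS = {
    "height_m": 1.70,
    "cutoff_hz": 6.0,
    "filter_order": 4,
    "threshold": 1.96,
    "stations": 101,
    "stance_end_pct": 60.0,
    "frame_rate_hz": 60.0,
    "min_stride_s": 0.4,
    "qc_max_jump_deg": 15.0,
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated analysis parameters with the pipeline defaults
    (6 Hz 4th-order filter, |Z| threshold 1.96, 101 stations)."""

    height_m: float = _CONFIG_DEFAULTS["height_m"]
    cutoff_hz: float = _CONFIG_DEFAULTS["cutoff_hz"]
    filter_order: int = _CONFIG_DEFAULTS["filter_order"]
    threshold: float = _CONFIG_DEFAULTS["threshold"]
    stations: int = _CONFIG_DEFAULTS["stations"]
    stance_end_pct: float = _CONFIG_DEFAULTS["stance_end_pct"]
    frame_rate_hz: float = _CONFIG_DEFAULTS["frame_rate_hz"]
    min_stride_s: float = _CONFIG_DEFAULTS["min_stride_s"]
    qc_max_jump_deg: float = _CONFIG_DEFAULTS["qc_max_jump_deg"]
    seed: int = _CONFIG_DEFAULTS["seed"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, applying defaults and rejecting
    unknown keys; all invalid values are reported together."""
    raw = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    raw.update(overrides or {})
    errors = []
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    for k in sorted(unknown):
        errors.append(f"unknown config key {k!r}")
    merged = {**_CONFIG_DEFAULTS, **{k: v for k, v in raw.items() if k not in unknown}}

    def check(cond, msg):
        if not cond:
            errors.append(msg)

    check(merged["height_m"] > 0, f"height_m must be > 0, got {merged['height_m']}")
    check(merged["cutoff_hz"] > 0, f"cutoff_hz must be > 0, got {merged['cutoff_hz']}")
    check(merged["cutoff_hz"] < merged["frame_rate_hz"] / 2.0,
          f"cutoff_hz {merged['cutoff_hz']} must be below the Nyquist frequency "
          f"{merged['frame_rate_hz'] / 2.0}")
    check(merged["filter_order"] >= 1, "filter_order must be >= 1")
    check(merged["threshold"] > 0, f"threshold must be > 0, got {merged['threshold']}")
    check(merged["stations"] >= 2, "stations must be >= 2")
    check(0 < merged["stance_end_pct"] < 100, "stance_end_pct must lie in (0, 100)")
    check(merged["frame_rate_hz"] > 0, "frame_rate_hz must be > 0")
    check(merged["min_stride_s"] > 0, "min_stride_s must be > 0")
    check(merged["qc_max_jump_deg"] > 0, "qc_max_jump_deg must be > 0")
    if errors:
        raise ConfigError("; ".join(errors))
    return RunConfig(**merged)
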