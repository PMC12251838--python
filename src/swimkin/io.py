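"""File formats and session configuration.

Sensor streams travel as one CSV per sensor with a mandatory unit
header line::

    # units: gyro=rad/s accel=m/s2
    t,gx,gy,gz,ax,ay,az
    0.000,...

Accepted gyro units are ``rad/s`` and ``deg/s`` (converted on read);
accel units are ``m/s2`` and ``g``.  The session configuration is a
single YAML file mapping sensor file stems to placements and carrying
the calibration window, lap metadata and threshold overrides.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusion import GRAVITY, Placement, SensorStream
from .pipeline import AnalysisOptions

__all__ = ["SessionConfig", "read_streams", "write_streams",
           "write_truth", "read_truth"]

log = logging.getLogger("swimkin")

_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]
_GYRO_FACTORS = {"rad/s": 1.0, "deg/s": np.pi / 180.0}
_ACCEL_FACTORS = {"m/s2": 1.0, "g": GRAVITY}


@dataclass
class SessionConfig:
    """One recording session's metadata and analysis settings."""

    sensors: dict[str, str]                  # file stem -> placement name
    calibration_window: tuple[float, float] = (0.5, 4.5)
    rate: float = 200.0
    lap_length: float | None = 5.0
    n_laps: int | None = None
    more_impaired: str | None = None         # "L" or "R"
    seed: int = 0
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    def __post_init__(self) -> None:
        placements = sorted(self.sensors.values())
        expected = sorted(p.value for p in Placement)
        if placements != expected:
            raise ValueError(
                "config must map all eight placements exactly once; got %s"
                % placements)
        if self.lap_length is not None and self.lap_length <= 0:
            raise ValueError("lap_length must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        opt = AnalysisOptions(**raw.pop("options", {}))
        window = tuple(raw.pop("calibration_window", (0.5, 4.5)))
        return cls(options=opt, calibration_window=window, **raw)

    def to_yaml(self, path: str | Path) -> None:
        o = self.options
        data = {
            "sensors": dict(self.sensors),
            "calibration_window": list(self.calibration_window),
            "rate": self.rate,
            "lap_length": self.lap_length,
            "n_laps": self.n_laps,
            "more_impaired": self.more_impaired,
            "seed": self.seed,
            "options": {
                "min_prominence": o.min_prominence,
                "min_period": o.min_period,
                "lowpass_cutoff": o.lowpass_cutoff,
                "beta_move": o.beta_move,
                "beta_static": o.beta_static,
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _parse_unit_header(line: str) -> tuple[float, float]:
    if not line.startswith("#"):
        raise ValueError("missing unit header line ('# units: ...')")
    fields = dict(tok.split("=") for tok in line.lstrip("#").split()
                  if "=" in tok)
    if "gyro" not in fields or "accel" not in fields:
        raise ValueError("unit header must declare gyro= and accel= units")
    try:
        return _GYRO_FACTORS[fields["gyro"]], _ACCEL_FACTORS[fields["accel"]]
    except KeyError as e:
        raise ValueError("unsupported unit %s" % e) from None


def write_streams(streams: dict[Placement, SensorStream],
                  directory: str | Path) -> None:
    """One CSV per placement, rad/s and m/s² with the unit header."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for plc, s in streams.items():
        df = pd.DataFrame(
            np.column_stack([s.t, s.gyro, s.accel]), columns=_COLUMNS)
        path = directory / ("%s.csv" % plc.value)
        with open(path, "w") as fh:
            fh.write("# units: gyro=rad/s accel=m/s2\n")
            df.to_csv(fh, index=False, float_format="%.9g")


def read_streams(directory: str | Path, config: SessionConfig,
                 max_offset: float = 0.005) -> dict[Placement, SensorStream]:
    """Read and unit-normalize all configured sensor CSVs.

    Validates the unit header, column set, per-stream gaps (via
    :class:`SensorStream`) and cross-sensor time alignment (first
    timestamps within ``max_offset`` seconds).
    """
    directory = Path(directory)
    streams: dict[Placement, SensorStream] = {}
    for stem, placement in config.sensors.items():
        path = directory / ("%s.csv" % stem)
        if not path.exists():
            raise FileNotFoundError("sensor file missing: %s" % path)
        with open(path) as fh:
            gyro_f, accel_f = _parse_unit_header(fh.readline())
            df = pd.read_csv(fh)
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError("%s: missing columns %s" % (path.name, missing))
        streams[Placement(placement)] = SensorStream(
            placement, df["t"].to_numpy(),
            df[["gx", "gy", "gz"]].to_numpy() * gyro_f,
            df[["ax", "ay", "az"]].to_numpy() * accel_f,
            config.rate)
    starts = [s.t[0] for s in streams.values()]
    if max(starts) - min(starts) > max_offset:
        raise ValueError("cross-sensor time offset %.4f s exceeds %.3f s"
                         % (max(starts) - min(starts), max_offset))
    log.info("read %d streams from %s", len(streams), directory)
    return streams


def write_truth(truth: dict, path: str | Path) -> None:
    """Ground-truth side-file (JSON) accompanying simulated streams."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, dict):
            return o
        raise TypeError(type(o))

    clean = {str(k): v for k, v in truth.items()}
    if "rom" in clean:
        clean["rom"] = {"%s:%s" % k: v for k, v in clean["rom"].items()}
    Path(path).write_text(json.dumps(clean, default=default, indent=1))


def read_truth(path: str | Path) -> dict:
    truth = json.loads(Path(path).read_text())
    if "rom" in truth:
        truth["rom"] = {tuple(k.split(":")): v
                        for k, v in truth["rom"].items()}
    return truth
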