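"""File I/O: internal trace/trial CSVs and a minimal EyeLink-ASC-like dialect.

Internal formats are plain CSV with a versioned comment header so that a
write -> read round trip is lossless.  The ASC-like dialect mirrors the
text layout of eye-tracker exports: one sample per line
(``<t>\\t<x>\\t<y>\\t...``), ``MSG <t> <label>`` marker lines, and ``.``
fields for blink gaps (read back as flagged NaNs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pursuit import EyeTrace

SCHEMA_VERSION = "gazebias-v1"

__all__ = ["read_trace", "write_trace", "read_trials", "write_trials",
           "read_asc", "write_asc", "SCHEMA_VERSION"]


def write_trace(path, trace: EyeTrace, trial_id: int = 0) -> None:
    """Internal trace CSV: t_ms, x_deg, y_deg, trial_id (+ marker comments)."""
    with open(path, "w") as f:
        f.write(f"# schema: {SCHEMA_VERSION} trace\n")
        f.write("# units: t_ms=ms x_deg=deg y_deg=deg\n")
        for name, tm in trace.markers.items():
            f.write(f"# marker: {name}={float(tm)!r}\n")
        f.write("t_ms,x_deg,y_deg,trial_id\n")
        for t, x, y in zip(trace.t, trace.x, trace.y):
            f.write(f"{float(t)!r},{float(x)!r},{float(y)!r},{trial_id}\n")


def read_trace(path) -> EyeTrace:
    """Read the internal trace CSV back into an EyeTrace."""
    markers = {}
    header_lines = 0
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.startswith("# marker:"):
                name, _, val = line[len("# marker:"):].strip().partition("=")
                markers[name] = float(val)
            elif line.startswith("# schema:") and SCHEMA_VERSION not in line:
                raise ValueError(f"unknown schema in {path}: {line.strip()}")
    df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    required = {"t_ms", "x_deg", "y_deg"}
    if not required <= set(df.columns):
        raise ValueError(f"malformed trace file {path}: columns {list(df.columns)}")
    return EyeTrace(t=df.t_ms.to_numpy(), x=df.x_deg.to_numpy(),
                    y=df.y_deg.to_numpy(), markers=markers)


def write_trials(path, trials: pd.DataFrame) -> None:
    """Trial table CSV with a versioned header line."""
    with open(path, "w") as f:
        f.write(f"# schema: {SCHEMA_VERSION} trials\n")
        trials.to_csv(f, index=False)


def read_trials(path) -> pd.DataFrame:
    with open(path) as f:
        first = f.readline()
        if not first.startswith("#") or SCHEMA_VERSION not in first:
            raise ValueError(f"missing or unknown schema header in {path}")
        return pd.read_csv(f)


def write_asc(path, trace: EyeTrace) -> None:
    """Minimal EyeLink-ASC-like text dialect: SAMPLES + MSG lines."""
    with open(path, "w") as f:
        f.write("** gazebias ASC-like export\n")
        f.write("SAMPLES\tGAZE\tLEFT\tRATE\t"
                f"{1000.0 / trace.dt:.2f}\n")
        events = sorted(trace.markers.items(), key=lambda kv: kv[1])
        ei = 0
        for t, x, y in zip(trace.t, trace.x, trace.y):
            while ei < len(events) and events[ei][1] <= t:
                f.write(f"MSG\t{events[ei][1]:g} {events[ei][0]}\n")
                ei += 1
            if np.isnan(x) or np.isnan(y):
                f.write(f"{t:g}\t.\t.\t0.0\n")
            else:
                f.write(f"{t:g}\t{x:.4f}\t{y:.4f}\t0.0\n")
        for name, tm in events[ei:]:
            f.write(f"MSG\t{tm:g} {name}\n")
        f.write("END\n")


def read_asc(path) -> EyeTrace:
    """Read the ASC-like dialect; blink gaps ('.') become NaN samples."""
    ts, xs, ys = [], [], []
    markers = {}
    saw_end = False
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("**") or line.startswith("SAMPLES"):
                continue
            if line.startswith("MSG"):
                try:
                    _, rest = line.split("\t", 1)
                    t_str, label = rest.split(" ", 1)
                    markers[label.strip()] = float(t_str)
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: malformed MSG line") from e
                continue
            if line == "END":
                saw_end = True
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed sample line {line!r}")
            try:
                ts.append(float(parts[0]))
                xs.append(np.nan if parts[1] == "." else float(parts[1]))
                ys.append(np.nan if parts[2] == "." else float(parts[2]))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed sample line {line!r}") from e
    if not saw_end:
        raise ValueError(f"{path}: truncated file (missing END line)")
    if not ts:
        raise ValueError(f"{path}: no samples")
    return EyeTrace(t=np.asarray(ts), x=np.asarray(xs), y=np.asarray(ys),
                    markers=markers)
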