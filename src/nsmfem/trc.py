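"""Reading and writing marker trajectories (TRC) and force-profile tables.

TRC is the tab-separated motion-capture trajectory format used by most
marker-based gait tools: a five-line header carrying the sample rate and
marker names followed by one row per frame of ``Frame# Time X1 Y1 Z1 ...``.
A plain-CSV fallback (``time`` plus ``<marker>_x/_y/_z`` columns) is
accepted as well.  Units are millimetres throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_trc",
    "read_trc",
    "read_marker_csv",
    "write_events_csv",
    "read_events_csv",
    "profiles_to_frame",
    "write_profiles_csv",
]


def write_trc(path: str | Path, times: np.ndarray, landmarks: dict[str, np.ndarray]) -> None:
    """Write marker trajectories as a TRC file (units mm)."""
    path = Path(path)
    times = np.asarray(times, dtype=float)
    names = list(landmarks)
    n_frames = len(times)
    rate = 1.0 / np.median(np.diff(times)) if n_frames > 1 else 0.0

    header = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:.1f}\t{rate:.1f}\t{n_frames}\t{len(names)}\tmm\t{rate:.1f}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1)),
        "",
    ]
    rows = []
    for k in range(n_frames):
        cells = [str(k + 1), f"{times[k]:.6f}"]
        for name in names:
            cells.extend(f"{c:.6f}" for c in landmarks[name][k])
        rows.append("\t".join(cells))
    path.write_text("\n".join(header + rows) + "\n")


def read_trc(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a TRC file; returns (times, marker -> (n, 3) trajectory)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: too short to be a TRC file")
    names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    data = np.array([[float(c) for c in row.split("\t") if c.strip() != ""] for row in data_rows])
    expected = 2 + 3 * len(names)
    if data.shape[1] != expected:
        raise ValueError(
            f"{path}: expected {expected} columns for {len(names)} markers, got {data.shape[1]}"
        )
    times = data[:, 1]
    landmarks = {
        name: data[:, 2 + 3 * i : 5 + 3 * i] for i, name in enumerate(names)
    }
    return times, landmarks


def read_marker_csv(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """CSV fallback: a ``time`` column plus ``<marker>_x/_y/_z`` triplets."""
    table = pd.read_csv(path)
    if "time" not in table.columns:
        raise ValueError(f"{path}: marker CSV needs a 'time' column")
    names = sorted({c[:-2] for c in table.columns if c.endswith(("_x", "_y", "_z"))})
    landmarks = {}
    for name in names:
        cols = [f"{name}_x", f"{name}_y", f"{name}_z"]
        if not all(c in table.columns for c in cols):
            raise ValueError(f"{path}: marker {name!r} is missing one of {cols}")
        landmarks[name] = table[cols].to_numpy(dtype=float)
    return table["time"].to_numpy(dtype=float), landmarks


def write_events_csv(path: str | Path, foot_strikes: dict[str, np.ndarray]) -> None:
    rows = [
        {"side": side, "time_s": float(t)}
        for side, events in foot_strikes.items()
        for t in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> dict[str, np.ndarray]:
    table = pd.read_csv(path)
    return {
        side: np.sort(group["time_s"].to_numpy(dtype=float))
        for side, group in table.groupby("side")
    }


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Long-format table (muscle, cycle_pct, active, passive, offset_pct)."""
    rows = []
    for name, prof in profiles.items():
        for pct, a, p in zip(prof.grid, prof.active, prof.passive):
            rows.append(
                {
                    "muscle": name,
                    "cycle_pct": pct,
                    "active": a,
                    "passive": p,
                    "offset_pct": prof.applied_offset_pct,
                }
            )
    return pd.DataFrame(rows)


def write_profiles_csv(path: str | Path, profiles: dict) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)
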