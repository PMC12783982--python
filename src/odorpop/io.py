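"""Session-bundle reading and writing.

A bundle is a directory of comma-delimited tables plus a JSON manifest:

    units.csv   unit_id, tetrode_id, session_id, genotype, region
    spikes.csv  unit_id, spike_time_s
    trials.csv  trial_id, odour_carbon, onset_s, offset_s
    manifest.json  format_version, session metadata, duration, seed/config hash

Times are stored in seconds at 10 µs precision with deterministic column
order, so identical sessions produce byte-identical bundles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RecordingSession, Unit

FORMAT_VERSION = 1
VALID_CARBONS = set(range(3, 9))


class BundleError(ValueError):
    pass


class ReferentialIntegrityError(BundleError):
    pass


def write_session_bundle(session: RecordingSession, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    units = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "tetrode_id": [u.tetrode_id for u in session.units],
            "session_id": session.session_id,
            "genotype": session.genotype,
            "region": session.region,
        }
    )
    spikes = pd.DataFrame(
        {
            "unit_id": np.repeat(
                [u.unit_id for u in session.units],
                [u.spike_times.size for u in session.units],
            ),
            "spike_time_s": np.concatenate(
                [u.spike_times for u in session.units] or [np.empty(0)]
            ),
        }
    )
    trials = session.trials[["trial_id", "odour_carbon", "onset_s", "offset_s"]]
    units.to_csv(path / "units.csv", index=False)
    spikes.to_csv(path / "spikes.csv", index=False, float_format="%.5f")
    trials.to_csv(path / "trials.csv", index=False, float_format="%.5f")
    manifest = {
        "format_version": FORMAT_VERSION,
        "session_id": session.session_id,
        "genotype": session.genotype,
        "region": session.region,
        "duration": round(session.duration, 5),
        **{k: session.meta[k] for k in sorted(session.meta)},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def read_session_bundle(path) -> RecordingSession:
    path = Path(path)
    for name in ("units.csv", "spikes.csv", "trials.csv", "manifest.json"):
        if not (path / name).exists():
            raise BundleError(f"missing bundle file {name} in {path}")
    manifest = json.loads((path / "manifest.json").read_text())
    units_df = pd.read_csv(path / "units.csv", dtype={"unit_id": str})
    spikes_df = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
    trials = pd.read_csv(path / "trials.csv")

    expected = {"unit_id", "tetrode_id", "session_id", "genotype", "region"}
    if set(units_df.columns) != expected:
        raise BundleError(f"units.csv columns {list(units_df.columns)} != {sorted(expected)}")
    if units_df["unit_id"].duplicated().any():
        raise BundleError("duplicate unit_id in units.csv")

    bad = set(trials["odour_carbon"]) - VALID_CARBONS
    if bad:
        rows = trials.index[trials["odour_carbon"].isin(bad)].tolist()
        raise BundleError(f"invalid odour carbon(s) {sorted(bad)} at row(s) {rows}")

    known = set(units_df["unit_id"])
    dangling = set(spikes_df["unit_id"]) - known
    if dangling:
        raise ReferentialIntegrityError(
            f"spikes reference unknown unit(s): {sorted(dangling)}"
        )

    units = []
    grouped = dict(list(spikes_df.groupby("unit_id")["spike_time_s"]))
    for _, row in units_df.iterrows():
        times = grouped.get(row["unit_id"])
        times = np.sort(times.to_numpy()) if times is not None else np.empty(0)
        if times.size > 1 and np.any(np.diff(times) < 0):  # pragma: no cover
            raise BundleError(f"non-monotone spike times for unit {row['unit_id']}")
        units.append(Unit(row["unit_id"], int(row["tetrode_id"]), times))

    duration = float(manifest.get("duration") or
                     (trials["offset_s"].max() + 5.0))
    meta = {k: v for k, v in manifest.items()
            if k not in ("format_version", "session_id", "genotype", "region", "duration")}
    return RecordingSession(
        session_id=manifest["session_id"],
        genotype=manifest["genotype"],
        region=manifest["region"],
        units=units,
        trials=trials,
        duration=duration,
        meta=meta,
    )


def write_raw_traces(traces: np.ndarray, fs: float, path) -> Path:
    """Flat binary float32 channel-major trace plus a small text header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traces = np.asarray(traces, dtype=np.float32)
    traces.tofile(path)
    header = path.with_suffix(path.suffix + ".hdr")
    header.write_text(
        json.dumps({"fs": fs, "n_channels": traces.shape[0], "dtype": "float32",
                    "order": "channel-major"})
    )
    return path


def read_raw_traces(path):
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".hdr").read_text())
    flat = np.fromfile(path, dtype=np.float32)
    n_ch = int(header["n_channels"])
    return flat.reshape(n_ch, -1), float(header["fs"])
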