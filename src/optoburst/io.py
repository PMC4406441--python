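"""On-disk formats: recordings as CSV with a JSON sidecar, reports as JSON.

A recording ``<name>.csv`` has the header
``time_ms,F_A,mask_A,F_B,mask_B``; masked fluorescence values are written
as empty fields (mask columns are 0/1). The sidecar ``<name>.json`` stores
the sampling rate, the stimulation protocol and provenance. A batch
manifest is a CSV with one device recording per row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List

import pandas as pd

from .config import StimulationProtocol
from .errors import FormatError
from .recording import GroundTruthBurst, LineScanRecording, PopulationActivity

RECORDING_COLUMNS = ["time_ms", "F_A", "mask_A", "F_B", "mask_B"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: LineScanRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus its JSON sidecar; returns the CSV path."""
    path = Path(path)
    frame = pd.DataFrame(
        {
            "time_ms": recording.time_ms,
            "F_A": recording.trace_A,
            "mask_A": recording.mask_A.astype(int),
            "F_B": recording.trace_B,
            "mask_B": recording.mask_B.astype(int),
        }
    )
    # %.17g guarantees float64 round-trips bit-exactly through the text form
    frame.to_csv(path, index=False, float_format="%.17g", na_rep="")
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "n_samples": len(recording.time_ms),
        "protocol": recording.protocol.model_dump(),
        "provenance": recording.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> LineScanRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"missing sidecar JSON for {path.name}")
    sidecar = json.loads(sidecar_file.read_text())
    # round_trip parsing: the default fast parser can be 1 ulp off
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RECORDING_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    if len(frame) != sidecar.get("n_samples"):
        raise FormatError(
            f"{path.name}: n_samples in sidecar ({sidecar.get('n_samples')}) "
            f"differs from the CSV ({len(frame)})"
        )
    mask_a = frame["mask_A"].to_numpy().astype(bool)
    mask_b = frame["mask_B"].to_numpy().astype(bool)
    return LineScanRecording(
        sampling_rate=float(sidecar["sampling_rate"]),
        time_ms=frame["time_ms"].to_numpy(dtype=float),
        trace_A=frame["F_A"].to_numpy(dtype=float),
        trace_B=frame["F_B"].to_numpy(dtype=float),
        mask_A=mask_a,
        mask_B=mask_b,
        protocol=StimulationProtocol.model_validate(sidecar["protocol"]),
        provenance=sidecar.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(activity: PopulationActivity, path: str | Path) -> Path:
    """Write the ground-truth burst list as JSON."""
    path = Path(path)
    payload = [dataclasses.asdict(b) for b in activity.bursts]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> List[GroundTruthBurst]:
    return [GroundTruthBurst(**d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# burst-event and rate exports
# ---------------------------------------------------------------------------

def write_burst_events(events, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["device_id", "recording", "geometry", "cnqx_um"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a batch manifest CSV (device_id, recording, geometry, cnqx_um)."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    bad = set(frame["geometry"]) - {"straight", "diode"}
    if bad:
        raise FormatError(f"{path.name}: unknown geometry label(s) {sorted(bad)}")
    return frame


def write_report(report, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    return path
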