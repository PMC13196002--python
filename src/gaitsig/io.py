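"""File formats, configuration and provenance.

All artefacts are plain text — CSV/TSV for tables, JSON for structured
results and provenance — so runs diff cleanly and re-runs with the same
configuration reproduce result files byte for byte.  Proprietary
motion-capture containers are out of scope; real exports can be
substituted for the simulator's files because the schemas are shared
(an import adapter would only need to produce these CSVs).

Waveform long format (exact header)::

    id,joint,plane,side,stride,node,angle_deg

with every curve carrying the complete node set 0..100.  Floats are
written with 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import AngleWaveformSet

__all__ = [
    "write_waveform_table",
    "read_waveform_table",
    "write_participants_table",
    "read_participants_table",
    "RunConfig",
    "write_provenance",
    "verify_provenance",
]

WAVEFORM_COLUMNS = ["id", "joint", "plane", "side", "stride", "node", "angle_deg"]
PLANES = {"sagittal", "frontal", "transverse"}
FLOAT_FORMAT = "%.6g"


def write_waveform_table(waveforms: dict, path) -> None:
    """Write {participant id -> AngleWaveformSet} as long-format CSV."""
    frames = []
    for pid in sorted(waveforms):
        ws = waveforms[pid]
        for (joint, plane, side, stride), curve in sorted(ws.curves.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "id": pid, "joint": joint, "plane": plane, "side": side,
                        "stride": stride, "node": np.arange(curve.size),
                        "angle_deg": curve,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_waveform_table(path, node_count: int = 101) -> dict:
    """Read a long-format waveform CSV back into AngleWaveformSets.

    Validates the exact header, known plane labels, and node
    completeness (0..node_count-1 per curve), naming the offending curve
    on failure.
    """
    df = pd.read_csv(path)
    if list(df.columns) != WAVEFORM_COLUMNS:
        raise ValueError(
            f"waveform table {path}: header must be {','.join(WAVEFORM_COLUMNS)}"
        )
    bad_planes = set(df["plane"].unique()) - PLANES
    if bad_planes:
        raise ValueError(f"waveform table {path}: unknown plane labels {sorted(bad_planes)}")
    out: dict[str, AngleWaveformSet] = {}
    expected = np.arange(node_count)
    for pid, sub in df.groupby("id", sort=True):
        curves = {}
        for key, curve_df in sub.groupby(["joint", "plane", "side", "stride"], sort=True):
            nodes = curve_df["node"].to_numpy()
            if nodes.size != node_count or not np.array_equal(np.sort(nodes), expected):
                raise ValueError(
                    f"waveform table {path}: incomplete nodes for curve "
                    f"(id={pid}, joint={key[0]}, plane={key[1]}, side={key[2]}, "
                    f"stride={key[3]})"
                )
            curves[tuple(key)] = curve_df.sort_values("node")["angle_deg"].to_numpy()
        out[pid] = AngleWaveformSet(participant_id=pid, curves=curves, node_count=node_count)
    return out


def write_participants_table(participants, path) -> None:
    rows = [dataclasses.asdict(p) for p in participants]
    df = pd.DataFrame(rows).drop(columns=["index"])
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_participants_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "group", "sex", "age", "mass", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants table {path}: missing columns {sorted(missing)}")
    return df


@dataclasses.dataclass
class RunConfig:
    """Pipeline run parameters (YAML/JSON-serialisable)."""

    seed: int = 0
    out_dir: str = "gaitsig_run"
    # simulate
    n_cases: int = 23
    n_controls: int = 18
    effect_amplitude_scale: float = 1.0
    # spm
    alpha: float = 0.05
    min_extent_pct: float = 5.0
    # train
    folds: int = 5
    repeats: int = 10
    consensus: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(out_dir, config: RunConfig, inputs=()) -> Path:
    """Record config snapshot, seed, version, input digests and timestamp.

    Result files are byte-reproducible under a fixed config; the
    provenance record itself carries the (non-reproducible) wall-clock
    timestamp.
    """
    from . import __version__

    record = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(out_dir) / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path


def verify_provenance(path) -> bool:
    """Re-digest the recorded inputs; True iff all digests still match."""
    record = json.loads(Path(path).read_text())
    return all(_sha256(p) == d for p, d in record["inputs"].items())
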