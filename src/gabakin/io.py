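"""File formats, deterministic seeding and run manifests.

On-disk conventions: traces are dot-decimal TSV with unit-suffixed column
names (``time_s``, ``popen`` or ``current_pA``, one column per state with
full output), dwell lists are CSV (``index, class, state, duration_ms``),
fit results and truth sidecars are JSON.  Time columns are absolute from
protocol start.  All randomness flows from one user seed through
``child_seed``.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dwell import DwellSequence
from .simulate import CurrentTrace, OccupancyTrace

__all__ = [
    "child_seed",
    "read_trace",
    "write_trace",
    "read_dwells",
    "write_dwells",
    "write_json",
    "RunManifest",
]

_PRECISION = "%.12g"


def child_seed(seed: int, *keys: str) -> int:
    """Derive a stream-specific 31-bit seed from the master seed.

    The rule: SeedSequence([seed, crc32(key), ...]) -> first state word,
    reduced mod 2^31 - 1.  Deterministic and documented, so every stage
    of a pipeline run can be reproduced in isolation.
    """
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31 - 1))


def _check_dialect(text_head: str, path) -> None:
    for token in text_head.replace("\t", " ").split():
        if "," in token:
            raise ValueError(
                f"{path}: comma decimals (or comma separators) detected; "
                "files must use dot-decimal TSV"
            )


def write_trace(path, trace: OccupancyTrace | CurrentTrace,
                full: bool = False) -> None:
    """Write a trace as TSV; ``full`` adds one occupancy column per state."""
    path = Path(path)
    if isinstance(trace, CurrentTrace):
        cols = {"time_s": trace.time_s, "current_pA": trace.current_pa}
    else:
        cols = {"time_s": trace.time_s, "popen": trace.popen}
        if full:
            for j, name in enumerate(trace.state_names):
                cols[f"occ_{name}"] = trace.occupancy[:, j]
    frame = pd.DataFrame(cols)
    frame.to_csv(path, sep="\t", index=False, float_format=_PRECISION)


def read_trace(path) -> pd.DataFrame:
    """Read a TSV trace; validates header, dialect and time monotonicity."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if not head or not head.split("\t")[0].strip().startswith("time_s"):
        raise ValueError(f"{path}: line 1 must be a header starting with 'time_s'")
    with open(path) as fh:
        fh.readline()
        _check_dialect(fh.read(4096), path)
    frame = pd.read_csv(path, sep="\t")
    t = frame["time_s"].to_numpy()
    if not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    return frame


def write_dwells(path, dwells: DwellSequence, state_names=None) -> None:
    path = Path(path)
    alt = dwells.alternating()
    labels = ["open" if o else "shut" for o in alt.open]
    if state_names is not None:
        states = [state_names[s] if 0 <= s < len(state_names) else ""
                  for s in alt.states]
    else:
        states = [str(s) for s in alt.states]
    frame = pd.DataFrame({
        "index": np.arange(len(alt)),
        "class": labels,
        "state": states,
        "duration_ms": alt.durations_ms,
    })
    frame.to_csv(path, index=False, float_format=_PRECISION)


def read_dwells(path) -> DwellSequence:
    frame = pd.read_csv(path)
    required = {"class", "duration_ms"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: dwell CSV needs columns {sorted(required)}")
    return DwellSequence(
        durations_ms=frame["duration_ms"].to_numpy(dtype=float),
        open=(frame["class"] == "open").to_numpy(),
        states=np.full(len(frame), -1, dtype=int),
    )


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


@dataclass
class RunManifest:
    """Audit record emitted once per CLI run."""

    command: str
    seed: int | None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    config_hash: str = ""
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, command: str, seed: int | None, config: dict | None = None,
               inputs=(), outputs=()) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config or {}, sort_keys=True, default=_jsonify)
        return cls(
            command=command,
            seed=seed,
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            config_hash=hashlib.sha256(blob.encode()).hexdigest()[:16],
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def write(self, path) -> None:
        write_json(path, self.__dict__)
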