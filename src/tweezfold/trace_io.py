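"""Plain-text trajectory and result-table formats.

Traces are tab-separated values with a ``#``-prefixed ``key: value`` header
(format version, trace kind, construct, protocol metadata). Units are fixed
by the format: seconds, nanometres, piconewtons. Two kinds exist:

* ``.fec.tsv`` — force-ramp (force-extension) cycles: columns
  time, extension, force, segment (stretch|relax)
* ``.fct.tsv`` — force-clamp traces: columns time, extension

Titration counts travel as ``.counts.tsv`` with columns
conc_nM, n_A0B0, n_A1B0, n_A0B1, n_A1B1. Result tables are written with a
JSON manifest listing file names and SHA-256 digests, so re-runs can be
diffed by content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "ForceRampTrace",
    "ForceClampTrace",
    "read_trace",
    "write_trace",
    "read_counts",
    "write_counts",
    "write_results",
    "SEGMENT_STRETCH",
    "SEGMENT_RELAX",
]

FORMAT_VERSION = 1
SEGMENT_STRETCH = 0
SEGMENT_RELAX = 1
_SEGMENT_NAMES = {SEGMENT_STRETCH: "stretch", SEGMENT_RELAX: "relax"}
_SEGMENT_CODES = {v: k for k, v in _SEGMENT_NAMES.items()}

COUNTS_COLUMNS = ["conc_nM", "n_A0B0", "n_A1B0", "n_A0B1", "n_A1B1"]


def _check_time_axis(time: np.ndarray, kind: str) -> None:
    if time.size < 2:
        return
    dt = np.diff(time)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"{kind}: time not strictly increasing at sample {bad[0] + 1}"
        )
    # uniform grid within 1 ppm of the median spacing
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 1e-6 * med + 1e-12:
        off = int(np.argmax(np.abs(dt - med)))
        raise ValidationError(
            f"{kind}: non-uniform sample spacing at sample {off + 1}"
        )


@dataclass
class ForceRampTrace:
    """One pulling cycle: stretch then relax at constant trap velocity."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    segment: np.ndarray  # int8, SEGMENT_STRETCH / SEGMENT_RELAX
    cycle_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype=np.int8)
        n = self.time.size
        if not (self.extension.size == self.force.size == self.segment.size == n):
            raise ValidationError("force-ramp trace arrays must have equal length")
        _check_time_axis(self.time, "force_ramp")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    def stretch(self) -> "ForceRampTrace":
        """View of the stretch segment only (as a new trace)."""
        m = self.segment == SEGMENT_STRETCH
        return ForceRampTrace(
            self.time[m], self.extension[m], self.force[m],
            self.segment[m], self.cycle_id, dict(self.meta),
        )


@dataclass
class ForceClampTrace:
    """Extension vs time while force is held at a constant setpoint."""

    time: np.ndarray
    extension: np.ndarray
    setpoint_force: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.size != self.extension.size:
            raise ValidationError("force-clamp trace arrays must have equal length")
        if self.setpoint_force <= 0:
            raise ValidationError("setpoint force must be positive")
        _check_time_axis(self.time, "force_clamp")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


# ---------------------------------------------------------------------------
# trace files
# ---------------------------------------------------------------------------

def _format_meta_value(v):
    if isinstance(v, (float, np.floating)):
        return f"{float(v):.17g}"
    return str(v)


def write_trace(trace, path) -> Path:
    """Write a ramp or clamp trace; returns the path written."""
    path = Path(path)
    lines = ["# tweezfold-trace", f"# format_version: {FORMAT_VERSION}"]
    if isinstance(trace, ForceRampTrace):
        lines.append("# kind: force_ramp")
        lines.append(f"# cycle_id: {trace.cycle_id}")
    elif isinstance(trace, ForceClampTrace):
        lines.append("# kind: force_clamp")
        lines.append(f"# setpoint_force: {float(trace.setpoint_force):.17g}")
    else:
        raise SchemaError(f"cannot write object of type {type(trace).__name__}")
    for k in sorted(trace.meta):
        lines.append(f"# {k}: {_format_meta_value(trace.meta[k])}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        if isinstance(trace, ForceRampTrace):
            fh.write("time\textension\tforce\tsegment\n")
            for t, x, f, s in zip(
                trace.time, trace.extension, trace.force, trace.segment
            ):
                fh.write(
                    f"{t:.17g}\t{x:.17g}\t{f:.17g}\t{_SEGMENT_NAMES[int(s)]}\n"
                )
        else:
            fh.write("time\textension\n")
            for t, x in zip(trace.time, trace.extension):
                fh.write(f"{t:.17g}\t{x:.17g}\n")
    return path


def _parse_header(path: Path):
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# tweezfold-trace"):
            raise FormatError(f"{path}: missing 'tweezfold-trace' header")
        n_header += 1
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" not in body:
                raise FormatError(f"{path}: bad header line {n_header}: {line!r}")
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    if "kind" not in meta or "format_version" not in meta:
        raise FormatError(f"{path}: header must declare kind and format_version")
    return meta, n_header


def read_trace(path):
    """Read a ``.fec.tsv`` / ``.fct.tsv`` file back into a trace object.

    Malformed rows and invariant violations raise ValidationError naming
    the 1-based file line; a missing/invalid header raises FormatError.
    """
    path = Path(path)
    meta, n_header = _parse_header(path)
    kind = meta.pop("kind")
    meta.pop("format_version")
    df = pd.read_csv(
        path, sep="\t", comment="#", header=0, float_precision="round_trip"
    )
    first_data_line = n_header + 2  # header lines + column row, 1-based

    def _line(i: int) -> int:
        return first_data_line + int(i)

    if kind == "force_ramp":
        expected = ["time", "extension", "force", "segment"]
        if list(df.columns) != expected:
            raise FormatError(f"{path}: columns {list(df.columns)} != {expected}")
        for col in ("time", "extension", "force"):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-numeric {col} at line {_line(bad[0])}"
                )
        badseg = df.index[~df["segment"].isin(_SEGMENT_CODES)]
        if len(badseg):
            raise ValidationError(
                f"{path}: unknown segment at line {_line(badseg[0])}"
            )
        t = df["time"].to_numpy(float)
        dt = np.diff(t)
        dup = np.nonzero(dt <= 0)[0]
        if dup.size:
            raise ValidationError(
                f"{path}: time not strictly increasing at line {_line(dup[0] + 1)}"
            )
        cycle_id = int(meta.pop("cycle_id", 0))
        seg = df["segment"].map(_SEGMENT_CODES).to_numpy(np.int8)
        return ForceRampTrace(
            t, df["extension"].to_numpy(float), df["force"].to_numpy(float),
            seg, cycle_id, meta,
        )
    if kind == "force_clamp":
        expected = ["time", "extension"]
        if list(df.columns) != expected:
            raise FormatError(f"{path}: columns {list(df.columns)} != {expected}")
        if "setpoint_force" not in meta:
            raise FormatError(f"{path}: clamp header missing setpoint_force")
        t = df["time"].to_numpy(float)
        dup = np.nonzero(np.diff(t) <= 0)[0]
        if dup.size:
            raise ValidationError(
                f"{path}: time not strictly increasing at line {_line(dup[0] + 1)}"
            )
        setpoint = float(meta.pop("setpoint_force"))
        # a "clamp" whose recorded setpoint column drifts is not a clamp;
        # optional per-sample force column tolerated in meta-extended files
        if "force" in df.columns and np.ptp(df["force"].to_numpy(float)) > 0.1:
            raise ValidationError(f"{path}: setpoint drifts by more than 0.1 pN")
        return ForceClampTrace(t, df["extension"].to_numpy(float), setpoint, meta)
    raise FormatError(f"{path}: unknown trace kind {kind!r}")


# ---------------------------------------------------------------------------
# titration counts
# ---------------------------------------------------------------------------

def write_counts(df: pd.DataFrame, path) -> Path:
    """Write per-concentration species counts (columns COUNTS_COLUMNS)."""
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"counts table missing column {missing[0]!r}")
    path = Path(path)
    df[COUNTS_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column {missing[0]!r}")
    cnt = df[COUNTS_COLUMNS[1:]].to_numpy()
    if (cnt < 0).any():
        raise ValidationError(f"{path}: negative count")
    if (df["conc_nM"] < 0).any():
        raise ValidationError(f"{path}: negative concentration")
    return df[COUNTS_COLUMNS]


# ---------------------------------------------------------------------------
# result tables + manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(tables: dict, path, schemas: dict | None = None) -> dict:
    """Write result DataFrames as TSV plus a JSON manifest.

    Column order and float formatting are deterministic, so identical
    records yield identical digests. ``schemas`` optionally maps table
    name -> required columns; a missing column raises SchemaError naming it.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(tables):
        df = tables[name]
        if schemas and name in schemas:
            missing = [c for c in schemas[name] if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} missing field {missing[0]!r}")
        fname = f"{name}.tsv"
        fpath = outdir / fname
        df = df[sorted(df.columns)] if schemas is None or name not in schemas else df[
            list(schemas[name]) + sorted(c for c in df.columns if c not in schemas[name])
        ]
        df.to_csv(fpath, sep="\t", index=False, float_format="%.10g")
        entries.append({"file": fname, "sha256": _sha256(fpath), "rows": int(len(df))})
    manifest = {"format_version": FORMAT_VERSION, "files": entries}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
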