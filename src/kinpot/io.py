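"""CSV/JSON/YAML readers and writers and the run manifest.

File conventions: comma-separated values, '.' decimal separator, SI
units (s, V, M) everywhere, and '#'-prefixed metadata header lines
(``# key: value``).  Numbers are written with 12 significant digits so
that a write/read round trip is lossless at test tolerance.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import __version__
from .electrochem import ElectrodeModel, FerroFerriCell
from .exceptions import InputError
from .kinetics import AntioxidantSpec, RateParameters
from .rate_constant import ConcentrationSeries
from .synthetic import ExperimentConfig
from .trace import PotentialTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_series",
    "write_series",
    "load_config",
    "RunManifest",
]

_FMT = "%.12e"


def _parse_file(path) -> tuple[dict, list[tuple[int, list[str]]]]:
    """Split a CSV file into metadata dict and (line_no, fields) rows."""
    meta: dict = {}
    rows: list[tuple[int, list[str]]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                header_seen = True  # column header row
                continue
            rows.append((lineno, [f.strip() for f in line.split(",")]))
    return meta, rows


def _parse_columns(path, n_cols: int) -> tuple[dict, np.ndarray]:
    meta, rows = _parse_file(path)
    if not rows:
        raise InputError(f"{path}: no data rows")
    data = np.empty((len(rows), n_cols))
    for i, (lineno, fields) in enumerate(rows):
        if len(fields) != n_cols:
            raise InputError(
                f"{path}:{lineno}: expected {n_cols} comma-separated values, "
                f"got {len(fields)}"
            )
        try:
            data[i] = [float(f) for f in fields]
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: malformed number ({exc})") from None
    return meta, data


def write_trace(trace: PotentialTrace, path) -> None:
    """Write a potential trace: metadata header plus (t_s, E_V) rows."""
    meta = {"t_add_s": trace.t_add}
    truth = trace.meta.get("truth")
    if truth is not None:
        meta["seed"] = truth.get("seed")
        meta["sampling_hz"] = truth.get("sampling_hz")
    with open(path, "w") as fh:
        for k, v in meta.items():
            if v is not None:
                fh.write(f"# {k}: {v}\n")
        fh.write("t_s,E_V\n")
        for t, e in zip(trace.t, trace.e):
            fh.write(f"{_FMT % t},{_FMT % e}\n")


def read_trace(path, t_add: float | None = None) -> PotentialTrace:
    """Read a potential trace CSV; ``t_add`` may override the metadata."""
    meta, data = _parse_columns(path, 2)
    if t_add is None:
        if "t_add_s" not in meta:
            raise InputError(
                f"{path}: missing 't_add_s' metadata (and no t_add override given)"
            )
        t_add = float(meta["t_add_s"])
    t = data[:, 0]
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # data rows start after metadata+header; recover the file line
        n_head = sum(1 for line in open(path) if line.strip().startswith("#")) + 1
        raise InputError(
            f"{path}: non-increasing time at data row {bad[0] + 2} "
            f"(file line {n_head + bad[0] + 2})"
        )
    return PotentialTrace(t=t, e=data[:, 1], t_add=t_add, meta={"file_meta": meta})


def write_series(series: ConcentrationSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# c0_M: {_FMT % series.c0}\n")
        if series.name:
            fh.write(f"# name: {series.name}\n")
        fh.write("t_s,c_M\n")
        for t, c in zip(series.t, series.c):
            fh.write(f"{_FMT % t},{_FMT % c}\n")


def read_series(path) -> ConcentrationSeries:
    meta, data = _parse_columns(path, 2)
    if "c0_M" not in meta:
        raise InputError(f"{path}: missing 'c0_M' metadata")
    return ConcentrationSeries(
        t=data[:, 0], c=data[:, 1], c0=float(meta["c0_M"]), name=meta.get("name", "")
    )


def _build_config(doc: dict) -> ExperimentConfig:
    kin = RateParameters(**doc.get("kinetics", {}))
    aos = [AntioxidantSpec(**a) for a in doc.get("antioxidants", [])]
    cell = FerroFerriCell(**doc.get("mediator_cell", {}))
    electrode = ElectrodeModel(**doc.get("electrode", {}))
    keys = (
        "t_add",
        "duration",
        "sampling_hz",
        "noise_sigma",
        "drift_sigma",
        "aliquot_every",
        "seed",
    )
    extra = {k: doc[k] for k in keys if k in doc}
    unknown = set(doc) - set(keys) - {"kinetics", "antioxidants", "mediator_cell", "electrode"}
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(
        kinetics=kin, antioxidants=aos, mediator_cell=cell, electrode=electrode, **extra
    )


def load_config(path) -> ExperimentConfig:
    """Load an experiment config from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InputError(f"{path}: config must be a YAML mapping")
    try:
        return _build_config(doc)
    except TypeError as exc:
        raise InputError(f"{path}: {exc}") from None


@dataclass
class RunManifest:
    """Provenance record emitted with every CLI run."""

    tool: str
    version: str
    command: str
    seed: int | None
    config_sha256: str | None
    input_sha256: dict
    timestamp: str

    @classmethod
    def create(cls, command: str, seed=None, config_path=None, inputs=()) -> "RunManifest":
        return cls(
            tool="kinpot",
            version=__version__,
            command=command,
            seed=seed,
            config_sha256=_sha256(config_path) if config_path else None,
            input_sha256={str(p): _sha256(p) for p in inputs},
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def dump_json(obj, path=None) -> str:
    """Serialize results (12 significant digits for floats)."""

    def default(o):
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    text = json.dumps(obj, indent=2, default=default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
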