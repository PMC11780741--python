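"""Readers and writers for the documented exchange formats.

Tensor exchange format, version 1.  One record per nucleus with
molecule_id, nucleus_id and the 9 matrix entries in row-major order, units
ppm, plus file-level method and orientation labels.  Two dialects:

* JSON::

    {"format": "cst-exchange", "version": 1, "units": "ppm",
     "method": "KT2", "orientation": "CCSD(T) frames",
     "tensors": [{"molecule_id": "...", "nucleus_id": "...",
                  "matrix": [9 floats, row-major]}, ...]}

* whitespace-delimited text::

    # cst-exchange v1
    # units: ppm
    # method: KT2
    # orientation: CCSD(T) frames
    mol1 C1 <9 floats row-major>

The file-level orientation note is stored into each tensor's frame_note,
so comparisons can refuse frame-mismatched pairs.  Parsers never coerce
units silently: a header declaring anything but ppm is an error.

The RCSA CSV has columns nucleus_id, ddRCSA_Hz, error_Hz, is_reference
with exactly one row flagged as reference (that row carries no fitted
observation; its value column is ignored and conventionally 0).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .rcsa import RCSADataset, RCSAObservation
from .tensor import ShieldingTensor

logger = logging.getLogger("cstkit")

EXCHANGE_VERSION = 1

__all__ = [
    "read_tensor_file",
    "write_tensor_file",
    "read_rcsa_csv",
    "write_rcsa_csv",
    "zenodo_adapter",
    "RunConfig",
    "provenance_record",
]


class ParseError(ValueError):
    pass


def _check_units(units, where):
    if units != "ppm":
        raise ParseError(f"{where}: units must be 'ppm', got {units!r}")


def _tensor_from_record(rec: dict, orientation: str, where: str) -> ShieldingTensor:
    try:
        entries = [float(x) for x in rec["matrix"]]
    except (KeyError, TypeError, ValueError) as e:
        raise ParseError(f"{where}: malformed matrix ({e})") from e
    if len(entries) != 9:
        raise ParseError(f"{where}: expected 9 matrix entries, got {len(entries)}")
    return ShieldingTensor(
        molecule_id=str(rec["molecule_id"]),
        nucleus_id=str(rec["nucleus_id"]),
        matrix=np.array(entries).reshape(3, 3),
        frame_note=orientation,
    )


def _check_unique(tensors, where):
    seen = set()
    for t in tensors:
        if t.key in seen:
            raise ParseError(f"{where}: duplicate nucleus key {t.key}")
        seen.add(t.key)


def read_tensor_file(path, dialect: str | None = None) -> tuple[list[ShieldingTensor], dict]:
    """Read a tensor exchange file; returns (tensors, metadata).

    ``dialect`` is 'json', 'text', or None to infer from the suffix.
    Metadata carries the file-level method and orientation labels.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "text"
    if dialect == "json":
        return _read_json(path)
    if dialect == "text":
        return _read_text(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_json(path: Path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "cst-exchange":
        raise ParseError(f"{path}: missing 'format: cst-exchange' header")
    if doc.get("version") != EXCHANGE_VERSION:
        raise ParseError(f"{path}: unsupported exchange version {doc.get('version')!r}")
    _check_units(doc.get("units"), str(path))
    orientation = doc.get("orientation", "")
    tensors = [
        _tensor_from_record(rec, orientation, f"{path} record {i}")
        for i, rec in enumerate(doc.get("tensors", []))
    ]
    _check_unique(tensors, str(path))
    meta = {"method": doc.get("method", ""), "orientation": orientation}
    return tensors, meta


_TEXT_HEADER = re.compile(r"^#\s*cst-exchange\s+v(\d+)\s*$")


def _read_text(path: Path):
    meta = {"method": "", "orientation": ""}
    units = None
    version = None
    tensors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _TEXT_HEADER.match(line)
                if m:
                    version = int(m.group(1))
                    continue
                key, _, val = line.lstrip("# ").partition(":")
                key, val = key.strip().lower(), val.strip()
                if key == "units":
                    units = val
                elif key in meta:
                    meta[key] = val
                continue
            parts = line.split()
            if len(parts) != 11:
                raise ParseError(
                    f"{path}:{lineno}: expected 'molecule nucleus + 9 entries' "
                    f"(11 fields), got {len(parts)}"
                )
            tensors.append(
                _tensor_from_record(
                    {"molecule_id": parts[0], "nucleus_id": parts[1], "matrix": parts[2:]},
                    meta["orientation"],
                    f"{path}:{lineno}",
                )
            )
    if version != EXCHANGE_VERSION:
        raise ParseError(f"{path}: missing or unsupported '# cst-exchange v1' header")
    _check_units(units, str(path))
    _check_unique(tensors, str(path))
    return tensors, meta


def write_tensor_file(
    path, tensors, method: str = "", orientation: str | None = None, dialect: str | None = None
):
    """Write a tensor set in the exchange format (dialect inferred from suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "text"
    if orientation is None:
        notes = {t.frame_note for t in tensors}
        orientation = notes.pop() if len(notes) == 1 else ""
    if dialect == "json":
        doc = {
            "format": "cst-exchange",
            "version": EXCHANGE_VERSION,
            "units": "ppm",
            "method": method,
            "orientation": orientation,
            "tensors": [
                {
                    "molecule_id": t.molecule_id,
                    "nucleus_id": t.nucleus_id,
                    "matrix": t.matrix.ravel().tolist(),
                }
                for t in tensors
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    elif dialect == "text":
        lines = [
            f"# cst-exchange v{EXCHANGE_VERSION}",
            "# units: ppm",
            f"# method: {method}",
            f"# orientation: {orientation}",
        ]
        for t in tensors:
            entries = " ".join(f"{x:.12g}" for x in t.matrix.ravel())
            lines.append(f"{t.molecule_id} {t.nucleus_id} {entries}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


RCSA_COLUMNS = ["nucleus_id", "ddRCSA_Hz", "error_Hz", "is_reference"]


def read_rcsa_csv(path, larmor_frequency: float, alignment_note: str = "") -> RCSADataset:
    """Read a ddRCSA table; exactly one row must be flagged as reference."""
    df = pd.read_csv(path)
    missing = [c for c in RCSA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    flags = df["is_reference"].astype(bool)
    n_ref = int(flags.sum())
    if n_ref != 1:
        raise ParseError(f"{path}: exactly one reference row required, found {n_ref}")
    reference = str(df.loc[flags, "nucleus_id"].iloc[0])
    body = df.loc[~flags]
    if (body["error_Hz"] <= 0).any():
        bad = body.loc[body["error_Hz"] <= 0, "nucleus_id"].tolist()
        raise ParseError(f"{path}: non-positive errors for {bad}")
    obs = tuple(
        RCSAObservation(str(r.nucleus_id), float(r.ddRCSA_Hz), float(r.error_Hz))
        for r in body.itertuples()
    )
    return RCSADataset(obs, reference, larmor_frequency, alignment_note)


def write_rcsa_csv(path, dataset: RCSADataset):
    rows = [
        {
            "nucleus_id": dataset.reference_nucleus,
            "ddRCSA_Hz": 0.0,
            "error_Hz": float(dataset.errors[0]) if len(dataset.observations) else 0.5,
            "is_reference": True,
        }
    ]
    rows += [
        {
            "nucleus_id": o.nucleus_id,
            "ddRCSA_Hz": o.value,
            "error_Hz": o.error,
            "is_reference": False,
        }
        for o in dataset.observations
    ]
    pd.DataFrame(rows, columns=RCSA_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Deposit adapter

_MPSHIFT_ATOM = re.compile(r"ATOM\s+(\w+)\s+(\d+)", re.IGNORECASE)


def _try_mpshift_block(path: Path) -> list[ShieldingTensor] | None:
    """Parse a Turbomole mpshift-like block listing: per atom a line
    'ATOM <element> <index>' followed by three rows of three numbers."""
    tensors = []
    lines = path.read_text().splitlines()
    i = 0
    molecule = path.stem
    while i < len(lines):
        m = _MPSHIFT_ATOM.search(lines[i])
        if m:
            try:
                rows = [
                    [float(x) for x in lines[i + k + 1].split()[:3]]
                    for k in range(3)
                ]
            except (ValueError, IndexError):
                return None
            if any(len(r) != 3 for r in rows):
                return None
            tensors.append(
                ShieldingTensor(
                    molecule_id=molecule,
                    nucleus_id=f"{m.group(1).capitalize()}{m.group(2)}",
                    matrix=np.array(rows),
                    frame_note=f"deposit:{path.name}",
                )
            )
            i += 4
        else:
            i += 1
    return tensors or None


def zenodo_adapter(path) -> dict[str, list[ShieldingTensor]]:
    """Best-effort conversion of a local deposit directory into tensor sets.

    Walks the directory, trying (in order) the JSON exchange dialect, the
    text dialect, and a Turbomole mpshift-like block format.  Returns a
    mapping file-stem -> tensor list.  Every unconverted file is logged,
    never silently skipped; an empty or unrecognized directory is an error.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    files = sorted(p for p in root.rglob("*") if p.is_file())
    if not files:
        raise ParseError(f"deposit directory {root} is empty")
    converted: dict[str, list[ShieldingTensor]] = {}
    skipped = []
    for f in files:
        tensors = None
        for reader in ("json", "text", "mpshift"):
            try:
                if reader == "mpshift":
                    tensors = _try_mpshift_block(f)
                else:
                    tensors, _ = read_tensor_file(f, dialect=reader)
            except (ParseError, ValueError, json.JSONDecodeError, UnicodeDecodeError):
                tensors = None
            if tensors:
                break
        if tensors:
            converted[str(f.relative_to(root))] = tensors
        else:
            skipped.append(f)
            logger.warning("zenodo_adapter: could not convert %s", f)
    if not converted:
        raise ParseError(
            f"no file under {root} matched a recognized layout "
            f"({len(skipped)} files skipped)"
        )
    return converted


# ---------------------------------------------------------------------------
# Run configuration and provenance


class MCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = Field(default=1000, ge=1)
    noise_sd: float = Field(default=0.5, ge=0.0)
    seed: int = 12345


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    larmor_frequency: float = Field(gt=0.0)
    convention: str = "maryland"
    degeneracy_threshold: float = Field(default=3.0, ge=0.0)
    reference_nucleus: str | None = None
    conformer_weights: dict[str, float] | None = None
    monte_carlo: MCSettings = MCSettings()
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def provenance_record(config: dict, seed: int | None = None) -> dict:
    """Machine-readable provenance: config hash, seed, format version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "cstkit_version": __version__,
        "exchange_format_version": EXCHANGE_VERSION,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
    }
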