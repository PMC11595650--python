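"""File formats and the reproducibility harness.

Tables are RFC-4180 CSV with a schema tag in the first line (``# qsea-morph
schema=<name>.v1``); readers reject unknown schema versions loudly and
report missing columns by name.  Mask stacks are multi-page TIFF with a
JSON sidecar declaring the label map, µm-per-pixel scale and frame times
(labels are never assumed).  Every pipeline run can be sealed with a JSON
manifest: config hash, seed, package version and a SHA-256 per output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import MaskFrame
from .synth import MILESTONES, TIMING_NAMES, GroupCalibration

_SCHEMA_PREFIX = "# qsea-morph schema="

#: required columns per schema (wide assay tables carry variable offset
#: columns and are validated structurally instead)
SCHEMAS: dict[str, tuple[str, ...]] = {
    "cohort.v1": (
        "embryo_id", "cycle_id", "ploidy", "grade_tier",
        "tSB", "tB", "tEB", "t_biopsy",
        "transferred", "transfer_order", "live_birth",
    ),
    "trajectories.v1": ("embryo_id", "metric", "time_hpi", "value"),
    "qsea_wide.v1": ("embryo_id",),
    "milestones.v1": ("embryo_id", "metric"),
    "morphometrics.v1": ("time_hpi", "zp_A", "emb_A", "zp_T", "ICM_A", "ICM_TE_ratio"),
    "expansion_map.v1": ("offset_min", "p", "p_holm"),
}

DEFAULT_LABEL_MAP = {"background": 0, "zona": 1, "embryo": 2, "icm": 3}


class SchemaError(ValueError):
    """Unknown schema version or missing required columns."""


def write_table(df: pd.DataFrame, path: str | Path, schema: str, index: bool = False) -> Path:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"{_SCHEMA_PREFIX}{schema}\n")
        df.to_csv(fh, index=index)
    return path


def read_table(path: str | Path, schema: str, index_col: str | None = None) -> pd.DataFrame:
    """Read a tagged CSV, validating schema version and required columns."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    skip = 0
    if first.startswith(_SCHEMA_PREFIX):
        tag = first[len(_SCHEMA_PREFIX):]
        if tag != schema:
            raise SchemaError(f"{path}: schema {tag!r} does not match expected {schema!r}")
        skip = 1
    elif first.startswith("#"):
        raise SchemaError(f"{path}: unrecognized header comment {first!r}")
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema}")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_qsea_wide(df: pd.DataFrame, path: str | Path) -> Path:
    return write_table(df.reset_index(), path, "qsea_wide.v1")


def read_qsea_wide(path: str | Path) -> pd.DataFrame:
    df = read_table(path, "qsea_wide.v1", index_col="embryo_id")
    df.columns = [int(c) for c in df.columns]
    return df


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def write_mask_stack(frames: list[MaskFrame], path: str | Path) -> tuple[Path, Path]:
    """Multi-page TIFF of label frames plus a JSON sidecar (label map,
    µm-per-pixel scale, frame times in hpi)."""
    if not frames:
        raise ValueError("no frames to write")
    scales = {f.scale for f in frames}
    if len(scales) != 1:
        raise ValueError("all frames in a stack must share one scale")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.labels.astype(np.uint8) for f in frames])
    tifffile.imwrite(path, stack)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "label_map": DEFAULT_LABEL_MAP,
                "um_per_px": frames[0].scale,
                "times_hpi": [f.time_hpi for f in frames],
            },
            fh,
            indent=2,
        )
    return path, sidecar


def read_mask_stack(path: str | Path, sidecar: str | Path | None = None) -> list[MaskFrame]:
    path = Path(path)
    sidecar = path.with_suffix(".json") if sidecar is None else Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(f"mask sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    label_map = meta["label_map"]
    expected = DEFAULT_LABEL_MAP
    remap = {int(label_map[k]): expected[k] for k in expected if k in label_map}
    if sorted(remap.values()) != sorted(expected.values()):
        raise SchemaError(f"{sidecar}: incomplete label map {label_map}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    times = meta.get("times_hpi") or [None] * len(stack)
    frames = []
    for img, t in zip(stack, times):
        lab = np.zeros_like(img, dtype=np.uint8)
        for src, dst in remap.items():
            lab[img == src] = dst
        frames.append(MaskFrame(labels=lab, scale=float(meta["um_per_px"]), time_hpi=t))
    return frames


# ---------------------------------------------------------------------------
# calibration YAML
# ---------------------------------------------------------------------------


def load_calibrations(path: str | Path) -> dict[str, GroupCalibration]:
    """YAML layout: {group: {anchor_correlation?, timings: {tSB: [m, sd], ...},
    anchors: {zp_A: {tB: [m, sd], ...}, ...}}}"""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for label, block in raw.items():
        timings = {k: tuple(map(float, block["timings"][k])) for k in TIMING_NAMES}
        anchors = {
            metric: {ms: tuple(map(float, per_ms[ms])) for ms in MILESTONES}
            for metric, per_ms in block["anchors"].items()
        }
        out[label] = GroupCalibration(
            label=label,
            timings=timings,
            anchors=anchors,
            anchor_correlation=float(block.get("anchor_correlation", 0.6)),
        )
    return out


def dump_calibrations(cals: dict[str, GroupCalibration], path: str | Path) -> Path:
    raw = {
        label: {
            "anchor_correlation": c.anchor_correlation,
            "timings": {k: list(v) for k, v in c.timings.items()},
            "anchors": {m: {ms: list(v) for ms, v in per.items()} for m, per in c.anchors.items()},
        }
        for label, c in cals.items()
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(
    path: str | Path, config: dict, outputs: list[str | Path], seed: int | None = None
) -> Path:
    from . import __version__

    path = Path(path)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def verify_manifest(path: str | Path) -> dict[str, bool]:
    """Re-hash every listed output; True means unchanged."""
    with open(path) as fh:
        manifest = json.load(fh)
    return {
        p: Path(p).exists() and _sha256(Path(p)) == digest
        for p, digest in manifest["outputs"].items()
    }
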