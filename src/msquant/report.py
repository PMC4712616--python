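"""Region statistics, the CSV output, and the provenance log.

The final analysis masks every quantitative map (ADC, CBF, CBV, MTT) with
every region mask (NAGM, NAWM, deep grey structures, total lesion burden,
classes C1–C4, single lesions) and reports per-region voxel counts, volumes
and intensity statistics to one CSV.  Voxels flagged invalid upstream
(clamped ADC, zero-CBF) are excluded from the statistics; an empty region is
reported with missing markers, never with fabricated zeros.

The provenance log is an append-only JSON-lines record of every pipeline
step: parameters, content hashes of inputs and outputs, software version and
timestamps.  Step inputs are snapshot-copied before any mutation and reruns
write to fresh versioned directories, so earlier outputs are never
overwritten.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image import VolumeImage

__all__ = ["RegionStats", "region_stats", "write_csv", "read_csv",
           "ProvenanceLog", "StepRecord"]

CSV_COLUMNS = ["patient_id", "region", "map", "n_voxels", "volume_mm3",
               "normalized_volume", "mean", "sd", "median",
               "iqr_low", "iqr_high", "min", "max"]


@dataclass
class RegionStats:
    """Statistics of one quantitative map over one region mask."""

    patient_id: str
    region: str
    map: str                      # adc|cbf|cbv|mtt|none
    n_voxels: int
    volume_mm3: float
    normalized_volume: float
    mean: float | None
    sd: float | None
    median: float | None
    iqr_low: float | None = None
    iqr_high: float | None = None
    min: float | None = None
    max: float | None = None


def region_stats(map_img: VolumeImage | None, mask: VolumeImage,
                 patient_id: str, region: str, map_name: str = "none",
                 valid_mask: VolumeImage | None = None,
                 vscale: float = 1.0) -> RegionStats:
    """Summarize ``map_img`` over ``mask`` (both on one grid).

    ``valid_mask`` marks voxels whose map value is a real measurement;
    voxels outside it are excluded from the intensity statistics but still
    counted in the region's voxel count and volume.  With ``map_img=None``
    only geometry (voxels, volume) is reported.
    """
    arr = np.asarray(mask.data)
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("mask must be binary")
    region_sel = arr.astype(bool)
    n_voxels = int(region_sel.sum())
    volume = n_voxels * mask.voxel_volume_mm3

    mean = sd = median = iqr_low = iqr_high = vmin = vmax = None
    if map_img is not None:
        if not map_img.same_grid(mask):
            raise ValueError("map and mask must share a grid")
        sel = region_sel
        if valid_mask is not None:
            sel = sel & np.asarray(valid_mask.data).astype(bool)
        values = np.asarray(map_img.data, dtype=float)[sel]
        if values.size:
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
            median = float(np.median(values))
            iqr_low, iqr_high = (float(q) for q in np.percentile(values, [25, 75]))
            vmin, vmax = float(values.min()), float(values.max())
    return RegionStats(patient_id=patient_id, region=region, map=map_name,
                       n_voxels=n_voxels, volume_mm3=volume,
                       normalized_volume=volume * vscale,
                       mean=mean, sd=sd, median=median,
                       iqr_low=iqr_low, iqr_high=iqr_high, min=vmin, max=vmax)


def write_csv(rows: list[RegionStats], path: str | Path) -> Path:
    """Stable-column CSV; missing statistics become empty fields."""
    path = Path(path)
    frame = pd.DataFrame([asdict(r) for r in rows], columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)
    return path


def read_csv(path: str | Path) -> list[RegionStats]:
    frame = pd.read_csv(path, dtype={"patient_id": str, "region": str, "map": str})
    rows = []
    for rec in frame.to_dict(orient="records"):
        clean = {k: (None if (isinstance(v, float) and np.isnan(v)) else v)
                 for k, v in rec.items()}
        clean["n_voxels"] = int(clean["n_voxels"])
        rows.append(RegionStats(**clean))
    return rows


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class StepRecord:
    step: str
    parameters: dict = field(default_factory=dict)
    input_hashes: dict[str, str] = field(default_factory=dict)
    output_hashes: dict[str, str] = field(default_factory=dict)
    software_version: str = ""
    start_time: float = 0.0
    end_time: float = 0.0
    tool_output: str = ""
    version_dir: str = ""


class ProvenanceLog:
    """Append-only JSON-lines log with copy-before-modify snapshots.

    ``begin_step`` snapshots the declared input files into a fresh versioned
    directory (``<step>_v<k>``) before the step may touch anything, and
    ``finish_step`` appends the completed record.  Existing records are
    immutable; a rerun of a step gets a new version directory.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.log_path = self.root / "provenance.jsonl"
        self._open: dict[str, StepRecord] = {}

    @property
    def records(self) -> list[StepRecord]:
        if not self.log_path.exists():
            return []
        return [StepRecord(**json.loads(line))
                for line in self.log_path.read_text().splitlines() if line.strip()]

    def _next_version_dir(self, step: str) -> Path:
        k = 1
        while (self.root / f"{step}_v{k}").exists():
            k += 1
        path = self.root / f"{step}_v{k}"
        path.mkdir(parents=True)
        return path

    def begin_step(self, step: str, parameters: dict | None = None,
                   inputs: list[str | Path] | None = None,
                   software_version: str = "") -> Path:
        """Snapshot inputs and open a record; returns the step's output dir."""
        vdir = self._next_version_dir(step)
        record = StepRecord(step=step, parameters=parameters or {},
                            software_version=software_version,
                            start_time=time.time(), version_dir=str(vdir))
        snap = vdir / "input_snapshot"
        for p in inputs or []:
            p = Path(p)
            if p.is_file():
                snap.mkdir(exist_ok=True)
                shutil.copy2(p, snap / p.name)
                record.input_hashes[p.name] = _hash_file(p)
        self._open[step] = record
        return vdir

    def finish_step(self, step: str, outputs: list[str | Path] | None = None,
                    tool_output: str = "") -> StepRecord:
        if step not in self._open:
            raise ValueError(f"finish_step before begin_step for {step!r}")
        record = self._open.pop(step)
        record.end_time = time.time()
        record.tool_output = tool_output
        for p in outputs or []:
            p = Path(p)
            if p.is_file():
                record.output_hashes[p.name] = _hash_file(p)
        with self.log_path.open("a") as fh:
            fh.write(json.dumps(asdict(record)) + "\n")
        return record

    def verify(self) -> dict[str, list[str]]:
        """Re-hash every recorded output still on disk; report mismatches."""
        mismatches: dict[str, list[str]] = {}
        for record in self.records:
            vdir = Path(record.version_dir)
            bad = [name for name, digest in record.output_hashes.items()
                   if (vdir / name).exists() and _hash_file(vdir / name) != digest]
            if bad:
                mismatches[record.step] = bad
        return mismatches
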