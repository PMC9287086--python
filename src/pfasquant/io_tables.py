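"""Tabular and scan-stream I/O.

Area tables are plain CSV with the normalized schema
``replicate_id, level_ngL, compound, is_internal_standard, area``; foreign
exports (e.g. from Skyline) are adapted through a column-mapping dict.

Scan streams are written as a JSON-lines dialect — one scan per line with
keys ``rt_min, polarity, ms_level, mz, intensity, precursor_mz,
trigger_id`` — and read back bit-identically.  Standard centroided mzML is
also accepted on read (via pyteomics); there is no mzML writer here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .synth import AREA_COLUMNS, Scan, ScanStream

__all__ = [
    "read_area_table",
    "write_area_table",
    "write_scan_stream_jsonl",
    "read_scan_stream_jsonl",
    "read_scan_stream_mzml",
    "RunConfig",
]

_REQUIRED = ["replicate_id", "level_ngL", "compound", "area"]


def read_area_table(path: str | Path, column_map: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Read a peak-area CSV, normalizing foreign headers via ``column_map``.

    ``column_map`` maps foreign header -> normalized name.  Rows whose area
    or level fails numeric coercion are dropped; the dropped count is
    attached as ``df.attrs["rejected_rows"]``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(
            f"area table missing columns {missing}; expected schema {AREA_COLUMNS} "
            "(use column_map for foreign headers)"
        )
    if "is_internal_standard" not in df.columns:
        df["is_internal_standard"] = False
    n0 = len(df)
    for col in ("level_ngL", "area"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["level_ngL", "area"]).reset_index(drop=True)
    df.attrs["rejected_rows"] = n0 - len(df)
    return df[AREA_COLUMNS]


def write_area_table(df: pd.DataFrame, path: str | Path) -> None:
    df[AREA_COLUMNS].to_csv(path, index=False)


def write_scan_stream_jsonl(stream: ScanStream, path: str | Path) -> None:
    """One scan per line; float lists verbatim via repr round-trip."""
    with Path(path).open("w") as fh:
        header = {"format": "pfasquant-scan-jsonl", "version": 1,
                  "positive_window": list(stream.positive_window)}
        fh.write(json.dumps(header) + "\n")
        for s in stream:
            rec = {
                "rt_min": s.rt_min,
                "polarity": s.polarity,
                "ms_level": s.ms_level,
                "mz": s.mz.tolist(),
                "intensity": s.intensity.tolist(),
                "precursor_mz": s.precursor_mz,
                "trigger_id": s.trigger_id,
            }
            fh.write(json.dumps(rec) + "\n")


def read_scan_stream_jsonl(path: str | Path) -> ScanStream:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty scan stream file")
    header = json.loads(lines[0])
    if header.get("format") != "pfasquant-scan-jsonl":
        raise ValueError(f"{path}: not a pfasquant scan-stream JSONL file")
    scans = []
    for line in lines[1:]:
        d = json.loads(line)
        scans.append(
            Scan(d["rt_min"], d["polarity"], d["ms_level"],
                 np.array(d["mz"], dtype=float),
                 np.array(d["intensity"], dtype=float),
                 d.get("precursor_mz"), d.get("trigger_id"))
        )
    return ScanStream(scans, positive_window=tuple(header["positive_window"]))


def read_scan_stream_mzml(path: str | Path,
                          positive_window: Tuple[float, float] = (0.0, float("inf"))
                          ) -> ScanStream:
    """Read a centroided mzML run into a ScanStream (MS1 and MS2 scans)."""
    from pyteomics import mzml as _mzml

    scans = []
    with _mzml.read(str(path)) as reader:
        for sp in reader:
            level = int(sp.get("ms level", 1))
            polarity = "-" if "negative scan" in sp else "+"
            rt = float(sp["scanList"]["scan"][0]["scan start time"])
            precursor = None
            if level == 2 and sp.get("precursorList"):
                ions = sp["precursorList"]["precursor"][0]["selectedIonList"]["selectedIon"]
                precursor = float(ions[0]["selected ion m/z"])
            scans.append(Scan(rt, polarity, level,
                              np.asarray(sp["m/z array"], dtype=float),
                              np.asarray(sp["intensity array"], dtype=float),
                              precursor_mz=precursor))
    scans.sort(key=lambda s: s.rt_min)
    return ScanStream(scans, positive_window=positive_window)


@dataclass
class RunConfig:
    """Declarative run configuration; round-trips through YAML.

    The seed is mandatory and persisted with every output so any run can be
    reproduced exactly.
    """

    seed: int
    levels_ngL: Tuple[float, ...] = (2.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0, 2000.0)
    n_replicates: int = 10
    is_conc_ngL: float = 10_000.0
    qc_level_ngL: float = 500.0
    area_cv: float = 0.05
    area_floor: float = 0.0
    mz_jitter_ppm: float = 1.0
    response_factor: float = 1000.0
    noise_correlation: float = 0.8
    ppm_tolerance: float = 5.0
    weighting: str = "1/x"
    boundary_fraction: float = 0.02
    alpha: float = 0.01
    sided: str = "two"
    min_replicates: int = 7
    output_dir: str = "."

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["levels_ngL"] = list(self.levels_ngL)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["levels_ngL"] = tuple(d["levels_ngL"])
        return cls(**d)

    def digest(self) -> str:
        d = asdict(self)
        d["levels_ngL"] = list(self.levels_ngL)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
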