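"""CSV readers/writers for trap layouts and capture histories, plus run config.

Dialect: comma-separated, UTF-8, "." decimal, header row mandatory.

* Trap layout CSV: columns ``array_id, detector_id, x_m, y_m``.
* Capture CSV: columns ``array_id, animal_id, occasion, detector_id`` with
  one row per detection event and 1-based occasions; a duplicated
  (animal, occasion, detector) row is an error because a proximity detector
  records an animal at most once per occasion.

These are this package's own formats; the native input formats of other
SECR software are not parsed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CaptureData, Detector, DetectorArray

__all__ = [
    "read_traps",
    "write_traps",
    "read_captures",
    "write_captures",
    "RunConfig",
]

_TRAP_COLS = ["array_id", "detector_id", "x_m", "y_m"]
_CAPT_COLS = ["array_id", "animal_id", "occasion", "detector_id"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_traps(path, n_occasions: int = 6) -> list[DetectorArray]:
    """Read a trap layout CSV into arrays (grouped by array_id, order kept).

    ``n_occasions`` is attached to every array; the layout file itself
    carries only geometry.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"array_id": str, "detector_id": str})
    _require_columns(df, _TRAP_COLS, path)
    for col in ("x_m", "y_m"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.nonzero((bad | df[col].isna()).to_numpy())[0][0]) + 2
            raise ValueError(f"{path}: non-numeric {col} at row {row}")
    dup = df.duplicated(subset=["array_id", "detector_id"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise ValueError(f"{path}: duplicated (array_id, detector_id) at row {row}")
    arrays = []
    for aid, grp in df.groupby("array_id", sort=False):
        dets = tuple(
            Detector(id=r.detector_id, x=float(r.x_m), y=float(r.y_m))
            for r in grp.itertuples()
        )
        arrays.append(DetectorArray(array_id=aid, detectors=dets, n_occasions=n_occasions))
    return arrays


def write_traps(arrays, path) -> None:
    rows = [
        dict(array_id=a.array_id, detector_id=d.id, x_m=d.x, y_m=d.y)
        for a in arrays
        for d in a.detectors
    ]
    pd.DataFrame(rows, columns=_TRAP_COLS).to_csv(path, index=False)


def read_captures(path, arrays) -> list[CaptureData]:
    """Read detection events and build one binary tensor per array.

    Animals are indexed in first-seen order.  Detections at unknown
    detectors, out-of-range occasions, and duplicated events raise with the
    offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"array_id": str, "animal_id": str, "detector_id": str})
    _require_columns(df, _CAPT_COLS, path)
    by_id = {a.array_id: a for a in arrays}
    det_index = {
        a.array_id: {d.id: k for k, d in enumerate(a.detectors)} for a in arrays
    }
    dup = df.duplicated(subset=["array_id", "animal_id", "occasion", "detector_id"])
    if dup.any():
        row = int(np.nonzero(dup.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}: duplicate (animal, occasion, detector) detection at row {row}"
        )
    out = []
    grouped = dict(tuple(df.groupby("array_id", sort=False)))
    for array in arrays:
        grp = grouped.get(array.array_id)
        if grp is None:
            out.append(
                CaptureData(
                    array_id=array.array_id,
                    individuals=(),
                    omega=np.zeros((0, array.n_occasions, array.n_detectors), dtype=np.int8),
                )
            )
            continue
        animals: list[str] = []
        index: dict[str, int] = {}
        events = []
        for r in grp.itertuples():
            row = r.Index + 2
            k = det_index[array.array_id].get(r.detector_id)
            if k is None:
                raise ValueError(
                    f"{path}: row {row}: unknown detector {r.detector_id!r} "
                    f"on array {array.array_id}"
                )
            occ = int(r.occasion)
            if not (1 <= occ <= array.n_occasions):
                raise ValueError(
                    f"{path}: row {row}: occasion {occ} outside 1..{array.n_occasions}"
                )
            if r.animal_id not in index:
                index[r.animal_id] = len(animals)
                animals.append(r.animal_id)
            events.append((index[r.animal_id], occ - 1, k))
        omega = np.zeros((len(animals), array.n_occasions, array.n_detectors), dtype=np.int8)
        for i, s, k in events:
            omega[i, s, k] = 1
        out.append(
            CaptureData(array_id=array.array_id, individuals=tuple(animals), omega=omega)
        )
    unknown = set(grouped) - set(by_id)
    if unknown:
        raise ValueError(f"{path}: detections reference unknown arrays {sorted(unknown)}")
    return out


def write_captures(datasets, arrays, path) -> None:
    """Write one row per detection event (inverse of :func:`read_captures`)."""
    det_ids = {a.array_id: [d.id for d in a.detectors] for a in arrays}
    rows = []
    for data in datasets:
        ids = det_ids[data.array_id]
        for i, animal in enumerate(data.individuals):
            s_idx, k_idx = np.nonzero(data.omega[i])
            for s, k in zip(s_idx, k_idx):
                rows.append(
                    dict(
                        array_id=data.array_id,
                        animal_id=animal,
                        occasion=int(s) + 1,
                        detector_id=ids[k],
                    )
                )
    pd.DataFrame(rows, columns=_CAPT_COLS).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Structured run configuration; round-trips losslessly through YAML."""

    scenario: int = 1
    iterations: int = 100
    seed: int = 1
    out_dir: str = "out"
    sharing: str = "independent"
    buffer_m: float | None = None
    cell_side_m: float | None = None
    estimator: str = "eq3"
    variance: str = "both"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"known keys are {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
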