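"""File formats: beat-series CSV, annotation/PSG TSV, intermittent CSV.

Files carry times in seconds (editable by clinicians); in memory all
annotations use 0-based beat indices.  ``read_annotations`` therefore
returns time-based records which :func:`resolve_annotations` snaps to the
nearest valid beat of the companion series (warning beyond 2 s, error
beyond 10 s).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    BeatSeries,
    FormatError,
    IntermittentSeries,
    PsgEvent,
    SurgeAnnotation,
    ValidationError,
    QUALITIES,
    QUALITY_VALID,
)

__all__ = [
    "read_beat_series",
    "write_beat_series",
    "TimedAnnotation",
    "read_annotations",
    "write_annotations",
    "resolve_annotations",
    "read_psg_events",
    "write_psg_events",
    "read_intermittent",
    "write_intermittent",
    "write_run_record",
]

log = logging.getLogger(__name__)


def read_beat_series(path, night_id: Optional[str] = None) -> BeatSeries:
    """Read a beat series CSV (columns ``time_s,sbp[,dbp][,quality]``).

    A missing quality column defaults to all-valid; a dbp column that is
    entirely empty is treated as absent.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "sbp"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    time_s = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        # 1-based file line of the offending beat, counting the header
        row = int(np.argmax(dt <= 0)) + 3
        raise FormatError(
            f"{path}: non-monotone time_s at row {row}"
        )
    if "quality" in df.columns:
        quality = df["quality"].fillna(QUALITY_VALID).to_numpy(dtype=object)
        bad = set(np.unique(quality)) - set(QUALITIES)
        if bad:
            raise FormatError(f"{path}: unknown quality flags {sorted(bad)}")
    else:
        quality = None
    dbp = None
    if "dbp" in df.columns and not df["dbp"].isna().all():
        dbp = df["dbp"].to_numpy(dtype=float)
    return BeatSeries(
        night_id=night_id or path.stem,
        time_s=time_s,
        sbp_mmHg=df["sbp"].to_numpy(dtype=float),
        dbp_mmHg=dbp,
        quality=quality,
    )


def write_beat_series(series: BeatSeries, path) -> None:
    """Write a beat series CSV; time at 3 dp, pressures at 1 dp, and the
    quality column always present."""
    df = pd.DataFrame({
        "time_s": [f"{x:.3f}" for x in series.time_s],
        "sbp": [f"{x:.1f}" for x in series.sbp_mmHg],
        "dbp": ([f"{x:.1f}" for x in series.dbp_mmHg]
                if series.dbp_mmHg is not None else [""] * series.n_beats),
        "quality": series.quality,
    })
    df.to_csv(path, index=False)


@dataclass
class TimedAnnotation:
    """An annotation as stored on disk: times in seconds, not beat indices."""

    night_id: str
    start_s: float
    peak_s: float
    end_s: float
    sa_class: str = "unassigned"


def read_annotations(path) -> List[TimedAnnotation]:
    """Read a label/detection TSV (``night_id,start_s,peak_s,end_s[,class]``),
    sorted by start time within each night."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("night_id", "start_s", "peak_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if not row.start_s < row.end_s:
            raise ValidationError(
                f"{path}: start_s >= end_s at data row {row_no}"
            )
        if not row.start_s <= row.peak_s <= row.end_s:
            raise ValidationError(
                f"{path}: peak_s outside [start_s, end_s] at data row {row_no}"
            )
        cls = "unassigned"
        if "class" in df.columns:
            raw = row[list(df.columns).index("class")]
            if isinstance(raw, str) and raw:
                cls = raw
        out.append(TimedAnnotation(
            night_id=str(row.night_id), start_s=float(row.start_s),
            peak_s=float(row.peak_s), end_s=float(row.end_s), sa_class=cls,
        ))
    out.sort(key=lambda a: (a.night_id, a.start_s))
    return out


def write_annotations(annotations: Sequence[SurgeAnnotation],
                      series: BeatSeries, path) -> None:
    """Write annotations for one night as TSV, converting indices to times."""
    t = series.time_s
    rows = [{
        "night_id": a.night_id,
        "start_s": f"{t[a.start_idx]:.3f}",
        "peak_s": f"{t[a.peak_idx]:.3f}",
        "end_s": f"{t[a.end_idx]:.3f}",
        "class": a.sa_class,
    } for a in annotations]
    pd.DataFrame(rows, columns=["night_id", "start_s", "peak_s", "end_s",
                                "class"]).to_csv(path, sep="\t", index=False)


def resolve_annotations(timed: Sequence[TimedAnnotation], series: BeatSeries,
                        source: str = "label",
                        warn_snap_s: float = 2.0,
                        max_snap_s: float = 10.0) -> List[SurgeAnnotation]:
    """Snap time-based annotations to the nearest valid beat of ``series``.

    Snap distances beyond ``warn_snap_s`` warn; beyond ``max_snap_s`` raise.
    """
    v = series.valid_indices
    tv = series.time_s[v]

    def snap(ts: float) -> int:
        pos = int(np.searchsorted(tv, ts))
        best = min(
            (p for p in (pos - 1, pos) if 0 <= p < tv.size),
            key=lambda p: abs(tv[p] - ts),
        )
        dist = abs(tv[best] - ts)
        if dist > max_snap_s:
            raise ValidationError(
                f"{series.night_id}: annotation time {ts:.1f} s is "
                f"{dist:.1f} s from the nearest valid beat"
            )
        if dist > warn_snap_s:
            warnings.warn(
                f"{series.night_id}: annotation time {ts:.1f} s snapped "
                f"{dist:.1f} s"
            )
        return int(v[best])

    out = []
    for a in timed:
        if a.night_id != series.night_id:
            continue
        out.append(SurgeAnnotation(
            night_id=a.night_id,
            start_idx=snap(a.start_s),
            peak_idx=snap(a.peak_s),
            end_idx=snap(a.end_s),
            source=source,
            sa_class=a.sa_class if a.sa_class in ("sa", "non_sa")
            else "unassigned",
        ))
    return out


def read_psg_events(path) -> List[PsgEvent]:
    df = pd.read_csv(path, sep="\t")
    for col in ("night_id", "kind", "start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [PsgEvent(night_id=str(r.night_id), kind=str(r.kind),
                     start_s=float(r.start_s), end_s=float(r.end_s))
            for r in df.itertuples(index=False)]


def write_psg_events(events: Sequence[PsgEvent], path) -> None:
    pd.DataFrame([{
        "night_id": e.night_id, "kind": e.kind,
        "start_s": f"{e.start_s:.3f}", "end_s": f"{e.end_s:.3f}",
    } for e in events], columns=["night_id", "kind", "start_s", "end_s"]
    ).to_csv(path, sep="\t", index=False)


def read_intermittent(path, night_id: Optional[str] = None
                      ) -> IntermittentSeries:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "sbp"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return IntermittentSeries(
        night_id=night_id or path.stem,
        time_s=df["time_s"].to_numpy(dtype=float),
        sbp_mmHg=df["sbp"].to_numpy(dtype=float),
    )


def write_intermittent(readings: IntermittentSeries, path) -> None:
    pd.DataFrame({
        "time_s": [f"{x:.3f}" for x in readings.time_s],
        "sbp": [f"{x:.1f}" for x in readings.sbp_mmHg],
    }).to_csv(path, index=False)


def write_run_record(path, command: str, config_dict: dict, seed: int,
                     counts: dict) -> None:
    """JSON run record: command, config hash, seed, per-stage counts."""
    blob = json.dumps(config_dict, sort_keys=True).encode()
    record = {
        "command": command,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config_dict,
        "seed": seed,
        "counts": counts,
    }
    Path(path).write_text(json.dumps(record, indent=2))
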