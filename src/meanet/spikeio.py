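"""Data model and I/O for multielectrode-array (MEA) spike recordings.

A recording is a set of per-electrode spike timestamp trains plus metadata
(duration, experimental group, days in vitro).  Timestamps are stored in
seconds as floats; all window arithmetic elsewhere in the package is done on
an integer grid of 0.01 ms ticks to keep comparisons unambiguous.

On disk a recording is a two-column delimited table (``electrode_id,time_s``,
CSV or TSV chosen by extension) with a YAML sidecar ``<path>.meta.yaml``
holding ``duration_s``, ``group_label``, ``div`` and friends.  A collection of
recordings with a group x DIV design is a :class:`RecordingBundle`, serialised
as a YAML manifest next to the spike tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: one tick = 0.01 ms; spike times are compared at this resolution
TICKS_PER_SECOND = 100_000

#: canonical MEA60 electrode labels (8x8 grid minus the four corners),
#: column-major "<col><row>" naming as used by 60-channel arrays
MEA60_LAYOUT = tuple(
    f"{c}{r}"
    for c in range(1, 9)
    for r in range(1, 9)
    if (c, r) not in {(1, 1), (1, 8), (8, 1), (8, 8)}
)

DEFAULT_DIVS = (14, 15, 17, 19, 21)


class ValidationError(ValueError):
    """Raised when a recording or table violates the data-model invariants."""


def to_ticks(time_s: float | np.ndarray) -> np.ndarray:
    """Convert seconds to the integer 0.01 ms grid."""
    return np.rint(np.asarray(time_s, dtype=float) * TICKS_PER_SECOND).astype(np.int64)


@dataclass
class SpikeTrainSet:
    """Per-electrode sorted spike timestamps with recording metadata.

    Parameters
    ----------
    electrode_ids
        Unique electrode labels (strings).  Electrodes with no spikes are
        legitimate and retained.
    spikes
        Mapping electrode id -> 1-D float array of spike times in seconds,
        strictly increasing at 0.01 ms resolution.
    duration_s
        Recording length in seconds.
    meta
        Free-form metadata; recognised keys: ``group_label``, ``div``,
        ``recording_id``, ``notes``.
    """

    electrode_ids: tuple[str, ...]
    spikes: dict[str, np.ndarray]
    duration_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.electrode_ids = tuple(str(e) for e in self.electrode_ids)
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValidationError("electrode_ids must be unique")
        if not (self.duration_s > 0):
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        clean: dict[str, np.ndarray] = {}
        known = set(self.electrode_ids)
        for eid, times in self.spikes.items():
            eid = str(eid)
            if eid not in known:
                raise ValidationError(f"spikes on unknown electrode {eid!r}")
            t = np.sort(np.asarray(times, dtype=float))
            if t.size:
                if t[0] < 0:
                    raise ValidationError(f"negative spike time on {eid!r}")
                if t[-1] > self.duration_s:
                    raise ValidationError(
                        f"spike at {t[-1]:.6f}s on {eid!r} exceeds duration "
                        f"{self.duration_s}s"
                    )
                ticks = to_ticks(t)
                if np.any(np.diff(ticks) == 0):
                    raise ValidationError(
                        f"duplicate spike times (< 0.1 ms apart is fine, "
                        f"< 0.01 ms is not) on electrode {eid!r}"
                    )
            clean[eid] = t
        for eid in self.electrode_ids:
            clean.setdefault(eid, np.empty(0, dtype=float))
        self.spikes = clean

    # -- convenience -------------------------------------------------------

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spikes.values()))

    def merged(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes pooled across electrodes.

        Returns
        -------
        ticks : int64 array, sorted
            Spike times on the 0.01 ms grid.
        electrode_index : int array
            Index into :attr:`electrode_ids` per spike.  Ties in time are
            ordered by electrode index for determinism.
        """
        if self.n_spikes == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.intp)
        parts_t, parts_e = [], []
        for i, eid in enumerate(self.electrode_ids):
            t = self.spikes[eid]
            if t.size:
                parts_t.append(to_ticks(t))
                parts_e.append(np.full(t.size, i, dtype=np.intp))
        ticks = np.concatenate(parts_t)
        eidx = np.concatenate(parts_e)
        order = np.lexsort((eidx, ticks))
        return ticks[order], eidx[order]

    def equals(self, other: "SpikeTrainSet") -> bool:
        """Equality at the 0.01 ms comparison resolution (metadata included)."""
        if self.electrode_ids != other.electrode_ids:
            return False
        if to_ticks(self.duration_s) != to_ticks(other.duration_s):
            return False
        for eid in self.electrode_ids:
            a, b = self.spikes[eid], other.spikes[eid]
            if a.size != b.size or not np.array_equal(to_ticks(a), to_ticks(b)):
                return False
        return _normalise_meta(self.meta) == _normalise_meta(other.meta)


def _normalise_meta(meta: Mapping) -> dict:
    return {k: meta[k] for k in sorted(meta, key=str) if meta[k] is not None}


@dataclass
class RecordingBundle:
    """A set of recordings plus the group x DIV design that indexes them."""

    recordings: list[SpikeTrainSet]
    design: dict[str, dict[int, list[str]]]  # group -> DIV -> recording_ids

    def __post_init__(self) -> None:
        by_id = self.by_id()
        for group, per_div in self.design.items():
            for div, rec_ids in per_div.items():
                for rid in rec_ids:
                    if rid not in by_id:
                        raise ValidationError(
                            f"design references unknown recording {rid!r} "
                            f"({group}, DIV{div})"
                        )

    def by_id(self) -> dict[str, SpikeTrainSet]:
        out = {}
        for rec in self.recordings:
            rid = rec.meta.get("recording_id")
            if rid is None:
                raise ValidationError("bundle recordings need a recording_id")
            if rid in out:
                raise ValidationError(f"duplicate recording_id {rid!r}")
            out[rid] = rec
        return out

    def iter_design(self) -> Iterable[tuple[str, int, SpikeTrainSet]]:
        by_id = self.by_id()
        for group in sorted(self.design):
            for div in sorted(self.design[group]):
                for rid in self.design[group][div]:
                    yield group, div, by_id[rid]


# ---------------------------------------------------------------------------
# table I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def read_spike_table(
    path: str | Path,
    duration_s: float | None = None,
    meta: Mapping | None = None,
) -> SpikeTrainSet:
    """Read a delimited (electrode_id, time_s) table into a SpikeTrainSet.

    Duration and metadata come from, in order of precedence: the ``duration_s``
    / ``meta`` arguments, the YAML sidecar ``<path>.meta.yaml``, or — with a
    warning — ``max(time) + 1 ms`` when no duration is stated anywhere.
    Rows need not be sorted; electrodes are ordered by first appearance unless
    the sidecar lists ``electrode_ids``.
    """
    path = Path(path)
    side: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        side = yaml.safe_load(sp.read_text()) or {}
    try:
        df = pd.read_csv(
            path,
            sep=_sep_for(path),
            header=None,
            names=["electrode_id", "time_s"],
            dtype={"electrode_id": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["electrode_id", "time_s"])
    # tolerate an optional header row
    if len(df) and not _is_number(df.iloc[0]["time_s"]):
        df = df.iloc[1:]
    df["time_s"] = df["time_s"].astype(float)

    if duration_s is None:
        duration_s = side.get("duration_s")
    if duration_s is None:
        duration_s = (float(df["time_s"].max()) if len(df) else 0.0) + 1e-3
        warnings.warn(
            f"{path.name}: no stated duration; using max(time)+1ms = "
            f"{duration_s:.6f}s",
            stacklevel=2,
        )
    full_meta = dict(side.get("meta", {}))
    if meta:
        full_meta.update(meta)

    eids = side.get("electrode_ids")
    if eids is None:
        eids = list(dict.fromkeys(df["electrode_id"].tolist()))
    spikes = {
        str(eid): grp["time_s"].to_numpy()
        for eid, grp in df.groupby("electrode_id", sort=False)
    }
    return SpikeTrainSet(
        electrode_ids=tuple(str(e) for e in eids),
        spikes=spikes,
        duration_s=float(duration_s),
        meta=full_meta,
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_spike_table(s: SpikeTrainSet, path: str | Path) -> Path:
    """Write a SpikeTrainSet as a delimited table plus a YAML sidecar.

    Rows are ordered by (time, electrode index) and times printed with 0.1 us
    precision, so ``read_spike_table(write_spike_table(s)) == s`` at the
    package's comparison resolution and repeated writes are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = _sep_for(path)
    ticks, eidx = s.merged()
    with open(path, "w", newline="") as fh:
        for t, e in zip(ticks, eidx):
            fh.write(f"{s.electrode_ids[e]}{sep}{t / TICKS_PER_SECOND:.7f}\n")
    side = {
        "duration_s": float(s.duration_s),
        "electrode_ids": list(s.electrode_ids),
        "meta": _normalise_meta(s.meta),
    }
    sidecar_path(path).write_text(yaml.safe_dump(side, sort_keys=True))
    return path


def split_minutes(s: SpikeTrainSet, segment_s: float = 60.0) -> list[SpikeTrainSet]:
    """Split a recording into re-zeroed segments over half-open windows.

    Segment ``k`` covers ``[k*segment_s, (k+1)*segment_s)``; the last segment
    may be shorter and is closed at the recording end (a spike exactly at
    ``duration_s`` belongs to it).  The union of the segments' spikes is
    exactly the original spike set (boundary spikes go to the later segment).
    """
    n_seg = max(1, math.ceil(s.duration_s / segment_s - 1e-12))
    seg_ticks = to_ticks(segment_s)
    out = []
    for k in range(n_seg):
        lo_t, hi_t = k * seg_ticks, (k + 1) * seg_ticks
        dur = min(segment_s, s.duration_s - k * segment_s)
        last = k == n_seg - 1
        spikes = {}
        for eid in s.electrode_ids:
            t = to_ticks(s.spikes[eid])
            m = (t >= lo_t) & ((t <= to_ticks(s.duration_s)) if last else (t < hi_t))
            spikes[eid] = (t[m] - lo_t) / TICKS_PER_SECOND
        meta = dict(s.meta)
        meta["segment_index"] = k
        out.append(
            SpikeTrainSet(
                electrode_ids=s.electrode_ids,
                spikes=spikes,
                duration_s=dur,
                meta=meta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# bundle manifest I/O


def write_bundle(bundle: RecordingBundle, directory: str | Path) -> Path:
    """Write every recording table plus a ``manifest.yaml`` into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in bundle.recordings:
        rid = rec.meta["recording_id"]
        fname = f"{rid}.csv"
        write_spike_table(rec, directory / fname)
        entries.append({"recording_id": rid, "path": fname})
    manifest = {
        "recordings": entries,
        "design": {
            g: {int(d): list(r) for d, r in per.items()}
            for g, per in bundle.design.items()
        },
    }
    mpath = directory / "manifest.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return mpath


def read_bundle(manifest_path: str | Path) -> RecordingBundle:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    doc = yaml.safe_load(manifest_path.read_text())
    if not isinstance(doc, dict) or "recordings" not in doc or "design" not in doc:
        raise ValidationError(f"malformed manifest {manifest_path}")
    base = manifest_path.parent
    recordings = []
    for entry in doc["recordings"]:
        try:
            rec = read_spike_table(base / entry["path"])
        except (KeyError, FileNotFoundError) as exc:
            raise ValidationError(f"malformed manifest entry {entry!r}") from exc
        rec.meta.setdefault("recording_id", entry["recording_id"])
        recordings.append(rec)
    design = {
        str(g): {int(d): [str(r) for r in rids] for d, rids in per.items()}
        for g, per in doc["design"].items()
    }
    return RecordingBundle(recordings=recordings, design=design)
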