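"""Domain types and CSV I/O for plate-reader OD time courses.

A microtiter-plate growth assay produces, for every well, a vector of OD600
readings on a shared measurement schedule.  Wells are identified by a
:class:`SampleKey` — strain, treatment, trial, biological replicate and
technical replicate — and a :class:`PlateSet` collects the curves of one
study together with provenance metadata.

Two on-disk dialects are supported:

* **long CSV** — one row per (well, time point) with header
  ``strain,treatment,trial,bio_rep,tech_rep,time_h,od``;
* **plate grid** — 8x12 OD matrices (rows A-H, columns 1-12), one block per
  time point introduced by a ``# time_h=<value>`` comment line, paired with a
  plate-map CSV that assigns well addresses to sample identities.

Times are hours (float); OD is dimensionless OD600.  Non-positive OD is
always an error — the natural log is taken downstream and no blank
correction is applied here.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TimePointSchedule",
    "SampleKey",
    "GrowthCurve",
    "PlateSet",
    "PlateDataError",
    "default_schedule",
    "make_schedule",
    "log_transform",
    "read_long_csv",
    "write_long_csv",
    "read_plate_grid",
    "write_plate_grid",
    "LONG_COLUMNS",
]

#: Default measurement schedule, hours: every 2 h over 12-24 h, then 35-45 h.
DEFAULT_TIMES: tuple[float, ...] = (
    12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 24.0,
    35.0, 37.0, 39.0, 41.0, 43.0, 45.0,
)

LONG_COLUMNS = ("strain", "treatment", "trial", "bio_rep", "tech_rep", "time_h", "od")

#: Canonical treatment labels (the set is extensible; these are the defaults).
CANONICAL_TREATMENTS = ("no_mix", "mixer", "pipette")

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = tuple(range(1, 13))

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class PlateDataError(ValueError):
    """Raised for malformed or inconsistent plate data files."""


@dataclass(frozen=True)
class TimePointSchedule:
    """Ordered measurement times in hours; strictly increasing and positive."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        if len(times) == 0:
            raise ValueError("schedule must contain at least one time point")
        if any(t <= 0 or not math.isfinite(t) for t in times):
            raise ValueError("schedule times must be finite and > 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[float]:
        return iter(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    def indices_in(self, start: float, end: float) -> list[int]:
        """Indices of scheduled times inside the closed interval [start, end]."""
        return [i for i, t in enumerate(self.times) if start <= t <= end]


def default_schedule() -> TimePointSchedule:
    """The 13-point assay schedule: 12-24 h and 35-45 h, every 2 hours."""
    return TimePointSchedule(DEFAULT_TIMES)


def make_schedule(start: float, end: float, step: float) -> TimePointSchedule:
    """Arithmetic-progression schedule from *start* to *end* inclusive."""
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if end < start:
        raise ValueError(f"empty schedule: end {end} < start {start}")
    n = int(math.floor((end - start) / step + 1e-9)) + 1
    return TimePointSchedule(tuple(start + i * step for i in range(n)))


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one well's time course.

    The replicate index used by the paired analysis is the pair
    ``(bio_rep, tech_rep)`` flattened in ascending ``(bio_rep, tech_rep)``
    order, which is deterministic and shared across treatments.
    """

    strain: str
    treatment: str
    trial: int
    bio_rep: int
    tech_rep: int

    def __post_init__(self) -> None:
        for name in ("trial", "bio_rep", "tech_rep"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def replicate(self) -> tuple[int, int]:
        return (self.bio_rep, self.tech_rep)


@dataclass(frozen=True)
class GrowthCurve:
    """One well's readings on a schedule, in OD space or (after transform) ln space."""

    key: SampleKey
    schedule: TimePointSchedule
    od: np.ndarray
    log_space: bool = False

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "od", od)
        if od.ndim != 1 or len(od) != len(self.schedule):
            raise ValueError(
                f"curve {self.key}: expected {len(self.schedule)} readings, got {od.shape}"
            )
        if not np.all(np.isfinite(od)):
            raise ValueError(f"curve {self.key}: non-finite reading")
        if not self.log_space and np.any(od <= 0):
            t = self.schedule.times[int(np.argmax(od <= 0))]
            raise ValueError(
                f"curve {self.key}: non-positive OD at time {t} h"
            )


def log_transform(curve: GrowthCurve) -> GrowthCurve:
    """Natural-log transform a curve's OD readings (schedule unchanged).

    Raises ``ValueError`` naming the offending key and time if any reading
    is non-positive; ln-space curves are returned unchanged.
    """
    if curve.log_space:
        return curve
    if np.any(curve.od <= 0):  # unreachable for validated curves; keep the message exact
        t = curve.schedule.times[int(np.argmax(curve.od <= 0))]
        raise ValueError(f"cannot ln-transform {curve.key}: OD <= 0 at {t} h")
    return replace(curve, od=np.log(curve.od), log_space=True)


class PlateSet:
    """A collection of growth curves sharing one schedule, keyed by SampleKey."""

    def __init__(
        self,
        curves: Iterable[GrowthCurve],
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self._curves: dict[SampleKey, GrowthCurve] = {}
        self.metadata: dict[str, object] = dict(metadata or {})
        schedule: TimePointSchedule | None = None
        for c in curves:
            if schedule is None:
                schedule = c.schedule
            elif c.schedule.times != schedule.times:
                raise PlateDataError(
                    f"curve {c.key} has schedule {c.schedule.times}, "
                    f"expected {schedule.times}"
                )
            if c.key in self._curves:
                raise PlateDataError(f"duplicate sample key {c.key}")
            self._curves[c.key] = c
        if schedule is None:
            raise PlateDataError("PlateSet requires at least one curve")
        self.schedule = schedule

    def __len__(self) -> int:
        return len(self._curves)

    def __iter__(self) -> Iterator[GrowthCurve]:
        return iter(self._curves.values())

    def __contains__(self, key: SampleKey) -> bool:
        return key in self._curves

    def get(self, key: SampleKey) -> GrowthCurve:
        try:
            return self._curves[key]
        except KeyError:
            raise KeyError(f"no curve for {key}") from None

    @property
    def log_space(self) -> bool:
        return next(iter(self._curves.values())).log_space

    def strains(self) -> list[str]:
        return sorted({k.strain for k in self._curves})

    def treatments(self) -> list[str]:
        return sorted({k.treatment for k in self._curves})

    def trials(self) -> list[int]:
        return sorted({k.trial for k in self._curves})

    def keys(self) -> list[SampleKey]:
        return sorted(self._curves)

    def replicate_keys(self, strain: str, treatment: str, trial: int) -> list[SampleKey]:
        """Keys for one condition in one trial, in the canonical replicate order."""
        out = [
            k
            for k in self._curves
            if k.strain == strain and k.treatment == treatment and k.trial == trial
        ]
        return sorted(out, key=lambda k: (k.bio_rep, k.tech_rep))

    def log_transform(self) -> "PlateSet":
        """Return a new PlateSet with every curve ln-transformed."""
        return PlateSet(
            (log_transform(c) for c in self),
            metadata={**self.metadata, "log_space": True},
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per (well, time point)."""
        records = []
        for key in self.keys():
            c = self._curves[key]
            for t, v in zip(c.schedule.times, c.od):
                records.append(
                    (key.strain, key.treatment, key.trial, key.bio_rep, key.tech_rep, t, v)
                )
        return pd.DataFrame.from_records(records, columns=list(LONG_COLUMNS))

    @classmethod
    def from_long_frame(
        cls, df: pd.DataFrame, metadata: Mapping[str, object] | None = None
    ) -> "PlateSet":
        df = df.rename(columns={c: c.strip().lower() for c in df.columns})
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise PlateDataError(f"missing column(s): {sorted(missing)}")
        od = pd.to_numeric(df["od"], errors="coerce")
        if od.isna().any():
            raise PlateDataError("non-numeric OD value")
        if (od <= 0).any():
            row = df.loc[od.le(0).idxmax()]
            raise PlateDataError(
                f"non-positive OD for {row['strain']}/{row['treatment']} "
                f"at {row['time_h']} h"
            )
        df = df.assign(od=od)

        key_cols = ["strain", "treatment", "trial", "bio_rep", "tech_rep"]
        dup = df.duplicated(subset=key_cols + ["time_h"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise PlateDataError(
                f"duplicate row for {tuple(row[c] for c in key_cols)} at {row['time_h']} h"
            )

        schedule: tuple[float, ...] | None = None
        curves = []
        for (strain, treatment, trial, bio, tech), grp in df.groupby(key_cols, sort=True):
            grp = grp.sort_values("time_h")
            times = tuple(float(t) for t in grp["time_h"])
            if schedule is None:
                schedule = times
                sched = TimePointSchedule(times)
            elif times != schedule:
                raise PlateDataError(
                    f"inconsistent schedule for ({strain}, {treatment}, {trial}, "
                    f"{bio}, {tech}): {times} vs {schedule}"
                )
            curves.append(
                GrowthCurve(
                    SampleKey(str(strain), str(treatment), int(trial), int(bio), int(tech)),
                    sched,
                    grp["od"].to_numpy(),
                )
            )
        return cls(curves, metadata=metadata)


def _as_text(source: IO | str) -> IO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_long_csv(source: IO | str, metadata: Mapping[str, object] | None = None) -> PlateSet:
    """Read a long-format CSV stream (or literal string) into a PlateSet.

    Header columns are order- and case-insensitive; ``#`` comment lines are
    ignored.  Errors on missing columns, duplicate (key, time) rows,
    inconsistent schedules across wells, and non-positive or non-numeric OD.
    """
    try:
        df = pd.read_csv(
            _as_text(source), comment="#", skip_blank_lines=True,
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PlateDataError(f"unreadable long CSV: {exc}") from exc
    return PlateSet.from_long_frame(df, metadata=metadata)


def write_long_csv(plate_set: PlateSet, dest: IO) -> None:
    """Write the long-CSV representation (full float precision)."""
    df = plate_set.to_long_frame()
    df.to_csv(dest, index=False, float_format="%.17g")


def parse_well(address: str) -> tuple[int, int]:
    """Parse a well address like ``"B07"`` into 0-based (row, column)."""
    m = _WELL_RE.match(address.strip())
    if not m:
        raise PlateDataError(f"malformed well address {address!r}")
    row = PLATE_ROWS.index(m.group(1).upper())
    col = int(m.group(2))
    if not 1 <= col <= 12:
        raise PlateDataError(f"well address {address!r} outside A1-H12")
    return row, col - 1


def format_well(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col + 1:02d}"


def _parse_grid_blocks(source: IO | str) -> dict[float, np.ndarray]:
    """Parse ``# time_h=`` delimited 8x12 CSV blocks into {time: matrix}.

    Cells may be empty (NaN) for unread wells; mapped wells must be non-NaN.
    """
    blocks: dict[float, np.ndarray] = {}
    current_time: float | None = None
    current_lines: list[str] = []

    def flush() -> None:
        nonlocal current_lines
        if current_time is None:
            return
        if not current_lines:
            raise PlateDataError(f"empty grid block at time {current_time} h")
        df = pd.read_csv(io.StringIO("\n".join(current_lines)), index_col=0,
                         float_precision="round_trip")
        rows = [str(r).strip().upper() for r in df.index]
        cols = [str(c).strip() for c in df.columns]
        if rows != list(PLATE_ROWS) or cols != [str(c) for c in PLATE_COLUMNS]:
            raise PlateDataError(
                f"malformed grid at time {current_time} h: rows {rows}, columns {cols}"
            )
        mat = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        if current_time in blocks:
            raise PlateDataError(f"duplicate grid block for time {current_time} h")
        blocks[current_time] = mat
        current_lines = []

    for raw in _as_text(source):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("#"):
            m = re.match(r"#\s*time_h\s*=\s*([0-9.eE+-]+)", stripped)
            if m:
                flush()
                current_time = float(m.group(1))
            continue
        if not stripped:
            continue
        if current_time is None:
            raise PlateDataError("grid data before any '# time_h=' declaration")
        current_lines.append(line)
    flush()
    if not blocks:
        raise PlateDataError("no '# time_h=' blocks found in grid source")
    return blocks


def read_plate_grid(
    grid_source: IO | str,
    plate_map_source: IO | str,
    metadata: Mapping[str, object] | None = None,
) -> PlateSet:
    """Assemble a PlateSet from plate-grid blocks plus a plate-map CSV.

    The plate map has columns ``well,strain,treatment,trial,bio_rep,tech_rep``;
    wells absent from the map are ignored.  The result equals the long-format
    representation of the same readings.
    """
    blocks = _parse_grid_blocks(grid_source)
    times = sorted(blocks)
    schedule = TimePointSchedule(tuple(times))

    pmap = pd.read_csv(_as_text(plate_map_source), comment="#")
    pmap = pmap.rename(columns={c: c.strip().lower() for c in pmap.columns})
    required = {"well", "strain", "treatment", "trial", "bio_rep", "tech_rep"}
    missing = required - set(pmap.columns)
    if missing:
        raise PlateDataError(f"plate map missing column(s): {sorted(missing)}")

    curves = []
    for rec in pmap.itertuples(index=False):
        row, col = parse_well(str(rec.well))
        od = np.array([blocks[t][row, col] for t in times])
        if np.isnan(od).any():
            t_bad = times[int(np.argmax(np.isnan(od)))]
            raise PlateDataError(
                f"well {rec.well}: no reading at {t_bad} h"
            )
        key = SampleKey(
            str(rec.strain), str(rec.treatment),
            int(rec.trial), int(rec.bio_rep), int(rec.tech_rep),
        )
        curves.append(GrowthCurve(key, schedule, od))
    return PlateSet(curves, metadata=metadata)


def write_plate_grid(
    plate_set: PlateSet,
    layout: Mapping[SampleKey, str],
    grid_dest: IO,
    map_dest: IO,
) -> None:
    """Serialize a PlateSet as grid blocks plus a plate map, given a well layout."""
    addr = {key: parse_well(well) for key, well in layout.items()}
    if len(set(addr.values())) != len(addr):
        raise PlateDataError("layout assigns two samples to one well")
    for key in plate_set.keys():
        if key not in addr:
            raise PlateDataError(f"layout missing well for {key}")

    for t_idx, t in enumerate(plate_set.schedule.times):
        mat = np.full((8, 12), np.nan)
        for key in plate_set.keys():
            r, c = addr[key]
            mat[r, c] = plate_set.get(key).od[t_idx]
        grid_dest.write(f"# time_h={t:g}\n")
        grid_dest.write("," + ",".join(str(c) for c in PLATE_COLUMNS) + "\n")
        for r, row_label in enumerate(PLATE_ROWS):
            cells = ["" if np.isnan(v) else f"{v:.17g}" for v in mat[r]]
            grid_dest.write(row_label + "," + ",".join(cells) + "\n")

    map_dest.write("well,strain,treatment,trial,bio_rep,tech_rep\n")
    for key in plate_set.keys():
        r, c = addr[key]
        map_dest.write(
            f"{format_well(r, c)},{key.strain},{key.treatment},"
            f"{key.trial},{key.bio_rep},{key.tech_rep}\n"
        )
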