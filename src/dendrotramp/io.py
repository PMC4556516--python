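"""Reading, writing, validation and normalization of dated ring-width series.

A ring-width series is one tree's sequence of annual radial increments
(TRW, mm), dated to calendar years.  Two on-disk layouts are supported:

* the study-style wide table (``s1_wide``): rows are calendar years,
  columns are trees named ``StudyPlot_Zone_TreeNr`` (zone code ``T`` for
  the trampled track zone, ``C`` for control); an entirely empty column
  marks a flawed tree that was cored but excluded from analysis;
* the Tucson decadal RWL format used by most dendro software, with the
  stop marker (999 or -9999) selecting the 0.01 / 0.001 mm dialect.

Normalization pools every retained ring measurement and replaces each
width by its z-score, so that zone/plot chronologies are comparable on a
common dimensionless scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

ZONES = ("track", "control")

_ZONE_CODES = {"T": "track", "C": "control"}
_ZONE_TO_CODE = {v: k for k, v in _ZONE_CODES.items()}


class RingDataError(ValueError):
    """Raised for malformed or invariant-violating ring-width data."""


@dataclass(frozen=True)
class RingSeries:
    """One tree's dated ring widths with plot/zone/flaw metadata.

    ``widths[k]`` is the increment formed in calendar year
    ``first_year + k``; years are consecutive with no internal gaps.
    A flawed tree (cored but unusable) may carry an empty width vector.
    """

    tree_id: str
    plot_id: str
    zone: str
    first_year: int
    widths: np.ndarray
    flawed: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if self.zone not in ZONES:
            raise RingDataError(
                f"{self.tree_id}: zone must be one of {ZONES}, got {self.zone!r}"
            )
        if not self.plot_id or not self.tree_id:
            raise RingDataError("tree_id and plot_id must be non-empty")
        if w.ndim != 1:
            raise RingDataError(f"{self.tree_id}: widths must be 1-D")
        if not self.flawed and w.size < 1:
            raise RingDataError(f"{self.tree_id}: non-flawed series must have >= 1 ring")
        if w.size and not np.all(np.isfinite(w)):
            raise RingDataError(f"{self.tree_id}: widths must all be finite")

    def __len__(self) -> int:
        return int(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self))

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.widths, index=self.years, name=self.tree_id)


@dataclass(frozen=True)
class NormalizationParams:
    """Grand mean/SD of all pooled ring measurements used for z-scoring."""

    grand_mean: float
    grand_sd: float
    n_measurements: int

    def __post_init__(self) -> None:
        if self.n_measurements < 2:
            raise RingDataError("normalization requires >= 2 measurements")
        if not self.grand_sd > 0:
            raise RingDataError("grand_sd must be > 0 (degenerate scale)")


@dataclass(frozen=True)
class RingDataset:
    """A validated collection of :class:`RingSeries`.

    ``units`` is ``"mm"`` for raw widths (all > 0) or ``"z"`` after
    global normalization (signed, dimensionless).
    """

    series: tuple[RingSeries, ...]
    units: str = "mm"

    def __post_init__(self) -> None:
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        ids = [s.tree_id for s in series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RingDataError(f"duplicate tree_ids: {dupes}")
        if self.units not in ("mm", "z"):
            raise RingDataError(f"unknown units {self.units!r}")
        if self.units == "mm":
            for s in series:
                if len(s) and not np.all(s.widths > 0):
                    raise RingDataError(f"{s.tree_id}: mm widths must be > 0")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def year_span(self) -> tuple[int, int]:
        dated = [s for s in self.series if len(s)]
        if not dated:
            raise RingDataError("dataset has no dated rings")
        return (min(s.first_year for s in dated), max(s.last_year for s in dated))

    @property
    def plots(self) -> tuple[str, ...]:
        return tuple(sorted({s.plot_id for s in self.series}))

    def select(self, plot_id: str | None = None, zone: str | None = None) -> "RingDataset":
        kept = [
            s
            for s in self.series
            if (plot_id is None or s.plot_id == plot_id)
            and (zone is None or s.zone == zone)
        ]
        return RingDataset(tuple(kept), units=self.units)

    def to_frame(self) -> pd.DataFrame:
        """Wide year x tree table (NaN outside each tree's dated span)."""
        cols = {s.tree_id: s.to_pandas() for s in self.series if len(s)}
        return pd.DataFrame(cols).sort_index()

    def all_widths(self) -> np.ndarray:
        if not self.series:
            return np.empty(0)
        return np.concatenate([s.widths for s in self.series if len(s)] or [np.empty(0)])


# ---------------------------------------------------------------------------
# study-style wide CSV layout


def _decode_column(name: str) -> tuple[str, str]:
    parts = str(name).strip().split("_")
    if len(parts) != 3:
        raise RingDataError(
            f"column {name!r} does not follow the StudyPlot_Zone_TreeNr naming"
        )
    plot, zone_code, _nr = parts
    if zone_code not in _ZONE_CODES:
        raise RingDataError(f"column {name!r}: zone code must be T or C, got {zone_code!r}")
    return plot, _ZONE_CODES[zone_code]


def _series_from_column(name: str, col: pd.Series) -> RingSeries:
    plot, zone = _decode_column(name)
    vals = pd.to_numeric(col, errors="coerce")
    bad = col.notna() & vals.isna()
    if bad.any():
        row = bad.idxmax()
        raise RingDataError(f"non-numeric cell at row {row!r}, column {name!r}")
    present = vals.notna().to_numpy()
    if not present.any():
        return RingSeries(str(name), plot, zone, int(col.index[0]), np.empty(0), flawed=True)
    first, last = np.flatnonzero(present)[[0, -1]]
    if not present[first : last + 1].all():
        gap = col.index[first + np.flatnonzero(~present[first : last + 1])[0]]
        raise RingDataError(
            f"column {name!r}: internal gap at year {gap} (series must be consecutive)"
        )
    years = col.index[first : last + 1]
    return RingSeries(
        str(name), plot, zone, int(years[0]), vals.iloc[first : last + 1].to_numpy()
    )


def read_ring_csv(source, dialect: str = "s1_wide") -> RingDataset:
    """Read the wide year x tree CSV layout into a :class:`RingDataset`.

    The first column holds calendar years; remaining headers follow the
    ``StudyPlot_Zone_TreeNr`` convention.  Entirely empty columns become
    flawed series with zero rings; leading/trailing blanks are trimmed.
    """
    if dialect != "s1_wide":
        raise RingDataError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(source, index_col=0)
    df.index = df.index.astype(int)
    return RingDataset(tuple(_series_from_column(c, df[c]) for c in df.columns))


def read_ring_excel(path, sheet_name: str = "RD") -> RingDataset:
    """Read the wide layout from an xlsx workbook sheet."""
    df = pd.read_excel(path, sheet_name=sheet_name, index_col=0)
    df.index = df.index.astype(int)
    return RingDataset(tuple(_series_from_column(c, df[c]) for c in df.columns))


def write_ring_csv(dataset: RingDataset, target, blank_flawed: bool = True) -> None:
    """Write the wide layout; flawed trees appear as empty columns."""
    y0, y1 = dataset.year_span
    years = pd.RangeIndex(y0, y1 + 1, name="year")
    out = pd.DataFrame(index=years)
    for s in dataset.series:
        if s.flawed and blank_flawed:
            out[s.tree_id] = np.nan
        elif len(s):
            out[s.tree_id] = s.to_pandas().reindex(years)
        else:
            out[s.tree_id] = np.nan
    out.to_csv(target, float_format="%.3f")


# ---------------------------------------------------------------------------
# Tucson decadal RWL format

_STOP_PRECISION = {"-9999": 0.001, "999": 0.01}


def write_rwl(dataset: RingDataset, target: TextIO | str, precision: float = 0.001) -> None:
    """Write Tucson decadal RWL.  ``precision`` 0.001 mm uses stop marker
    -9999; 0.01 mm uses 999."""
    if precision not in (0.001, 0.01):
        raise RingDataError("RWL precision must be 0.001 or 0.01 mm")
    stop = "-9999" if precision == 0.001 else "999"
    close = False
    if isinstance(target, str):
        target = open(target, "w")
        close = True
    try:
        for s in dataset.series:
            if not len(s):
                continue
            sid = s.tree_id[:8]
            vals = [int(round(w / precision)) for w in s.widths] + [int(stop)]
            years = list(s.years) + [s.last_year + 1]
            line_year = None
            buf: list[str] = []
            for y, v in zip(years, vals):
                if line_year is None:
                    line_year = y
                    buf = []
                buf.append(f"{v:6d}")
                if (y + 1) % 10 == 0 or v == int(stop):
                    target.write(f"{sid:<8s}{line_year:4d}{''.join(buf)}\n")
                    line_year = None
    finally:
        if close:
            target.close()


def read_rwl(source: TextIO | str) -> RingDataset:
    """Read Tucson decadal RWL.  Precision dialect is auto-detected from
    the stop marker (999 -> 0.01 mm, -9999 -> 0.001 mm).

    Plot/zone metadata is not part of the format; series ids that follow
    the ``Plot_Zone_Nr`` convention are decoded, otherwise plot defaults
    to the id and zone to control.
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    try:
        raw: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        stops: dict[str, int] = {}
        for lineno, line in enumerate(source, 1):
            if not line.strip():
                continue
            sid = line[:8].strip()
            try:
                year = int(line[8:12])
                fields = line[12:].split()
                vals = [int(v) for v in fields]
            except ValueError:
                raise RingDataError(f"malformed decade line {lineno}: {line.rstrip()!r}")
            if not sid or not vals:
                raise RingDataError(f"malformed decade line {lineno}: {line.rstrip()!r}")
            if sid in stops:
                raise RingDataError(f"line {lineno}: duplicate series id {sid!r}")
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            for k, v in enumerate(vals):
                if v in (999, -9999) and k == len(vals) - 1:
                    stops[sid] = v
                else:
                    raw[sid].append((year + k, v))
    finally:
        if close:
            source.close()

    series = []
    for sid in order:
        pairs = raw[sid]
        if sid not in stops:
            raise RingDataError(f"series {sid!r} has no stop marker")
        precision = _STOP_PRECISION[str(stops[sid])]
        years = np.array([y for y, _ in pairs])
        if len(years) and np.any(np.diff(years) != 1):
            raise RingDataError(f"series {sid!r}: non-consecutive years in RWL body")
        widths = np.array([v for _, v in pairs], dtype=float) * precision
        try:
            plot, zone = _decode_column(sid)
        except RingDataError:
            plot, zone = sid, "control"
        series.append(RingSeries(sid, plot, zone, int(years[0]), widths))
    return RingDataset(tuple(series))


# ---------------------------------------------------------------------------
# flaw exclusion and normalization


def flaw_counts(dataset: RingDataset) -> pd.DataFrame:
    """Bored / flawed / retained counts per (plot, zone)."""
    rows = [
        {"plot": s.plot_id, "zone": s.zone, "flawed": int(s.flawed)} for s in dataset.series
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["plot", "zone"])
        .agg(n_bored=("flawed", "size"), n_flawed=("flawed", "sum"))
        .reset_index()
    )
    out["n_kept"] = out["n_bored"] - out["n_flawed"]
    return out


def exclude_flawed(dataset: RingDataset, return_counts: bool = False):
    """Drop flawed series (cored trees excluded from all statistics)."""
    kept = RingDataset(
        tuple(s for s in dataset.series if not s.flawed), units=dataset.units
    )
    if return_counts:
        return kept, flaw_counts(dataset)
    return kept


def normalize_global(
    dataset: RingDataset, ddof: int = 1, per_plot: bool = False
) -> tuple[RingDataset, NormalizationParams | dict[str, NormalizationParams]]:
    """z-score every ring against the pooled mean/SD of all measurements.

    Flawed series are excluded from both the parameter estimate and the
    output.  ``ddof=1`` (sample SD) is the default; ``per_plot=True``
    normalizes each study plot against its own pooled parameters.
    """
    data = exclude_flawed(dataset)
    if dataset.units != "mm":
        raise RingDataError("normalize_global expects raw mm data")
    if per_plot:
        out: list[RingSeries] = []
        params: dict[str, NormalizationParams] = {}
        for plot in data.plots:
            sub, p = normalize_global(data.select(plot_id=plot), ddof=ddof)
            out.extend(sub.series)
            params[plot] = p
        return RingDataset(tuple(out), units="z"), params
    pooled = data.all_widths()
    if pooled.size < 2:
        raise RingDataError("normalization requires >= 2 measurements")
    sd = float(np.std(pooled, ddof=ddof))
    if not sd > 0:
        raise RingDataError("all widths identical: degenerate scale")
    params = NormalizationParams(float(np.mean(pooled)), sd, int(pooled.size))
    series = tuple(
        replace(s, widths=(s.widths - params.grand_mean) / params.grand_sd)
        for s in data.series
    )
    return RingDataset(series, units="z"), params


def denormalize(dataset: RingDataset, params: NormalizationParams) -> RingDataset:
    """Inverse of :func:`normalize_global` (z back to mm)."""
    series = tuple(
        replace(s, widths=s.widths * params.grand_sd + params.grand_mean)
        for s in dataset.series
    )
    return RingDataset(series, units="mm")


def mean_annual_increment(
    dataset: RingDataset, group_by: Sequence[str] = ("plot", "zone")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group, per-calendar-year arithmetic mean increment.

    Returns ``(means, counts)`` DataFrames indexed by year with one
    column per group (group label = "plot/zone" pieces joined by "/").
    Only trees with a ring in a given year contribute to that year.
    """
    data = exclude_flawed(dataset)
    if not len(data):
        raise RingDataError("no series remain after flaw exclusion")
    group_by = tuple(group_by)
    for g in group_by:
        if g not in ("plot", "zone"):
            raise RingDataError(f"unknown grouping key {g!r}")

    def label(s: RingSeries) -> str:
        parts = []
        if "plot" in group_by:
            parts.append(s.plot_id)
        if "zone" in group_by:
            parts.append(s.zone)
        return "/".join(parts) if parts else "all"

    groups: dict[str, list[RingSeries]] = {}
    for s in data.series:
        groups.setdefault(label(s), []).append(s)
    means, counts = {}, {}
    for name, members in sorted(groups.items()):
        frame = pd.DataFrame({s.tree_id: s.to_pandas() for s in members})
        means[name] = frame.mean(axis=1)
        counts[name] = frame.notna().sum(axis=1)
    m = pd.DataFrame(means).sort_index()
    c = pd.DataFrame(counts).reindex(m.index).fillna(0).astype(int)
    m.index.name = c.index.name = "year"
    return m, c
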