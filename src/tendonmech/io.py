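"""Readers and writers for every tabular artifact the pipeline touches.

The raw tensile records come in the "mtt" dialect: tab-delimited text with
five columns [Time (ms), Displacement signal (mV), Load signal (mV),
Displacement (mm), Load (gram-force)], one file per fascicle specimen, named
``mttNN_X_tYZ`` (NN = age group, X = sample/mouse, Y = fascicle, Z = segment
letter).  Derived mechanical-property sheets, fibril area-fraction and
diameter-histogram sheets are plain CSV mirrors of the deposited worksheet
layouts.  A run log records the analysis parameters of every invocation as
one machine-parsable ``key=value`` line.

Round trips through any writer/reader pair here are lossless to 1e-9 for
numeric fields; readers validate invariants (monotone time, non-negative
frequencies) rather than silently repairing them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ContractError,
    DataError,
    FormatError,
    InsufficientDataError,
)

AGE_GROUPS = ("01M", "02M", "04M", "11M", "23M", "29M", "31M", "35M")

#: months of age corresponding to each group id
AGE_MONTHS = {
    "01M": 1.6, "02M": 2.6, "04M": 4.0, "11M": 11.5,
    "23M": 23.0, "29M": 29.0, "31M": 31.5, "35M": 35.3,
}

_SPECIMEN_ID_RE = re.compile(r"^mtt(\d{2})_(\d+)_t(\d+)([a-z])$")


@dataclass
class LoadDisplacementTrace:
    """One specimen's raw time/displacement/load record (mtt dialect)."""

    specimen_id: str
    time_ms: np.ndarray
    disp_signal_mv: np.ndarray
    load_signal_mv: np.ndarray
    disp_mm: np.ndarray
    load_g: np.ndarray

    def __post_init__(self):
        arrays = [self.time_ms, self.disp_signal_mv, self.load_signal_mv,
                  self.disp_mm, self.load_g]
        n = len(self.time_ms)
        if any(len(a) != n for a in arrays):
            raise DataError("trace series have unequal lengths")
        if n < 2:
            raise InsufficientDataError(
                f"trace '{self.specimen_id}' has {n} rows; need at least 2")
        if not np.all(np.diff(self.time_ms) > 0):
            raise DataError("time must be strictly increasing")
        if not np.all(np.diff(self.disp_mm) >= 0):
            raise DataError("displacement (mm) must be non-decreasing")

    def __len__(self) -> int:
        return len(self.time_ms)


def parse_specimen_id(specimen_id: str) -> dict | None:
    """Split ``mttNN_X_tYZ`` into its components.

    Returns ``None`` (the id is kept as opaque text) when the pattern does
    not match; malformed ids are never rejected.
    """
    m = _SPECIMEN_ID_RE.match(specimen_id)
    if m is None:
        return None
    nn, x, y, z = m.groups()
    return {"age_group": f"{nn}M", "sample": int(x),
            "fascicle": int(y), "segment": z}


def _as_lines(source: str | Path | IO[str]) -> list[str]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    return text.splitlines()


def _row_is_numeric(fields: Sequence[str]) -> bool:
    try:
        [float(f) for f in fields[:5]]
        return True
    except ValueError:
        return False


def read_mtt_trace(source: str | Path | IO[str],
                   specimen_id: str | None = None) -> LoadDisplacementTrace:
    """Read one mtt-dialect trace.

    Tab-delimited, >=5 columns; an optional header row is detected by a
    non-numeric first row and skipped.  Data rows with non-parsable numeric
    fields are rejected (dropped); a row with fewer than five columns is a
    :class:`FormatError` naming the offending line.
    """
    if specimen_id is None:
        specimen_id = Path(source).stem if isinstance(source, (str, Path)) else "<stream>"
    lines = [ln for ln in _as_lines(source) if ln.strip()]
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines, start=1):
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise FormatError(
                f"{specimen_id}: line {lineno} has {len(fields)} column(s); "
                f"the mtt dialect requires 5: {ln!r}")
        if not _row_is_numeric(fields):
            if lineno == 1:
                continue  # header row
            continue  # non-parsable data row: rejected
        rows.append([float(f) for f in fields[:5]])
    if len(rows) < 2:
        raise InsufficientDataError(
            f"{specimen_id}: {len(rows)} usable data rows; need at least 2")
    arr = np.asarray(rows, dtype=float)
    return LoadDisplacementTrace(
        specimen_id=specimen_id,
        time_ms=arr[:, 0], disp_signal_mv=arr[:, 1], load_signal_mv=arr[:, 2],
        disp_mm=arr[:, 3], load_g=arr[:, 4])


def write_mtt_trace(trace: LoadDisplacementTrace,
                    path: str | Path, header: bool = True) -> None:
    """Write a trace back out in the mtt dialect (tab-delimited)."""
    df = pd.DataFrame({
        "Time": trace.time_ms, "Displacement": trace.disp_signal_mv,
        "Load": trace.load_signal_mv, "mm": trace.disp_mm,
        "grams": trace.load_g,
    })
    df.to_csv(path, sep="\t", index=False, header=header,
              float_format="%.9g")


# ---------------------------------------------------------------------------
# Mechanical-property sheets (CSV mirrors of the deposited worksheets)
# ---------------------------------------------------------------------------

@dataclass
class PropertyRecord:
    """One row of a property worksheet at a given aggregation level."""

    age_group_id: str
    sample_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.age_group_id not in AGE_GROUPS:
            raise ContractError(
                f"unknown age group '{self.age_group_id}'; "
                f"expected one of {AGE_GROUPS}")


_PROPS = ["sY", "sU", "E", "uY", "uP", "uR", "uF", "u0", "uY/sY", "uF/sU"]

#: column layouts of the three worksheet levels (Data-record-2 order)
SHEET_COLUMNS = {
    "specimen": ["age_group", "sample", "file_name",
                 "sY", "eY", "E", "sU", "eU",
                 "uY", "uP", "uR", "uF", "u0", "uY/sY", "uF/sU"],
    "tail": ["age_group", "sample"] + _PROPS,
    "age_group": ["age_group"] + [f"mean_{p}" for p in _PROPS]
                 + [f"sem_{p}" for p in _PROPS],
}

_MANDATORY = {
    "specimen": SHEET_COLUMNS["specimen"][3:],
    "tail": SHEET_COLUMNS["tail"][2:],
    "age_group": [f"mean_{p}" for p in _PROPS],
}


def write_property_sheet(records: Sequence[PropertyRecord], level: str,
                         path: str | Path) -> None:
    """Write one property worksheet as CSV.

    `level` is one of ``specimen`` (columns A-O of the 'Derived parameters'
    sheet), ``tail`` ('Mean-individual mouse', A-L) or ``age_group``
    ('Mean-age group', A-U: means then SEMs).  All records must share the
    level's column set; missing mandatory columns are a contract error.
    """
    if level not in SHEET_COLUMNS:
        raise ContractError(f"unknown sheet level '{level}'")
    cols = SHEET_COLUMNS[level]
    rows = []
    for rec in records:
        missing = [c for c in _MANDATORY[level] if c not in rec.values]
        if missing:
            raise ContractError(
                f"record {rec.age_group_id}/{rec.sample_id} is missing "
                f"mandatory column(s) {missing} for level '{level}'")
        extraneous = set(rec.values) - set(cols)
        if extraneous:
            raise ContractError(
                f"record carries columns {sorted(extraneous)} not in the "
                f"'{level}' layout; records may be of mixed levels")
        row = {"age_group": rec.age_group_id, "sample": rec.sample_id}
        row.update(rec.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    if level == "age_group":
        df = df.drop(columns=["sample"], errors="ignore")
    df.to_csv(path, index=False, float_format="%.12g")


def read_property_sheet(path: str | Path, level: str) -> list[PropertyRecord]:
    """Read back a property worksheet written by :func:`write_property_sheet`."""
    if level not in SHEET_COLUMNS:
        raise ContractError(f"unknown sheet level '{level}'")
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        values = {c: row[c] for c in df.columns
                  if c not in ("age_group", "sample")}
        records.append(PropertyRecord(
            age_group_id=str(row["age_group"]),
            sample_id=str(row.get("sample", "")),
            values=values))
    return records


# ---------------------------------------------------------------------------
# Fibril structural sheets
# ---------------------------------------------------------------------------

@dataclass
class FibrilHistogram:
    """Diameter histogram for one age group (raw and normalised frequencies)."""

    bin_edges: np.ndarray      # nm, len = nbins + 1, contiguous, increasing
    freq: np.ndarray           # raw counts per bin
    norm_freq: np.ndarray      # freq / sum(freq)
    group_id: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        self.norm_freq = np.asarray(self.norm_freq, dtype=float)
        if len(self.bin_edges) != len(self.freq) + 1:
            raise DataError("bin_edges must have one more entry than freq")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise DataError("bin edges must be strictly increasing")
        if np.any(self.freq < 0):
            raise DataError("negative frequency")
        total = self.norm_freq.sum()
        if self.freq.sum() > 0 and abs(total - 1.0) > 1e-6:
            raise DataError(f"normalised frequencies sum to {total}, not 1")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def write_fibril_tables(area_fractions: Mapping[str, Sequence[float]],
                        histograms: Mapping[str, FibrilHistogram],
                        area_path: str | Path,
                        hist_path: str | Path) -> None:
    """Write the two structural sheets.

    ``area_path``: per-image area fractions, one column per age group (ragged
    groups padded with blanks).  ``hist_path``: shared 'bin' column (lower
    edge, nm) then ``freq_<group>`` and ``normfreq_<group>`` columns,
    mirroring the deposited 'Fibril diameter' worksheet.
    """
    if area_fractions:
        width = max(len(v) for v in area_fractions.values())
        adf = pd.DataFrame({
            g: list(v) + [np.nan] * (width - len(v))
            for g, v in area_fractions.items()})
        adf.to_csv(area_path, index=False, float_format="%.12g")
    if histograms:
        edges = None
        for h in histograms.values():
            if edges is None:
                edges = h.bin_edges
            elif len(h.bin_edges) != len(edges) or not np.allclose(h.bin_edges, edges):
                raise ContractError("histograms must share bin edges in one sheet")
        cols = {"bin": edges[:-1]}
        for g, h in histograms.items():
            cols[f"freq_{g}"] = h.freq
        for g, h in histograms.items():
            cols[f"normfreq_{g}"] = h.norm_freq
        pd.DataFrame(cols).to_csv(hist_path, index=False, float_format="%.12g")


def read_fibril_tables(area_path: str | Path | None,
                       hist_path: str | Path | None,
                       ) -> tuple[dict[str, np.ndarray], dict[str, FibrilHistogram]]:
    """Read area-fraction and diameter-histogram sheets.

    Bin edges are honoured as declared by the file (the deposited bin width
    is whatever the sheet says).  A group whose frequency column is all zero
    raises :class:`DataError`; negative frequencies always do.
    """
    fractions: dict[str, np.ndarray] = {}
    histograms: dict[str, FibrilHistogram] = {}
    if area_path is not None:
        adf = pd.read_csv(area_path)
        for g in adf.columns:
            vals = adf[g].dropna().to_numpy(dtype=float)
            if np.any(vals < 0):
                raise DataError(f"negative area fraction in group '{g}'")
            fractions[g] = vals
    if hist_path is not None:
        hdf = pd.read_csv(hist_path)
        if "bin" not in hdf.columns:
            raise FormatError("histogram sheet must have a 'bin' column")
        lowers = hdf["bin"].to_numpy(dtype=float)
        if len(lowers) < 2:
            raise InsufficientDataError("histogram sheet needs >= 2 bins")
        w = lowers[1] - lowers[0]
        edges = np.append(lowers, lowers[-1] + w)
        groups = [c[len("freq_"):] for c in hdf.columns if c.startswith("freq_")]
        for g in groups:
            freq = hdf[f"freq_{g}"].to_numpy(dtype=float)
            if np.any(freq < 0):
                raise DataError(f"negative frequency in group '{g}'")
            if freq.sum() == 0:
                raise DataError(f"group '{g}' has an all-zero frequency column")
            nf_col = f"normfreq_{g}"
            norm = (hdf[nf_col].to_numpy(dtype=float) if nf_col in hdf.columns
                    else freq / freq.sum())
            histograms[g] = FibrilHistogram(edges, freq, norm, group_id=g)
    return fractions, histograms


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------

RUN_LOG_MANDATORY = ("specimen", "diameter", "laststrainpt", "orderpoly",
                     "loadat1percent")


def append_run_log(path: str | Path, entry: Mapping[str, object]) -> str:
    """Append one timestamped ``key=value`` line; returns the line written.

    The entry must carry the specimen id and the four analysis inputs
    (diameter, laststrainpt, orderpoly, loadat1percent).
    """
    missing = [k for k in RUN_LOG_MANDATORY if k not in entry]
    if missing:
        raise ContractError(f"run-log entry missing mandatory key(s) {missing}")
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    parts = [stamp] + [f"{k}={entry[k]}" for k in entry]
    for p in parts:
        if " " in p:
            raise ContractError(f"run-log fields may not contain spaces: {p!r}")
    line = " ".join(parts)
    with open(path, "a") as fh:
        fh.write(line + "\n")
    return line


def _coerce(text: str) -> object:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def parse_run_log(path: str | Path) -> list[dict[str, object]]:
    """Parse a run log back into one mapping per line (order preserved)."""
    entries = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        fields = ln.split(" ")
        entry: dict[str, object] = {"timestamp": fields[0]}
        for f in fields[1:]:
            k, _, v = f.partition("=")
            entry[k] = _coerce(v)
        entries.append(entry)
    return entries
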