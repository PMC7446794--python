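"""Spectrum containers and text-format I/O.

Raman spectra of liquid urine are exchanged here as plain delimited text
(comma or tab), either *wide* (one wavenumber column, one column per scan)
or *long* (one row per measured point), plus a specimen metadata CSV.
A thin JCAMP-DX adapter handles single-block ``##XYDATA`` files.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectrumSet",
    "FormatError",
    "DataError",
    "read_spectra_table",
    "write_spectra_table",
    "read_metadata",
    "read_jcamp",
    "assemble_set",
]

REQUIRED_METADATA_COLUMNS = ("specimen_id", "class_label", "dataset")


class FormatError(ValueError):
    """A file does not follow the expected layout (headers, columns)."""


class DataError(ValueError):
    """The file parsed, but its content violates a spectrum invariant."""


@dataclass(frozen=True)
class RamanSpectrum:
    """A single Raman scan: intensity (a.u.) versus wavenumber (cm^-1).

    Wavenumbers must be strictly increasing and finite; intensity and
    wavenumber vectors have equal length >= 2.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    specimen_id: str
    scan_index: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or len(w) != len(y):
            raise DataError("wavenumbers and intensities must be equal-length 1-D vectors")
        if len(w) < 2:
            raise DataError(f"spectrum {self.specimen_id!r}:{self.scan_index} has fewer than 2 points")
        if not np.all(np.isfinite(w)):
            raise DataError("non-finite wavenumber")
        if np.any(np.diff(w) <= 0):
            raise DataError("wavenumbers must be strictly increasing")
        if self.scan_index < 0:
            raise DataError("scan_index must be >= 0")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def replace_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.wavenumbers, intensities, self.specimen_id, self.scan_index)


@dataclass
class SpectrumSet:
    """Spectra aligned on a common wavenumber grid, joined to metadata.

    ``matrix`` holds one spectrum per row (rows x wavenumbers);
    ``metadata`` is indexed by ``specimen_id`` and must cover every row.
    """

    grid: np.ndarray
    matrix: np.ndarray
    specimen_ids: list[str]
    scan_indices: list[int]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.grid):
            raise DataError("matrix must be rows x len(grid)")
        if len(self.specimen_ids) != self.matrix.shape[0] or len(self.scan_indices) != self.matrix.shape[0]:
            raise DataError("one specimen_id and scan_index per matrix row required")
        if self.metadata.index.name != "specimen_id":
            if "specimen_id" in self.metadata.columns:
                self.metadata = self.metadata.set_index("specimen_id")
            else:
                raise DataError("metadata must carry a specimen_id index or column")
        if self.metadata.index.has_duplicates:
            dupes = self.metadata.index[self.metadata.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate specimen_id in metadata: {dupes}")
        missing = sorted(set(self.specimen_ids) - set(self.metadata.index))
        if missing:
            raise DataError(f"specimens lacking metadata: {missing}")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def labels(self, column: str = "class_label") -> np.ndarray:
        """Per-row metadata values (class label by default)."""
        return self.metadata.loc[self.specimen_ids, column].to_numpy()

    def spectra(self) -> list[RamanSpectrum]:
        return [
            RamanSpectrum(self.grid, row, sid, scan)
            for row, sid, scan in zip(self.matrix, self.specimen_ids, self.scan_indices)
        ]

    def subset_rows(self, mask: np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectrumSet(
            self.grid,
            self.matrix[idx],
            [self.specimen_ids[i] for i in idx],
            [self.scan_indices[i] for i in idx],
            self.metadata,
        )


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _parse_wide_header(name: str) -> tuple[str, int]:
    m = re.fullmatch(r"(.+):(\d+)", name.strip())
    if m is None:
        raise FormatError(
            f"wide-dialect column header {name!r} must look like 'specimen_id:scan_index'"
        )
    return m.group(1), int(m.group(2))


def read_spectra_table(path: str | Path, dialect: str = "wide") -> list[RamanSpectrum]:
    """Read scans from a delimited text table.

    wide: first column is the wavenumber, each further column one scan,
    headed ``specimen_id:scan_index``.  long: columns
    ``specimen_id, scan_index, wavenumber, intensity``.  Rows with a
    non-finite intensity are dropped; wavenumbers are sorted ascending.
    Duplicate (specimen, scan) identities are a hard error.
    """
    path = Path(path)
    text = path.read_text()
    sep = _sniff_delimiter(text.splitlines()[0] if text else ",")
    if dialect == "wide":
        df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
        if df.shape[1] < 2:
            raise FormatError("wide table needs a wavenumber column plus at least one scan")
        keys = [_parse_wide_header(c) for c in df.columns[1:]]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (specimen_id, scan_index) columns")
        w = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
        out = []
        for (sid, scan), col in zip(keys, df.columns[1:]):
            y = pd.to_numeric(df[col], errors="raise").to_numpy(float)
            out.append(_build_sorted(w, y, sid, scan))
        return out
    if dialect == "long":
        df = pd.read_csv(io.StringIO(text), sep=sep, float_precision="round_trip")
        expected = ["specimen_id", "scan_index", "wavenumber", "intensity"]
        if list(df.columns[:4]) != expected:
            raise FormatError(f"long table must start with columns {expected}, got {list(df.columns)}")
        out = []
        for (sid, scan), grp in df.groupby(["specimen_id", "scan_index"], sort=True):
            out.append(
                _build_sorted(
                    grp["wavenumber"].to_numpy(float),
                    grp["intensity"].to_numpy(float),
                    str(sid),
                    int(scan),
                )
            )
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def _build_sorted(w: np.ndarray, y: np.ndarray, sid: str, scan: int) -> RamanSpectrum:
    keep = np.isfinite(y)
    w, y = w[keep], y[keep]
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    if len(w) >= 2 and np.any(np.diff(w) == 0):
        dup = w[:-1][np.diff(w) == 0]
        raise DataError(f"spectrum {sid!r}:{scan}: duplicate wavenumbers {np.unique(dup)[:5]}")
    return RamanSpectrum(w, y, sid, scan)


def write_spectra_table(spectra: Sequence[RamanSpectrum], path: str | Path, dialect: str = "wide") -> None:
    """Write scans in a format :func:`read_spectra_table` round-trips exactly."""
    path = Path(path)
    if dialect == "wide":
        grids = {tuple(s.wavenumbers) for s in spectra}
        if len(grids) != 1:
            raise DataError("wide dialect requires a shared wavenumber grid")
        cols = {"wavenumber": spectra[0].wavenumbers}
        for s in spectra:
            key = f"{s.specimen_id}:{s.scan_index}"
            if key in cols:
                raise DataError(f"duplicate scan {key}")
            cols[key] = s.intensities
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    elif dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "specimen_id": s.specimen_id,
                    "scan_index": s.scan_index,
                    "wavenumber": s.wavenumbers,
                    "intensity": s.intensities,
                }
            )
            for s in spectra
        ]
        pd.concat(frames).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata CSV (specimen_id, class_label, dataset, ...)."""
    df = pd.read_csv(path, dtype={"specimen_id": str})
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if df["specimen_id"].duplicated().any():
        raise DataError("duplicate specimen_id in metadata")
    return df.set_index("specimen_id")


# ---------------------------------------------------------------------------
# JCAMP-DX (single-block ##XYDATA=(X++(Y..Y)) only)

_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def read_jcamp(path: str | Path, specimen_id: str | None = None, scan_index: int = 0) -> RamanSpectrum:
    """Read one spectrum from a single-block JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` with XFACTOR/YFACTOR applied; each
    data line carries an abscissa followed by ordinates at DELTAX spacing.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for ln in lines:
        if ln.startswith("##"):
            key, _, val = ln[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val.strip()
        elif in_data and ln.strip():
            data_lines.append(ln)
    if not data_lines:
        raise FormatError("no ##XYDATA block found")
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    npoints = int(float(header["NPOINTS"])) if "NPOINTS" in header else None
    firstx = float(header["FIRSTX"]) if "FIRSTX" in header else None
    lastx = float(header["LASTX"]) if "LASTX" in header else None
    xs: list[float] = []
    ys: list[float] = []
    for ln in data_lines:
        vals = [float(v) for v in _NUM.findall(ln)]
        if len(vals) < 2:
            raise FormatError(f"unparseable JCAMP data line: {ln!r}")
        x0, ordinates = vals[0], vals[1:]
        if firstx is not None and lastx is not None and npoints and npoints > 1:
            dx = (lastx - firstx) / (npoints - 1)
        elif "DELTAX" in header:
            dx = float(header["DELTAX"])
        else:
            raise FormatError("cannot determine DELTAX")
        for j, y in enumerate(ordinates):
            xs.append((x0 + j * dx / xfac) * xfac)
            ys.append(y * yfac)
    sid = specimen_id or header.get("TITLE", Path(path).stem)
    return _build_sorted(np.array(xs), np.array(ys), sid, scan_index)


# ---------------------------------------------------------------------------
# assembly


def assemble_set(
    spectra: Iterable[RamanSpectrum],
    metadata: pd.DataFrame,
    grid_policy: str = "strict",
) -> SpectrumSet:
    """Align scans onto a common grid and join specimen metadata.

    ``strict`` demands identical grids.  ``intersect`` builds a uniform grid
    spanning the intersection of all wavenumber ranges at the median native
    spacing and linearly interpolates each scan onto it (interior points
    only — never extrapolates).
    """
    spectra = list(spectra)
    if not spectra:
        raise DataError("no spectra to assemble")
    seen: set[tuple[str, int]] = set()
    for s in spectra:
        key = (s.specimen_id, s.scan_index)
        if key in seen:
            raise DataError(f"duplicate (specimen, scan) {key}")
        seen.add(key)
    if metadata.index.name != "specimen_id":
        metadata = metadata.set_index("specimen_id")
    missing = sorted({s.specimen_id for s in spectra} - set(metadata.index))
    if missing:
        raise DataError(f"specimens lacking metadata: {missing}")

    if grid_policy == "strict":
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if len(s.wavenumbers) != len(grid) or not np.array_equal(s.wavenumbers, grid):
                raise DataError(f"grid of {s.specimen_id!r}:{s.scan_index} differs under strict policy")
        matrix = np.vstack([s.intensities for s in spectra])
    elif grid_policy == "intersect":
        lo = max(s.wavenumbers[0] for s in spectra)
        hi = min(s.wavenumbers[-1] for s in spectra)
        if not lo < hi:
            raise DataError(f"empty wavenumber intersection [{lo}, {hi}]")
        spacing = float(np.median(np.concatenate([np.diff(s.wavenumbers) for s in spectra])))
        n = int(np.floor((hi - lo) / spacing)) + 1
        grid = lo + spacing * np.arange(n)
        matrix = np.vstack([np.interp(grid, s.wavenumbers, s.intensities) for s in spectra])
    else:
        raise ValueError(f"unknown grid_policy {grid_policy!r}")

    return SpectrumSet(
        grid,
        matrix,
        [s.specimen_id for s in spectra],
        [s.scan_index for s in spectra],
        metadata,
    )
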