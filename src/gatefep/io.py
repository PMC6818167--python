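"""Plain-text I/O for the pipeline: XVG-dialect tables, TSV tables, and
PDB/GRO coordinates.

All tables round-trip through :func:`write_table` / :func:`read_table` at
full double precision. Coordinates are held in Å regardless of the source
format (GRO files store nm; MDAnalysis converts on load).
"""
from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

__all__ = [
    "TimeSeries",
    "StructureModel",
    "read_xvg",
    "read_table",
    "write_table",
    "read_structure",
]


@dataclass
class TimeSeries:
    """A time-indexed table of one or more named numeric columns.

    ``time`` is in ps and must be monotonically nondecreasing for traces
    that genuinely are time series; generic column tables (e.g. λ vs
    ⟨dH/dλ⟩) reuse the container with ``time`` as the leading column.
    """

    time: np.ndarray
    columns: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.size < 1:
            raise ParseError("TimeSeries needs at least one row")
        clean = {}
        for name, vals in self.columns.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != self.time.shape:
                raise ParseError(
                    f"column {name!r} has length {arr.size}, time has {self.time.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ParseError(f"column {name!r} contains non-finite values")
            clean[name] = arr
        self.columns = clean

    @property
    def n_rows(self) -> int:
        return int(self.time.size)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def values(self, name: str | None = None) -> np.ndarray:
        if name is None:
            name = next(iter(self.columns))
        return self.columns[name]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time})
        for k, v in self.columns.items():
            df[k] = v
        return df


@dataclass
class StructureModel:
    """Static coordinates: one row per atom, positions in Å."""

    atoms: pd.DataFrame  # columns: name, resname, resid, chain, x, y, z

    def __post_init__(self):
        required = {"name", "resname", "resid", "chain", "x", "y", "z"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ParseError(f"StructureModel missing columns {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ParseError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def ca_positions(self, resids) -> dict[int, np.ndarray]:
        """Map residue number → Cα position (Å) for the requested residues."""
        sel = self.atoms[(self.atoms["name"] == "CA") & self.atoms["resid"].isin(list(resids))]
        return {
            int(r.resid): np.array([r.x, r.y, r.z], dtype=float)
            for r in sel.itertuples()
        }


_LEGEND_RE = re.compile(r'@\s*s\d+\s+legend\s+"([^"]*)"')


def read_xvg(path: str | os.PathLike) -> TimeSeries:
    """Read an XVG-dialect table ('#' and '@' header lines, whitespace-
    separated numeric rows). The first column is taken as time; remaining
    columns are named from ``@ sN legend`` lines when present, else
    ``col1``, ``col2``, ...
    """
    legends: list[str] = []
    rows: list[list[float]] = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                continue
            if s.startswith("@"):
                m = _LEGEND_RE.match(s)
                if m:
                    legends.append(m.group(1))
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric data on line {lineno}") from exc
            if n_cols is None:
                n_cols = len(vals)
            elif len(vals) != n_cols:
                raise ParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(vals)} fields, expected {n_cols})"
                )
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    names = [legends[i] if i < len(legends) else f"col{i + 1}" for i in range(data.shape[1] - 1)]
    return TimeSeries(time=data[:, 0], columns={n: data[:, i + 1] for i, n in enumerate(names)})


def write_table(path: str | os.PathLike, frame: pd.DataFrame, units: dict | None = None) -> None:
    """Write a TSV with a one-line '#' header naming columns (and units)."""
    units = units or {}
    headers = [f"{c}[{units[c]}]" if c in units else str(c) for c in frame.columns]
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(headers) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(f"{v:.17g}" if isinstance(v, float) else str(v) for v in row) + "\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (units stripped from names)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}: expected '#' header line")
        names = [re.sub(r"\[[^\]]*\]$", "", c) for c in header[1:].strip().split("\t")]
        df = pd.read_csv(fh, sep="\t", names=names, comment="#")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def read_structure(path: str | os.PathLike) -> StructureModel:
    """Read coordinates from a PDB or GRO file (dialect from extension).

    GRO coordinates (nm) are converted to Å on load.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".pdb", ".gro"):
        raise FormatError(f"unsupported structure format {ext!r} (use .pdb or .gro)")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            ag = u.atoms
            n = len(ag)
            if n == 0:
                raise ParseError(f"{path}: no atoms parsed")
            try:
                chains = ag.chainIDs
            except (AttributeError, mda.exceptions.NoDataError):
                chains = ag.segids if hasattr(ag, "segids") else np.array([""] * n)
            pos = ag.positions.astype(float)  # Å in MDAnalysis for both dialects
            df = pd.DataFrame(
                {
                    "name": ag.names,
                    "resname": ag.resnames,
                    "resid": ag.resids.astype(int),
                    "chain": [str(c) for c in chains],
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                }
            )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed {ext[1:].upper()} record ({exc})") from exc
    return StructureModel(atoms=df)
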