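"""Plate-organized image discovery, image I/O and measurement export.

A plate experiment is a folder of single-plane grayscale TIFFs, one file per
(well, field, channel, timepoint) coordinate. Files are discovered by a
user-configurable filename template with named placeholders, e.g. the
default ``{row}{col:02d}_f{field:02d}_t{time:02d}_c{channel}.tif`` matches
``B03_f01_t02_c1.tif``. Vendor-specific metadata formats are deliberately
out of scope; the pattern parser covers the generic nested-folder case.

Conventions used throughout the package:

* wells are addressed with letter rows A-P and 1-based columns (microtiter
  convention); ``well_name`` renders them zero-padded, e.g. ``A01``;
* pixel coordinates are 0-based ``(row, col)`` with origin top-left;
* undefined measurements are carried as NaN in memory and exported as empty
  cells by default.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, DataIntegrityError, ImageIOError, InputError

logger = logging.getLogger(__name__)

#: Default filename template for plate folders (also used by the synthetic
#: plate writer, so generated plates parse with no configuration).
DEFAULT_PATTERN = "{row}{col:02d}_f{field:02d}_t{time:02d}_c{channel}.tif"

_ROWS = "ABCDEFGHIJKLMNOP"

Level = Literal["cell", "image", "well"]


@dataclass(frozen=True, order=True)
class PlateImageRef:
    """Coordinates of one image file within a plate."""

    well_row: str
    well_col: int
    field: int
    channel: int
    timepoint: int
    path: Path = field(compare=False)

    def __post_init__(self) -> None:
        if self.well_row not in _ROWS:
            raise InputError(f"well row must be a letter A-P, got {self.well_row!r}")
        if not 1 <= self.well_col <= 24:
            raise InputError(f"well column must be 1-24, got {self.well_col}")
        if self.field < 1 or self.channel < 1 or self.timepoint < 0:
            raise InputError(
                f"invalid coordinates field={self.field} channel={self.channel} "
                f"timepoint={self.timepoint}"
            )

    @property
    def well_name(self) -> str:
        return f"{self.well_row}{self.well_col:02d}"

    @property
    def coords(self) -> tuple[str, int, int, int, int]:
        return (self.well_row, self.well_col, self.field, self.channel, self.timepoint)


@dataclass
class MeasurementTable:
    """Flat keyed records at a single aggregation level.

    Backed by a :class:`pandas.DataFrame`; provenance columns (well_row,
    well_col, field, timepoint, and cell_id at cell level) travel with the
    records so generic export needs no extra context.
    """

    data: pd.DataFrame
    level: Level = "cell"

    def __len__(self) -> int:
        return len(self.data)

    def require_provenance(self) -> None:
        needed = {"well_row", "well_col", "field", "timepoint"}
        if self.level == "cell":
            needed.add("cell_id")
        missing = needed - set(self.data.columns)
        if missing:
            raise DataIntegrityError(
                f"{self.level}-level table missing provenance keys: {sorted(missing)}"
            )


# ---------------------------------------------------------------------------
# filename pattern handling
# ---------------------------------------------------------------------------

_PLACEHOLDER = re.compile(r"\{(row|col|field|time|channel)(?::0(\d+)d)?\}")
_GROUPS = {
    "row": r"[A-Pa-p]",
    "col": r"\d+",
    "field": r"\d+",
    "time": r"\d+",
    "channel": r"\d+",
}


def _pattern_to_regex(pattern: str) -> tuple[re.Pattern, set[str]]:
    """Compile a filename template into a regex with named groups."""
    names: set[str] = set()
    out: list[str] = []
    pos = 0
    for m in _PLACEHOLDER.finditer(pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        name, width = m.group(1), m.group(2)
        if name in names:
            raise ConfigurationError(f"placeholder {{{name}}} appears twice in pattern")
        names.add(name)
        body = rf"\d{{{int(width)},}}" if width else _GROUPS[name]
        if name == "row":
            body = _GROUPS["row"]
        out.append(rf"(?P<{name}>{body})")
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    if not names:
        raise ConfigurationError(f"pattern {pattern!r} contains no placeholders")
    required = {"row", "col", "channel"}
    if not required <= names:
        raise ConfigurationError(
            f"pattern must contain {{row}}, {{col}} and {{channel}}; got {sorted(names)}"
        )
    return re.compile("^" + "".join(out) + "$"), names


def format_ref_name(
    pattern: str, row: str, col: int, fieldno: int, time: int, channel: int
) -> str:
    """Render a filename from the template for the given coordinates."""
    return pattern.format(row=row, col=col, field=fieldno, time=time, channel=channel)


def parse_plate_folder(
    root: str | Path, pattern: str = DEFAULT_PATTERN
) -> list[PlateImageRef]:
    """Discover plate images under ``root`` matching the filename template.

    Returns one :class:`PlateImageRef` per matching file, sorted by
    (row, col, field, timepoint, channel). Non-matching files are ignored
    but counted in a log summary. Placeholders ``{field}`` and ``{time}``
    are optional in the pattern and default to 1 and 0 respectively.

    Raises
    ------
    InputError
        if ``root`` does not exist.
    ConfigurationError
        if the pattern has no placeholders or misses a required one.
    DataIntegrityError
        if two files map to the same plate coordinates.
    """
    root = Path(root)
    if not root.is_dir():
        raise InputError(f"plate folder does not exist: {root}")
    regex, _ = _pattern_to_regex(pattern)

    refs: list[PlateImageRef] = []
    seen: dict[tuple, Path] = {}
    n_ignored = 0
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        m = regex.match(path.name)
        if m is None:
            n_ignored += 1
            continue
        g = m.groupdict()
        ref = PlateImageRef(
            well_row=g["row"].upper(),
            well_col=int(g["col"]),
            field=int(g.get("field") or 1),
            channel=int(g["channel"]),
            timepoint=int(g["time"]) if g.get("time") is not None else 0,
            path=path,
        )
        if ref.coords in seen:
            raise DataIntegrityError(
                f"duplicate plate coordinates {ref.coords}: "
                f"{seen[ref.coords]} and {path}"
            )
        seen[ref.coords] = path
        refs.append(ref)

    refs.sort(key=lambda r: (r.well_row, r.well_col, r.field, r.timepoint, r.channel))
    if not refs:
        logger.warning("no files matching pattern %r under %s", pattern, root)
    logger.info(
        "parsed %s: %d refs matched, %d files ignored", root, len(refs), n_ignored
    )
    return refs


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------


def read_image(ref: PlateImageRef | str | Path) -> np.ndarray:
    """Read a single-plane grayscale TIFF, bit-exact for integer data.

    Accepts a :class:`PlateImageRef` or a bare path. Raises
    :class:`ImageIOError` carrying the plate coordinates on unreadable or
    corrupt files.
    """
    path = ref.path if isinstance(ref, PlateImageRef) else Path(ref)
    where = ref.coords if isinstance(ref, PlateImageRef) else path.name
    try:
        pixels = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ImageIOError(f"cannot read image {where} at {path}: {exc}") from exc
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ImageIOError(f"expected a single-plane 2D image at {where}, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels.astype(float, copy=False))):
        raise ImageIOError(f"non-finite intensities in image {where}")
    return pixels


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write a 2D array as a single-plane TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(pixels))


# ---------------------------------------------------------------------------
# table export
# ---------------------------------------------------------------------------


def export_table(
    table: MeasurementTable,
    destination: str | Path,
    dialect: Literal["csv", "tsv"] = "csv",
    na_rep: str = "",
) -> Path:
    """Write a measurement table as CSV/TSV with full numeric precision.

    Undefined values are rendered as empty cells by default (``na_rep``
    switches to a sentinel string); floats are written with enough digits to
    round-trip.
    """
    destination = Path(destination)
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    try:
        destination.parent.mkdir(parents=True, exist_ok=True)
        table.data.to_csv(
            destination, sep=sep, index=False, na_rep=na_rep, float_format="%.17g"
        )
    except OSError as exc:
        raise ImageIOError(f"cannot write table to {destination}: {exc}") from exc
    logger.info("wrote %d %s-level records to %s", len(table), table.level, destination)
    return destination


def read_table(source: str | Path, dialect: Literal["csv", "tsv"] = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    return pd.read_csv(source, sep=sep)


def well_name(row: str, col: int) -> str:
    """Canonical zero-padded well name, e.g. ('A', 3) -> 'A03'."""
    return f"{row.upper()}{int(col):02d}"


def normalize_well(name: str) -> str:
    """Normalize 'a1' / 'A1' / 'A01' to the canonical 'A01' form."""
    m = re.fullmatch(r"([A-Pa-p])0*(\d{1,2})", name.strip())
    if m is None:
        raise ConfigurationError(f"not a well name: {name!r}")
    return well_name(m.group(1), int(m.group(2)))


def is_undefined(value: float) -> bool:
    """True for the NaN sentinel used for undefined measurements."""
    return value is None or (isinstance(value, float) and math.isnan(value))


def iter_well_groups(
    refs: Iterable[PlateImageRef],
) -> dict[tuple[str, int, int, int], list[PlateImageRef]]:
    """Group refs by (well_row, well_col, field, timepoint), channels inside."""
    groups: dict[tuple[str, int, int, int], list[PlateImageRef]] = {}
    for ref in refs:
        key = (ref.well_row, ref.well_col, ref.field, ref.timepoint)
        groups.setdefault(key, []).append(ref)
    for g in groups.values():
        g.sort(key=lambda r: r.channel)
    return groups
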