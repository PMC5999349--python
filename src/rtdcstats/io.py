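"""Readers and writers for the plain-text interchange formats.

Event tables are TSV with a header row and ``#``-prefixed provenance
comments (seed, config hash); contours are line-oriented text blocks
(``#event <id> pixel_size=<float>`` header, ``x<TAB>y`` integer lines,
blank line terminates); image patches are 8-bit PGM files.  All numeric
output uses 9 significant digits so write-then-read round-trips are
stable at the text level.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import Contour, ImagePatch

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_contours",
    "write_contours",
    "read_pgm",
    "write_pgm",
    "read_config",
    "config_hash",
]

#: Columns allowed to carry non-numeric values.
TEXT_COLUMNS = {"roi", "condition", "verdict", "feature", "statistic",
                "event_id", "replicate"}

FLOAT_FORMAT = "%.9g"


class TableFormatError(ValueError):
    """Malformed event table (ragged row, bad cell, missing header)."""


def config_hash(config: dict | None) -> str:
    """Stable short hash of a configuration mapping."""
    items = sorted((str(k), str(v)) for k, v in (config or {}).items())
    return hashlib.md5(repr(items).encode()).hexdigest()[:12]


def write_event_table(df: pd.DataFrame, path, seed=None,
                      config: dict | None = None) -> None:
    """TSV with provenance comment lines, 9 significant digits."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write(f"# config-hash={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_event_table(path) -> pd.DataFrame:
    """Parse a TSV event table, validating shape and cell types.

    Raises :class:`TableFormatError` naming the 1-based file line for a
    ragged row or a non-numeric cell in a numeric feature column.
    Unknown extra columns are preserved untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()
    data_lines = [(i + 1, ln) for i, ln in enumerate(lines)
                  if ln.strip() and not ln.lstrip().startswith("#")]
    if not data_lines:
        raise TableFormatError(f"{path}: no header row")
    header_no, header = data_lines[0]
    ncol = len(header.split("\t"))
    for lineno, ln in data_lines[1:]:
        if len(ln.split("\t")) != ncol:
            raise TableFormatError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(_io.StringIO("\n".join(ln for _, ln in data_lines)),
                     sep="\t")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableFormatError(f"{path}: duplicate column {dup!r}")
    for col in df.columns:
        if col in TEXT_COLUMNS or df[col].dtype != object:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.all():
            continue  # a fully textual column is metadata, not a feature
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            lineno = data_lines[1 + row][0]
            raise TableFormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in "
                f"column {col!r} at line {lineno}")
        df[col] = coerced
    return df


def write_contours(events, path) -> None:
    """Write ``(event_id, Contour)`` pairs in the block text format.

    Coordinates are written as integers (pixel grid); non-integer
    vertices are rounded.
    """
    path = Path(path)
    with path.open("w") as fh:
        for event_id, contour in events:
            fh.write(f"#event {event_id} pixel_size={contour.pixel_size:.9g}\n")
            for x, y in np.round(contour.points).astype(int):
                fh.write(f"{x}\t{y}\n")
            fh.write("\n")


def read_contours(path) -> list[tuple[str, Contour]]:
    """Parse the block contour format into ``(event_id, Contour)`` pairs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    events: list[tuple[str, Contour]] = []
    event_id = None
    pixel_size = 1.0
    points: list[tuple[int, int]] = []

    def flush():
        nonlocal event_id, points
        if event_id is None:
            return
        if len(points) < 3:
            raise TableFormatError(
                f"{path}: event {event_id!r} has fewer than 3 points")
        events.append((event_id, Contour(np.array(points, dtype=float),
                                         pixel_size)))
        event_id, points = None, []

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#event"):
            flush()
            parts = line.split()
            if len(parts) < 3 or not parts[2].startswith("pixel_size="):
                raise TableFormatError(
                    f"{path}: malformed event header at line {lineno}")
            event_id = parts[1]
            pixel_size = float(parts[2].split("=", 1)[1])
            continue
        if event_id is None:
            raise TableFormatError(
                f"{path}: coordinate outside an event block at line {lineno}")
        try:
            xs, ys = line.split("\t")
            points.append((int(xs), int(ys)))
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: malformed coordinate for event {event_id!r} "
                f"at line {lineno}") from exc
    flush()
    return events


def write_pgm(image: ImagePatch, path) -> None:
    """8-bit binary (P5) PGM."""
    Image.fromarray(np.asarray(image.values, dtype=np.uint8)).save(
        Path(path), format="PPM")


def read_pgm(path, origin=(0.0, 0.0)) -> ImagePatch:
    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("L"))
    return ImagePatch(arr, origin=origin)


def read_config(path) -> dict:
    """``key = value`` lines with ``#`` comments; values auto-coerced."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise TableFormatError(f"{path}: expected key=value at line {lineno}")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = val
    return out
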