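"""Reading, writing and cataloguing explant image files.

The dataset names every file with a fixed grammar::

    EE_PPXX[u|d]_<steep>_<conc>[n|x].tif

``EE`` is the experiment number, ``PP`` the plate within the experiment and
``XX`` the explant within the plate (two digits each). The letter records the
plate orientation at capture time; ``d`` images were rotated 180° upstream so
that in *every* file the NGF gradient, when present, increases toward the top
of the image (row 0). ``<steep>`` is the gradient steepness in % concentration
change per 10 µm and ``<conc>`` the background concentration in nM, both with
``p`` as the decimal separator (``0p3`` = 0.3). A trailing ``n`` marks the
neurite-outgrowth mask, ``x`` the explant-body mask, and no suffix the raw
image. Example: ``03_0704d_0p3_000p100.tif`` is experiment 3, plate 7,
explant 4, steepness 0.3 %/10 µm, background 0.1 nM.

Masks are stored as single-plane grayscale TIFFs; any non-zero value is
foreground (the distributed masks are already binarised).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile

from .config import DEFAULT_SCALE_UM_PER_PX, log

Role = Literal["raw", "neurite_mask", "explant_mask"]

_ROLE_BY_SUFFIX: dict[str, Role] = {"": "raw", "n": "neurite_mask", "x": "explant_mask"}
_SUFFIX_BY_ROLE = {v: k for k, v in _ROLE_BY_SUFFIX.items()}


class FilenameParseError(ValueError):
    """A filename does not follow the dataset grammar."""


class FilenameFormatError(ValueError):
    """A record cannot be represented in the dataset's digit widths."""


class CatalogError(ValueError):
    """Inconsistent file collection (e.g. duplicate stems)."""


class MaskIOError(IOError):
    """A mask file could not be read as a single-plane grayscale image."""


@dataclass(frozen=True)
class ExplantRecord:
    """Identity and condition metadata parsed from one filename.

    ``orientation`` is provenance only: ``d`` images were already rotated
    upstream, so no geometric correction is applied anywhere in the package.
    """

    experiment: int
    plate: int
    explant: int
    orientation: Literal["u", "d"]
    steepness: float  # % concentration change per 10 µm
    concentration: float  # background concentration, nM
    role: Role = "raw"

    def __post_init__(self) -> None:
        if self.steepness < 0:
            raise ValueError("steepness must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.orientation not in ("u", "d"):
            raise ValueError("orientation must be 'u' or 'd'")
        if self.role not in _SUFFIX_BY_ROLE:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def stem(self) -> str:
        """Canonical filename stem without role suffix or extension."""
        return format_filename(self.with_role("raw"))[: -len(".tif")]

    def with_role(self, role: Role) -> "ExplantRecord":
        return ExplantRecord(
            self.experiment, self.plate, self.explant, self.orientation,
            self.steepness, self.concentration, role,
        )


# Grammar element checks in left-to-right order so parse errors can name the
# first violated element.
_ELEMENTS = [
    ("experiment number (2 digits)", r"\d{2}"),
    ("separator '_'", r"_"),
    ("plate number (2 digits)", r"\d{2}"),
    ("explant number (2 digits)", r"\d{2}"),
    ("orientation letter 'u' or 'd'", r"[ud]"),
    ("separator '_'", r"_"),
    ("steepness digits with 'p' decimal separator", r"\d+p\d+"),
    ("separator '_'", r"_"),
    ("concentration digits with 'p' decimal separator", r"\d+p\d+"),
    ("role suffix ('', 'n' or 'x')", r"[nx]?"),
    ("extension", r"(?:\.tiff?)?"),
]


def _decode_p_number(text: str) -> float:
    whole, frac = text.split("p")
    # single division so e.g. '001p997' decodes to exactly 1997/1000
    return (int(whole) * 10 ** len(frac) + int(frac)) / 10 ** len(frac)


def parse_filename(name: str) -> ExplantRecord:
    """Parse a dataset filename (with or without ``.tif``) into a record.

    Raises
    ------
    FilenameParseError
        Naming the first grammar element the name violates.
    """
    base = Path(name).name
    pos = 0
    groups: list[str] = []
    for label, pattern in _ELEMENTS:
        m = re.match(pattern, base[pos:])
        if m is None:
            raise FilenameParseError(
                f"{base!r}: expected {label} at position {pos}"
            )
        groups.append(m.group(0))
        pos += m.end()
    if pos != len(base):
        raise FilenameParseError(f"{base!r}: trailing characters at position {pos}")
    return ExplantRecord(
        experiment=int(groups[0]),
        plate=int(groups[2]),
        explant=int(groups[3]),
        orientation=groups[4],  # type: ignore[arg-type]
        steepness=_decode_p_number(groups[6]),
        concentration=_decode_p_number(groups[8]),
        role=_ROLE_BY_SUFFIX[groups[9]],
    )


def _encode_p_number(value: float, int_digits: int, frac_digits: int, what: str) -> str:
    scaled = value * 10**frac_digits
    if abs(scaled - round(scaled)) > 1e-6:
        raise FilenameFormatError(
            f"{what} {value} not representable with {frac_digits} fractional digits"
        )
    scaled = round(scaled)
    whole, frac = divmod(scaled, 10**frac_digits)
    if whole >= 10**int_digits:
        raise FilenameFormatError(
            f"{what} {value} exceeds {int_digits} integer digits"
        )
    return f"{whole:0{int_digits}d}p{frac:0{frac_digits}d}"


def format_filename(record: ExplantRecord) -> str:
    """Render a record back to its canonical filename (inverse of parse).

    Digit widths follow the dataset exemplars: two digits for experiment,
    plate and explant, ``1p1`` for steepness and ``3p3`` for concentration
    (e.g. 0.1 nM -> ``000p100``).
    """
    for field_name in ("experiment", "plate", "explant"):
        v = getattr(record, field_name)
        if not 0 <= v <= 99:
            raise FilenameFormatError(f"{field_name} {v} outside 2-digit range")
    steep = _encode_p_number(record.steepness, 1, 1, "steepness")
    conc = _encode_p_number(record.concentration, 3, 3, "concentration")
    return (
        f"{record.experiment:02d}_{record.plate:02d}{record.explant:02d}"
        f"{record.orientation}_{steep}_{conc}{_SUFFIX_BY_ROLE[record.role]}.tif"
    )


@dataclass
class BinaryMask:
    """A 2-D boolean pixel grid with its physical scale.

    Orientation contract shared by the whole package: the gradient, when
    present, increases toward row 0 (the top of the image).
    """

    pixels: np.ndarray
    scale: float = DEFAULT_SCALE_UM_PER_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        """Number of foreground pixels."""
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


def load_mask(path: str | Path, scale: float = DEFAULT_SCALE_UM_PER_PX) -> BinaryMask:
    """Load a single-plane grayscale image as a boolean mask.

    A pixel is foreground iff its stored value is non-zero; works for 8- and
    16-bit masks alike.
    """
    try:
        data = tifffile.imread(str(path))
    except FileNotFoundError:
        raise MaskIOError(f"mask file not found: {path}") from None
    except Exception as exc:  # tifffile raises several error types
        raise MaskIOError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 2:
        raise MaskIOError(
            f"{path}: expected a single-plane grayscale image, got shape {data.shape}"
        )
    return BinaryMask(data != 0, scale=scale)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a boolean mask as an 8-bit TIFF (foreground = 255)."""
    tifffile.imwrite(str(path), mask.pixels.astype(np.uint8) * 255)


@dataclass
class CatalogEntry:
    """All files sharing one stem: raw image plus the two masks."""

    record: ExplantRecord  # canonical (role 'raw') identity
    paths: dict[Role, Path] = field(default_factory=dict)

    @property
    def stem(self) -> str:
        return self.record.stem

    @property
    def missing_roles(self) -> tuple[Role, ...]:
        return tuple(r for r in ("raw", "neurite_mask", "explant_mask") if r not in self.paths)

    @property
    def complete(self) -> bool:
        return "neurite_mask" in self.paths and "explant_mask" in self.paths


@dataclass
class ConditionGrid:
    """Index of catalog entries by (steepness, concentration) condition."""

    steepness_levels: list[float]
    concentration_levels: list[float]
    cells: dict[tuple[float, float], list[int]]

    def indices(self, steepness: float, concentration: float) -> list[int]:
        return self.cells.get((steepness, concentration), [])


def build_catalog(directory: str | Path) -> tuple[list[CatalogEntry], ConditionGrid]:
    """Scan a directory tree for grammar-conforming files and group by stem.

    Files whose names do not parse are ignored with a log message. Entries
    missing one or both masks are kept and flagged (``CatalogEntry.complete``),
    never silently dropped. Condition levels are inferred from the files
    actually present.

    Raises
    ------
    CatalogError
        If two files claim the same stem and role.
    """
    directory = Path(directory)
    entries: dict[str, CatalogEntry] = {}
    for path in sorted(directory.rglob("*.tif")) + sorted(directory.rglob("*.tiff")):
        try:
            rec = parse_filename(path.name)
        except FilenameParseError:
            log.debug("skipping non-conforming file %s", path.name)
            continue
        stem = rec.stem
        entry = entries.setdefault(stem, CatalogEntry(record=rec.with_role("raw")))
        if rec.role in entry.paths:
            raise CatalogError(
                f"duplicate role {rec.role!r} for stem {stem!r}: "
                f"{entry.paths[rec.role]} and {path}"
            )
        entry.paths[rec.role] = path

    ordered = [entries[s] for s in sorted(entries)]
    for e in ordered:
        if not e.complete:
            log.warning("incomplete entry %s: missing %s", e.stem, ", ".join(e.missing_roles))

    cells: dict[tuple[float, float], list[int]] = {}
    for i, e in enumerate(ordered):
        key = (e.record.steepness, e.record.concentration)
        cells.setdefault(key, []).append(i)
    grid = ConditionGrid(
        steepness_levels=sorted({k[0] for k in cells}),
        concentration_levels=sorted({k[1] for k in cells}),
        cells=cells,
    )
    return ordered, grid


def catalog_to_frame(entries: list[CatalogEntry]) -> pd.DataFrame:
    """One row per explant: record fields, file paths, completeness flag."""
    rows = []
    for e in entries:
        r = e.record
        rows.append(
            {
                "stem": e.stem,
                "experiment": r.experiment,
                "plate": r.plate,
                "explant": r.explant,
                "orientation": r.orientation,
                "steepness": r.steepness,
                "concentration": r.concentration,
                "raw_path": str(e.paths.get("raw", "")),
                "neurite_mask_path": str(e.paths.get("neurite_mask", "")),
                "explant_mask_path": str(e.paths.get("explant_mask", "")),
                "complete": e.complete,
            }
        )
    return pd.DataFrame(rows)


def export_catalog(
    entries: list[CatalogEntry], grid: ConditionGrid, csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write the catalog as CSV (one explant per row) and optional JSON."""
    catalog_to_frame(entries).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "entries": catalog_to_frame(entries).to_dict(orient="records"),
            "steepness_levels": grid.steepness_levels,
            "concentration_levels": grid.concentration_levels,
            "cells": {
                f"{s}|{c}": idx for (s, c), idx in sorted(grid.cells.items())
            },
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))
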