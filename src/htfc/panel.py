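"""Antibody panels, plate maps, and the no-staining antibody table.

A screen is laid out as an "antibody array": 96-well plates with one
directly conjugated antibody per well plus buffer-only CONTROL wells that
serve as fluorescence-minus-one (FMO) references for gating.  The plate
map is the experimental-design object the rest of the pipeline keys on.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Antibody",
    "CONTROL",
    "PanelPlateMap",
    "NonStainingRecord",
    "PlateMapError",
    "FLUOROCHROME_CHANNELS",
    "load_plate_map",
    "save_plate_map",
    "demo_plate_map",
    "compute_staining_dilution",
    "load_nonstaining_table",
    "summarize_nonstaining",
]

#: Sentinel token marking an FMO/buffer-only control well in plate maps.
CONTROL = "CONTROL"

#: Detector channel reported by each supported fluorochrome.  The panel
#: proper uses PE/FITC/APC; the extended entries are for lineage co-stains.
FLUOROCHROME_CHANNELS: dict[str, str] = {
    "PE": "PE-A",
    "FITC": "FITC-A",
    "APC": "APC-A",
    "APC-Cy7": "APC-Cy7-A",
    "PE-Cy7": "PE-Cy7-A",
    "PerCP-Cy5.5": "PerCP-Cy5.5-A",
    "eFluor450": "eFluor450-A",
}

_WELL_RE = re.compile(r"^([A-H])([1-9]|1[0-2])$")


class PlateMapError(ValueError):
    """Structured plate-map validation failure; message names plate/well."""


@dataclass(frozen=True)
class Antibody:
    """A directly fluorochrome-conjugated antibody against one surface antigen."""

    antigen_name: str
    fluorochrome: str
    clone: str | None = None

    def __post_init__(self) -> None:
        if not self.antigen_name:
            raise PlateMapError("antigen_name must be non-empty")
        if self.fluorochrome not in FLUOROCHROME_CHANNELS:
            raise PlateMapError(
                f"unknown fluorochrome {self.fluorochrome!r} for antigen "
                f"{self.antigen_name!r}; known: {sorted(FLUOROCHROME_CHANNELS)}"
            )

    @property
    def channel_name(self) -> str:
        return FLUOROCHROME_CHANNELS[self.fluorochrome]


@dataclass(frozen=True)
class ControlWell:
    """FMO/buffer-only well; carries the fluorochrome whose channel it controls."""

    fluorochrome: str

    def __post_init__(self) -> None:
        if self.fluorochrome not in FLUOROCHROME_CHANNELS:
            raise PlateMapError(f"unknown control fluorochrome {self.fluorochrome!r}")

    @property
    def channel_name(self) -> str:
        return FLUOROCHROME_CHANNELS[self.fluorochrome]


def _validate_well(plate: str, well: str) -> str:
    if not _WELL_RE.match(well):
        raise PlateMapError(
            f"malformed well coordinate {well!r} on plate {plate!r} "
            "(expected A1..H12, uppercase, no zero padding)"
        )
    return well


@dataclass
class PanelPlateMap:
    """Plate/well -> antibody assignment for a screening run.

    ``wells`` maps ``(plate, well)`` to an :class:`Antibody` or a
    :class:`ControlWell`.  Staining volumes default to the 2 µl antibody +
    48 µl buffer + 50 µl cells layout (a 1:50 final dilution).
    """

    plates: list[str]
    wells: dict[tuple[str, str], Antibody | ControlWell]
    antibody_volume_ul: float = 2.0
    buffer_volume_ul: float = 48.0
    cell_volume_ul: float = 50.0

    def __post_init__(self) -> None:
        seen_antigens: dict[str, tuple[str, str]] = {}
        per_plate_controls: dict[str, int] = {p: 0 for p in self.plates}
        for (plate, well), entry in self.wells.items():
            if plate not in self.plates:
                raise PlateMapError(f"well {well!r} references unknown plate {plate!r}")
            _validate_well(plate, well)
            if isinstance(entry, ControlWell):
                per_plate_controls[plate] += 1
            else:
                prev = seen_antigens.get(entry.antigen_name)
                if prev is not None:
                    raise PlateMapError(
                        f"antigen {entry.antigen_name!r} assigned twice: "
                        f"{prev} and {(plate, well)}"
                    )
                seen_antigens[entry.antigen_name] = (plate, well)
        for plate, n in per_plate_controls.items():
            if n == 0:
                raise PlateMapError(f"no control well on plate {plate!r}")

    @property
    def antibodies(self) -> list[Antibody]:
        return [e for e in self.wells.values() if isinstance(e, Antibody)]

    @property
    def control_wells(self) -> list[tuple[str, str]]:
        return [k for k, e in self.wells.items() if isinstance(e, ControlWell)]

    @property
    def antigens(self) -> list[str]:
        return [ab.antigen_name for ab in self.antibodies]

    def dilution_factor(self) -> float:
        return compute_staining_dilution(
            self.antibody_volume_ul, self.buffer_volume_ul, self.cell_volume_ul
        )


def compute_staining_dilution(
    antibody_volume_ul: float, buffer_volume_ul: float, cell_volume_ul: float
) -> float:
    """Final antibody dilution factor in the well (fold).

    (antibody + buffer + cells) / antibody; the default plate layout
    (2, 48, 50) gives the canonical 1:50.
    """
    if antibody_volume_ul <= 0:
        raise ValueError("antibody volume must be > 0")
    if buffer_volume_ul < 0 or cell_volume_ul < 0:
        raise ValueError("volumes must be >= 0")
    return (antibody_volume_ul + buffer_volume_ul + cell_volume_ul) / antibody_volume_ul


# ---------------------------------------------------------------------------
# Plate-map I/O: CSV dialect  plate,well,antigen,fluorochrome,clone
# with the literal token CONTROL in the antigen column for control wells.
# ---------------------------------------------------------------------------

_HEADER = ["plate", "well", "antigen", "fluorochrome", "clone"]


def _parse_plate_map(rows: Iterable[dict[str, str]]) -> PanelPlateMap:
    plates: list[str] = []
    wells: dict[tuple[str, str], Antibody | ControlWell] = {}
    for i, row in enumerate(rows, start=2):
        missing = [c for c in _HEADER[:4] if not (row.get(c) or "").strip()]
        if missing:
            raise PlateMapError(f"line {i}: missing column(s) {missing}")
        plate = row["plate"].strip()
        well = _validate_well(plate, row["well"].strip())
        if plate not in plates:
            plates.append(plate)
        key = (plate, well)
        if key in wells:
            raise PlateMapError(f"duplicate well {well!r} on plate {plate!r}")
        antigen = row["antigen"].strip()
        fluor = row["fluorochrome"].strip()
        clone = (row.get("clone") or "").strip() or None
        if antigen == CONTROL:
            wells[key] = ControlWell(fluor)
        else:
            wells[key] = Antibody(antigen, fluor, clone)
    if not wells:
        raise PlateMapError("plate map has no wells")
    return PanelPlateMap(plates=plates, wells=wells)


def load_plate_map(path: str | Path) -> PanelPlateMap:
    """Load and validate a plate map from the documented CSV dialect."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _HEADER:
            raise PlateMapError(
                f"{path}: expected header {','.join(_HEADER)}, got {reader.fieldnames}"
            )
        return _parse_plate_map(reader)


def save_plate_map(pmap: PanelPlateMap, path: str | Path) -> None:
    """Write the canonical CSV form (row order: plate order, then well sort)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_HEADER)

    def well_key(item: tuple[tuple[str, str], object]) -> tuple[int, str, int]:
        (plate, well), _ = item
        m = _WELL_RE.match(well)
        assert m is not None
        return (pmap.plates.index(plate), m.group(1), int(m.group(2)))

    for (plate, well), entry in sorted(pmap.wells.items(), key=well_key):
        if isinstance(entry, ControlWell):
            writer.writerow([plate, well, CONTROL, entry.fluorochrome, ""])
        else:
            writer.writerow([plate, well, entry.antigen_name, entry.fluorochrome, entry.clone or ""])
    Path(path).write_text(buf.getvalue())


def demo_plate_map() -> PanelPlateMap:
    """The packaged 24-antibody single-plate demo panel (plus 4 control wells)."""
    with resources.as_file(resources.files("htfc.data") / "demo_panel.csv") as p:
        return load_plate_map(p)


# ---------------------------------------------------------------------------
# No-staining antibody table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NonStainingRecord:
    """One antibody that never stained any cell type in the screen."""

    antigen_name: str
    expected_cell_type: str
    cell_type_analyzed: bool


def load_nonstaining_table(path: str | Path | None = None) -> list[NonStainingRecord]:
    """Load the packaged no-staining antibody table (or a user CSV)."""
    if path is None:
        ctx = resources.as_file(resources.files("htfc.data") / "table1_nonstaining.csv")
    else:
        ctx = None
    if ctx is not None:
        with ctx as p:
            return load_nonstaining_table(p)
    records = []
    with open(path, newline="") as fh:  # type: ignore[arg-type]
        for row in csv.DictReader(fh):
            records.append(
                NonStainingRecord(
                    antigen_name=row["antigen"],
                    expected_cell_type=row["expected_cell_type"],
                    cell_type_analyzed=row["cell_type_analyzed"].strip().lower()
                    in {"true", "yes", "1"},
                )
            )
    return records


def summarize_nonstaining(records: list[NonStainingRecord]) -> dict[str, int]:
    """Direct counts over the no-staining table.

    Returns total records, how many were on a cell type actually analyzed
    (antibodies that should have stained but did not), and the complement.
    """
    if not records:
        raise ValueError("records must be non-empty")
    analyzed_yes = sum(r.cell_type_analyzed for r in records)
    return {
        "total": len(records),
        "analyzed_yes": analyzed_yes,
        "analyzed_no": len(records) - analyzed_yes,
    }
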