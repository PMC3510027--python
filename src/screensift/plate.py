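"""Per-well caspase activity from kinetic fluorescence plate reads.

A screening plate is read repeatedly on a fluorescence reader while a
fluorogenic caspase 3/7 substrate is cleaved; the cleavage rate in a well
is the ordinary-least-squares slope of RFU against time.  Activity is that
slope normalized to the total protein recovered from the well (BCA assay),
in RFU·min⁻¹·mg⁻¹, so wells with unequal cell mass remain comparable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("test", "neg_control", "pos_control", "tox_control_nt", "tox_control_casp3")
CONTROL_ROLES = ROLES[1:]

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class PlateError(ValueError):
    """Raised on malformed plate inputs (bad wells, duplicate reads, ...)."""


def well_to_rc(well: str) -> tuple[int, int]:
    """Parse a letter+number well label ('A1'..'H12') to 0-based (row, col)."""
    m = _WELL_RE.match(well.strip())
    if not m:
        raise PlateError(f"malformed well label {well!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if not 0 <= col < 12:
        raise PlateError(f"well column out of range in {well!r}")
    return row, col


def rc_to_well(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass
class KineticRead:
    """Time series of fluorescence reads for one well.

    Parameters
    ----------
    plate_id : str
        Plate identifier.
    well : str
        Well label, 'A1'..'H12'.
    times : ndarray
        Read times in minutes, strictly increasing, length >= 2.
    rfu : ndarray
        Relative fluorescence units, same length as ``times``, finite.
    """

    plate_id: str
    well: str
    times: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        well_to_rc(self.well)
        if self.times.size != self.rfu.size:
            raise PlateError(
                f"{self.plate_id}/{self.well}: times and rfu lengths differ"
            )
        if self.times.size < 2:
            raise PlateError(f"{self.plate_id}/{self.well}: need >= 2 reads")
        if not np.all(np.diff(self.times) > 0):
            raise PlateError(
                f"{self.plate_id}/{self.well}: times not strictly increasing"
            )
        if not np.all(np.isfinite(self.rfu)):
            raise PlateError(f"{self.plate_id}/{self.well}: non-finite rfu")


@dataclass
class WellMeasurement:
    """Fitted slope, protein mass, and derived activity for one well."""

    plate_id: str
    well: str
    slope: float
    protein_mg: float
    activity: float


@dataclass
class PlateLayout:
    """Role map of a plate: which wells hold test siRNAs vs controls.

    Each plate carries a configured number of wells (default 3) for each
    of four control types: mutant construct with non-targeting siRNA
    (``neg_control``, the normalization reference), mutant construct with
    CASP3 siRNA (``pos_control``), and wild-type construct with
    non-targeting or CASP3 siRNA (the two toxicity controls).
    """

    plate_id: str
    roles: dict[str, str]
    sirna: dict[str, str] = field(default_factory=dict)
    n_control_wells: int = 3

    def __post_init__(self) -> None:
        for well, role in self.roles.items():
            well_to_rc(well)
            if role not in ROLES:
                raise PlateError(f"{self.plate_id}/{well}: unknown role {role!r}")
        for role in CONTROL_ROLES:
            n = sum(1 for r in self.roles.values() if r == role)
            if n != self.n_control_wells:
                raise PlateError(
                    f"{self.plate_id}: role {role} occupies {n} wells, "
                    f"expected {self.n_control_wells}"
                )
        for well in self.sirna:
            if self.roles.get(well) != "test":
                raise PlateError(
                    f"{self.plate_id}/{well}: siRNA assigned to non-test well"
                )

    @property
    def test_wells(self) -> list[str]:
        return [w for w, r in self.roles.items() if r == "test"]


def read_kinetic_csv(path) -> list[KineticRead]:
    """Read long-format kinetic data (plate_id,well,time_min,rfu) into reads.

    One :class:`KineticRead` is produced per (plate_id, well), with times
    sorted ascending; row order in the file is irrelevant.  Duplicate
    (plate, well, time) triples and non-numeric fields are hard errors.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    required = {"plate_id", "well", "time_min", "rfu"}
    missing = required - set(df.columns)
    if missing:
        raise PlateError(f"kinetic CSV missing columns: {sorted(missing)}")
    for col in ("time_min", "rfu"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            # +2: header line plus 1-based numbering
            line = int((bad | df[col].isna()).idxmax()) + 2
            raise PlateError(f"non-numeric {col} at line {line}")
        df[col] = vals
    dup = df.duplicated(subset=["plate_id", "well", "time_min"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise PlateError(
            "duplicate kinetic read for "
            f"({row.plate_id}, {row.well}, {row.time_min})"
        )
    reads = []
    for (plate_id, well), grp in df.groupby(["plate_id", "well"], sort=True):
        grp = grp.sort_values("time_min")
        reads.append(
            KineticRead(plate_id, well, grp["time_min"].to_numpy(), grp["rfu"].to_numpy())
        )
    return reads


def write_kinetic_csv(reads: list[KineticRead], path) -> None:
    """Write reads back to the long CSV dialect consumed by read_kinetic_csv."""
    rows = []
    for r in sorted(reads, key=lambda r: (r.plate_id, well_to_rc(r.well))):
        for t, y in zip(r.times, r.rfu):
            rows.append((r.plate_id, r.well, t, y))
    pd.DataFrame(rows, columns=["plate_id", "well", "time_min", "rfu"]).to_csv(
        path, index=False
    )


def fit_kinetic_slope(read: KineticRead) -> float:
    """OLS slope of RFU against time, in RFU/min.

    Negative slopes are returned unmodified; downstream normalization
    operates on raw values.
    """
    t = read.times
    y = read.rfu
    if np.ptp(t) == 0:
        raise PlateError(f"{read.plate_id}/{read.well}: degenerate time axis")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))


def compute_activity(slope: float, protein_mg: float) -> float:
    """Caspase activity in RFU·min⁻¹·mg⁻¹: slope over total well protein."""
    if protein_mg <= 0:
        raise PlateError(f"nonpositive protein mass {protein_mg}")
    return slope / protein_mg


def read_protein_csv(path) -> dict[tuple[str, str], float]:
    """Read per-well protein masses (plate_id,well,protein_mg)."""
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    missing = {"plate_id", "well", "protein_mg"} - set(df.columns)
    if missing:
        raise PlateError(f"protein CSV missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["plate_id", "well"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise PlateError(f"duplicate protein row for ({row.plate_id}, {row.well})")
    return {
        (r.plate_id, r.well): float(r.protein_mg) for r in df.itertuples(index=False)
    }


def read_layout_csv(path, n_control_wells: int = 3) -> dict[str, PlateLayout]:
    """Read plate layouts (plate_id,well,role,sirna_id) keyed by plate."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"plate_id", "well", "role", "sirna_id"} - set(df.columns)
    if missing:
        raise PlateError(f"layout CSV missing columns: {sorted(missing)}")
    layouts = {}
    for plate_id, grp in df.groupby("plate_id", sort=True):
        if grp.duplicated(subset="well").any():
            raise PlateError(f"{plate_id}: duplicate well in layout")
        roles = dict(zip(grp.well, grp.role))
        sirna = {w: s for w, s in zip(grp.well, grp.sirna_id) if s}
        layouts[plate_id] = PlateLayout(plate_id, roles, sirna, n_control_wells)
    return layouts


def quantify_plates(
    reads: list[KineticRead],
    protein: dict[tuple[str, str], float],
    layouts: dict[str, PlateLayout],
) -> pd.DataFrame:
    """Combine kinetics, protein and layout into a per-well activity table.

    Returns a DataFrame with columns plate_id, well, role, sirna_id,
    slope, protein_mg, activity — the interchange format consumed by the
    normalization stage.
    """
    rows = []
    for read in reads:
        key = (read.plate_id, read.well)
        if key not in protein:
            raise PlateError(f"no protein mass for {key[0]}/{key[1]}")
        layout = layouts.get(read.plate_id)
        if layout is None:
            raise PlateError(f"no layout for plate {read.plate_id}")
        role = layout.roles.get(read.well)
        if role is None:
            raise PlateError(f"no layout role for {read.plate_id}/{read.well}")
        slope = fit_kinetic_slope(read)
        mg = protein[key]
        rows.append(
            {
                "plate_id": read.plate_id,
                "well": read.well,
                "role": role,
                "sirna_id": layout.sirna.get(read.well, ""),
                "slope": slope,
                "protein_mg": mg,
                "activity": compute_activity(slope, mg),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["plate_id", "well"], key=_well_sort_key).reset_index(
        drop=True
    )


def _well_sort_key(col: pd.Series) -> pd.Series:
    if col.name == "well":
        return col.map(well_to_rc)
    return col


def write_activity_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_activity_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well": str})
    df["sirna_id"] = df["sirna_id"].fillna("")
    return df
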