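"""Combinatorial layout of the spheroid drug-combination screen.

The screen titrates two drugs in 3-fold dilutions across a 6x6 checkerboard
(five non-zero concentrations per drug plus a zero-dose row/column), one
single-spheroid well per cell in a round-bottom plate.  Each plate holds one
cell line x one drug pair x one technical replicate; the well at matrix
position (0, 0) is the untreated control used as the 100 %-viability
reference.  This module is the single source of truth for that coordinate
system: every other stage (simulation, decoding, synergy) addresses wells as
``(cell_line, pair, replicate, row, col)`` records produced here.

Matrix orientation: row index = drug-1 dose, column index = drug-2 dose,
both ascending from index 0 (zero dose), so the top-left cell is untreated
and doses increase toward the bottom-right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

__all__ = [
    "DoseSeries",
    "DrugPair",
    "StudyDesign",
    "DRUG_PAIR_REGISTRY",
    "CELL_LINES",
    "IMAGING_DAYS",
    "IMAGING_DAYS_FIGURE_CONVENTION",
    "EXPOSURE_WINDOWS",
    "dilution_series",
    "enumerate_wells",
    "paper_design",
    "desk_design",
    "write_plate_map",
    "read_plate_map",
    "write_design_config",
    "read_design_config",
]

#: Cell-line identifiers of the glioblastoma sphere models screened.
CELL_LINES: tuple[str, ...] = ("GBM8", "GSC11", "GSC7-10")

#: Imaging days, 0-based from the seeding day, as given in the methods text.
IMAGING_DAYS: tuple[int, ...] = (1, 4, 8, 11, 15, 18)

#: The experiment-overview figure instead lists day 0 as the first imaging
#: day.  The discrepancy with :data:`IMAGING_DAYS` is in the source protocol
#: itself; both conventions are kept and neither is silently "corrected".
IMAGING_DAYS_FIGURE_CONVENTION: tuple[int, ...] = (0, 4, 8, 11, 15, 18)

#: Drug-exposure windows (start_day, end_day): combinations applied on days
#: 4 and 11, washed out at the start of the recovery days 8 and 15.
EXPOSURE_WINDOWS: tuple[tuple[int, int], ...] = ((4, 8), (11, 15))


@dataclass(frozen=True)
class DoseSeries:
    """A geometric dilution series ending in a zero dose.

    ``values`` holds the unrounded concentrations in descending order with a
    single trailing 0; ``rounded_values`` applies the presentation rounding
    (the screen's concentration tables print 4 decimals).
    """

    max_conc: float
    factor: float
    n_nonzero: int
    decimals: int = 4

    @property
    def values(self) -> tuple[float, ...]:
        vals = tuple(self.max_conc / self.factor**i for i in range(self.n_nonzero))
        return vals + (0.0,)

    @property
    def rounded_values(self) -> tuple[float, ...]:
        return tuple(round(v, self.decimals) for v in self.values)

    @property
    def ascending(self) -> tuple[float, ...]:
        """Concentrations ascending from 0, the dose-matrix axis order."""
        return tuple(reversed(self.values))

    def __len__(self) -> int:
        return self.n_nonzero + 1


def dilution_series(
    max_conc: float, factor: float, n_nonzero: int, decimals: int = 4
) -> DoseSeries:
    """Build the n-point serial dilution of a drug plus its zero dose.

    Parameters
    ----------
    max_conc:
        Highest concentration in µM; the screen starts each titration here.
    factor:
        Dilution ratio between consecutive doses (3 for a 3-fold series).
    n_nonzero:
        Number of non-zero concentrations (5 in the 6x6 checkerboard).
    decimals:
        Presentation rounding for :attr:`DoseSeries.rounded_values`.
    """
    if max_conc <= 0:
        raise ValueError(f"max_conc must be positive, got {max_conc}")
    if factor <= 1:
        raise ValueError(f"dilution factor must exceed 1, got {factor}")
    if n_nonzero < 1:
        raise ValueError(f"need at least one non-zero dose, got {n_nonzero}")
    return DoseSeries(float(max_conc), float(factor), int(n_nonzero), int(decimals))


@dataclass(frozen=True)
class DrugPair:
    """A two-drug combination with per-cell-line maximum concentrations (µM)."""

    drug1: str
    drug2: str
    #: cell line -> (max conc drug1, max conc drug2), µM
    max_conc: dict[str, tuple[float, float]] = field(hash=False)

    @property
    def name(self) -> str:
        return f"{self.drug1}+{self.drug2}"

    def series(
        self, cell_line: str, factor: float = 3.0, n_nonzero: int = 5
    ) -> tuple[DoseSeries, DoseSeries]:
        m1, m2 = self.max_conc[cell_line]
        return (
            dilution_series(m1, factor, n_nonzero),
            dilution_series(m2, factor, n_nonzero),
        )


def _pair(d1: str, d2: str, gbm8, gsc11, gsc710) -> DrugPair:
    return DrugPair(d1, d2, {"GBM8": gbm8, "GSC11": gsc11, "GSC7-10": gsc710})


#: The 16 screened combinations with the highest used concentration (µM) of
#: each drug per glioblastoma culture; each titrated 3-fold from these maxima.
DRUG_PAIR_REGISTRY: tuple[DrugPair, ...] = (
    _pair("CGP-082996", "Obatoclax mesylate", (5, 0.50), (5, 0.50), (5, 0.50)),
    _pair("Lapatinib", "Gemcitabine", (5, 0.05), (5, 5.00), (5, 5.00)),
    _pair("Lapatinib", "Vinorelbine", (5, 0.05), (5, 0.05), (5, 0.05)),
    _pair("Lapatinib", "Obatoclax mesylate", (5, 0.50), (5, 0.50), (5, 0.50)),
    _pair("Erlotinib", "Gemcitabine", (5, 0.05), (5, 5.00), (5, 5.00)),
    _pair("Erlotinib", "Vinorelbine", (5, 0.05), (5, 0.05), (5, 0.05)),
    _pair("CGP-082996", "Thapsigargin", (5, 0.05), (5, 0.05), (5, 0.05)),
    _pair("Lapatinib", "Thapsigargin", (5, 0.05), (5, 0.05), (5, 0.05)),
    _pair("Lapatinib", "Tipifarnib", (5, 1.00), (5, 5.00), (5, 5.00)),
    _pair("Lapatinib", "Bleomycin", (5, 1.00), (5, 5.00), (5, 1.00)),
    _pair("Tipifarnib", "NVP-TAE684", (1, 0.50), (5, 0.50), (5, 0.50)),
    _pair("Pazopanib", "BMS-536924", (0.1, 1.00), (5, 5.00), (5, 1.00)),
    _pair("PHA-665752", "NVP-LAQ824", (0.1, 0.05), (0.5, 0.05), (0.1, 0.05)),
    _pair("Thapsigargin", "Midostaurin", (0.05, 0.05), (0.05, 1), (0.05, 1)),
    _pair("Bleomycin", "A-770041", (1.00, 1.00), (5.00, 1), (1.00, 5)),
    _pair("Lapatinib", "CGP-082996", (5, 5), (5, 5), (5, 5)),
)


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial layout: cell lines x drug pairs x replicates x 6x6 grid."""

    cell_lines: tuple[str, ...]
    drug_pairs: tuple[DrugPair, ...]
    n_replicates: int = 2
    dose_grid_size: int = 6
    dilution_factor: float = 3.0
    imaging_days: tuple[int, ...] = IMAGING_DAYS
    exposure_windows: tuple[tuple[int, int], ...] = EXPOSURE_WINDOWS

    def __post_init__(self) -> None:
        if self.dose_grid_size < 1:
            raise ValueError("dose_grid_size must be >= 1")
        if list(self.imaging_days) != sorted(self.imaging_days):
            raise ValueError("imaging_days must be sorted ascending")
        days = set(range(0, max(self.imaging_days) + 1))
        for start, end in self.exposure_windows:
            if not (start < end and start in days and end in days):
                raise ValueError(
                    f"exposure window ({start}, {end}) outside study days"
                )

    @property
    def endpoint_day(self) -> int:
        return max(self.imaging_days)

    @property
    def n_nonzero_doses(self) -> int:
        return self.dose_grid_size - 1

    @property
    def wells_per_plate(self) -> int:
        return self.dose_grid_size**2

    @property
    def n_plates(self) -> int:
        return len(self.cell_lines) * len(self.drug_pairs) * self.n_replicates

    @property
    def wells_per_day(self) -> int:
        return self.n_plates * self.wells_per_plate

    def doses(self, cell_line: str, pair: DrugPair) -> tuple[tuple[float, ...], tuple[float, ...]]:
        """Ascending dose axes (first entry 0) for one plate's matrix."""
        if self.dose_grid_size == 1:
            return (0.0,), (0.0,)
        s1, s2 = pair.series(cell_line, self.dilution_factor, self.n_nonzero_doses)
        return s1.ascending, s2.ascending


def paper_design() -> StudyDesign:
    """The screen at full scale: 3 lines x 16 pairs x 2 technical replicates."""
    return StudyDesign(cell_lines=CELL_LINES, drug_pairs=DRUG_PAIR_REGISTRY)


def desk_design(
    n_cell_lines: int = 1,
    n_pairs: int = 4,
    n_replicates: int = 2,
    imaging_days: Sequence[int] = IMAGING_DAYS,
) -> StudyDesign:
    """A reduced layout (subset of lines/pairs) for fast desk-scale runs."""
    return StudyDesign(
        cell_lines=CELL_LINES[:n_cell_lines],
        drug_pairs=DRUG_PAIR_REGISTRY[:n_pairs],
        n_replicates=n_replicates,
        imaging_days=tuple(imaging_days),
    )


def plate_id(cell_line: str, pair: DrugPair, replicate: int) -> str:
    safe = lambda s: s.replace(" ", "").replace("+", "-")
    return f"{safe(cell_line)}__{safe(pair.drug1)}_{safe(pair.drug2)}__rep{replicate}"


def enumerate_wells(design: StudyDesign) -> pd.DataFrame:
    """Expand a design into one record per culture well.

    Returns a DataFrame with one row per (cell line, pair, replicate, row,
    col): columns ``plate_id, cell_line, drug1, drug2, pair_index, pair,
    replicate, row, col, dose1_uM, dose2_uM, well_index``.  ``well_index``
    is ``row * grid + col``; the untreated control is (row, col) == (0, 0),
    exactly one per plate.  Deterministic: the output is a pure function of
    the design.
    """
    rows = []
    for cell_line in design.cell_lines:
        for pair_index, pair in enumerate(design.drug_pairs):
            d1_axis, d2_axis = design.doses(cell_line, pair)
            for replicate in range(1, design.n_replicates + 1):
                pid = plate_id(cell_line, pair, replicate)
                for i, dose1 in enumerate(d1_axis):
                    for j, dose2 in enumerate(d2_axis):
                        rows.append(
                            {
                                "plate_id": pid,
                                "cell_line": cell_line,
                                "drug1": pair.drug1,
                                "drug2": pair.drug2,
                                "pair_index": pair_index,
                                "pair": pair.name,
                                "replicate": replicate,
                                "row": i,
                                "col": j,
                                "dose1_uM": dose1,
                                "dose2_uM": dose2,
                                "well_index": i * design.dose_grid_size + j,
                            }
                        )
    return pd.DataFrame(rows)


_PLATE_MAP_COLUMNS = [
    "plate_id",
    "cell_line",
    "drug1",
    "drug2",
    "replicate",
    "row",
    "col",
    "dose1_uM",
    "dose2_uM",
]


def write_plate_map(design: StudyDesign, path: str | Path) -> pd.DataFrame:
    """Serialize the well layout to the documented plate-map CSV schema."""
    wells = enumerate_wells(design)
    out = wells[_PLATE_MAP_COLUMNS]
    out.to_csv(path, index=False)
    return out


def read_plate_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PLATE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    return df


def write_design_config(design: StudyDesign, path: str | Path) -> None:
    """Flat key-value design description (YAML)."""
    payload = {
        "cell_lines": list(design.cell_lines),
        "drug_pairs": [
            {
                "drug1": p.drug1,
                "drug2": p.drug2,
                "max_conc": {k: list(v) for k, v in p.max_conc.items()},
            }
            for p in design.drug_pairs
        ],
        "n_replicates": design.n_replicates,
        "dose_grid_size": design.dose_grid_size,
        "dilution_factor": design.dilution_factor,
        "imaging_days": list(design.imaging_days),
        "exposure_windows": [list(w) for w in design.exposure_windows],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_design_config(path: str | Path) -> StudyDesign:
    payload = yaml.safe_load(Path(path).read_text())
    pairs = tuple(
        DrugPair(
            p["drug1"],
            p["drug2"],
            {k: tuple(v) for k, v in p["max_conc"].items()},
        )
        for p in payload["drug_pairs"]
    )
    return StudyDesign(
        cell_lines=tuple(payload["cell_lines"]),
        drug_pairs=pairs,
        n_replicates=payload["n_replicates"],
        dose_grid_size=payload["dose_grid_size"],
        dilution_factor=payload["dilution_factor"],
        imaging_days=tuple(payload["imaging_days"]),
        exposure_windows=tuple(tuple(w) for w in payload["exposure_windows"]),
    )
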