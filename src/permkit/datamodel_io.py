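"""Domain types, unit conventions and CSV/config I/O.

Unit conventions
----------------
All internal computation uses ng, mL, min and cm:

* receptor concentrations: ng/mL
* test-solution concentration ``c_test``: mg/mL (as labelled on the
  pharmaceutical products; the 10^-3 factor in the clearance formula
  depends on this mixed convention)
* permeation rates: ng/min/cm^2
* apparent permeation clearance: uL/min/cm^2
* glove thickness is *stored* in mm and converted to cm exactly once,
  at the membrane-simulator boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ResultBundle

logger = logging.getLogger("permkit")

#: mg/mL -> ng/mL
NG_PER_MG = 1e6
#: mm -> cm
CM_PER_MM = 0.1

#: Collection windows of the continuous-flow in-line cell protocol (min).
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (0.0, 15.0),
    (15.0, 30.0),
    (30.0, 60.0),
    (60.0, 120.0),
    (120.0, 240.0),
)

#: Conventional short names for the ten-drug panel.
ABBREVIATIONS: dict[str, str] = {
    "Carboplatin": "CBDCA",
    "Carmustine": "BCNU",
    "Cisplatin": "CDDP",
    "Cyclophosphamide": "CPA",
    "Doxorubicin": "DXR",
    "Etoposide": "ETP",
    "Fluorouracil": "5FU",
    "Ifosfamide": "IFM",
    "Oxaliplatin": "OXA",
    "Paclitaxel": "PTX",
}

PANEL_COLUMNS = ["name", "mw", "logp", "c_test_mg_ml", "loq_ng_ml"]
MEASUREMENT_COLUMNS = [
    "drug",
    "glove_thickness_mm",
    "replicate",
    "interval_start_min",
    "interval_end_min",
    "conc_ng_ml",
]


class ValidationError(ValueError):
    """Raised when an input record or file violates a model invariant."""


@dataclass(frozen=True)
class DrugRecord:
    """One antineoplastic agent of the test panel.

    Parameters
    ----------
    name:
        Drug name, unique within a panel.
    mw:
        Molecular weight, g/mol.
    logp:
        Log10 octanol-water partition coefficient (dimensionless).
    c_test:
        Concentration of the test solution applied to the glove, mg/mL.
    loq_conc:
        Assay limit of quantitation in the receptor solution, ng/mL.
    """

    name: str
    mw: float
    logp: float
    c_test: float
    loq_conc: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("drug name must be non-empty")
        for fname in ("mw", "c_test", "loq_conc"):
            v = getattr(self, fname)
            if not (v > 0):
                raise ValidationError(
                    f"drug {self.name!r}: field {fname!r} must be > 0, got {v!r}"
                )

    @property
    def abbrev(self) -> str:
        return ABBREVIATIONS.get(self.name, self.name)


@dataclass(frozen=True)
class GloveSpec:
    """A medical-glove specification.

    ``allowance_mm`` is the supplier's thickness tolerance; it is
    inspection metadata, not an analysis input, so out-of-range
    measured thicknesses are only warned about (see :meth:`check_thickness`).
    """

    material: str = "nitrile"
    thickness_mm: float = 0.05
    allowance_mm: float = 0.03

    def __post_init__(self) -> None:
        if not (self.thickness_mm > 0):
            raise ValidationError(f"thickness_mm must be > 0, got {self.thickness_mm!r}")
        if self.allowance_mm < 0:
            raise ValidationError(f"allowance_mm must be >= 0, got {self.allowance_mm!r}")

    @property
    def thickness_cm(self) -> float:
        """Thickness in cm (the single mm -> cm conversion point)."""
        return self.thickness_mm * CM_PER_MM

    def check_thickness(self, measured_mm: float) -> bool:
        """Return whether a measured thickness is within the allowance.

        Out-of-range values are logged at warning level, not rejected.
        """
        ok = abs(measured_mm - self.thickness_mm) <= self.allowance_mm
        if not ok:
            logger.warning(
                "measured thickness %.4g mm outside %s +/- %.3g mm",
                measured_mm,
                self.thickness_mm,
                self.allowance_mm,
            )
        return ok


@dataclass(frozen=True)
class FlowCellConfig:
    """Geometry and sampling scheme of the continuous-flow in-line cell.

    The collected volume of each interval is ``flow_ml_min`` times the
    interval duration; intervals must be contiguous from t = 0.
    """

    area_cm2: float = 1.0
    flow_ml_min: float = 1.0
    temperature_c: float = 27.0
    intervals: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS

    def __post_init__(self) -> None:
        if not (self.area_cm2 > 0):
            raise ValidationError(f"area_cm2 must be > 0, got {self.area_cm2!r}")
        if not (self.flow_ml_min > 0):
            raise ValidationError(f"flow_ml_min must be > 0, got {self.flow_ml_min!r}")
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValidationError("at least one collection interval is required")
        if ivs[0][0] != 0:
            raise ValidationError(f"first interval must start at 0, got {ivs[0]!r}")
        prev_end = 0.0
        for start, end in ivs:
            if start != prev_end:
                raise ValidationError(
                    f"intervals must be contiguous: expected start {prev_end}, got {start}"
                )
            if not (end > start):
                raise ValidationError(f"interval ({start}, {end}) must have end > start")
            prev_end = end

    @property
    def durations_min(self) -> tuple[float, ...]:
        return tuple(end - start for start, end in self.intervals)

    @property
    def volumes_ml(self) -> tuple[float, ...]:
        """Receptor volume collected per interval (flow x duration)."""
        return tuple(self.flow_ml_min * d for d in self.durations_min)

    @property
    def end_times_min(self) -> tuple[float, ...]:
        return tuple(end for _, end in self.intervals)


@dataclass(frozen=True)
class IntervalMeasurement:
    """Receptor-solution concentration over one collection interval.

    ``below_loq`` marks readings under the assay's effective
    quantitation limit; such readings enter downstream analysis as zero.
    The flag always implies ``conc_ng_ml < loq_conc`` of the drug.
    """

    drug: str
    thickness_mm: float
    replicate: int
    interval: tuple[float, float]
    conc_ng_ml: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.conc_ng_ml < 0:
            raise ValidationError(
                f"{self.drug}: concentration must be >= 0, got {self.conc_ng_ml!r}"
            )
        object.__setattr__(
            self, "interval", (float(self.interval[0]), float(self.interval[1]))
        )


def default_flow_cell() -> FlowCellConfig:
    """The flow cell used throughout: 1 cm^2, 1 mL/min, 27 degC, five windows."""
    return FlowCellConfig()


# ---------------------------------------------------------------------------
# drug panel I/O


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def _as_float(value: object, row: int, fieldname: str) -> float:
    try:
        out = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: field {fieldname!r} is not numeric: {value!r}"
        ) from None
    if out != out:  # NaN
        raise ValidationError(f"row {row}: field {fieldname!r} is missing")
    return out


def load_drug_panel(path: str | Path) -> list[DrugRecord]:
    """Load a drug panel CSV (columns name, mw, logp, c_test_mg_ml, loq_ng_ml)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty drug panel file") from None
    _require_columns(df, PANEL_COLUMNS, str(path))
    if df.empty:
        raise ValidationError(f"{path}: drug panel contains no rows")
    records: list[DrugRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        name = str(row["name"]).strip()
        try:
            rec = DrugRecord(
                name=name,
                mw=_as_float(row["mw"], rowno, "mw"),
                logp=_as_float(row["logp"], rowno, "logp"),
                c_test=_as_float(row["c_test_mg_ml"], rowno, "c_test_mg_ml"),
                loq_conc=_as_float(row["loq_ng_ml"], rowno, "loq_ng_ml"),
            )
        except ValidationError as err:
            raise ValidationError(f"row {rowno}: {err}") from None
        records.append(rec)
    names = [r.name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate drug name(s) in panel: {dupes}")
    return records


def write_drug_panel(records: Iterable[DrugRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": r.name,
                "mw": r.mw,
                "logp": r.logp,
                "c_test_mg_ml": r.c_test,
                "loq_ng_ml": r.loq_conc,
            }
            for r in records
        ],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.12g")


def default_drug_panel() -> list[DrugRecord]:
    """The packaged ten-drug antineoplastic panel with its test-solution
    concentrations, literature MW/LogP values and assay LOQs."""
    ref = resources.files("permkit").joinpath("fixtures/drug_panel.csv")
    with resources.as_file(ref) as p:
        return load_drug_panel(p)


# ---------------------------------------------------------------------------
# measurement I/O


def load_measurements(
    path: str | Path,
    panel: Sequence[DrugRecord] | None = None,
    cell: FlowCellConfig | None = None,
) -> list[IntervalMeasurement]:
    """Load flow-cell measurements from CSV.

    When ``panel`` is given, ``below_loq`` flags are derived by comparing
    each reading's permeation rate against the drug's PR-equivalent
    quantitation limit (see :func:`permkit.permeation_metrics.loq_to_pr_limit`);
    otherwise flags are left False and censoring is recomputed downstream.
    Schema violations are reported with their CSV row number.
    """
    from .permeation_metrics import compute_pr, loq_to_pr_limit

    try:
        # correctly rounded parsing, so exported doubles round-trip exactly
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty measurements file") from None
    _require_columns(df, MEASUREMENT_COLUMNS, str(path))
    by_name = {r.name: r for r in panel} if panel is not None else {}
    cell = cell or default_flow_cell()
    out: list[IntervalMeasurement] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2
        drug = str(row["drug"]).strip()
        conc = _as_float(row["conc_ng_ml"], rowno, "conc_ng_ml")
        start = _as_float(row["interval_start_min"], rowno, "interval_start_min")
        end = _as_float(row["interval_end_min"], rowno, "interval_end_min")
        try:
            m = IntervalMeasurement(
                drug=drug,
                thickness_mm=_as_float(row["glove_thickness_mm"], rowno, "glove_thickness_mm"),
                replicate=int(_as_float(row["replicate"], rowno, "replicate")),
                interval=(start, end),
                conc_ng_ml=conc,
            )
        except ValidationError as err:
            raise ValidationError(f"row {rowno}: {err}") from None
        if panel is not None:
            if drug not in by_name:
                raise ValidationError(f"row {rowno}: drug {drug!r} not in panel")
            rec = by_name[drug]
            pr = compute_pr(conc, cell.flow_ml_min * (end - start), end - start, cell.area_cm2)
            if pr < loq_to_pr_limit(rec.loq_conc):
                m = IntervalMeasurement(
                    m.drug, m.thickness_mm, m.replicate, m.interval, m.conc_ng_ml, True
                )
        out.append(m)
    return out


def measurements_to_frame(measurements: Iterable[IntervalMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": m.drug,
                "glove_thickness_mm": m.thickness_mm,
                "replicate": m.replicate,
                "interval_start_min": m.interval[0],
                "interval_end_min": m.interval[1],
                "conc_ng_ml": m.conc_ng_ml,
            }
            for m in measurements
        ],
        columns=MEASUREMENT_COLUMNS,
    )


def write_measurements(measurements: Iterable[IntervalMeasurement], path: str | Path) -> None:
    # %.17g round-trips doubles exactly, so re-analyzing an exported
    # measurements CSV reproduces the in-memory results bit for bit.
    measurements_to_frame(measurements).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# result bundle output


def write_results(results: "ResultBundle", outdir: str | Path) -> list[Path]:
    """Write a pipeline result bundle as CSV tables plus run metadata.

    Produces ``profiles.csv``, ``clearances.csv``, ``zones.csv``,
    ``correlations.csv`` (and ``concordance.csv`` when present) plus
    ``run_metadata.json`` capturing the configuration and seed.
    Numeric formatting is fixed so reruns with the same seed are
    byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    tables = {
        "profiles.csv": results.profiles,
        "clearances.csv": results.clearances,
        "zones.csv": results.zones,
        "correlations.csv": results.correlations,
    }
    if results.concordance is not None:
        tables["concordance.csv"] = results.concordance
    for fname, df in tables.items():
        p = out / fname
        df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)
    if results.measurements is not None:
        # full double precision so re-analysis of the export is exact
        p = out / "measurements.csv"
        results.measurements.to_csv(p, index=False, float_format="%.17g")
        written.append(p)
    meta = out / "run_metadata.json"
    meta.write_text(json.dumps(results.metadata, indent=2, sort_keys=True) + "\n")
    written.append(meta)
    logger.info("wrote %d result files to %s", len(written), out)
    return written
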