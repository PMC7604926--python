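"""End-to-end study orchestration.

Composes the full analysis — simulate (or ingest) measurements, build
permeation-rate profiles, compute clearances, classify zones, run the
correlation analyses, and tabulate predicted-vs-observed concordance —
into a single reproducible bundle. Bundle contents are a pure function
of (config, seed, input files): per-combination random generators are
spawned from one root seed sequence in fixed (drug, thickness) order,
and every stage failure is re-raised with a stage label.

Correlation analyses computed:

* apparent clearance vs glove thickness, pooled across all drugs and
  thicknesses (censored clearances enter as 0);
* clearance vs molecular weight at the thinnest glove;
* clearance vs LogP at the thinnest glove;
* clearance vs LogP restricted to Zone A drugs at the thinnest glove.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel_io import (
    DrugRecord,
    FlowCellConfig,
    GloveSpec,
    IntervalMeasurement,
    ValidationError,
    default_drug_panel,
    load_drug_panel,
    load_measurements,
    measurements_to_frame,
)
from .membrane_simulator import (
    DEFAULT_CALIBRATION,
    NoiseModel,
    QsprCalibration,
    simulate_experiment,
)
from .permeation_metrics import (
    ClearanceResult,
    PermeationProfile,
    build_profile,
    compute_clp,
    pr240_of,
)
from .rank_stats import (
    DEFAULT_N_PERM,
    UndefinedCorrelationError,
    spearman_test,
)
from .zone_classifier import (
    ConcordanceTable,
    ZoneAssignment,
    ZoneBounds,
    classify_panel,
    validate_against_observations,
)

logger = logging.getLogger("permkit")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated or measured study."""

    panel_path: str | None = None
    thicknesses_mm: tuple[float, ...] = (0.05, 0.07, 0.10)
    area_cm2: float = 1.0
    flow_ml_min: float = 1.0
    temperature_c: float = 27.0
    calibration: QsprCalibration = DEFAULT_CALIBRATION
    noise_cv: float = 0.1
    n_reps: int = 3
    logp_cut: float = -1.0
    mw_cut: float = 500.0
    stats_method: str = "auto"
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.thicknesses_mm:
            raise ValidationError("at least one glove thickness is required")
        object.__setattr__(
            self, "thicknesses_mm", tuple(float(t) for t in self.thicknesses_mm)
        )
        for t in self.thicknesses_mm:
            if not (t > 0):
                raise ValidationError(f"thickness must be > 0, got {t!r}")
        if self.n_reps < 1:
            raise ValidationError(f"n_reps must be >= 1, got {self.n_reps!r}")

    @property
    def cell(self) -> FlowCellConfig:
        return FlowCellConfig(
            area_cm2=self.area_cm2,
            flow_ml_min=self.flow_ml_min,
            temperature_c=self.temperature_c,
        )

    @property
    def bounds(self) -> ZoneBounds:
        return ZoneBounds(logp_cut=self.logp_cut, mw_cut=self.mw_cut)

    def load_panel(self) -> list[DrugRecord]:
        if self.panel_path is None:
            return default_drug_panel()
        return load_drug_panel(self.panel_path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        cal = raw.pop("calibration", None)
        kwargs = dict(raw)
        if cal is not None:
            kwargs["calibration"] = QsprCalibration(**cal)
        if "thicknesses_mm" in kwargs:
            kwargs["thicknesses_mm"] = tuple(kwargs["thicknesses_mm"])
        try:
            return cls(**kwargs)
        except TypeError as err:
            raise ValidationError(f"{path}: {err}") from None

    def to_dict(self) -> dict:
        return {
            "panel_path": self.panel_path,
            "thicknesses_mm": list(self.thicknesses_mm),
            "area_cm2": self.area_cm2,
            "flow_ml_min": self.flow_ml_min,
            "temperature_c": self.temperature_c,
            "calibration": {
                "alpha": self.calibration.alpha,
                "beta": self.calibration.beta,
                "gamma": self.calibration.gamma,
                "delta": self.calibration.delta,
            },
            "noise_cv": self.noise_cv,
            "n_reps": self.n_reps,
            "logp_cut": self.logp_cut,
            "mw_cut": self.mw_cut,
            "stats_method": self.stats_method,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ResultBundle:
    """All study outputs as data frames, plus run metadata."""

    profiles: pd.DataFrame
    clearances: pd.DataFrame
    zones: pd.DataFrame
    correlations: pd.DataFrame
    concordance: pd.DataFrame | None
    measurements: pd.DataFrame | None
    metadata: dict = field(default_factory=dict)


def _stage(name: str):
    """Decorator labelling exceptions with the pipeline stage."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}': {err}") from err
            logger.info("stage %s completed in %.3f s", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("simulate")
def _simulate_all(
    panel: Sequence[DrugRecord], config: RunConfig
) -> list[IntervalMeasurement]:
    """Simulate every drug x thickness combination deterministically.

    One child generator per combination, spawned in (drug, thickness)
    index order from the root seed, so adding drugs or thicknesses at
    the end does not perturb earlier streams.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(panel) * len(config.thicknesses_mm))
    noise = NoiseModel(cv=config.noise_cv, seed=config.seed)
    cell = config.cell
    out: list[IntervalMeasurement] = []
    for i, drug in enumerate(panel):
        for j, thickness in enumerate(config.thicknesses_mm):
            rng = np.random.default_rng(children[i * len(config.thicknesses_mm) + j])
            glove = GloveSpec(thickness_mm=thickness)
            exp = simulate_experiment(
                drug,
                glove,
                cell=cell,
                cal=config.calibration,
                noise=noise,
                n_reps=config.n_reps,
                rng=rng,
            )
            out.extend(exp.all_measurements())
    logger.info(
        "simulated %d measurements (%d drugs x %d thicknesses x %d reps)",
        len(out),
        len(panel),
        len(config.thicknesses_mm),
        config.n_reps,
    )
    return out


@_stage("profiles")
def _build_profiles(
    measurements: Sequence[IntervalMeasurement],
    panel: Sequence[DrugRecord],
    cell: FlowCellConfig,
) -> list[PermeationProfile]:
    by_name = {d.name: d for d in panel}
    groups: dict[tuple[str, float], list[IntervalMeasurement]] = {}
    for m in measurements:
        if m.drug not in by_name:
            raise ValidationError(f"measured drug {m.drug!r} not in panel")
        groups.setdefault((m.drug, m.thickness_mm), []).append(m)
    profiles = []
    for drug in panel:  # stable panel order, then ascending thickness
        for (name, thickness) in sorted(k for k in groups if k[0] == drug.name):
            profiles.append(build_profile(groups[(name, thickness)], drug, cell))
    if not profiles:
        raise ValidationError("no measurements to analyze")
    return profiles


@_stage("clearances")
def _compute_clearances(
    profiles: Sequence[PermeationProfile], panel: Sequence[DrugRecord]
) -> list[ClearanceResult]:
    by_name = {d.name: d for d in panel}
    out = []
    for p in profiles:
        pr240, censored = pr240_of(p)
        if censored:
            logger.warning(
                "%s at %.2f mm: final window fully censored, clearance 0",
                p.drug,
                p.thickness_mm,
            )
        out.append(
            compute_clp(
                pr240,
                by_name[p.drug].c_test,
                censored,
                drug=p.drug,
                glove=GloveSpec(thickness_mm=p.thickness_mm),
            )
        )
    return out


@_stage("correlations")
def _correlate(
    clearances: Sequence[ClearanceResult],
    panel: Sequence[DrugRecord],
    assignments: Sequence[ZoneAssignment],
    config: RunConfig,
) -> pd.DataFrame:
    by_name = {d.name: d for d in panel}
    thinnest = min(c.thickness_mm for c in clearances)
    thin = [c for c in clearances if c.thickness_mm == thinnest]
    zone_a = {a.drug for a in assignments if a.zone == "A"}
    analyses: list[tuple[str, list[float], list[float]]] = [
        (
            "clp_vs_thickness_pooled",
            [c.thickness_mm for c in clearances],
            [c.clp_app for c in clearances],
        ),
        (
            "clp_vs_mw_thinnest",
            [by_name[c.drug].mw for c in thin],
            [c.clp_app for c in thin],
        ),
        (
            "clp_vs_logp_thinnest",
            [by_name[c.drug].logp for c in thin],
            [c.clp_app for c in thin],
        ),
        (
            "clp_vs_logp_zoneA_thinnest",
            [by_name[c.drug].logp for c in thin if c.drug in zone_a],
            [c.clp_app for c in thin if c.drug in zone_a],
        ),
    ]
    rows = []
    for label, x, y in analyses:
        if len(x) < 3:
            logger.warning("correlation %s skipped: only %d points", label, len(x))
            continue
        try:
            res = spearman_test(
                x, y, method=config.stats_method, n_perm=config.n_perm, seed=config.seed
            )
            rows.append(
                {
                    "analysis": label,
                    "n": res.n,
                    "rs": res.rs,
                    "p_value": res.p_value,
                    "method": res.method,
                    "seed": config.seed,
                }
            )
        except UndefinedCorrelationError as err:
            logger.warning("correlation %s undefined: %s", label, err)
            rows.append(
                {
                    "analysis": label,
                    "n": len(x),
                    "rs": float("nan"),
                    "p_value": float("nan"),
                    "method": "undefined",
                    "seed": config.seed,
                }
            )
    return pd.DataFrame(
        rows, columns=["analysis", "n", "rs", "p_value", "method", "seed"]
    )


def _profiles_frame(profiles: Sequence[PermeationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": p.drug,
                "thickness_mm": p.thickness_mm,
                "t_end_min": tp.t_end_min,
                "pr_mean": tp.mean_pr,
                "pr_sd": tp.sd,
                "n": tp.n,
                "censored": tp.censored,
            }
            for p in profiles
            for tp in p.timepoints
        ],
        columns=["drug", "thickness_mm", "t_end_min", "pr_mean", "pr_sd", "n", "censored"],
    )


def _clearances_frame(clearances: Sequence[ClearanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": c.drug,
                "thickness_mm": c.thickness_mm,
                "pr240": c.pr240,
                "clp_app": c.clp_app,
                "censored": c.censored,
            }
            for c in clearances
        ],
        columns=["drug", "thickness_mm", "pr240", "clp_app", "censored"],
    )


def _zones_frame(
    assignments: Sequence[ZoneAssignment], panel: Sequence[DrugRecord]
) -> pd.DataFrame:
    by_name = {d.name: d for d in panel}
    return pd.DataFrame(
        [
            {
                "drug": a.drug,
                "mw": by_name[a.drug].mw,
                "logp": by_name[a.drug].logp,
                "zone": a.zone,
                "risk": a.risk,
                "on_boundary": a.on_boundary,
            }
            for a in assignments
        ],
        columns=["drug", "mw", "logp", "zone", "risk", "on_boundary"],
    )


def _analyze(
    measurements: Sequence[IntervalMeasurement],
    panel: Sequence[DrugRecord],
    config: RunConfig,
    source: str,
) -> ResultBundle:
    from . import __version__

    cell = config.cell
    profiles = _build_profiles(measurements, panel, cell)
    clearances = _compute_clearances(profiles, panel)
    assignments = _stage("classify")(classify_panel)(panel, config.bounds)
    correlations = _correlate(clearances, panel, assignments, config)

    thinnest = min(c.thickness_mm for c in clearances)
    thin = [c for c in clearances if c.thickness_mm == thinnest]
    concordance_df = None
    if {c.drug for c in thin} == {d.name for d in panel}:
        table: ConcordanceTable = _stage("concordance")(validate_against_observations)(
            assignments, thin
        )
        concordance_df = pd.DataFrame(table.as_records())
        concordance_df["thickness_mm"] = thinnest

    metadata = {
        "source": source,
        "seed": config.seed,
        "config": config.to_dict(),
        "package_version": __version__,
        "n_measurements": len(measurements),
    }
    return ResultBundle(
        profiles=_profiles_frame(profiles),
        clearances=_clearances_frame(clearances),
        zones=_zones_frame(assignments, panel),
        correlations=correlations,
        concordance=concordance_df,
        measurements=measurements_to_frame(measurements),
        metadata=metadata,
    )


def run_simulated_study(config: RunConfig | None = None) -> ResultBundle:
    """Simulate the full drug x thickness grid and analyze it."""
    config = config or RunConfig()
    panel = _stage("panel")(config.load_panel)()
    measurements = _simulate_all(panel, config)
    return _analyze(measurements, panel, config, source="simulated")


def run_measured_study(
    measurements_path: str | Path, config: RunConfig | None = None
) -> ResultBundle:
    """Analyze user-supplied measurements, skipping simulation."""
    config = config or RunConfig()
    panel = _stage("panel")(config.load_panel)()
    measurements = _stage("ingest")(load_measurements)(
        measurements_path, panel=panel, cell=config.cell
    )
    return _analyze(measurements, panel, config, source="measured")
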