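"""Permeation-rate and apparent-permeation-clearance metrics.

Implements the two study endpoints computed from receptor-solution
concentrations of the continuous-flow in-line cell:

* interval permeation rate ``PR = (C x V) / t / S`` (ng/min/cm^2),
  where ``C`` is the receptor concentration over a collection window,
  ``V`` the collected volume, ``t`` the window duration and ``S`` the
  exposed membrane area;
* apparent permeation clearance
  ``CLp = 1e-3 x PR_240 / C_test`` (uL/min/cm^2), where ``PR_240`` is
  the mean permeation rate of the final (120-240 min) window and
  ``C_test`` the test-solution concentration in mg/mL.

Censoring convention
--------------------
An assay limit of quantitation ``LOQ`` (ng/mL) translates into a
permeation-rate quantitation limit ``LOQ / 60`` under the reference
protocol, because the final window is 120 min long and collects 120 mL
over a 1 cm^2 membrane at 1 mL/min, but the printed limits follow the
60-min-equivalent convention of reporting. A measurement is treated as
censored (and contributes a rate of zero) when its permeation rate falls
below this PR-equivalent limit; a timepoint is censored only when *all*
of its replicates are. A fully censored final window yields ``CLp = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .datamodel_io import (
    DrugRecord,
    FlowCellConfig,
    GloveSpec,
    IntervalMeasurement,
    ValidationError,
    default_flow_cell,
)

#: Divisor converting an assay LOQ in ng/mL into the equivalent
#: permeation-rate quantitation limit in ng/min/cm^2 under the
#: reference flow-cell protocol.
LOQ_TO_PR_DIVISOR = 60.0

#: 1e-3 factor of the clearance formula (PR in ng/min/cm^2, C_test in
#: mg/mL, CLp in uL/min/cm^2).
_CLP_UNIT_FACTOR = 1e-3


def compute_pr(
    conc_ng_ml: float,
    volume_ml: float,
    duration_min: float,
    area_cm2: float,
) -> float:
    """Interval permeation rate (ng/min/cm^2).

    ``PR = (C x V) / t / S`` with the receptor concentration ``C`` in
    ng/mL, collected volume ``V`` in mL, window duration ``t`` in min
    and membrane area ``S`` in cm^2.
    """
    if not (duration_min > 0):
        raise ValidationError(f"duration_min must be > 0, got {duration_min!r}")
    if not (area_cm2 > 0):
        raise ValidationError(f"area_cm2 must be > 0, got {area_cm2!r}")
    if volume_ml < 0 or conc_ng_ml < 0:
        raise ValidationError("concentration and volume must be >= 0")
    return conc_ng_ml * volume_ml / duration_min / area_cm2


def loq_to_pr_limit(loq_ng_ml: float) -> float:
    """PR-equivalent quantitation limit (ng/min/cm^2) for an assay LOQ."""
    if not (loq_ng_ml > 0):
        raise ValidationError(f"loq_ng_ml must be > 0, got {loq_ng_ml!r}")
    return loq_ng_ml / LOQ_TO_PR_DIVISOR


@dataclass(frozen=True)
class Timepoint:
    """Replicate-aggregated permeation rate at the end of one window.

    ``censored`` is True only when every replicate of the window fell
    below the PR-equivalent quantitation limit; individual below-limit
    replicates contribute a rate of zero to the mean. ``sd`` is the
    sample standard deviation (n - 1 denominator), zero when n = 1.
    """

    t_end_min: float
    mean_pr: float
    sd: float
    n: int
    censored: bool


@dataclass(frozen=True)
class PermeationProfile:
    """Permeation-rate time course of one drug/glove combination."""

    drug: str
    thickness_mm: float
    timepoints: tuple[Timepoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        ends = [tp.t_end_min for tp in self.timepoints]
        if ends != sorted(ends) or len(set(ends)) != len(ends):
            raise ValidationError(
                f"{self.drug}: timepoints must be strictly ordered by end time"
            )
        for tp in self.timepoints:
            if tp.mean_pr < 0 or tp.sd < 0:
                raise ValidationError(
                    f"{self.drug}: negative rate statistics at {tp.t_end_min} min"
                )

    def timepoint_at(self, t_end_min: float) -> Timepoint:
        for tp in self.timepoints:
            if tp.t_end_min == t_end_min:
                return tp
        raise ValidationError(f"{self.drug}: no window ending at {t_end_min} min")


def _sample_sd(values: Sequence[float]) -> float:
    n = len(values)
    if n < 2:
        return 0.0
    m = sum(values) / n
    return math.sqrt(sum((v - m) ** 2 for v in values) / (n - 1))


def build_profile(
    measurements: Sequence[IntervalMeasurement],
    drug: DrugRecord,
    cell: FlowCellConfig | None = None,
) -> PermeationProfile:
    """Aggregate replicate measurements of one drug into a rate profile.

    All measurements must belong to ``drug`` and share one glove
    thickness; every configured collection window must be covered by at
    least one replicate. Each reading is converted to a permeation rate
    and censored against the drug's PR-equivalent quantitation limit.
    """
    cell = cell or default_flow_cell()
    if not measurements:
        raise ValidationError(f"{drug.name}: no measurements supplied")
    names = {m.drug for m in measurements}
    if names != {drug.name}:
        raise ValidationError(
            f"measurements for {sorted(names)} do not match drug {drug.name!r}"
        )
    thicknesses = {m.thickness_mm for m in measurements}
    if len(thicknesses) != 1:
        raise ValidationError(
            f"{drug.name}: measurements mix glove thicknesses {sorted(thicknesses)}"
        )
    limit = loq_to_pr_limit(drug.loq_conc)
    timepoints: list[Timepoint] = []
    for (start, end), volume in zip(cell.intervals, cell.volumes_ml):
        window = [m for m in measurements if m.interval == (start, end)]
        if not window:
            raise ValidationError(
                f"{drug.name}: no measurement for window ({start:g}, {end:g}) min"
            )
        duration = end - start
        rates: list[float] = []
        n_detected = 0
        for m in window:
            pr = compute_pr(m.conc_ng_ml, volume, duration, cell.area_cm2)
            below = m.below_loq or pr < limit
            rates.append(0.0 if below else pr)
            n_detected += 0 if below else 1
        timepoints.append(
            Timepoint(
                t_end_min=end,
                mean_pr=sum(rates) / len(rates),
                sd=_sample_sd(rates),
                n=len(rates),
                censored=n_detected == 0,
            )
        )
    return PermeationProfile(
        drug=drug.name,
        thickness_mm=float(next(iter(thicknesses))),
        timepoints=tuple(timepoints),
    )


def pr240_of(
    profile: PermeationProfile, t_end_min: float = 240.0
) -> tuple[float, bool]:
    """Final-window mean rate and censoring status (default 240 min).

    Raises :class:`~permkit.datamodel_io.ValidationError` if the profile
    lacks a window ending at ``t_end_min``.
    """
    tp = profile.timepoint_at(t_end_min)
    return tp.mean_pr, tp.censored


@dataclass(frozen=True)
class ClearanceResult:
    """Apparent permeation clearance of one drug/glove combination.

    ``clp_app`` is in uL/min/cm^2; censored combinations (final window
    entirely below the quantitation limit) carry ``clp_app = 0``.
    """

    drug: str
    thickness_mm: float
    pr240: float
    clp_app: float
    censored: bool

    def __post_init__(self) -> None:
        if self.clp_app < 0:
            raise ValidationError(f"{self.drug}: clp_app must be >= 0")
        if self.censored and self.clp_app != 0:
            raise ValidationError(f"{self.drug}: censored result must have clp_app 0")


def compute_clp(
    pr240: float,
    c_test: float,
    censored: bool,
    drug: str = "",
    glove: GloveSpec | None = None,
) -> ClearanceResult:
    """Apparent permeation clearance ``CLp = 1e-3 x PR_240 / C_test``.

    ``pr240`` is the mean rate of the final window in ng/min/cm^2 and
    ``c_test`` the test-solution concentration in mg/mL. A censored
    final window yields ``clp_app = 0`` regardless of ``pr240``,
    matching the convention of reporting non-detected drugs as
    non-permeating.
    """
    if not (c_test > 0):
        raise ValidationError(f"c_test must be > 0, got {c_test!r}")
    if pr240 < 0:
        raise ValidationError(f"pr240 must be >= 0, got {pr240!r}")
    thickness = glove.thickness_mm if glove is not None else 0.05
    clp = 0.0 if censored else _CLP_UNIT_FACTOR * pr240 / c_test
    return ClearanceResult(
        drug=drug,
        thickness_mm=thickness,
        pr240=pr240,
        clp_app=clp,
        censored=censored,
    )


def breakthrough_time(
    profile: PermeationProfile, threshold: float = 10.0
) -> float | None:
    """Earliest window end whose mean rate strictly exceeds ``threshold``.

    The 10 ng/min/cm^2 default is the standardized breakthrough
    criterion for protective-glove permeation testing. Returns None if
    the profile never exceeds the threshold (a profile sitting exactly
    at the threshold has not broken through).
    """
    if not (threshold > 0):
        raise ValidationError(f"threshold must be > 0, got {threshold!r}")
    for tp in profile.timepoints:
        if tp.mean_pr > threshold:
            return tp.t_end_min
    return None
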