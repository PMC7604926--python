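"""MW/LogP zone classification of glove-permeation risk.

Drugs are placed in three zones of the (MW, LogP) plane:

* Zone A — LogP >= logp_cut and MW <= mw_cut: high risk (breakthrough,
  final-window rate above the 10 ng/min/cm^2 limit);
* Zone B — LogP >= logp_cut and MW > mw_cut: moderate risk (detectable
  permeation below the limit);
* Zone C — LogP < logp_cut: low risk (no detectable permeation).

Default cuts are LogP -1 and MW 500 g/mol, appropriate for 0.05 mm
nitrile gloves; the cuts are configurable because they shift with glove
thickness. Boundary inclusivity follows the rule verbatim (both cuts
inclusive into Zone A), and drugs sitting exactly on a cut are flagged
``on_boundary`` to surface the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .datamodel_io import DrugRecord, ValidationError
from .permeation_metrics import ClearanceResult

#: Risk level of each zone.
ZONE_RISK = {"A": "high", "B": "moderate", "C": "low"}

#: Standardized breakthrough limit (ng/min/cm^2) separating the
#: observed high and moderate permeation categories.
DEFAULT_THRESHOLD = 10.0


@dataclass(frozen=True)
class ZoneBounds:
    """Classification cutoffs: LogP cut and MW cut (g/mol)."""

    logp_cut: float = -1.0
    mw_cut: float = 500.0

    def __post_init__(self) -> None:
        if not (self.mw_cut > 0):
            raise ValidationError(f"mw_cut must be > 0, got {self.mw_cut!r}")


@dataclass(frozen=True)
class ZoneAssignment:
    """A drug's zone, risk level, and boundary flag."""

    drug: str
    zone: str
    risk: str
    on_boundary: bool

    def __post_init__(self) -> None:
        if self.zone not in ZONE_RISK:
            raise ValidationError(f"unknown zone {self.zone!r}")
        if self.risk != ZONE_RISK[self.zone]:
            raise ValidationError(
                f"zone {self.zone} must carry risk {ZONE_RISK[self.zone]!r}"
            )


def classify(
    mw: float, logp: float, bounds: ZoneBounds | None = None, drug: str = ""
) -> ZoneAssignment:
    """Classify one (MW, LogP) point; cuts are inclusive into Zone A."""
    if not (mw > 0):
        raise ValidationError(f"mw must be > 0, got {mw!r}")
    bounds = bounds or ZoneBounds()
    if logp < bounds.logp_cut:
        zone = "C"
    elif mw <= bounds.mw_cut:
        zone = "A"
    else:
        zone = "B"
    return ZoneAssignment(
        drug=drug,
        zone=zone,
        risk=ZONE_RISK[zone],
        on_boundary=(logp == bounds.logp_cut or mw == bounds.mw_cut),
    )


def classify_panel(
    drugs: Sequence[DrugRecord], bounds: ZoneBounds | None = None
) -> list[ZoneAssignment]:
    """Classify a drug panel, preserving input order."""
    if not drugs:
        raise ValidationError("cannot classify an empty panel")
    return [classify(d.mw, d.logp, bounds, drug=d.name) for d in drugs]


def observed_category(result: ClearanceResult, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Observed permeation category of one clearance result.

    ``high`` when the final-window rate exceeds the breakthrough
    threshold, ``low`` when fully censored, ``moderate`` otherwise
    (detectable but at or below the threshold).
    """
    if result.censored:
        return "low"
    if result.pr240 > threshold:
        return "high"
    return "moderate"


@dataclass(frozen=True)
class ConcordanceTable:
    """Predicted (zone) vs observed permeation categories per drug."""

    rows: tuple[tuple[str, str, str, bool], ...]  # drug, predicted, observed, match

    @property
    def concordance(self) -> float:
        """Fraction of drugs whose predicted risk matches the observation."""
        return sum(1 for r in self.rows if r[3]) / len(self.rows)

    def as_records(self) -> list[dict[str, object]]:
        return [
            {
                "drug": drug,
                "predicted_risk": predicted,
                "observed_category": observed,
                "match": match,
            }
            for drug, predicted, observed, match in self.rows
        ]


def validate_against_observations(
    assignments: Sequence[ZoneAssignment],
    clearances: Sequence[ClearanceResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> ConcordanceTable:
    """Compare predicted risk against observed permeation per drug.

    Assignments and clearances must cover exactly the same drugs.
    """
    if not assignments:
        raise ValidationError("no zone assignments supplied")
    pred: Mapping[str, str] = {a.drug: a.risk for a in assignments}
    obs = {c.drug: observed_category(c, threshold) for c in clearances}
    if set(pred) != set(obs):
        missing = sorted(set(pred) ^ set(obs))
        raise ValidationError(f"assignment/clearance drug sets differ: {missing}")
    rows = tuple(
        (a.drug, pred[a.drug], obs[a.drug], pred[a.drug] == obs[a.drug])
        for a in assignments
    )
    return ConcordanceTable(rows=rows)
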