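"""Deterministic classification rules applied to sperm measurements.

* Em behavior class: the sign and size of the capacitation-associated
  membrane-potential change (Em_CAP - Em_NC) partitions samples into
  hyperpolarizing, depolarizing or unchanged, with "unchanged" the open
  band |delta| < 5 mV and the boundary assigned to the signed class.
* Hyperactivated motility: VCL >= 150 µm/s AND LIN < 50% AND ALH >= 5 µm
  (conjunction; VCL/ALH inclusive, LIN strict).
* Induced acrosome reaction: progesterone-stimulated minus spontaneous
  reacted percentage, in percentage points (may be negative).
* IVF success: fertilization rate >= 60% ("at least", inclusive).
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from empredict.errors import InvalidInputError

HA_VCL_MIN = 150.0   # µm/s, inclusive
HA_LIN_MAX = 50.0    # %, strict upper bound
HA_ALH_MIN = 5.0     # µm, inclusive
AR_MIN_COUNT = 200   # design minimum sperm scored per AR condition
IVF_SUCCESS_THRESHOLD = 0.60
BEHAVIOR_THRESHOLD_MV = 5.0

KINEMATIC_FIELDS = ("VCL", "VSL", "VAP", "LIN", "STR", "ALH")


@dataclass(frozen=True)
class ArResult:
    """Acrosome-reaction score for one assay arm."""

    reacted: int
    total: int
    arm: str = "spontaneous"  # or "progesterone"

    def __post_init__(self) -> None:
        if self.total < 1 or self.reacted < 0 or self.reacted > self.total:
            raise InvalidInputError("need 0 <= reacted <= total, total >= 1")

    @property
    def percent(self) -> float:
        return 100.0 * self.reacted / self.total


@dataclass(frozen=True)
class IvfOutcome:
    """Oocyte and two-pronuclei (2PN) fertilization counts for one patient."""

    oocytes: int
    fertilized_2pn: int

    def __post_init__(self) -> None:
        if self.oocytes < 1 or not 0 <= self.fertilized_2pn <= self.oocytes:
            raise InvalidInputError("need 0 <= fertilized <= oocytes, oocytes >= 1")

    @property
    def rate(self) -> float:
        return self.fertilized_2pn / self.oocytes


def classify_behavior(
    em_nc: float,
    em_cap: float,
    threshold: float = BEHAVIOR_THRESHOLD_MV,
) -> str:
    """Behavior class from the capacitation-associated Em change.

    delta = em_cap - em_nc.  |delta| < threshold -> "unchanged";
    delta <= -threshold -> "hyperpolarizing"; delta >= +threshold ->
    "depolarizing".  A change of exactly the threshold goes to the
    signed class ("unchanged" is the open band).
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be > 0")
    if not (math.isfinite(em_nc) and math.isfinite(em_cap)):
        raise InvalidInputError("Em values must be finite")
    delta = em_cap - em_nc
    if abs(delta) < threshold:
        return "unchanged"
    return "hyperpolarizing" if delta < 0 else "depolarizing"


def classify_hyperactivated(record: Mapping[str, float]) -> bool:
    """True iff a sperm's kinematics meet all three hyperactivation
    criteria: VCL >= 150 µm/s, LIN < 50%, ALH >= 5 µm."""
    try:
        vcl, lin, alh = record["VCL"], record["LIN"], record["ALH"]
    except (KeyError, IndexError) as exc:
        raise InvalidInputError(f"kinematic record missing field: {exc}") from exc
    if vcl is None or lin is None or alh is None or any(
        not math.isfinite(v) for v in (vcl, lin, alh)
    ):
        raise InvalidInputError("VCL, LIN and ALH must be finite numbers")
    return vcl >= HA_VCL_MIN and lin < HA_LIN_MAX and alh >= HA_ALH_MIN


def hyperactivation_rate(records: Iterable[Mapping[str, float]]) -> float:
    """Percentage of hyperactivated sperm in a sample (order-invariant)."""
    flags = [classify_hyperactivated(r) for r in records]
    if not flags:
        raise InvalidInputError("no kinematic records supplied")
    return 100.0 * sum(flags) / len(flags)


def induced_ar(
    pg: ArResult,
    spont: ArResult,
    min_count: int = AR_MIN_COUNT,
) -> float:
    """Induced acrosome reaction: progesterone minus spontaneous, in
    percentage points.  May be negative.  Counts below ``min_count``
    raise a warning (a design minimum, not an exclusion filter)."""
    if pg.total < min_count or spont.total < min_count:
        warnings.warn(
            f"AR counts below the design minimum of {min_count} sperm "
            f"(progesterone {pg.total}, spontaneous {spont.total})",
            stacklevel=2,
        )
    return pg.percent - spont.percent


def ivf_success(
    outcome: IvfOutcome | float,
    threshold: float = IVF_SUCCESS_THRESHOLD,
) -> bool:
    """IVF procedure classified successful iff the 2PN fertilization
    rate is at least ``threshold`` (inclusive).  Accepts an
    :class:`IvfOutcome` or a bare rate."""
    rate = outcome.rate if isinstance(outcome, IvfOutcome) else float(outcome)
    if not 0.0 <= rate <= 1.0:
        raise InvalidInputError("fertilization rate must lie in [0,1]")
    return rate >= threshold
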