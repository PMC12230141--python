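"""ACC threshold estimation and cochlear dead-region classification rules.

The ACC threshold is the lowest SNR at which the response is present,
with the response absent 3 dB below and present 3 dB above (clauses at
grid edges are vacuous).  Dead-region screens: the electrophysiological
rule flags an ACC threshold at or above 12 dB SNR; the behavioural TEN
rule requires the masked threshold to be both >= TEN level + 10 dB and
>= absolute threshold + 10 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .design import ConfigurationError, StimulusDesign
from .detect import ABSENT, INCONCLUSIVE, PRESENT, DetectionResult

__all__ = ["ThresholdResult", "DRClassification", "estimate_threshold", "classify_dead_region"]

_PATTERN_CHAR = {PRESENT: "P", ABSENT: "A", INCONCLUSIVE: "I", None: "-"}


@dataclass
class ThresholdResult:
    """Threshold (a grid SNR, or None when undetermined) plus the rule's audit trail."""

    threshold_db_snr: Optional[float]
    pattern: str            # ascending-SNR outcome string of P/A/I/-
    reason: str
    snr_grid_db: tuple
    flags: list = field(default_factory=list)

    @property
    def determined(self) -> bool:
        return self.threshold_db_snr is not None


@dataclass
class DRClassification:
    """Joint result of the ACC 12-dB rule and the behavioural TEN 10-dB rule."""

    acc_rule_positive: Optional[bool]   # None when the ACC threshold is undetermined
    ten_rule_positive: bool
    acc_threshold_db_snr: Optional[float]
    masked_threshold_dbhl: float
    ten_level_dbhl: float
    absolute_threshold_dbhl: float
    acc_cutoff_db: float


def _normalise_outcome(o: Union[DetectionResult, str, None]) -> Optional[str]:
    if o is None:
        return None
    if isinstance(o, DetectionResult):
        o = o.outcome
    if o not in (PRESENT, ABSENT, INCONCLUSIVE):
        raise ConfigurationError(f"unknown outcome {o!r}")
    return o


def estimate_threshold(
    outcomes: Sequence[Union[DetectionResult, str, None]],
    design: StimulusDesign,
    snr_levels_db: Optional[Sequence[float]] = None,
) -> ThresholdResult:
    """Apply the three-clause threshold rule over the SNR grid.

    ``outcomes`` align with ``snr_levels_db`` (default: the design's grid
    in its stated order); ``None`` marks a missing cell.  Inconclusive
    cells are treated as missing: a +3/-3 clause that lands on one is
    vacuous and flagged, but the threshold level itself must be a
    determinate "present".  The lowest qualifying level wins, with no
    smoothing of non-monotone patterns.
    """
    levels = list(snr_levels_db if snr_levels_db is not None else design.snr_levels_db)
    if len(outcomes) == 0:
        raise ConfigurationError("empty outcome list")
    if len(outcomes) != len(levels):
        raise ConfigurationError(
            f"{len(outcomes)} outcomes for {len(levels)} SNR levels"
        )
    cells = {float(l): _normalise_outcome(o) for l, o in zip(levels, outcomes)}
    grid = sorted(cells)
    step = design.snr_step_db
    pattern = "".join(_PATTERN_CHAR[cells[l]] for l in grid)

    flags: list = []
    for level in grid:
        if cells[level] != PRESENT:
            continue
        above, below = level + step, level - step
        clauses_ok = True
        local_flags = []
        if above in cells:
            if cells[above] in (None, INCONCLUSIVE):
                local_flags.append(f"+{step:g} dB clause vacuous at {level:g} dB (cell {_PATTERN_CHAR[cells[above]]})")
            elif cells[above] != PRESENT:
                clauses_ok = False
        if below in cells:
            if cells[below] in (None, INCONCLUSIVE):
                local_flags.append(f"-{step:g} dB clause vacuous at {level:g} dB (cell {_PATTERN_CHAR[cells[below]]})")
            elif cells[below] != ABSENT:
                clauses_ok = False
        if clauses_ok:
            parts = ["present at threshold"]
            parts.append("present above" if above in cells and cells[above] == PRESENT
                         else "+clause vacuous")
            parts.append("absent below" if below in cells and cells[below] == ABSENT
                         else "-clause vacuous")
            return ThresholdResult(
                threshold_db_snr=level, pattern=pattern,
                reason="; ".join(parts), snr_grid_db=tuple(grid),
                flags=flags + local_flags,
            )
        flags.extend(local_flags)
    return ThresholdResult(
        threshold_db_snr=None, pattern=pattern,
        reason="no level satisfies the rule", snr_grid_db=tuple(grid), flags=flags,
    )


def classify_dead_region(
    acc_threshold_db_snr: Optional[float],
    masked_threshold_dbhl: float,
    ten_level_dbhl: float,
    absolute_threshold_dbhl: float,
    acc_cutoff_db: float = 12.0,
) -> DRClassification:
    """Apply the ACC 12-dB-SNR rule and the two-criterion behavioural TEN rule.

    An undetermined ACC threshold propagates as ``acc_rule_positive=None``
    (not False).  The behavioural rule is positive only when BOTH
    criteria hold: masked >= TEN level + 10 and masked >= absolute
    threshold + 10 (dB HL throughout).
    """
    if acc_threshold_db_snr is None:
        acc_positive: Optional[bool] = None
    else:
        acc_positive = acc_threshold_db_snr >= acc_cutoff_db
    ten_positive = (
        masked_threshold_dbhl >= ten_level_dbhl + 10.0
        and masked_threshold_dbhl >= absolute_threshold_dbhl + 10.0
    )
    return DRClassification(
        acc_rule_positive=acc_positive,
        ten_rule_positive=bool(ten_positive),
        acc_threshold_db_snr=acc_threshold_db_snr,
        masked_threshold_dbhl=masked_threshold_dbhl,
        ten_level_dbhl=ten_level_dbhl,
        absolute_threshold_dbhl=absolute_threshold_dbhl,
        acc_cutoff_db=acc_cutoff_db,
    )
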