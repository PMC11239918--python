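"""CelTIL scoring of paired tumor biopsies.

CelTIL combines tumor cellularity and stromal tumor-infiltrating
lymphocytes (TILs), both scored by a pathologist on H&E sections as
percentages, into a single score::

    raw = -0.8 * cellularity% + 1.3 * TILs%

which is then affinely rescaled from its theoretical range [-80, 130]
onto [0, 100].  High scores mark tumors that are highly immune
infiltrated with little residual tumor cellularity.  The change between
a baseline biopsy and an on-treatment (day 21) biopsy is the trial
endpoint: an absolute increase of the scaled score of >= 20 points is
called a CelTIL response (other cutoffs >0, >=10, >=30, >=40 are used in
sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

CELLULARITY_COEF = -0.8
TILS_COEF = 1.3
RAW_MIN = -80.0  # cellularity 100, TILs 0
RAW_MAX = 130.0  # cellularity 0, TILs 100
RAW_RANGE = RAW_MAX - RAW_MIN  # 210

#: cutoffs evaluated in the sensitivity analysis; 0 means strict "> 0",
#: the others mean ">= cutoff".
SENSITIVITY_CUTOFFS = (0.0, 10.0, 20.0, 30.0, 40.0)

TIMEPOINTS = ("baseline", "day21")


class CelTILValidationError(ValueError):
    """Raised for out-of-range percentages or malformed assessments."""


class PairingError(ValueError):
    """Raised when two assessments do not form a valid baseline/day21 pair."""


@dataclass(frozen=True)
class BiopsyAssessment:
    """One pathology read-out: cellularity % and TILs % for a sample at a timepoint."""

    sample_id: str
    timepoint: str
    cellularity: float
    tils: float

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise CelTILValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        _check_percent("cellularity", self.cellularity)
        _check_percent("tils", self.tils)


@dataclass(frozen=True)
class CelTILResult:
    """Scored biopsy pair: raw/scaled scores at both timepoints, delta and response call."""

    sample_id: str
    baseline_scaled: float
    day21_scaled: float
    delta: float
    responder: bool
    cutoff: float


def _check_percent(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise CelTILValidationError(f"{name} must be in [0, 100], got {value}")


def celtil_raw(cellularity: float, tils: float) -> float:
    """Raw CelTIL score: -0.8*cellularity + 1.3*TILs, both in percent."""
    _check_percent("cellularity", cellularity)
    _check_percent("tils", tils)
    return CELLULARITY_COEF * cellularity + TILS_COEF * tils


def celtil_scaled(raw: float) -> float:
    """Affine rescaling of the raw score from [-80, 130] onto [0, 100]."""
    if not (RAW_MIN <= raw <= RAW_MAX):
        raise CelTILValidationError(
            f"raw CelTIL must be in [{RAW_MIN}, {RAW_MAX}], got {raw}"
        )
    return (raw - RAW_MIN) / RAW_RANGE * 100.0


def celtil_score(cellularity: float, tils: float) -> float:
    """Scaled CelTIL score straight from the two percentages."""
    return celtil_scaled(celtil_raw(cellularity, tils))


def is_responder(delta: float, cutoff: float = 20.0) -> bool:
    """Response call on a scaled-score delta.

    ``cutoff == 0`` uses the strict ``delta > 0`` rule; every other cutoff
    is inclusive (``delta >= cutoff``), mirroring the sensitivity set
    (>0, >=10, >=20, >=30, >=40).
    """
    if cutoff == 0:
        return delta > 0
    return delta >= cutoff


def celtil_delta(
    baseline: BiopsyAssessment, day21: BiopsyAssessment, cutoff: float = 20.0
) -> CelTILResult:
    """Score a baseline/day-21 pair and call CelTIL response.

    Delta is computed on the scaled score (day21 minus baseline); the
    responder flag applies :func:`is_responder` at ``cutoff``.
    """
    if baseline.sample_id != day21.sample_id:
        raise PairingError(
            f"sample_id mismatch: {baseline.sample_id!r} vs {day21.sample_id!r}"
        )
    if baseline.timepoint != "baseline" or day21.timepoint != "day21":
        raise PairingError(
            "expected timepoints (baseline, day21), got "
            f"({baseline.timepoint!r}, {day21.timepoint!r})"
        )
    b = celtil_score(baseline.cellularity, baseline.tils)
    d = celtil_score(day21.cellularity, day21.tils)
    delta = d - b
    return CelTILResult(
        sample_id=baseline.sample_id,
        baseline_scaled=b,
        day21_scaled=d,
        delta=delta,
        responder=is_responder(delta, cutoff),
        cutoff=cutoff,
    )


def score_pairs(
    assessments: Iterable[BiopsyAssessment], cutoff: float = 20.0
) -> list[CelTILResult]:
    """Pair assessments by sample_id and score every complete pair.

    Raises :class:`PairingError` on a duplicated timepoint for a sample;
    samples missing one of the two timepoints are skipped.
    """
    by_sample: dict[str, dict[str, BiopsyAssessment]] = {}
    for a in assessments:
        slot = by_sample.setdefault(a.sample_id, {})
        if a.timepoint in slot:
            raise PairingError(
                f"duplicated timepoint {a.timepoint!r} for sample {a.sample_id!r}"
            )
        slot[a.timepoint] = a
    results = []
    for sid in sorted(by_sample):
        slot = by_sample[sid]
        if "baseline" in slot and "day21" in slot:
            results.append(celtil_delta(slot["baseline"], slot["day21"], cutoff))
    return results


def response_rate(results: Sequence[CelTILResult]) -> tuple[int, int, float]:
    """(n_responders, n_total, proportion) over a list of scored pairs."""
    if not results:
        raise CelTILValidationError("response_rate requires a non-empty result list")
    n_resp = sum(1 for r in results if r.responder)
    return n_resp, len(results), n_resp / len(results)
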