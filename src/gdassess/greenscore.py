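"""Green Score and its genetic-diversity correction.

The Green Score aggregates the recovery state of a species' spatial
units (geographic populations):

    G = Σ_S W_S / (W_F × N) × 100

with W_S the per-unit state weight, W_F the weight of the fully
functional state, and N the number of units. The GD-corrected variant
discounts each unit by its genetic diversity relative to the average of
Least-Concern relatives, capped at 1:

    G' = Σ_S W_S · min(GD_S / GD_LC, 1) / (W_F × N) × 100

Two weight presets ship: ``main-text`` uses the published ladder
absent 0 / present 3 / viable 6 / functional 9 with W_F = 9; ``box1``
uses viable 9 / functional 12 with W_F = 12, the weighting under which
the California towhee worked examples reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STATES = ("absent", "present", "viable", "functional")


@dataclass(frozen=True)
class SpatialUnit:
    label: str
    state: str
    gd: float | None = None  # unit-level genetic diversity, e.g. heterozygosity

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown spatial-unit state {self.state!r}")
        if self.gd is not None and self.gd < 0:
            raise ValueError("gd must be non-negative")


@dataclass(frozen=True)
class GreenWeights:
    name: str
    state_weights: Mapping[str, float]
    w_f: float

    def __post_init__(self) -> None:
        if set(self.state_weights) != set(STATES):
            raise ValueError("weights must cover exactly the four unit states")
        if any(w < 0 for w in self.state_weights.values()) or self.w_f <= 0:
            raise ValueError("weights must be non-negative and w_f positive")

    def weight(self, state: str) -> float:
        return self.state_weights[state]


MAIN_TEXT_WEIGHTS = GreenWeights(
    name="main-text",
    state_weights={"absent": 0.0, "present": 3.0, "viable": 6.0, "functional": 9.0},
    w_f=9.0,
)
BOX1_WEIGHTS = GreenWeights(
    name="box1",
    state_weights={"absent": 0.0, "present": 3.0, "viable": 9.0, "functional": 12.0},
    w_f=12.0,
)
PRESETS = {w.name: w for w in (MAIN_TEXT_WEIGHTS, BOX1_WEIGHTS)}


@dataclass(frozen=True)
class GreenResult:
    score: float  # Green Score points, 0-100 when W_S <= W_F
    corrected: bool
    n_units: int
    weights: str
    gd_lc: float | None = None


def green_score(
    units: Sequence[SpatialUnit], weights: GreenWeights = MAIN_TEXT_WEIGHTS
) -> GreenResult:
    """Uncorrected Green Score over the given spatial units."""
    if not units:
        raise ValueError("at least one spatial unit is required")
    total = sum(weights.weight(u.state) for u in units)
    score = total / (weights.w_f * len(units)) * 100.0
    return GreenResult(score=score, corrected=False, n_units=len(units),
                       weights=weights.name)


def gd_corrected_green_score(
    units: Sequence[SpatialUnit],
    weights: GreenWeights,
    gd_lc: float,
) -> GreenResult:
    """GD-corrected Green Score; each unit's weight is scaled by
    min(GD_S/GD_LC, 1)."""
    if not units:
        raise ValueError("at least one spatial unit is required")
    if gd_lc <= 0:
        raise ValueError("gd_lc must be positive")
    for u in units:
        if u.gd is None:
            raise ValueError(f"spatial unit {u.label!r} lacks a gd value")
    total = sum(
        weights.weight(u.state) * min(u.gd / gd_lc, 1.0) for u in units
    )
    score = total / (weights.w_f * len(units)) * 100.0
    return GreenResult(score=score, corrected=True, n_units=len(units),
                       weights=weights.name, gd_lc=gd_lc)


def mean_reference_gd(values: Iterable[float]) -> float:
    """Arithmetic mean GD of Least-Concern reference species (GD_LC)."""
    vals = list(values)
    if not vals:
        raise ValueError("no reference GD values")
    return sum(vals) / len(vals)
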