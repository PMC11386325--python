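"""Genetic conservation-status assessment.

Projects the drift-driven loss of heterozygosity over a fixed horizon,
H_T = H_O · (1 − 1/(2·Ne))^T with T the number of generations in the
horizon (default 100 years), and assigns a genetic Red List category
from the H_T:H_O ratio, explicit Ne floors, and — when Ne cannot be
derived or the size-based tree returns Least Concern — a relative-H_O
comparison against the maximum observed heterozygosity of already
genetically Threatened relatives in the same taxonomic Order (or
Family).

Categories follow Red List vocabulary: LC, NT, VU, EN, CR, with
"Threatened" the union of VU+EN+CR. The decision tree itself emits only
CR/EN/VU/LC plus the relative-H_O Threatened determination; NT is
accepted on input (e.g. in reference tables) but never produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

DEFAULT_HORIZON_YEARS = 100.0
DEFAULT_LONG_GENERATION_YEARS = 15.0

_SEVERITY = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}
THREATENED_LABEL = "Threatened-by-relative-HO"


@dataclass(frozen=True)
class SpeciesProfile:
    """Inputs for one taxon's genetic assessment.

    Ne may be given directly, derived from census size via the Ne/Nc
    ratio, or from Watterson's θ and the mutation rate (θ_W = 4·Ne·μ).
    """

    label: str
    order: str | None = None
    family: str | None = None
    H_O: float | None = None
    theta_w: float | None = None
    Nc: float | None = None
    Ne: float | None = None
    ne_nc_ratio: float = 0.10
    generation_time_years: float | None = None
    mu: float | None = None
    category: "GeneticCategory | None" = None  # carried by reference members


@dataclass(frozen=True)
class Projection:
    H_O: float
    Ne: float
    T: float
    H_T: float

    @property
    def ratio(self) -> float:
        return self.H_T / self.H_O if self.H_O > 0 else 1.0


@dataclass(frozen=True)
class CategoryThresholds:
    """Ratio cut points and Ne floors of the categorization tree.

    ratio ≤ ratio_cr → CR; ≤ ratio_en → EN; ≤ ratio_vu → VU. An Ne
    below a floor can only worsen the ratio-derived category.
    """

    ratio_cr: float = 0.90
    ratio_en: float = 0.95
    ratio_vu: float = 0.975
    ne_floor_vu: float = 1000.0
    ne_floor_en: float = 500.0
    ne_floor_cr: float = 100.0
    long_generation_years: float = DEFAULT_LONG_GENERATION_YEARS

    def __post_init__(self) -> None:
        if not self.ratio_cr < self.ratio_en < self.ratio_vu < 1.0:
            raise ValueError("ratio thresholds must increase: CR < EN < VU < 1")
        if not self.ne_floor_cr < self.ne_floor_en < self.ne_floor_vu:
            raise ValueError("Ne floors must decrease from VU to CR")


@dataclass(frozen=True)
class GeneticCategory:
    value: str  # LC / NT / VU / EN / CR / Threatened-by-relative-HO
    provenance: str


def generations_in_horizon(
    generation_time_years: float, horizon_years: float = DEFAULT_HORIZON_YEARS
) -> float:
    """T = horizon / generation time, real-valued (no rounding)."""
    if generation_time_years <= 0:
        raise ValueError("generation time must be positive")
    return horizon_years / generation_time_years


def project_heterozygosity(H_O: float, Ne: float, T: float) -> Projection:
    """H_T = H_O · (1 − 1/(2Ne))^T, evaluated in log space."""
    if Ne <= 0.5:
        raise ValueError("Ne must exceed 0.5 for a positive retention base")
    if T < 0:
        raise ValueError("T must be non-negative")
    if H_O < 0:
        raise ValueError("H_O must be non-negative")
    log_retention = T * math.log1p(-1.0 / (2.0 * Ne))
    return Projection(H_O=H_O, Ne=Ne, T=T, H_T=H_O * math.exp(log_retention))


def ne_from_nc(Nc: float, ratio: float) -> float:
    """Ne = Nc × (Ne/Nc ratio)."""
    if Nc <= 0:
        raise ValueError("Nc must be positive")
    if not 0 < ratio <= 1:
        raise ValueError("Ne/Nc ratio must lie in (0, 1]")
    return Nc * ratio


def ne_from_theta(theta_w_per_site: float, mu: float) -> float:
    """Ne = θ_W / (4μ), from θ_W = 4·Ne·μ at mutation–drift equilibrium."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if theta_w_per_site < 0:
        raise ValueError("theta must be non-negative")
    return theta_w_per_site / (4.0 * mu)


def derive_ne(profile: SpeciesProfile) -> tuple[float | None, str]:
    """Best available Ne and a short provenance tag for how it was obtained."""
    if profile.Ne is not None:
        return profile.Ne, "Ne given"
    if profile.Nc is not None:
        return ne_from_nc(profile.Nc, profile.ne_nc_ratio), (
            f"Ne = Nc × {profile.ne_nc_ratio:g}"
        )
    if profile.theta_w is not None and profile.mu is not None:
        return ne_from_theta(profile.theta_w, profile.mu), "Ne = theta_w / (4 mu)"
    return None, "Ne not derivable"


def _is_threatened_value(value: str) -> bool:
    return value in ("VU", "EN", "CR", THREATENED_LABEL)


def relative_ho_threshold(
    reference: Sequence[SpeciesProfile],
    order: str | None = None,
    family: str | None = None,
) -> float | None:
    """Maximum H_O among genetically Threatened reference relatives.

    Matches at the Order level first; falls back to Family when the
    Order yields no threatened members with an H_O. None when neither
    level applies.
    """
    def max_at(attr: str, value: str | None) -> float | None:
        if value is None:
            return None
        vals = [
            p.H_O
            for p in reference
            if getattr(p, attr) == value
            and p.H_O is not None
            and p.category is not None
            and _is_threatened_value(p.category.value)
        ]
        return max(vals) if vals else None

    return max_at("order", order) if max_at("order", order) is not None else max_at(
        "family", family
    )


def _ratio_category(ratio: float, th: CategoryThresholds) -> str:
    if ratio <= th.ratio_cr:
        return "CR"
    if ratio <= th.ratio_en:
        return "EN"
    if ratio <= th.ratio_vu:
        return "VU"
    return "LC"


def _floor_category(ne: float, th: CategoryThresholds) -> str:
    if ne < th.ne_floor_cr:
        return "CR"
    if ne < th.ne_floor_en:
        return "EN"
    if ne < th.ne_floor_vu:
        return "VU"
    return "LC"


def assign_genetic_category(
    profile: SpeciesProfile,
    thresholds: CategoryThresholds = CategoryThresholds(),
    reference: Sequence[SpeciesProfile] | None = None,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
) -> GeneticCategory | None:
    """Run the categorization tree for one profile.

    Order of evaluation: (1) with a derivable Ne and generation time,
    the H_T:H_O ratio sets CR/EN/VU; (2) Ne floors may only worsen the
    result; (3) when Ne is not derivable, or the size-based rules leave
    the taxon at LC, the relative-H_O comparison can still flag it as
    Threatened; (4) otherwise LC. Returns None (no applicable route)
    when neither Ne nor a usable reference exists.
    """
    ne, ne_prov = derive_ne(profile)
    category: str | None = None
    provenance = ""

    if ne is not None and profile.generation_time_years is not None:
        T = generations_in_horizon(profile.generation_time_years, horizon_years)
        proj = project_heterozygosity(profile.H_O if profile.H_O else 1.0, ne, T)
        ratio_cat = _ratio_category(proj.ratio, thresholds)
        floor_cat = _floor_category(ne, thresholds)
        long_gen = profile.generation_time_years > thresholds.long_generation_years
        if _SEVERITY[floor_cat] > _SEVERITY[ratio_cat]:
            category = floor_cat
            provenance = (
                f"Ne floor: Ne={ne:g} ({ne_prov}) below {floor_cat} floor; "
                f"H_T:H_O={proj.ratio:.4f}"
                + ("; long generation time" if long_gen else "")
            )
        else:
            category = ratio_cat
            provenance = f"H_T:H_O={proj.ratio:.4f} with Ne={ne:g} ({ne_prov}), T={T:g}"

    if category in (None, "LC") and reference is not None and profile.H_O is not None:
        ref_max = relative_ho_threshold(reference, profile.order, profile.family)
        if ref_max is not None and profile.H_O < ref_max:
            return GeneticCategory(
                value=THREATENED_LABEL,
                provenance=(
                    f"relative H_O: {profile.H_O:g} < max threatened relative "
                    f"H_O {ref_max:g}"
                    + (f" (after {provenance})" if provenance else "")
                ),
            )
        if category is None and ref_max is not None:
            return GeneticCategory(
                value="LC", provenance=f"relative H_O: {profile.H_O:g} >= {ref_max:g}"
            )

    if category is None:
        return None  # no applicable route: Ne underivable and no usable reference
    return GeneticCategory(value=category, provenance=provenance)


def collapse_binary(category: GeneticCategory | str) -> str:
    """Map a category to the Threatened / Non-Threatened dichotomy."""
    value = category.value if isinstance(category, GeneticCategory) else category
    if _is_threatened_value(value):
        return "Threatened"
    if value in ("LC", "NT"):
        return "Non-Threatened"
    raise ValueError(f"cannot collapse category {value!r}")
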