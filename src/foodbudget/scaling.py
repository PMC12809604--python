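"""Anchor an observed diet to the recommended energy intake.

The observed mean energy intake cE of a country usually deviates from the
recommended intake rE of the reference person. The percentage energy
structure between food groups is kept fixed and every quantity is rescaled
by the single factor rE/cE, so the scaled diet sC has total energy exactly
rE while preserving all between-group energy shares. This scaled diet is
the starting point of the optimisation.
"""

from __future__ import annotations

from .model import ConsumptionProfile, FoodModelError, NutrientTable, PersonProfile, ScaledProfile


def scale_to_energy(
    profile: ConsumptionProfile,
    nutrients: NutrientTable,
    person: PersonProfile,
) -> ScaledProfile:
    """Rescale a diet so its energy equals the recommended intake.

    sC_i = C_i x rE/cE for every group i; groups with zero consumption stay
    zero, and the single common factor preserves the percentage energy
    structure between groups.
    """
    ce = profile.energy(nutrients)
    if ce <= 0:
        raise FoodModelError(
            f"{profile.country}/{profile.gender}: observed diet has no energy, cannot scale"
        )
    re_kcal = person.energy_kcal
    if re_kcal <= 0:
        raise FoodModelError("recommended energy intake must be positive")
    factor = re_kcal / ce
    return ScaledProfile(
        country=profile.country,
        gender=person.gender,
        quantities={code: q * factor for code, q in profile.quantities.items()},
        re_kcal=re_kcal,
        factor=factor,
    )


def scaled_as_profile(scaled: ScaledProfile) -> ConsumptionProfile:
    """View a scaled diet as a plain consumption profile (e.g. to re-scale)."""
    return ConsumptionProfile(
        country=scaled.country, gender=scaled.gender, quantities=dict(scaled.quantities)
    )
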