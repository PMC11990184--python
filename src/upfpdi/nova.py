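"""NOVA classification and ultra-processed-food (UPF) energy share.

Handmade mixed dishes are first disaggregated into ingredients using the
recipe table, each resulting item is attached to one of the four NOVA
processing groups, and the percent of each participant's daily energy coming
from NOVA group 4 (UPFs) is computed from the single-day 24 h recall.

Energy reconciliation rule: the reported recall energy of a recipe item is
authoritative.  Ingredient energies computed from ingredient energy
densities are proportionally rescaled so they sum to the reported recipe
energy, which keeps every participant's energy total identical before and
after disaggregation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .reference import ReferenceBundle

log = logging.getLogger(__name__)

RECALL_COLUMNS = ("participant_id", "food_code", "grams", "energy_kj")


class ClassificationError(ValueError):
    """An item could not be assigned exactly one NOVA group."""


def validate_recall(recall: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECALL_COLUMNS if c not in recall.columns]
    if missing:
        raise ValueError(f"recall table missing column(s): {', '.join(missing)}")
    recall = recall.copy()
    recall["food_code"] = recall["food_code"].astype("int64")
    if (recall["grams"] < 0).any() or (recall["energy_kj"] < 0).any():
        raise ValueError("recall grams and energy must be non-negative")
    return recall


def disaggregate(
    recall: pd.DataFrame,
    recipes: pd.DataFrame,
    composition: pd.DataFrame,
) -> pd.DataFrame:
    """Replace recipe items by their ingredients.

    Grams are split by the recipe weight fractions.  Ingredient energies are
    computed from ingredient energy density x grams and then rescaled so the
    ingredients of each eaten recipe item sum to the item's reported energy;
    if every ingredient has zero density the reported energy is split by
    weight fraction instead.  Non-recipe items pass through unchanged.
    """
    recall = validate_recall(recall)
    recipe_codes = set(composition.loc[composition["is_recipe"], "food_code"])
    is_recipe_item = recall["food_code"].isin(recipe_codes)
    plain = recall.loc[~is_recipe_item].copy()
    eaten = recall.loc[is_recipe_item].copy()
    if eaten.empty:
        return plain.reset_index(drop=True)

    unknown = set(eaten["food_code"]) - set(recipes["parent_code"])
    if unknown:
        raise ClassificationError(
            f"recipe foods eaten but absent from the recipe table: {sorted(unknown)}"
        )

    eaten = eaten.reset_index(drop=True).rename_axis("item_idx").reset_index()
    merged = eaten.merge(
        recipes, left_on="food_code", right_on="parent_code", how="left", validate="m:m"
    )
    dens = composition.set_index("food_code")["energy_density_kj_100g"]
    missing_ing = set(merged["ingredient_code"]) - set(dens.index)
    if missing_ing:
        raise ClassificationError(
            f"recipe references unknown ingredient(s): {sorted(missing_ing)}"
        )
    merged["ing_grams"] = merged["grams"] * merged["weight_fraction"]
    merged["raw_energy"] = merged["ing_grams"] * merged["ingredient_code"].map(dens) / 100.0

    raw_sum = merged.groupby("item_idx")["raw_energy"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(raw_sum > 0, merged["energy_kj"] / raw_sum, np.nan)
    merged["ing_energy"] = np.where(
        raw_sum > 0,
        merged["raw_energy"] * scale,
        merged["energy_kj"] * merged["weight_fraction"],
    )

    out = merged[["participant_id", "ingredient_code", "ing_grams", "ing_energy"]].rename(
        columns={
            "ingredient_code": "food_code",
            "ing_grams": "grams",
            "ing_energy": "energy_kj",
        }
    )
    result = pd.concat([plain, out], ignore_index=True)
    return result.sort_values(["participant_id", "food_code"], kind="mergesort").reset_index(
        drop=True
    )


def classify(items: pd.DataFrame, nova: pd.DataFrame) -> pd.DataFrame:
    """Attach a NOVA group (1-4) to each (post-disaggregation) item.

    Items whose food code has no NOVA assignment raise
    :class:`ClassificationError` rather than being silently classified.
    """
    items = validate_recall(items)
    mapping = nova.set_index("food_code")["nova_group"]
    groups = items["food_code"].map(mapping)
    if groups.isna().any():
        missing = sorted(items.loc[groups.isna(), "food_code"].unique())
        raise ClassificationError(f"items without a NOVA assignment: {missing}")
    out = items.copy()
    out["nova_group"] = groups.astype("int64")
    return out


def energy_shares_by_nova(classified: pd.DataFrame) -> pd.DataFrame:
    """Percent of daily energy by NOVA group, one row per participant."""
    tot = classified.groupby("participant_id")["energy_kj"].sum()
    by = (
        classified.groupby(["participant_id", "nova_group"])["energy_kj"]
        .sum()
        .unstack("nova_group", fill_value=0.0)
        .reindex(columns=[1, 2, 3, 4], fill_value=0.0)
    )
    shares = by.div(tot, axis=0) * 100.0
    shares.columns = [f"pct_energy_nova{g}" for g in [1, 2, 3, 4]]
    shares["total_energy_kj"] = tot
    return shares.reset_index()


def upf_energy_share(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-participant percent of daily energy from NOVA group 4.

    Participants with zero total reported energy cannot have a defined share
    and are excluded with a logged warning.

    Returns a frame with columns ``participant_id``, ``total_energy_kj``,
    ``pct_energy_upf``.
    """
    shares = energy_shares_by_nova(classified)
    zero = shares["total_energy_kj"] <= 0
    if zero.any():
        log.warning(
            "excluding %d participant(s) with zero total energy: %s",
            int(zero.sum()),
            list(shares.loc[zero, "participant_id"].head(10)),
        )
        shares = shares.loc[~zero]
    out = shares[["participant_id", "total_energy_kj"]].copy()
    out["pct_energy_upf"] = shares["pct_energy_nova4"].to_numpy()
    return out.reset_index(drop=True)


def compute_upf_share(recall: pd.DataFrame, bundle: ReferenceBundle) -> pd.DataFrame:
    """Convenience chain: disaggregate -> classify -> UPF energy share."""
    items = disaggregate(recall, bundle.recipes, bundle.composition)
    return upf_energy_share(classify(items, bundle.nova))
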