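"""Reference tables for dietary coding.

Four delimited tables drive the pipeline: a food-composition table keyed by
8-digit food codes, a recipe/ingredient table used to disaggregate handmade
mixed dishes, a NOVA processing-level assignment table, and a plant-group
apportionment table that distributes each food's servings across 23 source
food groups.  A :class:`GroupScheme` collapses the 23 source groups to the
18 analysis groups used by the plant-based diet indices and labels each
analysis group as healthy plant, unhealthy plant, or animal.

Validation is fail-fast: reference tables are small and any malformed row
would propagate silently into every downstream score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: kJ per kcal; internal canonical energy unit is kJ, tables report kcal.
KJ_PER_KCAL = 4.184

HEALTHY_PLANT: tuple[str, ...] = (
    "whole_grains",
    "fruits",
    "vegetables",
    "nuts_seeds",
    "legumes",
    "plant_oils",
    "tea_coffee",
)
UNHEALTHY_PLANT: tuple[str, ...] = (
    "refined_grains",
    "fruit_juices",
    "saturated_plant_fats",
    "sugars_syrups",
    "misc_plant",
)
ANIMAL: tuple[str, ...] = (
    "animal_fats",
    "dairy",
    "eggs",
    "fish_seafood",
    "meat",
    "misc_animal",
)

#: The 18 analysis food groups (7 healthy plant, 5 unhealthy plant, 6 animal).
ANALYSIS_GROUPS: tuple[str, ...] = HEALTHY_PLANT + UNHEALTHY_PLANT + ANIMAL

HEALTH_CLASS: dict[str, str] = {
    **{g: "healthy_plant" for g in HEALTHY_PLANT},
    **{g: "unhealthy_plant" for g in UNHEALTHY_PLANT},
    **{g: "animal" for g in ANIMAL},
}

# Source-level strata that collapse into single analysis groups: the dairy
# group is recorded at three fat levels and meat as four red-meat/poultry
# strata, giving 23 source groups in total.
DAIRY_SOURCES: tuple[str, ...] = ("dairy_low_fat", "dairy_medium_fat", "dairy_high_fat")
MEAT_SOURCES: tuple[str, ...] = (
    "red_meat_lean",
    "red_meat_fatty",
    "poultry_lean",
    "poultry_fatty",
)

SOURCE_GROUPS: tuple[str, ...] = tuple(
    g for g in ANALYSIS_GROUPS if g not in ("dairy", "meat")
) + DAIRY_SOURCES + MEAT_SOURCES

DEFAULT_COLLAPSE_MAP: dict[str, str] = {
    **{g: g for g in ANALYSIS_GROUPS if g not in ("dairy", "meat")},
    **{g: "dairy" for g in DAIRY_SOURCES},
    **{g: "meat" for g in MEAT_SOURCES},
}

COMPOSITION_COLUMNS = ("food_code", "description", "energy_density_kj_100g", "is_recipe")
RECIPE_COLUMNS = ("parent_code", "ingredient_code", "weight_fraction")
NOVA_COLUMNS = ("food_code", "nova_group")
APPORTIONMENT_COLUMNS = ("food_code", "source_group", "servings_per_100g")


class SchemaError(ValueError):
    """A reference table is missing a required column."""


class ReferenceValidationError(ValueError):
    """A reference table violates a structural invariant."""


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {', '.join(missing)}")


def _check_food_codes(codes: pd.Series, table: str) -> None:
    bad = codes[(codes < 10_000_000) | (codes > 99_999_999)]
    if len(bad):
        raise ReferenceValidationError(
            f"{table} table has non-8-digit food codes: {sorted(bad.unique())[:5]}"
        )


@dataclass(frozen=True)
class GroupScheme:
    """Mapping from the 23 source food groups to the 18 analysis groups.

    Parameters
    ----------
    collapse_map
        source_group -> analysis_group.  The shipped default collapses the
        three dairy fat strata into ``dairy`` and the four red-meat/poultry
        strata into ``meat``; every other source group maps to itself.
    health_class
        analysis_group -> one of ``healthy_plant``, ``unhealthy_plant``,
        ``animal``.
    """

    collapse_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_COLLAPSE_MAP))
    health_class: dict[str, str] = field(default_factory=lambda: dict(HEALTH_CLASS))

    def __post_init__(self) -> None:
        analysis = sorted(set(self.collapse_map.values()))
        if len(analysis) != 18:
            raise ReferenceValidationError(
                f"collapse map must target exactly 18 analysis groups, got {len(analysis)}"
            )
        if set(analysis) != set(self.health_class):
            raise ReferenceValidationError(
                "health_class keys must coincide with the analysis groups"
            )
        counts = pd.Series(list(self.health_class.values())).value_counts()
        expected = {"healthy_plant": 7, "unhealthy_plant": 5, "animal": 6}
        if counts.to_dict() != expected:
            raise ReferenceValidationError(
                f"health classes must be 7 healthy_plant / 5 unhealthy_plant / 6 animal, got {counts.to_dict()}"
            )

    @property
    def analysis_groups(self) -> tuple[str, ...]:
        # keep canonical ordering where possible
        ordered = [g for g in ANALYSIS_GROUPS if g in self.health_class]
        extra = [g for g in sorted(self.health_class) if g not in ordered]
        return tuple(ordered + extra)

    @property
    def source_groups(self) -> tuple[str, ...]:
        return tuple(self.collapse_map)

    def groups_of_class(self, health_class: str) -> tuple[str, ...]:
        return tuple(g for g in self.analysis_groups if self.health_class[g] == health_class)

    @classmethod
    def default(cls) -> "GroupScheme":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(collapse_map=dict(raw["collapse_map"]), health_class=dict(raw["health_class"]))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"collapse_map": dict(self.collapse_map), "health_class": dict(self.health_class)},
                fh,
                sort_keys=True,
            )


def validate_composition(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, COMPOSITION_COLUMNS, "composition")
    df = df.copy()
    df["food_code"] = df["food_code"].astype("int64")
    df["is_recipe"] = df["is_recipe"].astype(bool)
    _check_food_codes(df["food_code"], "composition")
    dup = df["food_code"][df["food_code"].duplicated()]
    if len(dup):
        raise ReferenceValidationError(
            f"duplicate food codes in composition table: {sorted(dup.unique())}"
        )
    if (df["energy_density_kj_100g"] < 0).any():
        raise ReferenceValidationError("negative energy density in composition table")
    return df


def validate_recipes(df: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, RECIPE_COLUMNS, "recipes")
    df = df.copy()
    for c in ("parent_code", "ingredient_code"):
        df[c] = df[c].astype("int64")
    if ((df["weight_fraction"] < 0) | (df["weight_fraction"] > 1)).any():
        raise ReferenceValidationError("recipe weight fractions must lie in [0, 1]")
    sums = df.groupby("parent_code")["weight_fraction"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ReferenceValidationError(
            "recipe weight fractions must sum to 1 per parent; offending parents: "
            f"{ {int(k): float(v) for k, v in bad.items()} }"
        )
    recipe_codes = set(composition.loc[composition["is_recipe"], "food_code"])
    unknown_parents = set(df["parent_code"]) - recipe_codes
    if unknown_parents:
        raise ReferenceValidationError(
            f"recipe parents not flagged as recipes in composition: {sorted(unknown_parents)}"
        )
    known = set(composition["food_code"])
    unknown_ing = set(df["ingredient_code"]) - known
    if unknown_ing:
        raise ReferenceValidationError(
            f"recipe ingredients missing from composition: {sorted(unknown_ing)}"
        )
    # one-level resolution only: an ingredient must not itself be a recipe
    nested = set(df["ingredient_code"]) & recipe_codes
    if nested:
        raise ReferenceValidationError(
            f"recipe cycle / nesting: ingredients that are themselves recipes: {sorted(nested)}"
        )
    return df


def validate_nova(df: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, NOVA_COLUMNS, "nova")
    df = df.copy()
    df["food_code"] = df["food_code"].astype("int64")
    df["nova_group"] = df["nova_group"].astype("int64")
    dup = df["food_code"][df["food_code"].duplicated()]
    if len(dup):
        raise ReferenceValidationError(
            f"duplicate food codes in NOVA table: {sorted(dup.unique())}"
        )
    if (~df["nova_group"].isin([1, 2, 3, 4])).any():
        raise ReferenceValidationError("NOVA groups must be integers in 1..4")
    non_recipe = set(composition.loc[~composition["is_recipe"], "food_code"])
    missing = non_recipe - set(df["food_code"])
    if missing:
        raise ReferenceValidationError(
            f"non-recipe foods without a NOVA assignment: {sorted(missing)}"
        )
    return df


def validate_apportionment(df: pd.DataFrame, scheme: GroupScheme) -> pd.DataFrame:
    _require_columns(df, APPORTIONMENT_COLUMNS, "apportionment")
    df = df.copy()
    df["food_code"] = df["food_code"].astype("int64")
    if (df["servings_per_100g"] < 0).any():
        raise ReferenceValidationError("servings_per_100g must be non-negative")
    unknown = set(df["source_group"]) - set(scheme.source_groups)
    if unknown:
        raise ReferenceValidationError(f"unknown source group(s): {sorted(unknown)}")
    return df


@dataclass
class ReferenceBundle:
    """Validated bundle of the four reference tables plus the group scheme."""

    composition: pd.DataFrame
    recipes: pd.DataFrame
    nova: pd.DataFrame
    apportionment: pd.DataFrame
    scheme: GroupScheme

    FILE_NAMES = {
        "composition": "composition.csv",
        "recipes": "recipes.csv",
        "nova": "nova.csv",
        "apportionment": "apportionment.csv",
        "scheme": "scheme.yaml",
    }

    def collapsed_apportionment(self) -> pd.DataFrame:
        return collapse_groups(self.apportionment, self.scheme)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.composition.to_csv(path / self.FILE_NAMES["composition"], index=False)
        self.recipes.to_csv(path / self.FILE_NAMES["recipes"], index=False)
        self.nova.to_csv(path / self.FILE_NAMES["nova"], index=False)
        self.apportionment.to_csv(path / self.FILE_NAMES["apportionment"], index=False)
        self.scheme.to_yaml(path / self.FILE_NAMES["scheme"])


def load_reference_tables(
    path: str | Path | dict[str, str | Path],
    scheme_config: str | Path | None = None,
) -> ReferenceBundle:
    """Load and validate the four reference tables.

    Parameters
    ----------
    path
        Either a directory containing ``composition.csv``, ``recipes.csv``,
        ``nova.csv``, ``apportionment.csv`` (and optionally ``scheme.yaml``),
        or a dict with those four keys mapped to file paths.
    scheme_config
        Optional YAML file overriding the shipped 23 -> 18 collapse scheme.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ReferenceValidationError
        On duplicate food codes, invalid fractions, recipe nesting, missing
        NOVA assignments, or unknown source groups.
    """
    if isinstance(path, dict):
        paths = {k: Path(v) for k, v in path.items()}
    else:
        d = Path(path)
        paths = {k: d / v for k, v in ReferenceBundle.FILE_NAMES.items() if k != "scheme"}
        if scheme_config is None and (d / "scheme.yaml").exists():
            scheme_config = d / "scheme.yaml"

    for key in ("composition", "recipes", "nova", "apportionment"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"reference table not found: {key} ({paths.get(key)})")

    scheme = GroupScheme.from_yaml(scheme_config) if scheme_config else GroupScheme.default()

    composition = validate_composition(pd.read_csv(paths["composition"]))
    recipes = validate_recipes(pd.read_csv(paths["recipes"]), composition)
    nova = validate_nova(pd.read_csv(paths["nova"]), composition)
    apportionment = validate_apportionment(pd.read_csv(paths["apportionment"]), scheme)

    log.info(
        "loaded reference tables: %d foods (%d recipes), %d recipe rows, %d NOVA rows, %d apportionment rows",
        len(composition),
        int(composition["is_recipe"].sum()),
        len(recipes),
        len(nova),
        len(apportionment),
    )
    return ReferenceBundle(composition, recipes, nova, apportionment, scheme)


def collapse_groups(apportionment: pd.DataFrame, scheme: GroupScheme) -> pd.DataFrame:
    """Collapse a source-group apportionment to the 18 analysis groups.

    Servings are summed within each analysis group, so the total servings
    carried by each food are conserved exactly.
    """
    unknown = set(apportionment["source_group"]) - set(scheme.collapse_map)
    if unknown:
        raise ReferenceValidationError(f"unmapped source group(s): {sorted(unknown)}")
    out = apportionment.copy()
    out["analysis_group"] = out["source_group"].map(scheme.collapse_map)
    out = (
        out.groupby(["food_code", "analysis_group"], as_index=False)["servings_per_100g"]
        .sum()
        .sort_values(["food_code", "analysis_group"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out
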