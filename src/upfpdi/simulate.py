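"""Synthetic dietary-survey generator with known ground truth.

Emits everything the pipeline consumes — reference tables, single-day 24 h
recalls, sociodemographic covariates, anthropometry, and person + replicate
survey weights — for a population whose index-UPF structure is known by
construction, so end-to-end effect-size recovery is testable without any
restricted microdata.

Generation model
----------------
1. A latent "unhealthful diet" axis ``z ~ N(0,1)`` tilts per-group daily
   servings: healthy plant groups load negatively on z, unhealthy plant
   groups positively, animal groups mildly positively.  Servings are
   zero-inflated (group-specific probability of zero consumption on the
   recall day) and log-normal when consumed.
2. Recall items realise the servings: for each consumed group the
   participant eats one food of that group, with grams chosen so the food's
   servings-per-100g yields the drawn servings.  A fraction of participants
   additionally consume a handmade recipe dish (all-non-UPF ingredients).
3. The recalls are scored with the package's own pipeline (disaggregation,
   apportionment, weighted quintiles, index sums), giving each participant
   their realised PDI/hPDI/uPDI *before* any energy is assigned.
4. The UPF energy share is then set to
   ``target_upf_mean + sum_k slope_k (index_k - weighted mean) [+
   interaction] + N(0, noise_sd)``, clipped to (0.5, 99.5).  Because the
   indices entering this formula are exactly the indices the analysis
   recomputes, each configured slope is the exact conditional expectation
   of the corresponding single-index regression coefficient.
5. Item energies realise both the daily total (drawn around
   ``mean_energy``) and the UPF share: two always-consumed zero-serving
   beverage "filler" foods (one NOVA 1, one NOVA 4) guarantee every
   participant has both UPF and non-UPF energy pools, and each pool is
   proportionally scaled to its target.  Recipe ingredients are all
   non-UPF, so disaggregation leaves the UPF share unchanged.

Sociodemographic gradients (younger age and lower education at higher z,
mirroring the published uPDI pattern) are available but default to off so
that slope-recovery tests are uncontaminated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import nova as nova_mod
from .reference import (
    ANALYSIS_GROUPS,
    DAIRY_SOURCES,
    HEALTH_CLASS,
    KJ_PER_KCAL,
    MEAT_SOURCES,
    GroupScheme,
    ReferenceBundle,
)
from .scoring import score_population
from .survey import SurveyDesign

log = logging.getLogger(__name__)

GENERATOR_VERSION = "1"

UPF_FILLER_CODE = 19_900_004   # NOVA 4 beverage, zero servings
MIN_FILLER_CODE = 19_900_001   # NOVA 1 beverage, zero servings

#: Per-group generation parameters: probability of zero servings on the
#: recall day, median servings/day when consumed, and the loading of log
#: servings on the latent unhealthful-diet axis.
GROUP_PARAMS: dict[str, tuple[float, float, float]] = {
    "whole_grains": (0.30, 1.2, -0.35),
    "fruits": (0.25, 1.5, -0.35),
    "vegetables": (0.05, 2.8, -0.35),
    "nuts_seeds": (0.55, 0.8, -0.35),
    "legumes": (0.75, 0.7, -0.35),
    "plant_oils": (0.30, 1.0, -0.35),
    "tea_coffee": (0.15, 2.2, -0.35),
    "refined_grains": (0.10, 2.0, 0.40),
    "fruit_juices": (0.60, 0.9, 0.40),
    "saturated_plant_fats": (0.50, 0.5, 0.40),
    "sugars_syrups": (0.20, 1.5, 0.40),
    "misc_plant": (0.40, 0.6, 0.40),
    "animal_fats": (0.45, 0.6, 0.15),
    "dairy": (0.10, 1.8, 0.15),
    "eggs": (0.55, 0.9, 0.15),
    "fish_seafood": (0.70, 0.8, 0.15),
    "meat": (0.15, 1.6, 0.15),
    "misc_animal": (0.50, 0.5, 0.15),
}

#: Plausible energy density (kJ/100 g) per analysis group for generated foods.
GROUP_DENSITY: dict[str, float] = {
    "whole_grains": 550.0,
    "fruits": 250.0,
    "vegetables": 130.0,
    "nuts_seeds": 2500.0,
    "legumes": 400.0,
    "plant_oils": 3400.0,
    "tea_coffee": 30.0,
    "refined_grains": 1000.0,
    "fruit_juices": 180.0,
    "saturated_plant_fats": 3100.0,
    "sugars_syrups": 1300.0,
    "misc_plant": 800.0,
    "animal_fats": 3000.0,
    "dairy": 350.0,
    "eggs": 550.0,
    "fish_seafood": 700.0,
    "meat": 900.0,
    "misc_animal": 650.0,
}

#: NOVA groups a generated food of each analysis group may plausibly carry.
GROUP_NOVA: dict[str, tuple[int, ...]] = {
    "whole_grains": (1, 3),
    "fruits": (1, 1, 3),
    "vegetables": (1, 1, 3),
    "nuts_seeds": (1, 3),
    "legumes": (1, 3),
    "plant_oils": (2, 4),
    "tea_coffee": (1, 1),
    "refined_grains": (3, 4, 4),
    "fruit_juices": (1, 4),
    "saturated_plant_fats": (2, 4),
    "sugars_syrups": (2, 4, 4),
    "misc_plant": (4, 3),
    "animal_fats": (2, 3),
    "dairy": (1, 3, 4),
    "eggs": (1, 1),
    "fish_seafood": (1, 3),
    "meat": (1, 1, 3),
    "misc_animal": (3, 4),
}


class InteractionSpec(BaseModel):
    """Optional built-in moderation: adds size * 1[moderator level] * centred index."""

    moderator: str = "sex"
    level: str = "female"
    index: str = "updi"
    size: float = 0.0


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic survey.

    Defaults follow the target population's published marginals: mean daily
    energy 2001 kcal, mean UPF energy share 39.1%, mean age about 49 years,
    49.4% female, delete-a-group jackknife replicate weights with R = 30.
    Index-UPF slopes default to zero (no built-in association).
    """

    n_participants: int = Field(default=2000, ge=50)
    seed: int = 0
    n_foods: int = Field(default=54, ge=18)
    mean_energy: float = 2001.0  # kcal/day
    sd_energy: float = 600.0
    target_upf_mean: float = 39.1  # percent of daily energy
    noise_sd: float = 4.0  # residual SD of the UPF share, percent points
    slope_pdi: float = 0.0
    slope_hpdi: float = 0.0
    slope_updi: float = 0.0
    zero_inflation: dict[str, float] = Field(
        default_factory=lambda: {g: GROUP_PARAMS[g][0] for g in ANALYSIS_GROUPS}
    )
    n_replicates: int = Field(default=30, ge=2)
    interaction: InteractionSpec | None = None
    demographic_gradients: bool = False
    weighted_quintiles: bool = True
    recipe_fraction: float = 0.15

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        bad = {g: p for g, p in self.zero_inflation.items() if not 0 <= p <= 1}
        if bad:
            raise ValueError(f"zero-inflation probabilities outside [0,1]: {bad}")
        unknown = set(self.zero_inflation) - set(ANALYSIS_GROUPS)
        if unknown:
            raise ValueError(f"zero-inflation for unknown groups: {sorted(unknown)}")
        return self


@dataclass
class SimulatedDataset:
    """A complete generated dataset plus its ground truth."""

    bundle: ReferenceBundle
    recall: pd.DataFrame
    participants: pd.DataFrame
    design: SurveyDesign
    ground_truth: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bundle.to_dir(outdir)
        self.recall.to_csv(outdir / "recall.csv", index=False)
        self.participants.reset_index().to_csv(outdir / "participants.csv", index=False)
        weights = self.design.replicate_weights.copy()
        weights.insert(0, "person_weight", self.design.person_weight)
        weights.reset_index().to_csv(outdir / "weights.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        return outdir

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (
            self.bundle.composition,
            self.bundle.recipes,
            self.bundle.nova,
            self.bundle.apportionment,
            self.recall,
            self.participants.reset_index(),
            self.design.replicate_weights.reset_index(),
        ):
            h.update(df.round(10).to_csv(index=False).encode())
        return h.hexdigest()


def _source_group_cycle(scheme: GroupScheme) -> list[str]:
    """Source groups ordered so the first 18 cover all analysis groups."""
    first: list[str] = []
    for g in ANALYSIS_GROUPS:
        if g == "dairy":
            first.append(DAIRY_SOURCES[0])
        elif g == "meat":
            first.append(MEAT_SOURCES[0])
        else:
            first.append(g)
    rest = [s for s in scheme.source_groups if s not in first]
    return first + rest


def generate_reference_bundle(config: SimulationConfig) -> ReferenceBundle:
    """Generate a valid reference bundle with every analysis group reachable."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    scheme = GroupScheme.default()
    sources = _source_group_cycle(scheme)
    comp_rows, nova_rows, app_rows = [], [], []
    for i in range(config.n_foods):
        code = 10_000_001 + i
        src = sources[i % len(sources)]
        grp = scheme.collapse_map[src]
        density = GROUP_DENSITY[grp] * rng.uniform(0.8, 1.25)
        novas = GROUP_NOVA[grp]
        nova_g = int(novas[int(rng.integers(len(novas)))])
        comp_rows.append((code, f"{grp} food {i + 1}", round(density, 1), False))
        nova_rows.append((code, nova_g))
        app_rows.append((code, src, round(GROUP_PARAMS[grp][1] / 2.0 * rng.uniform(0.8, 1.25), 4)))
    # one mixed dish mapped to two source groups
    mixed_code = comp_rows[0][0]
    app_rows.append((mixed_code, sources[1], 0.05))
    # zero-serving beverage fillers (always consumed; carry energy only)
    for code, nova_g, desc in (
        (MIN_FILLER_CODE, 1, "plain beverage (filler)"),
        (UPF_FILLER_CODE, 4, "ultra-processed beverage (filler)"),
    ):
        comp_rows.append((code, desc, 180.0, False))
        nova_rows.append((code, nova_g))
        app_rows.append((code, "misc_plant", 0.0))

    composition = pd.DataFrame(
        comp_rows, columns=["food_code", "description", "energy_density_kj_100g", "is_recipe"]
    )
    nova = pd.DataFrame(nova_rows, columns=["food_code", "nova_group"])
    apportionment = pd.DataFrame(app_rows, columns=["food_code", "source_group", "servings_per_100g"])

    # two handmade recipes over non-UPF ingredients
    nova_map = nova.set_index("food_code")["nova_group"]
    non_upf = [c for c, _, _, _ in comp_rows if nova_map[c] != 4 and c < 19_000_000]
    recipe_rows = []
    recipe_defs = {19_800_001: [0.5, 0.3, 0.2], 19_800_002: [0.6, 0.4]}
    picked = iter(non_upf)
    for parent, fracs in recipe_defs.items():
        composition.loc[len(composition)] = [parent, f"handmade dish {parent}", 0.0, True]
        for f in fracs:
            recipe_rows.append((parent, next(picked), f))
    recipes = pd.DataFrame(recipe_rows, columns=["parent_code", "ingredient_code", "weight_fraction"])
    return ReferenceBundle(composition, recipes, nova, apportionment, scheme)


def _draw_covariates(rng: np.random.Generator, n: int, z: np.ndarray, gradients: bool) -> pd.DataFrame:
    shift = z if gradients else np.zeros(n)
    age = np.clip(rng.normal(49.4 - 4.0 * shift, 17.3), 19, 95).round(1)
    sex = np.where(rng.random(n) < 0.494, "female", "male")
    edu_p = np.array([0.26, 0.48, 0.26])
    edu = np.empty(n, dtype=object)
    u = rng.random(n)
    # gradient: higher z -> more likely low education
    lo = edu_p[0] + (0.08 * shift if gradients else 0.0)
    lo = np.clip(lo, 0.05, 0.6)
    hi_cut = 1 - (edu_p[2] - (0.05 * shift if gradients else 0.0))
    edu[u < lo] = "low"
    edu[(u >= lo) & (u < hi_cut)] = "medium"
    edu[u >= hi_cut] = "high"
    country = rng.choice(["australia", "english_speaking", "other"], size=n, p=[0.69, 0.12, 0.19])
    rurality = rng.choice(["major_city", "inner_regional", "other"], size=n, p=[0.71, 0.19, 0.10])
    seifa = rng.choice(["q1", "q2", "q3", "q4", "q5"], size=n, p=[0.2] * 5)
    weight = np.where(
        sex == "male", rng.normal(85.0, 13.0, n), rng.normal(71.0, 14.0, n)
    ).clip(40, 180).round(1)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "education": edu,
            "country_of_birth": country,
            "rurality": rurality,
            "area_disadvantage": seifa,
            "body_weight_kg": weight,
            "pregnant": False,
            "breastfeeding": False,
        }
    )


def _jackknife_design(
    rng: np.random.Generator, index: pd.Index, n_replicates: int
) -> SurveyDesign:
    n = len(index)
    pw = pd.Series(np.exp(rng.normal(0.0, 0.25, n)), index=index, name="person_weight")
    groups = rng.integers(0, n_replicates, n)
    factor = n_replicates / (n_replicates - 1)
    reps = np.repeat(pw.to_numpy()[:, None], n_replicates, axis=1) * factor
    reps[np.arange(n), groups] = 0.0
    rep_df = pd.DataFrame(
        reps, index=index, columns=[f"rw_{r + 1}" for r in range(n_replicates)]
    )
    return SurveyDesign(pw, rep_df)


def generate_population(config: SimulationConfig, bundle: ReferenceBundle) -> SimulatedDataset:
    """Generate recalls, covariates, weights and ground truth for one cohort."""
    ss = np.random.SeedSequence([config.seed, 23])
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_serv, rng_food, rng_cov, rng_wt, rng_upf, rng_energy = streams
    n = config.n_participants
    pid = pd.Index([f"P{i + 1:06d}" for i in range(n)], name="participant_id")

    z = rng_serv.normal(0.0, 1.0, n)

    # --- servings per analysis group ------------------------------------
    servings = np.zeros((n, len(ANALYSIS_GROUPS)))
    for j, g in enumerate(ANALYSIS_GROUPS):
        p0, med, load = GROUP_PARAMS[g]
        p0 = config.zero_inflation.get(g, p0)
        consumed = rng_serv.random(n) >= p0
        amount = np.exp(rng_serv.normal(np.log(med) + load * z, 0.5))
        servings[:, j] = np.where(consumed, amount, 0.0)

    # --- realise items ---------------------------------------------------
    collapsed = bundle.collapsed_apportionment()
    primary = (
        collapsed.sort_values("servings_per_100g", ascending=False)
        .groupby("food_code", as_index=False)
        .first()
    )
    primary = primary[primary["servings_per_100g"] > 0]
    foods_by_group = {
        g: sub[["food_code", "servings_per_100g"]].to_numpy()
        for g, sub in primary.groupby("analysis_group")
    }
    missing_groups = set(ANALYSIS_GROUPS) - set(foods_by_group)
    if missing_groups:
        raise ValueError(f"bundle lacks foods for groups: {sorted(missing_groups)}")

    rows_pid, rows_code, rows_grams = [], [], []
    for j, g in enumerate(ANALYSIS_GROUPS):
        idx = np.nonzero(servings[:, j] > 0)[0]
        if idx.size == 0:
            continue
        foods = foods_by_group[g]
        choice = rng_food.integers(0, len(foods), idx.size)
        codes = foods[choice, 0].astype("int64")
        spg = foods[choice, 1].astype(float)
        grams = servings[idx, j] / spg * 100.0
        rows_pid.append(idx)
        rows_code.append(codes)
        rows_grams.append(grams)

    # recipe dishes for a random subset
    recipe_parents = bundle.composition.loc[bundle.composition["is_recipe"], "food_code"].to_numpy()
    eats_recipe = np.nonzero(rng_food.random(n) < config.recipe_fraction)[0]
    if eats_recipe.size and recipe_parents.size:
        codes = recipe_parents[rng_food.integers(0, len(recipe_parents), eats_recipe.size)]
        rows_pid.append(eats_recipe)
        rows_code.append(codes.astype("int64"))
        rows_grams.append(np.full(eats_recipe.size, 250.0))

    # fillers for everyone
    for code in (MIN_FILLER_CODE, UPF_FILLER_CODE):
        rows_pid.append(np.arange(n))
        rows_code.append(np.full(n, code, dtype="int64"))
        rows_grams.append(np.full(n, 300.0))

    items = pd.DataFrame(
        {
            "participant_id": pid.to_numpy()[np.concatenate(rows_pid)],
            "food_code": np.concatenate(rows_code),
            "grams": np.round(np.concatenate(rows_grams), 4),
        }
    ).sort_values(["participant_id", "food_code"], kind="mergesort").reset_index(drop=True)

    # --- provisional energies -> scoring ---------------------------------
    dens = bundle.composition.set_index("food_code")["energy_density_kj_100g"]
    # recipe parents carry ingredient-weighted density
    rec_dens = (
        bundle.recipes.assign(
            d=lambda r: r["ingredient_code"].map(dens) * r["weight_fraction"]
        )
        .groupby("parent_code")["d"]
        .sum()
    )
    item_density = items["food_code"].map(dens)
    item_density = item_density.where(
        ~items["food_code"].isin(rec_dens.index), items["food_code"].map(rec_dens)
    )
    items["energy_kj"] = items["grams"] * item_density / 100.0

    design = _jackknife_design(rng_wt, pid, config.n_replicates)

    disagg = nova_mod.disaggregate(items, bundle.recipes, bundle.composition)
    weights = design.person_weight if config.weighted_quintiles else None
    scores = score_population(disagg, collapsed, bundle.scheme, weights)
    indices = scores.indices.reindex(pid)

    covariates = _draw_covariates(rng_cov, n, z, config.demographic_gradients)
    covariates.index = pid

    # --- UPF share from the realised indices ------------------------------
    w = design.person_weight.to_numpy()
    upf = np.full(n, config.target_upf_mean)
    slopes = {"pdi": config.slope_pdi, "hpdi": config.slope_hpdi, "updi": config.slope_updi}
    centred = {}
    for k, s in slopes.items():
        c = indices[k].to_numpy(dtype=float) - np.average(indices[k], weights=w)
        centred[k] = c
        upf = upf + s * c
    if config.interaction is not None and config.interaction.size != 0:
        ind = (covariates[config.interaction.moderator] == config.interaction.level).to_numpy()
        upf = upf + config.interaction.size * ind * centred[config.interaction.index]
    upf = np.clip(upf + rng_upf.normal(0.0, config.noise_sd, n), 0.5, 99.5)

    # --- energy allocation -------------------------------------------------
    energy_kcal = np.clip(rng_energy.normal(config.mean_energy, config.sd_energy, n), 600, None)
    energy_kj = energy_kcal * KJ_PER_KCAL

    nova_map = bundle.nova.set_index("food_code")["nova_group"]
    item_nova = items["food_code"].map(nova_map)  # recipes NaN -> non-UPF pool
    is_upf = (item_nova == 4).to_numpy()
    pid_codes, pid_pos = np.unique(items["participant_id"].to_numpy(), return_inverse=True)
    energy_s = pd.Series(energy_kj, index=pid)
    upf_s = pd.Series(upf, index=pid)
    target_tot = energy_s.loc[pid_codes].to_numpy()
    target_upf = (upf_s.loc[pid_codes] / 100.0).to_numpy() * target_tot

    raw = items["energy_kj"].to_numpy()
    raw_upf = np.bincount(pid_pos, weights=np.where(is_upf, raw, 0.0), minlength=len(pid_codes))
    raw_non = np.bincount(pid_pos, weights=np.where(is_upf, 0.0, raw), minlength=len(pid_codes))
    scale_upf = target_upf / raw_upf
    scale_non = (target_tot - target_upf) / raw_non
    items["energy_kj"] = np.round(
        raw * np.where(is_upf, scale_upf[pid_pos], scale_non[pid_pos]), 6
    )

    participants = covariates
    participants["energy_kcal"] = np.round(energy_kcal, 2)

    ground_truth = {
        "generator_version": GENERATOR_VERSION,
        "seed": config.seed,
        "n_participants": n,
        "slopes": slopes,
        "interaction": config.interaction.model_dump() if config.interaction else None,
        "target_upf_mean": config.target_upf_mean,
        "noise_sd": config.noise_sd,
        "latent_axis": [round(float(v), 6) for v in z],
        "true_upf_share": [round(float(v), 6) for v in upf],
    }
    return SimulatedDataset(bundle, items, participants, design, ground_truth)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate the reference bundle and a population in one call."""
    bundle = generate_reference_bundle(config)
    return generate_population(config, bundle)


def load_dataset(path: str | Path) -> SimulatedDataset:
    """Load a dataset directory written by :meth:`SimulatedDataset.write`."""
    from .reference import load_reference_tables

    path = Path(path)
    bundle = load_reference_tables(path)
    recall = pd.read_csv(path / "recall.csv")
    participants = pd.read_csv(path / "participants.csv").set_index("participant_id")
    wdf = pd.read_csv(path / "weights.csv").set_index("participant_id")
    design = SurveyDesign(wdf["person_weight"], wdf.drop(columns=["person_weight"]))
    gt_path = path / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    return SimulatedDataset(bundle, recall, participants, design, ground_truth)
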