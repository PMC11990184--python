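"""Plant-based diet index scoring (PDI, hPDI, uPDI).

Daily servings per participant are accumulated over the 18 analysis food
groups, the population is divided into quintiles of each group's serving
distribution (survey-weighted by default), each quintile receives a 1-5
component score, and the 18 component scores are summed into the overall
(PDI), healthful (hPDI) and unhealthful (uPDI) plant-based diet indices:

* PDI  — forward score for every plant group, reverse for animal groups;
* hPDI — forward for healthy plant groups, reverse for unhealthy plant and
  animal groups;
* uPDI — forward for unhealthy plant groups, reverse for healthy plant and
  animal groups,

where the forward score is the quintile (1-5) and the reverse score is
``6 - quintile``.  Each index therefore ranges from 18 to 90.

Quantile and tie conventions
----------------------------
Cutpoints are the weighted 20/40/60/80th percentiles defined as the
left-continuous inverse of the weighted empirical distribution function.
Quintile membership uses half-open intervals ``(-inf, c1], (c1, c2], ...``;
a value tied with a boundary falls in the lower quintile.  Under heavy
zero-inflation (e.g., legumes) several cutpoints collapse to 0 and all
non-consumers share quintile 1 — the lowest applicable quintile — so
non-consumers of a healthy group score 1 under forward scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reference import GroupScheme

log = logging.getLogger(__name__)

INDEX_TYPES = ("pdi", "hpdi", "updi")

#: index -> health classes that are scored forward (score = quintile);
#: everything else is reverse-scored (score = 6 - quintile).
FORWARD_CLASSES = {
    "pdi": ("healthy_plant", "unhealthy_plant"),
    "hpdi": ("healthy_plant",),
    "updi": ("unhealthy_plant",),
}


def servings_profile(items: pd.DataFrame, apportionment18: pd.DataFrame) -> pd.DataFrame:
    """Per-participant daily servings for each of the 18 analysis groups.

    ``items`` is a (post-disaggregation) recall table with ``participant_id``,
    ``food_code`` and ``grams``; ``apportionment18`` is a collapsed
    apportionment with ``food_code``, ``analysis_group``,
    ``servings_per_100g``.  servings(group) = sum over items of
    grams/100 x servings_per_100g; groups without consumption are
    zero-filled.
    """
    missing = set(items["food_code"]) - set(apportionment18["food_code"])
    if missing:
        raise KeyError(f"items with food codes absent from the apportionment: {sorted(missing)}")
    groups = sorted(apportionment18["analysis_group"].unique())
    merged = items.merge(apportionment18, on="food_code", how="left")
    merged["servings"] = merged["grams"] / 100.0 * merged["servings_per_100g"]
    wide = (
        merged.pivot_table(
            index="participant_id",
            columns="analysis_group",
            values="servings",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=groups, fill_value=0.0)
        .sort_index()
    )
    wide.columns.name = None
    return wide


def weighted_quantile(values, weights, probs) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF.

    q(p) is the smallest observed value x with F(x) >= p, where
    F(x) = sum of weights at values <= x divided by the total weight.
    Invariant under uniform rescaling of the weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    probs = np.atleast_1d(np.asarray(probs, dtype=float))
    if values.size == 0:
        raise ValueError("cannot take quantiles of an empty sample")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    cw = np.cumsum(weights[order]) / weights.sum()
    idx = np.searchsorted(cw, probs - 1e-12, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    return v[idx]


def quintile_cutpoints(
    profiles: pd.DataFrame, weights: pd.Series | None = None
) -> pd.DataFrame:
    """Weighted 20/40/60/80th percentile cutpoints per analysis group.

    With ``weights=None`` every participant counts equally.  Degenerate
    (all-identical) distributions yield collapsed cutpoints and a logged
    warning; quintile assignment then places all tied values in the lowest
    applicable quintile.
    """
    if len(profiles) < 5:
        raise ValueError("at least 5 participants are required for quintiles")
    w = (
        np.ones(len(profiles))
        if weights is None
        else weights.reindex(profiles.index).to_numpy(dtype=float)
    )
    if np.isnan(w).any():
        raise ValueError("weights missing for some participants in the profile table")
    rows = {}
    for g in profiles.columns:
        cuts = weighted_quantile(profiles[g].to_numpy(), w, [0.2, 0.4, 0.6, 0.8])
        if cuts[0] == cuts[-1]:
            log.warning("degenerate quintile cutpoints for group %s (all cutpoints %.4g)", g, cuts[0])
        rows[g] = cuts
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["q20", "q40", "q60", "q80"])
    out.index.name = "analysis_group"
    return out


def assign_quintile(values, cutpoints) -> np.ndarray:
    """Quintile index 1..5 for each value given four ascending cutpoints.

    Intervals are ``(-inf, c1], (c1, c2], (c2, c3], (c3, c4], (c4, inf)``;
    boundary ties fall into the lower quintile, and with collapsed cutpoints
    equal values share the lowest applicable quintile.
    """
    cut = np.asarray(cutpoints, dtype=float)
    if cut.shape != (4,):
        raise ValueError("cutpoints must be the four quintile boundaries")
    if (np.diff(cut) < 0).any():
        raise ValueError("cutpoints must be non-decreasing")
    return np.searchsorted(cut, np.asarray(values, dtype=float), side="left") + 1


def quintiles_from_cutpoints(profiles: pd.DataFrame, cutpoints: pd.DataFrame) -> pd.DataFrame:
    """Quintile (1-5) of every participant in every analysis group."""
    out = {}
    for g in profiles.columns:
        out[g] = assign_quintile(profiles[g].to_numpy(), cutpoints.loc[g].to_numpy())
    return pd.DataFrame(out, index=profiles.index)


def score_component(quintile, health_class: str, index_type: str):
    """1-5 component score for a quintile under one scoring scheme.

    Forward score = quintile; reverse score = 6 - quintile.  An animal group
    is reverse-scored under all three indices, so its lowest consumption
    quintile always scores 5.
    """
    index_type = index_type.lower()
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index type {index_type!r}")
    if health_class not in ("healthy_plant", "unhealthy_plant", "animal"):
        raise ValueError(f"unknown health class {health_class!r}")
    q = np.asarray(quintile)
    if ((q < 1) | (q > 5)).any():
        raise ValueError("quintile must be in 1..5")
    forward = health_class in FORWARD_CLASSES[index_type]
    scored = q if forward else 6 - q
    return scored if scored.ndim else scored.item()


def component_scores(quintiles: pd.DataFrame, scheme: GroupScheme) -> dict[str, pd.DataFrame]:
    """Component score tables, one participants x groups frame per index."""
    out: dict[str, pd.DataFrame] = {}
    for index_type in INDEX_TYPES:
        cols = {
            g: score_component(quintiles[g].to_numpy(), scheme.health_class[g], index_type)
            for g in quintiles.columns
        }
        out[index_type] = pd.DataFrame(cols, index=quintiles.index)
    return out


def compute_indices(scores: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum the 18 component scores per participant into PDI, hPDI, uPDI."""
    out = {}
    for index_type in INDEX_TYPES:
        df = scores[index_type]
        if df.shape[1] != 18:
            raise ValueError(
                f"{index_type} needs 18 component scores per participant, got {df.shape[1]}"
            )
        if df.isna().any().any():
            raise ValueError(f"missing component scores for {index_type}")
        out[index_type] = df.sum(axis=1).astype("int64")
    result = pd.DataFrame(out)
    bad = result[(result < 18).any(axis=1) | (result > 90).any(axis=1)]
    if len(bad):
        raise ValueError("index scores outside the 18..90 range — invalid component scores")
    return result


@dataclass
class ScoreSet:
    """Scored population: servings, cutpoints, quintiles, components, indices."""

    profiles: pd.DataFrame
    cutpoints: pd.DataFrame
    quintiles: pd.DataFrame
    components: dict[str, pd.DataFrame]
    indices: pd.DataFrame
    weighted: bool

    def to_table(self) -> pd.DataFrame:
        """Flat participant-level table: 18x3 component scores + 3 indices."""
        parts = []
        for index_type in INDEX_TYPES:
            df = self.components[index_type].copy()
            df.columns = [f"{index_type}_{g}" for g in df.columns]
            parts.append(df)
        parts.append(self.indices)
        return pd.concat(parts, axis=1).reset_index()

    def cutpoints_to_yaml(self, path: str | Path) -> None:
        payload = {
            "weighted": bool(self.weighted),
            "cutpoints": {
                g: [float(x) for x in row] for g, row in self.cutpoints.iterrows()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def score_population(
    items: pd.DataFrame,
    apportionment18: pd.DataFrame,
    scheme: GroupScheme,
    weights: pd.Series | None = None,
) -> ScoreSet:
    """Full scoring chain from (post-disaggregation) items to index scores."""
    profiles = servings_profile(items, apportionment18)
    cuts = quintile_cutpoints(profiles, weights)
    quintiles = quintiles_from_cutpoints(profiles, cuts)
    comps = component_scores(quintiles, scheme)
    indices = compute_indices(comps)
    return ScoreSet(profiles, cuts, quintiles, comps, indices, weighted=weights is not None)
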