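"""Energy-misreporting covariate: energy intake to basal metabolic rate ratio.

Basal metabolic rate (BMR) is predicted from body weight with Schofield-type
age- and sex-specific linear equations (MJ/day); the EI:BMR ratio is the
participant's reported daily energy intake divided by that prediction.
Misreporters are never excluded — the ratio enters the regression models as
a continuous adjustment covariate.

The coefficient table is configurable (YAML) so an alternative equation
family (e.g., Henry) can be swapped in without code changes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

KJ_PER_MJ = 1000.0

#: Default Schofield coefficients: (sex, age_lo, age_hi) -> (slope MJ/kg/d, intercept MJ/d).
#: Adult bands; ages 19-30 use the younger-adult band.
SCHOFIELD_COEFFICIENTS: dict[tuple[str, int, int], tuple[float, float]] = {
    ("male", 19, 30): (0.063, 2.896),
    ("male", 31, 60): (0.048, 3.653),
    ("male", 61, 200): (0.049, 2.459),
    ("female", 19, 30): (0.062, 2.036),
    ("female", 31, 60): (0.034, 3.538),
    ("female", 61, 200): (0.038, 2.755),
}


def load_bmr_coefficients(path: str | Path) -> dict[tuple[str, int, int], tuple[float, float]]:
    """Load a BMR coefficient table from YAML.

    Expected layout::

        - {sex: male, age_lo: 19, age_hi: 30, slope: 0.063, intercept: 2.896}
        - ...
    """
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    return {
        (r["sex"], int(r["age_lo"]), int(r["age_hi"])): (float(r["slope"]), float(r["intercept"]))
        for r in rows
    }


def estimate_bmr(
    sex,
    age,
    body_weight_kg,
    coefficients: dict[tuple[str, int, int], tuple[float, float]] | None = None,
):
    """Predicted basal metabolic rate in MJ/day.

    Vectorised over aligned array-likes of sex ('male'/'female'), age in
    years and body weight in kg.  Ages or sexes outside the coefficient
    table raise ``ValueError``.
    """
    coefficients = coefficients or SCHOFIELD_COEFFICIENTS
    sex = np.asarray(sex, dtype=object)
    age = np.asarray(age, dtype=float)
    w = np.asarray(body_weight_kg, dtype=float)
    if (w[~np.isnan(w)] <= 0).any():
        raise ValueError("body weight must be positive")
    bmr = np.full(age.shape, np.nan, dtype=float)
    matched = np.zeros(age.shape, dtype=bool)
    age_band = np.floor(age)  # bands are inclusive integer ranges
    for (s, lo, hi), (slope, intercept) in coefficients.items():
        mask = (sex == s) & (age_band >= lo) & (age_band <= hi)
        bmr[mask] = slope * w[mask] + intercept
        matched |= mask
    if not matched.all():
        bad = sorted({(str(s), float(a)) for s, a in zip(sex[~matched], age[~matched])})
        raise ValueError(f"no BMR coefficients for sex/age combination(s): {bad[:5]}")
    return bmr if bmr.ndim else float(bmr)


def ei_bmr_ratio(energy_intake_mj, bmr_mj):
    """Energy intake / BMR, both in MJ/day (any common unit cancels)."""
    ei = np.asarray(energy_intake_mj, dtype=float)
    bmr = np.asarray(bmr_mj, dtype=float)
    if (bmr <= 0).any():
        raise ValueError("BMR must be positive")
    ratio = ei / bmr
    return ratio if ratio.ndim else float(ratio)


def compute_misreporting(
    participants: pd.DataFrame,
    energy_kj: pd.Series,
    person_weight: pd.Series | None = None,
    coefficients: dict | None = None,
) -> pd.Series:
    """EI:BMR ratio per participant, indexed like ``energy_kj``.

    ``participants`` must carry ``sex``, ``age`` and ``body_weight_kg``
    indexed by participant.  Participants missing body weight receive the
    survey-weighted population mean ratio (with a logged count) so the
    covariate is non-missing in the adjusted models.
    """
    part = participants.loc[energy_kj.index]
    missing = part["body_weight_kg"].isna()
    ratio = pd.Series(np.nan, index=energy_kj.index, name="ei_bmr_ratio")
    if (~missing).any():
        sub = part.loc[~missing]
        bmr = estimate_bmr(sub["sex"], sub["age"], sub["body_weight_kg"], coefficients)
        ratio.loc[~missing] = ei_bmr_ratio(energy_kj.loc[~missing] / KJ_PER_MJ, bmr)
    if missing.any():
        if (~missing).sum() == 0:
            raise ValueError("no participant has body weight; cannot impute EI:BMR")
        w = (
            np.ones(int((~missing).sum()))
            if person_weight is None
            else person_weight.reindex(ratio.index[~missing]).to_numpy(dtype=float)
        )
        mean_ratio = float(np.average(ratio.loc[~missing], weights=w))
        ratio.loc[missing] = mean_ratio
        log.info(
            "imputed EI:BMR for %d participant(s) missing body weight with weighted mean %.3f",
            int(missing.sum()),
            mean_ratio,
        )
    return ratio
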