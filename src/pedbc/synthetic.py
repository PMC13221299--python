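"""Synthetic pediatric cohort and wearable-trace generator.

Emulates a three-wave school cohort of children aged 7-14 measured by
bioelectrical impedance analysis (BIA): per-wave anthropometry and body
composition, a non-fasting lipid panel, abdominal circumference, per-year
activity/sleep summaries, 11-day wrist-device traces, a planted 5-cluster
latent structure in body-composition z-space, and injected missingness at
configurable rates.

Generating conventions (the BIA device's internal identities are not public,
so the generator declares its own and the rest of the package treats them as
ground truth):

* ``fat_mass + lean_mass == weight`` exactly,
* ``muscle_mass + bone_mass == lean_mass`` exactly,
* ``water_mass = 0.73 * lean_mass * (1 + small noise)``, clipped below lean,
* ``bfp = 100 * fat_mass / weight``,
* ages advance exactly 1.0 year per wave.

Each subject-wave draws a z-vector over (FMI, MMI, BNI) — fat, muscle and
bone mass indices — either from a latent-factor model or, when planted
cluster centroids are supplied, as ``centroid + within-cluster noise``.
Component masses are then reconstructed through per-sex cubic reference
curves so that standardizing the cohort against those same curves recovers
the planted z-structure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STUDY_DESIGN",
    "CohortParams",
    "default_centroids",
    "generate_cohort",
    "generate_device_days",
    "inject_missing",
    "generating_mean_sd",
    "generating_zscores",
    "missing_percentages",
]

#: Printed study-design counts used as generator defaults: per-fiscal-year
#: body-composition dataset counts and per-indicator missing-value counts
#: out of the 917 collected subject-wave observations.
STUDY_DESIGN = {
    "wave_counts": (336, 318, 263),
    "n_children": 353,
    "missing_counts": {
        "ac": 3,
        "lipids": 110,
        "steps_per_day": 86,
        "activity_min": 134,
        "sleep_min": 183,
    },
}

#: Columns nulled together by the block key ``"lipids"`` (one blood draw).
LIPID_COLUMNS = ("tc", "tg", "hdlc")

#: Fraction of lean mass that is water in the generating convention.
WATER_FRACTION = 0.73


def _total_observations(design: Mapping = STUDY_DESIGN) -> int:
    return int(sum(design["wave_counts"]))


def missing_percentages(design: Mapping = STUDY_DESIGN) -> dict[str, float]:
    """Missing-value percentages implied by the design counts.

    Returns ``100 * count / total`` rounded to two decimals, e.g. 110 missing
    lipid panels out of 917 observations -> 12.00.
    """
    total = _total_observations(design)
    return {
        key: round(100.0 * count / total, 2)
        for key, count in design["missing_counts"].items()
    }


def default_centroids() -> list[tuple[float, ...]]:
    """Default planted centroids in (FMI, MMI, BNI, TWI) z-space.

    Mirrors the five observed subpopulations: all-low, slightly-low,
    slightly-high, all-high, and high-fat/average-muscle; minimum pairwise
    Euclidean separation >= 2.
    """
    return [
        (-1.6, -1.5, -1.4, -1.5),
        (-0.5, -0.4, -0.4, -0.4),
        (0.6, 0.6, 0.6, 0.6),
        (1.7, 1.6, 1.6, 1.6),
        (2.2, -0.1, -0.1, -0.1),
    ]


def _default_curves() -> dict:
    # Cubic mean curves (ascending powers of age in years) and polynomial SD
    # curves per sex, in kg/m^2 (height in cm). Values are plausible for
    # Japanese elementary-school children; they are the generator's toy
    # reference, not population norms.
    return {
        "male": {
            "fmi": {"mean": (2.0, 0.25, 0.0, 0.0), "sd": (0.70, 0.05)},
            "mmi": {"mean": (9.0, 0.55, -0.03, 0.0008), "sd": (0.50, 0.04)},
            "bni": {"mean": (0.70, 0.05, 0.0, 0.0), "sd": (0.050, 0.005)},
            "height": {"mean": (86.0, 5.15, 0.0, 0.0), "sd": (6.0,)},
        },
        "female": {
            "fmi": {"mean": (2.4, 0.27, 0.0, 0.0), "sd": (0.75, 0.05)},
            "mmi": {"mean": (8.8, 0.55, -0.03, 0.0008), "sd": (0.50, 0.04)},
            "bni": {"mean": (0.68, 0.05, 0.0, 0.0), "sd": (0.050, 0.005)},
            "height": {"mean": (88.0, 5.00, 0.0, 0.0), "sd": (5.5,)},
        },
    }


@dataclass
class CohortParams:
    """Parameters of the synthetic three-wave cohort.

    Defaults emulate the study conditions: 353 enrolled children, per-wave
    participation probabilities tuned to expected wave sizes 336/318/263,
    ages 7.0-14.0, a planted five-cluster structure with within-cluster SD
    0.3, and missingness at the printed per-indicator rates.
    """

    n_subjects: int = STUDY_DESIGN["n_children"]
    waves: int = 3
    participation: Sequence[float] = (336 / 353, 318 / 353, 263 / 353)
    age_range: tuple[float, float] = (7.0, 14.0)
    curves: dict = field(default_factory=_default_curves)
    #: latent-factor loadings used when no centroids are planted
    fat_lean_loading: float = 0.55
    bone_muscle_loading: float = 0.95
    #: relative noise SD on water mass around 0.73*lean
    water_noise_sd: float = 0.005
    cluster_centroids: Sequence[Sequence[float]] | None = field(
        default_factory=default_centroids
    )
    cluster_weights: Sequence[float] = (0.30, 0.25, 0.20, 0.15, 0.10)
    within_cluster_sd: float = 0.3
    #: per-wave jitter of a child's z-vector around its per-child base value
    wave_jitter_sd: float = 0.15
    missing_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            key: count / _total_observations()
            for key, count in STUDY_DESIGN["missing_counts"].items()
        }
    )
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.age_range
        if not (lo < hi) or lo < 0:
            raise ValueError(f"invalid age_range {self.age_range!r}")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for p in self.participation[: self.waves]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"participation probability {p} outside [0, 1]")
        if self.within_cluster_sd < 0 or self.wave_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for sex_curves in self.curves.values():
            for spec in sex_curves.values():
                if np.polynomial.polynomial.polyval(
                    np.mean(self.age_range), np.asarray(spec["sd"], float)
                ) < 0:
                    raise ValueError("SD curve must be non-negative over the age range")
        if self.cluster_centroids is not None:
            w = np.asarray(self.cluster_weights, float)
            if len(w) != len(self.cluster_centroids):
                raise ValueError("one mixing weight per centroid required")
            if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
                raise ValueError("mixing weights must be non-negative and sum to 1")
        for key, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {key!r} outside [0, 1]: {rate}")


def _polyval(coeffs: Sequence[float], age) -> np.ndarray:
    return np.polynomial.polynomial.polyval(age, np.asarray(coeffs, float))


def generating_mean_sd(params: CohortParams, sex: str, index: str, age):
    """Mean and SD of a body-composition index under the generating curves.

    Base indices (``fmi``, ``mmi``, ``bni``, ``height``) come straight from
    the per-sex curves. Derived indices use the generating identities:
    ``lmi = mmi + bni`` (SDs add, since muscle and bone z's share the
    planted/latent structure), ``twi = 0.73 * lmi``, and ``bmi = fmi + lmi``
    with SDs combined in quadrature (fat and lean vary separately).
    """
    curves = params.curves[sex]
    if index in curves:
        spec = curves[index]
        return _polyval(spec["mean"], age), _polyval(spec["sd"], age)
    m_mean, m_sd = generating_mean_sd(params, sex, "mmi", age)
    b_mean, b_sd = generating_mean_sd(params, sex, "bni", age)
    if index == "lmi":
        return m_mean + b_mean, m_sd + b_sd
    if index == "twi":
        return WATER_FRACTION * (m_mean + b_mean), WATER_FRACTION * (m_sd + b_sd)
    if index == "bmi":
        f_mean, f_sd = generating_mean_sd(params, sex, "fmi", age)
        return f_mean + m_mean + b_mean, np.hypot(f_sd, m_sd + b_sd)
    raise KeyError(f"unknown index {index!r}")


#: cohort mass column backing each index
_INDEX_MASS = {
    "bmi": "weight",
    "fmi": "fat_mass",
    "lmi": "lean_mass",
    "mmi": "muscle_mass",
    "bni": "bone_mass",
    "twi": "water_mass",
}


def generating_zscores(
    params: CohortParams,
    cohort: pd.DataFrame,
    indices=("bmi", "fmi", "lmi", "mmi", "bni", "twi"),
) -> pd.DataFrame:
    """Ground-truth z-scores of a generated cohort under the generating curves.

    Standardizes each body-composition index against the exact reference the
    cohort was drawn from (no curve estimation), so planted cluster structure
    appears at its nominal scale. Column names are ``z_<index>``.
    """
    out = pd.DataFrame(index=cohort.index)
    for c in ("subject_id", "wave"):
        if c in cohort.columns:
            out[c] = cohort[c]
    for index in indices:
        value = (
            cohort[_INDEX_MASS[index]].to_numpy(float)
            / (cohort["height"].to_numpy(float) / 100.0) ** 2
        )
        z = np.empty(len(cohort))
        for sex in ("male", "female"):
            sel = (cohort["sex"] == sex).to_numpy()
            if not sel.any():
                continue
            mean, sd = generating_mean_sd(
                params, sex, index, cohort.loc[sel, "age"].to_numpy(float)
            )
            z[sel] = (value[sel] - mean) / sd
        out[f"z_{index}"] = z
    return out


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Splittable per-operation streams off one root seed: adding a generator
    # call with a new stream id does not perturb existing ones.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_cohort(
    params: CohortParams | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Generate a subject-wave cohort table.

    Returns ``(cohort, labels)`` where ``cohort`` has one row per
    subject-wave observation and ``labels`` maps ``subject_id`` to the
    planted cluster index 1..k (``None`` when no centroids are planted).
    Deterministic given ``params.seed``.
    """
    params = params or CohortParams()
    params.validate()
    n = params.n_subjects
    empty = pd.DataFrame(
        columns=[
            "subject_id", "sex", "wave", "age", "height", "weight",
            "fat_mass", "lean_mass", "muscle_mass", "bone_mass", "water_mass",
            "bfp", "ac", "tc", "tg", "hdlc",
            "steps_per_day", "activity_min", "sleep_min",
        ]
    )
    if n == 0:
        labels = pd.Series(dtype=int) if params.cluster_centroids is not None else None
        return empty, labels

    rng = _rng(params.seed, 0)
    lo, hi = params.age_range
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    # baseline ages leave room for the later waves inside [lo, hi]; the top
    # 0.1 year is shaved so final-wave ages stay below the next integer bin
    base_age = np.round(
        rng.uniform(lo, max(hi - (params.waves - 1) - 0.1, lo + 0.1), n), 1
    )

    centroids = params.cluster_centroids
    if centroids is not None:
        centroids = np.asarray(centroids, float)
        labels_arr = rng.choice(
            len(centroids), size=n, p=np.asarray(params.cluster_weights, float)
        ) + 1
        base_z = centroids[labels_arr - 1, :3] + rng.normal(
            0.0, params.within_cluster_sd, (n, 3)
        )
    else:
        labels_arr = None
        z_m = rng.normal(size=n)
        lam_f, lam_b = params.fat_lean_loading, params.bone_muscle_loading
        z_f = lam_f * z_m + np.sqrt(1 - lam_f**2) * rng.normal(size=n)
        z_b = lam_b * z_m + np.sqrt(1 - lam_b**2) * rng.normal(size=n)
        base_z = np.column_stack([z_f, z_m, z_b])

    z_height = rng.normal(size=n)
    subject_ids = np.array([f"S{i:04d}" for i in range(1, n + 1)])
    participates = (
        rng.random((n, params.waves))
        < np.asarray(params.participation[: params.waves], float)
    )

    rows = []
    for wave in range(1, params.waves + 1):
        mask = participates[:, wave - 1]
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        age = np.round(base_age[idx] + (wave - 1), 1)
        zw = base_z[idx] + rng.normal(0.0, params.wave_jitter_sd, (len(idx), 3))
        s = sex[idx]
        height = np.empty(len(idx))
        comp = {}
        for j, name in enumerate(("fmi", "mmi", "bni")):
            comp[name] = np.empty(len(idx))
        for sx in ("male", "female"):
            sel = s == sx
            if not sel.any():
                continue
            h_mean, h_sd = generating_mean_sd(params, sx, "height", age[sel])
            height[sel] = h_mean + h_sd * z_height[idx][sel]
            for j, name in enumerate(("fmi", "mmi", "bni")):
                mean, sd = generating_mean_sd(params, sx, name, age[sel])
                comp[name][sel] = np.maximum(mean + sd * zw[sel, j], 0.05)
        h2 = (height / 100.0) ** 2
        fat = comp["fmi"] * h2
        muscle = comp["mmi"] * h2
        bone = comp["bni"] * h2
        lean = muscle + bone
        water = WATER_FRACTION * lean * (
            1.0 + rng.normal(0.0, params.water_noise_sd, len(idx))
        )
        water = np.minimum(water, lean * (1 - 1e-6))
        weight = fat + lean
        bfp = 100.0 * fat / weight
        z_fat = zw[:, 0]
        ac = 36.0 + 2.0 * age + 3.5 * z_fat + rng.normal(0, 1.5, len(idx))
        tc = 170.0 + 6.0 * z_fat + rng.normal(0, 22.0, len(idx))
        hdlc = np.maximum(60.0 - 4.0 * z_fat + rng.normal(0, 10.0, len(idx)), 20.0)
        tg = np.exp(4.1 + 0.18 * z_fat + rng.normal(0, 0.35, len(idx)))
        steps = np.maximum(
            11500.0 - 500.0 * z_fat + rng.normal(0, 2500.0, len(idx)), 0.0
        )
        activity = np.maximum(
            300.0 - 15.0 * z_fat + rng.normal(0, 45.0, len(idx)), 0.0
        )
        sleep = 485.0 - 9.0 * z_fat + rng.normal(0, 28.0, len(idx))
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[idx],
                    "sex": s,
                    "wave": wave,
                    "age": age,
                    "height": height,
                    "weight": weight,
                    "fat_mass": fat,
                    "lean_mass": lean,
                    "muscle_mass": muscle,
                    "bone_mass": bone,
                    "water_mass": water,
                    "bfp": bfp,
                    "ac": ac,
                    "tc": tc,
                    "tg": tg,
                    "hdlc": hdlc,
                    "steps_per_day": steps,
                    "activity_min": activity,
                    "sleep_min": sleep,
                }
            )
        )
    cohort = pd.concat(rows, ignore_index=True) if rows else empty
    cohort = cohort.sort_values(["wave", "subject_id"], ignore_index=True)
    if labels_arr is not None:
        labels = pd.Series(labels_arr, index=pd.Index(subject_ids, name="subject_id"))
        seen = labels.index.isin(cohort["subject_id"])
        return cohort, labels[seen]
    return cohort, None


def generate_device_days(
    subject_id: str,
    n_days: int = 11,
    seed: int = 0,
    start_date: str = "2021-01-05",
    low_wear_fraction: float = 0.2,
    low_activity_fraction: float = 0.05,
    mvpa_base: float | None = None,
) -> pd.DataFrame:
    """Generate an ``n_days`` daily wrist-device trace for one subject.

    Each day carries the four activity-category minutes, the monitored total
    (their exact sum, at most 1440), steps and sleep minutes. A
    ``low_wear_fraction`` of days is forced under the 0.8 monitored-time
    screening criterion and a ``low_activity_fraction`` under the 0.1
    total-activity criterion. ``mvpa_base`` sets the subject's mean daily
    moderate+vigorous minutes (default drawn ~N(80, 20), which puts roughly
    83% of subjects above the WHO 60-minute guideline).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 <= low_wear_fraction <= 1.0 or not 0.0 <= low_activity_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence(
            seed, spawn_key=(1, zlib.crc32(str(subject_id).encode()))
        )
    )
    if mvpa_base is None:
        mvpa_base = rng.normal(80.0, 20.0)
    steps_base = rng.normal(11500.0, 2500.0)
    dates = pd.date_range(start_date, periods=n_days, freq="D")

    kind = rng.random(n_days)
    low_wear = kind < low_wear_fraction
    low_act = (~low_wear) & (kind < low_wear_fraction + low_activity_fraction)

    mvpa = np.maximum(mvpa_base + rng.normal(0, 15.0, n_days), 0.0)
    moderate = mvpa * rng.uniform(0.6, 0.75, n_days)
    vigorous = mvpa - moderate
    light = np.maximum(rng.normal(200.0, 40.0, n_days), 30.0)
    monitored = np.minimum(1440.0 - np.abs(rng.normal(0.0, 40.0, n_days)), 1440.0)
    # force designed violations
    monitored[low_wear] = rng.uniform(500.0, 1150.0, low_wear.sum())
    scale = np.where(low_wear, monitored / 1400.0, 1.0)
    light, moderate, vigorous = light * scale, moderate * scale, vigorous * scale
    if low_act.any():
        act_scale = rng.uniform(60.0, 130.0, low_act.sum()) / np.maximum(
            (light + moderate + vigorous)[low_act], 1.0
        )
        for arr in (light, moderate, vigorous):
            arr[low_act] *= act_scale
    sedentary = np.maximum(monitored - light - moderate - vigorous, 0.0)
    monitored = sedentary + light + moderate + vigorous
    steps = np.maximum(steps_base + rng.normal(0, 2500.0, n_days), 0.0)
    sleep = np.maximum(rng.normal(480.0, 45.0, n_days), 0.0)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "date": dates,
            "sedentary_min": np.round(sedentary, 1),
            "light_min": np.round(light, 1),
            "moderate_min": np.round(moderate, 1),
            "vigorous_min": np.round(vigorous, 1),
            "monitored_min": np.round(sedentary + light + moderate + vigorous, 1),
            "steps": np.round(steps).astype(int),
            "sleep_min": np.round(sleep, 1),
        }
    )


def inject_missing(
    records: pd.DataFrame,
    missing_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Null nullable fields independently at the given per-field rates.

    The key ``"lipids"`` nulls ``tc``, ``tg`` and ``hdlc`` jointly (one
    missed blood draw removes the whole panel). Non-nullable fields are never
    touched. Deterministic given ``seed``; a copy is returned.
    """
    if missing_rates is None:
        missing_rates = CohortParams().missing_rates
    for key, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {key!r} outside [0, 1]: {rate}")
    out = records.copy()
    rng = _rng(seed, 2)
    for key in sorted(missing_rates):
        rate = missing_rates[key]
        cols = list(LIPID_COLUMNS) if key == "lipids" else [key]
        missing_cols = [c for c in cols if c not in out.columns]
        if missing_cols:
            raise KeyError(f"no such column(s) {missing_cols} for rate key {key!r}")
        mask = rng.random(len(out)) < rate
        out.loc[mask, cols] = np.nan
    return out
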