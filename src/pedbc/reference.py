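"""Age/sex reference-value models for body-composition indices (BCIs).

A BCI is a component mass divided by height squared (kg/m^2): FMI (fat),
LMI (lean), MMI (muscle), BNI (bone), TWI (total body water); BMI is treated
through the identical machinery. The reference model is built in three
steps:

1. bin observations by sex and integer age (floor) and take the mean and
   sample SD of each index per bin;
2. fit a third-order polynomial in integer age to each of the three score
   series — mean, mean + 1 SD, mean - 1 SD — by least squares;
3. evaluate the fitted curves at age rounded to 0.1 years, with
   ``sd(age) = (upper(age) - lower(age)) / 2``, and standardize:
   ``z = (value - mean(age)) / sd(age)``.

The same three-curve machinery is applied to height, weight and BMI, for
which the original workflow used an external spreadsheet tool.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BCI_INDICES",
    "BinStats",
    "compute_bci",
    "add_bci_columns",
    "bin_stats",
    "fit_reference",
    "BCIReferenceModel",
    "export_reference_table",
]

#: Default indices modelled, in reporting order.
BCI_INDICES = ("bmi", "fmi", "lmi", "mmi", "bni", "twi")

#: mass column backing each derived index
_MASS_FOR_INDEX = {
    "fmi": "fat_mass",
    "lmi": "lean_mass",
    "mmi": "muscle_mass",
    "bni": "bone_mass",
    "twi": "water_mass",
    "bmi": "weight",
}


@dataclass(frozen=True)
class BinStats:
    """Per (sex, integer age, index) summary: count, mean and sample SD."""

    sex: str
    age: int
    index: str
    n: int
    mean: float
    sd: float


def compute_bci(mass: float, height: float):
    """Index value ``mass / (height/100)**2`` in kg/m^2 (height in cm)."""
    mass = np.asarray(mass, float)
    height = np.asarray(height, float)
    if np.any(height <= 0):
        raise ValueError("height must be positive (cm)")
    if np.any(mass < 0):
        raise ValueError("mass must be non-negative (kg)")
    out = mass / (height / 100.0) ** 2
    return out.item() if out.ndim == 0 else out


def add_bci_columns(cohort: pd.DataFrame, indices=BCI_INDICES) -> pd.DataFrame:
    """Return a copy of the cohort with one column per requested index."""
    out = cohort.copy()
    for index in indices:
        out[index] = compute_bci(out[_MASS_FOR_INDEX[index]], out["height"])
    return out


def bin_stats(
    records: pd.DataFrame,
    indices=BCI_INDICES,
    sex_col: str = "sex",
    age_col: str = "age",
) -> list[BinStats]:
    """Mean/sample-SD of each index per (sex, floored integer age) bin.

    Bins with fewer than two observations cannot contribute an SD and are
    dropped with a warning.
    """
    out: list[BinStats] = []
    grouped = records.groupby([sex_col, np.floor(records[age_col]).astype(int)])
    for (sex, age), grp in grouped:
        if len(grp) < 2:
            warnings.warn(
                f"bin (sex={sex}, age={age}) has n={len(grp)} < 2; excluded",
                stacklevel=2,
            )
            continue
        for index in indices:
            vals = grp[index].to_numpy(float)
            out.append(
                BinStats(
                    sex=sex,
                    age=int(age),
                    index=index,
                    n=len(vals),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)),
                )
            )
    return out


def _polyfit(ages: np.ndarray, values: np.ndarray, degree: int):
    coeffs = np.polynomial.polynomial.polyfit(ages, values, degree)
    resid = values - np.polynomial.polynomial.polyval(ages, coeffs)
    return coeffs, float(resid @ resid)


def fit_reference(
    bins: list[BinStats], degree: int = 3
) -> dict[tuple[str, str], dict]:
    """Fit mean / mean+1SD / mean-1SD polynomial curves per (sex, index).

    Returns ``{(sex, index): {"c_mean", "c_upper", "c_lower",
    "residual_ss", "age_domain"}}`` with coefficient vectors in ascending
    powers of age. Requires at least ``degree + 1`` distinct integer ages
    per (sex, index).
    """
    table: dict[tuple[str, str], list[BinStats]] = {}
    for b in bins:
        table.setdefault((b.sex, b.index), []).append(b)
    curves = {}
    for key, rows in table.items():
        rows = sorted(rows, key=lambda b: b.age)
        ages = np.array([b.age for b in rows], float)
        if len(np.unique(ages)) < degree + 1:
            raise ValueError(
                f"cannot fit degree-{degree} curve for sex={key[0]}, "
                f"index={key[1]}: only {len(np.unique(ages))} distinct ages"
            )
        mean = np.array([b.mean for b in rows])
        sd = np.array([b.sd for b in rows])
        c_mean, ss_mean = _polyfit(ages, mean, degree)
        c_upper, ss_upper = _polyfit(ages, mean + sd, degree)
        c_lower, ss_lower = _polyfit(ages, mean - sd, degree)
        curves[key] = {
            "c_mean": c_mean,
            "c_upper": c_upper,
            "c_lower": c_lower,
            "residual_ss": {"mean": ss_mean, "upper": ss_upper, "lower": ss_lower},
            "age_domain": (float(ages.min()), float(ages.max() + 0.9)),
        }
    return curves


class BCIReferenceModel(BaseEstimator, TransformerMixin):
    """Sex- and age-specific polynomial reference model with z-scoring.

    Parameters
    ----------
    indices : sequence of str
        Index columns to model (default the six BCIs; height/weight can be
        added since any numeric column works through the same machinery).
    degree : int
        Polynomial degree in integer age (3 = the standard cubic).
    sd_floor : float
        Lower bound for the recovered SD, guarding degenerate fits.
    clamp_age : bool
        If True, ages outside the fitted domain are clamped to its edge
        instead of raising (cubic tails are untrustworthy, so the default
        refuses extrapolation).

    Attributes
    ----------
    curves_ : dict
        ``(sex, index) ->`` coefficient triples and diagnostics.
    bins_ : list of BinStats
        The per-bin summaries the curves were fitted to.
    """

    def __init__(
        self,
        indices=BCI_INDICES,
        degree: int = 3,
        sd_floor: float = 1e-6,
        clamp_age: bool = False,
        sex_col: str = "sex",
        age_col: str = "age",
    ):
        self.indices = indices
        self.degree = degree
        self.sd_floor = sd_floor
        self.clamp_age = clamp_age
        self.sex_col = sex_col
        self.age_col = age_col

    def fit(self, X: pd.DataFrame, y=None):
        missing = [c for c in self.indices if c not in X.columns]
        if missing:
            raise ValueError(f"missing index columns {missing}; run add_bci_columns first")
        self.bins_ = bin_stats(
            X, indices=self.indices, sex_col=self.sex_col, age_col=self.age_col
        )
        self.curves_ = fit_reference(self.bins_, degree=self.degree)
        return self

    def _curve(self, sex: str, index: str) -> dict:
        try:
            return self.curves_[(sex, index)]
        except KeyError:
            raise KeyError(f"no fitted curve for sex={sex!r}, index={index!r}") from None

    def evaluate(self, sex: str, index: str, age):
        """Reference ``(mean, sd)`` at age rounded to 0.1 years.

        ``sd = (upper - lower) / 2``, floored at ``sd_floor``.
        """
        check_is_fitted(self, "curves_")
        curve = self._curve(sex, index)
        age = np.round(np.asarray(age, float) * 10.0) / 10.0
        lo, hi = curve["age_domain"]
        if self.clamp_age:
            age = np.clip(age, lo, hi)
        elif np.any(age < lo) or np.any(age > hi):
            raise ValueError(
                f"age {age} outside fitted domain [{lo}, {hi}] for "
                f"sex={sex!r}, index={index!r}"
            )
        pv = np.polynomial.polynomial.polyval
        mean = pv(age, curve["c_mean"])
        sd = (pv(age, curve["c_upper"]) - pv(age, curve["c_lower"])) / 2.0
        sd = np.maximum(sd, self.sd_floor)
        return mean, sd

    def zscore(self, value, sex: str, index: str, age):
        """Standardize ``value`` against the (sex, index, age) reference."""
        mean, sd = self.evaluate(sex, index, age)
        if np.any(sd <= self.sd_floor) and np.any(
            np.asarray(value, float) != np.asarray(mean)
        ):
            warnings.warn(
                f"SD at floor for sex={sex!r}, index={index!r}; z-scores unstable",
                stacklevel=2,
            )
        return (np.asarray(value, float) - mean) / sd

    def sd_asymmetry(self, sex: str, index: str, age):
        """Diagnostic ``(upper - mean) - (mean - lower)`` at the given age."""
        check_is_fitted(self, "curves_")
        curve = self._curve(sex, index)
        age = np.round(np.asarray(age, float) * 10.0) / 10.0
        pv = np.polynomial.polynomial.polyval
        return (
            pv(age, curve["c_upper"]) + pv(age, curve["c_lower"])
            - 2.0 * pv(age, curve["c_mean"])
        )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Z-score every modelled index; returns columns ``z_<index>``.

        The output keeps ``X``'s row index and carries along subject/wave
        identifier columns when present.
        """
        check_is_fitted(self, "curves_")
        carried = [c for c in ("subject_id", "wave") if c in X.columns]
        out = X[carried].copy() if carried else pd.DataFrame(index=X.index)
        for index in self.indices:
            z = np.empty(len(X))
            for sex in X[self.sex_col].unique():
                sel = (X[self.sex_col] == sex).to_numpy()
                z[sel] = self.zscore(
                    X.loc[sel, index].to_numpy(float),
                    sex,
                    index,
                    X.loc[sel, self.age_col].to_numpy(float),
                )
            out[f"z_{index}"] = z
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "curves_")
        return {
            "format": "pedbc-reference",
            "version": 1,
            "degree": self.degree,
            "sd_floor": self.sd_floor,
            "coefficient_order": "ascending",
            "curves": [
                {
                    "sex": sex,
                    "index": index,
                    "c_mean": list(map(float, c["c_mean"])),
                    "c_upper": list(map(float, c["c_upper"])),
                    "c_lower": list(map(float, c["c_lower"])),
                    "residual_ss": c["residual_ss"],
                    "age_domain": list(c["age_domain"]),
                }
                for (sex, index), c in self.curves_.items()
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "BCIReferenceModel":
        if payload.get("format") != "pedbc-reference":
            raise ValueError("not a pedbc reference-model payload")
        curves = {}
        for entry in payload["curves"]:
            curves[(entry["sex"], entry["index"])] = {
                "c_mean": np.asarray(entry["c_mean"]),
                "c_upper": np.asarray(entry["c_upper"]),
                "c_lower": np.asarray(entry["c_lower"]),
                "residual_ss": entry["residual_ss"],
                "age_domain": tuple(entry["age_domain"]),
            }
        model = cls(
            indices=tuple(sorted({k[1] for k in curves}, key=lambda i: (
                BCI_INDICES.index(i) if i in BCI_INDICES else len(BCI_INDICES)
            ))),
            degree=payload["degree"],
            sd_floor=payload["sd_floor"],
        )
        model.curves_ = curves
        model.bins_ = []
        return model

    @classmethod
    def from_json(cls, path) -> "BCIReferenceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def export_reference_table(model: BCIReferenceModel, step: float = 0.1) -> pd.DataFrame:
    """Tabulate reference mean/SD at every 0.1-year age per sex and index.

    The table round-trips: reading it back and interpolating at its own grid
    reproduces ``model.evaluate`` exactly at those ages.
    """
    check_is_fitted(model, "curves_")
    rows = []
    for (sex, index), curve in model.curves_.items():
        lo, hi = curve["age_domain"]
        ages = np.arange(round(lo * 10), round(hi * 10) + 1) / 10.0
        mean, sd = model.evaluate(sex, index, ages)
        rows.append(
            pd.DataFrame(
                {"sex": sex, "index": index, "age": ages, "mean": mean, "sd": sd}
            )
        )
    return pd.concat(rows, ignore_index=True)
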