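"""Normative RNFL-thickness database and probability score scales.

A :class:`NormativeDB` is built from a healthy cohort by fitting, at every
one of the 256 A-scan positions, an ordinary least-squares regression of
thickness on age and spherical equivalent.  Test measurements are corrected
to the normative reference covariates (cohort means) and located within the
empirical residual distribution, yielding per-position percentiles.

Two probability scoring scales translate statistical abnormality into the
integer scores consumed by the fusion transforms: one for SAP
pattern-deviation categories, one for OCT percentile bands (sub-normal
bands score positive and graded; supra-normal thickening scores negative so
that attenuation of visual-field scores remains possible).
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import Cohort, Label, N_ASCANS, OCTTest, PDCategory

__all__ = [
    "ScoreScale",
    "DEFAULT_SCALE",
    "NormativeDB",
    "build_normative_db",
    "correct_ascan",
    "rnflt_percentile",
    "score_pd",
    "score_oct_band",
]


@dataclass(frozen=True)
class ScoreScale:
    """Probability scoring scale for PD categories and OCT percentile bands.

    ``pd_scores`` maps each pattern-deviation category to a non-negative
    integer, 0 for the normal category.  ``oct_low_bands`` lists
    ``(percentile_upper_bound, score)`` pairs in ascending bound order: a
    percentile strictly below the first bound it satisfies takes that score.
    ``oct_high_bands`` lists ``(percentile_lower_bound, score)`` pairs in
    descending bound order for supra-normal thickening; scores there are
    negative (flagging the opposite tail).
    """

    pd_scores: dict[PDCategory, int] = field(
        default_factory=lambda: {
            PDCategory.GE5: 0,
            PDCategory.LT5: 2,
            PDCategory.LT2: 5,
            PDCategory.LT1: 8,
            PDCategory.LT05: 10,
        }
    )
    oct_low_bands: tuple[tuple[float, int], ...] = ((0.5, 10), (1.0, 8), (2.0, 5), (5.0, 2))
    oct_high_bands: tuple[tuple[float, int], ...] = ((95.0, -2),)

    def __post_init__(self) -> None:
        if self.pd_scores[PDCategory.GE5] != 0:
            raise ValueError("pd_scores: the normal category GE5 must score 0")
        if any(s < 0 for s in self.pd_scores.values()):
            raise ValueError("pd_scores: scores must be non-negative")
        if any(s <= 0 for _, s in self.oct_low_bands):
            raise ValueError("oct_low_bands: sub-normal scores must be positive")
        if any(s >= 0 for _, s in self.oct_high_bands):
            raise ValueError("oct_high_bands: supra-normal scores must be negative")

    @property
    def max_pd_score(self) -> int:
        return max(self.pd_scores.values())


DEFAULT_SCALE = ScoreScale()


def score_pd(category: PDCategory | str, scale: ScoreScale = DEFAULT_SCALE) -> int:
    """Integer score of one pattern-deviation probability category."""
    return scale.pd_scores[PDCategory(category)]


def score_oct_band(percentile: float, scale: ScoreScale = DEFAULT_SCALE) -> int:
    """Signed score of an RNFLT percentile.

    Percentiles below the graded sub-normal bounds score positive (more
    extreme thinning scores higher); percentiles above the supra-normal
    bound score negative; the central band scores 0.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile {percentile} outside [0, 100]")
    for bound, score in scale.oct_low_bands:
        if percentile < bound:
            return score
    for bound, score in scale.oct_high_bands:
        if percentile > bound:
            return score
    return 0


@dataclass
class NormativeDB:
    """Per-A-scan-position normative regression and residual distribution.

    ``residuals`` holds the fitted OLS residuals, one row per normative
    subject and one column per A-scan position; empirical quantiles are
    taken from them (midrank convention).
    """

    intercept_um: np.ndarray          # (256,) predicted thickness at reference covariates
    beta_age_um_per_year: np.ndarray  # (256,)
    beta_se_um_per_diopter: np.ndarray  # (256,)
    residuals: np.ndarray             # (n_subjects, 256)
    reference_age_years: float
    reference_se_diopters: float
    n_subjects: int

    _sorted_residuals: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("intercept_um", "beta_age_um_per_year", "beta_se_um_per_diopter"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_ASCANS,):
                raise ValueError(f"{name}: expected shape ({N_ASCANS},), got {arr.shape}")
            setattr(self, name, arr)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.residuals.ndim != 2 or self.residuals.shape[1] != N_ASCANS:
            raise ValueError("residuals: expected shape (n_subjects, 256)")
        if self.residuals.shape[0] == 0:
            raise ValueError("residuals: table must be non-empty")

    @property
    def sorted_residuals(self) -> np.ndarray:
        if self._sorted_residuals is None:
            self._sorted_residuals = np.sort(self.residuals, axis=0)
        return self._sorted_residuals

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "glaufuse-normative-db",
            "intercept_um": self.intercept_um.tolist(),
            "beta_age_um_per_year": self.beta_age_um_per_year.tolist(),
            "beta_se_um_per_diopter": self.beta_se_um_per_diopter.tolist(),
            "residuals": self.residuals.tolist(),
            "reference_age_years": self.reference_age_years,
            "reference_se_diopters": self.reference_se_diopters,
            "n_subjects": self.n_subjects,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormativeDB":
        doc = json.loads(Path(path).read_text())
        return cls(
            intercept_um=np.array(doc["intercept_um"]),
            beta_age_um_per_year=np.array(doc["beta_age_um_per_year"]),
            beta_se_um_per_diopter=np.array(doc["beta_se_um_per_diopter"]),
            residuals=np.array(doc["residuals"]),
            reference_age_years=doc["reference_age_years"],
            reference_se_diopters=doc["reference_se_diopters"],
            n_subjects=doc["n_subjects"],
        )


def build_normative_db(healthy: Cohort, min_records: int = 30) -> NormativeDB:
    """Fit the per-position age/refraction regressions on a healthy cohort.

    At every A-scan position, thickness is regressed on age and spherical
    equivalent by least squares; residuals are stored for empirical quantile
    lookup and the reference covariates are the cohort means.  A covariate
    with zero variance is dropped from the design (its coefficient set to 0)
    with a warning.
    """
    recs = [r for r in healthy.records if r.label is Label.HEALTHY]
    n = len(recs)
    if n < min_records:
        raise ValueError(f"normative cohort too small: {n} healthy records < {min_records}")

    thickness = np.array([r.oct.ascan_um for r in recs], dtype=float)  # (n, 256)
    age = np.array([r.oct.age_years for r in recs], dtype=float)
    se = np.array([r.oct.se_diopters for r in recs], dtype=float)
    ref_age = float(age.mean())
    ref_se = float(se.mean())

    cols = [np.ones(n)]
    use: list[str] = []
    for name, v in (("age", age), ("spherical equivalent", se)):
        if np.ptp(v) == 0.0:
            _warnings.warn(
                f"normative covariate {name!r} has zero variance; coefficient set to 0",
                stacklevel=2,
            )
        else:
            cols.append(v - v.mean())  # centering: intercept = reference prediction
            use.append(name)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, thickness, rcond=None)

    beta_age = np.zeros(N_ASCANS)
    beta_se = np.zeros(N_ASCANS)
    i = 1
    if "age" in use:
        beta_age = coef[i]
        i += 1
    if "spherical equivalent" in use:
        beta_se = coef[i]
    residuals = thickness - X @ coef

    return NormativeDB(
        intercept_um=coef[0],
        beta_age_um_per_year=beta_age,
        beta_se_um_per_diopter=beta_se,
        residuals=residuals,
        reference_age_years=ref_age,
        reference_se_diopters=ref_se,
        n_subjects=n,
    )


def correct_ascan(test: OCTTest, db: NormativeDB) -> np.ndarray:
    """Age/refraction-corrected A-scan profile (additive, in µm).

    ``corrected[p] = raw[p] - beta_age[p]*(age - ref_age) - beta_se[p]*(se - ref_se)``
    """
    raw = np.asarray(test.ascan_um, dtype=float)
    return (
        raw
        - db.beta_age_um_per_year * (test.age_years - db.reference_age_years)
        - db.beta_se_um_per_diopter * (test.se_diopters - db.reference_se_diopters)
    )


def _midrank_percentile(sorted_vals: np.ndarray, value: float) -> float:
    """Empirical percentile with a midrank tie convention.

    A query between two stored values at rank k takes ``100*(k+0.5)/n``; a
    tie on m stored values takes ``100*(n_less + m/2)/n`` (coinciding with
    the gap rule when the tied block is entered); results are clipped to
    ``[100*0.5/n, 100*(n-0.5)/n]`` so a value beyond either extreme maps to
    the corresponding half-rank.
    """
    n = sorted_vals.shape[0]
    n_less = int(np.searchsorted(sorted_vals, value, side="left"))
    n_leq = int(np.searchsorted(sorted_vals, value, side="right"))
    n_equal = n_leq - n_less
    if n_equal:
        frac = n_less + 0.5 * n_equal
    else:
        frac = n_less + 0.5
    frac = min(max(frac, 0.5), n - 0.5)
    return 100.0 * frac / n


def rnflt_percentile(db: NormativeDB, position: int, corrected_value_um: float) -> float:
    """Percentile of a corrected thickness within the normative residuals.

    The query is referred to the reference prediction at ``position`` and
    ranked among the stored residuals (midrank convention for ties).
    """
    if not 0 <= position < N_ASCANS:
        raise IndexError(f"position {position} outside 0..{N_ASCANS - 1}")
    resid = corrected_value_um - db.intercept_um[position]
    return _midrank_percentile(db.sorted_residuals[:, position], resid)


def rnflt_percentiles(db: NormativeDB, corrected: Sequence[float]) -> np.ndarray:
    """Vector of :func:`rnflt_percentile` over all 256 positions."""
    corrected = np.asarray(corrected, dtype=float)
    return np.array(
        [
            _midrank_percentile(db.sorted_residuals[:, p], corrected[p] - db.intercept_um[p])
            for p in range(N_ASCANS)
        ]
    )
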