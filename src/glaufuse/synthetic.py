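"""Synthetic paired SAP/OCT cohorts with spatially coupled glaucomatous
defects.

The generator emulates the statistical structure the fusion pipeline
assumes, not any particular instrument's physics:

* Healthy circumpapillary RNFL profiles follow a stylised double-hump
  TSNIT curve (thick superior and inferior arcuate bundles, thin temporal
  and nasal regions) with linear age and spherical-equivalent effects of
  known magnitude and independent Gaussian measurement noise per A-scan.
* Glaucomatous damage is sector-coherent: 1-3 scan-circle sectors of the
  structure-function map are thinned by a severity-scaled fraction, and
  the *same* sectors' visual-field points are depressed through a linear
  structure-function coupling slope (dB of sensitivity loss per unit
  thinning fraction), on top of a severity-scaled diffuse loss.
* Pattern-deviation categories come from ranking the simulated deviations
  against the healthy deviation distribution at the conventional
  5/2/1/0.5% cuts; Mean Deviation is the mean simulated deviation and is
  resampled into the severity's band (early > -6 dB >= moderate > -12 dB
  >= advanced).
* A deliberately simplified hemifield labeler assigns WNL / BORDERLINE /
  ONL from superior-inferior score asymmetry and total abnormality.  It is
  NOT the commercial Glaucoma Hemifield Test; it only feeds the GHT
  comparator rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import (
    CANONICAL_GRID,
    Cohort,
    GHTLabel,
    Label,
    N_ASCANS,
    OCTTest,
    SAPTest,
    Severity,
    SubjectRecord,
    PDCategory,
)
from .fusion import DEG_PER_ASCAN, Sector, SectorMap, default_sector_map

__all__ = [
    "SeverityModel",
    "SimConfig",
    "PAPER_STUDY",
    "generate_normative_cohort",
    "generate_glaucoma_record",
    "generate_healthy_record",
    "generate_study",
]


@dataclass(frozen=True)
class SeverityModel:
    """Defect-model parameters of one severity stratum."""

    n_sectors: tuple[int, ...]          # candidate counts of affected sectors
    thinning_range: tuple[float, float]  # fractional RNFL loss in affected sectors
    diffuse_range: tuple[float, float]   # dB of diffuse sensitivity loss


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    The defaults mirror the emulated study: 125 healthy / 135 glaucoma
    with severity counts 49 early, 32 moderate, 54 advanced.
    """

    n_healthy: int = 125
    n_glaucoma: int = 135
    severity_counts: dict = field(
        default_factory=lambda: {Severity.EARLY: 49, Severity.MODERATE: 32, Severity.ADVANCED: 54}
    )

    # normative TSNIT profile: baseline + superior/inferior Gaussian humps
    profile_base_um: float = 62.0
    hump_superior_um: float = 65.0
    hump_inferior_um: float = 70.0
    hump_center_superior_deg: float = 95.0
    hump_center_inferior_deg: float = 270.0
    hump_width_deg: float = 35.0

    # covariate effects (per A-scan position, uniform across positions)
    beta_age_um_per_year: float = -0.2
    beta_se_um_per_diopter: float = 0.8

    # measurement noise of the 3-scan-average profile: a per-test offset
    # (acquisition/registration shift common to all positions), a smooth
    # correlated field (segmentation wander along the circle) and a small
    # independent component.  A-scan noise is strongly spatially correlated
    # in practice; independent per-position noise would flood the sector
    # percentile rules with false flags.
    noise_subject_sd_um: float = 2.5
    noise_smooth_sd_um: float = 1.2
    noise_smooth_halfwidth: float = 6.0  # Gaussian kernel width, A-scan positions
    noise_white_sd_um: float = 0.6

    # population distributions
    age_mean: float = 62.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (45.0, 90.0)
    se_mean: float = 0.0
    se_sd: float = 1.8
    se_range: tuple[float, float] = (-5.0, 3.0)

    # visual-field model
    td_noise_sd_db: float = 2.0          # healthy deviation spread (test-retest scale)
    vf_false_positive_rate: float = 0.02  # isolated LT5 points in healthy fields
    coupling_slope_db: float = 25.0       # dB of loss per unit thinning fraction
    coupling_noise_sd: float = 0.15       # relative jitter on the coupled loss

    # severity bands: EARLY > md_thresholds[0] >= MODERATE > md_thresholds[1] >= ADVANCED
    md_thresholds: tuple[float, float] = (-6.0, -12.0)
    severity_models: dict = field(
        default_factory=lambda: {
            Severity.EARLY: SeverityModel((1, 2), (0.12, 0.32), (0.0, 1.0)),
            Severity.MODERATE: SeverityModel((2, 3), (0.30, 0.50), (3.0, 6.0)),
            Severity.ADVANCED: SeverityModel((3,), (0.45, 0.70), (8.0, 15.0)),
        }
    )
    max_resamples: int = 100

    # simplified hemifield labeler
    ght_borderline_asymmetry: float = 4.0
    ght_onl_asymmetry: float = 10.0
    ght_borderline_total: float = 8.0
    ght_onl_total: float = 20.0

    def md_band(self, severity: Severity) -> tuple[float, float]:
        early_cut, adv_cut = self.md_thresholds
        if severity is Severity.EARLY:
            return (early_cut, 0.0)
        if severity is Severity.MODERATE:
            return (adv_cut, early_cut)
        return (-math.inf, adv_cut)


PAPER_STUDY = SimConfig()

# PD category cuts: deviations ranked against the healthy N(0, td_sd)
# distribution at the 5 / 2 / 1 / 0.5 % levels.
_PD_LEVELS = ((0.005, PDCategory.LT05), (0.01, PDCategory.LT1), (0.02, PDCategory.LT2), (0.05, PDCategory.LT5))


def _mean_profile(cfg: SimConfig) -> np.ndarray:
    theta = np.arange(N_ASCANS) * DEG_PER_ASCAN
    def hump(center, amp):
        d = np.minimum(np.abs(theta - center), 360.0 - np.abs(theta - center))
        return amp * np.exp(-0.5 * (d / cfg.hump_width_deg) ** 2)
    return (
        cfg.profile_base_um
        + hump(cfg.hump_center_superior_deg, cfg.hump_superior_um)
        + hump(cfg.hump_center_inferior_deg, cfg.hump_inferior_um)
    )


def _pd_cut_db(cfg: SimConfig, level: float) -> float:
    if cfg.td_noise_sd_db == 0.0:  # degenerate healthy distribution
        return 0.0
    return float(stats.norm.ppf(level, scale=cfg.td_noise_sd_db))


def _categories_from_deviations(td: np.ndarray, cfg: SimConfig) -> list[PDCategory]:
    cats = []
    for v in td:
        cat = PDCategory.GE5
        for level, category in _PD_LEVELS:
            if v < _pd_cut_db(cfg, level):
                cat = category
                break
        cats.append(cat)
    return cats


def _ght_label(categories: list[PDCategory], cfg: SimConfig) -> GHTLabel:
    """Simplified hemifield rule from superior/inferior score asymmetry."""
    from .normative import DEFAULT_SCALE, score_pd

    sup = sum(score_pd(c, DEFAULT_SCALE) for c, (x, y) in zip(categories, CANONICAL_GRID) if y > 0)
    inf = sum(score_pd(c, DEFAULT_SCALE) for c, (x, y) in zip(categories, CANONICAL_GRID) if y < 0)
    asym, total = abs(sup - inf), sup + inf
    if asym >= cfg.ght_onl_asymmetry or total >= cfg.ght_onl_total:
        return GHTLabel.ONL
    if asym >= cfg.ght_borderline_asymmetry or total >= cfg.ght_borderline_total:
        return GHTLabel.BORDERLINE
    return GHTLabel.WNL


def _draw_covariates(rng: np.random.Generator, cfg: SimConfig) -> tuple[float, float]:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), *cfg.age_range))
    se = float(np.clip(rng.normal(cfg.se_mean, cfg.se_sd), *cfg.se_range))
    return age, se


def _measurement_noise(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Spatially correlated measurement noise along the scan circle."""
    noise = np.full(N_ASCANS, rng.normal(0.0, cfg.noise_subject_sd_um))
    if cfg.noise_smooth_sd_um > 0:
        d = np.minimum(np.arange(N_ASCANS), N_ASCANS - np.arange(N_ASCANS)).astype(float)
        kernel = np.exp(-0.5 * (d / cfg.noise_smooth_halfwidth) ** 2)
        kernel /= np.linalg.norm(kernel)  # unit L2: white in -> unit-sd smooth out
        white = rng.normal(0.0, 1.0, size=N_ASCANS)
        smooth = np.fft.irfft(np.fft.rfft(white) * np.fft.rfft(kernel), n=N_ASCANS)
        noise += cfg.noise_smooth_sd_um * smooth
    noise += rng.normal(0.0, cfg.noise_white_sd_um, size=N_ASCANS)
    return noise


def _ascan_profile(
    rng: np.random.Generator, cfg: SimConfig, age: float, se: float,
    thinning: np.ndarray | None = None,
) -> np.ndarray:
    base = _mean_profile(cfg)
    if thinning is not None:
        base = base * (1.0 - thinning)
    prof = (
        base
        + cfg.beta_age_um_per_year * (age - cfg.age_mean)
        + cfg.beta_se_um_per_diopter * (se - cfg.se_mean)
        + _measurement_noise(rng, cfg)
    )
    return np.clip(prof, 5.0, 395.0)


def generate_healthy_record(
    subject_id: str, cfg: SimConfig, rng: np.random.Generator
) -> SubjectRecord:
    age, se = _draw_covariates(rng, cfg)
    ascans = _ascan_profile(rng, cfg, age, se)
    td = rng.normal(0.0, cfg.td_noise_sd_db, size=len(CANONICAL_GRID))
    cats = [
        PDCategory.LT5 if rng.random() < cfg.vf_false_positive_rate else PDCategory.GE5
        for _ in CANONICAL_GRID
    ]
    sap = SAPTest.from_categories(cats, md_db=float(td.mean()), ght_label=_ght_label(cats, cfg))
    oct_ = OCTTest(
        ascan_um=ascans,
        signal_strength=int(np.clip(round(rng.normal(9.9, 0.3)), 6, 10)),
        age_years=age,
        se_diopters=se,
    )
    return SubjectRecord(subject_id=subject_id, label=Label.HEALTHY, sap=sap, oct=oct_)


def generate_normative_cohort(n: int, cfg: SimConfig = PAPER_STUDY, seed: int = 0) -> Cohort:
    """Healthy cohort for normative-database construction.

    The true covariate coefficients are recorded in the cohort metadata so
    parameter-recovery tests can compare against ground truth.
    """
    if n < 30:
        raise ValueError("normative cohort requires n >= 30")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x40]))
    records = [generate_healthy_record(f"N{i + 1:04d}", cfg, rng) for i in range(n)]
    return Cohort(
        records=records,
        metadata={
            "generator": "glaufuse-synthetic",
            "seed": int(seed),
            "true_beta_age_um_per_year": cfg.beta_age_um_per_year,
            "true_beta_se_um_per_diopter": cfg.beta_se_um_per_diopter,
            "reference_age_years": cfg.age_mean,
        },
    )


def _sector_index_mask(smap: SectorMap, sectors: list[Sector]) -> np.ndarray:
    angles = np.arange(N_ASCANS) * DEG_PER_ASCAN
    mask = np.zeros(N_ASCANS, dtype=bool)
    for i, ang in enumerate(angles):
        if smap.sector_of_angle(ang) in sectors:
            mask[i] = True
    return mask


def generate_glaucoma_record(
    severity: Severity,
    cfg: SimConfig = PAPER_STUDY,
    seed: int | np.random.Generator = 0,
    smap: SectorMap | None = None,
    subject_id: str = "G0001",
    return_details: bool = False,
):
    """One glaucomatous record with sector-coherent structure-function damage.

    Draws affected scan-circle sectors, thins their A-scans, depresses the
    retinotopically corresponding visual-field points through the coupling
    slope, and resamples until the Mean Deviation lands in the severity's
    band.  ``return_details=True`` additionally returns the drawn defect
    parameters (affected sectors, per-sector thinning, diffuse loss).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x61])
    )
    severity = Severity(severity)
    if smap is None:
        smap = default_sector_map()
    model: SeverityModel = cfg.severity_models[severity]
    lo, hi = cfg.md_band(severity)

    for _ in range(cfg.max_resamples):
        k = int(rng.choice(model.n_sectors))
        sectors = [Sector(s) for s in rng.choice([s.value for s in Sector], size=k, replace=False)]
        thin_frac = {s: float(rng.uniform(*model.thinning_range)) for s in sectors}
        diffuse = float(rng.uniform(*model.diffuse_range))

        thinning = np.zeros(N_ASCANS)
        for s in sectors:
            thinning[_sector_index_mask(smap, [s])] = thin_frac[s]

        age, se = _draw_covariates(rng, cfg)
        ascans = _ascan_profile(rng, cfg, age, se, thinning=thinning)

        td = rng.normal(0.0, cfg.td_noise_sd_db, size=len(CANONICAL_GRID)) - diffuse
        for j, pt in enumerate(CANONICAL_GRID):
            s = smap.sector_of_point(pt)
            if s in sectors:
                loss = cfg.coupling_slope_db * thin_frac[s]
                td[j] -= loss * (1.0 + rng.normal(0.0, cfg.coupling_noise_sd))
        md = float(td.mean())
        if lo < md <= hi:
            cats = _categories_from_deviations(td, cfg)
            sap = SAPTest.from_categories(cats, md_db=md, ght_label=_ght_label(cats, cfg))
            oct_ = OCTTest(
                ascan_um=ascans,
                signal_strength=int(np.clip(round(rng.normal(9.4, 0.8)), 6, 10)),
                age_years=age,
                se_diopters=se,
            )
            rec = SubjectRecord(
                subject_id=subject_id, label=Label.GLAUCOMA, sap=sap, oct=oct_, severity=severity
            )
            if return_details:
                return rec, {"sectors": sectors, "thinning": thin_frac, "diffuse_db": diffuse}
            return rec
    raise RuntimeError(
        f"could not reach the {severity.value} MD band ({lo}, {hi}] in "
        f"{cfg.max_resamples} resamples; defect model and band are inconsistent"
    )


def generate_study(cfg: SimConfig = PAPER_STUDY, seed: int = 0) -> Cohort:
    """Full study cohort with the configured class and severity composition."""
    if sum(cfg.severity_counts.values()) != cfg.n_glaucoma:
        raise ValueError("severity counts must sum to n_glaucoma")
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x57])
    rng = np.random.default_rng(ss)
    smap = default_sector_map()
    records: list[SubjectRecord] = [
        generate_healthy_record(f"H{i + 1:04d}", cfg, rng) for i in range(cfg.n_healthy)
    ]
    g = 0
    for severity in (Severity.EARLY, Severity.MODERATE, Severity.ADVANCED):
        for _ in range(cfg.severity_counts[severity]):
            g += 1
            records.append(
                generate_glaucoma_record(
                    severity, cfg, seed=rng, smap=smap, subject_id=f"G{g:04d}"
                )
            )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    return Cohort(
        records=records,
        metadata={
            "generator": "glaufuse-synthetic",
            "seed": int(seed),
            "n_healthy": cfg.n_healthy,
            "n_glaucoma": cfg.n_glaucoma,
            "severity_counts": {s.value: c for s, c in cfg.severity_counts.items()},
        },
    )
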