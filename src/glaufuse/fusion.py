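"""Six-sector structure-function correspondence and the two fusion transforms.

The anatomical map divides the peripapillary scan circle into six angular
sectors (temporal, superotemporal, superonasal, nasal, inferonasal,
inferotemporal) and assigns each of the 52 visual-field points to the
sector where its retinal nerve-fibre bundle enters the disc.  Because the
retinal image is inverted, superior field points belong to inferior
scan-circle sectors and vice versa.

Two transforms exploit the map:

* ``fuse_oct`` — A-scan values whose thickness falls below the normative
  5th percentile are multiplied by ``exp(-alpha * mean_sector_pd_score)``
  of the corresponding visual-field sector, so structurally thinned
  positions are further depressed when the matching field area is also
  abnormal and left untouched when it is not.
* ``fuse_sap`` — each field point's pattern-deviation score receives an
  additive factor from the corresponding scan sector: the score of the most
  extreme sub-5th-percentile A-scan if one exists (a low value always wins
  over a supra-normal one), otherwise the (negative) score of the most
  extreme supra-95th position, otherwise 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import CANONICAL_GRID, N_ASCANS, SAPTest
from .normative import (
    DEFAULT_SCALE,
    NormativeDB,
    ScoreScale,
    rnflt_percentiles,
    score_oct_band,
    score_pd,
)

__all__ = [
    "Sector",
    "SectorMap",
    "FusionConfig",
    "default_sector_map",
    "ascan_angle_deg",
    "sector_of_ascan",
    "sector_of_vf_point",
    "mean_sector_pd_score",
    "fuse_oct",
    "fuse_sap",
]

DEG_PER_ASCAN = 360.0 / N_ASCANS


class Sector(str, Enum):
    TEMPORAL = "TEMPORAL"
    SUPEROTEMPORAL = "SUPEROTEMPORAL"
    SUPERONASAL = "SUPERONASAL"
    NASAL = "NASAL"
    INFERONASAL = "INFERONASAL"
    INFEROTEMPORAL = "INFEROTEMPORAL"


#: Scan-circle angular intervals, degrees, half-open [start, end), angle 0 on
#: the temporal horizontal meridian increasing superiorly.  The temporal
#: interval wraps through 0.
DEFAULT_INTERVALS: dict[Sector, tuple[float, float]] = {
    Sector.TEMPORAL: (311.0, 41.0),
    Sector.SUPEROTEMPORAL: (41.0, 81.0),
    Sector.SUPERONASAL: (81.0, 121.0),
    Sector.NASAL: (121.0, 231.0),
    Sector.INFERONASAL: (231.0, 271.0),
    Sector.INFEROTEMPORAL: (271.0, 311.0),
}


@dataclass(frozen=True)
class SectorMap:
    """Angular sector intervals plus the visual-field points of each sector.

    ``intervals`` are half-open ``[start, end)`` degree ranges that must
    partition [0, 360) (wrap-around allowed); ``vf_points`` must partition
    the 52 canonical grid locations.  Superior field points may only belong
    to sectors whose interval lies in the inferior half of the circle (and
    vice versa) — the retinotopic inversion.
    """

    intervals: Mapping[Sector, tuple[float, float]]
    vf_points: Mapping[Sector, frozenset[tuple[int, int]]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vf_points", {s: frozenset(pts) for s, pts in self.vf_points.items()}
        )
        self.validate()

    def validate(self) -> None:
        # angular partition, checked on the A-scan lattice (exhaustive)
        for i in range(N_ASCANS):
            angle = i * DEG_PER_ASCAN
            hits = [s for s in Sector if self._contains(self.intervals[s], angle)]
            if len(hits) != 1:
                raise ValueError(f"angular intervals do not partition: angle {angle} in {hits}")
        # VF point partition
        all_pts = [p for s in Sector for p in self.vf_points[s]]
        if len(all_pts) != len(CANONICAL_GRID) or set(all_pts) != set(CANONICAL_GRID):
            raise ValueError("vf_points do not partition the 52 canonical grid points")
        # retinotopic inversion
        superior_disc = {Sector.SUPEROTEMPORAL, Sector.SUPERONASAL}
        inferior_disc = {Sector.INFERONASAL, Sector.INFEROTEMPORAL}
        for s in Sector:
            for (x, y) in self.vf_points[s]:
                if y > 0 and s in superior_disc:
                    raise ValueError(f"superior field point {(x, y)} assigned to {s.value}")
                if y < 0 and s in inferior_disc:
                    raise ValueError(f"inferior field point {(x, y)} assigned to {s.value}")

    @staticmethod
    def _contains(interval: tuple[float, float], angle: float) -> bool:
        start, end = interval
        angle %= 360.0
        if start <= end:
            return start <= angle < end
        return angle >= start or angle < end

    def sector_of_angle(self, angle_deg: float) -> Sector:
        for s in Sector:
            if self._contains(self.intervals[s], angle_deg):
                return s
        raise ValueError(f"no sector contains angle {angle_deg}")  # pragma: no cover

    def sector_of_point(self, point: tuple[int, int]) -> Sector:
        for s in Sector:
            if point in self.vf_points[s]:
                return s
        raise ValueError(f"{point} is not on the canonical 24-2 grid")

    # -- serialization (override support) ---------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "intervals": {s.value: list(self.intervals[s]) for s in Sector},
            "vf_points": {s.value: sorted(self.vf_points[s]) for s in Sector},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SectorMap":
        doc = json.loads(Path(path).read_text())
        return cls(
            intervals={Sector(k): tuple(v) for k, v in doc["intervals"].items()},
            vf_points={
                Sector(k): frozenset(tuple(p) for p in v) for k, v in doc["vf_points"].items()
            },
        )


def _fibre_entry_angle(x: int, y: int, arcuate_gain: float = 2.9, polar_limit: float = 80.0) -> float:
    """Scan-circle entry angle of the nerve-fibre bundle serving field point (x, y).

    Simplified trajectory model.  The field point images onto the retina at
    ``(-x, -y)`` (both axes invert); the disc sits at the retinal projection
    of the blind spot, ``(-15, 0)``.  Fibres from nasal retina (temporal
    field) run straight to the disc, so the entry angle is the geometric
    direction from disc to retinal point, measured from the temporal
    meridian, positive superiorly.  Fibres from temporal retina (nasal
    field) arc around the fovea: their entry angle is pushed toward the
    vertical poles in proportion to retinal eccentricity (``arcuate_gain``
    degrees per degree), respecting the horizontal raphe and never crossing
    into the nasal half (``polar_limit``).
    """
    xr, yr = -float(x), -float(y)
    theta = math.degrees(math.atan2(yr, xr + 15.0))
    if xr > 0:  # temporal retina: arcuate course
        if yr >= 0:
            theta = min(theta + arcuate_gain * xr, polar_limit)
        else:
            theta = max(theta - arcuate_gain * xr, -polar_limit)
    return theta % 360.0


def default_sector_map() -> SectorMap:
    """The default six-sector correspondence map.

    Angular intervals follow the classical disc sectors (temporal 311-40,
    superotemporal 41-80, superonasal 81-120, nasal 121-230, inferonasal
    231-270, inferotemporal 271-310 degrees); field points are assigned by
    the fibre-trajectory model of :func:`_fibre_entry_angle`.  Serialize
    with :meth:`SectorMap.to_json` to inspect or override the assignment.
    """
    vf_points: dict[Sector, set[tuple[int, int]]] = {s: set() for s in Sector}
    probe = SectorMap.__new__(SectorMap)  # interval lookup before full validation
    object.__setattr__(probe, "intervals", DEFAULT_INTERVALS)
    for (x, y) in CANONICAL_GRID:
        vf_points[probe.sector_of_angle(_fibre_entry_angle(x, y))].add((x, y))
    return SectorMap(intervals=dict(DEFAULT_INTERVALS), vf_points=vf_points)


@dataclass(frozen=True)
class FusionConfig:
    """Tunable constants of the two fusion transforms.

    alpha
        Exponential weighting rate per unit of mean sector PD score (>0);
        the multiplicative factor applied to sub-threshold A-scans is
        ``exp(-alpha * mean_score)``, identity on a fully normal field.
    low_percentile_cut / high_percentile_cut
        Normative percentile bounds delimiting "abnormally thin" and
        "abnormally thick".
    floor_fused_sap_at_zero
        Clamp attenuated fused SAP scores at 0.
    """

    alpha: float = 0.1
    low_percentile_cut: float = 5.0
    high_percentile_cut: float = 95.0
    floor_fused_sap_at_zero: bool = True

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError("alpha must be positive and finite")
        if not 0 < self.low_percentile_cut < self.high_percentile_cut < 100:
            raise ValueError("require 0 < low_percentile_cut < high_percentile_cut < 100")


DEFAULT_CONFIG = FusionConfig()


def ascan_angle_deg(index: int) -> float:
    """Scan-circle angle of A-scan ``index`` (0 = temporal meridian)."""
    if not 0 <= index < N_ASCANS:
        raise IndexError(f"A-scan index {index} outside 0..{N_ASCANS - 1}")
    return index * DEG_PER_ASCAN


def sector_of_ascan(index: int, smap: SectorMap) -> Sector:
    return smap.sector_of_angle(ascan_angle_deg(index))


def sector_of_vf_point(point: tuple[int, int], smap: SectorMap) -> Sector:
    return smap.sector_of_point(tuple(point))


def ascan_indices_of_sector(sector: Sector, smap: SectorMap) -> np.ndarray:
    return np.array([i for i in range(N_ASCANS) if sector_of_ascan(i, smap) is sector])


def mean_sector_pd_score(
    sap: SAPTest, sector: Sector, smap: SectorMap, scale: ScoreScale = DEFAULT_SCALE
) -> float:
    """Mean pattern-deviation score over the field points of one sector."""
    pts = smap.vf_points[sector]
    if not pts:
        raise ValueError(f"sector {sector.value} has no visual-field points")
    by_loc = {(p.x_deg, p.y_deg): p.pd_category for p in sap.points}
    return float(np.mean([score_pd(by_loc[pt], scale) for pt in pts]))


def fuse_oct(
    corrected: Sequence[float],
    sap: SAPTest,
    db: NormativeDB,
    smap: SectorMap,
    scale: ScoreScale = DEFAULT_SCALE,
    cfg: FusionConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Fused A-scan profile: field-weighted depression of sub-normal positions.

    Positions whose corrected thickness sits below the ``low_percentile_cut``
    of the normative distribution are multiplied by
    ``exp(-alpha * mean_sector_pd_score)`` of their sector; all other
    positions pass through unchanged.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != (N_ASCANS,):
        raise ValueError(f"corrected: expected {N_ASCANS} values")
    pct = rnflt_percentiles(db, corrected)
    factors = {
        s: math.exp(-cfg.alpha * mean_sector_pd_score(sap, s, smap, scale)) for s in Sector
    }
    fused = corrected.copy()
    for i in range(N_ASCANS):
        if pct[i] < cfg.low_percentile_cut:
            fused[i] *= factors[sector_of_ascan(i, smap)]
    return fused


def fuse_sap(
    sap: SAPTest,
    corrected: Sequence[float],
    db: NormativeDB,
    smap: SectorMap,
    scale: ScoreScale = DEFAULT_SCALE,
    cfg: FusionConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Fused SAP scores (canonical grid order): OCT-weighted PD scores.

    Per sector, the additive factor is the score of the most extreme
    sub-``low_percentile_cut`` A-scan when any exists (low values take
    precedence), else the negative score of the most extreme
    supra-``high_percentile_cut`` position, else 0.
    """
    corrected = np.asarray(corrected, dtype=float)
    pct = rnflt_percentiles(db, corrected)
    factor: dict[Sector, int] = {}
    for s in Sector:
        idx = ascan_indices_of_sector(s, smap)
        scores = [score_oct_band(pct[i], scale) for i in idx]
        positive = [sc for sc in scores if sc > 0]
        negative = [sc for sc in scores if sc < 0]
        if positive:
            factor[s] = max(positive)
        elif negative:
            factor[s] = min(negative)
        else:
            factor[s] = 0
    by_loc = {(p.x_deg, p.y_deg): p.pd_category for p in sap.points}
    fused = np.empty(len(CANONICAL_GRID))
    for k, pt in enumerate(CANONICAL_GRID):
        val = score_pd(by_loc[pt], scale) + factor[smap.sector_of_point(pt)]
        if cfg.floor_fused_sap_at_zero:
            val = max(val, 0)
        fused[k] = val
    return fused
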