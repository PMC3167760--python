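"""Classifier input assembly: PCA with a retained-variance rule and the six
input types (raw/fused SAP scores, PCA-reduced raw/fused OCT profiles, and
their concatenations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort, N_ASCANS, N_VF_POINTS
from .fusion import (
    DEFAULT_CONFIG,
    FusionConfig,
    SectorMap,
    default_sector_map,
    fuse_oct,
    fuse_sap,
)
from .normative import DEFAULT_SCALE, NormativeDB, ScoreScale, correct_ascan, score_pd

__all__ = ["InputType", "VarianceRetainedPCA", "FeatureSet", "assemble_features"]

_EPS = 1e-12


class InputType(str, Enum):
    """The six examined classifier input types."""

    SAP = "SAP"                  # 52 scored pattern-deviation parameters
    F_SAP = "F_SAP"              # 52 fused SAP parameters
    OCT = "OCT"                  # PCA of corrected A-scan profiles
    F_OCT = "F_OCT"              # PCA of fused A-scan profiles
    SAP_OCT = "SAP_OCT"          # concatenation SAP || OCT
    F_SAP_F_OCT = "F_SAP_F_OCT"  # concatenation F_SAP || F_OCT


#: Input types whose OCT block passes through PCA.
_OCT_BEARING = {InputType.OCT, InputType.F_OCT, InputType.SAP_OCT, InputType.F_SAP_F_OCT}


class VarianceRetainedPCA(TransformerMixin, BaseEstimator):
    """Centered PCA retaining the fewest components reaching a variance target.

    The retained count is the smallest leading number of components whose
    cumulative explained-variance fraction is at least
    ``variance_threshold`` (default 0.999, i.e. 99.9%).  Loadings carry a
    fixed sign convention — the largest-magnitude element of every
    component is positive — so fitted models are deterministic across runs
    and platforms.

    Attributes (after fit): ``mean_``, ``components_`` (retained x dims),
    ``explained_variance_``, ``explained_variance_ratio_`` (retained),
    ``n_components_``, ``variance_retained_fraction_``.
    """

    def __init__(self, variance_threshold: float = 0.999):
        self.variance_threshold = variance_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA requires a 2-d matrix with at least 2 rows")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if float(np.var(X - X.mean(axis=0), axis=0).sum()) <= _EPS:
            raise ValueError("matrix has zero variance (rank 0 after centering)")
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X)
        total = float(pca.explained_variance_.sum())
        if total <= _EPS:
            raise ValueError("matrix has zero variance (rank 0 after centering)")
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.variance_threshold - 1e-9) + 1)
        k = min(k, len(cum))
        comps = pca.components_[:k].copy()
        # deterministic sign: largest-magnitude loading of each component positive
        for row in comps:
            if row[np.argmax(np.abs(row))] < 0:
                row *= -1.0
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_[:k].copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:k].copy()
        self.n_components_ = k
        self.variance_retained_fraction_ = float(cum[k - 1])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: model fitted on {self.n_features_in_} features, "
                f"got {X.shape}"
            )
        return (X - self.mean_) @ self.components_.T


@dataclass
class FeatureSet:
    """Assembled classifier input for one cohort.

    When ``pca_block`` is set (train-fold PCA policy), ``matrix`` still
    holds the raw µm-scale block in columns ``pca_block[0]:pca_block[1]``;
    cross-validation fits a :class:`VarianceRetainedPCA` on the training
    rows of that block in every fold and projects the held-out rows.  With
    the whole-cohort policy the projection has already been applied and
    ``pca_model`` records the fitted model.
    """

    input_type: InputType
    matrix: np.ndarray                 # (records, features)
    labels: np.ndarray                 # (records,) 0 healthy / 1 glaucoma
    provenance: list[str] = field(default_factory=list)  # one tag per column
    pca_model: VarianceRetainedPCA | None = None
    pca_block: tuple[int, int, float] | None = None  # (col_start, col_end, threshold)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _pd_score_matrix(cohort: Cohort, scale: ScoreScale) -> np.ndarray:
    rows = []
    for rec in cohort.records:
        rows.append([score_pd(c, scale) for c in rec.sap.categories_in_canonical_order()])
    return np.asarray(rows, dtype=float)


def assemble_features(
    cohort: Cohort,
    input_type: InputType | str,
    norm: NormativeDB | None = None,
    smap: SectorMap | None = None,
    scale: ScoreScale = DEFAULT_SCALE,
    cfg: FusionConfig = DEFAULT_CONFIG,
    pca_policy: str = "train_fold",
    variance_threshold: float = 0.999,
) -> FeatureSet:
    """Build the feature matrix for one input type.

    ``pca_policy`` is either ``"train_fold"`` (default: defer PCA to the
    cross-validation loop so the projection is fitted on training folds
    only) or ``"whole_cohort"`` (fit here on all records).  All input types
    except plain SAP require a normative database.
    """
    input_type = InputType(input_type)
    if pca_policy not in ("train_fold", "whole_cohort"):
        raise ValueError(f"unknown pca_policy {pca_policy!r}")
    if input_type is not InputType.SAP and norm is None:
        raise ValueError(f"input type {input_type.value} requires a normative database")
    if smap is None:
        smap = default_sector_map()
    labels = np.asarray(cohort.labels(), dtype=int)

    sap_block: np.ndarray | None = None
    oct_block: np.ndarray | None = None
    sap_tag = oct_tag = ""

    if input_type in (InputType.SAP, InputType.SAP_OCT):
        sap_block, sap_tag = _pd_score_matrix(cohort, scale), "pd_score"
    if input_type in (InputType.F_SAP, InputType.F_SAP_F_OCT):
        rows = [
            fuse_sap(r.sap, correct_ascan(r.oct, norm), norm, smap, scale, cfg)
            for r in cohort.records
        ]
        sap_block, sap_tag = np.asarray(rows), "fused_pd_score"
    if input_type in (InputType.OCT, InputType.SAP_OCT):
        oct_block = np.asarray([correct_ascan(r.oct, norm) for r in cohort.records])
        oct_tag = "corrected_ascan"
    if input_type in (InputType.F_OCT, InputType.F_SAP_F_OCT):
        rows = [
            fuse_oct(correct_ascan(r.oct, norm), r.sap, norm, smap, scale, cfg)
            for r in cohort.records
        ]
        oct_block, oct_tag = np.asarray(rows), "fused_ascan"

    pca_model = None
    pca_block = None
    if oct_block is not None:
        if pca_policy == "whole_cohort":
            pca_model = VarianceRetainedPCA(variance_threshold).fit(oct_block)
            oct_block = pca_model.transform(oct_block)
            oct_tag += "_pc"

    if sap_block is not None and oct_block is not None:
        matrix = np.hstack([sap_block, oct_block])
        offset = sap_block.shape[1]
    elif sap_block is not None:
        matrix, offset = sap_block, sap_block.shape[1]
    else:
        matrix, offset = oct_block, 0

    if oct_block is not None and pca_policy == "train_fold":
        pca_block = (offset, offset + oct_block.shape[1], variance_threshold)

    provenance = []
    if sap_block is not None:
        provenance += [f"{sap_tag}[{i}]" for i in range(sap_block.shape[1])]
    if oct_block is not None:
        provenance += [f"{oct_tag}[{i}]" for i in range(oct_block.shape[1])]

    fs = FeatureSet(
        input_type=input_type,
        matrix=np.asarray(matrix, dtype=float),
        labels=labels,
        provenance=provenance,
        pca_model=pca_model,
        pca_block=pca_block,
    )
    if sap_block is not None and sap_block.shape[1] != N_VF_POINTS:
        raise AssertionError("SAP block must have 52 columns")
    return fs
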