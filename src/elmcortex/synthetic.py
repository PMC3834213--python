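"""Synthetic two-class cortical-morphometry cohorts.

The generator emulates a case/control cohort of the kind used in
structural-MRI classification studies: ~110 adolescents (55 patients,
55 controls), 340 cortical features, where a small subset of features
carries a class-dependent mean shift against correlated within-parcel
noise.

Generative model
----------------
Class-conditional Gaussians with equal covariance.  For each of the 68
parcels (34 regions x 2 hemispheres) the five morphometric measures
share an equicorrelated noise component with correlation ``rho``;
parcels are independent of each other.  Informative features receive a
mean shift of ``effect_size * noise_sd`` (a standardized mean
difference d) in the patient class.  Raw values are then mapped to
measure-specific plausible scales (thickness ~ mm, area ~ mm**2, ...);
the mapping is affine per measure, so it changes nothing after min-max
normalization, but makes fixtures look like real summary tables.

Under this model the Bayes-optimal accuracy has the closed form
Phi(Delta / 2) with Delta the Mahalanobis distance between the class
means, which serves as an oracle for classifier evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .schema import (
    MEASURES,
    N_FEATURES,
    REGIONS,
    FeatureDescriptor,
    FeatureTable,
    standard_schema,
)

#: Plausible (location, scale) per measure; affine, so irrelevant after
#: min-max normalization.
MEASURE_LOC_SCALE = {
    "thickness": (2.5, 0.25),       # mm
    "surface_area": (700.0, 90.0),  # mm^2
    "volume": (1900.0, 280.0),      # mm^3
    "folding_index": (14.0, 4.0),
    "curvature": (0.13, 0.02),
}

#: Default informative set: ten features in the parcels reported as most
#: discriminative for this disorder (cuneus, lingual, transverse/middle
#: temporal, pars opercularis, paracentral, precentral, insula).
DEFAULT_INFORMATIVE = (72, 84, 101, 119, 140, 148, 218, 227, 238, 271)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    effect_size is the standardized mean difference d (unitless);
    within_region_correlation couples the five measures of one parcel.
    """

    n_patients: int = 55
    n_controls: int = 55
    informative_indices: tuple[int, ...] = DEFAULT_INFORMATIVE
    effect_size: float = 1.5
    within_region_correlation: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValidationError("need at least one subject per class")
        if not 0.0 <= self.within_region_correlation < 1.0:
            raise ValidationError("within_region_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        bad = [i for i in self.informative_indices if not 1 <= i <= N_FEATURES]
        if bad:
            raise ValidationError(f"informative indices outside schema: {bad}")
        object.__setattr__(self, "informative_indices",
                           tuple(sorted(set(self.informative_indices))))

    @property
    def n_subjects(self) -> int:
        return self.n_patients + self.n_controls

    def to_json(self) -> str:
        return json.dumps({
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
            "informative_indices": list(self.informative_indices),
            "effect_size": self.effect_size,
            "within_region_correlation": self.within_region_correlation,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["informative_indices"] = tuple(d["informative_indices"])
        return cls(**d)


N_PARCELS = 2 * len(REGIONS)  # 68


def _parcel_of_column(col: int) -> int:
    """0-based column -> 0-based parcel id (hemisphere x region)."""
    return col % N_PARCELS


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a cohort from the Gaussian class-conditional model.

    Rows are patients (label +1) followed by controls (label -1);
    bit-identical for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    rho = spec.within_region_correlation

    # equicorrelated parcel noise: z = sqrt(rho)*shared + sqrt(1-rho)*own
    shared = rng.standard_normal((n, N_PARCELS))
    own = rng.standard_normal((n, N_FEATURES))
    z = np.empty((n, N_FEATURES))
    for col in range(N_FEATURES):
        p = _parcel_of_column(col)
        z[:, col] = np.sqrt(rho) * shared[:, p] + np.sqrt(1 - rho) * own[:, col]

    raw = spec.noise_sd * z
    labels = np.concatenate([np.ones(spec.n_patients, int),
                             -np.ones(spec.n_controls, int)])
    shift = spec.effect_size * spec.noise_sd
    for idx in spec.informative_indices:
        raw[labels == 1, idx - 1] += shift

    schema = standard_schema()
    values = np.empty_like(raw)
    for j, d in enumerate(schema):
        loc, scale = MEASURE_LOC_SCALE[d.measure]
        values[:, j] = loc + scale * raw[:, j]

    ids = [f"P{i + 1:03d}" for i in range(spec.n_patients)] + \
          [f"C{i + 1:03d}" for i in range(spec.n_controls)]
    return FeatureTable(values, labels, ids, schema, normalized=False)


def class_mean_difference(spec: CohortSpec) -> np.ndarray:
    """Patient-minus-control mean difference on the raw (unit-noise) scale."""
    delta = np.zeros(N_FEATURES)
    for idx in spec.informative_indices:
        delta[idx - 1] = spec.effect_size * spec.noise_sd
    return delta


def theoretical_bayes_accuracy(spec: CohortSpec) -> float:
    """Bayes-optimal two-class accuracy, Phi(Delta/2).

    Delta is the Mahalanobis separation of the class means under the
    generator's block covariance; it is computed parcel by parcel since
    parcels are independent and the per-measure affine scaling cancels.
    """
    rho = spec.within_region_correlation
    sigma2 = spec.noise_sd ** 2
    delta = class_mean_difference(spec)
    maha2 = 0.0
    for p in range(N_PARCELS):
        cols = np.arange(p, N_FEATURES, N_PARCELS)
        d_p = delta[cols]
        if not np.any(d_p):
            continue
        k = len(cols)
        cov = sigma2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        maha2 += float(d_p @ np.linalg.solve(cov, d_p))
    return float(norm.cdf(np.sqrt(maha2) / 2.0))


def bayes_rule_scores(spec: CohortSpec, table: FeatureTable) -> np.ndarray:
    """Log-likelihood-ratio scores of the true generating model.

    Oracle classifier: positive score favors the patient class.  Works
    on un-normalized tables produced by :func:`generate_cohort` (it
    undoes the per-measure affine scaling first).
    """
    if table.n_features != N_FEATURES:
        raise ValidationError("Bayes-rule scoring needs the full feature schema")
    rho = spec.within_region_correlation
    sigma2 = spec.noise_sd ** 2
    delta = class_mean_difference(spec)
    raw = np.empty_like(table.values)
    for j, d in enumerate(table.descriptors):
        loc, scale = MEASURE_LOC_SCALE[d.measure]
        raw[:, j] = (table.values[:, j] - loc) / scale
    scores = np.zeros(table.n_subjects)
    for p in range(N_PARCELS):
        cols = np.arange(p, N_FEATURES, N_PARCELS)
        d_p = delta[cols]
        if not np.any(d_p):
            continue
        k = len(cols)
        cov = sigma2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
        w = np.linalg.solve(cov, d_p)
        centered = raw[:, cols] - d_p / 2.0  # midpoint between class means
        scores += centered @ w
    return scores
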