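"""Synthetic labeled cohorts drawn from the reference table.

The study's raw 90-sample GC-IMS dataset is not deposited; what the
reference table preserves is the per-origin mean and standard deviation of
every VOC's signal intensity (n = 30 per city).  The generator emulates that
design: for each origin and feature it draws independent Normal values with
the tabulated moments, optionally clipped at zero (intensities are
non-negative).  Features are sampled independently because only marginal
moments are published; real monomer/dimer intensities covary, and a user
covariance hook is accepted but none ships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ORIGINS, ReferenceTable

__all__ = ["CohortConfig", "SampleMatrix", "generate_cohort", "write_cohort",
           "read_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Generation settings.

    n_per_origin matches the published design (30 samples per city);
    sd_scale multiplies every tabulated SD to stress-test separability.

    clip_at_zero truncates negative draws at 0 (intensities are physically
    non-negative) but is off by default: for the widest-SD features
    (mean/SD ratios down to ~0.54) clipping moves ~29% of draws, biasing the
    group mean upward and shrinking its variance enough to distort the
    downstream significance screen, whereas unclipped draws reproduce the
    tabulated moments exactly.
    """

    n_per_origin: int = 30
    seed: int = 0
    clip_at_zero: bool = False
    sd_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_origin < 2:
            raise ValueError("n_per_origin must be >= 2 (ANOVA needs df)")
        if not (self.sd_scale > 0):
            raise ValueError("sd_scale must be > 0")


@dataclass
class SampleMatrix:
    """A labeled cohort: samples x features intensities plus origin labels."""

    intensities: np.ndarray  # (n_samples, n_features), signal intensity a.u.
    labels: np.ndarray  # origin codes 0/1/2
    feature_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.intensities.shape
        if len(self.labels) != n:
            raise ValueError("labels length does not match sample count")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length does not match column count")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:03d}" for i in range(n)]
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def column(self, feature_id: str) -> np.ndarray:
        return self.intensities[:, self.feature_ids.index(feature_id)]

    def subset_features(self, keep_ids: list[str]) -> "SampleMatrix":
        idx = [self.feature_ids.index(f) for f in keep_ids]
        return SampleMatrix(
            intensities=self.intensities[:, idx],
            labels=self.labels.copy(),
            feature_ids=list(keep_ids),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, rows: np.ndarray) -> "SampleMatrix":
        rows = np.asarray(rows)
        return SampleMatrix(
            intensities=self.intensities[rows],
            labels=self.labels[rows],
            feature_ids=list(self.feature_ids),
            sample_ids=[self.sample_ids[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.feature_ids)
        df.insert(0, "origin_label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def generate_cohort(
    ref: ReferenceTable,
    config: CohortConfig | None = None,
    covariance: np.ndarray | None = None,
) -> SampleMatrix:
    """Draw a synthetic cohort from the reference table's per-origin moments.

    For each origin o and feature j, ``n_per_origin`` values are drawn from
    Normal(mean[o, j], (sd_scale * sd[o, j])^2), independently across
    features unless a full feature covariance is supplied.  Deterministic for
    a fixed seed.
    """
    config = config or CohortConfig()
    means = ref.mean_matrix()  # (3, d)
    sds = ref.sd_matrix() * config.sd_scale
    n_origins, d = means.shape
    rng = np.random.default_rng(config.seed)

    blocks = []
    for o in range(n_origins):
        if covariance is not None:
            scale = np.diag(sds[o])
            cov = scale @ covariance @ scale
            block = rng.multivariate_normal(
                means[o], cov, size=config.n_per_origin
            )
        else:
            block = rng.normal(
                loc=means[o], scale=sds[o], size=(config.n_per_origin, d)
            )
        blocks.append(block)
    X = np.vstack(blocks)
    if config.clip_at_zero:
        X = np.clip(X, 0.0, None)
    labels = np.repeat(np.arange(n_origins), config.n_per_origin)
    sample_ids = [
        f"{ORIGINS[o][:2].upper()}{i:02d}"
        for o in range(n_origins)
        for i in range(config.n_per_origin)
    ]
    return SampleMatrix(
        intensities=X,
        labels=labels,
        feature_ids=list(ref.feature_ids),
        sample_ids=sample_ids,
    )


def write_cohort(matrix: SampleMatrix, path: str | Path) -> None:
    """Write a cohort as a TSV: sample_id, origin_label, then one column per
    feature in canonical order.  17 significant digits for lossless
    round-trips."""
    matrix.to_frame().to_csv(path, sep="\t", index=False,
                             float_format="%.17g")


def read_cohort(path: str | Path) -> SampleMatrix:
    """Read a cohort file written by :func:`write_cohort`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     float_precision="round_trip")
    for col in ("sample_id", "origin_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    feature_cols = [c for c in df.columns if c not in ("sample_id", "origin_label")]
    raw = df[feature_cols]
    try:
        values = raw.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in feature_cols:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: non-numeric cell at data row {i + 1}, "
                    f"column {col!r}: {raw[col].iloc[i]!r}"
                ) from None
        raise
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ValueError(
            f"{path}: missing or non-finite cell at data row {i + 1}, "
            f"column {feature_cols[j]!r}"
        )
    return SampleMatrix(
        intensities=values,
        labels=df["origin_label"].to_numpy(dtype=int),
        feature_ids=feature_cols,
        sample_ids=df["sample_id"].tolist(),
    )
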