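"""Voxelwise linear encoding models: OLS fits, cross-validation, controls.

Two model forms share one code path. The *full* model has one free weight
per orientation x scale energy channel; the *constrained* model pools energy
across orientations first, so it has one weight per scale and by construction
cannot express orientation preference (its columns are exact sums of full
design column groups — the models are nested). Fits are unregularized
ordinary least squares; accuracy is out-of-sample R^2 over two image
partitions, with coefficients and R^2 averaged across the partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "build_design",
    "fit_ols",
    "split_partitions",
    "cross_validated_fit",
    "residual_control_fit",
    "prediction_control_fit",
    "VoxelFit",
]


def build_design(features: np.ndarray, n_orientations: int | None = None) -> np.ndarray:
    """Design matrix: feature columns (level-major) plus a trailing constant.

    ``features`` is (n_images, n_channels). Pass ``n_orientations`` to pool a
    full feature matrix into the constrained form (orientation-group sums)
    before appending the constant.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"features must be a non-empty 2D array, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if n_orientations is not None:
        n_img, n_chan = X.shape
        if n_chan % n_orientations:
            raise ValueError(
                f"{n_chan} channels not divisible by {n_orientations} orientations"
            )
        X = X.reshape(n_img, n_chan // n_orientations, n_orientations).sum(axis=2)
    return np.column_stack([X, np.ones(X.shape[0])])


def constrain_features(features: np.ndarray, n_orientations: int) -> np.ndarray:
    """Orientation-group sums of a full (level-major) feature matrix."""
    feats = np.asarray(features)
    n_chan = feats.shape[-1]
    if n_chan % n_orientations:
        raise ValueError(
            f"{n_chan} channels not divisible by {n_orientations} orientations"
        )
    shape = feats.shape[:-1] + (n_chan // n_orientations, n_orientations)
    return feats.reshape(shape).sum(axis=-1)


def fit_ols(design: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """OLS coefficients via a rank-revealing least-squares solve.

    Mathematically ``(X^T X)^{-1} X^T y``; solved with an SVD-based routine
    for numerical stability. Rank deficiency falls back to the minimum-norm
    solution with a warning.
    """
    X = np.asarray(design, dtype=np.float64)
    y = np.asarray(responses, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows but responses has {y.shape[0]}"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank} < {X.shape[1]}); "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    return beta


def r_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 = 1 - SS(resid) / SS(y - mean(y))."""
    y = np.asarray(y, dtype=np.float64)
    resid = y - np.asarray(y_pred, dtype=np.float64)
    denom = np.sum((y - y.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum(resid**2) / denom)


def split_partitions(
    n_images: int, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random split of image indices into two (near-)equal halves."""
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n_images)
    half = n_images // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


@dataclass
class VoxelFit:
    """Result of a cross-validated (or control) fit for one voxel.

    ``beta`` and ``cv_r2`` are means over the two partitions; the
    per-partition coefficients, R^2 values and held-out residuals are kept
    for the control analyses and diagnostics.
    """

    beta: np.ndarray
    cv_r2: float
    partition_betas: tuple[np.ndarray, np.ndarray]
    partition_r2: tuple[float, float]
    partition_residuals: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def channel_beta(self) -> np.ndarray:
        """Coefficients without the trailing constant term."""
        return self.beta[:-1]


def _check_partition(
    part: tuple[np.ndarray, np.ndarray], n_images: int, n_cols: int
) -> tuple[np.ndarray, np.ndarray]:
    a, b = (np.asarray(p, dtype=np.intp) for p in part)
    if np.intersect1d(a, b).size:
        raise ValueError("partitions overlap")
    for p in (a, b):
        if p.size < n_cols + 1:
            raise ValueError(
                f"partition of {p.size} images too small for {n_cols} columns"
            )
        if p.size and (p.min() < 0 or p.max() >= n_images):
            raise ValueError("partition indices out of range")
    return a, b


def cross_validated_fit(
    features: np.ndarray,
    responses: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> VoxelFit:
    """Two-fold cross-validated OLS fit of one voxel.

    Fit on each partition, predict the other, score out-of-sample R^2 against
    the held-out responses; report the mean coefficients and mean R^2.
    """
    X = build_design(features)
    y = np.asarray(responses, dtype=np.float64)
    a, b = _check_partition(partition, X.shape[0], X.shape[1])

    betas, r2s, resids = [], [], []
    for train, test in ((a, b), (b, a)):
        beta = fit_ols(X[train], y[train])
        pred = X[test] @ beta
        betas.append(beta)
        r2s.append(r_squared(y[test], pred))
        resids.append(y[test] - pred)
    return VoxelFit(
        beta=0.5 * (betas[0] + betas[1]),
        cv_r2=0.5 * (r2s[0] + r2s[1]),
        partition_betas=(betas[0], betas[1]),
        partition_r2=(r2s[0], r2s[1]),
        partition_residuals=(resids[0], resids[1]),
    )


def _two_stage_fit(
    features_full: np.ndarray,
    features_constrained: np.ndarray,
    responses: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
    stage_two_target: str,
) -> VoxelFit:
    Xf = build_design(features_full)
    Xc = build_design(features_constrained)
    y = np.asarray(responses, dtype=np.float64)
    a, b = _check_partition(partition, Xf.shape[0], Xf.shape[1])

    betas, r2s = [], []
    for part in (a, b):
        gamma = fit_ols(Xc[part], y[part])
        fitted = Xc[part] @ gamma
        target = y[part] - fitted if stage_two_target == "residual" else fitted
        beta = fit_ols(Xf[part], target)
        betas.append(beta)
        r2s.append(r_squared(target, Xf[part] @ beta))
    return VoxelFit(
        beta=0.5 * (betas[0] + betas[1]),
        cv_r2=0.5 * (r2s[0] + r2s[1]),
        partition_betas=(betas[0], betas[1]),
        partition_r2=(r2s[0], r2s[1]),
    )


def residual_control_fit(
    features_full: np.ndarray,
    features_constrained: np.ndarray,
    responses: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> VoxelFit:
    """Fit the full model to the constrained model's in-partition residuals.

    The first stage fits the constrained (orientation-pooled) model within a
    partition; the second stage regresses that same partition's residuals on
    the full design. Any orientation structure in the result cannot have come
    from the orientation-pooled component of the response. Reported R^2 here
    is in-sample for the second stage.
    """
    return _two_stage_fit(
        features_full, features_constrained, responses, partition, "residual"
    )


def prediction_control_fit(
    features_full: np.ndarray,
    features_constrained: np.ndarray,
    responses: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> VoxelFit:
    """Fit the full model to the constrained model's in-partition predictions.

    Because the constrained columns lie in the span of the full design, the
    second-stage fit is exact; its orientation weights inherit no genuine
    orientation preference, so any apparent map derived from them reflects
    vignetting alone.
    """
    return _two_stage_fit(
        features_full, features_constrained, responses, partition, "prediction"
    )


def fit_population(
    features: np.ndarray,
    responses: np.ndarray,
    partition: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated fits for many voxels sharing one partition.

    ``features``: (n_images, n_voxels, n_channels); ``responses``:
    (n_images, n_voxels). Returns (betas (n_voxels, n_channels+1),
    cv_r2 (n_voxels,)).
    """
    n_img, n_vox, n_chan = features.shape
    betas = np.empty((n_vox, n_chan + 1))
    r2 = np.empty(n_vox)
    for v in range(n_vox):
        fit = cross_validated_fit(features[:, v, :], responses[:, v], partition)
        betas[v] = fit.beta
        r2[v] = fit.cv_r2
    return betas, r2
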