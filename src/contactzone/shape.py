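"""Generalized Procrustes alignment, relative warps, allometry correction.

The morphometric core: landmark configurations are translated, scaled to
unit centroid size and rotated (proper rotations only) onto an iteratively
re-estimated consensus; aligned shapes are projected orthogonally onto the
tangent plane at the consensus; relative warps are the principal components
of the tangent coordinates (equivalent to a relative-warp analysis with the
bending-energy weighting exponent alpha = 0 and the uniform component
included).  Size-related shape variation (allometry) is removed by taking
per-axis least-squares residuals of scores on centroid size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from contactzone.morpho_io import LandmarkConfiguration, LandmarkDataset


class DegenerateShapeError(ValueError):
    """Raised when a configuration has no shape information (all landmarks coincident)."""


@dataclass
class AlignedShapes:
    """Result of generalized Procrustes alignment.

    ``tangent_coords`` holds each specimen's flattened 2k-vector after
    orthogonal projection onto the tangent plane at ``mean_shape``;
    ``aligned`` keeps the pre-projection superimposed coordinates.
    ``centroid_sizes`` are the sizes before unit scaling.
    """

    tangent_coords: np.ndarray  # (n, 2k)
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    mean_shape: np.ndarray  # (2k,), unit centroid size
    iterations: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.tangent_coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.tangent_coords.shape[1] // 2


@dataclass
class ShapeSpace:
    """Relative-warp decomposition of tangent coordinates.

    ``axes`` is (m, 2k) with orthonormal rows ordered by decreasing
    variance; ``scores`` is (n, m) with zero-mean columns;
    ``variance_fraction`` sums to 1 over all retained axes.
    """

    axes: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    mean_tangent: np.ndarray  # (2k,) column means removed before the SVD

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]

    def axis_names(self) -> list[str]:
        return [f"RW{i + 1}" for i in range(self.n_axes)]

    def reconstruct(self) -> np.ndarray:
        """Tangent coordinates rebuilt from all axes (exact at full rank)."""
        return self.scores @ self.axes + self.mean_tangent


@dataclass
class SizeCorrectedScores:
    """Per-axis residuals of relative-warp scores regressed on centroid size."""

    residuals: np.ndarray  # (n, m)
    r_squared: np.ndarray  # (m,)
    slopes: np.ndarray  # (m,)


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark deviations from the centroid.

    The standard geometric-morphometric size measure; scales linearly with
    the configuration.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0:
        raise DegenerateShapeError("all landmarks coincident; centroid size is zero")
    return cs


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt((centered**2).sum())
    if cs <= 0.0:
        raise DegenerateShapeError("degenerate configuration (zero centroid size)")
    return centered / cs, float(cs)


def _rotate_onto(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det +1) of centered config ``x`` onto ``target``."""
    u, _, vt = np.linalg.svd(x.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    return x @ r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then optimally
    rotated (no reflection); the distance is the Frobenius norm of the
    difference.
    """
    xa, _ = _center_and_scale(np.asarray(a, float))
    xb, _ = _center_and_scale(np.asarray(b, float))
    return float(np.linalg.norm(_rotate_onto(xa, xb) - xb))


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> AlignedShapes:
    """Generalized Procrustes alignment of a landmark dataset.

    Each configuration is centered, scaled to unit centroid size and rotated
    (proper rotation only) to minimize its squared distance to the
    iteratively re-estimated consensus.  Iteration stops when the consensus
    moves by less than ``tol``; failure to converge within ``max_iter``
    issues a warning and returns the current state with ``converged=False``.
    Aligned shapes are finally projected orthogonally onto the tangent plane
    at the consensus.
    """
    if isinstance(dataset, LandmarkDataset):
        stack = dataset.coords_array()
    else:
        stack = np.asarray(dataset, dtype=float)
        if stack.ndim != 3 or stack.shape[2] != 2:
            raise ValueError(f"expected (n, k, 2) array, got shape {stack.shape}")
    n = stack.shape[0]
    if n < 2:
        raise ValueError("GPA requires at least 2 specimens")

    scaled = np.empty_like(stack)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _center_and_scale(stack[i])

    mean = scaled[0].copy()
    iterations = 0
    converged = False
    aligned = scaled.copy()
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = _rotate_onto(scaled[i], mean)
        new_mean = aligned.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        norm = np.sqrt((new_mean**2).sum())
        if norm <= 0.0:
            raise DegenerateShapeError("degenerate consensus shape")
        new_mean /= norm
        # anchor the consensus orientation on the previous iterate so the
        # stopping rule measures shape change, not slow joint rotation of
        # the whole configuration set
        new_mean = _rotate_onto(new_mean, mean)
        delta = np.linalg.norm(new_mean - mean)
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last delta above tol)",
            RuntimeWarning,
            stacklevel=2,
        )
    # final superimposition on the converged consensus
    for i in range(n):
        aligned[i] = _rotate_onto(scaled[i], mean)

    mu = mean.reshape(-1)  # unit norm by construction
    flat = aligned.reshape(n, -1)
    tangent = flat - np.outer(flat @ mu, mu)

    return AlignedShapes(
        tangent_coords=tangent,
        aligned=aligned,
        centroid_sizes=sizes,
        mean_shape=mu,
        iterations=iterations,
        converged=converged,
    )


def relative_warps(aligned: AlignedShapes) -> ShapeSpace:
    """Principal-component decomposition of the Procrustes tangent coordinates.

    Axes are ordered by decreasing variance and sign-fixed so each axis's
    largest-magnitude loading is positive.  All axes with non-negligible
    variance are retained, so variance fractions sum to 1 and full-rank
    reconstruction is exact.
    """
    n = aligned.n_specimens
    if n < 3:
        raise ValueError("relative warps require at least 3 specimens")
    x = aligned.tangent_coords
    mean_tangent = x.mean(axis=0)
    centered = x - mean_tangent
    u, s, vt = np.linalg.svd(centered, full_matrices=False)

    total = float((s**2).sum())
    if total <= 0.0:
        raise DegenerateShapeError("no shape variance in dataset")
    keep = s > s[0] * 1e-12
    s, u, vt = s[keep], u[:, keep], vt[keep]

    # sign convention: largest-|loading| entry of each axis positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]

    scores = u * s
    var_frac = s**2 / (s**2).sum()
    return ShapeSpace(axes=vt, scores=scores, variance_fraction=var_frac, mean_tangent=mean_tangent)


def allometry_residuals(
    space: ShapeSpace,
    centroid_sizes: np.ndarray,
    groups: np.ndarray | None = None,
) -> SizeCorrectedScores:
    """Remove the linear size effect from relative-warp scores.

    Fits, for each axis, an ordinary least-squares regression of score on
    centroid size and returns the residuals together with the per-axis
    fraction of score variance explained by size.  By default the fit pools
    all specimens; passing ``groups`` fits a separate slope within each
    group (an option for designs where allometry differs between crosses).
    """
    cs = np.asarray(centroid_sizes, dtype=float)
    scores = space.scores
    if cs.shape[0] != scores.shape[0]:
        raise ValueError("one centroid size required per specimen")
    if np.ptp(cs) == 0.0:
        raise ValueError("all centroid sizes equal; allometry regression undefined")

    def _fit(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float]:
        xc = x - x.mean()
        yc = y - y.mean()
        slope = float(xc @ yc / (xc @ xc))
        resid = yc - slope * xc
        ss_tot = float(yc @ yc)
        r2 = 0.0 if ss_tot == 0.0 else 1.0 - float(resid @ resid) / ss_tot
        return resid, r2, slope

    m = scores.shape[1]
    residuals = np.empty_like(scores)
    r2 = np.empty(m)
    slopes = np.empty(m)
    if groups is None:
        for j in range(m):
            residuals[:, j], r2[j], slopes[j] = _fit(scores[:, j], cs)
    else:
        groups = np.asarray(groups)
        for j in range(m):
            ss_res = 0.0
            ss_tot = float(((scores[:, j] - scores[:, j].mean()) ** 2).sum())
            slope_acc = []
            for g in np.unique(groups):
                sel = groups == g
                if np.ptp(cs[sel]) == 0.0:
                    raise ValueError(f"all centroid sizes equal within group {g!r}")
                res_g, _, b = _fit(scores[sel, j], cs[sel])
                residuals[sel, j] = res_g
                ss_res += float(res_g @ res_g)
                slope_acc.append(b)
            r2[j] = 0.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
            slopes[j] = float(np.mean(slope_acc))
    return SizeCorrectedScores(residuals=residuals, r_squared=r2, slopes=slopes)
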