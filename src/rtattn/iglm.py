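"""Incremental mass-univariate general linear model.

The localizer t-maps are computed in real time, one scan per update, by
accumulating the GLM sufficient statistics (X'X, X'y per voxel, y'y per
voxel).  This recursion is algebraically exact — after n updates the state
equals the batch statistics of the first n scans — so per-scan cost is
constant in run length.  :func:`batch_fit` is an independent full-data
reference implementation (stacked least squares via ``numpy.linalg.lstsq``)
used for equivalence testing and the Dice comparison of incrementally and
batch-derived ROIs.

The default design has four columns: HRF-convolved right-attention and
left-attention boxcars, a linear drift term, and an intercept.  The
differential contrasts right-left and left-right are used downstream, so
regions responding to attention in general cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .synth import Condition, Schedule, condition_regressor

#: Guard value replacing an infinite t in the zero-residual limit.
T_CAP = 1e6

#: Differential contrasts on the default design [right, left, drift, const].
CONTRAST_RIGHT_MINUS_LEFT = np.array([1.0, -1.0, 0.0, 0.0])
CONTRAST_LEFT_MINUS_RIGHT = np.array([-1.0, 1.0, 0.0, 0.0])


def build_design(
    schedule: Schedule,
    n_scans: int | None = None,
    convolve_hrf: bool = True,
    intercept: bool = True,
) -> np.ndarray:
    """Design matrix for the localizer model.

    Columns: right-attention regressor, left-attention regressor, linear
    drift (centered ramp), and optionally an intercept.  ``convolve_hrf``
    toggles HRF convolution of the attention boxcars (a raw-boxcar mode is
    retained because the hemodynamic model of the original online system is
    a configuration choice, not a constraint).
    """
    n = schedule.n_scans_total if n_scans is None else n_scans
    cols = [
        condition_regressor(schedule, Condition.RIGHT, convolve_hrf, n),
        condition_regressor(schedule, Condition.LEFT, convolve_hrf, n),
        np.linspace(-0.5, 0.5, n),
    ]
    if intercept:
        cols.append(np.ones(n))
    return np.column_stack(cols)


@dataclass
class GlmState:
    """Running sufficient statistics of the mass-univariate GLM.

    ``xtx`` is the (p, p) regressor cross-product, ``xty`` the (p, n_voxels)
    regressor-data products, ``yty`` the per-voxel squared-data sums and
    ``n_scans`` the number of update calls absorbed so far.
    """

    n_regressors: int
    grid_shape: tuple[int, ...]
    xtx: np.ndarray = field(init=False)
    xty: np.ndarray = field(init=False)
    yty: np.ndarray = field(init=False)
    n_scans: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        p = self.n_regressors
        nvox = int(np.prod(self.grid_shape))
        self.xtx = np.zeros((p, p))
        self.xty = np.zeros((p, nvox))
        self.yty = np.zeros(nvox)

    def update(self, row: np.ndarray, volume: np.ndarray) -> "GlmState":
        """Absorb one scan: design row ``row`` (length p) and its volume.

        Constant time per scan; mutates and returns ``self``.
        """
        row = np.asarray(row, dtype=float).reshape(-1)
        if row.shape[0] != self.n_regressors:
            raise ValueError(
                f"design row has {row.shape[0]} entries, "
                f"expected {self.n_regressors}"
            )
        vol = np.asarray(volume, dtype=float)
        if vol.shape != tuple(self.grid_shape):
            raise ValueError(
                f"volume shape {vol.shape} != grid {tuple(self.grid_shape)}"
            )
        y = vol.ravel()
        self.xtx += np.outer(row, row)
        self.xty += np.outer(row, y)
        self.yty += y * y
        self.n_scans += 1
        return self


@dataclass
class TMap:
    """Voxelwise t-statistics for one contrast."""

    t: np.ndarray          # grid-shaped
    contrast: np.ndarray
    dof: int

    def to_nifti(self, path: str | Path,
                 voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
                 ) -> None:
        aff = np.diag(list(voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.t.astype(np.float32), aff), str(path))


def _t_from_sufficient_stats(
    xtx: np.ndarray,
    xty: np.ndarray,
    yty: np.ndarray,
    n_scans: int,
    contrast: np.ndarray,
) -> tuple[np.ndarray, int]:
    """t = c'b / sqrt(s2 * c'(X'X)^-1 c) from sufficient statistics.

    Zero contrasts give t = 0 everywhere; zero-residual voxels give a
    sign-preserving capped t (0 if the numerator is also 0), keeping the
    ranking total for downstream top-K selection.
    """
    c = np.asarray(contrast, dtype=float).reshape(-1)
    p = xtx.shape[0]
    if c.shape[0] != p:
        raise ValueError(f"contrast length {c.shape[0]} != {p} regressors")
    rank = int(np.linalg.matrix_rank(xtx))
    if rank < p:
        raise np.linalg.LinAlgError("design is rank-deficient")
    dof = n_scans - rank
    if dof <= 0:
        raise ValueError("n_scans must exceed design rank")
    if not np.any(c):
        return np.zeros(xty.shape[1]), dof

    beta = np.linalg.solve(xtx, xty)                # (p, nvox)
    rss = yty - np.einsum("pv,pv->v", beta, xty)    # y'y - b'X'y
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / dof
    cvc = float(c @ np.linalg.solve(xtx, c))
    num = c @ beta
    se = np.sqrt(sigma2 * cvc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    zero_rv = se == 0
    t[zero_rv] = np.sign(num[zero_rv]) * T_CAP
    t = np.clip(t, -T_CAP, T_CAP)
    return t, dof


def tmap(state: GlmState, contrast: np.ndarray) -> TMap:
    """t-map from the current incremental state (requires more scans than
    the design rank)."""
    t, dof = _t_from_sufficient_stats(
        state.xtx, state.xty, state.yty, state.n_scans, contrast
    )
    return TMap(t.reshape(state.grid_shape), np.asarray(contrast, float), dof)


def batch_fit(
    design: np.ndarray,
    series: np.ndarray,
    contrast: np.ndarray,
    grid_shape: tuple[int, ...] | None = None,
) -> TMap:
    """Full-data GLM reference: ``design`` (n, p), ``series`` (n, n_voxels).

    Fits by stacked least squares and computes residuals explicitly, staying
    numerically independent of the sufficient-statistic path it validates.
    """
    X = np.asarray(design, dtype=float)
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design and series disagree on scan count")
    c = np.asarray(contrast, dtype=float).reshape(-1)
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    if rank < p:
        raise np.linalg.LinAlgError("design is rank-deficient")
    dof = n - rank
    if dof <= 0:
        raise ValueError("need more scans than regressors")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid * resid, axis=0)
    sigma2 = rss / dof
    cvc = float(c @ np.linalg.pinv(X.T @ X) @ c)
    num = c @ beta
    se = np.sqrt(sigma2 * cvc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    zero_rv = se == 0
    t[zero_rv] = np.sign(num[zero_rv]) * T_CAP
    t = np.clip(t, -T_CAP, T_CAP)
    if not np.any(c):
        t = np.zeros_like(t)
    shape = grid_shape if grid_shape is not None else t.shape
    return TMap(t.reshape(shape), c, dof)


def fit_localizer(
    series: np.ndarray,
    schedule: Schedule,
    n_scans: int | None = None,
    convolve_hrf: bool = True,
) -> tuple[TMap, TMap, GlmState]:
    """Run the incremental GLM over the first ``n_scans`` volumes of
    ``series`` (scan, x, y, z) and return the right-left and left-right
    t-maps plus the final state."""
    n = series.shape[0] if n_scans is None else n_scans
    design = build_design(schedule, n, convolve_hrf=convolve_hrf)
    state = GlmState(design.shape[1], series.shape[1:])
    for i in range(n):
        state.update(design[i], series[i])
    return (
        tmap(state, CONTRAST_RIGHT_MINUS_LEFT),
        tmap(state, CONTRAST_LEFT_MINUS_RIGHT),
        state,
    )
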