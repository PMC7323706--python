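"""Diffusion-tensor estimation and tensor shape metrics.

The diffusion tensor D is a symmetric positive-semidefinite 3×3 matrix per
voxel, estimated from the mono-exponential signal model

    S_i = S0 · exp(−b_i · g_iᵀ D g_i)

by least squares on log-transformed signals.  Its ordered eigenvalues
λ1 ≥ λ2 ≥ λ3 yield fractional anisotropy

    FA = sqrt( ½ [(λ1−λ2)² + (λ1−λ3)² + (λ2−λ3)²] / (λ1²+λ2²+λ3²) )

and the Westin shape decomposition

    C_L = (λ1 − λ2) / tr(D)
    C_P = 2 (λ2 − λ3) / tr(D)
    C_S = 3 λ3 / tr(D)

with tr(D) = λ1 + λ2 + λ3, so that C_L + C_P + C_S = 1: a barycentric
coordinate of the tensor's shape between the stick (linear), disc (planar)
and sphere (spherical) limits.

The model/results pair follows the statsmodels convention:
``DiffusionTensorModel(signals, scheme).fit()`` returns a
:class:`TensorFitResults` carrying the estimates, per-voxel diagnostics and
a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .gradients import GradientScheme

__all__ = [
    "DiffusionTensorModel",
    "TensorFitResults",
    "EigenSystem",
    "ShapeMetrics",
    "build_design_matrix",
    "fit_tensor",
    "eigendecompose",
    "fractional_anisotropy",
    "westin_metrics",
    "shape_to_eigenvalues",
    "shape_triangle_coords",
    "triangle_to_shape",
    "tensor_from_eigensystem",
    "IllPosedSchemeError",
    "UnderdeterminedError",
    "InconsistentShapeError",
    "NonFiniteTensorError",
]

DESIGN_COLUMNS = ("ln_s0", "dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

#: Fraction of the per-voxel S0 estimate used as the positivity floor for
#: signals before the log transform.
SIGNAL_FLOOR_FRACTION = 1e-6


class IllPosedSchemeError(ValueError):
    """Gradient scheme cannot determine all seven tensor parameters."""


class UnderdeterminedError(IllPosedSchemeError):
    """Fewer than seven usable measurements."""


class InconsistentShapeError(ValueError):
    """A (cl, cp, cs) triple too far from the unit simplex."""


class NonFiniteTensorError(ValueError):
    """Non-finite tensor elements where finite values are required."""


# ---------------------------------------------------------------------------
# design matrix and fitting


def build_design_matrix(scheme: GradientScheme, check: bool = True) -> np.ndarray:
    """Log-linear DTI design matrix, one row per measurement.

    Row i is ``[1, −b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz]``
    so that ``ln S = row · [ln S0, dxx, dyy, dzz, dxy, dxz, dyz]``.

    Raises
    ------
    IllPosedSchemeError
        If the matrix has rank < 7 (e.g. too few distinct directions),
        naming the unresolvable columns.
    """
    b = scheme.bvals
    gx, gy, gz = scheme.bvecs[:, 0], scheme.bvecs[:, 1], scheme.bvecs[:, 2]
    X = np.column_stack([
        np.ones_like(b),
        -b * gx**2,
        -b * gy**2,
        -b * gz**2,
        -2.0 * b * gx * gy,
        -2.0 * b * gx * gz,
        -2.0 * b * gy * gz,
    ])
    if check:
        # scale columns so rank detection is not dominated by b's magnitude
        scale = np.linalg.norm(X, axis=0)
        scale[scale == 0] = 1.0
        u, s, vt = np.linalg.svd(X / scale, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps * 10))
        if rank < 7:
            null = vt[rank:]
            involved = np.any(np.abs(null) > 1e-8, axis=0)
            names = [c for c, bad in zip(DESIGN_COLUMNS, involved) if bad]
            raise IllPosedSchemeError(
                f"design matrix rank {rank} < 7; unresolvable columns: "
                + ", ".join(names)
            )
    return X


class DiffusionTensorModel:
    """Per-voxel diffusion tensor model for a DWI signal array.

    Parameters
    ----------
    signals : array-like, shape (..., N)
        Measured intensities; the last axis indexes the scheme's N
        measurements.  Any leading shape (a single voxel, a slice, a
        volume) is supported.
    scheme : GradientScheme
        Acquisition b-values and directions.
    mask : array-like of bool, shape (...), optional
        Voxels to fit.  Unmasked voxels yield NaN sentinels.

    Notes
    -----
    Nonpositive signals are clamped to ``1e-6 × S0_estimate`` before the
    log transform and counted per voxel; voxels whose signals are all
    nonpositive are masked out entirely.
    """

    def __init__(self, signals, scheme: GradientScheme, mask=None):
        signals = np.asarray(signals, dtype=float)
        if signals.shape[-1] != scheme.n:
            raise ValueError(
                f"signals last axis ({signals.shape[-1]}) does not match "
                f"scheme length ({scheme.n})"
            )
        if scheme.n < 7:
            raise UnderdeterminedError(
                f"{scheme.n} measurements < 7 tensor parameters"
            )
        self.signals = signals
        self.scheme = scheme
        self.design = build_design_matrix(scheme)
        if mask is None:
            mask = np.ones(signals.shape[:-1], dtype=bool)
        else:
            mask = np.broadcast_to(np.asarray(mask, dtype=bool), signals.shape[:-1])
        self.mask = mask

    def fit(self, method: str = "ols") -> "TensorFitResults":
        """Estimate ln S0 and the six tensor elements per voxel.

        Parameters
        ----------
        method : {"ols", "wls"}
            Ordinary least squares on log signals (default), or weighted
            least squares with one reweighting pass using squared
            predicted signals as weights.
        """
        if method not in ("ols", "wls"):
            raise ValueError(f"unknown fit method {method!r}")
        S = self.signals
        b0 = self.scheme.b0_mask
        # S0 estimate per voxel for the positivity floor: mean positive b0
        # signal, falling back to the largest positive signal.
        b0sig = np.where(S[..., b0] > 0, S[..., b0], np.nan)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            s0_est = np.nanmean(b0sig, axis=-1)
        fallback = np.max(np.where(S > 0, S, 0.0), axis=-1)
        s0_est = np.where(np.isnan(s0_est), fallback, s0_est)
        all_nonpos = fallback <= 0
        usable = self.mask & ~all_nonpos

        floor = SIGNAL_FLOOR_FRACTION * np.where(s0_est > 0, s0_est, 1.0)
        clamped = S <= 0
        n_clamped = clamped.sum(axis=-1)
        Sc = np.where(clamped, floor[..., None], S)
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(Sc)
        y = np.where(usable[..., None], y, 0.0)

        X = self.design
        if method == "ols":
            beta = y @ np.linalg.pinv(X).T
        else:
            beta = y @ np.linalg.pinv(X).T  # OLS start
            w = np.exp(2.0 * (beta @ X.T))  # squared predicted signals
            A = np.einsum("...n,ni,nj->...ij", w, X, X)
            rhs = np.einsum("...n,ni,...n->...i", w, X, y)
            beta = np.linalg.solve(A, rhs[..., None])[..., 0]
        beta = np.where(usable[..., None], beta, np.nan)
        return TensorFitResults(
            model=self, params=beta, method=method,
            n_clamped_signals=np.where(usable, n_clamped, 0),
            usable=usable,
        )


@dataclass(frozen=True)
class EigenSystem:
    """Ordered eigensystem of a (batch of) symmetric diffusion tensor(s).

    ``evals`` are sorted descending (λ1 ≥ λ2 ≥ λ3) with negative values
    clamped to 0 (``clamped`` flags affected voxels; ``evals_raw`` keeps
    the unclamped values).  ``evecs[..., :, k]`` is the eigenvector of
    ``evals[..., k]``, sign-fixed so its largest-magnitude component is
    positive.
    """

    evals: np.ndarray
    evecs: np.ndarray
    evals_raw: np.ndarray
    clamped: np.ndarray

    @property
    def lambda1(self) -> np.ndarray:
        return self.evals[..., 0]

    @property
    def lambda2(self) -> np.ndarray:
        return self.evals[..., 1]

    @property
    def lambda3(self) -> np.ndarray:
        return self.evals[..., 2]


def eigendecompose(tensor: np.ndarray, check_finite: bool = True) -> EigenSystem:
    """Diagonalise symmetric tensor(s) of shape (..., 3, 3).

    Eigenvalues are returned in descending order; negative eigenvalues are
    clamped to zero (flagged per voxel) so downstream shape metrics stay in
    [0, 1] under noise.  NaN tensors (masked voxels) propagate NaN.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) tensor array; got {tensor.shape}")
    nanvox = np.isnan(tensor).any(axis=(-2, -1))
    if check_finite:
        bad = np.isinf(tensor).any(axis=(-2, -1))
        if np.any(bad):
            idx = np.argwhere(bad)[0]
            raise NonFiniteTensorError(
                f"non-finite tensor at voxel index {tuple(idx)}"
            )
    work = np.where(nanvox[..., None, None], 0.0, tensor)
    w, v = np.linalg.eigh(work)
    # eigh returns ascending; flip to descending
    w = w[..., ::-1]
    v = v[..., ::-1]
    # sign convention: largest-|component| of each eigenvector positive
    comp = np.argmax(np.abs(v), axis=-2, keepdims=True)
    sign = np.sign(np.take_along_axis(v, comp, axis=-2))
    sign = np.where(sign == 0, 1.0, sign)
    v = v * sign
    clamped = np.any(w < 0, axis=-1) & ~nanvox
    w_cl = np.clip(w, 0.0, None)
    w = np.where(nanvox[..., None], np.nan, w)
    w_cl = np.where(nanvox[..., None], np.nan, w_cl)
    v = np.where(nanvox[..., None, None], np.nan, v)
    return EigenSystem(evals=w_cl, evecs=v, evals_raw=w, clamped=clamped)


def tensor_from_eigensystem(evals, evecs) -> np.ndarray:
    """Reassemble ``e · diag(λ) · eᵀ`` (inverse of :func:`eigendecompose`)."""
    evals = np.asarray(evals, dtype=float)
    evecs = np.asarray(evecs, dtype=float)
    return np.einsum("...ik,...k,...jk->...ij", evecs, evals, evecs)


# ---------------------------------------------------------------------------
# shape metrics


def _as_evals(eigs) -> np.ndarray:
    if isinstance(eigs, EigenSystem):
        return eigs.evals
    return np.asarray(eigs, dtype=float)


def fractional_anisotropy(eigs) -> np.ndarray:
    """FA of eigenvalue triples (last axis length 3); in [0, 1].

    The all-zero (fully degenerate) triple maps to FA = 0.
    """
    lam = _as_evals(eigs)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = 0.5 * ((l1 - l2) ** 2 + (l1 - l3) ** 2 + (l2 - l3) ** 2)
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(num / den)
    fa = np.where(den == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


@dataclass(frozen=True)
class ShapeMetrics:
    """Per-voxel tensor shape metrics (arrays broadcast alike).

    ``cl + cp + cs = 1`` wherever the trace is positive; voxels with
    nonpositive trace carry NaN sentinels.
    """

    fa: np.ndarray
    cl: np.ndarray
    cp: np.ndarray
    cs: np.ndarray
    trace: np.ndarray
    md: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"fa": self.fa, "cl": self.cl, "cp": self.cp,
                "cs": self.cs, "md": self.md}


def westin_metrics(eigs) -> ShapeMetrics:
    """Westin linear/planar/spherical shape metrics plus FA, trace and MD.

    Requires non-negative eigenvalues with positive trace; voxels with
    trace ≤ 0 (or NaN input) yield NaN in all metrics.
    """
    lam = _as_evals(eigs)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    trace = l1 + l2 + l3
    with np.errstate(invalid="ignore", divide="ignore"):
        cl = (l1 - l2) / trace
        cp = 2.0 * (l2 - l3) / trace
        cs = 3.0 * l3 / trace
    invalid = ~(trace > 0)
    cl = np.where(invalid, np.nan, cl)
    cp = np.where(invalid, np.nan, cp)
    cs = np.where(invalid, np.nan, cs)
    fa = np.where(invalid, np.nan, fractional_anisotropy(lam))
    tr = np.where(invalid, np.nan, trace)
    return ShapeMetrics(fa=fa, cl=cl, cp=cp, cs=cs, trace=tr, md=tr / 3.0)


#: Tolerance on |cl+cp+cs − 1| beyond which a triple is rejected instead of
#: renormalised (printed triples are rounded and may sum to 0.99–1.01).
SHAPE_SUM_TOL = 0.02


def shape_to_eigenvalues(cl, cp, cs, trace=1.0) -> np.ndarray:
    """Invert the Westin decomposition: (cl, cp, cs, trace) → (λ1, λ2, λ3).

    Triples whose sum is within ±0.02 of 1 are renormalised by their sum;
    larger deviations raise :class:`InconsistentShapeError`.  Returned
    eigenvalues satisfy λ1 ≥ λ2 ≥ λ3 ≥ 0 and sum to ``trace``.
    """
    cl = np.asarray(cl, dtype=float)
    cp = np.asarray(cp, dtype=float)
    cs = np.asarray(cs, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.any(cl < 0) or np.any(cp < 0) or np.any(cs < 0):
        raise InconsistentShapeError("shape metrics must be non-negative")
    if np.any(~(trace > 0)):
        raise InconsistentShapeError("trace must be positive")
    s = cl + cp + cs
    if np.any(np.abs(s - 1.0) > SHAPE_SUM_TOL):
        worst = float(np.max(np.abs(s - 1.0)))
        raise InconsistentShapeError(
            f"cl+cp+cs deviates from 1 by {worst:.4f} (> {SHAPE_SUM_TOL})"
        )
    cl, cp, cs = cl / s, cp / s, cs / s
    l3 = cs * trace / 3.0
    l2 = l3 + cp * trace / 2.0
    l1 = cl * trace + l2
    return np.stack([l1, l2, l3], axis=-1)


# shape-triangle corners: linear bottom-left, planar bottom-right,
# spherical at the apex of an equilateral triangle with unit base.
_SQRT3_2 = np.sqrt(3.0) / 2.0


def shape_triangle_coords(cl, cp, cs=None) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric plot coordinates of (cl, cp, cs) in the shape triangle.

    Pure linear maps to (0, 0), pure planar to (1, 0), pure spherical to
    the apex (0.5, √3/2); the map is affine and invertible on the simplex
    (see :func:`triangle_to_shape`).  Accepts a :class:`ShapeMetrics` as
    the single first argument.
    """
    if cs is None and isinstance(cl, ShapeMetrics):
        m = cl
        cl, cp, cs = m.cl, m.cp, m.cs
    cl = np.asarray(cl, dtype=float)
    cp = np.asarray(cp, dtype=float)
    cs = np.asarray(cs, dtype=float)
    x = cp + 0.5 * cs
    y = _SQRT3_2 * cs
    return x, y


def triangle_to_shape(x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`shape_triangle_coords` on the simplex."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cs = y / _SQRT3_2
    cp = x - 0.5 * cs
    cl = 1.0 - cp - cs
    return cl, cp, cs


# ---------------------------------------------------------------------------
# results object


class TensorFitResults:
    """Results of a :class:`DiffusionTensorModel` fit.

    Attributes
    ----------
    params : ndarray, shape (..., 7)
        ``[ln S0, dxx, dyy, dzz, dxy, dxz, dyz]`` per voxel (NaN where the
        voxel was masked or had no positive signal).
    n_clamped_signals : ndarray
        Per-voxel count of nonpositive signals clamped before the log.
    """

    def __init__(self, model, params, method, n_clamped_signals, usable):
        self.model = model
        self.params = params
        self.method = method
        self.n_clamped_signals = n_clamped_signals
        self.usable = usable

    @cached_property
    def s0(self) -> np.ndarray:
        return np.exp(self.params[..., 0])

    @cached_property
    def tensor(self) -> np.ndarray:
        """Symmetric tensor array, shape (..., 3, 3), in mm²/s."""
        p = self.params
        D = np.empty(p.shape[:-1] + (3, 3), dtype=float)
        D[..., 0, 0] = p[..., 1]
        D[..., 1, 1] = p[..., 2]
        D[..., 2, 2] = p[..., 3]
        D[..., 0, 1] = D[..., 1, 0] = p[..., 4]
        D[..., 0, 2] = D[..., 2, 0] = p[..., 5]
        D[..., 1, 2] = D[..., 2, 1] = p[..., 6]
        return D

    @cached_property
    def eigensystem(self) -> EigenSystem:
        return eigendecompose(self.tensor)

    @cached_property
    def shape_metrics(self) -> ShapeMetrics:
        return westin_metrics(self.eigensystem)

    # convenient flat accessors
    @property
    def evals(self) -> np.ndarray:
        return self.eigensystem.evals

    @property
    def evecs(self) -> np.ndarray:
        return self.eigensystem.evecs

    @property
    def fa(self) -> np.ndarray:
        return self.shape_metrics.fa

    @property
    def cl(self) -> np.ndarray:
        return self.shape_metrics.cl

    @property
    def cp(self) -> np.ndarray:
        return self.shape_metrics.cp

    @property
    def cs(self) -> np.ndarray:
        return self.shape_metrics.cs

    @property
    def md(self) -> np.ndarray:
        return self.shape_metrics.md

    @property
    def eval_clamped(self) -> np.ndarray:
        return self.eigensystem.clamped

    @cached_property
    def fitted_signals(self) -> np.ndarray:
        return np.exp(self.params @ self.model.design.T)

    @cached_property
    def resid_log(self) -> np.ndarray:
        S = self.model.signals
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(np.where(S > 0, S, np.nan))
        return y - self.params @ self.model.design.T

    @cached_property
    def sigma2(self) -> np.ndarray:
        """Per-voxel residual variance of the log-signal regression."""
        r = self.resid_log
        dof = self.model.scheme.n - 7
        if dof <= 0:
            return np.full(r.shape[:-1], np.nan)
        return np.nansum(r**2, axis=-1) / dof

    @cached_property
    def bse(self) -> np.ndarray:
        """Per-voxel standard errors of the 7 parameters (OLS formula)."""
        X = self.model.design
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        return np.sqrt(self.sigma2[..., None] * xtx_inv_diag)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        n_vox = int(self.usable.sum())
        lines = [
            "Diffusion tensor fit",
            "====================",
            f"estimator:          {self.method}",
            f"measurements:       {self.model.scheme.n} "
            f"({int(self.model.scheme.b0_mask.sum())} b=0)",
            f"voxels fit:         {n_vox}",
            f"signals clamped:    {int(self.n_clamped_signals.sum())}",
            f"evals clamped vox:  {int(np.sum(self.eval_clamped & self.usable))}",
        ]
        if self.params.ndim == 1:
            lines.append("")
            lines.append(f"{'param':>6} {'estimate':>14} {'std err':>12}")
            for name, est, se in zip(DESIGN_COLUMNS, self.params, self.bse):
                lines.append(f"{name:>6} {est:14.6e} {se:12.3e}")
            m = self.shape_metrics
            lines.append("")
            lines.append(
                f"FA={float(m.fa):.4f}  CL={float(m.cl):.4f}  "
                f"CP={float(m.cp):.4f}  CS={float(m.cs):.4f}  "
                f"MD={float(m.md):.4e} mm²/s"
            )
        else:
            m = self.shape_metrics
            lines.append("")
            lines.append(f"{'metric':>6} {'mean':>10} {'sd':>10}")
            for name, arr in m.as_dict().items():
                vals = arr[self.usable]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    lines.append(
                        f"{name:>6} {vals.mean():10.4f} {vals.std(ddof=1 if vals.size > 1 else 0):10.4f}"
                    )
        return "\n".join(lines)


def fit_tensor(signals, scheme: GradientScheme, method: str = "ols") -> TensorFitResults:
    """Convenience wrapper: fit tensor(s) for a signal array.

    Equivalent to ``DiffusionTensorModel(signals, scheme).fit(method)``.
    """
    return DiffusionTensorModel(signals, scheme).fit(method=method)
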