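"""Diffusion gradient schemes and FSL-dialect bval/bvec tables.

A :class:`GradientScheme` pairs b-values (s/mm²) with unit gradient
directions expressed in the image coordinate frame (FSL convention:
``*.bval`` is one whitespace-separated row of N values, ``*.bvec`` is
three rows x/y/z of N values each).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "DIRECTIONS_20",
    "default_protocol",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "GradientTableError",
]


class GradientTableError(ValueError):
    """Malformed or inconsistent gradient table."""


#: Fixed 20-point electrostatic-repulsion direction set (antipodally
#: symmetric Coulomb energy minimised, hemisphere-canonicalised).  Shipped
#: as a versioned constant so phantom datasets are reproducible across
#: releases; the acquisition it emulates used 20 directions at b=1000 s/mm²
#: but did not publish the direction vectors.
DIRECTIONS_20 = np.array([
    (-0.124847267336606, -0.261498043378981, +0.957095571584963),
    (+0.043295184215658, +0.365240131451999, +0.929906002454366),
    (+0.451124953774889, +0.033682107838723, +0.891824978172929),
    (-0.493463350730130, +0.115222361568527, +0.862100764922967),
    (+0.303348267981356, -0.534761935370306, +0.788675789403805),
    (-0.658944297509185, -0.390720474121891, +0.642751836934047),
    (-0.485591712402107, +0.600611782420599, +0.635189873710169),
    (+0.138731297851874, +0.776798517724388, +0.614278186050529),
    (-0.182026425055133, -0.780255069358410, +0.598388174450457),
    (+0.799140969850591, +0.237491826039349, +0.552242105304142),
    (+0.749515386901871, -0.408885377870627, +0.520614475942547),
    (-0.884593431020324, +0.148904379039216, +0.441952426963171),
    (+0.605675402758596, +0.697562984229420, +0.382835721329865),
    (+0.364295488419826, -0.872227095745296, +0.326356692232113),
    (-0.306140355165879, +0.920149462719621, +0.244137357230930),
    (-0.606888059201203, -0.766662333593924, +0.209560849987101),
    (+0.983187303769945, -0.133628791928873, +0.124443045901390),
    (-0.772167092779173, +0.631400710482318, +0.071352110209755),
    (-0.929322350978121, -0.362320944599734, +0.071298675140951),
    (+0.166220439833644, +0.986088529819391, +0.000420404736668),
])
DIRECTIONS_20.setflags(write=False)

_UNIT_TOL = 1e-6
_UNIT_WARN = 1e-3


@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions for one acquisition.

    Parameters
    ----------
    bvals : array-like, shape (N,)
        Diffusion weightings in s/mm².  At least one entry must be 0.
    bvecs : array-like, shape (N, 3)
        Gradient directions.  Entries with ``b > 0`` must be unit vectors
        (within 1e-6 after normalisation); b=0 entries may be zero vectors.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(
                f"bvecs must have shape (N, 3); got {bvecs.shape}"
            )
        if bvals.shape[0] != bvecs.shape[0]:
            raise GradientTableError(
                f"bvals ({bvals.shape[0]}) and bvecs ({bvecs.shape[0]}) "
                "lengths differ"
            )
        if bvals.shape[0] < 7:
            raise GradientTableError(
                f"need at least 7 measurements for a tensor fit; got {bvals.shape[0]}"
            )
        if not np.any(bvals == 0):
            raise GradientTableError("scheme has no b=0 measurement")
        nz = bvals > 0
        norms = np.linalg.norm(bvecs[nz], axis=1)
        if np.any(norms == 0):
            raise GradientTableError("zero-length direction with nonzero b-value")
        if np.any(np.abs(norms - 1.0) > _UNIT_WARN):
            warnings.warn(
                "bvec norms deviate from unit length by more than 1e-3; "
                "renormalising",
                stacklevel=2,
            )
        bvecs = bvecs.copy()
        bvecs[nz] /= norms[:, None]
        bvals.setflags(write=False)
        bvecs.setflags(write=False)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(self, "_validated", True)

    @property
    def n(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


def default_protocol(b: float = 1000.0) -> GradientScheme:
    """One b=0 volume plus 20 directions at ``b`` s/mm² (default 1000).

    This mirrors the emulated ex-vivo acquisition: a single unweighted
    volume followed by 20 diffusion directions at b = 1000 s/mm².
    """
    bvals = np.concatenate([[0.0], np.full(20, float(b))])
    bvecs = np.vstack([np.zeros(3), DIRECTIONS_20])
    return GradientScheme(bvals, bvecs)


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientScheme:
    """Read an FSL-dialect gradient table pair."""
    bval_rows = _read_rows(bval_path)
    if len(bval_rows) != 1:
        raise GradientTableError(
            f"{bval_path}: expected one row of b-values, found {len(bval_rows)}"
        )
    bvec_rows = _read_rows(bvec_path)
    if len(bvec_rows) != 3:
        raise GradientTableError(
            f"{bvec_path}: expected three rows (x, y, z), found {len(bvec_rows)}"
        )
    bvals = np.array(bval_rows[0], dtype=float)
    bvecs = np.array(bvec_rows, dtype=float)
    if bvecs.shape[1] != bvals.shape[0]:
        raise GradientTableError(
            f"bval count {bvals.shape[0]} does not match bvec count {bvecs.shape[1]}"
        )
    return GradientScheme(bvals, bvecs.T)


def write_bvals_bvecs(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write a scheme as an FSL-dialect bval/bvec pair."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for axis in range(3):
            fh.write(" ".join(f"{v:.15g}" for v in scheme.bvecs[:, axis]) + "\n")


def _read_rows(path: str | Path) -> list[list[float]]:
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                try:
                    rows.append([float(tok) for tok in line.split()])
                except ValueError as exc:
                    raise GradientTableError(f"{path}: non-numeric entry ({exc})")
    return rows
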