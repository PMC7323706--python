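"""Synthetic neuraxial DWI phantom.

Builds stylised labelled geometries (a coronal brain slab or an axial
spinal-cord block), paints each labelled voxel with a ground-truth
diffusion tensor whose eigenvalues realise the structure's target
(cl, cp, cs) shape triple, simulates the mono-exponential DWI signal for
a one-b0 + 20-direction b=1000 s/mm² protocol, and corrupts magnitudes
with Rician noise.

The geometry is deliberately schematic (ellipsoid shells, slabs,
cylindrical sectors): the quantity under test is shape-metric recovery
per labelled region, not anatomical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientScheme, default_protocol, write_bvals_bvecs
from .tensor import (
    fractional_anisotropy,
    shape_to_eigenvalues,
    tensor_from_eigensystem,
)
from .tissue import LABEL_NAMES, TissueSpec, specs_for_group

__all__ = [
    "PhantomConfig",
    "AcquisitionProtocol",
    "PhantomDataset",
    "GeometryError",
    "build_label_volume",
    "paint_tensor_field",
    "simulate_signal",
    "crossing_signal",
    "add_rician_noise",
    "generate_dataset",
]


class GeometryError(ValueError):
    """Grid cannot accommodate the requested labelled regions."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Gradient scheme plus baseline signal amplitude.

    Defaults emulate the target acquisition: one b=0 volume and 20
    directions at b = 1000 s/mm², S0 = 1000 arbitrary units.
    """

    scheme: GradientScheme = field(default_factory=default_protocol)
    s0: float = 1000.0

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic subject.

    ``snr`` is the S0-to-noise ratio (σ = s0 / snr); ``math.inf`` (or
    ``numpy.inf``) requests a noiseless dataset.  ``voxel_size`` defaults
    to the emulated 200 µm isotropic resolution.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 0.2
    group: str = "WT"
    snr: float = np.inf
    seed: int = 0
    geometry: str = "brain_slab"
    s0: float = 1000.0
    s0_background: float = 50.0
    noise_model: str = "rician"  # rician | gaussian

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise GeometryError(
                f"grid {self.shape} too small: need at least 16 voxels per axis"
            )
        if self.geometry not in ("brain_slab", "spinal_cord"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not self.snr > 0:
            raise ValueError("snr must be positive (use inf for noiseless)")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine placing the grid centre at the origin."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -0.5 * self.voxel_size * (np.array(self.shape) - 1)
        return aff


# ---------------------------------------------------------------------------
# geometry

_MIN_REGION_VOXELS = 50


def build_label_volume(config: PhantomConfig) -> np.ndarray:
    """Integer label volume for the configured geometry (background = 0).

    brain_slab: cortical shell (CCX=1), two hippocampal blobs (Hipp=2), a
    left-right corpus-callosum strip (CC=3) and two rostro-caudal
    corticospinal columns (CST=4) inside an ellipsoidal brain mask.

    spinal_cord: an axial cord cylinder with inner gray matter (SC_gm=5)
    containing two anterior-horn wedges (GM_ah=6), and a white-matter
    annulus partitioned into anterior (Af=7), lateral (Lf=8) and
    posterior (Pf=9) funiculi.
    """
    nx, ny, nz = config.shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    labels = np.zeros(config.shape, dtype=np.int16)

    if config.geometry == "brain_slab":
        ax, ay, az = 0.46 * nx, 0.46 * ny, 0.46 * nz
        rho = np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2
                      + ((z - cz) / az) ** 2)
        brain = rho <= 1.0
        # dorsal cortical shell
        ccx = brain & (rho >= 0.80) & (y > cy + 0.15 * ny)
        labels[ccx] = 1
        # corpus callosum: thin dorsal left-right slab under the cortex
        cc = (
            brain & (labels == 0)
            & (np.abs(y - (cy + 0.22 * ny)) <= max(1.5, 0.045 * ny))
            & (np.abs(z - cz) <= 0.18 * nz)
            & (rho <= 0.78)
        )
        labels[cc] = 3
        # hippocampi: two lateral ellipsoidal blobs below the CC
        for sx in (-1.0, 1.0):
            hx, hy, hz = cx + sx * 0.22 * nx, cy + 0.05 * ny, cz
            blob = (((x - hx) / (0.10 * nx)) ** 2
                    + ((y - hy) / (0.09 * ny)) ** 2
                    + ((z - hz) / (0.16 * nz)) ** 2) <= 1.0
            labels[blob & (labels == 0) & brain] = 2
        # corticospinal tract: two ventral rostro-caudal columns
        for sx in (-1.0, 1.0):
            col = (
                np.sqrt((x - (cx + sx * 0.10 * nx)) ** 2
                        + (y - (cy - 0.25 * ny)) ** 2) <= max(2.0, 0.055 * nx)
            )
            labels[col & (labels == 0) & brain] = 4
        required = (1, 2, 3, 4)
    else:  # spinal_cord
        R = 0.42 * min(nx, ny)
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
        theta = np.arctan2(x - cx, y - cy)  # 0 at +y (anterior), ±π posterior
        cord = r <= R
        gm = cord & (r <= 0.45 * R)
        wm = cord & ~gm
        labels[gm] = 5
        horns = gm & (r >= 0.18 * R) & (np.abs(theta) <= np.deg2rad(50))
        labels[horns] = 6
        af = wm & (np.abs(theta) <= np.deg2rad(45))
        pf = wm & (np.abs(theta) >= np.deg2rad(135))
        labels[af] = 7
        labels[pf] = 9
        labels[wm & (labels == 0)] = 8
        required = (5, 6, 7, 8, 9)

    for lab in required:
        n = int(np.sum(labels == lab))
        if n < _MIN_REGION_VOXELS:
            raise GeometryError(
                f"region {LABEL_NAMES[lab]} has only {n} voxels "
                f"(< {_MIN_REGION_VOXELS}) on grid {config.shape}"
            )
    return labels


# ---------------------------------------------------------------------------
# tensor painting

class SpecMissingError(KeyError):
    """A label present in the volume has no matching TissueSpec."""


def _orthonormal_frame(e1: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel right-handed frames (n, 3, 3) with given first column and a
    random in-plane rotation of the transverse pair."""
    n = e1.shape[0]
    # helper axis least aligned with e1, per voxel
    helper = np.eye(3)[np.argmin(np.abs(e1), axis=1)]
    e2 = helper - (helper * e1).sum(axis=1, keepdims=True) * e1
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    c, s = np.cos(psi)[:, None], np.sin(psi)[:, None]
    e2r = c * e2 + s * e3
    e3r = -s * e2 + c * e3
    return np.stack([e1, e2r, e3r], axis=-1)


def _sample_directions(spec: TissueSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if spec.orientation_mode == "coherent":
        return np.tile(axis, (n, 1))
    if spec.orientation_mode == "dispersed" and spec.dispersion_kappa > 0:
        from scipy.stats import vonmises_fisher

        return vonmises_fisher(mu=axis, kappa=spec.dispersion_kappa).rvs(
            n, random_state=rng
        ).reshape(n, 3)
    # random: uniform on the sphere
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def paint_tensor_field(
    labels: np.ndarray,
    specs: list[TissueSpec],
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign a ground-truth tensor to every labelled voxel.

    Returns ``(tensors, e1)`` with shapes ``labels.shape + (3, 3)`` and
    ``labels.shape + (3,)``.  Background voxels get zero tensors.  Each
    voxel's eigenvalues are the inverse-map image of its structure's
    shape triple; the principal axis follows the spec's orientation mode.
    Deterministic for a fixed seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_label = {s.label: s for s in specs}
    present = [int(l) for l in np.unique(labels) if l != 0]
    missing = [l for l in present if l not in by_label]
    if missing:
        names = ", ".join(LABEL_NAMES.get(l, str(l)) for l in missing)
        raise SpecMissingError(f"no TissueSpec for label(s): {names}")

    tensors = np.zeros(labels.shape + (3, 3), dtype=float)
    e1_field = np.zeros(labels.shape + (3,), dtype=float)
    for lab in present:
        spec = by_label[lab]
        vox = labels == lab
        n = int(vox.sum())
        evals = spec.eigenvalues
        e1 = _sample_directions(spec, n, rng)
        frames = _orthonormal_frame(e1, rng)
        D = tensor_from_eigensystem(np.tile(evals, (n, 1)), frames)
        tensors[vox] = D
        e1_field[vox] = e1
    return tensors, e1_field


# ---------------------------------------------------------------------------
# signal simulation and noise


def simulate_signal(
    tensors: np.ndarray, protocol: AcquisitionProtocol, s0=None
) -> np.ndarray:
    """Noiseless mono-exponential signals S_i = s0·exp(−b_i g_iᵀ D g_i).

    ``tensors`` has shape (..., 3, 3); ``s0`` may be a scalar or an array
    broadcastable to the leading shape (defaults to the protocol's s0).
    Returns shape (..., N).
    """
    scheme = protocol.scheme
    q = np.einsum("ni,...ij,nj->...n", scheme.bvecs, tensors, scheme.bvecs)
    s0 = protocol.s0 if s0 is None else np.asarray(s0)[..., None]
    return s0 * np.exp(-scheme.bvals * q)


def crossing_signal(
    tensor_a: np.ndarray,
    tensor_b: np.ndarray,
    f: float,
    protocol: AcquisitionProtocol,
    s0=None,
) -> np.ndarray:
    """Two-compartment crossing-fibre signal.

    ``S_i = s0·[(1−f)·exp(−b_i g_iᵀ D_a g_i) + f·exp(−b_i g_iᵀ D_b g_i)]``
    — the stand-in for voxels containing two fibre populations, which a
    single-tensor fit renders more planar/spherical as ``f`` grows.
    """
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mixing fraction f={f} outside [0, 1]")
    sa = simulate_signal(tensor_a, protocol, s0=s0)
    sb = simulate_signal(tensor_b, protocol, s0=s0)
    return (1.0 - f) * sa + f * sb


def add_rician_noise(
    signals: np.ndarray,
    snr: float,
    s0: float = 1000.0,
    seed: int | np.random.Generator | None = 0,
    model: str = "rician",
) -> np.ndarray:
    """Corrupt magnitude signals with Rician noise of σ = s0 / snr.

    ``S_noisy = sqrt((S + n1)² + n2²)`` with independent
    ``n1, n2 ~ N(0, σ)`` per sample; this is the magnitude of a complex
    Gaussian perturbation, the standard magnitude-MRI noise model.
    ``snr=inf`` returns the input unchanged.  ``model="gaussian"`` adds
    ``n1`` only (debugging aid).
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    signals = np.asarray(signals, dtype=float)
    if np.isinf(snr):
        return signals.copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, signals.shape)
    if model == "gaussian":
        return signals + n1
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class PhantomDataset:
    """In-memory synthetic subject: DWI stack, labels and ground truth."""

    dwi: np.ndarray
    labels: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme
    truth: pd.DataFrame
    manifest: dict
    tensors: np.ndarray | None = None


def generate_dataset(
    config: PhantomConfig,
    specs: list[TissueSpec] | None = None,
    protocol: AcquisitionProtocol | None = None,
    out_dir: str | Path | None = None,
    keep_tensors: bool = False,
) -> PhantomDataset:
    """Build one synthetic subject end to end.

    Child seeds for geometry jitter, orientation sampling and noise are
    spawned deterministically from ``config.seed``, so identical configs
    yield identical datasets.  When ``out_dir`` is given, writes
    ``dwi.nii.gz``, ``labels.nii.gz``, ``dwi.bval``/``dwi.bvec``, a
    ``ground_truth.csv`` table and a ``manifest.json``.
    """
    if protocol is None:
        protocol = AcquisitionProtocol(s0=config.s0)
    if specs is None:
        specs = specs_for_group(config.group, config.geometry)

    ss = np.random.SeedSequence(int(config.seed))
    geom_ss, orient_ss, noise_ss = ss.spawn(3)
    orient_rng = np.random.default_rng(orient_ss)
    noise_rng = np.random.default_rng(noise_ss)

    labels = build_label_volume(config)
    tensors, _ = paint_tensor_field(labels, specs, seed=orient_rng)

    signal = simulate_signal(tensors, protocol)
    background = labels == 0
    # air-like background: weak unstructured baseline, exercised by masking
    signal[background] = config.s0_background

    crossing = [s for s in specs if s.crossing_fraction > 0]
    for spec in crossing:
        vox = labels == spec.label
        Da = tensors[vox]
        Db = _rotated_tensors(Da, spec.crossing_angle, orient_rng)
        signal[vox] = crossing_signal(Da, Db, spec.crossing_fraction, protocol)

    dwi = add_rician_noise(
        signal, config.snr, s0=config.s0, seed=noise_rng,
        model=config.noise_model,
    )

    truth = _truth_table(labels, specs)
    manifest = {
        "tool": "dtishape",
        "config": {**asdict(config), "snr": repr(config.snr)},
        "protocol": {
            "n_measurements": protocol.scheme.n,
            "bvals": protocol.scheme.bvals.tolist(),
            "s0": protocol.s0,
        },
        "seed_children": {
            "geometry": geom_ss.entropy,
            "orientation": orient_ss.spawn_key,
            "noise": noise_ss.spawn_key,
        },
        "specs": [
            {k: v for k, v in asdict(s).items()} for s in specs
        ],
    }

    ds = PhantomDataset(
        dwi=dwi, labels=labels, affine=config.affine,
        scheme=protocol.scheme, truth=truth, manifest=manifest,
        tensors=tensors if keep_tensors else None,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _rotated_tensors(
    tensors: np.ndarray, angle_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Rotate each tensor by ``angle_deg`` about a random axis ⊥ its e1."""
    from scipy.spatial.transform import Rotation

    from .tensor import eigendecompose

    eig = eigendecompose(tensors)
    e1 = eig.evecs[..., 0]
    helper = np.eye(3)[np.argmin(np.abs(e1), axis=-1)]
    perp = np.cross(e1, helper)
    perp /= np.linalg.norm(perp, axis=-1, keepdims=True)
    psi = rng.uniform(0.0, 2.0 * np.pi, size=e1.shape[0])
    # random perpendicular axis: rotate `perp` about e1 by psi
    perp = (Rotation.from_rotvec(e1 * psi[:, None]).apply(perp))
    R = Rotation.from_rotvec(perp * np.deg2rad(angle_deg)).as_matrix()
    return np.einsum("nij,njk,nlk->nil", R, tensors, R)


def _truth_table(labels: np.ndarray, specs: list[TissueSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        cl, cp, cs = s.shape_triple
        rows.append({
            "structure": s.name,
            "group": s.group,
            "label": s.label,
            "cl": cl, "cp": cp, "cs": cs,
            "fa_implied": float(fractional_anisotropy(s.eigenvalues)),
            "trace": s.trace,
            "orientation_mode": s.orientation_mode,
            "crossing_fraction": s.crossing_fraction,
            "n_voxels": int(np.sum(labels == s.label)),
        })
    return pd.DataFrame(rows)


def _write_dataset(ds: PhantomDataset, out_dir: Path) -> None:
    from .io import write_dwi, write_labels

    out_dir.mkdir(parents=True, exist_ok=True)
    write_dwi(ds.dwi, ds.affine, ds.scheme, out_dir / "dwi")
    write_labels(ds.labels, ds.affine, out_dir / "labels.nii.gz")
    ds.truth.to_csv(out_dir / "ground_truth.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(_jsonable(ds.manifest), fh, indent=2, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
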