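"""Tissue specifications for the neuraxial phantom.

Each :class:`TissueSpec` gives one labelled structure its ground-truth
tensor shape for one experimental group: wild-type controls (WT), the
presymptomatic G93A-SOD1 stage at postnatal day 80 (P80), and the
symptomatic stage at day 120 (P120).  The (cl, cp, cs) targets are the
published per-structure group means for this mouse model; they drive the
simulator via the inverse Westin map, so a noiseless simulate-and-fit
round trip recovers them exactly.

Structures
----------
Gray matter: prefrontal cortex (CCX), hippocampus (Hipp), spinal-cord gray
matter (SC_gm) and its anterior horn (GM_ah).  White matter: corpus
callosum (CC, left-right), corticospinal tract (CST, rostro-caudal),
spinal-cord white matter split into anterior / lateral / posterior
funiculi (Af, Lf, Pf, all rostro-caudal).

The anterior funiculus and anterior horn have published values only for
WT and P120; their P80 entry falls back to the parent SC_wm / SC_gm
triple, which preserves the monotone WT→P80→P120 ordering.  Lf and Pf use
the SC_wm triples throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueSpec",
    "GROUPS",
    "LABELS",
    "LABEL_NAMES",
    "WM_STRUCTURES",
    "GM_STRUCTURES",
    "SHAPE_TARGETS",
    "FA_TARGETS",
    "TRACT_AXES",
    "DEFAULT_TRACE",
    "DEFAULT_CROSSING_FRACTIONS",
    "specs_for_group",
    "shape_target",
]

GROUPS = ("WT", "P80", "P120")

#: label code → structure name (brain slab uses 1–4, spinal cord 5–9)
LABELS = {
    "CCX": 1,
    "Hipp": 2,
    "CC": 3,
    "CST": 4,
    "SC_gm": 5,
    "GM_ah": 6,
    "Af": 7,
    "Lf": 8,
    "Pf": 9,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

WM_STRUCTURES = ("CC", "CST", "SC_wm", "Af", "Lf", "Pf")
GM_STRUCTURES = ("CCX", "Hipp", "SC_gm", "GM_ah")

#: (structure, group) → (cl, cp, cs) group-mean shape targets.  Printed
#: triples are rounded to 2–3 decimals and may sum to 0.99–1.01; they are
#: renormalised where consumed.
SHAPE_TARGETS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("CCX", "WT"): (0.050, 0.090, 0.860),
    ("CCX", "P80"): (0.050, 0.070, 0.870),
    ("CCX", "P120"): (0.050, 0.070, 0.880),
    ("Hipp", "WT"): (0.060, 0.100, 0.830),
    ("Hipp", "P80"): (0.060, 0.080, 0.860),
    ("Hipp", "P120"): (0.050, 0.070, 0.880),
    ("SC_gm", "WT"): (0.080, 0.140, 0.790),
    ("SC_gm", "P80"): (0.070, 0.120, 0.810),
    ("SC_gm", "P120"): (0.060, 0.110, 0.830),
    ("CC", "WT"): (0.200, 0.160, 0.650),
    ("CC", "P80"): (0.140, 0.140, 0.720),
    ("CC", "P120"): (0.120, 0.130, 0.740),
    ("CST", "WT"): (0.230, 0.150, 0.620),
    ("CST", "P80"): (0.200, 0.130, 0.680),
    ("CST", "P120"): (0.180, 0.110, 0.710),
    ("SC_wm", "WT"): (0.410, 0.150, 0.440),
    ("SC_wm", "P80"): (0.350, 0.150, 0.490),
    ("SC_wm", "P120"): (0.290, 0.140, 0.560),
    # lumbar sub-regions (WT / P120 only in the source data)
    ("Af", "WT"): (0.390, 0.152, 0.477),
    ("Af", "P120"): (0.296, 0.135, 0.567),
    ("GM_ah", "WT"): (0.075, 0.132, 0.792),
    ("GM_ah", "P120"): (0.067, 0.115, 0.822),
}

#: published per-group FA means (reported alongside the shape triples;
#: not exactly the FA implied by the triples, because both were averaged
#: voxelwise in the source data).  Used for reporting only.
FA_TARGETS: dict[tuple[str, str], float] = {
    ("CCX", "WT"): 0.160, ("CCX", "P80"): 0.140, ("CCX", "P120"): 0.120,
    ("Hipp", "WT"): 0.180, ("Hipp", "P80"): 0.150, ("Hipp", "P120"): 0.130,
    ("SC_gm", "WT"): 0.220, ("SC_gm", "P80"): 0.200, ("SC_gm", "P120"): 0.180,
    ("CC", "WT"): 0.420, ("CC", "P80"): 0.330, ("CC", "P120"): 0.300,
    ("CST", "WT"): 0.460, ("CST", "P80"): 0.410, ("CST", "P120"): 0.370,
    ("SC_wm", "WT"): 0.640, ("SC_wm", "P80"): 0.560, ("SC_wm", "P120"): 0.510,
}

#: fall-back parent for structures without their own target in a group
_PARENT = {"Af": "SC_wm", "Lf": "SC_wm", "Pf": "SC_wm", "GM_ah": "SC_gm"}

#: coherent-tract principal axes in the image frame (x = left-right,
#: y = anterior-posterior, z = rostro-caudal)
TRACT_AXES = {
    "CC": (1.0, 0.0, 0.0),
    "CST": (0.0, 0.0, 1.0),
    "Af": (0.0, 0.0, 1.0),
    "Lf": (0.0, 0.0, 1.0),
    "Pf": (0.0, 0.0, 1.0),
}

#: default tensor trace in mm²/s (MD 0.5e-3, plausible for fixed ex-vivo
#: tissue at room temperature); shape metrics are trace-invariant.
DEFAULT_TRACE = 1.5e-3

#: qualitative two-compartment crossing-fibre mixture weights used by the
#: opt-in crossing preset (callosal layers cross more than the compact
#: corticospinal and spinal tracts); not part of the recovery targets.
DEFAULT_CROSSING_FRACTIONS = {"CC": 0.20, "CST": 0.05, "Af": 0.05,
                              "Lf": 0.05, "Pf": 0.05}


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth tissue description for one structure in one group."""

    label: int
    name: str
    group: str
    cl: float
    cp: float
    cs: float
    trace: float = DEFAULT_TRACE
    orientation_mode: str = "coherent"  # coherent | dispersed | random
    dispersion_kappa: float = 50.0
    crossing_fraction: float = 0.0
    crossing_angle: float = 90.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.orientation_mode not in ("coherent", "dispersed", "random"):
            raise ValueError(f"unknown orientation mode {self.orientation_mode!r}")
        s = self.cl + self.cp + self.cs
        if abs(s - 1.0) > 0.02:
            raise ValueError(
                f"{self.name}/{self.group}: cl+cp+cs = {s:.4f} deviates from 1 "
                "by more than 0.02"
            )
        if not self.trace > 0:
            raise ValueError("trace must be positive")
        if not 0.0 <= self.crossing_fraction <= 0.5:
            raise ValueError("crossing_fraction must lie in [0, 0.5]")

    @property
    def shape_triple(self) -> tuple[float, float, float]:
        """The renormalised (cl, cp, cs) target."""
        s = self.cl + self.cp + self.cs
        return (self.cl / s, self.cp / s, self.cs / s)

    @property
    def eigenvalues(self) -> np.ndarray:
        """Ground-truth eigenvalues implied by the shape target and trace."""
        from .tensor import shape_to_eigenvalues

        return shape_to_eigenvalues(self.cl, self.cp, self.cs, self.trace)


def shape_target(structure: str, group: str) -> tuple[float, float, float]:
    """Target triple for a structure/group, applying the parent fallback."""
    key = (structure, group)
    if key in SHAPE_TARGETS:
        return SHAPE_TARGETS[key]
    parent = _PARENT.get(structure)
    if parent is not None and (parent, group) in SHAPE_TARGETS:
        return SHAPE_TARGETS[(parent, group)]
    raise KeyError(f"no shape target for {structure}/{group}")


def specs_for_group(
    group: str,
    geometry: str = "brain_slab",
    trace: float = DEFAULT_TRACE,
    with_crossing: bool = False,
) -> list[TissueSpec]:
    """Default tissue specs for one group and phantom geometry.

    White-matter tracts are coherently oriented along their tract axis
    with mild orientation dispersion; gray matter is isotropic-ish with
    random principal directions.  ``with_crossing`` enables the
    qualitative two-fibre mixture preset in white matter (off by default:
    the shape targets are defined for the single-tensor ground truth).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if geometry == "brain_slab":
        names = ["CCX", "Hipp", "CC", "CST"]
    elif geometry == "spinal_cord":
        names = ["SC_gm", "GM_ah", "Af", "Lf", "Pf"]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    specs = []
    for name in names:
        cl, cp, cs = shape_target(name, group)
        is_wm = name in WM_STRUCTURES
        f = DEFAULT_CROSSING_FRACTIONS.get(name, 0.0) if with_crossing else 0.0
        specs.append(
            TissueSpec(
                label=LABELS[name],
                name=name,
                group=group,
                cl=cl, cp=cp, cs=cs,
                trace=trace,
                orientation_mode="dispersed" if is_wm else "random",
                dispersion_kappa=100.0 if is_wm else 0.0,
                crossing_fraction=f,
                axis=TRACT_AXES.get(name, (0.0, 0.0, 1.0)),
            )
        )
    return specs
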