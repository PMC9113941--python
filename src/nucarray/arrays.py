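"""Pairwise nucleosome stacking metrics, stack detection, H1-compatibility
classification and a coarse steric screen for linker-histone placement.

Stacking is quantified geometrically: distance between core centers, angle
between the disc normals (best-fit plane normals of the 147 core
centroids), tilt between the dyad axes, and the lateral offset of the
centers perpendicular to the mean normal.  A pair is called *stacked*
(face-to-face) when the centers are close and the discs near-parallel;
the aligned/offset split mirrors the distinction between closely packed
stacks and slightly offset ones.  All thresholds are configurable.

H1 compatibility follows the delta-beta rule: a nucleosome is compatible
with on-dyad linker-histone binding when the linker trajectories on every
defined side deviate from the H1-bound reference by at most a threshold
(default 6 degrees, inclusive).  The steric screen maps a pseudo-atom H1
footprint from the reference onto the target nucleosome by core
superposition and counts environment points that fall within the contact
cutoff of a footprint sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .frames import NucleosomeFrame, superpose
from .trajectory import SIDES, DeltaAngles

if TYPE_CHECKING:  # pragma: no cover
    from .io import BasePairCentroidTrack

__all__ = [
    "StackThresholds",
    "StackGeometry",
    "NucleosomeUnit",
    "H1Call",
    "H1Footprint",
    "disc_normal",
    "stack_metrics",
    "detect_stacks",
    "classify_h1",
    "steric_screen",
    "DEFAULT_H1_THRESHOLD",
]

DEFAULT_H1_THRESHOLD = 6.0


@dataclass(frozen=True)
class StackThresholds:
    """Geometric thresholds of the stacking classification (Å, degrees)."""

    max_center_distance: float = 75.0
    max_normal_angle: float = 30.0
    aligned_offset: float = 15.0


@dataclass(frozen=True)
class NucleosomeUnit:
    """One nucleosome of an array, ready for pairwise analysis."""

    label: str
    frame: NucleosomeFrame
    core_centroids: np.ndarray
    h1_observed: Optional[bool] = None


@dataclass(frozen=True)
class StackGeometry:
    """Pairwise stacking metrics; symmetric under pair exchange."""

    pair: Tuple[str, str]
    center_distance: float
    normal_angle: float
    dyad_tilt: float
    lateral_offset: float
    interface_class: str  # "face-to-face aligned" | "face-to-face offset" | "not stacked"

    @property
    def stacked(self) -> bool:
        return self.interface_class != "not stacked"


def disc_normal(core_centroids: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane of the core centroids.

    The smallest principal component of the wrapped DNA is the disc
    normal; the sign is arbitrary and callers must fold angles to
    [0, 90] accordingly.
    """
    pts = np.asarray(core_centroids, dtype=float)
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[2] / np.linalg.norm(vt[2])


def _folded_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two axes, folded to [0, 90] degrees."""
    c = abs(float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(min(1.0, c))))


def stack_metrics(
    unit_a: NucleosomeUnit,
    unit_b: NucleosomeUnit,
    thresholds: StackThresholds = StackThresholds(),
) -> StackGeometry:
    """Stacking geometry of one nucleosome pair."""
    ca = np.asarray(unit_a.core_centroids, dtype=float).mean(axis=0)
    cb = np.asarray(unit_b.core_centroids, dtype=float).mean(axis=0)
    delta = cb - ca
    center_distance = float(np.linalg.norm(delta))
    na = disc_normal(unit_a.core_centroids)
    nb = disc_normal(unit_b.core_centroids)
    normal_angle = _folded_angle(na, nb)
    dyad_tilt = _folded_angle(unit_a.frame.u, unit_b.frame.u)
    # Mean normal with both axes folded into the same hemisphere.
    nb_folded = nb if float(na @ nb) >= 0.0 else -nb
    mean_normal = na + nb_folded
    mean_normal = mean_normal / np.linalg.norm(mean_normal)
    lateral = delta - (delta @ mean_normal) * mean_normal
    lateral_offset = float(np.linalg.norm(lateral))
    if (
        center_distance <= thresholds.max_center_distance
        and normal_angle <= thresholds.max_normal_angle
    ):
        cls = (
            "face-to-face aligned"
            if lateral_offset <= thresholds.aligned_offset
            else "face-to-face offset"
        )
    else:
        cls = "not stacked"
    pair = tuple(sorted((unit_a.label, unit_b.label)))
    return StackGeometry(
        pair=pair,
        center_distance=center_distance,
        normal_angle=normal_angle,
        dyad_tilt=dyad_tilt,
        lateral_offset=lateral_offset,
        interface_class=cls,
    )


def detect_stacks(
    units: Sequence[NucleosomeUnit],
    thresholds: StackThresholds = StackThresholds(),
) -> List[StackGeometry]:
    """All stacked pairs of an array, sorted by center distance."""
    if len(units) < 2:
        raise ValueError("stack detection needs at least 2 nucleosomes")
    stacked = []
    for i in range(len(units)):
        for j in range(i + 1, len(units)):
            geom = stack_metrics(units[i], units[j], thresholds)
            if geom.stacked:
                stacked.append(geom)
    return sorted(stacked, key=lambda g: g.center_distance)


@dataclass(frozen=True)
class H1Call:
    """H1-binding-compatibility call for one nucleosome.

    ``compatible`` is ``True``/``False`` or ``None`` (indeterminate: no
    defined linker side) — the indeterminate state is never coerced to a
    boolean.
    """

    label: str
    delta_beta: Dict[str, Optional[float]]
    avg_delta_beta: Optional[float]
    compatible: Optional[bool]
    threshold: float
    observed_h1: Optional[bool] = None

    @property
    def status(self) -> str:
        if self.compatible is None:
            return "indeterminate"
        return "compatible" if self.compatible else "incompatible"


def classify_h1(
    delta: DeltaAngles,
    threshold: float = DEFAULT_H1_THRESHOLD,
    label: str = "",
    observed_h1: Optional[bool] = None,
) -> H1Call:
    """Compatible iff every defined side has delta-beta <= threshold
    (inclusive).  Zero defined sides yield an indeterminate call."""
    defined = [v for v in delta.delta_beta.values() if v is not None]
    if not defined:
        compatible: Optional[bool] = None
    else:
        compatible = all(v <= threshold for v in defined)
    return H1Call(
        label=label,
        delta_beta=dict(delta.delta_beta),
        avg_delta_beta=delta.avg_delta_beta,
        compatible=compatible,
        threshold=threshold,
        observed_h1=observed_h1,
    )


@dataclass(frozen=True)
class H1Footprint:
    """Coarse pseudo-atom footprint of a bound linker histone: sphere
    centers (Å) with per-sphere radii."""

    centers: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if centers.shape[0] != radii.shape[0]:
            raise ValueError("footprint centers and radii must have equal length")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)

    def __len__(self) -> int:
        return len(self.radii)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "H1Footprint":
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return H1Footprint(centers=self.centers @ rot.T + t, radii=self.radii)


@dataclass(frozen=True)
class StericReport:
    clash_count: int
    contacts: List[Tuple[int, int, float]]  # (sphere index, environment index, distance)
    footprint: H1Footprint  # mapped onto the target


def steric_screen(
    target: "BasePairCentroidTrack",
    reference: "BasePairCentroidTrack",
    footprint: Optional[H1Footprint],
    environment: np.ndarray,
    cutoff: float = 4.0,
) -> StericReport:
    """Screen an H1 placement on the target nucleosome for steric clashes.

    The footprint (given in the reference coordinate system) is mapped
    onto the target by superposing the reference core onto the target
    core.  An environment point clashes with a footprint sphere when its
    distance to the sphere center is below ``cutoff + radius``.
    """
    if footprint is None or len(footprint) == 0:
        raise ValueError("steric screen requires a non-empty H1 footprint")
    transform = superpose(reference.core_centroids, target.core_centroids)
    mapped = footprint.transformed(transform.rotation, transform.translation)
    env = np.atleast_2d(np.asarray(environment, dtype=float))
    contacts: List[Tuple[int, int, float]] = []
    if env.size:
        dists = cdist(mapped.centers, env)
        limits = (cutoff + mapped.radii)[:, None]
        for si, ei in zip(*np.nonzero(dists < limits)):
            contacts.append((int(si), int(ei), float(dists[si, ei])))
    contacts.sort(key=lambda c: c[2])
    return StericReport(clash_count=len(contacts), contacts=contacts, footprint=mapped)
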