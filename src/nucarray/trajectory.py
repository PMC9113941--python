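"""Linker-DNA trajectory angles alpha/beta and deviations from a reference.

Each linker side (entry or exit) of a nucleosome is summarized by one
direction vector between two base-pair centroids:

* point 4 — the base pair 5 bp *into* the core, counted inclusively from
  that side's core edge,
* point 5 — the base pair 10 bp *outside* the core on that side.

The signed angle alpha is measured between the dyad axis ``u`` and the
linker vector projected onto the nucleosome-disc plane; beta is the same
construction in the plane perpendicular to the disc.  Delta angles compare
a target nucleosome against a reference mononucleosome whose core has been
rigid-body superposed onto the target core: the reference linker vectors
are mapped through the fitted transform and the unsigned angle between the
projected target and reference vectors is reported per side, together with
averages over the defined sides.  With consistent signed angles this equals
|signed angle difference|, and both readings are computed by the same code
path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, Optional, Tuple

import numpy as np

from .frames import NucleosomeFrame, build_frame, superpose

if TYPE_CHECKING:  # pragma: no cover
    from .io import BasePairCentroidTrack

__all__ = [
    "SIDES",
    "LinkerVector",
    "TrajectoryAngles",
    "DeltaAngles",
    "linker_vector",
    "linker_vectors",
    "projected_angle",
    "trajectory_angles",
    "delta_angles",
]

SIDES = ("entry", "exit")

#: Default register of the linker-vector endpoints, in bp counted
#: inclusively from the core edge.
INTO_CORE_OFFSET = 5
OUTSIDE_CORE_OFFSET = 10

#: Minimum norm of a projected vector for the angle to be defined.
PROJECTION_TOL = 1e-9


@dataclass(frozen=True)
class LinkerVector:
    """Direction of one linker side, or an explicitly undefined result."""

    side: str
    p4: Optional[np.ndarray]
    p5: Optional[np.ndarray]
    direction: Optional[np.ndarray]
    defined: bool

    @classmethod
    def undefined(cls, side: str) -> "LinkerVector":
        return cls(side=side, p4=None, p5=None, direction=None, defined=False)


@dataclass(frozen=True)
class TrajectoryAngles:
    """Signed alpha/beta (degrees) per linker side; ``None`` marks NA."""

    alpha: Dict[str, Optional[float]]
    beta: Dict[str, Optional[float]]

    def defined_sides(self) -> Tuple[str, ...]:
        return tuple(s for s in SIDES if self.beta.get(s) is not None)


@dataclass(frozen=True)
class DeltaAngles:
    """Per-side deviations from a superposed reference (degrees, >= 0)."""

    delta_alpha: Dict[str, Optional[float]]
    delta_beta: Dict[str, Optional[float]]
    avg_delta_alpha: Optional[float]
    avg_delta_beta: Optional[float]
    reference_id: str
    superposition_rmsd: float = 0.0
    #: Signed angles of the target, for reporting.
    target_angles: Optional[TrajectoryAngles] = field(default=None, compare=False)

    def defined_sides(self) -> Tuple[str, ...]:
        return tuple(s for s in SIDES if self.delta_beta.get(s) is not None)


def linker_vector(
    track: "BasePairCentroidTrack",
    side: str,
    into_offset: int = INTO_CORE_OFFSET,
    outside_offset: int = OUTSIDE_CORE_OFFSET,
) -> LinkerVector:
    """Linker direction on one side of the core.

    Returns an undefined (not an error) result whenever point 5 falls
    outside the track or onto an unresolved base pair.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    track.require_complete_core()
    if side == "entry":
        i4 = track.core_start + into_offset - 1
        i5 = track.core_start - outside_offset
    else:
        core_end = track.core_start + track.core_len - 1
        i4 = core_end - into_offset + 1
        i5 = core_end + outside_offset
    if i5 < 1 or i5 > len(track):
        return LinkerVector.undefined(side)
    p4 = track.centroid(i4)
    p5 = track.centroid(i5)
    if not (np.all(np.isfinite(p4)) and np.all(np.isfinite(p5))):
        return LinkerVector.undefined(side)
    direction = p5 - p4
    norm = float(np.linalg.norm(direction))
    if norm < PROJECTION_TOL:
        return LinkerVector.undefined(side)
    return LinkerVector(side=side, p4=p4, p5=p5, direction=direction / norm, defined=True)


def linker_vectors(
    track: "BasePairCentroidTrack",
    into_offset: int = INTO_CORE_OFFSET,
    outside_offset: int = OUTSIDE_CORE_OFFSET,
) -> Dict[str, LinkerVector]:
    """Both linker sides of a track."""
    return {
        side: linker_vector(track, side, into_offset, outside_offset)
        for side in SIDES
    }


def projected_angle(
    frame: NucleosomeFrame,
    vec: np.ndarray,
    plane: str,
) -> Optional[float]:
    """Signed angle (degrees, in (-180, 180]) from the dyad axis to ``vec``
    projected onto the chosen plane (``"disc"`` or ``"perp"``).

    The sign comes from the plane's second basis vector (``w`` for the
    disc plane, the orthonormalized ``v`` for the perpendicular plane).
    Returns ``None`` when the projection is shorter than the tolerance.
    """
    if plane == "disc":
        _, second = frame.disc_plane
    elif plane == "perp":
        _, second = frame.perp_plane
    else:
        raise ValueError(f"plane must be 'disc' or 'perp', got {plane!r}")
    d = np.asarray(vec, dtype=float)
    x = float(d @ frame.u)
    y = float(d @ second)
    if math.hypot(x, y) < PROJECTION_TOL:
        return None
    angle = math.degrees(math.atan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return angle


def trajectory_angles(
    frame: NucleosomeFrame,
    linkers: Dict[str, LinkerVector],
) -> TrajectoryAngles:
    """Signed alpha/beta per side; undefined sides propagate as ``None``."""
    alpha: Dict[str, Optional[float]] = {}
    beta: Dict[str, Optional[float]] = {}
    for side in SIDES:
        lv = linkers.get(side)
        if lv is None or not lv.defined:
            alpha[side] = None
            beta[side] = None
            continue
        alpha[side] = projected_angle(frame, lv.direction, "disc")
        beta[side] = projected_angle(frame, lv.direction, "perp")
    return TrajectoryAngles(alpha=alpha, beta=beta)


def _projected_separation(
    frame: NucleosomeFrame,
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    plane: str,
) -> Optional[float]:
    """Unsigned angle (degrees) between the projections of two vectors."""
    ang_a = projected_angle(frame, vec_a, plane)
    ang_b = projected_angle(frame, vec_b, plane)
    if ang_a is None or ang_b is None:
        return None
    diff = abs(ang_a - ang_b) % 360.0
    if diff > 180.0:
        diff = 360.0 - diff
    return diff


def delta_angles(
    target: "BasePairCentroidTrack",
    reference: "BasePairCentroidTrack",
    reference_id: str = "reference",
    into_offset: int = INTO_CORE_OFFSET,
    outside_offset: int = OUTSIDE_CORE_OFFSET,
    upstream: int = 38,
    downstream: int = 39,
) -> DeltaAngles:
    """Deviation of the target's linker angles from a reference nucleosome.

    The reference core centroids are superposed onto the target core
    (Kabsch); the reference linker vectors are carried through the fitted
    rotation, and per defined target side the unsigned angle between the
    projected target and mapped-reference directions is reported (delta
    beta in the perpendicular plane, delta alpha in the disc plane).
    """
    target.require_complete_core()
    reference.require_complete_core()
    if target.core_len != reference.core_len:
        raise ValueError(
            f"core lengths differ: target {target.core_len} vs reference {reference.core_len}"
        )
    ref_linkers = linker_vectors(reference, into_offset, outside_offset)
    undefined_ref = [s for s in SIDES if not ref_linkers[s].defined]
    if undefined_ref:
        raise ValueError(
            f"reference {reference_id!r} must have both linkers defined; "
            f"missing: {', '.join(undefined_ref)}"
        )
    transform = superpose(reference.core_centroids, target.core_centroids)
    frame = build_frame(target, upstream, downstream)
    tgt_linkers = linker_vectors(target, into_offset, outside_offset)
    tgt_angles = trajectory_angles(frame, tgt_linkers)

    d_alpha: Dict[str, Optional[float]] = {}
    d_beta: Dict[str, Optional[float]] = {}
    for side in SIDES:
        tv = tgt_linkers[side]
        if not tv.defined:
            d_alpha[side] = None
            d_beta[side] = None
            continue
        mapped = transform.apply_vector(ref_linkers[side].direction)
        d_alpha[side] = _projected_separation(frame, tv.direction, mapped, "disc")
        d_beta[side] = _projected_separation(frame, tv.direction, mapped, "perp")

    def _avg(values: Dict[str, Optional[float]]) -> Optional[float]:
        defined = [v for v in values.values() if v is not None]
        return float(np.mean(defined)) if defined else None

    return DeltaAngles(
        delta_alpha=d_alpha,
        delta_beta=d_beta,
        avg_delta_alpha=_avg(d_alpha),
        avg_delta_beta=_avg(d_beta),
        reference_id=reference_id,
        superposition_rmsd=transform.rmsd,
        target_angles=tgt_angles,
    )
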