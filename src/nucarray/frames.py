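"""Per-nucleosome reference frames and rigid-body superposition.

The nucleosome frame is built from three base-pair centroids:

* ``p1`` — the central (dyad) base pair of the 147-bp core,
* ``p2`` — the base pair 38 bp upstream of ``p1``,
* ``p3`` — the base pair 39 bp downstream of ``p1``.

``p2`` and ``p3`` sit on the two different DNA gyres on the far side of the
dyad.  From these points two direction vectors are derived: ``u`` (from the
midpoint of ``p2``/``p3`` toward ``p1``) approximates the dyad axis, and
``v`` (from ``p2`` toward ``p3``) approximates the normal of the nucleosome
disc.  ``w`` is the normalized cross product of ``u`` and ``v``.  Two planes
are spanned by these axes: the *disc* plane span(u, w), in which the linker
angle alpha is measured, and the *perpendicular* plane span(u, v), in which
beta is measured.

Sign conventions: the signed-angle axes (``beta_axis`` for the perpendicular
plane, ``w`` for the disc plane) are pinned to the winding handedness of the
wrapped DNA.  For a physically wound core this coincides with the naive
p2-to-p3 convention; it additionally guarantees that mirroring a structure
through its disc plane flips the sign of beta while leaving alpha unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .io import BasePairCentroidTrack

__all__ = [
    "DegenerateFrameError",
    "NucleosomeFrame",
    "RigidTransform",
    "anchor_indices",
    "build_frame",
    "superpose",
]

#: Angular threshold (radians) below which u and v are considered parallel.
DEGENERACY_TOL = 1e-6

#: Default anchor offsets from the dyad base pair (in bp along strand I).
UPSTREAM_OFFSET = 38
DOWNSTREAM_OFFSET = 39


class DegenerateFrameError(ValueError):
    """Raised when anchor points are (near-)collinear and no frame exists."""


def _unit(vec: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(vec))
    if n == 0.0:
        raise DegenerateFrameError("zero-length vector cannot be normalized")
    return vec / n


@dataclass(frozen=True)
class NucleosomeFrame:
    """Anchor points and orthonormal axes of one nucleosome.

    Attributes
    ----------
    p1, p2, p3:
        Anchor base-pair centroids (Å).
    u:
        Unit dyad-axis approximation, pointing from midpoint(p2, p3) to p1.
    v:
        Unit vector from p2 toward p3 (disc-normal approximation).
    beta_axis:
        Unit vector: component of ``v`` orthogonal to ``u``, sign-pinned by
        the DNA winding handedness.  Second basis vector of the
        perpendicular plane; carries the sign of beta.
    w:
        Unit vector ``u x beta_axis``; second basis vector of the disc
        plane; carries the sign of alpha.  Equals normalize(u x v) up to
        the handedness pinning.
    handedness:
        +1 if the naive Gram-Schmidt axis was kept, -1 if it was flipped.
    """

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    u: np.ndarray
    v: np.ndarray
    beta_axis: np.ndarray
    w: np.ndarray
    handedness: int

    @property
    def disc_plane(self) -> Tuple[np.ndarray, np.ndarray]:
        """Orthonormal basis (u, w) of the nucleosome-disc plane."""
        return self.u, self.w

    @property
    def perp_plane(self) -> Tuple[np.ndarray, np.ndarray]:
        """Orthonormal basis (u, beta_axis) of the plane perpendicular
        to the disc that contains the dyad axis."""
        return self.u, self.beta_axis

    @property
    def disc_normal(self) -> np.ndarray:
        """Unit normal of the disc plane (= beta_axis up to sign)."""
        return self.beta_axis

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "NucleosomeFrame":
        """Return the frame mapped through a rigid motion."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return NucleosomeFrame(
            p1=rot @ self.p1 + t,
            p2=rot @ self.p2 + t,
            p3=rot @ self.p3 + t,
            u=rot @ self.u,
            v=rot @ self.v,
            beta_axis=rot @ self.beta_axis,
            w=rot @ self.w,
            handedness=self.handedness,
        )


def anchor_indices(
    core_start: int,
    core_len: int = 147,
    upstream: int = UPSTREAM_OFFSET,
    downstream: int = DOWNSTREAM_OFFSET,
) -> Tuple[int, int, int]:
    """1-based track indices (i1, i2, i3) of the dyad and flanking anchors.

    ``i1`` is the central base pair of the core, ``i2`` lies ``upstream`` bp
    before it and ``i3`` lies ``downstream`` bp after it.  ``core_len`` must
    be odd so that a central base pair exists, and both offsets must stay
    inside the core.
    """
    if core_len % 2 == 0:
        raise ValueError(f"core length {core_len} has no central base pair (must be odd)")
    if core_start < 1:
        raise ValueError(f"core_start must be >= 1, got {core_start}")
    i1 = core_start + (core_len - 1) // 2
    i2 = i1 - upstream
    i3 = i1 + downstream
    core_end = core_start + core_len - 1
    if not (core_start <= i2 <= core_end and core_start <= i3 <= core_end):
        raise ValueError(
            f"anchor offsets ({upstream} up, {downstream} down) leave the core "
            f"[{core_start}, {core_end}] for dyad index {i1}"
        )
    return i1, i2, i3


def winding_axis(points: np.ndarray) -> np.ndarray:
    """Right-hand-rule rotation axis of an ordered winding point sequence.

    Sums consecutive cross products about the centroid; used only to pin
    the sign of the frame axes to the physical handedness of the DNA wrap.
    """
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    axis = np.cross(centered[:-1], centered[1:]).sum(axis=0)
    return _unit(axis)


def frame_from_anchors(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    wind_axis: np.ndarray,
) -> NucleosomeFrame:
    """Construct a :class:`NucleosomeFrame` from the three anchor points.

    ``wind_axis`` is the right-hand winding axis of the wrapped core DNA,
    used to pin the signs of the angle axes (see module docstring).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    v_raw = p3 - p2
    u_raw = p1 - 0.5 * (p2 + p3)
    u = _unit(u_raw)
    v = _unit(v_raw)
    # Angle between u and v must exceed the degeneracy threshold.
    cross = np.cross(u, v)
    sin_angle = float(np.linalg.norm(cross))
    if sin_angle < DEGENERACY_TOL:
        raise DegenerateFrameError(
            f"anchor points are collinear within {DEGENERACY_TOL} rad: "
            "dyad and gyre-to-gyre directions are parallel"
        )
    # Gram-Schmidt: component of v orthogonal to u.
    v_perp = v - (v @ u) * u
    vhat = _unit(v_perp)
    # Pin the handedness: the beta axis keeps the naive sign exactly when
    # vhat points against the winding axis (true for a physically wrapped
    # left-handed superhelix in this parametrization).
    sign = -1 if float(vhat @ wind_axis) > 0.0 else 1
    beta_axis = sign * vhat
    w = np.cross(u, beta_axis)  # unit by construction (u ⟂ beta_axis)
    return NucleosomeFrame(
        p1=p1, p2=p2, p3=p3, u=u, v=v,
        beta_axis=beta_axis, w=w, handedness=sign,
    )


def build_frame(
    track: "BasePairCentroidTrack",
    upstream: int = UPSTREAM_OFFSET,
    downstream: int = DOWNSTREAM_OFFSET,
) -> NucleosomeFrame:
    """Build the nucleosome frame from a base-pair centroid track.

    Requires a complete (gap-free) core.  Raises
    :class:`DegenerateFrameError` for collinear anchors.
    """
    track.require_complete_core()
    i1, i2, i3 = anchor_indices(track.core_start, track.core_len, upstream, downstream)
    core = track.core_centroids
    return frame_from_anchors(
        track.centroid(i1), track.centroid(i2), track.centroid(i3),
        wind_axis=winding_axis(core),
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform (rotation then translation) plus the
    RMSD of the least-squares fit that produced it."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array of points (or one 3-vector)."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        """Apply the rotation only (for direction vectors)."""
        return self.rotation @ np.asarray(vec, dtype=float)


def superpose(ref_points: np.ndarray, tgt_points: np.ndarray) -> RigidTransform:
    """Least-squares superposition of ``ref_points`` onto ``tgt_points``.

    Kabsch algorithm on the ordered correspondence, with the reflection
    guard: the returned rotation is always proper (det = +1).  Raises
    ``ValueError`` for fewer than 3 points or a collinear configuration.
    """
    ref = np.asarray(ref_points, dtype=float)
    tgt = np.asarray(tgt_points, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {ref.shape} vs {tgt.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    ref_mean = ref.mean(axis=0)
    tgt_mean = tgt.mean(axis=0)
    ref_c = ref - ref_mean
    tgt_c = tgt - tgt_mean
    cov = ref_c.T @ tgt_c
    u_svd, s, vt = np.linalg.svd(cov)
    scale = float(np.linalg.norm(ref_c)) * float(np.linalg.norm(tgt_c))
    if scale > 0 and s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration: rotation is not unique")
    d = float(np.sign(np.linalg.det(vt.T @ u_svd.T)))
    if d == 0.0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u_svd.T
    translation = tgt_mean - rot @ ref_mean
    moved = ref @ rot.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=translation, rmsd=rmsd)
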