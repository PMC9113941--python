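"""End-to-end analysis: tracks -> frames -> angles -> deltas -> stacking
and H1 calls -> report rows.

This is the library entry point behind both the command-line interface and
the example scripts: it takes per-nucleosome base-pair centroid tracks plus
a reference mononucleosome track and produces one result row per
(nucleosome, linker side) in the shape consumed by
:func:`nucarray.io.write_report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .arrays import (
    DEFAULT_H1_THRESHOLD,
    H1Call,
    NucleosomeUnit,
    StackGeometry,
    StackThresholds,
    classify_h1,
    detect_stacks,
    stack_metrics,
)
from .frames import build_frame
from .io import BasePairCentroidTrack
from .trajectory import (
    INTO_CORE_OFFSET,
    OUTSIDE_CORE_OFFSET,
    SIDES,
    DeltaAngles,
    delta_angles,
)

__all__ = ["AnalysisOptions", "AnalysisResult", "analyze_tracks"]


@dataclass(frozen=True)
class AnalysisOptions:
    """Tunable registers and thresholds of one analysis run."""

    h1_threshold: float = DEFAULT_H1_THRESHOLD
    stack_thresholds: StackThresholds = field(default_factory=StackThresholds)
    into_offset: int = INTO_CORE_OFFSET
    outside_offset: int = OUTSIDE_CORE_OFFSET
    upstream: int = 38
    downstream: int = 39


@dataclass
class AnalysisResult:
    """Per-nucleosome deltas, stacking geometry, H1 calls and report rows."""

    array_label: str
    deltas: Dict[str, DeltaAngles]
    calls: Dict[str, H1Call]
    stacks: List[StackGeometry]
    pairwise: List[StackGeometry]
    rows: List[dict]
    warnings: List[str]

    def stack_partner(self, label: str) -> Optional[str]:
        for geom in self.stacks:
            if label in geom.pair:
                return geom.pair[0] if geom.pair[1] == label else geom.pair[1]
        return None


def analyze_tracks(
    tracks: Sequence[BasePairCentroidTrack],
    reference: BasePairCentroidTrack,
    options: AnalysisOptions = AnalysisOptions(),
    array_label: str = "array",
    reference_id: str = "reference",
) -> AnalysisResult:
    """Analyze the nucleosomes of one array against a reference.

    Undefined linker sides propagate as NA rows, never silently as zeros;
    the warnings list records every NA side and any stage irregularity.
    """
    if not tracks:
        raise ValueError("no nucleosome tracks to analyze")
    notes: List[str] = []
    deltas: Dict[str, DeltaAngles] = {}
    calls: Dict[str, H1Call] = {}
    units: List[NucleosomeUnit] = []
    for track in tracks:
        delta = delta_angles(
            track,
            reference,
            reference_id=reference_id,
            into_offset=options.into_offset,
            outside_offset=options.outside_offset,
            upstream=options.upstream,
            downstream=options.downstream,
        )
        deltas[track.label] = delta
        calls[track.label] = classify_h1(
            delta,
            threshold=options.h1_threshold,
            label=track.label,
            observed_h1=track.h1_present,
        )
        units.append(
            NucleosomeUnit(
                label=track.label,
                frame=build_frame(track, options.upstream, options.downstream),
                core_centroids=track.core_centroids,
                h1_observed=track.h1_present,
            )
        )
        for side in SIDES:
            if delta.delta_beta.get(side) is None:
                notes.append(f"{track.label}/{side}: linker side undefined (reported NA)")

    pairwise: List[StackGeometry] = []
    stacks: List[StackGeometry] = []
    if len(units) >= 2:
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                pairwise.append(stack_metrics(units[i], units[j], options.stack_thresholds))
        stacks = detect_stacks(units, options.stack_thresholds)

    tilt_of: Dict[str, Optional[float]] = {u.label: None for u in units}
    partner_of: Dict[str, Optional[str]] = {u.label: None for u in units}
    for geom in stacks:
        a, b = geom.pair
        for this, other in ((a, b), (b, a)):
            if partner_of.get(this) is None:
                partner_of[this] = other
                tilt_of[this] = geom.dyad_tilt

    rows: List[dict] = []
    for track in tracks:
        delta = deltas[track.label]
        call = calls[track.label]
        angles = delta.target_angles
        for side in SIDES:
            rows.append(
                {
                    "array": array_label,
                    "nucleosome": track.label,
                    "side": side,
                    "alpha": angles.alpha.get(side) if angles else None,
                    "beta": angles.beta.get(side) if angles else None,
                    "delta_alpha": delta.delta_alpha.get(side),
                    "delta_beta": delta.delta_beta.get(side),
                    "avg_delta_alpha": delta.avg_delta_alpha,
                    "avg_delta_beta": delta.avg_delta_beta,
                    "stack_partner": partner_of.get(track.label),
                    "dyad_tilt": tilt_of.get(track.label),
                    "h1_call": call.status,
                }
            )
    return AnalysisResult(
        array_label=array_label,
        deltas=deltas,
        calls=calls,
        stacks=stacks,
        pairwise=pairwise,
        rows=rows,
        warnings=notes,
    )
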