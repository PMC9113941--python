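"""Measure linker-DNA trajectory angles on a synthetic mononucleosome.

Builds a single nucleosome whose exit linker is prescribed to leave at
alpha = +15°, beta = -30° (absolute, in the nucleosome's own frame) and
whose entry linker continues the superhelical path naturally, then runs
the frame construction and angle measurement on the resulting base-pair
centroid track.
"""

from nucarray import LinkerSpec, SyntheticArraySpec, build_array, build_frame
from nucarray.trajectory import linker_vectors, trajectory_angles

spec = SyntheticArraySpec(
    n_nucleosomes=1,
    linker_len=30,
    linkers=(LinkerSpec(alpha=15.0, beta=-30.0, relative=False),),
    entry_stub=LinkerSpec(),  # natural tangent continuation
)
track = build_array(spec).track("nuc1")
frame = build_frame(track)
angles = trajectory_angles(frame, linker_vectors(track))

print("side   alpha (deg)   beta (deg)")
for side in ("entry", "exit"):
    print(f"{side:<6} {angles.alpha[side]:>10.3f} {angles.beta[side]:>11.3f}")
print()
print("alpha is the signed angle between the dyad axis and the linker")
print("projected onto the nucleosome-disc plane; beta the same in the")
print("plane perpendicular to the disc.  The exit side reproduces the")
print("prescribed (15, -30) exactly; the entry side shows the natural")
print("angles of a tangent-continued linker.")
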