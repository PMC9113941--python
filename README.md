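# nucarray

Geometry of nucleosome arrays: linker-DNA trajectory angles, nucleosome
stacking metrics and linker-histone (H1) binding compatibility.

## The problem

Nucleosomes in chromatin form regular arrays characterized by the
nucleosome repeat length (NRL) — the 147 bp of core DNA plus the linker
DNA to the next nucleosome.  Arrays with short NRLs are depleted of the
linker histone H1 and permissive to transcription; long-NRL arrays carry
full H1 occupancy.  A geometric mechanism connects the two: in compact
zig-zag arrays the linker DNA emerging from *stacked* nucleosomes is bent
away from the trajectory it adopts on an isolated H1-bound nucleosome, and
the altered trajectory sterically occludes the space the H1 globular
domain needs for its on-dyad binding mode.  As the NRL grows the linkers
relax and H1 binding becomes possible.

`nucarray` implements the quantitative toolkit for this analysis, for
structural biologists working with atomic models of nucleosome arrays:

* **per-nucleosome reference frames** from base-pair centroids: the dyad
  base pair (point 1), the base pairs 38 bp upstream (point 2) and 39 bp
  downstream (point 3) define **u** (dyad-axis approximation, from the
  midpoint of points 2/3 toward point 1), **v** (point 2 → point 3,
  disc-normal approximation) and **w** = normalize(u × v);
* **linker trajectory angles**: each linker side is summarized by the
  vector from the base pair 5 bp inside the core to the base pair 10 bp
  outside it; **α** is the signed angle from **u** to this vector
  projected onto the nucleosome-disc plane span(u, w), **β** the same in
  the perpendicular plane span(u, v);
* **Δα/Δβ**: after least-squares (Kabsch) superposition of a reference
  mononucleosome core onto the target core, the unsigned angle between
  the projected target and reference linker vectors, per side and
  averaged;
* **stacking metrics** for nucleosome pairs (center distance, disc-normal
  angle, dyad tilt, lateral offset) and stack detection;
* an **H1-compatibility classifier**: a nucleosome is compatible with
  on-dyad H1 binding when every defined linker side has Δβ ≤ 6°
  (threshold configurable);
* a coarse **steric screen** mapping a pseudo-atom H1 footprint onto a
  target nucleosome and counting contacts with its environment;
* a **synthetic array generator** producing coarse-grained (one
  pseudo-atom per base pair) nucleosome arrays with analytically known
  ground truth — superhelical 147-bp cores chained by straight linkers of
  30/40/50/60 bp (NRL 177/187/197/207) with prescribed per-linker exit
  angles — so the entire pipeline is testable without external data.

Input structures are read from mmCIF/PDB; a small YAML registry maps DNA
chains and residue ranges to per-nucleosome base-pair tracks.

## Worked example

```sh
python examples/h1_occupancy.py
```

prints the compatibility matrix of the four packaged array presets
(`avg Δβ` in parentheses, `+H1` = compatible):

```
NRL   nuc1          nuc2          nuc3          nuc4
177   -H1 ( 8.0°)   +H1 ( 2.0°)   -H1 (15.0°)   +H1 ( 2.5°)
187   +H1 ( 4.0°)   +H1 ( 2.0°)   -H1 ( 8.0°)   +H1 ( 2.5°)
197   +H1 ( 3.0°)   +H1 ( 2.0°)   -H1 ( 5.5°)   +H1 ( 2.0°)
207   +H1 ( 2.0°)   +H1 ( 1.0°)   +H1 ( 2.5°)   +H1 ( 1.5°)
```

The stacked nucleosomes 1 and 3 deviate strongly from the H1-bound
reference at the 177-bp repeat and relax progressively as the NRL grows
(nucleosome 1 becomes compatible from 187 bp, nucleosome 3 only at
207 bp), while the non-stacked nucleosomes 2 and 4 are compatible at
every repeat length.  `examples/stacking.py` shows the corresponding
zig-zag topology (nucleosomes 1/3 face-to-face ~60 Å apart), and
`examples/steric_screen.py` the steric side of the story — 11 footprint
contacts at the bent 4×177 nucleosome 1 versus none anywhere in 4×207.

The same pipeline runs on real structures from the shell:

```sh
nucarray analyze --structures model.cif --registry registry.yaml \
    --reference builtin --out results/
nucarray validate --seed 1 --replicates 200 --out validation/
```

`examples/deposited_models.py` shows the setup for user-downloaded
deposited models (an H1-bound mononucleosome as reference versus array
nucleosomes as targets).

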