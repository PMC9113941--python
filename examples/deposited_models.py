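"""Delta-beta analysis of deposited atomic models (user-supplied files).

The same pipeline that runs on the synthetic generator applies to real
coordinate files: an H1-bound mononucleosome serves as the reference
(e.g. PDB entry 7K5Y) and a nucleosome of an array model as the target
(e.g. the nucleosome-4 models 7PEZ or 7PF3).  Because this package ships
no third-party coordinates, download the mmCIF files yourself and write a
registry mapping the DNA chains and residue ranges of each model to
base-pair indices (see the registry schema in nucarray.io.load_registry);
then this script computes per-side delta angles, e.g.::

    python examples/deposited_models.py 7k5y.cif 7k5y_registry.yaml \\
        7pez.cif 7pez_registry.yaml

For models with full H1 occupancy at nucleosome 4, the measured delta
beta values are expected at or below ~6 degrees per defined side.
"""

import sys

from nucarray import delta_angles, extract_track, load_registry, read_structure

if len(sys.argv) != 5:
    print(__doc__)
    sys.exit(0)

ref_structure, ref_registry, tgt_structure, tgt_registry = sys.argv[1:5]

reference = extract_track(
    read_structure(ref_structure), load_registry(ref_registry).entries[0]
)
target = extract_track(
    read_structure(tgt_structure), load_registry(tgt_registry).entries[0]
)
d = delta_angles(target, reference, reference_id=ref_structure)
print(f"superposition rmsd over the core: {d.superposition_rmsd:.2f} Å")
for side in ("entry", "exit"):
    db = d.delta_beta[side]
    da = d.delta_alpha[side]
    print(f"{side}: delta beta = {'NA' if db is None else f'{db:.2f}°'}, "
          f"delta alpha = {'NA' if da is None else f'{da:.2f}°'}")
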