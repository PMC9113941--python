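"""Reading atomic models, mapping them to base-pair centroid tracks, and
writing tabular reports.

An :class:`AtomModel` is a flat carrier of the ATOM/HETATM records of one
structure (first model of multi-model files).  A user-supplied registry
(YAML) maps DNA chains and residue ranges to base-pair indices per
nucleosome: each registry entry names the two strands of the duplex, their
residue ranges (equal length, paired antiparallel by position), and where
the 147-bp core starts within the resulting track.  The base-pair centroid
is the arithmetic mean of all non-hydrogen atoms of the two paired
nucleotides (a C1'-only mode is available as a sensitivity check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "AtomModel",
    "StrandRange",
    "RegistryEntry",
    "ArrayRegistry",
    "BasePairCentroidTrack",
    "StructureParseError",
    "RegistryError",
    "TrackGapError",
    "read_structure",
    "load_registry",
    "extract_track",
    "write_report",
    "REPORT_COLUMNS",
]


class StructureParseError(ValueError):
    """A coordinate file could not be parsed or violates model invariants."""


class RegistryError(ValueError):
    """The registry config is malformed or inconsistent with the model."""


class TrackGapError(ValueError):
    """Base pairs required to be present are missing from the model."""


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    position: np.ndarray
    is_hydrogen: bool


@dataclass
class AtomModel:
    """All ATOM/HETATM records of one structure."""

    atoms: List[Atom]
    source: str = ""
    format: str = ""
    _index: Dict[Tuple[str, int], List[Atom]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        index: Dict[Tuple[str, int], List[Atom]] = {}
        for atom in self.atoms:
            if not np.all(np.isfinite(atom.position)):
                raise StructureParseError(
                    f"non-finite coordinates for {atom.chain}/{atom.resnum}/{atom.name}"
                )
            key = (atom.chain, atom.resnum, atom.name)
            if key in seen:
                raise StructureParseError(
                    f"duplicate atom record {atom.chain}/{atom.resnum}/{atom.name} "
                    f"in {self.source or 'model'}"
                )
            seen.add(key)
            index.setdefault((atom.chain, atom.resnum), []).append(atom)
        self._index = index

    def residue_atoms(self, chain: str, resnum: int) -> List[Atom]:
        return self._index.get((chain, resnum), [])

    def chains(self) -> Tuple[str, ...]:
        return tuple(sorted({a.chain for a in self.atoms}))


def read_structure(path, fmt: str = "auto") -> AtomModel:
    """Read a PDB or mmCIF file into an :class:`AtomModel`.

    ``fmt`` is ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from the file).
    Hydrogens are retained but flagged.  Only the first model of
    multi-model files is read, and only the first alternate location of
    each atom is kept.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"structure file not found: {path}")
    formats = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }
    if fmt not in formats:
        raise RegistryError(f"unknown structure format {fmt!r}; use pdb, mmcif or auto")
    try:
        structure = gemmi.read_structure(str(path), format=formats[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError(f"{path} contains no models")
    structure.setup_entities()
    model = structure[0]
    atoms: List[Atom] = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                element = atom.element.name if atom.element else ""
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name.strip(),
                        name=atom.name.strip(),
                        element=element,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        is_hydrogen=(element.upper() in ("H", "D")),
                    )
                )
    if not atoms:
        raise StructureParseError(f"{path} contains no atom records")
    return AtomModel(atoms=atoms, source=str(path), format=fmt)


@dataclass(frozen=True)
class StrandRange:
    chain: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise RegistryError(
                f"strand range end {self.end} precedes start {self.start} (chain {self.chain})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegistryEntry:
    """Mapping of one nucleosome to chains/residues of the model.

    Strand I runs 5'->3' and defines the base-pair order of the track;
    strand J (optional, for single-strand pseudo-atom models) is paired
    antiparallel by position: base pair *k* (0-based along the strand-I
    range) pairs strand-I residue ``start_i + k`` with strand-J residue
    ``end_j - k``.
    """

    label: str
    strand_i: StrandRange
    strand_j: Optional[StrandRange]
    core_start: int
    core_len: int = 147
    h1_chain: Optional[str] = None
    histone_chains: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand_j is not None and len(self.strand_j) != len(self.strand_i):
            raise RegistryError(
                f"nucleosome {self.label!r}: strand ranges have unequal lengths "
                f"({len(self.strand_i)} vs {len(self.strand_j)})"
            )
        if self.core_start < 1:
            raise RegistryError(f"nucleosome {self.label!r}: core start must be >= 1")
        if self.core_start + self.core_len - 1 > len(self.strand_i):
            raise RegistryError(
                f"nucleosome {self.label!r}: core [{self.core_start}, "
                f"{self.core_start + self.core_len - 1}] exceeds track length {len(self.strand_i)}"
            )


@dataclass(frozen=True)
class ArrayRegistry:
    label: str
    entries: Tuple[RegistryEntry, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise RegistryError(f"duplicate nucleosome labels in registry {self.label!r}")


def _parse_strand(raw, context: str) -> StrandRange:
    try:
        return StrandRange(chain=str(raw["chain"]), start=int(raw["start"]), end=int(raw["end"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise RegistryError(f"{context}: strand needs chain/start/end, got {raw!r}") from exc


def load_registry(path) -> ArrayRegistry:
    """Load and validate a registry YAML file.

    Schema::

        label: 4x177
        nucleosomes:
          - label: nuc1
            strand_i: {chain: I, start: 1, end: 217}
            strand_j: {chain: J, start: 492, end: 708}   # optional
            core_start: 31
            core_len: 147            # optional, default 147
            h1_chain: "H1"           # optional annotation
            histone_chains: [C]      # optional
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "nucleosomes" not in raw:
        raise RegistryError(f"registry {path}: top level must be a mapping with 'nucleosomes'")
    entries = []
    for i, item in enumerate(raw["nucleosomes"]):
        if not isinstance(item, dict):
            raise RegistryError(f"registry {path}: nucleosome #{i + 1} is not a mapping")
        label = str(item.get("label", f"nuc{i + 1}"))
        ctx = f"registry {path}, nucleosome {label!r}"
        if "strand_i" not in item:
            raise RegistryError(f"{ctx}: missing strand_i")
        strand_i = _parse_strand(item["strand_i"], ctx)
        strand_j = _parse_strand(item["strand_j"], ctx) if item.get("strand_j") else None
        try:
            core_start = int(item["core_start"])
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(f"{ctx}: missing or invalid core_start") from exc
        entries.append(
            RegistryEntry(
                label=label,
                strand_i=strand_i,
                strand_j=strand_j,
                core_start=core_start,
                core_len=int(item.get("core_len", 147)),
                h1_chain=(str(item["h1_chain"]) if item.get("h1_chain") else None),
                histone_chains=tuple(item.get("histone_chains", []) or ()),
            )
        )
    return ArrayRegistry(label=str(raw.get("label", path.stem)), entries=tuple(entries))


@dataclass
class BasePairCentroidTrack:
    """Ordered base-pair centroids of one nucleosome plus flanking linker.

    ``centroids`` has one row per base pair (5'->3' of strand I); rows of
    NaN mark unresolved base pairs (allowed only outside the core).
    Indexing through :meth:`centroid` is 1-based, matching the bp-counting
    conventions of the analysis.
    """

    centroids: np.ndarray
    core_start: int
    core_len: int
    label: str = ""
    h1_present: bool = False

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError(f"centroids must be (n, 3), got {self.centroids.shape}")
        n = len(self.centroids)
        if self.core_start < 1 or self.core_start + self.core_len - 1 > n:
            raise ValueError(
                f"track {self.label!r}: core [{self.core_start}, "
                f"{self.core_start + self.core_len - 1}] does not fit track of length {n}"
            )

    def __len__(self) -> int:
        return len(self.centroids)

    def centroid(self, i: int) -> np.ndarray:
        """Centroid of base pair ``i`` (1-based)."""
        if not 1 <= i <= len(self):
            raise IndexError(f"base-pair index {i} outside track [1, {len(self)}]")
        return self.centroids[i - 1]

    @property
    def core_centroids(self) -> np.ndarray:
        return self.centroids[self.core_start - 1 : self.core_start - 1 + self.core_len]

    @property
    def entry_linker_len(self) -> int:
        return self.core_start - 1

    @property
    def exit_linker_len(self) -> int:
        return len(self) - (self.core_start + self.core_len - 1)

    def core_gap_indices(self) -> List[int]:
        """1-based track indices of unresolved base pairs inside the core."""
        mask = ~np.all(np.isfinite(self.core_centroids), axis=1)
        return [self.core_start + int(i) for i in np.nonzero(mask)[0]]

    def require_complete_core(self) -> None:
        gaps = self.core_gap_indices()
        if gaps:
            raise TrackGapError(
                f"track {self.label!r}: core has {len(gaps)} unresolved base pair(s) "
                f"at indices {gaps}"
            )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BasePairCentroidTrack":
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return BasePairCentroidTrack(
            centroids=self.centroids @ rot.T + t,
            core_start=self.core_start,
            core_len=self.core_len,
            label=self.label,
            h1_present=self.h1_present,
        )


def _bp_centroid(
    atoms_i: Sequence[Atom],
    atoms_j: Sequence[Atom],
    mode: str,
) -> Optional[np.ndarray]:
    if mode == "heavy":
        selected = [a for a in list(atoms_i) + list(atoms_j) if not a.is_hydrogen]
    elif mode == "c1":
        selected = [a for a in list(atoms_i) + list(atoms_j) if a.name in ("C1'", "C1*")]
    else:
        raise ValueError(f"centroid mode must be 'heavy' or 'c1', got {mode!r}")
    if not selected:
        return None
    return np.mean([a.position for a in selected], axis=0)


def extract_track(
    model: AtomModel,
    entry: RegistryEntry,
    mode: str = "heavy",
) -> BasePairCentroidTrack:
    """Build the base-pair centroid track of one registry entry.

    Base pair *i* is the mean of all non-hydrogen atom positions of
    strand-I residue *i* and its positionally paired strand-J residue
    (``mode="c1"`` restricts to the C1' atoms).  A base pair whose
    nucleotides are entirely missing becomes a NaN row; NaN rows inside
    the core raise :class:`TrackGapError` listing the indices.
    """
    n = len(entry.strand_i)
    centroids = np.full((n, 3), np.nan)
    missing_partner: List[int] = []
    for k in range(n):
        res_i = entry.strand_i.start + k
        atoms_i = model.residue_atoms(entry.strand_i.chain, res_i)
        if entry.strand_j is not None:
            res_j = entry.strand_j.end - k
            atoms_j = model.residue_atoms(entry.strand_j.chain, res_j)
        else:
            atoms_j = []
        if atoms_i and entry.strand_j is not None and not atoms_j:
            missing_partner.append(k + 1)
        c = _bp_centroid(atoms_i, atoms_j, mode)
        if c is not None:
            centroids[k] = c
    h1_present = bool(
        entry.h1_chain is not None
        and any(a.chain == entry.h1_chain for a in model.atoms)
    )
    track = BasePairCentroidTrack(
        centroids=centroids,
        core_start=entry.core_start,
        core_len=entry.core_len,
        label=entry.label,
        h1_present=h1_present,
    )
    gaps = track.core_gap_indices()
    if gaps:
        raise TrackGapError(
            f"nucleosome {entry.label!r}: {len(gaps)} base pair(s) missing inside "
            f"the core at track indices {gaps}"
        )
    if missing_partner and not gaps:
        # Gaps outside the core are tolerated but must not pass silently.
        import warnings

        warnings.warn(
            f"nucleosome {entry.label!r}: paired residue missing for base pair(s) "
            f"{missing_partner} (outside the core)",
            stacklevel=2,
        )
    return track


REPORT_COLUMNS = [
    "array",
    "nucleosome",
    "side",
    "alpha",
    "beta",
    "delta_alpha",
    "delta_beta",
    "avg_delta_alpha",
    "avg_delta_beta",
    "stack_partner",
    "dyad_tilt",
    "h1_call",
]


def write_report(rows: Sequence[dict], path) -> pd.DataFrame:
    """Write per-(nucleosome, side) result rows as a TSV report.

    One row per nucleosome side, deterministic column order, angles in
    degrees with 3 decimals, missing values rendered as ``NA``.  Returns
    the formatted DataFrame.
    """
    if not rows:
        raise ValueError("report rows must be nonempty")
    df = pd.DataFrame(list(rows))
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df = df[REPORT_COLUMNS]
    float_cols = [
        "alpha", "beta", "delta_alpha", "delta_beta",
        "avg_delta_alpha", "avg_delta_beta", "dyad_tilt",
    ]
    out = df.copy()
    for col in float_cols:
        out[col] = [
            "NA" if v is None or (isinstance(v, float) and not np.isfinite(v)) else f"{v:.3f}"
            for v in df[col]
        ]
    for col in ("stack_partner", "h1_call"):
        out[col] = ["NA" if v in (None, "") else str(v) for v in df[col]]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return out
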