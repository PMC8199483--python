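"""Core data model: topology, trajectory, regions, selections, alignments.

Conventions
-----------
* Internal atom indexing is 0-based.
* User-facing residue numbers are the PDB 1-based ``residue_seq`` values;
  region intervals are 1-based inclusive, matching how structural regions of
  an enzyme are tabulated in the literature.
* Solvent is identified by residue name (configurable); a ligand is any
  HETATM residue that is not solvent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .elements import lookup

#: residue names treated as water/solvent by default
DEFAULT_SOLVENT_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP3P", "TIP", "SOL", "SPC"})

#: the twenty standard amino acids (3-letter codes)
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class SelectionError(ValueError):
    """Raised for unknown selection keywords or malformed selection syntax."""


class TopologyError(ValueError):
    """Raised for inconsistent or invalid structural input."""


@dataclass
class StructureModel:
    """Topology plus reference coordinates against which all selections resolve.

    All per-atom attributes are parallel numpy arrays of length ``n_atoms``.
    """

    atom_names: np.ndarray          # str, PDB atom-name convention
    elements: np.ndarray            # str, upper-case symbols
    residue_seq: np.ndarray         # int, PDB numbering (1-based as read)
    residue_names: np.ndarray       # str, 3-letter codes
    chain_ids: np.ndarray           # str
    coords: np.ndarray              # (n_atoms, 3) float64, Å
    record_types: np.ndarray        # "ATOM" | "HETATM"
    masses: np.ndarray = None       # amu
    vdw_radii: np.ndarray = None    # Å
    solvent_names: frozenset = DEFAULT_SOLVENT_NAMES
    source_path: str | None = None
    element_overrides: dict | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        for name in ("atom_names", "elements", "residue_names", "chain_ids", "record_types"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.residue_seq = np.asarray(self.residue_seq, dtype=int)
        n = len(self.atom_names)
        if n == 0:
            raise TopologyError("structure has no atoms")
        if self.coords.shape != (n, 3):
            raise TopologyError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.isfinite(self.coords).all():
            raise TopologyError("non-finite coordinates in structure")
        if self.masses is None or self.vdw_radii is None:
            mr = [
                lookup(el, self.element_overrides,
                       atom_label=f"{self.chain_ids[i]}/{self.residue_names[i]}"
                                  f"{self.residue_seq[i]}/{self.atom_names[i]}")
                for i, el in enumerate(self.elements)
            ]
            self.masses = np.array([m for m, _ in mr])
            self.vdw_radii = np.array([r for _, r in mr])
        if (self.masses <= 0).any() or (self.vdw_radii <= 0).any():
            raise TopologyError("masses and radii must be strictly positive")
        keys = list(zip(self.chain_ids, self.residue_seq, self.atom_names))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise TopologyError(f"duplicate atom (chain, residue, name) = {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    # ---- classification -------------------------------------------------
    def is_solvent(self) -> np.ndarray:
        return np.array([rn in self.solvent_names for rn in self.residue_names])

    def is_protein(self) -> np.ndarray:
        return np.array([
            rt == "ATOM" and rn in STANDARD_AA
            for rt, rn in zip(self.record_types, self.residue_names)
        ])

    def is_ligand(self) -> np.ndarray:
        solv = self.is_solvent()
        return np.array([
            rt == "HETATM" and not s
            for rt, s in zip(self.record_types, solv)
        ])

    # ---- residue bookkeeping --------------------------------------------
    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique ``(chain_id, residue_seq)`` keys in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.residue_seq):
            seen.setdefault((c, int(r)), None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int], np.ndarray]:
        """Map ``(chain, resseq)`` -> atom indices belonging to that residue."""
        out: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_ids, self.residue_seq)):
            out.setdefault((c, int(r)), []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def protein_sequence(self, chain: str | None = None) -> str:
        """One-letter protein sequence in residue order (for alignment matching)."""
        prot = self.is_protein()
        letters = []
        seen = set()
        for i in np.nonzero(prot)[0]:
            key = (self.chain_ids[i], int(self.residue_seq[i]))
            if key in seen or (chain is not None and key[0] != chain):
                continue
            seen.add(key)
            letters.append(AA_3TO1[self.residue_names[i]])
        return "".join(letters)

    def attached_hydrogens(self, cutoff: float = 1.2) -> dict[int, list[int]]:
        """Map heavy-atom index -> indices of covalently attached hydrogens.

        A hydrogen belongs to the nearest same-residue heavy atom within
        ``cutoff`` Å of it (distance fallback of the name-based rule; with
        standard geometries the two coincide).
        """
        res_atoms = self.residue_atoms()
        out: dict[int, list[int]] = {}
        for idxs in res_atoms.values():
            h = [i for i in idxs if self.elements[i] == "H"]
            heavy = [i for i in idxs if self.elements[i] != "H"]
            if not h or not heavy:
                continue
            hc = self.coords[h]
            yc = self.coords[heavy]
            d = np.linalg.norm(hc[:, None, :] - yc[None, :, :], axis=-1)
            for k, hi in enumerate(h):
                j = int(np.argmin(d[k]))
                if d[k, j] < cutoff:
                    out.setdefault(heavy[j], []).append(hi)
        return out


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) bound to a :class:`StructureModel`."""

    coords: np.ndarray                     # (n_frames, n_atoms, 3)
    topology: StructureModel
    frame_interval: float | None = None    # informational, time units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError(f"trajectory coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise TopologyError("trajectory needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise TopologyError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def strided(self, stride: int = 1) -> "Trajectory":
        if stride == 1:
            return self
        return Trajectory(self.coords[::stride], self.topology,
                          self.frame_interval, dict(self.metadata))


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, de-duplicated set of atom indices with a human-readable label."""

    label: str
    atom_ids: np.ndarray

    def __post_init__(self):
        ids = np.asarray(self.atom_ids, dtype=int)
        _, order = np.unique(ids, return_index=True)
        object.__setattr__(self, "atom_ids", ids[np.sort(order)])

    def __len__(self) -> int:
        return len(self.atom_ids)

    def intersect(self, other: "AtomSelection") -> "AtomSelection":
        common = np.intersect1d(self.atom_ids, other.atom_ids)
        return AtomSelection(f"{self.label}&{other.label}", common)


@dataclass
class RegionMap:
    """Named structural regions (fingers, thumb, palm, cord, ...) per enzyme.

    Each entry maps ``(enzyme_label, region_name)`` to a list of 1-based
    inclusive residue-number intervals; multi-interval regions are preserved.
    """

    entries: list[tuple[str, str, list[tuple[int, int]]]]

    def __post_init__(self):
        seen = set()
        for region, enzyme, ranges in self.entries:
            key = (enzyme, region)
            if key in seen:
                raise ValueError(f"duplicate region {region!r} for enzyme {enzyme!r}")
            seen.add(key)
            for a, b in ranges:
                if a > b:
                    raise ValueError(
                        f"region {region!r} ({enzyme!r}): interval start {a} > end {b}"
                    )

    def enzymes(self) -> list[str]:
        return sorted({e for _, e, _ in self.entries})

    def region_names(self, enzyme_label: str) -> list[str]:
        return [r for r, e, _ in self.entries if e == enzyme_label]

    def ranges(self, enzyme_label: str, region_name: str) -> list[tuple[int, int]]:
        for r, e, rngs in self.entries:
            if e == enzyme_label and r == region_name:
                return rngs
        avail = ", ".join(self.region_names(enzyme_label)) or "<none>"
        raise KeyError(
            f"unknown region {region_name!r} for enzyme {enzyme_label!r}; "
            f"available: {avail}"
        )

    def residue_numbers(self, enzyme_label: str, region_name: str) -> np.ndarray:
        rngs = self.ranges(enzyme_label, region_name)
        return np.concatenate([np.arange(a, b + 1) for a, b in rngs])


def region_residue_count(region_map: RegionMap, enzyme_label: str, region_name: str) -> int:
    """Number of residues in a region: sum over intervals of ``end − start + 1``."""
    return sum(b - a + 1 for a, b in region_map.ranges(enzyme_label, region_name))


@dataclass
class AlignedPair:
    """A pairwise sequence alignment with a per-column residue-index map.

    ``column_map[k] = (i, j)`` gives the 0-based ungapped residue index of
    each sequence at alignment column ``k``; a gap is ``None``.
    """

    seq_a: str
    seq_b: str
    column_map: list[tuple[int | None, int | None]] = None
    id_a: str = "A"
    id_b: str = "B"

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"gapped lengths differ: {len(self.seq_a)} vs {len(self.seq_b)}"
            )
        if self.column_map is None:
            cmap, ia, ib = [], 0, 0
            for ca, cb in zip(self.seq_a, self.seq_b):
                a = None if ca == "-" else ia
                b = None if cb == "-" else ib
                ia += ca != "-"
                ib += cb != "-"
                cmap.append((a, b))
            self.column_map = cmap

    @property
    def ungapped_a(self) -> str:
        return self.seq_a.replace("-", "")

    @property
    def ungapped_b(self) -> str:
        return self.seq_b.replace("-", "")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_HIS_N = {("HIS", "ND1"), ("HIS", "NE2")}

_KEYWORDS = (
    "backbone", "calpha", "protein", "solvent", "ligand",
    "acidic-O", "basic-N", "donors", "acceptors", "all",
)


def select_atoms(model: StructureModel, label: str,
                 include_his_basic: bool = False) -> AtomSelection:
    """Resolve a selection keyword or residue-range expression on a model.

    Keywords: ``backbone`` (protein N/CA/C), ``calpha``, ``protein``,
    ``solvent``, ``ligand``, ``acidic-O`` (Asp/Glu carboxylate oxygens),
    ``basic-N`` (Lys NZ, Arg NE/NH1/NH2; His optional), ``donors`` (N/O heavy
    atoms carrying at least one hydrogen), ``acceptors`` (all N/O), ``all``.
    A residue-range expression like ``"resid 10-20,35"`` selects whole
    residues by PDB number.

    Selections are deterministic and order-stable: indices come out in
    topology order.  An empty result is allowed but warned about.
    """
    n = model.n_atoms
    names = model.atom_names
    resnames = model.residue_names
    if label.startswith("resid "):
        wanted: set[int] = set()
        for part in label[6:].split(","):
            part = part.strip()
            if "-" in part[1:]:
                lo, hi = part.rsplit("-", 1) if not part.startswith("-") else (part, part)
                wanted.update(range(int(lo), int(hi) + 1))
            else:
                wanted.add(int(part))
        mask = np.array([int(r) in wanted for r in model.residue_seq])
    elif label == "all":
        mask = np.ones(n, bool)
    elif label == "backbone":
        mask = model.is_protein() & np.isin(names.astype(str), ("N", "CA", "C"))
    elif label == "calpha":
        mask = model.is_protein() & (names.astype(str) == "CA")
    elif label == "protein":
        mask = model.is_protein()
    elif label == "solvent":
        mask = model.is_solvent()
    elif label == "ligand":
        mask = model.is_ligand()
    elif label == "acidic-O":
        mask = np.array([(rn, an) in _ACIDIC_O for rn, an in zip(resnames, names)])
    elif label == "basic-N":
        basic = _BASIC_N | (_HIS_N if include_his_basic else set())
        mask = np.array([(rn, an) in basic for rn, an in zip(resnames, names)])
    elif label == "donors":
        attached = model.attached_hydrogens()
        mask = np.zeros(n, bool)
        for i in attached:
            if model.elements[i] in ("N", "O"):
                mask[i] = True
    elif label == "acceptors":
        mask = np.isin(model.elements.astype(str), ("N", "O"))
    else:
        raise SelectionError(
            f"unknown selection keyword {label!r}; expected one of "
            f"{', '.join(_KEYWORDS)} or a 'resid ...' expression"
        )
    ids = np.nonzero(mask)[0]
    if len(ids) == 0:
        warnings.warn(f"selection {label!r} matched no atoms", stacklevel=2)
    return AtomSelection(label, ids)
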