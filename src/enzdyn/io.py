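"""File readers and writers: PDB (multi-model), DCD, region configs, alignments.

Reading goes through MDAnalysis (PDB topology + coordinates, DCD frames) and
Biopython (aligned FASTA).  Writing of multi-model PDB is done with a small
fixed-width formatter so that element columns, chain ids and coordinate
precision (%8.3f, i.e. 1e-3 Å) are exactly controlled.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import yaml
from Bio import SeqIO

from .model import (
    AlignedPair,
    RegionMap,
    StructureModel,
    TopologyError,
    Trajectory,
)

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_pdb",
    "load_region_map",
    "builtin_region_map",
    "read_alignment",
]

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "SE", "CA", "MN", "CU", "NI"}


def _element_from_name(name: str) -> str:
    """PDB convention fallback: strip digits, take the leading symbol."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    # within ATOM records two-letter symbols are right-justified names ("FE1");
    # CA/C/N/O side-chain names must not be read as calcium/carbon dimers
    if two in _TWO_LETTER and two not in {"CA"}:
        return two
    return stripped[0].upper()


def read_structure(path: str | os.PathLike, *, element_table: dict | None = None,
                   solvent_names=None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    The first MODEL provides the reference coordinates.  Masses and van der
    Waals radii are assigned from the built-in element table (extensible via
    ``element_table``); an atom whose element cannot be resolved is an error.
    HETATM records are retained and classified as ligand or solvent by
    residue name.
    """
    import MDAnalysis as mda

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(path)
        except Exception as exc:  # noqa: BLE001 - surface as input error
            raise TopologyError(f"could not read structure {path!r}: {exc}") from exc
        names = u.atoms.names.astype(object)
        try:
            elements = np.array([e.strip().upper() for e in u.atoms.elements], dtype=object)
        except Exception:
            elements = np.array([""] * len(names), dtype=object)
        for i, el in enumerate(elements):
            if not el:
                elements[i] = _element_from_name(str(names[i]))
        try:
            chains = u.atoms.chainIDs.astype(object)
        except Exception:
            chains = u.atoms.segids.astype(object)
        try:
            records = u.atoms.record_types.astype(object)
        except Exception:
            records = np.array(["ATOM"] * len(names), dtype=object)
        kwargs = {}
        if solvent_names is not None:
            kwargs["solvent_names"] = frozenset(solvent_names)
        return StructureModel(
            atom_names=names,
            elements=elements,
            residue_seq=u.atoms.resids,
            residue_names=u.atoms.resnames.astype(object),
            chain_ids=chains,
            coords=u.atoms.positions.astype(float),
            record_types=records,
            element_overrides=element_table,
            source_path=path,
            **kwargs,
        )


def read_trajectory(path: str | os.PathLike, topology: StructureModel,
                    frame_interval: float | None = None) -> Trajectory:
    """Read a multi-model PDB or a DCD file as a :class:`Trajectory`.

    Frames are loaded in file order; the atom count of every frame must match
    the topology.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.lower().endswith(".dcd"):
        from MDAnalysis.coordinates.DCD import DCDReader

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = DCDReader(path)
            if reader.n_atoms != topology.n_atoms:
                raise TopologyError(
                    f"trajectory {path!r} has {reader.n_atoms} atoms, "
                    f"expected {topology.n_atoms} from topology"
                )
            frames = np.array([ts.positions.astype(float) for ts in reader])
            reader.close()
    else:
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
            if len(u.atoms) != topology.n_atoms:
                raise TopologyError(
                    f"trajectory {path!r} has {len(u.atoms)} atoms, "
                    f"expected {topology.n_atoms} from topology"
                )
            frames = np.array([u.atoms.positions.astype(float) for _ in u.trajectory])
    return Trajectory(frames, topology, frame_interval=frame_interval)


def write_pdb(model: StructureModel, path: str | os.PathLike,
              trajectory: Trajectory | None = None) -> None:
    """Write a structure (or a whole trajectory as MODEL blocks) to PDB.

    Coordinates are printed at the format's %8.3f precision, so a round-trip
    through this writer reproduces them to 1e-3 Å.
    """
    frames = trajectory.coords if trajectory is not None else model.coords[None, :, :]
    lines: list[str] = []
    multi = frames.shape[0] > 1
    for f, frame in enumerate(frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        for i in range(model.n_atoms):
            el = str(model.elements[i])
            name = str(model.atom_names[i])
            # PDB alignment rule: 1-3 char names start in column 14
            fname = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = frame[i]
            lines.append(
                f"{str(model.record_types[i]):<6s}{(i % 99999) + 1:5d} {fname:<4s} "
                f"{str(model.residue_names[i]):<3s} {str(model.chain_ids[i])[:1] or 'A':1s}"
                f"{int(model.residue_seq[i]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {el:>2s}"
            )
        lines.append("ENDMDL" if multi else "TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_ranges(text: str) -> list[tuple[int, int]]:
    ranges = []
    for part in str(text).replace("–", "-").split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            lo, hi = part.split("-", 1)
            ranges.append((int(lo), int(hi)))
        else:
            ranges.append((int(part), int(part)))
    return ranges


def load_region_map(path: str | os.PathLike) -> RegionMap:
    """Load a YAML region definition into a :class:`RegionMap`.

    Expected shape::

        regions:
          NpXyn11A:
            Fingers: "4-62,76-95,199-216"
            Thumb: "137-167"

    Multi-interval regions are preserved as interval lists; validation
    rejects reversed intervals and duplicate region names per enzyme.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "regions" not in doc:
        raise ValueError(f"region config {path!r} must contain a top-level 'regions' map")
    entries = []
    for enzyme, regions in doc["regions"].items():
        for region, spec in regions.items():
            entries.append((str(region), str(enzyme), _parse_ranges(spec)))
    return RegionMap(entries)


def builtin_region_map() -> RegionMap:
    """The packaged GH-11 xylanase region table (NpXyn11A and EvXyn11TS)."""
    here = os.path.dirname(__file__)
    return load_region_map(os.path.join(here, "data", "gh11_regions.yaml"))


def read_alignment(path: str | os.PathLike) -> AlignedPair:
    """Read a pairwise alignment from aligned FASTA (exactly two records)."""
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"alignment must contain exactly 2 records, found {len(records)}")
    a, b = records
    return AlignedPair(str(a.seq).upper(), str(b.seq).upper(), id_a=a.id, id_b=b.id)
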