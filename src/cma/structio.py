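"""Macromolecular structure I/O and slicing primitives.

The in-memory representation is a thin, explicitly ordered hierarchy
(:class:`StructureModel` -> :class:`Chain` -> :class:`Residue` ->
:class:`AtomRecord`) holding author numbering and Å coordinates.
Reading and writing of PDB and mmCIF files is delegated to *biotite*;
this module owns the model data structures and the domain-extraction /
region-erasure operations that downstream reconstruction steps need.

Conventions
-----------
* Author residue numbering, 1-based; ranges are inclusive on both ends.
* Alternate locations are resolved on read to the highest-occupancy
  conformer (ties resolve to the first altloc id in file order, i.e.
  'A' before 'B').
* Hydrogens are retained on read; geometric operations downstream use
  heavy atoms only.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptySelectionError, ParseError, UsageError
from .geometry import RigidTransform

__all__ = [
    "AtomRecord",
    "ResidueRef",
    "Residue",
    "Chain",
    "StructureModel",
    "DomainSpec",
    "read_structure",
    "write_structure",
    "extract_domain",
    "erase_region",
    "select_chains",
    "merge_models",
    "rename_chains",
    "atom_table",
]

#: Residue names treated as solvent and skipped by analysis routines.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass
class AtomRecord:
    """One atom: identity, coordinates and crystallographic bookkeeping."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise UsageError(f"atom {self.serial} {self.name}: non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=self.coords.copy())


@dataclass(frozen=True, order=True)
class ResidueRef:
    """Identity of a residue under author numbering."""

    chain_id: str
    res_number: int
    insertion_code: str = ""
    res_name: str = ""

    @property
    def key(self) -> tuple:
        """Uniqueness key within a model (name excluded)."""
        return (self.chain_id, self.res_number, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.res_name}{self.res_number}{self.insertion_code}"


@dataclass
class Residue:
    ref: ResidueRef
    atoms: list = field(default_factory=list)

    def get_atom(self, name: str) -> AtomRecord | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if a.is_heavy]

    def copy(self) -> "Residue":
        return Residue(self.ref, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    """Ordered chains of residues of atoms; the currency of all geometry
    operations in this package."""

    chains: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------

    @property
    def chain_ids(self) -> list:
        return [c.chain_id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise UsageError(f"chain {chain_id!r} not present (have {self.chain_ids})")

    def has_chain(self, chain_id: str) -> bool:
        return chain_id in self.chain_ids

    def get_residue(
        self, chain_id: str, res_number: int, insertion_code: str = ""
    ) -> Residue:
        for res in self.get_chain(chain_id).residues:
            if (
                res.ref.res_number == res_number
                and res.ref.insertion_code == insertion_code
            ):
                return res
        raise EmptySelectionError(
            f"residue {chain_id}:{res_number}{insertion_code} not present"
        )

    def iter_residues(self):
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self):
        for chain in self.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    yield res.ref, atom

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        """All atom coordinates as an (N, 3) array, in model order."""
        pts = [
            a.coords
            for _, a in self.iter_atoms()
            if (a.is_heavy or not heavy_only)
        ]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "StructureModel":
        return StructureModel(
            [c.copy() for c in self.chains], dict(self.metadata)
        )

    # -- geometry ----------------------------------------------------------

    def transformed(self, transform: RigidTransform) -> "StructureModel":
        """A copy with every atom moved by the rigid transform."""
        out = self.copy()
        for _, atom in out.iter_atoms():
            atom.coords = transform.apply(atom.coords)
        return out

    def centroid(self, heavy_only: bool = True) -> np.ndarray:
        """Geometric centroid (barycenter) of the (heavy) atoms."""
        return self.coords(heavy_only=heavy_only).mean(axis=0)


@dataclass(frozen=True)
class DomainSpec:
    """A labelled inclusive residue range on one chain."""

    label: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise UsageError(
                f"domain {self.label}: start {self.start} > end {self.end}"
            )

    def contains(self, ref: ResidueRef) -> bool:
        return (
            ref.chain_id == self.chain_id
            and self.start <= ref.res_number <= self.end
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _from_atom_array(arr, metadata: dict) -> StructureModel:
    import biotite.structure as struc

    model = StructureModel(metadata=metadata)
    chains: dict[str, Chain] = {}
    current_key = None
    current_res = None
    has_atom_id = "atom_id" in arr.get_annotation_categories()
    has_occ = "occupancy" in arr.get_annotation_categories()
    has_b = "b_factor" in arr.get_annotation_categories()
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        icode = str(arr.ins_code[i]) if hasattr(arr, "ins_code") else ""
        key = (cid, int(arr.res_id[i]), icode)
        if key != current_key:
            ref = ResidueRef(cid, int(arr.res_id[i]), icode, str(arr.res_name[i]))
            current_res = Residue(ref)
            if cid not in chains:
                chains[cid] = Chain(cid)
                model.chains.append(chains[cid])
            chains[cid].residues.append(current_res)
            current_key = key
        current_res.atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]) if has_atom_id else i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                coords=np.array(arr.coord[i], dtype=float),
                occupancy=float(arr.occupancy[i]) if has_occ else 1.0,
                b_factor=float(arr.b_factor[i]) if has_b else 0.0,
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return model


def _to_atom_array(model: StructureModel):
    import biotite.structure as struc

    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.add_annotation("occupancy", dtype=float)
    arr.add_annotation("b_factor", dtype=float)
    arr.add_annotation("atom_id", dtype=int)
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                arr.chain_id[i] = chain.chain_id
                arr.res_id[i] = res.ref.res_number
                arr.ins_code[i] = res.ref.insertion_code
                arr.res_name[i] = res.ref.res_name
                arr.atom_name[i] = atom.name
                arr.element[i] = atom.element
                arr.hetero[i] = atom.is_hetero
                arr.coord[i] = atom.coords
                arr.occupancy[i] = atom.occupancy
                arr.b_factor[i] = atom.b_factor
                arr.atom_id[i] = i + 1
                i += 1
    return arr


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".pdb", ".ent", ".pdb1"):
        return "pdb"
    if ext in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    raise UsageError(
        f"cannot infer structure format from {path!r}; pass format='pdb' or 'mmcif'"
    )


def read_structure(source, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF structure into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        A filesystem path, or the file content as a string (anything
        containing a newline is treated as content, in which case
        ``format`` is required).
    format:
        ``"pdb"`` or ``"mmcif"``; inferred from the path suffix when
        omitted.

    Only the first model of multi-model files is read.  Alternate
    locations are resolved to the highest-occupancy conformer.
    """
    is_text = isinstance(source, str) and "\n" in source
    if is_text:
        if format is None:
            raise UsageError("format must be given when reading from a string")
        handle = io.StringIO(source)
        origin = "<string>"
    else:
        if not os.path.exists(str(source)):
            raise UsageError(f"no such file: {source}")
        format = format or _infer_format(source)
        handle = str(source)
        origin = str(source)
    format = format.lower()
    if format not in ("pdb", "mmcif", "cif"):
        raise UsageError(f"unknown structure format {format!r}")

    try:
        if format == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pdb = PDBFile.read(handle)
            arr = pdb.get_structure(
                model=1,
                altloc="occupancy",
                extra_fields=["atom_id", "b_factor", "occupancy"],
            )
        else:
            from biotite.structure.io.pdbx import CIFFile, get_structure

            cif = CIFFile.read(handle)
            arr = get_structure(
                cif,
                model=1,
                altloc="occupancy",
                extra_fields=["atom_id", "b_factor", "occupancy"],
            )
    except Exception as exc:  # biotite raises assorted exception types
        raise ParseError(f"failed to parse {origin} as {format}: {exc}") from exc

    return _from_atom_array(arr, {"source": origin, "format": format})


def write_structure(
    model: StructureModel, target=None, format: str | None = None
) -> str | None:
    """Write a model as PDB or mmCIF.

    ``target`` may be a path (format inferred from its suffix unless
    given) or ``None`` to return the serialisation as a string
    (``format`` required).  Atom serial numbers are re-issued
    sequentially; everything else round-trips.
    """
    if target is None and format is None:
        raise UsageError("format must be given when writing to a string")
    format = (format or _infer_format(target)).lower()
    arr = _to_atom_array(model)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile

        out = PDBFile()
        out.set_structure(arr)
    elif format in ("mmcif", "cif"):
        from biotite.structure.io.pdbx import CIFFile, set_structure

        out = CIFFile()
        set_structure(out, arr, data_block="model")
    else:
        raise UsageError(f"unknown structure format {format!r}")

    if target is None:
        handle = io.StringIO()
        out.write(handle)
        return handle.getvalue()
    out.write(str(target))
    return None


# ---------------------------------------------------------------------------
# Slicing operations
# ---------------------------------------------------------------------------


def extract_domain(model: StructureModel, spec: DomainSpec) -> StructureModel:
    """Return a new model holding exactly the residues of one domain.

    Selects residues with ``spec.start <= res_number <= spec.end`` on
    ``spec.chain_id``; coordinates, numbering and order are unchanged.
    Raises :class:`EmptySelectionError` when nothing matches.
    """
    chain = model.get_chain(spec.chain_id)
    picked = [
        r.copy() for r in chain.residues if spec.start <= r.ref.res_number <= spec.end
    ]
    if not picked:
        raise EmptySelectionError(
            f"no residues in {spec.chain_id}:{spec.start}-{spec.end}"
        )
    meta = dict(model.metadata)
    meta["domain"] = spec.label
    return StructureModel([Chain(chain.chain_id, picked)], meta)


def erase_region(
    model: StructureModel, chain_id: str, start: int, end: int
) -> StructureModel:
    """Remove all atoms of an inclusive residue range from one chain.

    Surviving residues keep their author numbers, so the erased range
    remains visible as a numbering gap.  Raises
    :class:`EmptySelectionError` if the range selects nothing.
    """
    if start > end:
        raise UsageError(f"erase range {start}-{end} is empty")
    chain = model.get_chain(chain_id)
    hit = [r for r in chain.residues if start <= r.ref.res_number <= end]
    if not hit:
        raise EmptySelectionError(
            f"no residues to erase in {chain_id}:{start}-{end}"
        )
    out = StructureModel(metadata=dict(model.metadata))
    for ch in model.chains:
        if ch.chain_id != chain_id:
            out.chains.append(ch.copy())
            continue
        kept = [
            r.copy()
            for r in ch.residues
            if not (start <= r.ref.res_number <= end)
        ]
        if kept:
            out.chains.append(Chain(ch.chain_id, kept))
    return out


def select_chains(model: StructureModel, chain_ids) -> StructureModel:
    """Sub-model restricted to the given chains (model order preserved)."""
    wanted = set(chain_ids)
    missing = wanted - set(model.chain_ids)
    if missing:
        raise UsageError(f"chains not present: {sorted(missing)}")
    return StructureModel(
        [c.copy() for c in model.chains if c.chain_id in wanted],
        dict(model.metadata),
    )


def rename_chains(model: StructureModel, mapping: dict) -> StructureModel:
    """Copy with chain ids renamed per ``mapping`` (missing ids kept)."""
    out = model.copy()
    for chain in out.chains:
        new_id = mapping.get(chain.chain_id, chain.chain_id)
        chain.chain_id = new_id
        for res in chain.residues:
            res.ref = replace(res.ref, chain_id=new_id)
    if len(set(out.chain_ids)) != len(out.chain_ids):
        raise UsageError(f"chain rename produced duplicates: {out.chain_ids}")
    return out


def merge_models(*models: StructureModel) -> StructureModel:
    """Concatenate the chains of several models into one.

    Chain ids must be globally unique; use :func:`rename_chains` first
    when merging two dimers that both use A/B.
    """
    out = StructureModel()
    for m in models:
        for chain in m.chains:
            if out.has_chain(chain.chain_id):
                raise UsageError(
                    f"duplicate chain id {chain.chain_id!r} in merge; rename first"
                )
            out.chains.append(chain.copy())
    return out


class AtomTable:
    """Flat numpy view of a model's atoms for neighbour-search kernels.

    Attributes are parallel arrays over the selected atoms: ``coords``
    (N, 3), ``res_index`` (index into ``residues``), ``names``,
    ``elements``; ``residues`` is the list of distinct
    :class:`ResidueRef` in model order.
    """

    def __init__(self, coords, res_index, names, elements, residues):
        self.coords = coords
        self.res_index = res_index
        self.names = names
        self.elements = elements
        self.residues = residues

    def __len__(self):
        return len(self.coords)


def atom_table(
    model: StructureModel,
    chain_ids=None,
    heavy_only: bool = True,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> AtomTable:
    """Flatten (a subset of) a model into parallel numpy arrays."""
    wanted = set(chain_ids) if chain_ids is not None else None
    coords, res_index, names, elements, residues = [], [], [], [], []
    for chain in model.chains:
        if wanted is not None and chain.chain_id not in wanted:
            continue
        for res in chain.residues:
            if res.ref.res_name in WATER_NAMES and not include_waters:
                continue
            atoms = [
                a
                for a in res.atoms
                if (a.is_heavy or not heavy_only)
                and (include_hetero or not a.is_hetero)
            ]
            if not atoms:
                continue
            ridx = len(residues)
            residues.append(res.ref)
            for a in atoms:
                coords.append(a.coords)
                res_index.append(ridx)
                names.append(a.name)
                elements.append(a.element)
    return AtomTable(
        np.array(coords, dtype=float).reshape(-1, 3),
        np.array(res_index, dtype=int),
        np.array(names, dtype=object),
        np.array(elements, dtype=object),
        residues,
    )
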