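"""Contact-based interface binding-energy prediction.

Implements the linear interfacial-contacts / non-interacting-surface
binding-affinity model: residue-residue contacts across two chain
groups are counted by physicochemical class (5.5 Å heavy-atom cutoff),
the solvent-exposed surface composition of the complex is profiled, and
a published linear model maps both to a ΔG in kcal/mol.  A magnitude
threshold on ΔG (default 3 kcal/mol) classifies a pose as a genuine
complex or as non-interacting.

Solvent accessibility is computed with a deterministic Shrake–Rupley
integration (golden-spiral sphere points, NACCESS-style radii, 1.4 Å
probe); relative accessibility is normalised by theoretical per-residue
maxima (see :mod:`cma.tables`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .errors import UsageError
from .structio import ResidueRef, StructureModel, atom_table, select_chains

__all__ = [
    "ContactPair",
    "ContactCounts",
    "NISProfile",
    "BindingEnergy",
    "compute_sasa",
    "interface_contacts",
    "contacts_between_selections",
    "nis_profile",
    "predict_dG",
    "binding_energy",
    "classify_complex",
    "CONTACT_CUTOFF",
    "NIS_RSA_THRESHOLD",
    "DG_THRESHOLD",
]

#: Heavy-atom distance defining an interfacial contact, Å.
CONTACT_CUTOFF = 5.5
#: Relative-SASA fraction above which a residue counts as surface.
NIS_RSA_THRESHOLD = 0.05
#: |ΔG| below this signs the absence of a complex, kcal/mol.
DG_THRESHOLD = 3.0


@dataclass(frozen=True)
class ContactPair:
    """One interfacial residue-residue contact."""

    residue_a: ResidueRef
    residue_b: ResidueRef
    min_heavy_atom_distance: float
    class_pair: str  # e.g. "charged/apolar"


@dataclass(frozen=True)
class ContactCounts:
    """Interfacial contact counts per residue-class pair.

    ``ic_cp`` (charged/polar) and ``ic_aa`` (apolar/apolar) do not enter
    the ΔG model but are kept for bookkeeping.
    """

    ic_cc: int = 0
    ic_ca: int = 0
    ic_pp: int = 0
    ic_pa: int = 0
    ic_cp: int = 0
    ic_aa: int = 0

    @property
    def total(self) -> int:
        return (
            self.ic_cc + self.ic_ca + self.ic_pp
            + self.ic_pa + self.ic_cp + self.ic_aa
        )


@dataclass(frozen=True)
class NISProfile:
    """Composition of the non-interacting (solvent-exposed) surface."""

    pct_apolar: float
    pct_charged: float
    n_surface_residues: int

    def __post_init__(self):
        for pct in (self.pct_apolar, self.pct_charged):
            if not 0.0 <= pct <= 100.0:
                raise UsageError(f"NIS percentage out of range: {pct}")


@dataclass(frozen=True)
class BindingEnergy:
    """Predicted interface binding free energy and its model inputs."""

    dg: float  # kcal/mol; negative = favourable
    counts: ContactCounts
    nis: NISProfile
    group_a: frozenset = frozenset()
    group_b: frozenset = frozenset()
    relaxed_input: bool = False

    def __post_init__(self):
        if not np.isfinite(self.dg):
            raise UsageError("non-finite ΔG")


@dataclass(frozen=True)
class ResidueSasa:
    area: float  # Å²
    relative: float  # fraction of residue-type theoretical maximum


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere points."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    model: StructureModel,
    n_points: int = 960,
    probe_radius: float = 1.4,
    include_hetero: bool = False,
) -> dict:
    """Per-residue solvent-accessible surface area of the (heavy-atom) model.

    Returns an ordered ``{ResidueRef: ResidueSasa}`` mapping.  Relative
    SASA is ``area / theoretical maximum`` for standard residues and
    ``nan`` otherwise.  Waters are always excluded; residues without
    heavy atoms are skipped with a warning.  Deterministic for a fixed
    ``n_points``.
    """
    table = atom_table(model, include_hetero=include_hetero)
    for res in model.iter_residues():
        if res.ref.res_name not in ("HOH", "WAT", "DOD") and not res.heavy_atoms:
            warnings.warn(f"residue {res.ref} has no heavy atoms; skipped")
    if len(table) == 0:
        return {}
    radii = np.array(
        [
            tables.sasa_radius(ref.res_name, nm, el)
            for ref, nm, el in zip(
                (table.residues[i] for i in table.res_index),
                table.names,
                table.elements,
            )
        ]
    )
    radii = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(table.coords)
    max_r = radii.max()
    per_res_area = np.zeros(len(table.residues))
    for i in range(len(table)):
        r_i = radii[i]
        neigh = tree.query_ball_point(table.coords[i], r_i + max_r)
        neigh = [j for j in neigh if j != i]
        pts = table.coords[i] + r_i * unit
        if neigh:
            nb = np.array(neigh, dtype=int)
            d2 = ((pts[:, None, :] - table.coords[nb][None, :, :]) ** 2).sum(-1)
            exposed = np.all(d2 > (radii[nb] ** 2)[None, :], axis=1)
            n_exposed = int(exposed.sum())
        else:
            n_exposed = n_points
        per_res_area[table.res_index[i]] += (
            4.0 * np.pi * r_i**2 * n_exposed / n_points
        )

    out = {}
    for ridx, ref in enumerate(table.residues):
        max_area = tables.MAX_SASA.get(ref.res_name)
        rel = per_res_area[ridx] / max_area if max_area else float("nan")
        out[ref] = ResidueSasa(float(per_res_area[ridx]), float(rel))
    return out


def _class_pair(name_a: str, name_b: str) -> str | None:
    """Contact class label for a residue-name pair, or None if either
    residue is outside the 20-type table."""
    ca = tables.IC_CLASS.get(name_a)
    cb = tables.IC_CLASS.get(name_b)
    if ca is None or cb is None:
        return None
    word = {"C": "charged", "P": "polar", "A": "apolar"}
    order = {"C": 0, "P": 1, "A": 2}
    first, second = sorted((ca, cb), key=order.get)
    return f"{word[first]}/{word[second]}"


_PAIR_FIELD = {
    "charged/charged": "ic_cc",
    "charged/apolar": "ic_ca",
    "polar/polar": "ic_pp",
    "polar/apolar": "ic_pa",
    "charged/polar": "ic_cp",
    "apolar/apolar": "ic_aa",
}


def _contacts_from_tables(ta, tb, cutoff):
    """Residue contact pairs between two AtomTables (KDTree kernel)."""
    if len(ta) == 0 or len(tb) == 0:
        return []
    tree_a = cKDTree(ta.coords)
    tree_b = cKDTree(tb.coords)
    pairs = tree_a.query_ball_tree(tree_b, cutoff)
    best: dict[tuple, float] = {}
    for ia, hits in enumerate(pairs):
        if not hits:
            continue
        ra = ta.res_index[ia]
        d = np.linalg.norm(tb.coords[hits] - ta.coords[ia], axis=1)
        for ib, dist in zip(hits, d):
            key = (ra, tb.res_index[ib])
            if dist < best.get(key, np.inf):
                best[key] = float(dist)
    contacts = []
    for (ra, rb), dist in sorted(best.items()):
        ref_a, ref_b = ta.residues[ra], tb.residues[rb]
        cls = _class_pair(ref_a.res_name, ref_b.res_name)
        if cls is None:
            continue
        contacts.append(ContactPair(ref_a, ref_b, dist, cls))
    return contacts


def _count(contacts) -> ContactCounts:
    counts = dict.fromkeys(_PAIR_FIELD.values(), 0)
    for c in contacts:
        counts[_PAIR_FIELD[c.class_pair]] += 1
    return ContactCounts(**counts)


def interface_contacts(
    model: StructureModel,
    group_a,
    group_b,
    cutoff: float = CONTACT_CUTOFF,
    include_hetero: bool = False,
):
    """Interfacial contacts between two disjoint chain groups.

    A residue pair is a contact iff any heavy-atom pair across the
    groups is within ``cutoff``.  Returns ``(contacts, counts)``; the
    relation is symmetric in group order up to pair orientation.
    """
    group_a, group_b = frozenset(group_a), frozenset(group_b)
    if not group_a or not group_b:
        raise UsageError("both chain groups must be non-empty")
    if group_a & group_b:
        raise UsageError(f"chain groups overlap: {sorted(group_a & group_b)}")
    for cid in group_a | group_b:
        model.get_chain(cid)  # raises on absence
    ta = atom_table(model, chain_ids=group_a, include_hetero=include_hetero)
    tb = atom_table(model, chain_ids=group_b, include_hetero=include_hetero)
    contacts = _contacts_from_tables(ta, tb, cutoff)
    return contacts, _count(contacts)


def contacts_between_selections(
    model: StructureModel,
    refs_a,
    refs_b,
    cutoff: float = CONTACT_CUTOFF,
):
    """Contacts between two explicit residue selections (sets of
    residue keys), e.g. two domains; used by topology classification."""
    keys_a = {r.key if isinstance(r, ResidueRef) else r for r in refs_a}
    keys_b = {r.key if isinstance(r, ResidueRef) else r for r in refs_b}
    if keys_a & keys_b:
        raise UsageError("residue selections overlap")
    full = atom_table(model)
    mask_a = np.array([full.residues[i].key in keys_a for i in full.res_index])
    mask_b = np.array([full.residues[i].key in keys_b for i in full.res_index])

    def _sub(mask):
        idx = np.nonzero(mask)[0]
        sub_res: list = []
        remap = {}
        res_index = []
        for i in idx:
            ri = full.res_index[i]
            if ri not in remap:
                remap[ri] = len(sub_res)
                sub_res.append(full.residues[ri])
            res_index.append(remap[ri])
        from .structio import AtomTable

        return AtomTable(
            full.coords[idx],
            np.array(res_index, dtype=int),
            full.names[idx],
            full.elements[idx],
            sub_res,
        )

    contacts = _contacts_from_tables(_sub(mask_a), _sub(mask_b), cutoff)
    return contacts, _count(contacts)


def nis_profile(
    sasa: dict, threshold: float = NIS_RSA_THRESHOLD
) -> NISProfile:
    """Surface composition from a per-residue SASA mapping.

    Surface residues are the standard residues with relative SASA above
    ``threshold`` (complex form); percentages are of the surface count.
    """
    classes = [
        tables.NIS_CLASS[ref.res_name]
        for ref, s in sasa.items()
        if ref.res_name in tables.NIS_CLASS
        and np.isfinite(s.relative)
        and s.relative > threshold
    ]
    n = len(classes)
    if n == 0:
        return NISProfile(0.0, 0.0, 0)
    return NISProfile(
        100.0 * classes.count("A") / n,
        100.0 * classes.count("C") / n,
        n,
    )


def predict_dG(
    counts: ContactCounts,
    nis: NISProfile,
    group_a=frozenset(),
    group_b=frozenset(),
    relaxed_input: bool = False,
) -> BindingEnergy:
    """Evaluate the linear ΔG model (kcal/mol, negative = favourable)."""
    c = tables.DG_COEFFICIENTS
    dg = (
        c["ic_cc"] * counts.ic_cc
        + c["ic_ca"] * counts.ic_ca
        + c["ic_pp"] * counts.ic_pp
        + c["ic_pa"] * counts.ic_pa
        + c["pct_apolar"] * nis.pct_apolar
        + c["pct_charged"] * nis.pct_charged
        + c["intercept"]
    )
    return BindingEnergy(
        float(dg), counts, nis,
        frozenset(group_a), frozenset(group_b), relaxed_input,
    )


def binding_energy(
    model: StructureModel,
    group_a,
    group_b,
    cutoff: float = CONTACT_CUTOFF,
    n_points: int = 960,
    relaxed_input: bool = False,
) -> BindingEnergy:
    """Contacts + surface profile + ΔG for one complex, in one call.

    The surface profile is computed on the complex restricted to the
    two groups' chains, matching the reference predictor's convention.
    """
    _, counts = interface_contacts(model, group_a, group_b, cutoff=cutoff)
    complex_only = select_chains(model, set(group_a) | set(group_b))
    nis = nis_profile(compute_sasa(complex_only, n_points=n_points))
    return predict_dG(counts, nis, group_a, group_b, relaxed_input)


def classify_complex(
    be: BindingEnergy, threshold: float = DG_THRESHOLD
) -> str:
    """``"no_complex"`` iff ``|ΔG| < threshold``, else ``"complex"``.

    The boundary is inclusive: ``|ΔG| == threshold`` is a complex.
    """
    return "no_complex" if abs(be.dg) < threshold else "complex"
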