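"""Symmetric rigid-body assembly of full-length dimers from partial models.

Workflow: detect the two-fold (C2) symmetry axis of each partial
homodimer from the optimal superposition of its two chains, rigidly move
the second part so both axes coincide, slide it along the common axis to
the shortest clash-free barycenter separation, and choose the rotation
(dihedral) angle about the axis as the midpoint of the largest arc that
is clash-free for every supplied variant.  All parts are moved as rigid
bodies; a returned assembly is clash-free by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .errors import InfeasibleAssemblyError, NoAxisError, UsageError
from .geometry import (
    RigidTransform,
    kabsch,
    rmsd,
    rotation_about_axis,
    rotation_angle,
    rotation_axis,
    screw_axis_point,
)
from .structio import DomainSpec, StructureModel, atom_table, merge_models, rename_chains

__all__ = [
    "SymmetryAxis",
    "ClashCriterion",
    "ClashReport",
    "AssemblyResult",
    "DihedralScan",
    "detect_c2_axis",
    "align_axes",
    "min_separation",
    "scan_dihedral",
    "detect_clashes",
    "compose_hybrid",
]


@dataclass(frozen=True)
class SymmetryAxis:
    """Parameters of a (near-)two-fold rotation axis."""

    direction: np.ndarray  # unit vector
    point: np.ndarray  # a point on the axis, Å
    rotation_angle: float  # degrees, in (0, 360)
    residual_rmsd: float  # superposition residual, Å

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise UsageError("axis direction must be non-zero")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(
            self, "point", np.asarray(self.point, dtype=float).reshape(3)
        )
        if not 0.0 < self.rotation_angle < 360.0:
            raise UsageError(f"rotation angle out of (0,360): {self.rotation_angle}")

    def transform(self) -> RigidTransform:
        """The rotation about this axis by its rotation angle."""
        return rotation_about_axis(self.direction, self.point, self.rotation_angle)


@dataclass(frozen=True)
class ClashCriterion:
    """Steric clash rule: heavy atoms closer than the sum of their van
    der Waals radii minus ``tolerance`` (or than ``fixed_cutoff``)."""

    tolerance: float = 0.4  # Å subtracted from the vdW sum
    fixed_cutoff: float | None = None  # Å; overrides radii when set

    def cutoff(self, element_a: str, element_b: str) -> float:
        if self.fixed_cutoff is not None:
            return self.fixed_cutoff
        return (
            tables.vdw_radius(element_a)
            + tables.vdw_radius(element_b)
            - self.tolerance
        )

    def max_cutoff(self) -> float:
        if self.fixed_cutoff is not None:
            return self.fixed_cutoff
        return 2.0 * max(tables.VDW_RADII.values()) - self.tolerance


@dataclass(frozen=True)
class ClashReport:
    clash_pairs: tuple  # of (ResidueRef+name, ResidueRef+name, distance)
    min_distance: float  # Å, over all cross-group heavy-atom pairs
    clash_count: int

    @property
    def clash_free(self) -> bool:
        return self.clash_count == 0


@dataclass(frozen=True)
class AssemblyResult:
    model: StructureModel
    separation: float  # barycenter distance along the axis, Å
    dihedral_angle: float | None  # degrees, None before the dihedral step
    feasible_arcs: tuple  # ((start_deg, end_deg), ...)
    clash_report: ClashReport
    chain_mapping: dict  # part-B original -> merged chain id


@dataclass(frozen=True)
class DihedralScan:
    chosen_angle: float
    feasible_arcs: tuple  # intersection across variants
    per_variant_arcs: tuple  # one arc tuple per variant
    assemblies: tuple  # one AssemblyResult per variant at chosen angle


# ---------------------------------------------------------------------------
# Axis detection and alignment
# ---------------------------------------------------------------------------


def _matched_ca(model: StructureModel, chain_a: str, chain_b: str):
    """CA coordinate pairs matched by author residue number."""
    def ca_map(cid):
        out = {}
        for res in model.get_chain(cid).residues:
            atom = res.get_atom("CA")
            if atom is not None:
                out[(res.ref.res_number, res.ref.insertion_code)] = atom.coords
        return out

    ma, mb = ca_map(chain_a), ca_map(chain_b)
    common = sorted(set(ma) & set(mb))
    if len(common) < 3:
        raise NoAxisError(
            f"only {len(common)} matched CA pairs between chains "
            f"{chain_a!r} and {chain_b!r}; need >= 3"
        )
    return (
        np.array([ma[k] for k in common]),
        np.array([mb[k] for k in common]),
    )


def detect_c2_axis(
    model: StructureModel, chain_a: str, chain_b: str
) -> SymmetryAxis:
    """Two-fold symmetry axis relating two sequence-identical chains.

    The least-squares superposition of ``chain_a`` onto ``chain_b``
    yields a rotation whose angle should be ~180° for a true C2 dimer
    (a warning is issued beyond 10° deviation); the axis direction is
    the rotation's fixed vector and the axis point the screw-axis
    solution.
    """
    ca_a, ca_b = _matched_ca(model, chain_a, chain_b)
    t = kabsch(ca_a, ca_b)
    angle = rotation_angle(t.rotation)
    if angle < 1.0:
        raise NoAxisError(
            f"chains {chain_a}/{chain_b} are related by a near-identity "
            f"rotation ({angle:.2f} deg); no symmetry axis"
        )
    if abs(angle - 180.0) > 10.0:
        warnings.warn(
            f"chain pair rotation angle {angle:.1f} deg deviates from "
            "two-fold symmetry by more than 10 deg"
        )
    return SymmetryAxis(
        direction=rotation_axis(t.rotation),
        point=screw_axis_point(t),
        rotation_angle=angle,
        residual_rmsd=rmsd(t.apply(ca_a), ca_b),
    )


def align_axes(
    part_a: StructureModel,
    axis_a: SymmetryAxis,
    part_b: StructureModel,
    axis_b: SymmetryAxis,
) -> tuple[StructureModel, RigidTransform]:
    """Rigidly move ``part_b`` so its symmetry axis coincides with
    ``part_a``'s (collinear and co-oriented).

    The rotation is the minimal one taking direction_b to direction_a
    (sign chosen so the directions co-orient); the translation removes
    the perpendicular offset between the two axis lines while keeping
    part_b's position along the axis.  Returns the moved copy and the
    transform used.
    """
    da = axis_a.direction
    db = axis_b.direction
    if np.dot(da, db) < 0:
        db = -db
    cross = np.cross(db, da)
    s = np.linalg.norm(cross)
    c = float(np.dot(db, da))
    if s < 1e-12:
        rot = RigidTransform.identity()
    else:
        angle = np.degrees(np.arctan2(s, c))
        rot = rotation_about_axis(cross / s, axis_b.point, angle)
    # after rotation the axis of part_b passes through axis_b.point along da
    offset = axis_a.point - axis_b.point
    perp = offset - np.dot(offset, da) * da
    move = RigidTransform(np.eye(3), perp).compose(rot)
    return part_b.transformed(move), move


# ---------------------------------------------------------------------------
# Clash detection
# ---------------------------------------------------------------------------


def detect_clashes(
    model: StructureModel,
    group_a,
    group_b,
    criterion: ClashCriterion = ClashCriterion(),
    include_hetero: bool = False,
) -> ClashReport:
    """Steric clashes between heavy atoms of two disjoint chain groups."""
    group_a, group_b = frozenset(group_a), frozenset(group_b)
    if group_a & group_b:
        raise UsageError(f"chain groups overlap: {sorted(group_a & group_b)}")
    ta = atom_table(model, chain_ids=group_a, include_hetero=include_hetero)
    tb = atom_table(model, chain_ids=group_b, include_hetero=include_hetero)
    return clashes_between_tables(ta, tb, criterion)


def clashes_between_tables(ta, tb, criterion: ClashCriterion) -> ClashReport:
    if len(ta) == 0 or len(tb) == 0:
        return ClashReport((), float("inf"), 0)
    tree_a = cKDTree(ta.coords)
    tree_b = cKDTree(tb.coords)
    # global minimum distance
    d_min, _ = tree_b.query(ta.coords, k=1)
    min_distance = float(d_min.min())
    pairs = tree_a.query_ball_tree(tree_b, criterion.max_cutoff())
    clashes = []
    for ia, hits in enumerate(pairs):
        for ib in hits:
            d = float(np.linalg.norm(ta.coords[ia] - tb.coords[ib]))
            if d < criterion.cutoff(ta.elements[ia], tb.elements[ib]):
                clashes.append(
                    (
                        (ta.residues[ta.res_index[ia]], str(ta.names[ia])),
                        (tb.residues[tb.res_index[ib]], str(tb.names[ib])),
                        d,
                    )
                )
    return ClashReport(tuple(clashes), min_distance, len(clashes))


def _count_clashes_coords(
    coords_a, elements_a, coords_b, elements_b, criterion: ClashCriterion
) -> int:
    """Fast clash count on raw coordinate arrays (scan inner loop)."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        return 0
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    pairs = tree_a.query_ball_tree(tree_b, criterion.max_cutoff())
    n = 0
    for ia, hits in enumerate(pairs):
        if not hits:
            continue
        d = np.linalg.norm(coords_b[hits] - coords_a[ia], axis=1)
        cut = np.array(
            [criterion.cutoff(elements_a[ia], elements_b[ib]) for ib in hits]
        )
        n += int((d < cut).sum())
    return n


# ---------------------------------------------------------------------------
# Separation and dihedral search
# ---------------------------------------------------------------------------


def _merge_parts(part_a: StructureModel, part_b: StructureModel):
    """Merge two parts, renaming part-B chains that collide with part A.

    Returns (merged model, mapping of part-B original -> merged id).
    """
    used = list(part_a.chain_ids)
    mapping = {}
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"
    for cid in part_b.chain_ids:
        if cid in used or cid in mapping.values():
            new = next(
                ch for ch in alphabet if ch not in used and ch not in mapping.values()
            )
            mapping[cid] = new
            used.append(new)
        else:
            mapping[cid] = cid
            used.append(cid)
    return merge_models(part_a, rename_chains(part_b, mapping)), mapping


def _axial_separation(part_a, part_b, axis: SymmetryAxis) -> float:
    return float(
        np.dot(part_b.centroid() - part_a.centroid(), axis.direction)
    )


def min_separation(
    part_a: StructureModel,
    part_b: StructureModel,
    axis: SymmetryAxis,
    criterion: ClashCriterion = ClashCriterion(),
    step: float = 0.1,
    max_extra: float = 30.0,
) -> AssemblyResult:
    """Slide ``part_b`` along the common axis to the shortest clash-free
    barycenter separation.

    The scan starts from a guaranteed clash-free separation (sum of the
    parts' bounding radii plus the clash cutoff plus ``max_extra`` slack
    is the upper bound) and moves inward in ``step`` increments; the
    separation returned is the innermost clash-free grid point of the
    outermost clash-free interval, which guards against spurious
    clash-free pockets inside interpenetrating arrangements.
    """
    ta = atom_table(part_a, include_hetero=True)
    tb = atom_table(part_b, include_hetero=True)
    if len(ta) == 0 or len(tb) == 0:
        raise UsageError("both parts must contain heavy atoms")
    d = axis.direction
    bary_a = part_a.centroid()
    bary_b = part_b.centroid()
    s0 = float(np.dot(bary_b - bary_a, d))
    sign = 1.0 if s0 >= 0 else -1.0

    r_a = float(np.linalg.norm(ta.coords - bary_a, axis=1).max())
    r_b = float(np.linalg.norm(tb.coords - bary_b, axis=1).max())
    s_max = r_a + r_b + criterion.max_cutoff() + step

    grid = np.arange(0.0, s_max + step, step)[::-1]  # outside -> inside
    best = None
    for s in grid:
        shift = (sign * s - s0) * d
        n = _count_clashes_coords(
            ta.coords, ta.elements, tb.coords + shift, tb.elements, criterion
        )
        if n == 0:
            best = float(s)
        else:
            break
    if best is None:
        raise InfeasibleAssemblyError(
            "no clash-free separation found within scan bounds"
        )
    shift = (sign * best - s0) * d
    moved_b = part_b.transformed(RigidTransform(np.eye(3), shift))
    merged, mapping = _merge_parts(part_a, moved_b)
    report = detect_clashes(
        merged,
        part_a.chain_ids,
        [mapping[c] for c in part_b.chain_ids],
        criterion,
        include_hetero=True,
    )
    return AssemblyResult(
        model=merged,
        separation=best,
        dihedral_angle=None,
        feasible_arcs=(),
        clash_report=report,
        chain_mapping=mapping,
    )


def _mask_to_arcs(mask: np.ndarray, step: float):
    """Contiguous True runs of a circular grid mask as degree arcs."""
    n = len(mask)
    if mask.all():
        return [(0.0, 360.0)]
    if not mask.any():
        return []
    arcs = []
    # find starts: True preceded by False (circularly)
    starts = [i for i in range(n) if mask[i] and not mask[(i - 1) % n]]
    for s in starts:
        length = 0
        while mask[(s + length) % n] and length < n:
            length += 1
        arcs.append((s * step, (s + length - 1) * step))
    return arcs


def _arc_span(arc) -> float:
    lo, hi = arc
    return hi - lo if hi >= lo else hi + 360.0 - lo


def _arc_midpoint(arc) -> float:
    lo, hi = arc
    if arc == (0.0, 360.0):
        return 180.0
    return (lo + _arc_span(arc) / 2.0) % 360.0


def scan_dihedral(
    part_a: StructureModel,
    part_b_variants,
    axis: SymmetryAxis,
    criterion: ClashCriterion = ClashCriterion(),
    angular_step: float = 1.0,
) -> DihedralScan:
    """Choose the rotation angle about the common axis that keeps every
    supplied variant of part B clash-free.

    Each variant (already placed at its fixed separation) is rotated
    about the axis over a full-circle grid; the feasible set is the
    intersection of the variants' clash-free masks and the chosen angle
    the midpoint of its largest contiguous arc.  An empty intersection
    raises :class:`InfeasibleAssemblyError` carrying per-variant arcs.
    """
    if isinstance(part_b_variants, StructureModel):
        part_b_variants = [part_b_variants]
    if not part_b_variants:
        raise UsageError("at least one part-B variant is required")
    ta = atom_table(part_a, include_hetero=True)
    angles = np.arange(0.0, 360.0, angular_step)
    masks = []
    for variant in part_b_variants:
        tb = atom_table(variant, include_hetero=True)
        mask = np.zeros(len(angles), dtype=bool)
        for i, ang in enumerate(angles):
            rot = rotation_about_axis(axis.direction, axis.point, float(ang))
            coords = rot.apply(tb.coords)
            mask[i] = (
                _count_clashes_coords(
                    ta.coords, ta.elements, coords, tb.elements, criterion
                )
                == 0
            )
        masks.append(mask)
    per_variant_arcs = tuple(
        tuple(_mask_to_arcs(m, angular_step)) for m in masks
    )
    common = np.logical_and.reduce(masks)
    arcs = _mask_to_arcs(common, angular_step)
    if not arcs:
        raise InfeasibleAssemblyError(
            "no dihedral angle is clash-free for all variants",
            per_variant_arcs=per_variant_arcs,
        )
    best_arc = max(arcs, key=_arc_span)
    chosen = _arc_midpoint(best_arc)
    rot = rotation_about_axis(axis.direction, axis.point, chosen)
    assemblies = []
    for variant in part_b_variants:
        moved = variant.transformed(rot)
        merged, mapping = _merge_parts(part_a, moved)
        report = detect_clashes(
            merged,
            part_a.chain_ids,
            [mapping[c] for c in variant.chain_ids],
            criterion,
            include_hetero=True,
        )
        assemblies.append(
            AssemblyResult(
                model=merged,
                separation=abs(_axial_separation(part_a, moved, axis)),
                dihedral_angle=chosen,
                feasible_arcs=tuple(arcs),
                clash_report=report,
                chain_mapping=mapping,
            )
        )
    return DihedralScan(
        chosen_angle=chosen,
        feasible_arcs=tuple(arcs),
        per_variant_arcs=per_variant_arcs,
        assemblies=tuple(assemblies),
    )


# ---------------------------------------------------------------------------
# Hybrid composition
# ---------------------------------------------------------------------------


def compose_hybrid(
    closed: StructureModel,
    open_: StructureModel,
    match_domains,
) -> tuple[StructureModel, float]:
    """Mixed-conformation dimer: chain 1 from ``closed``, chain 2 from
    ``open_`` after superposing ``open_`` onto ``closed``.

    The superposition is least-squares over the CA atoms of
    ``match_domains`` (matched by chain and residue number across the
    two models).  Both models must use the same two chain ids.  Returns
    the hybrid and the restricted-fit RMSD.
    """
    if closed.chain_ids != open_.chain_ids or len(closed.chain_ids) != 2:
        raise UsageError(
            "hybrid composition needs two models sharing the same two chain ids"
        )
    pairs_closed, pairs_open = [], []
    for spec in match_domains:
        try:
            chain_c = closed.get_chain(spec.chain_id)
            chain_o = open_.get_chain(spec.chain_id)
        except UsageError as exc:
            raise UsageError(f"domain {spec.label}: {exc}") from exc
        byn_o = {
            r.ref.res_number: r.get_atom("CA")
            for r in chain_o.residues
            if spec.start <= r.ref.res_number <= spec.end
        }
        found = 0
        for r in chain_c.residues:
            if not spec.start <= r.ref.res_number <= spec.end:
                continue
            ca_c = r.get_atom("CA")
            ca_o = byn_o.get(r.ref.res_number)
            if ca_c is not None and ca_o is not None:
                pairs_closed.append(ca_c.coords)
                pairs_open.append(ca_o.coords)
                found += 1
        if found == 0:
            raise UsageError(f"domain {spec.label} matches no CA pairs")
    t = kabsch(np.array(pairs_open), np.array(pairs_closed))
    fit_rmsd = rmsd(t.apply(np.array(pairs_open)), np.array(pairs_closed))
    open_moved = open_.transformed(t)
    first, second = closed.chain_ids
    hybrid = StructureModel(
        [
            closed.get_chain(first).copy(),
            open_moved.get_chain(second).copy(),
        ],
        {"hybrid_of": (first + ":closed", second + ":open"),
         "fit_rmsd": fit_rmsd},
    )
    return hybrid, float(fit_rmsd)
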