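"""Cofactor transfer between structures and linker-continuity checks.

Cofactors (heme, FMN, FAD, ...) are carried from a reference structure
into a model by least-squares superposition of a shared protein domain,
then copying the hetero group's atoms under the recovered transform.
Linker feasibility asks whether ``n`` missing residues can physically
span the gap between two anchor residues, using an extended-chain
per-residue reach bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import ClashCriterion, ClashReport, clashes_between_tables
from .errors import EmptySelectionError, UsageError
from .geometry import RigidTransform, kabsch, rmsd
from .structio import (
    Chain,
    DomainSpec,
    Residue,
    ResidueRef,
    StructureModel,
    atom_table,
)

__all__ = [
    "CofactorTemplate",
    "GraftResult",
    "LinkerGap",
    "LinkerCheck",
    "superpose_by_domain",
    "graft_cofactor",
    "check_linker_feasibility",
    "PER_RESIDUE_REACH",
]

#: Extended-chain CA-CA step used as the per-residue reach bound, Å.
PER_RESIDUE_REACH = 3.8
#: Reserved chain id for grafted hetero groups.
GRAFT_CHAIN_ID = "X"


@dataclass(frozen=True)
class CofactorTemplate:
    """A reference structure, the protein domain used for fitting, and
    the hetero group to transfer (residue name, optionally chain)."""

    reference: StructureModel
    domain_spec: DomainSpec
    cofactor_name: str
    cofactor_chain: str | None = None


@dataclass(frozen=True)
class GraftResult:
    model: StructureModel
    fit_rmsd: float
    n_matched_ca: int
    post_graft_clashes: ClashReport
    cofactor_ref: ResidueRef


@dataclass(frozen=True)
class LinkerGap:
    """A chain discontinuity: C-terminal anchor, N-terminal anchor, and
    the number of residues missing between them."""

    from_residue: ResidueRef
    to_residue: ResidueRef
    n_missing: int = 0

    def __post_init__(self):
        if self.n_missing < 0:
            raise UsageError("n_missing must be >= 0")


@dataclass(frozen=True)
class LinkerCheck:
    feasible: bool
    observed_gap: float  # C(from) -> N(to) distance, Å
    max_reach: float  # (n_missing + 1) * per-residue reach, Å
    per_residue_reach: float


def superpose_by_domain(
    reference: StructureModel,
    target: StructureModel,
    spec_ref: DomainSpec,
    spec_target: DomainSpec,
) -> tuple[RigidTransform, float, int]:
    """Optimal rigid transform taking the reference domain onto the
    target domain.

    CA atoms are matched positionally: the k-th number of the reference
    range pairs with the k-th number of the target range (i.e. by author
    numbering after applying the offset implied by the two ranges).
    Returns ``(transform, rmsd, n_matched)``.
    """
    if (spec_ref.end - spec_ref.start) != (spec_target.end - spec_target.start):
        raise UsageError(
            "reference and target domain ranges must have equal length "
            f"({spec_ref.label}: {spec_ref.start}-{spec_ref.end} vs "
            f"{spec_target.label}: {spec_target.start}-{spec_target.end})"
        )
    offset = spec_target.start - spec_ref.start

    def ca_map(model, spec):
        out = {}
        for res in model.get_chain(spec.chain_id).residues:
            if spec.start <= res.ref.res_number <= spec.end:
                ca = res.get_atom("CA")
                if ca is not None:
                    out[res.ref.res_number] = ca.coords
        return out

    ref_ca = ca_map(reference, spec_ref)
    tgt_ca = ca_map(target, spec_target)
    matched = sorted(n for n in ref_ca if n + offset in tgt_ca)
    if len(matched) < 3:
        raise UsageError(
            f"only {len(matched)} matched CA pairs between domains; need >= 3"
        )
    ref_pts = np.array([ref_ca[n] for n in matched])
    tgt_pts = np.array([tgt_ca[n + offset] for n in matched])
    t = kabsch(ref_pts, tgt_pts)
    return t, rmsd(t.apply(ref_pts), tgt_pts), len(matched)


def _find_cofactor(template: CofactorTemplate) -> Residue:
    hits = []
    for res in template.reference.iter_residues():
        if res.ref.res_name != template.cofactor_name:
            continue
        if (
            template.cofactor_chain is not None
            and res.ref.chain_id != template.cofactor_chain
        ):
            continue
        if not all(a.is_hetero for a in res.atoms):
            raise UsageError(
                f"cofactor residue {res.ref} has non-hetero atoms"
            )
        hits.append(res)
    if not hits:
        raise EmptySelectionError(
            f"cofactor {template.cofactor_name!r} not found in reference"
        )
    if len(hits) > 1:
        raise UsageError(
            f"cofactor {template.cofactor_name!r} is ambiguous "
            f"({[str(h.ref) for h in hits]}); give a chain id"
        )
    return hits[0]


def graft_cofactor(
    template: CofactorTemplate,
    target_model: StructureModel,
    spec_target: DomainSpec,
    criterion: ClashCriterion = ClashCriterion(),
) -> GraftResult:
    """Transfer the template's cofactor into the target model.

    The reference's fitting domain is superposed onto ``spec_target``;
    the cofactor atoms are copied under that transform as hetero records
    on the reserved chain ``X`` with sequential numbering.  Protein
    coordinates are never modified.  The result carries the fit RMSD
    and a clash report of the grafted group against the target's
    protein heavy atoms.
    """
    cofactor = _find_cofactor(template)
    transform, fit, n_matched = superpose_by_domain(
        template.reference, target_model, template.domain_spec, spec_target
    )
    out = target_model.copy()
    existing = [
        r.ref.res_number
        for r in out.iter_residues()
        if r.ref.chain_id == GRAFT_CHAIN_ID
    ]
    number = max(existing, default=0) + 1
    new_ref = ResidueRef(GRAFT_CHAIN_ID, number, "", cofactor.ref.res_name)
    new_res = Residue(
        new_ref,
        [
            replace(a.copy(), coords=transform.apply(a.coords), is_hetero=True)
            for a in cofactor.atoms
        ],
    )
    if out.has_chain(GRAFT_CHAIN_ID):
        out.get_chain(GRAFT_CHAIN_ID).residues.append(new_res)
    else:
        out.chains.append(Chain(GRAFT_CHAIN_ID, [new_res]))

    protein = atom_table(
        out, chain_ids=[c for c in out.chain_ids if c != GRAFT_CHAIN_ID]
    )
    grafted = atom_table(out, chain_ids=[GRAFT_CHAIN_ID], include_hetero=True)
    clashes = clashes_between_tables(protein, grafted, criterion)
    return GraftResult(out, float(fit), n_matched, clashes, new_ref)


def check_linker_feasibility(
    model: StructureModel,
    gap: LinkerGap,
    per_residue_reach: float = PER_RESIDUE_REACH,
) -> LinkerCheck:
    """Can ``n_missing`` residues bridge the gap between two anchors?

    The observed gap is the distance from the C atom of the C-terminal
    anchor to the N atom of the N-terminal anchor; the bound is
    ``(n_missing + 1) * per_residue_reach`` (each missing residue plus
    the closing peptide bond contributes one extended step).  The bound
    is deliberately generous — it asserts reachability, not a modelled
    conformation.
    """
    res_from = model.get_residue(
        gap.from_residue.chain_id,
        gap.from_residue.res_number,
        gap.from_residue.insertion_code,
    )
    res_to = model.get_residue(
        gap.to_residue.chain_id,
        gap.to_residue.res_number,
        gap.to_residue.insertion_code,
    )
    c_atom = res_from.get_atom("C")
    n_atom = res_to.get_atom("N")
    if c_atom is None or n_atom is None:
        raise UsageError(
            f"anchors {res_from.ref} / {res_to.ref} lack backbone C/N atoms"
        )
    observed = float(np.linalg.norm(c_atom.coords - n_atom.coords))
    max_reach = (gap.n_missing + 1) * per_residue_reach
    return LinkerCheck(observed <= max_reach, observed, max_reach, per_residue_reach)
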