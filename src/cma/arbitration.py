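"""Competitive arbitration among alternate predicted conformations.

Every member of a prediction ensemble is scored and classified
(artifactual overlap / no complex / complex), complex-status members are
clustered by the fraction of common interface contacts (fcc), cluster
frequencies are computed over *all* runs, a best representative is
picked per cluster by binding affinity (never by predictor confidence
rank), and two-chain multi-domain models are labelled by the topology of
their mobile-domain pairings (cis/trans, closed/crossed).

A geometry is significant when its cluster reaches ``min_frequency``
(default 20% of runs); singleton clusters are reported but are treated
as inconsistent-geometry noise and never significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import energetics
from .assembly import ClashCriterion, detect_clashes
from .errors import UsageError
from .structio import DomainSpec, StructureModel

__all__ = [
    "EnsembleMember",
    "GeometryCluster",
    "ArbitrationReport",
    "score_members",
    "cluster_geometries",
    "select_best",
    "classify_topology",
    "arbitrate",
    "contact_set",
    "fcc_similarity",
    "MIN_FREQUENCY",
    "FCC_CUTOFF",
    "OVERLAP_FRACTION",
]

#: Minimum fraction of runs for a geometry to be significant.
MIN_FREQUENCY = 0.2
#: fcc at or above which two poses count as the same geometry.
FCC_CUTOFF = 0.5
#: Fraction of interface residues in steric clash that signs a
#: randomly-overlapping prediction artifact.
OVERLAP_FRACTION = 0.1


@dataclass
class EnsembleMember:
    """One predicted structure of an ensemble plus its scoring state."""

    model: StructureModel
    run_id: int
    ptm_score: float | None = None
    dg: energetics.BindingEnergy | None = None
    status: str = "unscored"  # unscored | no_complex | artifact_overlap | complex


@dataclass(frozen=True)
class GeometryCluster:
    members: tuple  # run_ids
    representative: int  # run_id
    frequency: float  # fraction of all runs
    label: str | None = None  # topology label, when classified

    def __post_init__(self):
        if not 0.0 < self.frequency <= 1.0:
            raise UsageError(f"cluster frequency out of (0,1]: {self.frequency}")
        if self.representative not in self.members:
            raise UsageError("representative must belong to the cluster")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


@dataclass(frozen=True)
class ArbitrationReport:
    n_runs: int
    clusters: tuple
    significant: tuple
    verdict: str  # no_complex | single_geometry | alternate_geometries
    n_no_complex: int = 0
    n_artifact: int = 0


def _overlap_fraction(member, group_a, group_b) -> float:
    """Fraction of interface-group residues involved in steric clashes."""
    report = detect_clashes(member.model, group_a, group_b, ClashCriterion())
    clashing = {ref.key for (ref, _), _, _ in report.clash_pairs} | {
        ref.key for _, (ref, _), _ in report.clash_pairs
    }
    n_total = sum(
        1
        for res in member.model.iter_residues()
        if res.ref.chain_id in set(group_a) | set(group_b)
    )
    return len(clashing) / n_total if n_total else 0.0


def score_members(
    members,
    group_a,
    group_b,
    dg_threshold: float = energetics.DG_THRESHOLD,
    overlap_fraction: float = OVERLAP_FRACTION,
) -> list:
    """Score and classify every member (in place on copies; returns them).

    A member is ``artifact_overlap`` when more than ``overlap_fraction``
    of its interface-group residues are in steric clash (randomly
    interpenetrating chains), else ``no_complex``/``complex`` by the
    ΔG-magnitude rule.
    """
    chain_sets = {frozenset(m.model.chain_ids) for m in members}
    if len(chain_sets) > 1:
        raise UsageError(
            f"ensemble members disagree on chain ids: {sorted(map(sorted, chain_sets))}"
        )
    scored = []
    for m in members:
        be = energetics.binding_energy(m.model, group_a, group_b)
        if _overlap_fraction(m, group_a, group_b) > overlap_fraction:
            status = "artifact_overlap"
        else:
            status = energetics.classify_complex(be, dg_threshold)
        scored.append(replace_member(m, dg=be, status=status))
    return scored


def replace_member(member: EnsembleMember, **kw) -> EnsembleMember:
    out = EnsembleMember(
        model=member.model,
        run_id=member.run_id,
        ptm_score=member.ptm_score,
        dg=member.dg,
        status=member.status,
    )
    for k, v in kw.items():
        setattr(out, k, v)
    return out


def contact_set(
    model: StructureModel, group_a, group_b, cutoff: float = energetics.CONTACT_CUTOFF
) -> frozenset:
    """Interface contacts as a set of ((chain,res),(chain,res)) keys."""
    contacts, _ = energetics.interface_contacts(model, group_a, group_b, cutoff)
    return frozenset(
        (c.residue_a.key, c.residue_b.key) for c in contacts
    )


def _swap_two_chain(contacts: frozenset, chain_a: str, chain_b: str) -> frozenset:
    """Contact set under the A<->B chain relabelling of a homodimer."""
    def swap(key):
        cid, num, icode = key
        new = chain_b if cid == chain_a else chain_a if cid == chain_b else cid
        return (new, num, icode)

    return frozenset((swap(b), swap(a)) for a, b in contacts)


def fcc_similarity(set_a: frozenset, set_b: frozenset) -> float:
    """Fraction of common contacts, normalised by the larger set.

    Max-normalisation (rather than min) keeps a pose whose interface is
    a strict subset of another's from being conflated with it, which
    matters when alternate geometries share a sub-interface.
    """
    if not set_a or not set_b:
        return 0.0
    return len(set_a & set_b) / max(len(set_a), len(set_b))


def cluster_geometries(
    members,
    group_a,
    group_b,
    n_runs: int,
    similarity_cutoff: float = FCC_CUTOFF,
    cutoff: float = energetics.CONTACT_CUTOFF,
) -> list:
    """Single-linkage clustering of complex-status members by fcc.

    For two-chain homodimers the fcc of a pair is the best over both
    chain mappings (identity and swapped), since chain labels of
    identical sequences are arbitrary.  Frequencies are fractions of
    ``n_runs`` (all runs, not just complexes).
    """
    complexes = [m for m in members if m.status == "complex"]
    if not complexes:
        return []
    sets = {
        m.run_id: contact_set(m.model, group_a, group_b, cutoff) for m in complexes
    }
    two_chain = len(set(group_a)) == 1 and len(set(group_b)) == 1
    ids = [m.run_id for m in complexes]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sim = fcc_similarity(sets[a], sets[b])
            if two_chain:
                swapped = _swap_two_chain(
                    sets[b], next(iter(group_a)), next(iter(group_b))
                )
                sim = max(sim, fcc_similarity(sets[a], swapped))
            if sim >= similarity_cutoff:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    groups: dict[int, list] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    by_id = {m.run_id: m for m in complexes}
    clusters = []
    for group in sorted(groups.values(), key=len, reverse=True):
        rep = select_best(group, complexes)
        clusters.append(
            GeometryCluster(
                members=tuple(sorted(group)),
                representative=rep,
                frequency=len(group) / n_runs,
            )
        )
    return clusters


def select_best(cluster, members) -> int:
    """Run id of the member with the best (most negative) ΔG.

    Ties break to the lowest run id.  Predictor confidence (pTM) is
    deliberately ignored: representatives are picked on affinity alone.
    """
    if hasattr(cluster, "members"):
        cluster = cluster.members
    if not cluster:
        raise UsageError("cannot select from an empty cluster")
    by_id = {m.run_id: m for m in members}
    for rid in cluster:
        if by_id.get(rid) is None or by_id[rid].dg is None:
            raise UsageError(f"member {rid} is unscored")
    return min(cluster, key=lambda rid: (by_id[rid].dg.dg, rid))


def classify_topology(
    model: StructureModel,
    domains,
    mobile_label: str = "FMNd",
    cutoff: float = energetics.CONTACT_CUTOFF,
) -> str:
    """Label a two-chain multi-domain model by its mobile-domain pairing.

    Each chain's mobile domain is assigned the partner domain instance
    with which it shares the largest interface contact count.  Both
    mobile domains pairing within their own chain gives ``cis`` (partner
    is a P450-class domain) or ``closed`` (otherwise); both pairing with
    the opposite chain gives ``trans``/``crossed``; anything mixed or
    contact-free is ``undetermined``.
    """
    if len(model.chain_ids) != 2:
        raise UsageError("topology classification needs exactly two chains")
    mobiles = [d for d in domains if d.label == mobile_label]
    partners = [d for d in domains if d.label != mobile_label]
    if len(mobiles) != 2 or not partners:
        raise UsageError(
            f"need the mobile domain {mobile_label!r} on both chains plus "
            "at least one partner domain"
        )

    def residues_of(spec):
        return [
            res.ref
            for res in model.get_chain(spec.chain_id).residues
            if spec.start <= res.ref.res_number <= spec.end
        ]

    assignments = []  # (mobile_chain, partner_spec) per mobile domain
    for mob in mobiles:
        mob_res = residues_of(mob)
        if not mob_res:
            raise UsageError(f"mobile domain on chain {mob.chain_id} is empty")
        best_spec, best_count = None, 0
        for partner in partners:
            _, counts = energetics.contacts_between_selections(
                model, mob_res, residues_of(partner), cutoff
            )
            if counts.total > best_count:
                best_spec, best_count = partner, counts.total
        assignments.append((mob.chain_id, best_spec))

    if any(spec is None for _, spec in assignments):
        return "undetermined"
    same = [cid == spec.chain_id for cid, spec in assignments]
    partner_labels = {spec.label for _, spec in assignments}
    if len(partner_labels) != 1:
        return "undetermined"
    partner_label = partner_labels.pop()
    cis_trans = "p450" in partner_label.lower()
    if all(same):
        return "cis" if cis_trans else "closed"
    if not any(same):
        return "trans" if cis_trans else "crossed"
    return "undetermined"


def arbitrate(
    members,
    group_a,
    group_b,
    dg_threshold: float = energetics.DG_THRESHOLD,
    overlap_fraction: float = OVERLAP_FRACTION,
    similarity_cutoff: float = FCC_CUTOFF,
    min_frequency: float = MIN_FREQUENCY,
    domains=None,
    mobile_label: str = "FMNd",
) -> ArbitrationReport:
    """Full arbitration: score, cluster, select, and (optionally) label.

    The verdict is ``no_complex`` when no multi-member cluster reaches
    ``min_frequency``, ``single_geometry`` when exactly one does, and
    ``alternate_geometries`` otherwise.
    """
    n_runs = len(members)
    if n_runs == 0:
        raise UsageError("empty ensemble")
    scored = score_members(members, group_a, group_b, dg_threshold, overlap_fraction)
    clusters = cluster_geometries(
        scored, group_a, group_b, n_runs, similarity_cutoff
    )
    if domains is not None:
        by_id = {m.run_id: m for m in scored}
        labelled = []
        for cl in clusters:
            try:
                label = classify_topology(
                    by_id[cl.representative].model, domains, mobile_label
                )
            except UsageError:
                label = None
            labelled.append(replace(cl, label=label))
        clusters = labelled
    significant = tuple(
        cl
        for cl in clusters
        if cl.frequency >= min_frequency and not cl.is_singleton
    )
    verdict = (
        "no_complex"
        if not significant
        else "single_geometry"
        if len(significant) == 1
        else "alternate_geometries"
    )
    return ArbitrationReport(
        n_runs=n_runs,
        clusters=tuple(clusters),
        significant=significant,
        verdict=verdict,
        n_no_complex=sum(1 for m in scored if m.status == "no_complex"),
        n_artifact=sum(1 for m in scored if m.status == "artifact_overlap"),
    )
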