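"""Synthetic structures and ensembles with known ground truth.

Everything downstream (energetics, arbitration, assembly, grafting) is
testable offline against these generators: ideal poly-residue helices,
lattice-ball "blob" domains, exact C2 homodimers with a planted symmetry
axis, two-domain dimers with a planted topology label, and ensembles
with planted geometry proportions.  All randomness (coordinate noise,
rigid jitter) derives from the spec seed; identical specs give
bit-identical coordinates.

Domains are deliberately unphysical (poly-residue helices or lattice
balls with CA/CB-level side chains): the oracles here are geometric, not
biochemical.  The default residue cycle mixes charged, polar and apolar
types so that bound fixtures score as complexes under the contact-based
ΔG model while separated chains do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import SymmetryAxis
from .arbitration import EnsembleMember
from .errors import UsageError
from .geometry import RigidTransform, rotation_about_axis
from .structio import (
    AtomRecord,
    Chain,
    DomainSpec,
    Residue,
    ResidueRef,
    StructureModel,
)

__all__ = [
    "FixtureSpec",
    "EnsembleSpec",
    "make_c2_dimer",
    "make_topology_dimer",
    "make_ensemble",
    "build_helix_chain",
    "build_blob_chain",
    "model_from_points",
    "make_cofactor_reference",
    "DEFAULT_SEQUENCE_CYCLE",
    "TOPOLOGY_LABELS",
]

#: Mixed charged/polar/apolar residue cycle for fixture chains.
DEFAULT_SEQUENCE_CYCLE = (
    "LEU", "GLU", "LYS", "ALA", "VAL", "ASP", "SER", "LEU",
)

TOPOLOGY_LABELS = ("crossed", "closed", "cis", "trans")
_ENSEMBLE_LABELS = TOPOLOGY_LABELS + ("none", "overlap")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dimer fixture."""

    n_residues_per_domain: int = 24
    geometry: str = "helix"  # helix | blob
    axis_direction: tuple = (0.0, 0.0, 1.0)
    axis_point: tuple = (0.0, 0.0, 0.0)
    separation: float = 16.0  # chain-centroid separation, Å
    dihedral: float = 0.0  # initial placement angle about the axis, deg
    noise_sigma: float = 0.0  # per-atom isotropic Gaussian noise, Å
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise UsageError("noise_sigma must be >= 0")
        if self.geometry not in ("helix", "blob"):
            raise UsageError(f"unknown fixture geometry {self.geometry!r}")


@dataclass(frozen=True)
class EnsembleSpec:
    """Planted composition of a synthetic prediction ensemble."""

    n_runs: int = 10
    proportions: dict = field(default_factory=lambda: {"crossed": 0.8, "closed": 0.2})
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise UsageError("n_runs must be >= 1")
        unknown = set(self.proportions) - set(_ENSEMBLE_LABELS)
        if unknown:
            raise UsageError(f"unknown ensemble labels: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise UsageError(f"proportions sum to {total}, expected 1")

    def counts(self) -> dict:
        """Integer member counts by largest-remainder apportionment."""
        raw = {k: v * self.n_runs for k, v in self.proportions.items()}
        counts = {k: int(np.floor(v)) for k, v in raw.items()}
        remainder = self.n_runs - sum(counts.values())
        order = sorted(
            self.proportions, key=lambda k: raw[k] - counts[k], reverse=True
        )
        for k in order[:remainder]:
            counts[k] += 1
        return counts


# ---------------------------------------------------------------------------
# Chain builders
# ---------------------------------------------------------------------------

# (radius Å, phase offset deg, axial offset Å) of each atom's own helix
# relative to the CA trace; values give a plausible 5-atom residue.
_HELIX_ATOM_PARAMS = {
    "N": (1.60, -26.0, -0.90),
    "CA": (2.30, 0.0, 0.0),
    "C": (1.70, 26.0, 0.70),
    "O": (2.00, 38.0, 1.30),
    "CB": (3.30, -15.0, -0.30),
}
_HELIX_TWIST = 100.0  # deg per residue
_HELIX_RISE = 1.5  # Å per residue

_ATOM_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _sequence(n: int, cycle) -> list:
    return [cycle[i % len(cycle)] for i in range(n)]


def build_helix_chain(
    n_residues: int,
    chain_id: str = "A",
    start_res: int = 1,
    sequence=None,
    origin=(0.0, 0.0, 0.0),
) -> Chain:
    """Ideal helix along +z starting at ``origin``; 5 atoms per residue
    (N, CA, C, O, CB), poly-alanine unless a sequence cycle is given."""
    names = (
        _sequence(n_residues, sequence)
        if sequence
        else ["ALA"] * n_residues
    )
    origin = np.asarray(origin, dtype=float)
    chain = Chain(chain_id)
    serial = 1
    for i, res_name in enumerate(names):
        ref = ResidueRef(chain_id, start_res + i, "", res_name)
        res = Residue(ref)
        base_phi = np.deg2rad(i * _HELIX_TWIST)
        base_z = i * _HELIX_RISE
        for atom_name, (radius, dphi, dz) in _HELIX_ATOM_PARAMS.items():
            if res_name == "GLY" and atom_name == "CB":
                continue
            phi = base_phi + np.deg2rad(dphi)
            pos = origin + np.array(
                [radius * np.cos(phi), radius * np.sin(phi), base_z + dz]
            )
            res.atoms.append(
                AtomRecord(
                    serial=serial,
                    name=atom_name,
                    element=_ATOM_ELEMENT[atom_name],
                    coords=pos,
                )
            )
            serial += 1
        chain.residues.append(res)
    return chain


def _lattice_ball(n: int, spacing: float = 3.8) -> np.ndarray:
    """The n lattice points closest to the origin (deterministic ball)."""
    k = 1
    while (2 * k + 1) ** 3 < 4 * n:
        k += 1
    axes = np.arange(-k, k + 1)
    grid = np.array(np.meshgrid(axes, axes, axes)).reshape(3, -1).T * spacing
    # lexicographic tie-break keeps the selection deterministic
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0],
                        np.linalg.norm(grid, axis=1)))
    return grid[order[:n]]


def build_blob_chain(
    n_residues: int,
    chain_id: str = "A",
    start_res: int = 1,
    sequence=DEFAULT_SEQUENCE_CYCLE,
    center=(0.0, 0.0, 0.0),
) -> Chain:
    """Compact lattice ball of single-CA residues centred at ``center``."""
    pts = _lattice_ball(n_residues) + np.asarray(center, dtype=float)
    names = _sequence(n_residues, sequence)
    chain = Chain(chain_id)
    for i, (pos, res_name) in enumerate(zip(pts, names)):
        ref = ResidueRef(chain_id, start_res + i, "", res_name)
        chain.residues.append(
            Residue(ref, [AtomRecord(i + 1, "CA", "C", pos)])
        )
    return chain


def blob_radius(n_residues: int, spacing: float = 3.8) -> float:
    """Circumradius of the n-residue lattice ball."""
    pts = _lattice_ball(n_residues, spacing)
    return float(np.linalg.norm(pts, axis=1).max())


def blob_extent(n_residues: int, direction=(0.0, 1.0, 0.0), spacing: float = 3.8) -> float:
    """Extent of the lattice ball along one direction (for placement)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts = _lattice_ball(n_residues, spacing)
    return float(np.abs(pts @ d).max())


def model_from_points(
    points,
    chain_id: str = "A",
    res_name: str = "ALA",
    atom_name: str = "CA",
    element: str = "C",
    start_res: int = 1,
) -> StructureModel:
    """One chain of single-atom residues at the given coordinates
    (test helper for rings, probes and hand-built geometries)."""
    chain = Chain(chain_id)
    for i, pos in enumerate(np.asarray(points, dtype=float).reshape(-1, 3)):
        ref = ResidueRef(chain_id, start_res + i, "", res_name)
        chain.residues.append(
            Residue(ref, [AtomRecord(i + 1, atom_name, element, pos)])
        )
    return StructureModel([chain])


def _apply_noise(model: StructureModel, sigma: float, rng) -> None:
    if sigma <= 0:
        return
    for _, atom in model.iter_atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, 3)


def _frame(direction) -> tuple:
    """Orthonormal (e1, e2, d) with d along ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2, d


# ---------------------------------------------------------------------------
# Dimer generators
# ---------------------------------------------------------------------------


def make_c2_dimer(spec: FixtureSpec) -> tuple:
    """An exact C2 homodimer plus its ground-truth axis.

    Chain A is placed at lateral offset ``separation / 2`` from the
    planted axis; chain B is its exact 180° image about that axis.
    Gaussian noise (``noise_sigma``) is applied after the symmetry
    construction, so the returned axis refers to the noiseless frame.
    """
    e1, e2, d = _frame(spec.axis_direction)
    point = np.asarray(spec.axis_point, dtype=float)
    offset_dir = np.cos(np.deg2rad(spec.dihedral)) * e1 + np.sin(
        np.deg2rad(spec.dihedral)
    ) * e2
    lateral = spec.separation / 2.0

    if spec.geometry == "helix":
        chain_a = build_helix_chain(
            spec.n_residues_per_domain, "A", sequence=DEFAULT_SEQUENCE_CYCLE
        )
        # local frame: helix runs along +z; map +z onto the axis direction
        local = np.array([r.coords for r in _atoms(chain_a)])
        basis = np.column_stack((e1, e2, d))
        center = local.mean(axis=0)
        placed = (local - center) @ basis.T + point + lateral * offset_dir
        _set_coords(chain_a, placed)
    else:
        chain_a = build_blob_chain(
            spec.n_residues_per_domain,
            "A",
            center=point + lateral * offset_dir,
        )

    flip = rotation_about_axis(d, point, 180.0)
    chain_b = Chain("B")
    for res in chain_a.residues:
        ref = ResidueRef("B", res.ref.res_number, "", res.ref.res_name)
        chain_b.residues.append(
            Residue(
                ref,
                [
                    AtomRecord(a.serial, a.name, a.element, flip.apply(a.coords))
                    for a in res.atoms
                ],
            )
        )
    model = StructureModel([chain_a, chain_b], {"fixture": "c2_dimer"})
    rng = np.random.default_rng(spec.seed)
    _apply_noise(model, spec.noise_sigma, rng)
    axis = SymmetryAxis(d, point, 180.0, 0.0)
    return model, axis


def _atoms(chain: Chain):
    for res in chain.residues:
        yield from res.atoms


def _set_coords(chain: Chain, coords: np.ndarray) -> None:
    for atom, pos in zip(_atoms(chain), coords):
        atom.coords = np.asarray(pos, dtype=float)


#: Surface-to-surface gap between interacting fixture domains, Å.
INTERFACE_GAP = 3.8


def make_topology_dimer(label: str, spec: FixtureSpec) -> tuple:
    """Two-chain, two-domain-per-chain dimer with a planted topology.

    Each chain carries a partner domain ("FADd" for closed/crossed,
    "P450d" for cis/trans; residues 1..n) and a mobile domain ("FMNd",
    residues 101..100+n).  All four domains are stacked along the y
    axis: the two partner domains always face each other across a
    ~3.8 Å interface (the dimer-stabilising contact), and each mobile
    domain docks onto the outer face of the partner dictated by
    ``label`` — its own chain's for closed/cis, the opposite chain's
    for crossed/trans.  Returns ``(model, domain_specs)``.
    """
    if label not in TOPOLOGY_LABELS:
        raise UsageError(f"unknown topology label {label!r}")
    n = spec.n_residues_per_domain
    gap = INTERFACE_GAP
    ext = blob_extent(n)  # half-thickness along the stacking axis
    half = ext + gap / 2.0
    arm = 2.0 * ext + gap  # centre-to-centre step giving a ~gap surface gap

    pa = np.array([0.0, -half, 0.0])
    pb = np.array([0.0, +half, 0.0])
    lower = pa + np.array([0.0, -arm, 0.0])  # outer face of partner A
    upper = pb + np.array([0.0, +arm, 0.0])  # outer face of partner B
    same_chain = label in ("closed", "cis")
    if same_chain:
        ma, mb = lower, upper
    else:
        ma, mb = upper, lower

    partner_label = "P450d" if label in ("cis", "trans") else "FADd"
    chain_a = build_blob_chain(n, "A", start_res=1, center=pa)
    chain_a.residues += build_blob_chain(n, "A", start_res=101, center=ma).residues
    chain_b = build_blob_chain(n, "B", start_res=1, center=pb)
    chain_b.residues += build_blob_chain(n, "B", start_res=101, center=mb).residues
    model = StructureModel(
        [chain_a, chain_b], {"fixture": "topology_dimer", "label": label}
    )
    rng = np.random.default_rng(spec.seed)
    _apply_noise(model, spec.noise_sigma, rng)
    domains = [
        DomainSpec(partner_label, "A", 1, n),
        DomainSpec(partner_label, "B", 1, n),
        DomainSpec("FMNd", "A", 101, 100 + n),
        DomainSpec("FMNd", "B", 101, 100 + n),
    ]
    return model, domains


def _jitter_transform(rng) -> RigidTransform:
    """Small random rigid motion (contact-preserving global jitter)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 360.0)
    rot = rotation_about_axis(axis, np.zeros(3), angle)
    shift = RigidTransform(np.eye(3), rng.normal(0.0, 5.0, 3))
    return shift.compose(rot)


def make_ensemble(espec: EnsembleSpec, base: FixtureSpec) -> tuple:
    """A planted prediction ensemble plus per-member truth labels.

    Members are generated per the spec's proportions (largest-remainder
    counts) in label order; each gets per-member coordinate noise (the
    base spec's ``noise_sigma``) and a random global rigid jitter, which
    changes nothing about its interface contacts.  ``none`` members are
    far-separated chain pairs; ``overlap`` members are co-centred
    (artifactual) chain pairs.
    """
    counts = espec.counts()
    members, truth = [], []
    run_id = 0
    for label in _ENSEMBLE_LABELS:
        for _ in range(counts.get(label, 0)):
            seed_i = np.random.SeedSequence([espec.seed, run_id]).generate_state(1)[0]
            rng = np.random.default_rng(seed_i)
            if label in TOPOLOGY_LABELS:
                model, _ = make_topology_dimer(
                    label,
                    FixtureSpec(
                        n_residues_per_domain=base.n_residues_per_domain,
                        geometry="blob",
                        noise_sigma=base.noise_sigma,
                        seed=int(seed_i),
                    ),
                )
            elif label == "none":
                chain_a = build_blob_chain(base.n_residues_per_domain, "A")
                chain_b = build_blob_chain(
                    base.n_residues_per_domain, "B", center=(100.0, 0.0, 0.0)
                )
                model = StructureModel([chain_a, chain_b])
                _apply_noise(model, base.noise_sigma, rng)
            else:  # overlap
                chain_a = build_blob_chain(base.n_residues_per_domain, "A")
                chain_b = build_blob_chain(
                    base.n_residues_per_domain, "B", center=(0.4, 0.3, 0.2)
                )
                model = StructureModel([chain_a, chain_b])
                _apply_noise(model, base.noise_sigma, rng)
            jitter = _jitter_transform(rng)
            members.append(
                EnsembleMember(model=model.transformed(jitter), run_id=run_id)
            )
            truth.append(label)
            run_id += 1
    return members, truth


# ---------------------------------------------------------------------------
# Toy cofactor reference
# ---------------------------------------------------------------------------


def make_cofactor_reference(
    n_residues: int = 20, cofactor_name: str = "HEM"
) -> tuple:
    """A helix domain with a toy 4-atom planar cofactor docked beside it.

    Returns ``(reference model, CofactorTemplate-ready DomainSpec)``;
    the cofactor sits on hetero chain ``H`` as residue 1.
    """
    chain = build_helix_chain(n_residues, "A", sequence=DEFAULT_SEQUENCE_CYCLE)
    # planar 4-atom group next to the helix (x ~ 8 Å from the axis,
    # clear of the CB shell)
    base = np.array([8.0, 0.0, n_residues * _HELIX_RISE / 2.0])
    offsets = np.array(
        [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0], [1.5, 1.5, 0.0]]
    )
    ref = ResidueRef("H", 1, "", cofactor_name)
    res = Residue(
        ref,
        [
            AtomRecord(100 + i, f"C{i+1}", "C", base + off, is_hetero=True)
            for i, off in enumerate(offsets)
        ],
    )
    model = StructureModel([chain, Chain("H", [res])], {"fixture": "cofactor_ref"})
    spec = DomainSpec("fit", "A", 1, n_residues)
    return model, spec
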