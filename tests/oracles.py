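"""Independent brute-force oracles for dual-route checks.

Everything here is written as plainly as possible (explicit loops,
all-pairs scans, no spatial indexing) so it shares no kernel code with
the package implementations it validates.
"""

import itertools
import math

import numpy as np

from cma import tables


def brute_sasa(model, n_points=960, probe=1.4, include_hetero=False):
    """All-pairs Shrake-Rupley: per-residue areas, golden-spiral points."""
    atoms = []  # (ref, radius, xyz)
    for ref, atom in model.iter_atoms():
        if not atom.is_heavy:
            continue
        if ref.res_name in ("HOH", "WAT", "DOD"):
            continue
        if atom.is_hetero and not include_hetero:
            continue
        r = tables.sasa_radius(ref.res_name, atom.name, atom.element) + probe
        atoms.append((ref, r, np.asarray(atom.coords, dtype=float)))

    # golden-spiral points (same quadrature definition as the package;
    # the oracle differs in the neighbour search, not the grid)
    idx = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n_points)
    theta = np.pi * (1.0 + 5.0**0.5) * idx
    unit = np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )

    per_res = {}
    for i, (ref, r_i, xyz_i) in enumerate(atoms):
        exposed = 0
        for point in xyz_i + r_i * unit:
            buried = False
            for j, (_, r_j, xyz_j) in enumerate(atoms):
                if j == i:
                    continue
                if np.dot(point - xyz_j, point - xyz_j) <= r_j * r_j:
                    buried = True
                    break
            if not buried:
                exposed += 1
        area = 4.0 * math.pi * r_i * r_i * exposed / n_points
        per_res[ref] = per_res.get(ref, 0.0) + area
    return per_res


def brute_contacts(model, group_a, group_b, cutoff=5.5):
    """All-pairs interfacial residue contacts: {(key_a, key_b): min_dist}."""
    def atoms_of(group):
        out = []
        for ref, atom in model.iter_atoms():
            if ref.chain_id in group and atom.is_heavy and not atom.is_hetero \
                    and ref.res_name not in ("HOH", "WAT", "DOD"):
                out.append((ref, np.asarray(atom.coords, dtype=float)))
        return out

    pairs = {}
    for ref_a, xyz_a in atoms_of(set(group_a)):
        for ref_b, xyz_b in atoms_of(set(group_b)):
            d = float(np.linalg.norm(xyz_a - xyz_b))
            if d <= cutoff:
                key = (ref_a.key, ref_b.key)
                if d < pairs.get(key, float("inf")):
                    pairs[key] = d
    return pairs


def brute_clashes(model, group_a, group_b, tolerance=0.4, fixed_cutoff=None):
    """All-pairs clash list: [(key_a, name_a, key_b, name_b, dist)]."""
    def atoms_of(group, include_hetero=False):
        out = []
        for ref, atom in model.iter_atoms():
            if ref.chain_id in group and atom.is_heavy \
                    and (include_hetero or not atom.is_hetero) \
                    and ref.res_name not in ("HOH", "WAT", "DOD"):
                out.append((ref, atom.name, atom.element,
                            np.asarray(atom.coords, dtype=float)))
        return out

    clashes = []
    for ref_a, name_a, el_a, xyz_a in atoms_of(set(group_a)):
        for ref_b, name_b, el_b, xyz_b in atoms_of(set(group_b)):
            d = float(np.linalg.norm(xyz_a - xyz_b))
            if fixed_cutoff is not None:
                cut = fixed_cutoff
            else:
                cut = tables.vdw_radius(el_a) + tables.vdw_radius(el_b) - tolerance
            if d < cut:
                clashes.append((ref_a.key, name_a, ref_b.key, name_b, d))
    return clashes


def brute_fcc(contact_sets, normalise="max"):
    """Pairwise fraction-of-common-contacts matrix from raw sets."""
    n = len(contact_sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a, b = contact_sets[i], contact_sets[j]
            if not a or not b:
                mat[i, j] = 0.0
                continue
            common = len(set(a) & set(b))
            denom = max(len(a), len(b)) if normalise == "max" else min(len(a), len(b))
            mat[i, j] = common / denom
    return mat


def brute_min_separation(part_a, part_b, axis_direction, step=0.01,
                         tolerance=0.4, fixed_cutoff=None, s_max=None):
    """Exhaustive fine scan for the outermost clash-free separation.

    Slides part_b's heavy atoms along the axis so the barycenter
    separation equals s, scanning from far out inward; returns the last
    clash-free s before the first clash (or 0.0 if never clashing).
    """
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)

    def atoms_of(model):
        out = []
        for ref, atom in model.iter_atoms():
            if atom.is_heavy:
                out.append((atom.element, np.asarray(atom.coords, dtype=float)))
        return out

    atoms_a = atoms_of(part_a)
    atoms_b = atoms_of(part_b)
    bary_a = np.mean([x for _, x in atoms_a], axis=0)
    bary_b = np.mean([x for _, x in atoms_b], axis=0)
    s0 = float(np.dot(bary_b - bary_a, d))
    sign = 1.0 if s0 >= 0 else -1.0
    if s_max is None:
        r_a = max(np.linalg.norm(x - bary_a) for _, x in atoms_a)
        r_b = max(np.linalg.norm(x - bary_b) for _, x in atoms_b)
        big = fixed_cutoff if fixed_cutoff is not None else 2 * 2.0
        s_max = r_a + r_b + big + 1.0

    # all-pairs cutoff matrix and coordinate arrays (vectorised distance
    # evaluation; the scan itself stays exhaustive)
    xa = np.array([x for _, x in atoms_a])
    xb = np.array([x for _, x in atoms_b])
    if fixed_cutoff is not None:
        cut = np.full((len(atoms_a), len(atoms_b)), float(fixed_cutoff))
    else:
        ra = np.array([tables.vdw_radius(el) for el, _ in atoms_a])
        rb = np.array([tables.vdw_radius(el) for el, _ in atoms_b])
        cut = ra[:, None] + rb[None, :] - tolerance

    def clash_at(s):
        shift = (sign * s - s0) * d
        dist = np.linalg.norm(xa[:, None, :] - (xb + shift)[None, :, :], axis=2)
        return bool((dist < cut).any())

    best = None
    s = s_max
    while s >= -step / 2:
        if clash_at(max(s, 0.0)):
            break
        best = max(s, 0.0)
        s -= step
    return best


def closed_form_rmsd_after_fit(mobile, target):
    """RMSD after optimal superposition via the Kabsch residual formula:
    E = sum|p|^2 + sum|q|^2 - 2*sum(singular values of covariance),
    with a chirality sign on the smallest singular value."""
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(target, dtype=float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    cov = p.T @ q
    sv = np.linalg.svd(cov, compute_uv=False)
    sign = np.sign(np.linalg.det(cov)) or 1.0
    traced = sv[0] + sv[1] + sign * sv[2]
    e = (p**2).sum() + (q**2).sum() - 2.0 * traced
    return math.sqrt(max(e, 0.0) / len(p))
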