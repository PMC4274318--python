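"""Synthetic test structures: toy dimers, planted symmetric tetramers,
spin-label ensembles and restraint tables.

Everything the test-suite and the worked examples need is generated here
programmatically — toy two-chain bodies built from idealised backbone
internal coordinates (alpha-helical phi/psi), duplicated and placed by a
planted C2 transform to form a dimer-of-dimers whose ground-truth relative
pose is known exactly.  The docking start point mirrors the real workflow:
the second dimer carries the planted orientation but is separated by a
100 Å translation, so the minimiser has to bring the bodies back together
against the restraints.

These fixtures are deliberately *not* realistic proteins: no hydrogens, no
loops, idealised geometry, a handful of bulky side chains (PHE/TYR/LEU) at
the interface purely so that torsion refinement has something to move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pdb_model import Structure, concatenate, select_atoms
from .restraints import DistanceRestraint, NCSGroup, effective_distance
from .spin_labeller import (
    LabelSite,
    SamplerParams,
    build_cb,
    ensemble_to_structure,
    extract_n1_ensemble,
    place_atom,
    search_r1_conformers,
)

__all__ = [
    "FixtureSpec",
    "DockingCase",
    "make_toy_dimer",
    "make_exposed_site",
    "plant_tetramer",
    "synth_restraints",
    "planted_tetramer_case",
    "relative_pose_error",
]

# idealised alpha-helix backbone torsions (degrees)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


@dataclass
class FixtureSpec:
    """Parameters of the planted-assembly generator."""

    n_residues: int = 24
    fold: str = "helix"
    segids: tuple = ("A", "B")
    copy_segids: tuple = ("C", "D")
    # planted transform: rotation about z plus an in-plane offset; 180 deg
    # with tz = 0 makes the assembly an exact C2 dimer-of-dimers
    planted_rotation_deg: float = 180.0
    planted_offset: tuple = (43.0, 5.0)
    separation: tuple = (0.0, 100.0, 0.0)
    label_sites: tuple = (("A", 6), ("A", 18), ("B", 12), ("B", 20))
    restraint_noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")


@dataclass
class DockingCase:
    """A ready-to-dock planted problem with known ground truth."""

    structure: Structure  # separated start, protein + SPIN ensembles
    truth_structure: Structure  # assembled ground truth (same atoms)
    restraints: list
    ncs_groups: list
    group_selections: tuple
    truth_rotation: np.ndarray  # reference dimer -> planted copy
    truth_translation: np.ndarray
    flexible_ranges: dict  # segid -> list of (lo, hi) residue ranges
    spec: FixtureSpec = None


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

_SIDECHAINS = {
    # name: list of (atom, (a, b, c), bond, angle, dihedral); CB is implicit
    "ALA": [],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.53, 116.3, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, 180.0),
        ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, 60.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, 90.0),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, -90.0),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
}
_SIDECHAINS["TYR"] = _SIDECHAINS["PHE"] + [
    ("OH", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0),
]


def _build_chain(sequence, segid: str, chain: str, first_resid: int = 1) -> Structure:
    """Idealised alpha-helical chain with full backbone and side chains."""
    names, resnames, resids, coords = [], [], [], []
    prev = {}
    for i, resname in enumerate(sequence):
        resid = first_resid + i
        if i == 0:
            n = np.zeros(3)
            ca = np.array([1.458, 0.0, 0.0])
            c = place_atom(
                np.array([-0.5, 1.2, 0.0]), n, ca, 1.525, 111.2, _PHI
            )
        else:
            n = place_atom(prev["N"], prev["CA"], prev["C"], 1.33, 116.2, _PSI)
            ca = place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, _OMEGA)
            c = place_atom(prev["C"], n, ca, 1.525, 111.2, _PHI)
            o_prev = place_atom(n, prev["CA"], prev["C"], 1.23, 120.8, 180.0)
            names.append("O"); resnames.append(prev["resname"])
            resids.append(prev["resid"]); coords.append(o_prev)
        res_atoms = {"N": n, "CA": ca, "C": c}
        res_atoms["CB"] = build_cb(n, ca, c)
        for nm, (a, b, cc), bond, angle, dihe in _SIDECHAINS.get(resname, []):
            res_atoms[nm] = place_atom(
                res_atoms[a], res_atoms[b], res_atoms[cc], bond, angle, dihe
            )
        for nm, pos in res_atoms.items():
            names.append(nm); resnames.append(resname)
            resids.append(resid); coords.append(pos)
        prev = {"N": n, "CA": ca, "C": c, "resname": resname, "resid": resid}
    # carbonyl O of the final residue, anti to the phantom next N
    o_last = place_atom(prev["N"], prev["CA"], prev["C"], 1.23, 120.8, _PSI + 180.0)
    names.append("O"); resnames.append(prev["resname"])
    resids.append(prev["resid"]); coords.append(o_last)
    coords = np.array(coords)
    # align the helix axis with x and centre at the origin
    ca_idx = [k for k, nm in enumerate(names) if nm == "CA"]
    ca = coords[ca_idx]
    centre = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centre)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, axis)
    y /= np.linalg.norm(y)
    z2 = np.cross(axis, y)
    R = np.stack([axis, y, z2])  # rows: new basis
    coords = (coords - centre) @ R.T
    return Structure(
        names=names,
        resnames=resnames,
        chains=[chain] * len(names),
        resids=resids,
        coords=coords,
        segids=[segid] * len(names),
        provenance=f"toy chain {segid}",
    )


def _dimer_sequence(n_residues: int):
    seq = ["ALA"] * n_residues
    # bulky residues spaced along the chain for interface torsion tests
    for pos, res in ((n_residues // 3, "PHE"), (n_residues // 2, "LEU"),
                     (2 * n_residues // 3, "TYR")):
        seq[pos] = res
    return seq


def make_toy_dimer(spec: FixtureSpec) -> Structure:
    """Two-chain antiparallel helical body with segids ``spec.segids``."""
    if spec.fold != "helix":
        raise ValueError(f"unknown fold generator {spec.fold!r}")
    seq = _dimer_sequence(spec.n_residues)
    a = _build_chain(seq, spec.segids[0], spec.segids[0][:1])
    b = _build_chain(seq, spec.segids[1], spec.segids[1][:1])
    flip = np.diag([1.0, -1.0, -1.0])  # 180 deg about x: antiparallel partner
    b.coords = b.coords @ flip.T + np.array([0.0, 10.5, 0.0])
    dimer = concatenate([a, b], provenance="toy dimer")
    dimer.coords -= dimer.coords.mean(axis=0)
    return dimer


def make_exposed_site(segid: str = "A", resid: int = 1) -> Structure:
    """A single isolated residue: a labelling site with no clash partners."""
    return _build_chain(["ALA"], segid, segid[:1], first_resid=resid)


# ---------------------------------------------------------------------------
# Planted tetramer
# ---------------------------------------------------------------------------


def _planted_transform(spec: FixtureSpec):
    dx, dy = spec.planted_offset
    ang = np.deg2rad(spec.planted_rotation_deg)
    c, s = np.cos(ang), np.sin(ang)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t = np.array([dx, dy, 0.0])
    return R, t


def plant_tetramer(spec: FixtureSpec):
    """Duplicate the dimer, place the copy by the planted C2 transform, then
    separate it to build the docking start point.

    Returns ``(start_structure, (rotation, translation), truth_structure)``
    where the transform maps reference-dimer coordinates onto the planted
    copy, and the start structure has the copy displaced by
    ``spec.separation``.
    """
    dimer = make_toy_dimer(spec)
    R, t = _planted_transform(spec)
    copy = dimer.copy()
    copy.segids = [
        spec.copy_segids[spec.segids.index(g)] for g in copy.segids
    ]
    copy.chains = [g[:1] for g in copy.segids]
    copy.coords = copy.coords @ R.T + t
    truth = concatenate([dimer, copy], provenance="planted tetramer (truth)")
    min_d = _min_interbody_distance(dimer.coords, copy.coords)
    if min_d < 1.5:
        warnings.warn(
            f"planted transform leaves bodies overlapping (min distance "
            f"{min_d:.2f} Å)", stacklevel=2,
        )
    start_copy = copy.copy()
    start_copy.coords = start_copy.coords + np.asarray(spec.separation, dtype=float)
    start = concatenate([dimer, start_copy], provenance="planted tetramer (start)")
    return start, (R, t), truth


def _min_interbody_distance(xa, xb):
    from scipy.spatial import cKDTree

    return float(cKDTree(xb).query(xa, k=1)[0].min())


# ---------------------------------------------------------------------------
# Restraints from ground truth
# ---------------------------------------------------------------------------


def synth_restraints(ensemble_pairs, noise_sd: float, seed: int):
    """Restraints from ground-truth ensemble pairs with Gaussian noise.

    ``ensemble_pairs`` is a list of (SpinEnsemble, SpinEnsemble) evaluated
    at the ground-truth pose; targets are the R-3 effective distances plus
    N(0, noise_sd) noise, with bounds ±max(noise_sd, 0.1) Å.
    """
    rng = np.random.default_rng(seed)
    bound = max(noise_sd, 0.1)
    out = []
    for ea, eb in ensemble_pairs:
        d = effective_distance(ea.n1_positions, eb.n1_positions, "R-3")
        noisy = d + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        out.append(
            DistanceRestraint(
                f"segid {ea.segid_out} and resid {ea.resid_out} and name N*",
                f"segid {eb.segid_out} and resid {eb.resid_out} and name N*",
                round(float(noisy), 3),
                bound,
                bound,
                label=f"{ea.segid_out}{ea.resid_out}-{eb.segid_out}{eb.resid_out}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full planted docking case
# ---------------------------------------------------------------------------


def planted_tetramer_case(
    seed: int = 0,
    noise_sd: float = 0.0,
    n_residues: int = 24,
    max_conformers: int = 40,
    thoroughness: int = 800,
) -> DockingCase:
    """Planted C2 tetramer with spin ensembles, restraints and NCS groups.

    The seed drives the planted in-plane offset, the label conformer
    sampling and the restraint noise.  Label ensembles are generated on the
    ground-truth assembly (so the restraints are realisable), then carried
    rigidly with their parent bodies into the separated start structure.
    """
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        n_residues=n_residues,
        planted_offset=(float(rng.uniform(42.0, 44.0)), float(rng.uniform(4.0, 7.0))),
        restraint_noise_sd=noise_sd,
        rng_seed=seed,
    )
    start, (R, t), truth = plant_tetramer(spec)

    # label the truth assembly at mirrored sites on both bodies
    sites_body1 = [(seg, res) for seg, res in spec.label_sites]
    seg_map = dict(zip(spec.segids, spec.copy_segids))
    sites_body2 = [(seg_map[seg], res) for seg, res in sites_body1]
    ensembles_s, ensembles_t = [], []
    for k, ((seg1, res1), (seg2, res2)) in enumerate(
        zip(sites_body1, sites_body2), start=1
    ):
        p = SamplerParams(
            max_conformers=max_conformers,
            thoroughness=thoroughness,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        conf1 = search_r1_conformers(truth, LabelSite(seg1, res1), p)
        ensembles_s.append(extract_n1_ensemble(conf1, k, "S", parent_body="body1"))
        conf2 = search_r1_conformers(truth, LabelSite(seg2, res2), p)
        ensembles_t.append(extract_n1_ensemble(conf2, k, "T", parent_body="body2"))

    pair_ids = [(0, 0), (1, 1), (2, 2), (3, 3), (0, 1), (1, 0),
                (2, 3), (3, 2), (0, 2), (2, 0)]
    pairs = [(ensembles_s[i], ensembles_t[j]) for i, j in pair_ids]
    restraints = synth_restraints(pairs, noise_sd, int(rng.integers(0, 2**31 - 1)))

    truth_full = concatenate(
        [truth] + [ensemble_to_structure(e) for e in ensembles_s]
        + [ensemble_to_structure(e) for e in ensembles_t],
        provenance="planted tetramer truth + ensembles",
    )
    # build the start: displace body2 (copy segids + its T ensembles)
    start_full = truth_full.copy()
    body2_segids = set(spec.copy_segids) | {"T"}
    mask = np.array([g in body2_segids for g in start_full.segids])
    start_full.coords[mask] += np.asarray(spec.separation)
    start_full.provenance = "planted tetramer start + ensembles"

    # NCS equivalence groups consistent with the planted mapping A->C, B->D:
    # the A-to-D relationship maps under the C2 onto C-to-B (and B-to-C onto
    # D-to-A), so copies are ordered concatenations.
    a, b = spec.segids
    c, d = spec.copy_segids
    ncs_groups = [
        NCSGroup(
            copies=[
                [f"segid {a} and name CA", f"segid {d} and name CA"],
                [f"segid {c} and name CA", f"segid {b} and name CA"],
            ],
            weight_ncs=1.0,
            name="group1",
        ),
        NCSGroup(
            copies=[
                [f"segid {b} and name CA", f"segid {c} and name CA"],
                [f"segid {d} and name CA", f"segid {a} and name CA"],
            ],
            weight_ncs=1.0,
            name="group2",
        ),
    ]

    flex_lo, flex_hi = n_residues // 3 - 1, 2 * n_residues // 3 + 1
    flexible = {s: [(flex_lo, flex_hi)] for s in (a, b, c, d)}

    return DockingCase(
        structure=start_full,
        truth_structure=truth_full,
        restraints=restraints,
        ncs_groups=ncs_groups,
        group_selections=(
            f"segid {a} or segid {b} or segid S",
            f"segid {c} or segid {d} or segid T",
        ),
        truth_rotation=R,
        truth_translation=t,
        flexible_ranges=flexible,
        spec=spec,
    )


def relative_pose_error(final: Structure, case: DockingCase):
    """Rotation (deg) and translation (Å) error of the recovered
    inter-body transform against the planted one.

    The relative transform body1→body2 is computed by superposing the
    reference dimer onto each body of the final structure; the global pose
    of the assembly drops out.
    """
    from .restraints import kabsch_superpose

    spec = case.spec
    ref = make_toy_dimer(spec)
    sel1 = " or ".join(f"segid {s}" for s in spec.segids)
    sel2 = " or ".join(f"segid {s}" for s in spec.copy_segids)
    idx1 = select_atoms(final, sel1)
    idx2 = select_atoms(final, sel2)
    R1, t1, _ = kabsch_superpose(final.coords[idx1], ref.coords)
    R2, t2, _ = kabsch_superpose(final.coords[idx2], ref.coords)
    # relative transform in body1's frame: T_rel = T1^-1 o T2
    R_rel = R1.T @ R2
    t_rel = R1.T @ (t2 - t1)
    R_err = R_rel @ case.truth_rotation.T
    cos_ang = (np.trace(R_err) - 1.0) / 2.0
    angle = float(np.degrees(np.arccos(np.clip(cos_ang, -1.0, 1.0))))
    c_ref = ref.coords.mean(axis=0)
    trans_err = float(
        np.linalg.norm(
            (R_rel @ c_ref + t_rel)
            - (case.truth_rotation @ c_ref + case.truth_translation)
        )
    )
    return angle, trans_err
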