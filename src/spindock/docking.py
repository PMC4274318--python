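"""Rigid-body pose optimisation against restraint + symmetry + contact
energies, and interface side-chain torsion refinement.

Each rigid group (a protein body plus the spin ensembles riding on it)
moves only by rotation + translation, so its internal geometry is exactly
preserved.  The staged protocol mirrors the classic restraint-driven
docking recipe:

1. distance restraints only, with a vanishing repulsive radius scale so
   the bodies can pass through each other (``repel = 1e-9``, 100 steps);
2. restraints + symmetry (NCS) restraints, still ghost-like (200 steps);
3. restraints + NCS + soft repulsion at ``repel = 0.7`` to expel steric
   clashes (100 steps);
4. torsion refinement of interface side chains with the physical
   Lennard-Jones + electrostactics terms (``repel = 0``), backbone and
   ring moieties rigid.

The default minimiser is gradient descent over each group's 6-DOF pose
(force + torque about the group centroid) with a backtracking line search
whose first trial step is sized from ``drop`` (the expected initial energy
decrease); a derivative-free Powell fallback over the stacked pose vector
is available.  Accepted steps never increase the stage objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .forcefield import (
    InteractionBlock,
    NonbondedParams,
    assign_params,
    build_pair_list,
    lj_coulomb_energy,
    repel_energy,
)
from .pdb_model import Structure, select_atoms, write_pdb
from .restraints import (
    RestraintParams,
    effective_distance_gradient,
    ncs_energy_gradient,
    square_well_energy,
    well_energy_and_slope,
)

__all__ = [
    "RigidGroup",
    "StageConfig",
    "TorsionConfig",
    "EnergyBreakdown",
    "DockingSystem",
    "pose_energy_gradient",
    "minimize_rigid",
    "torsion_refine",
    "run_staged_protocol",
    "default_stages",
]

_TERM_NAMES = ("BOND", "ANGL", "DIHE", "IMPR", "VDW", "ELEC", "NCS", "NOE")


@dataclass
class RigidGroup:
    """One rigid body: an id and the member selection (protein segments
    plus their spin ensembles, e.g. ``segid A or segid B or segid S``)."""

    id: str
    selection: str
    indices: np.ndarray = None


@dataclass
class StageConfig:
    name: str
    terms: tuple = ("NOE",)
    repel: float = 1e-9
    nstep: int = 100
    drop: float = 10.0
    minimiser: str = "gradient"  # or "powell"

    def __post_init__(self):
        if self.nstep < 1:
            raise ValueError("nstep must be >= 1")
        if self.drop <= 0:
            raise ValueError("drop must be > 0")
        bad = set(self.terms) - {"NOE", "NCS", "VDW", "ELEC"}
        if bad:
            raise ValueError(f"unknown energy terms {sorted(bad)}")


@dataclass
class TorsionConfig:
    """Interface side-chain refinement options.

    ``flexible``: segid -> list of (lo, hi) inclusive residue ranges whose
    side chains may rotate.  Ring moieties (PHE/HIS/TYR/TRP) move only as
    rigid units and PRO is always rigid.  ``nstep`` caps the total number
    of trial energy evaluations, ``maxe`` the evaluations per sweep.
    """

    flexible: dict = field(default_factory=dict)
    nstep: int = 2000
    depred: float = 1.0
    maxe: int = 1000


@dataclass
class EnergyBreakdown:
    """XPLOR-style per-term energies.  Bonded terms (BOND/ANGL/DIHE/IMPR)
    are always 0 here: the bodies carry no bonded force field."""

    etotal: float
    grad_norm: float
    terms: dict
    noe_rows: list = field(default_factory=list)

    @classmethod
    def build(cls, terms: dict, grad_norm: float, noe_rows=None):
        full = {k: float(terms.get(k, 0.0)) for k in _TERM_NAMES}
        return cls(
            etotal=float(sum(full.values())),
            grad_norm=float(grad_norm),
            terms=full,
            noe_rows=list(noe_rows or []),
        )

    def to_dict(self):
        return {
            "etotal": self.etotal,
            "grad_norm": self.grad_norm,
            "terms": dict(self.terms),
            "noe_rows": [vars(r).copy() for r in self.noe_rows],
        }


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------


class DockingSystem:
    """Immutable problem definition + mutable coordinate state.

    Resolves selections once (groups, restraint endpoints, NCS copies),
    assigns non-bonded parameters, and evaluates stage energies and
    Cartesian gradients on demand.
    """

    def __init__(
        self,
        structure: Structure,
        group_selections,
        restraints,
        ncs_groups=(),
        restraint_params: RestraintParams | None = None,
        nb_params: NonbondedParams | None = None,
        flexible_ranges: dict | None = None,
        charges=None,
    ):
        self.structure = structure.copy()
        self.rparams = restraint_params or RestraintParams()
        self.nb = nb_params or NonbondedParams()
        self.atom_params = assign_params(structure, charges)
        self.groups = []
        for k, sel in enumerate(group_selections):
            idx = select_atoms(structure, sel)
            if len(idx) == 0:
                raise ValueError(f"rigid group {k} ({sel!r}) selects no atoms")
            self.groups.append(RigidGroup(id=f"group{k + 1}", selection=sel,
                                          indices=idx))
        owners = np.full(structure.natoms, -1, dtype=int)
        for k, g in enumerate(self.groups):
            if np.any(owners[g.indices] >= 0):
                raise ValueError("rigid groups must be disjoint")
            owners[g.indices] = k
        self.group_of_atom = owners

        self.restraints = list(restraints)
        self._restraint_idx = []
        for r in self.restraints:
            ia = select_atoms(structure, r.sel_a)
            ib = select_atoms(structure, r.sel_b)
            if len(ia) == 0 or len(ib) == 0:
                raise ValueError(f"restraint {r.label!r} resolves to empty selection")
            self._restraint_idx.append((ia, ib))

        self.ncs_groups = list(ncs_groups)
        self._ncs_resolved = [
            (g.resolve(structure), g.weight_ncs) for g in self.ncs_groups
        ]
        self.flexible_ranges = dict(flexible_ranges or {})
        self._protein = np.array(
            [rn.upper() != "SPIN" for rn in structure.resnames]
        )

    # -- interaction blocks ------------------------------------------------

    def _interbody_block(self):
        g1 = self.groups[0].indices[self._protein[self.groups[0].indices]]
        g2 = self.groups[1].indices[self._protein[self.groups[1].indices]]
        return InteractionBlock(g1, g2, 1.0, 1.0)

    def _intra_interface_blocks(self):
        """Per-segment self blocks over the flexible interface residues,
        with electrostatics weight zero (side-chain refinement stage)."""
        blocks = []
        for segid, ranges in self.flexible_ranges.items():
            sel = " or ".join(f"resid {lo}:{hi}" for lo, hi in ranges)
            idx = select_atoms(self.structure, f"segid {segid} and ({sel})")
            if len(idx):
                blocks.append(InteractionBlock(idx, idx, 1.0, 0.0))
        return blocks

    def interaction_blocks(self, stage: StageConfig):
        blocks = [self._interbody_block()]
        if stage.repel == 0.0:
            blocks.extend(self._intra_interface_blocks())
        return blocks

    # -- energy evaluation -------------------------------------------------

    def evaluate(self, coords: np.ndarray, stage: StageConfig):
        """Energy breakdown, Cartesian gradient and the stage objective.

        The objective differs from the reported breakdown only in the NOE
        term, which continues linearly beyond the ceiling cap so that
        badly violated restraints still exert force.
        """
        terms = {}
        grad = np.zeros_like(coords)
        e_opt = 0.0
        noe_rows = []
        if "NOE" in stage.terms:
            e_noe = 0.0
            for r, (ia, ib) in zip(self.restraints, self._restraint_idx):
                r_eff, ga, gb = effective_distance_gradient(
                    coords[ia], coords[ib], self.rparams.averaging
                )
                row = square_well_energy(r_eff, r, self.rparams)
                noe_rows.append(row)
                e_noe += row.energy
                e_ext, slope = well_energy_and_slope(r_eff, r, self.rparams)
                e_opt += e_ext
                if slope != 0.0:
                    np.add.at(grad, ia, slope * ga)
                    np.add.at(grad, ib, slope * gb)
            terms["NOE"] = e_noe
        if "NCS" in stage.terms and self._ncs_resolved:
            e_ncs, g_ncs = ncs_energy_gradient(coords, self._ncs_resolved)
            terms["NCS"] = e_ncs
            e_opt += e_ncs
            grad += g_ncs
        wants_nb = "VDW" in stage.terms or "ELEC" in stage.terms
        if wants_nb:
            blocks = self.interaction_blocks(stage)
            if stage.repel > 0.0:
                nb = NonbondedParams(**{**vars(self.nb), "repel": stage.repel})
                cutoff = stage.repel * 2.0 * float(self.atom_params.radius.max())
                pairs = build_pair_list(
                    coords, self.atom_params, blocks, cutoff,
                    self.structure.segids, self.structure.resids,
                )
                e_vdw, g_vdw = repel_energy(coords, pairs, self.atom_params, nb)
                terms["VDW"] = e_vdw
                e_opt += e_vdw
                grad += g_vdw
            else:
                pairs = build_pair_list(
                    coords, self.atom_params, blocks, self.nb.cutnb,
                    self.structure.segids, self.structure.resids,
                )
                e_vdw, e_elec, g_nb = lj_coulomb_energy(
                    coords, pairs, self.atom_params, self.nb
                )
                terms["VDW"] = e_vdw
                terms["ELEC"] = e_elec
                e_opt += e_vdw + e_elec
                grad += g_nb
        grad_norm = float(np.sqrt(np.mean(np.sum(grad * grad, axis=1))))
        breakdown = EnergyBreakdown.build(terms, grad_norm, noe_rows)
        return breakdown, grad, e_opt


# ---------------------------------------------------------------------------
# Rigid-body minimisation
# ---------------------------------------------------------------------------


def _group_generalized_gradient(coords, grad, group: RigidGroup):
    """Force, torque about the centroid, and mean squared radius."""
    idx = group.indices
    f = grad[idx].sum(axis=0)
    centre = coords[idx].mean(axis=0)
    rel = coords[idx] - centre
    tau = np.sum(np.cross(rel, grad[idx]), axis=0)
    m2 = float(np.mean(np.sum(rel * rel, axis=1)))
    return f, tau, max(m2, 1e-12), centre


def pose_energy_gradient(system: DockingSystem, stage: StageConfig, coords=None):
    """Stage energy breakdown plus the 6-DOF gradient of every group.

    Returns ``(breakdown, [(torque, force), ...])`` where the torque is
    taken about each group's centroid; spin ensembles contribute only
    through the NOE term (their atoms are excluded from non-bonded pairs).
    """
    if coords is None:
        coords = system.structure.coords
    breakdown, grad, _ = system.evaluate(coords, stage)
    out = []
    for g in system.groups:
        f, tau, _, _ = _group_generalized_gradient(coords, grad, g)
        out.append((tau, f))
    return breakdown, out


def _apply_group_step(coords, group, rotvec, trans):
    idx = group.indices
    centre = coords[idx].mean(axis=0)
    R = Rotation.from_rotvec(rotvec).as_matrix()
    coords[idx] = (coords[idx] - centre) @ R.T + centre + trans


@dataclass
class MinimizeResult:
    coords: np.ndarray
    pre: EnergyBreakdown
    post: EnergyBreakdown
    energies: list  # accepted-step objective values (non-increasing)
    n_iter: int


def minimize_rigid(system: DockingSystem, stage: StageConfig, coords=None
                   ) -> MinimizeResult:
    """Minimise the stage objective over the rigid-group poses.

    Gradient descent with backtracking line search (default): the descent
    direction is the negative force for translation and the negative
    torque scaled by the group's mean squared radius for rotation; the
    first trial step is sized so the predicted linear decrease equals
    ``drop``.  The ``powell`` minimiser optimises the stacked
    (rotation-vector, translation) parameters derivative-free.
    """
    if coords is None:
        coords = system.structure.coords.copy()
    else:
        coords = np.array(coords, dtype=float)
    pre, _, e0 = system.evaluate(coords, stage)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at minimisation start")
    if stage.minimiser == "powell":
        return _minimize_powell(system, stage, coords, pre)

    energies = [e0]
    e_cur = e0
    alpha = None
    stall = 0
    it = 0
    for it in range(1, stage.nstep + 1):
        _, grad, _ = system.evaluate(coords, stage)
        steps = []
        pred = 0.0
        for g in system.groups:
            f, tau, m2, _ = _group_generalized_gradient(coords, grad, g)
            dw = -tau / m2
            dt = -f
            pred += float(tau @ tau) / m2 + float(f @ f)
            steps.append((g, dw, dt))
        if pred < 1e-18:
            break
        if alpha is None:
            alpha = stage.drop / pred
        a = alpha
        accepted = False
        for _ in range(50):
            trial = coords.copy()
            for g, dw, dt in steps:
                _apply_group_step(trial, g, a * dw, a * dt)
            _, _, e_new = system.evaluate(trial, stage)
            if np.isfinite(e_new) and e_new < e_cur - 1e-12:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            break
        coords = trial
        energies.append(e_new)
        stall = stall + 1 if abs(e_cur - e_new) < 1e-6 else 0
        e_cur = e_new
        alpha = a * 2.0
        if stall >= 5:
            break
    post, _, _ = system.evaluate(coords, stage)
    return MinimizeResult(coords, pre, post, energies, it)


def _minimize_powell(system, stage, coords, pre) -> MinimizeResult:
    base = coords.copy()
    centres = [base[g.indices].mean(axis=0) for g in system.groups]
    n = len(system.groups)

    def build(x):
        out = base.copy()
        for k, g in enumerate(system.groups):
            w = x[6 * k:6 * k + 3]
            t = x[6 * k + 3:6 * k + 6]
            R = Rotation.from_rotvec(w).as_matrix()
            out[g.indices] = (base[g.indices] - centres[k]) @ R.T + centres[k] + t
        return out

    def objective(x):
        _, _, e = system.evaluate(build(x), stage)
        return e

    res = _scipy_minimize(
        objective,
        np.zeros(6 * n),
        method="Powell",
        options={"maxiter": stage.nstep, "xtol": 1e-6, "ftol": 1e-8},
    )
    final = build(res.x)
    post, _, e_final = system.evaluate(final, stage)
    _, _, e0 = system.evaluate(base, stage)
    if e_final > e0:  # never accept an uphill "optimum"
        final, post = base, pre
        e_final = e0
    return MinimizeResult(final, pre, post, [e0, e_final], int(res.nit))


# ---------------------------------------------------------------------------
# Torsion refinement
# ---------------------------------------------------------------------------

# side-chain rotatable dihedrals: resname -> [(axis (a, b), moving atoms)]
# ring atoms always appear together in a moving set, so rings stay rigid.
_CHI_MOVING = {
    "LEU": [
        (("CA", "CB"), ("CG", "CD1", "CD2")),
        (("CB", "CG"), ("CD1", "CD2")),
    ],
    "PHE": [
        (("CA", "CB"), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")),
        (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ")),
    ],
    "TYR": [
        (("CA", "CB"), ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
        (("CB", "CG"), ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    ],
    # HIS/TRP handled as single-ring chi pairs when present
    "HIS": [
        (("CA", "CB"), ("CG", "ND1", "CD2", "CE1", "NE2")),
        (("CB", "CG"), ("ND1", "CD2", "CE1", "NE2")),
    ],
    "TRP": [
        (("CA", "CB"),
         ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
        (("CB", "CG"),
         ("CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    ],
}
_BACKBONE = {"N", "CA", "C", "O", "HN", "HA", "CB"}


def _flexible_chis(system: DockingSystem, tc: TorsionConfig):
    """Resolve (residue, chi) rotation units within the flexible ranges."""
    s = system.structure
    units = []
    for segid, ranges in tc.flexible.items():
        resids = sorted(
            {
                int(r)
                for i, r in enumerate(s.resids)
                if s.segids[i] == segid
                and any(lo <= r <= hi for lo, hi in ranges)
            }
        )
        for resid in resids:
            idx = select_atoms(s, f"segid {segid} and resid {resid}")
            if len(idx) == 0:
                continue
            resname = s.resnames[idx[0]].upper()
            if resname == "PRO":
                continue  # whole residue rigid
            chis = _CHI_MOVING.get(resname)
            if not chis:
                continue
            names = {s.names[i]: i for i in idx}
            for (a, b), moving in chis:
                if a not in names or b not in names:
                    continue
                mov = [names[m] for m in moving if m in names]
                if not mov:
                    continue
                units.append(
                    {
                        "segid": segid,
                        "resid": resid,
                        "resname": resname,
                        "axis": (names[a], names[b]),
                        "moving": np.array(mov, dtype=int),
                        "residue": idx,
                    }
                )
    return units


def _rotate_about_axis(coords, unit, angle_deg):
    ia, ib = unit["axis"]
    origin = coords[ib]
    axis = coords[ib] - coords[ia]
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    mov = unit["moving"]
    coords[mov] = (coords[mov] - origin) @ R.T + origin


def _torsion_local_energy(system, coords, unit, stage):
    """Non-bonded energy of the moving atoms against everything outside
    their own residue (inter-body with full weights, intra-body with
    electrostatics off)."""
    s = system.structure
    mov = unit["moving"]
    own = np.zeros(s.natoms, dtype=bool)
    own[unit["residue"]] = True
    body = system.group_of_atom[mov[0]]
    others = np.nonzero(~own & system._protein)[0]
    same_body = system.group_of_atom[others] == body
    blocks = [
        InteractionBlock(mov, others[~same_body], 1.0, 1.0),
        InteractionBlock(mov, others[same_body], 1.0, 0.0),
    ]
    s_ids, r_ids = system.structure.segids, system.structure.resids
    if stage.repel > 0.0:
        nb = NonbondedParams(**{**vars(system.nb), "repel": stage.repel})
        cutoff = stage.repel * 2.0 * float(system.atom_params.radius.max())
        pairs = build_pair_list(coords, system.atom_params, blocks, cutoff,
                                s_ids, r_ids)
        e, _ = repel_energy(coords, pairs, system.atom_params, nb)
        return e
    pairs = build_pair_list(coords, system.atom_params, blocks, system.nb.cutnb,
                            s_ids, r_ids)
    e_vdw, e_elec, _ = lj_coulomb_energy(coords, pairs, system.atom_params,
                                         system.nb)
    return e_vdw + e_elec


def torsion_refine(system: DockingSystem, tc: TorsionConfig,
                   stage: StageConfig, coords=None):
    """Coordinate descent over interface side-chain torsions.

    For each flexible residue's chi angles in turn, a coarse 15-degree scan
    followed by a fine local scan picks the lowest-energy rotation of the
    distal atoms about the chi axis; backbone atoms never move and ring
    moieties rotate only as rigid units.  Sweeps repeat until no chi
    improves the energy by more than 1e-6 or the evaluation budget
    (``nstep`` total, ``maxe`` per sweep) is exhausted.
    """
    if coords is None:
        coords = system.structure.coords.copy()
    else:
        coords = np.array(coords, dtype=float)
    units = _flexible_chis(system, tc)
    if not units:
        post, _, _ = system.evaluate(coords, stage)
        return coords, post
    coarse = np.arange(-180.0, 180.0, 15.0)
    evals_total = 0
    for _ in range(32):  # sweeps; budget usually stops earlier
        improved = 0.0
        evals_sweep = 0
        for unit in units:
            if evals_total >= tc.nstep or evals_sweep >= tc.maxe:
                break
            e_base = _torsion_local_energy(system, coords, unit, stage)
            best_angle, best_e = 0.0, e_base
            for ang in coarse:
                if ang == 0.0:
                    continue
                trial = coords.copy()
                _rotate_about_axis(trial, unit, ang)
                e = _torsion_local_energy(system, trial, unit, stage)
                evals_total += 1
                evals_sweep += 1
                if e < best_e - 1e-12:
                    best_angle, best_e = ang, e
            for ang in np.arange(best_angle - 12.0, best_angle + 12.1, 3.0):
                if ang == 0.0:
                    continue
                trial = coords.copy()
                _rotate_about_axis(trial, unit, ang)
                e = _torsion_local_energy(system, trial, unit, stage)
                evals_total += 1
                evals_sweep += 1
                if e < best_e - 1e-12:
                    best_angle, best_e = ang, e
            if best_angle != 0.0 and best_e < e_base - 1e-9:
                _rotate_about_axis(coords, unit, best_angle)
                improved += e_base - best_e
        if improved < 1e-6 or evals_total >= tc.nstep:
            break
    post, _, _ = system.evaluate(coords, stage)
    return coords, post


# ---------------------------------------------------------------------------
# Staged protocol
# ---------------------------------------------------------------------------


def default_stages():
    return [
        StageConfig("noe", terms=("NOE",), repel=1e-9, nstep=100, drop=10.0),
        StageConfig("noencs", terms=("NOE", "NCS"), repel=1e-9, nstep=200,
                    drop=10.0),
        StageConfig("noencsvdw", terms=("NOE", "NCS", "VDW"), repel=0.7,
                    nstep=100, drop=10.0),
    ]


_STAGE_OUTPUTS = {
    "noe": "noe.pdb",
    "noencs": "noencs.pdb",
    "noencsvdw": "noencsvdw.pdb",
    "torsion": "noencsvdwdynint.pdb",
}


@dataclass
class StageResult:
    name: str
    pre: EnergyBreakdown
    post: EnergyBreakdown


@dataclass
class ProtocolResult:
    final: Structure
    stages: list
    outputs: dict


def run_staged_protocol(
    system: DockingSystem,
    stages=None,
    torsion_config: TorsionConfig | None = None,
    outdir=None,
) -> ProtocolResult:
    """Run the full staged docking protocol.

    Rigid stages in order (defaults: NOE; NOE+NCS; NOE+NCS+VDW at
    repel 0.7), then torsion refinement of the interface side chains with
    the physical non-bonded terms.  Intermediate structures are written
    under ``outdir/RES`` when requested.
    """
    if stages is None:
        stages = default_stages()
    if torsion_config is None:
        torsion_config = TorsionConfig(flexible=system.flexible_ranges)
    res_dir = None
    if outdir is not None:
        res_dir = Path(outdir) / "RES"
        res_dir.mkdir(parents=True, exist_ok=True)
    coords = system.structure.coords.copy()
    results = []
    outputs = {}

    def _snapshot(name, coords):
        if res_dir is None:
            return
        snap = system.structure.copy()
        snap.coords = coords.copy()
        path = res_dir / _STAGE_OUTPUTS.get(name, f"{name}.pdb")
        write_pdb(snap, path)
        outputs[name] = str(path)

    for stage in stages:
        r = minimize_rigid(system, stage, coords)
        coords = r.coords
        results.append(StageResult(stage.name, r.pre, r.post))
        _snapshot(stage.name, coords)

    # final refinement stage: physical non-bonded terms, repel = 0
    t_stage = StageConfig(
        "torsion", terms=("NOE", "NCS", "VDW", "ELEC"), repel=0.0,
        nstep=torsion_config.nstep, drop=torsion_config.depred,
    )
    pre, _, _ = system.evaluate(coords, t_stage)
    coords, post = torsion_refine(system, torsion_config, t_stage, coords)
    results.append(StageResult("torsion", pre, post))
    _snapshot("torsion", coords)

    final = system.structure.copy()
    final.coords = coords
    return ProtocolResult(final=final, stages=results, outputs=outputs)
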