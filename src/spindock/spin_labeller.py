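"""Spin-label conformer ensembles and nitroxide-nitrogen extraction.

Site-directed spin labelling attaches a nitroxide radical to an engineered
cysteine.  Two chemistries are modelled:

* **R1** (MTSL on a single cysteine): an accessible-volume search.  The
  label side chain (Cys-S-S-CH2-pyrroline linker, idealised bond lengths
  and angles) is rebuilt at the site for uniformly sampled values of its
  five rotatable dihedrals; conformers that clash with the surrounding
  protein are rejected, up to a configurable conformer cap.
* **Rx2** (bis-MTSL bridging two cysteines): the pseudo-cyclic side chain
  is not amenable to a rotamer search, so nitroxide positions are sampled
  geometrically from the intersection of two spherical shells centred on
  the anchor residues (each shell spanning the reachable arm lengths),
  again with clash rejection.  This is a deliberately simple, documented
  stand-in for ensemble generation by restrained dynamics.

What downstream docking consumes is only the cloud of N1 nitroxide
nitrogen positions (the unpaired-electron proxy), truncated to 190
positions per ensemble and emitted as a single ``SPIN`` residue whose
atoms are named ``N001``..``N190`` — the dialect required for segment- and
residue-based restraint selections like ``SEGID S and resid 1 and name N*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import _ELEMENT_TABLE, _DEFAULT_RADIUS
from .pdb_model import Structure, select_atoms, write_pdb

__all__ = [
    "LabelSite",
    "LabelConformer",
    "SpinEnsemble",
    "SamplerParams",
    "LabellingError",
    "search_r1_conformers",
    "generate_rx2_ensemble",
    "extract_n1_ensemble",
    "write_spin_ensemble_pdb",
    "ensemble_to_structure",
    "MAX_ENSEMBLE_ATOMS",
]

MAX_ENSEMBLE_ATOMS = 190  # per-residue atom cap in the emitted SPIN dialect

# clash-cutoff scale factors on vdW radius sums
_VDW_SCALES = {"tight": 0.90, "loose": 0.75}

# Rx2 arm-length band: reachable CB-to-nitroxide distances (Å)
RX2_ARM_MIN = 5.0
RX2_ARM_MAX = 8.0


class LabellingError(RuntimeError):
    pass


@dataclass
class LabelSite:
    """An engineered labelling site.

    R1 sites have a single anchor (the site itself); Rx2 sites bridge two
    anchor residues given as (segid, resid) pairs.
    """

    segid: str
    resid: int
    chemistry: str = "R1"
    anchors: tuple = ()

    def __post_init__(self):
        if self.chemistry not in ("R1", "Rx2"):
            raise ValueError(f"unknown label chemistry {self.chemistry!r}")
        if self.chemistry == "R1":
            self.anchors = ((self.segid, self.resid),)
        elif len(self.anchors) != 2:
            raise ValueError("Rx2 sites need exactly two (segid, resid) anchors")


@dataclass
class LabelConformer:
    atom_names: list
    coords: np.ndarray  # (n_atoms, 3)
    clash_score: float
    n1_index: int

    @property
    def n1_position(self) -> np.ndarray:
        return self.coords[self.n1_index]


@dataclass
class SamplerParams:
    max_conformers: int = 200
    vdw_mode: str = "tight"
    thoroughness: int = 5000  # number of sampling trials
    rng_seed: int = 0
    rx2_reach: float = 12.0  # max anchor CB-CB distance (Å)

    def __post_init__(self):
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")
        if self.vdw_mode not in _VDW_SCALES:
            raise ValueError(f"vdw_mode must be one of {sorted(_VDW_SCALES)}")

    @property
    def vdw_scale(self) -> float:
        return _VDW_SCALES[self.vdw_mode]


@dataclass
class SpinEnsemble:
    """Nitroxide-nitrogen ensemble rigidly tied to a parent rigid body."""

    site: LabelSite
    n1_positions: np.ndarray  # (n, 3), n <= 190
    resid_out: int
    segid_out: str
    parent_body: str = ""

    def __post_init__(self):
        self.n1_positions = np.asarray(self.n1_positions, dtype=float).reshape(-1, 3)
        if len(self.n1_positions) > MAX_ENSEMBLE_ATOMS:
            raise ValueError(
                f"ensemble has {len(self.n1_positions)} positions; "
                f"cap at {MAX_ENSEMBLE_ATOMS} before emission"
            )

    @property
    def atom_names(self) -> list[str]:
        return [f"N{k + 1:03d}" for k in range(len(self.n1_positions))]


# ---------------------------------------------------------------------------
# Internal-coordinate construction
# ---------------------------------------------------------------------------


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Place atom d given three predecessors and internal coordinates.

    Standard NeRF construction: ``bond`` = |c-d|, ``angle`` = b-c-d,
    ``dihedral`` = a-b-c-d.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(dihedral),
            np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_cb(n, ca, c):
    """Idealised CB from backbone N, CA, C (tetrahedral branch)."""
    return place_atom(c, n, ca, 1.53, 110.5, -122.6)


# Idealised R1 linker internal coordinates: each entry places one atom from
# the three preceding ones.  chi placeholders are substituted per sample.
# chain: N-CA-CB-SG-SD-CE-C3, then the planar pyrroline ring C3-C4-C5-N1-C2
# with the N-O bond on N1.  Methyl groups are omitted (steric envelope is
# dominated by the ring and linker heavy atoms).
_R1_RING = [
    # (name, frame atoms (a, b, c), bond, angle, dihedral-or-chi-slot)
    ("C4", ("SD", "CE", "C3"), 1.50, 126.0, "chi5"),
    ("C5", ("CE", "C3", "C4"), 1.45, 108.0, 180.0),
    ("N1", ("C3", "C4", "C5"), 1.40, 108.0, 0.0),
    ("C2", ("C4", "C5", "N1"), 1.48, 108.0, 0.0),
    ("O1", ("C5", "N1", "C2"), 1.28, 125.0, 180.0),
]


def _build_r1_sidechain(n, ca, cb, chis):
    """Heavy-atom R1 side chain for one set of five dihedrals (degrees)."""
    pos = {"N": n, "CA": ca, "CB": cb}
    pos["SG"] = place_atom(pos["N"], pos["CA"], pos["CB"], 1.81, 114.0, chis[0])
    pos["SD"] = place_atom(pos["CA"], pos["CB"], pos["SG"], 2.04, 104.0, chis[1])
    pos["CE"] = place_atom(pos["CB"], pos["SG"], pos["SD"], 1.81, 104.0, chis[2])
    pos["C3"] = place_atom(pos["SG"], pos["SD"], pos["CE"], 1.50, 114.0, chis[3])
    ring_dihedrals = {"chi5": chis[4]}
    for name, (a, b, c), bond, angle, dihe in _R1_RING:
        if isinstance(dihe, str):
            dihe = ring_dihedrals[dihe]
        pos[name] = place_atom(pos[a], pos[b], pos[c], bond, angle, dihe)
    names = ["SG", "SD", "CE", "C3", "C4", "C5", "N1", "C2", "O1"]
    coords = np.array([pos[nm] for nm in names])
    return names, coords


# ---------------------------------------------------------------------------
# Clash machinery
# ---------------------------------------------------------------------------


def _element_radius(name: str) -> float:
    from .pdb_model import infer_element

    return _ELEMENT_TABLE.get(infer_element(name), (_DEFAULT_RADIUS, 0.0))[0]


class _ClashChecker:
    """Scaled-radius-sum clash test against a fixed set of protein atoms."""

    def __init__(self, structure: Structure, exclude_idx, scale: float):
        exclude = np.zeros(structure.natoms, dtype=bool)
        exclude[exclude_idx] = True
        heavy = np.array([el != "H" for el in structure.elements])
        # SPIN pseudo-atoms are conformer populations, not physical matter
        physical = np.array([rn.upper() != "SPIN" for rn in structure.resnames])
        keep = heavy & physical & ~exclude
        self.coords = structure.coords[keep]
        self.radii = np.array(
            [_ELEMENT_TABLE.get(el, (_DEFAULT_RADIUS, 0.0))[0]
             for el, k in zip(structure.elements, keep) if k]
        )
        self.scale = scale
        self.max_radius = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.coords) if len(self.coords) else None

    def clash_score(self, atom_coords, atom_radii) -> float:
        """Worst fractional overlap (0 = no clash) of any atom pair."""
        if self.tree is None:
            return 0.0
        worst = 0.0
        for x, ra in zip(atom_coords, atom_radii):
            reach = self.scale * (ra + self.max_radius)
            for k in self.tree.query_ball_point(x, reach):
                cut = self.scale * (ra + self.radii[k])
                d = float(np.linalg.norm(x - self.coords[k]))
                if d < cut:
                    worst = max(worst, 1.0 - d / cut)
        return worst


def _site_atoms(s: Structure, segid: str, resid: int):
    idx = select_atoms(s, f"segid {segid} and resid {resid}")
    if len(idx) == 0:
        raise LabellingError(f"site segid {segid!r} resid {resid} not found")
    names = {s.names[i]: i for i in idx}
    return idx, names


# ---------------------------------------------------------------------------
# R1 accessible-volume search
# ---------------------------------------------------------------------------


def search_r1_conformers(
    s: Structure, site: LabelSite, p: SamplerParams
) -> list[LabelConformer]:
    """Accessible-volume conformer search for an R1 (MTSL) label.

    Uniformly samples the five linker dihedrals, rebuilds the idealised
    side chain at the site and keeps clash-free conformers (scaled
    radius-sum test against protein heavy atoms, the labelled residue
    itself excluded) until ``max_conformers`` survive or ``thoroughness``
    trials are exhausted.  Deterministic under ``rng_seed``.
    """
    idx, names = _site_atoms(s, site.segid, site.resid)
    for req in ("N", "CA", "C"):
        if req not in names:
            raise LabellingError(
                f"site {site.segid}:{site.resid} lacks backbone atom {req}"
            )
    n = s.coords[names["N"]]
    ca = s.coords[names["CA"]]
    c = s.coords[names["C"]]
    cb = s.coords[names["CB"]] if "CB" in names else build_cb(n, ca, c)

    checker = _ClashChecker(s, idx, p.vdw_scale)
    rng = np.random.default_rng(p.rng_seed)
    conformers: list[LabelConformer] = []
    for _ in range(p.thoroughness):
        chis = rng.uniform(0.0, 360.0, size=5)
        atom_names, coords = _build_r1_sidechain(n, ca, cb, chis)
        radii = np.array([_element_radius(nm) for nm in atom_names])
        score = checker.clash_score(coords, radii)
        if score > 0.0:
            continue
        conformers.append(
            LabelConformer(atom_names, coords, score, atom_names.index("N1"))
        )
        if len(conformers) >= p.max_conformers:
            break
    if not conformers:
        raise LabellingError(
            f"no clash-free R1 conformers at {site.segid}:{site.resid}; "
            "try increasing the thoroughness or reducing the vdW restraints"
        )
    return conformers


# ---------------------------------------------------------------------------
# Rx2 two-anchor constrained sampling
# ---------------------------------------------------------------------------

# minimal rigid nitroxide-ring template centred on N1 (local frame, Å)
_RX2_RING_LOCAL = {
    "N1": np.array([0.0, 0.0, 0.0]),
    "O1": np.array([0.0, 0.0, 1.28]),
    "C2": np.array([1.15, 0.85, -0.45]),
    "C5": np.array([-1.15, 0.85, -0.45]),
}


def generate_rx2_ensemble(
    s: Structure, site: LabelSite, p: SamplerParams
) -> list[LabelConformer]:
    """Two-anchor constrained ensemble for a bridging Rx2 label.

    Nitroxide positions are drawn from the intersection of two spherical
    shells of radius ``RX2_ARM_MIN``..``RX2_ARM_MAX`` centred on the two
    anchor CB atoms (two-sphere circle construction with uniformly sampled
    azimuth), then clash-filtered.  The resulting spread is intrinsically
    narrower than an R1 accessible volume at the same site.
    """
    if site.chemistry != "Rx2":
        raise ValueError("generate_rx2_ensemble requires an Rx2 site")
    anchors = []
    exclude = []
    for segid, resid in site.anchors:
        idx, names = _site_atoms(s, segid, resid)
        exclude.extend(idx.tolist())
        key = "CB" if "CB" in names else "CA"
        anchors.append(s.coords[names[key]])
    p1, p2 = anchors
    d12 = float(np.linalg.norm(p2 - p1))
    if d12 > p.rx2_reach:
        raise LabellingError(
            f"Rx2 anchors are {d12:.1f} Å apart, beyond the {p.rx2_reach:.1f} Å reach"
        )
    if d12 < 1e-6:
        raise LabellingError("Rx2 anchors coincide")

    axis = (p2 - p1) / d12
    # orthonormal frame around the anchor axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    checker = _ClashChecker(s, np.array(exclude, dtype=int), p.vdw_scale)
    rng = np.random.default_rng(p.rng_seed)
    conformers: list[LabelConformer] = []
    for _ in range(p.thoroughness):
        d1, d2 = rng.uniform(RX2_ARM_MIN, RX2_ARM_MAX, size=2)
        if not (abs(d1 - d2) < d12 < d1 + d2):
            continue  # shells do not intersect for this arm pair
        a = (d12 * d12 + d1 * d1 - d2 * d2) / (2.0 * d12)
        rho2 = d1 * d1 - a * a
        if rho2 <= 0:
            continue
        phi = rng.uniform(0.0, 2.0 * np.pi)
        n1 = p1 + a * axis + np.sqrt(rho2) * (np.cos(phi) * u + np.sin(phi) * v)
        # orient the small ring template with z pointing away from the axis
        z = n1 - (p1 + a * axis)
        z /= max(np.linalg.norm(z), 1e-9)
        x = np.cross(axis, z)
        nx = np.linalg.norm(x)
        x = u if nx < 1e-9 else x / nx
        y = np.cross(z, x)
        frame = np.stack([x, y, z], axis=1)
        names = list(_RX2_RING_LOCAL)
        coords = np.array([n1 + frame @ _RX2_RING_LOCAL[nm] for nm in names])
        radii = np.array([_element_radius(nm) for nm in names])
        score = checker.clash_score(coords, radii)
        if score > 0.0:
            continue
        conformers.append(LabelConformer(names, coords, score, names.index("N1")))
        if len(conformers) >= p.max_conformers:
            break
    if not conformers:
        raise LabellingError(
            f"no clash-free Rx2 conformers bridging {site.anchors}; "
            "try increasing the thoroughness or reducing the vdW restraints"
        )
    return conformers


# ---------------------------------------------------------------------------
# Extraction and emission
# ---------------------------------------------------------------------------


def extract_n1_ensemble(
    conformers, resid_out: int, segid_out: str, parent_body: str = "",
    site: LabelSite | None = None,
) -> SpinEnsemble:
    """Keep the first min(n, 190) N1 positions in input order."""
    conformers = list(conformers)
    if not conformers:
        raise ValueError("cannot extract an ensemble from zero conformers")
    kept = conformers[:MAX_ENSEMBLE_ATOMS]
    positions = np.array([c.n1_position for c in kept])
    if site is None:
        site = LabelSite(segid=segid_out, resid=resid_out, chemistry="R1")
    return SpinEnsemble(
        site=site,
        n1_positions=positions,
        resid_out=resid_out,
        segid_out=segid_out,
        parent_body=parent_body,
    )


def ensemble_to_structure(e: SpinEnsemble) -> Structure:
    """SPIN-residue Structure view of an ensemble (for merging/writing)."""
    n = len(e.n1_positions)
    return Structure(
        names=e.atom_names,
        resnames=["SPIN"] * n,
        chains=[e.segid_out[:1]] * n,
        resids=[e.resid_out] * n,
        coords=e.n1_positions,
        segids=[e.segid_out] * n,
        provenance=f"spin ensemble {e.segid_out}:{e.resid_out}",
    )


def write_spin_ensemble_pdb(e: SpinEnsemble, path) -> None:
    """Emit the ensemble as a single SPIN residue (N001.., terminal END)."""
    write_pdb(ensemble_to_structure(e), path)
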