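"""Minimal non-bonded energetics for rigid-body docking.

Two evaluation modes, switched by the ``repel`` parameter:

* ``repel > 0`` — a purely repulsive quartic contact term,
  ``E = k * sum max(0, (repel*(r_i + r_j))^2 - d^2)^2``, where ``repel``
  scales the contact radii.  A vanishing value (1e-9) lets rigid bodies
  pass through each other during the early restraint-driven stages; 0.7
  restores meaningful excluded volume.
* ``repel = 0`` — physical terms: 12-6 Lennard-Jones (Lorentz-Berthelot
  combination, switched off smoothly over the ctonnb..ctofnb window) plus
  Coulomb electrostatics with shift-function truncation.

Parameters come from a deliberately small per-element table (heavy-atom,
united-radius treatment; no bonded terms — the bodies are rigid), so
absolute VDW/ELEC magnitudes are not comparable with a full force field;
only their staging behaviour matters here.  Spin-ensemble (``SPIN``
residue) atoms are excluded from all non-bonded terms: each ensemble is a
population of label conformers, and scoring steric contacts against the
whole cloud would wildly overestimate the interaction of any one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .pdb_model import Structure

__all__ = [
    "NonbondedParams",
    "AtomParamTable",
    "InteractionBlock",
    "assign_params",
    "build_pair_list",
    "repel_energy",
    "lj_coulomb_energy",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.06  # kcal*Å/(mol*e^2)

# per-element vdW radius (Å), LJ well depth (kcal/mol); CHARMM-like magnitudes
_ELEMENT_TABLE = {
    "C": (1.90, 0.10),
    "N": (1.65, 0.17),
    "O": (1.55, 0.15),
    "S": (2.00, 0.25),
    "H": (1.10, 0.03),
}
_DEFAULT_RADIUS, _DEFAULT_EPS = (1.80, 0.10)

# crude backbone partial charges (e); side-chain heavy atoms default to 0
_NAME_CHARGES = {"N": -0.47, "C": 0.51, "O": -0.51, "CA": 0.07, "OH": -0.40}


@dataclass
class NonbondedParams:
    """Non-bonded evaluation options.

    ``e14fac`` and ``wmin`` are stored for interface fidelity but unused:
    there are no 1-4 pairs across rigid bodies and no pair-list warnings.
    """

    repel: float = 0.7
    eps_dielectric: float = 1.0
    e14fac: float = 0.4
    cutnb: float = 7.5
    ctonnb: float = 6.0
    ctofnb: float = 6.5
    wmin: float = 0.0
    repel_k: float = 4.0  # kcal/(mol*Å^4)

    def __post_init__(self):
        if not (self.ctonnb < self.ctofnb <= self.cutnb):
            raise ValueError("require ctonnb < ctofnb <= cutnb")
        if self.repel < 0:
            raise ValueError("repel must be >= 0")


@dataclass
class AtomParamTable:
    """Per-atom radius/well depth/partial charge plus a non-bonded
    exclusion flag (True for SPIN-residue atoms)."""

    radius: np.ndarray
    epsilon: np.ndarray
    charge: np.ndarray
    excluded: np.ndarray


def assign_params(s: Structure, charges=None) -> AtomParamTable:
    """Parameterise every atom from the built-in element table.

    ``charges`` may override the default name-based partial charges with an
    explicit per-atom array.
    """
    n = s.natoms
    radius = np.empty(n)
    epsilon = np.empty(n)
    charge = np.zeros(n)
    excluded = np.zeros(n, dtype=bool)
    for i in range(n):
        el = s.elements[i]
        radius[i], epsilon[i] = _ELEMENT_TABLE.get(el, (_DEFAULT_RADIUS, _DEFAULT_EPS))
        charge[i] = _NAME_CHARGES.get(s.names[i], 0.0)
        if s.resnames[i].upper() == "SPIN":
            excluded[i] = True
    if charges is not None:
        charge = np.asarray(charges, dtype=float).copy()
        if charge.shape != (n,):
            raise ValueError("charges must be a per-atom array")
    return AtomParamTable(radius, epsilon, charge, excluded)


@dataclass
class InteractionBlock:
    """One contributing selection pair with per-term weights."""

    idx_a: np.ndarray
    idx_b: np.ndarray
    w_vdw: float = 1.0
    w_elec: float = 1.0


@dataclass
class PairList:
    i: np.ndarray
    j: np.ndarray
    w_vdw: np.ndarray
    w_elec: np.ndarray


def build_pair_list(coords, params: AtomParamTable, blocks, cutoff: float,
                    segids=None, resids=None) -> PairList:
    """All contributing atom pairs within ``cutoff``.

    Honors the per-block weights and the SPIN-atom exclusion; a self block
    (identical index sets) yields each unordered pair once.  A pair listed
    by two blocks with identical weights is kept once; contradictory
    duplicate weights raise.  Ordering is deterministic (sorted by (i, j)).

    When ``segids``/``resids`` are given, pairs within the same segment and
    within one residue of each other are dropped: with no bonded force
    field, covalently connected (1-2/1-3/1-4) neighbours must not be scored
    as non-bonded contacts.
    """
    coords = np.asarray(coords, dtype=float)
    check_bonded = segids is not None and resids is not None
    seen: dict[tuple[int, int], tuple[float, float]] = {}
    for blk in blocks:
        ia = blk.idx_a[~params.excluded[blk.idx_a]]
        ib = blk.idx_b[~params.excluded[blk.idx_b]]
        if len(ia) == 0 or len(ib) == 0 or cutoff <= 0:
            continue
        self_block = len(ia) == len(ib) and np.array_equal(np.sort(ia), np.sort(ib))
        tree = cKDTree(coords[ib])
        hits = tree.query_ball_point(coords[ia], cutoff)
        for ai, neigh in zip(ia, hits):
            for k in neigh:
                bj = int(ib[k])
                ai_i = int(ai)
                if ai_i == bj:
                    continue
                key = (min(ai_i, bj), max(ai_i, bj)) if self_block else (ai_i, bj)
                if self_block and ai_i > bj:
                    continue
                if (
                    check_bonded
                    and segids[ai_i] == segids[bj]
                    and abs(int(resids[ai_i]) - int(resids[bj])) <= 1
                ):
                    continue
                w = (blk.w_vdw, blk.w_elec)
                prev = seen.get(key)
                if prev is None:
                    seen[key] = w
                elif prev != w:
                    raise ValueError(
                        f"pair {key} listed with contradictory weights {prev} vs {w}"
                    )
    if not seen:
        z = np.zeros(0, dtype=int)
        return PairList(z, z, np.zeros(0), np.zeros(0))
    keys = sorted(seen)
    i = np.array([k[0] for k in keys], dtype=int)
    j = np.array([k[1] for k in keys], dtype=int)
    wv = np.array([seen[k][0] for k in keys])
    we = np.array([seen[k][1] for k in keys])
    return PairList(i, j, wv, we)


def _pair_geometry(coords, pairs: PairList):
    d = coords[pairs.i] - coords[pairs.j]
    r2 = np.sum(d * d, axis=1)
    return d, r2


def repel_energy(coords, pairs: PairList, params: AtomParamTable,
                 nb: NonbondedParams):
    """Quartic soft repulsion energy and analytic gradient.

    ``E = k * sum w_vdw * max(0, (repel*(r_i + r_j))^2 - d^2)^2`` — zero
    beyond the scaled contact distance, non-negative, monotone in repel.
    """
    grad = np.zeros_like(np.asarray(coords, dtype=float))
    if len(pairs.i) == 0:
        return 0.0, grad
    d, r2 = _pair_geometry(coords, pairs)
    contact = nb.repel * (params.radius[pairs.i] + params.radius[pairs.j])
    over = contact * contact - r2
    active = over > 0
    if not np.any(active):
        return 0.0, grad
    ov = over[active]
    w = pairs.w_vdw[active]
    e = nb.repel_k * float(np.sum(w * ov * ov))
    # dE/dx_i = -4k*w*over*(x_i - x_j)
    f = (-4.0 * nb.repel_k * w * ov)[:, None] * d[active]
    np.add.at(grad, pairs.i[active], f)
    np.add.at(grad, pairs.j[active], -f)
    return e, grad


def _switch(r2, cton2, ctof2):
    """CHARMM-style switching function on r^2 and its derivative d(sw)/d(r2)."""
    sw = np.ones_like(r2)
    dsw = np.zeros_like(r2)
    mid = (r2 > cton2) & (r2 < ctof2)
    off = r2 >= ctof2
    sw[off] = 0.0
    denom = (ctof2 - cton2) ** 3
    a = ctof2 - r2[mid]
    b = ctof2 + 2.0 * r2[mid] - 3.0 * cton2
    sw[mid] = a * a * b / denom
    dsw[mid] = (-2.0 * a * b + 2.0 * a * a) / denom
    return sw, dsw


def lj_coulomb_energy(coords, pairs: PairList, params: AtomParamTable,
                      nb: NonbondedParams):
    """Physical-mode non-bonded terms (repel = 0).

    12-6 LJ with ``r_min = r_i + r_j`` and geometric-mean well depth,
    smoothly switched off over ctonnb..ctofnb; Coulomb with the shift
    function ``(1 - (r/ctofnb)^2)^2``, zero beyond ctofnb.  Returns
    ``(E_vdw, E_elec, gradient)``.
    """
    coords = np.asarray(coords, dtype=float)
    grad = np.zeros_like(coords)
    if len(pairs.i) == 0:
        return 0.0, 0.0, grad
    d, r2 = _pair_geometry(coords, pairs)
    ctof2 = nb.ctofnb**2
    cton2 = nb.ctonnb**2
    inside = r2 < ctof2
    if not np.any(inside):
        return 0.0, 0.0, grad
    ii, jj = pairs.i[inside], pairs.j[inside]
    dv, r2 = d[inside], r2[inside]
    r = np.sqrt(r2)
    wv, we = pairs.w_vdw[inside], pairs.w_elec[inside]

    rmin = params.radius[ii] + params.radius[jj]
    epsij = np.sqrt(params.epsilon[ii] * params.epsilon[jj])
    s6 = (rmin * rmin / r2) ** 3
    lj = epsij * (s6 * s6 - 2.0 * s6)
    dlj_dr2 = epsij * (-6.0 * s6 * s6 + 6.0 * s6) / r2
    sw, dsw = _switch(r2, cton2, ctof2)
    e_vdw = float(np.sum(wv * lj * sw))
    dvdw_dr2 = wv * (dlj_dr2 * sw + lj * dsw)

    qq = COULOMB_CONSTANT * params.charge[ii] * params.charge[jj] / nb.eps_dielectric
    shift = 1.0 - r2 / ctof2
    ec = qq / r * shift * shift
    e_elec = float(np.sum(we * ec))
    # d/dr2 [ q/r (1 - r2/c)^2 ] = q * (-(1/(2 r^3))*shift^2 - (2 shift)/(r c))
    dec_dr2 = qq * (-0.5 * shift * shift / (r2 * r) - 2.0 * shift / (r * ctof2))
    delec_dr2 = we * dec_dr2

    f = (2.0 * (dvdw_dr2 + delec_dr2))[:, None] * dv
    np.add.at(grad, ii, f)
    np.add.at(grad, jj, -f)
    return e_vdw, e_elec, grad
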