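"""Ensemble-averaged distance restraints and symmetry (NCS) restraints.

A PELDOR/DEER measurement constrains the distance between two *ensembles*
of nitroxide positions, not two atoms.  The effective distance between
ensembles A and B under R⁻³ averaging is

    r_eff = ( <r_ij^-3>_{i in A, j in B} )^(-1/3)

and the restraint contributes a square-well energy: zero inside
[target - minus, target + plus], quadratic (sqexponent = 2) in the
violation outside, capped at ``ceiling`` (applied to the unscaled well
term) and multiplied by ``scale``.

Because a hard cap would leave badly violated restraints force-free, the
*minimisation* objective continues linearly beyond the cap with the slope
at the crossing (C¹ continuous); the *reported* per-restraint energy is
always the capped value.  See docs/methods.md for the derivation.

Non-crystallographic-symmetry (NCS) restraints penalise the deviation of
equivalence groups of atoms from their least-squares-superposed mean
structure, keeping symmetric interfaces symmetric during docking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pdb_model import Selection, Structure, select_atoms

__all__ = [
    "DistanceRestraint",
    "RestraintParams",
    "RestraintRow",
    "NCSGroup",
    "NoeSummary",
    "effective_distance",
    "effective_distance_gradient",
    "square_well_energy",
    "well_energy_and_slope",
    "noe_summary",
    "kabsch_superpose",
    "ncs_energy",
    "ncs_energy_gradient",
    "read_restraint_table",
    "write_restraint_table",
]


@dataclass
class RestraintParams:
    """Restraint-class parameters (XPLOR NOE/EPR-class semantics)."""

    averaging: str = "R-3"  # one of {"R-3", "R-6", "center"}
    potential: str = "square"
    sqconstant: float = 1.0
    sqexponent: float = 2.0
    ceiling: float = 50.0
    scale: float = 10.0
    nres: int = 7000  # capacity hint, informational

    def __post_init__(self):
        if self.sqexponent < 1:
            raise ValueError("sqexponent must be >= 1")
        if self.ceiling <= 0:
            raise ValueError("ceiling must be > 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.potential != "square":
            raise ValueError(f"unsupported potential {self.potential!r}")
        if self.averaging not in ("R-3", "R-6", "center"):
            raise ValueError(f"unsupported averaging {self.averaging!r}")


@dataclass
class DistanceRestraint:
    """One site-pair restraint: selections, target and asymmetric bounds (Å)."""

    sel_a: object
    sel_b: object
    d_target: float
    d_minus: float
    d_plus: float
    label: str = ""

    def __post_init__(self):
        if self.d_minus < 0 or self.d_plus < 0:
            raise ValueError("restraint bounds must be >= 0")
        if not isinstance(self.sel_a, Selection):
            self.sel_a = Selection(self.sel_a)
        if not isinstance(self.sel_b, Selection):
            self.sel_b = Selection(self.sel_b)


@dataclass
class RestraintRow:
    """Evaluated restraint: effective distance, signed violation, energy."""

    r_average: float
    d_target: float
    d_minus: float
    d_plus: float
    delta: float
    energy: float
    label: str = ""


@dataclass
class NoeSummary:
    total_energy: float
    rms: float
    n_violated: int
    n_total: int


# ---------------------------------------------------------------------------
# Effective (ensemble-averaged) distances
# ---------------------------------------------------------------------------


def _pair_distances(pos_a: np.ndarray, pos_b: np.ndarray) -> np.ndarray:
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def effective_distance(pos_a, pos_b, averaging: str = "R-3") -> float:
    """Ensemble-averaged distance between two position sets (Å).

    R-3: ``(mean r^-3)^(-1/3)`` over all cross pairs (mean, not sum, so a
    singleton-vs-singleton pair reduces to the plain distance).  R-6 is the
    analogous sixth-power average; ``center`` is the centroid distance.
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    if pos_a.size == 0 or pos_b.size == 0:
        raise ValueError("both ensembles must be non-empty")
    if averaging == "center":
        return float(np.linalg.norm(pos_a.mean(axis=0) - pos_b.mean(axis=0)))
    r = _pair_distances(pos_a, pos_b)
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms across ensembles give a singular average")
    p = 3.0 if averaging == "R-3" else 6.0
    return float(np.mean(r ** (-p)) ** (-1.0 / p))


def effective_distance_gradient(pos_a, pos_b, averaging: str = "R-3"):
    """Effective distance and its gradient w.r.t. both ensembles.

    Returns ``(r_eff, grad_a, grad_b)`` with grads shaped like the inputs.
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, dtype=float))
    pos_b = np.atleast_2d(np.asarray(pos_b, dtype=float))
    if averaging == "center":
        ca, cb = pos_a.mean(axis=0), pos_b.mean(axis=0)
        d = ca - cb
        r = float(np.linalg.norm(d))
        if r < 1e-9:
            raise ValueError("coincident centroids")
        u = d / r
        ga = np.tile(u / len(pos_a), (len(pos_a), 1))
        gb = np.tile(-u / len(pos_b), (len(pos_b), 1))
        return r, ga, gb
    p = 3.0 if averaging == "R-3" else 6.0
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r < 1e-9):
        raise ValueError("coincident atoms across ensembles give a singular average")
    m = r.size
    s = np.mean(r ** (-p))
    r_eff = s ** (-1.0 / p)
    # d r_eff / d r_ij = (1/m) * r_eff * s^-1 * r_ij^-(p+1)
    w = (r_eff / (m * s)) * r ** (-(p + 1.0))
    unit = diff / r[..., None]
    ga = np.sum(w[..., None] * unit, axis=1)
    gb = -np.sum(w[..., None] * unit, axis=0)
    return float(r_eff), ga, gb


# ---------------------------------------------------------------------------
# Square-well potential
# ---------------------------------------------------------------------------


def square_well_energy(
    r_average: float, r: DistanceRestraint, p: RestraintParams
) -> RestraintRow:
    """Evaluate one restraint at an effective distance.

    The signed ``delta`` is (violated bound) - r_average, so an overlong
    distance gives a negative delta.  Energy is
    ``scale * min(ceiling, sqconstant * |delta|^sqexponent)``.
    """
    lo = r.d_target - r.d_minus
    hi = r.d_target + r.d_plus
    if lo <= r_average <= hi:
        delta, v = 0.0, 0.0
    elif r_average > hi:
        delta = hi - r_average
        v = -delta
    else:
        delta = lo - r_average
        v = delta
    energy = p.scale * min(p.ceiling, p.sqconstant * v**p.sqexponent)
    return RestraintRow(
        r_average=float(r_average),
        d_target=r.d_target,
        d_minus=r.d_minus,
        d_plus=r.d_plus,
        delta=float(delta),
        energy=float(energy),
        label=r.label,
    )


def well_energy_and_slope(
    r_average: float, r: DistanceRestraint, p: RestraintParams
):
    """Minimisation objective for one restraint: C¹ linear extension.

    Inside the cap this equals the reported energy; beyond the violation
    ``v_c = (ceiling/sqconstant)^(1/sqexponent)`` it continues linearly with
    the slope at the crossing so badly violated restraints keep pulling.
    Returns ``(energy, dE/dr_average)``.
    """
    lo = r.d_target - r.d_minus
    hi = r.d_target + r.d_plus
    if lo <= r_average <= hi:
        return 0.0, 0.0
    if r_average > hi:
        v, sign = r_average - hi, 1.0
    else:
        v, sign = lo - r_average, -1.0
    v_c = (p.ceiling / p.sqconstant) ** (1.0 / p.sqexponent)
    if v <= v_c:
        e = p.scale * p.sqconstant * v**p.sqexponent
        de = p.scale * p.sqconstant * p.sqexponent * v ** (p.sqexponent - 1.0)
    else:
        slope = p.sqconstant * p.sqexponent * v_c ** (p.sqexponent - 1.0)
        e = p.scale * (p.ceiling + slope * (v - v_c))
        de = p.scale * slope
    return float(e), float(sign * de)


def noe_summary(rows) -> NoeSummary:
    """Total energy, RMS violation over all rows and violation count."""
    rows = list(rows)
    if not rows:
        raise ValueError("noe_summary requires at least one row")
    deltas = np.array([row.delta for row in rows])
    return NoeSummary(
        total_energy=float(sum(row.energy for row in rows)),
        rms=float(np.sqrt(np.mean(deltas**2))),
        n_violated=int(np.sum(np.abs(deltas) > 0)),
        n_total=len(rows),
    )


# ---------------------------------------------------------------------------
# Least-squares superposition and NCS restraints
# ---------------------------------------------------------------------------


def kabsch_superpose(x, y):
    """Least-squares rigid superposition of ``y`` onto ``x``.

    Returns ``(rotation, translation, rmsd)`` such that ``y @ R.T + t``
    minimises the RMSD to ``x``; the rotation is proper (det +1).
    Degenerate (collinear or coincident) point sets raise ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("superposition requires two equal (n>=3, 3) point sets")
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - cx, y - cy
    sx = np.linalg.svd(xc, compute_uv=False)
    sy = np.linalg.svd(yc, compute_uv=False)
    if sx[1] < 1e-8 * max(sx[0], 1.0) or sy[1] < 1e-8 * max(sy[0], 1.0):
        raise ValueError("degenerate (collinear) point set in superposition")
    rot, rssd = Rotation.align_vectors(xc, yc)
    R = rot.as_matrix()
    t = cx - R @ cy
    return R, t, float(rssd / np.sqrt(x.shape[0]))


@dataclass
class NCSGroup:
    """One equivalence group: copies of corresponding atom selections.

    Each copy is either a single selection string or an ordered list of
    selection strings whose matches are concatenated in the given order
    (needed when the symmetry correspondence differs from structure order).
    ``sigb`` is parsed for interface fidelity but unused: no B factors are
    refined here.
    """

    copies: list
    weight_ncs: float = 1.0
    sigb: float = 1.0
    name: str = ""

    def resolve(self, s: Structure) -> list[np.ndarray]:
        out = []
        for copy in self.copies:
            parts = [copy] if isinstance(copy, (str, Selection)) else list(copy)
            idx = np.concatenate([select_atoms(s, p) for p in parts])
            out.append(idx)
        counts = {len(i) for i in out}
        if len(counts) != 1:
            raise ValueError(
                f"NCS group {self.name or self.copies!r}: copies resolve to "
                f"unequal atom counts {sorted(len(i) for i in out)}"
            )
        if 0 in counts:
            raise ValueError(f"NCS group {self.name or self.copies!r}: empty copies")
        return out


def _superpose_copies(copy_coords, max_passes: int = 50, tol: float = 1e-12):
    """Superpose every copy onto the running average, then refine.

    The refinement pass (superpose each copy onto the current mean,
    recompute the mean) is repeated to a fixed point: at convergence every
    copy is optimally superposed onto the final mean and the mean is
    self-consistent, which is what makes the envelope-theorem gradient in
    :func:`ncs_energy_gradient` exact.  Returns (transformed copies,
    final-pass rotations, mean).
    """
    ref = copy_coords[0]
    transformed = [ref.copy()]
    mean = ref.copy()
    for c in copy_coords[1:]:
        R, t, _ = kabsch_superpose(mean, c)
        transformed.append(c @ R.T + t)
        mean = np.mean(transformed, axis=0)
    final, rots = transformed, [np.eye(3)] * len(copy_coords)
    for _ in range(max_passes):
        final, rots = [], []
        for c in copy_coords:
            R, t, _ = kabsch_superpose(mean, c)
            final.append(c @ R.T + t)
            rots.append(R)
        new_mean = np.mean(final, axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    return final, rots, mean


def ncs_energy_gradient(coords: np.ndarray, resolved_groups):
    """NCS energy and its gradient w.r.t. atomic coordinates.

    ``resolved_groups`` is a list of ``(index_arrays, weight)`` pairs.  For
    each group the copies are least-squares superposed onto their mean and

        E = sum_copies weight * sum_atoms |z_i - mean_i|^2 .

    The gradient uses the envelope theorem: at the superposition optimum
    the rotations' implicit dependence on the coordinates contributes
    nothing, and the mean-structure cross terms cancel, leaving
    ``2 w (z - mean)`` rotated back into each copy's original frame.
    """
    total = 0.0
    grad = np.zeros_like(coords)
    for idx_list, weight in resolved_groups:
        copy_coords = [coords[idx] for idx in idx_list]
        final, rots, mean = _superpose_copies(copy_coords)
        for idx, z, R in zip(idx_list, final, rots):
            dev = z - mean
            total += weight * float(np.sum(dev * dev))
            grad[idx] += 2.0 * weight * dev @ R
    return total, grad


def ncs_energy(groups, s: Structure) -> float:
    """Total NCS restraint energy of a structure (kcal/mol-scale units)."""
    resolved = [(g.resolve(s), g.weight_ncs) for g in groups]
    e, _ = ncs_energy_gradient(s.coords, resolved)
    return e


# ---------------------------------------------------------------------------
# Restraint table I/O
# ---------------------------------------------------------------------------


def write_restraint_table(restraints, path) -> None:
    """Pipe-delimited text table: selA | selB | target | minus | plus | label."""
    lines = [
        "# selection_a | selection_b | target | minus | plus | label",
    ]
    for r in restraints:
        lines.append(
            f"{r.sel_a.expression} | {r.sel_b.expression} | "
            f"{r.d_target:g} | {r.d_minus:g} | {r.d_plus:g} | {r.label}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_restraint_table(path) -> list[DistanceRestraint]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("|")]
            if len(parts) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 'selA | selB | target | minus | "
                    f"plus [| label]', got {line!r}"
                )
            label = parts[5] if len(parts) > 5 else ""
            out.append(
                DistanceRestraint(
                    parts[0], parts[1], float(parts[2]), float(parts[3]),
                    float(parts[4]), label,
                )
            )
    return out
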