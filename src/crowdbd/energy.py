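"""Intermolecular energies, forces and torques.

Three energy models are supported, as selected by ``EnergyModelParams.mode``:

``steric``
    purely repulsive 1/r^12 interactions between exposed heavy atoms;
``steric_elec``
    the repulsive term plus grid-based effective-charge electrostatics;
``full``
    a 12-6 Lennard-Jones term (steric + van der Waals + hydrophobic,
    with the well depth eps_lj the model's single adjustable parameter)
    plus electrostatics.

Short-range terms are evaluated only for exposed-atom pairs within a
cutoff (default 12 Å) collected in a periodically rebuilt pair list;
electrostatics couples each molecule's effective charges to its
partners' potential grids (fine grid where available, else coarse, else
zero) by trilinear interpolation, symmetrized over the two directions.
All geometry uses the minimum-image convention in a cubic periodic box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import TEMPERATURE

__all__ = [
    "EnergyModelParams",
    "PairList",
    "minimum_image",
    "build_pair_list",
    "lj_pair_energy",
    "electrostatic_energy",
    "system_energy_forces",
]


@dataclass
class EnergyModelParams:
    """Parameters of the intermolecular energy model.

    eps_lj : kcal/mol, well depth of the 12-6 term ("full" mode).
    eps_rep : kcal/mol, amplitude of the repulsive-only term
        ("steric"/"steric_elec" modes); default 0.39 kcal/mol puts the
        repulsive energy at the 4.5 Å hard core near 1.4 kT for the
        default contact distance.
    lj_contact : Å, position r_m of the LJ minimum (global, all pairs).
    cutoff : Å, short-range interaction cutoff.
    hard_core : Å, minimum allowed exposed-atom separation.
    pairlist_refresh : steps between pair-list rebuilds.
    """

    mode: str = "full"
    eps_lj: float = 0.285
    eps_rep: float = 0.39
    lj_contact: float = 5.0
    cutoff: float = 12.0
    hard_core: float = 4.5
    pairlist_skin: float = 0.0
    pairlist_refresh: int = 40
    temperature: float = TEMPERATURE

    def __post_init__(self):
        if self.mode not in ("steric", "steric_elec", "full"):
            raise ValueError(f"unknown energy mode {self.mode!r}")
        if not (self.cutoff > self.lj_contact > 0):
            raise ValueError("need cutoff > lj_contact > 0")
        if self.hard_core < 0 or self.eps_lj < 0 or self.eps_rep < 0:
            raise ValueError("hard_core, eps_lj, eps_rep must be >= 0")

    @property
    def has_electrostatics(self) -> bool:
        return self.mode in ("steric_elec", "full")


@dataclass
class PairList:
    """Exposed-atom pairs of distinct molecules within cutoff + skin."""

    atom_i: np.ndarray  # global exposed-atom indices, see SystemState
    atom_j: np.ndarray
    mol_i: np.ndarray
    mol_j: np.ndarray
    build_time: float = 0.0

    def __len__(self) -> int:
        return len(self.atom_i)


def minimum_image(dr, box_edge: float) -> np.ndarray:
    """Minimum-image displacement; each component in (-L/2, L/2]."""
    if box_edge <= 0:
        raise ValueError("box_edge must be > 0")
    dr = np.asarray(dr, dtype=float)
    w = dr - box_edge * np.floor(dr / box_edge + 0.5)
    # floor convention yields [-L/2, L/2); move the closed end to +L/2
    return np.where(w <= -box_edge / 2, w + box_edge, w)


def build_pair_list(state, skin: float | None = None) -> PairList:
    """All exposed-atom pairs of distinct molecules within cutoff + skin."""
    params = state.params
    if skin is None:
        skin = params.pairlist_skin
    coords, mols, _ = state.exposed_atom_arrays()
    L = state.box_edge
    wrapped = np.mod(coords, L)
    # guard against coordinates landing exactly on L after fmod rounding
    wrapped[wrapped >= L] = 0.0
    tree = cKDTree(wrapped, boxsize=L)
    pairs = tree.query_pairs(params.cutoff + skin, output_type="ndarray")
    if len(pairs):
        keep = mols[pairs[:, 0]] != mols[pairs[:, 1]]
        pairs = pairs[keep]
    # canonical order: mol_i < mol_j
    a, b = pairs[:, 0] if len(pairs) else np.empty(0, int), \
        pairs[:, 1] if len(pairs) else np.empty(0, int)
    swap = mols[a] > mols[b] if len(pairs) else np.empty(0, bool)
    ai = np.where(swap, b, a)
    aj = np.where(swap, a, b)
    return PairList(atom_i=ai, atom_j=aj, mol_i=mols[ai], mol_j=mols[aj],
                    build_time=state.time)


def lj_pair_energy(r, params: EnergyModelParams):
    """Pair energy (kcal/mol) and radial force -dE/dr (kcal/mol/Å).

    Full mode: E = eps_lj [ (r_m/r)^12 - 2 (r_m/r)^6 ], minimum -eps_lj
    at r = r_m = lj_contact.  Steric modes: E = eps_rep (r_m/r)^12.
    Both vanish beyond the cutoff (no shift).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    x = params.lj_contact / r
    x6 = x ** 6
    if params.mode == "full":
        e = params.eps_lj * (x6 * x6 - 2.0 * x6)
        f = 12.0 * params.eps_lj * (x6 * x6 - x6) / r
    else:
        e = params.eps_rep * x6 * x6
        f = 12.0 * params.eps_rep * x6 * x6 / r
    live = r < params.cutoff
    return np.where(live, e, 0.0), np.where(live, f, 0.0)


def _interp_with_fallback(template, pts_body, gradient=True):
    """Potential of ``template`` at body-frame points: fine grid where the
    point lies inside it, else coarse grid, else zero."""
    n = len(pts_body)
    vals = np.zeros(n)
    grads = np.zeros((n, 3))
    remaining = np.ones(n, dtype=bool)
    for grid in (template.fine_grid, template.coarse_grid):
        if grid is None or not np.any(remaining):
            continue
        v, g, inside = grid.interpolate(pts_body[remaining], gradient=True)
        idx = np.where(remaining)[0][inside]
        vals[idx] = v[inside]
        grads[idx] = g[inside]
        remaining[idx] = False
    if gradient:
        return vals, grads
    return vals


def _elec_one_way(qpos_i, qmag_i, Ri, tmpl_j, Rj, d_ij):
    """Energy of molecule i's effective charges in molecule j's grids.

    ``d_ij`` is the minimum-image vector from j's centre to i's centre.
    Returns (E, force_on_each_charge (lab), charge offsets from i's
    centre (lab), charge offsets from j's centre (lab)).
    """
    off_i = qpos_i @ Ri.T  # lab offsets from i's centre
    rel_j = d_ij + off_i  # lab offsets from j's centre
    body_j = rel_j @ Rj  # into j's body frame
    vals, grads_body = _interp_with_fallback(tmpl_j, body_j)
    e = float(np.dot(qmag_i, vals))
    grads_lab = grads_body @ Rj.T
    forces = -qmag_i[:, None] * grads_lab
    return e, forces, off_i, rel_j


def electrostatic_energy(state, i: int, j: int, with_forces: bool = True):
    """Symmetrized grid electrostatic energy between molecules i and j.

    E = 1/2 [ sum_a q_a^(i) Phi^(j)(r_a) + sum_b q_b^(j) Phi^(i)(r_b) ],
    with Phi interpolated trilinearly (fine grid, else coarse, else 0).
    Returns E or (E, f_i, t_i, f_j, t_j) with forces (kcal/mol/Å) and
    torques (kcal/mol) about each molecule's centre.
    """
    ti, tj = state.template_of(i), state.template_of(j)
    eci, ecj = ti.effective_charges, tj.effective_charges
    zero = (eci is None or np.all(np.abs(eci.magnitudes) < 1e-14)
            or ecj is None or np.all(np.abs(ecj.magnitudes) < 1e-14))
    if zero:
        if with_forces:
            return 0.0, np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3)
        return 0.0
    d_ij = minimum_image(state.centres[i] - state.centres[j], state.box_edge)
    Ri, Rj = state.rotations[i], state.rotations[j]
    e1, f1, off1_i, rel1_j = _elec_one_way(
        eci.positions, eci.magnitudes, Ri, tj, Rj, d_ij)
    e2, f2, off2_j, rel2_i = _elec_one_way(
        ecj.positions, ecj.magnitudes, Rj, ti, Ri, -d_ij)
    e = 0.5 * (e1 + e2)
    if not with_forces:
        return e
    f_i = 0.5 * (f1.sum(axis=0) - f2.sum(axis=0))
    f_j = 0.5 * (f2.sum(axis=0) - f1.sum(axis=0))
    t_i = 0.5 * (np.cross(off1_i, f1).sum(axis=0)
                 + np.cross(rel2_i, -f2).sum(axis=0))
    t_j = 0.5 * (np.cross(off2_j, f2).sum(axis=0)
                 + np.cross(rel1_j, -f1).sum(axis=0))
    return e, f_i, t_i, f_j, t_j


def _electrostatic_pairs(state):
    """Molecule pairs close enough for any grid overlap, by centre distance."""
    M = state.n_molecules
    reach = np.empty(M)
    qb = np.empty(M)
    active = np.zeros(M, dtype=bool)
    for m in range(M):
        t = state.template_of(m)
        ec = t.effective_charges
        active[m] = (ec is not None and np.any(np.abs(ec.magnitudes) > 1e-14)
                     and (t.fine_grid is not None or t.coarse_grid is not None))
        grids = [g for g in (t.coarse_grid, t.fine_grid) if g is not None]
        reach[m] = max((g.max_reach for g in grids), default=0.0)
        qb[m] = (np.max(np.linalg.norm(ec.positions, axis=1))
                 if ec is not None and len(ec) else 0.0)
    idx = np.where(active)[0]
    out = []
    for a in range(len(idx)):
        i = idx[a]
        for b in range(a + 1, len(idx)):
            j = idx[b]
            d = np.linalg.norm(minimum_image(
                state.centres[i] - state.centres[j], state.box_edge))
            if d < max(reach[i] + qb[j], reach[j] + qb[i]):
                out.append((i, j))
    return out


def system_energy_forces(state, pairlist: PairList):
    """Total energy, per-molecule forces and torques.

    Returns ``(energy, forces, torques)`` where ``energy`` is a dict with
    keys ``lj``, ``elec``, ``total`` (kcal/mol), and forces/torques are
    (M, 3) arrays.  Distances below the hard core are clamped to it for
    LJ scoring (the dynamics prevents such overlaps separately).
    """
    params = state.params
    M = state.n_molecules
    forces = np.zeros((M, 3))
    torques = np.zeros((M, 3))
    e_lj = 0.0
    coords, mols, _ = state.exposed_atom_arrays()
    if len(pairlist):
        dr = minimum_image(coords[pairlist.atom_i] - coords[pairlist.atom_j],
                           state.box_edge)
        r = np.linalg.norm(dr, axis=1)
        keep = r < params.cutoff
        if np.any(keep):
            dr, r = dr[keep], r[keep]
            mi = pairlist.mol_i[keep]
            mj = pairlist.mol_j[keep]
            rc = np.maximum(r, params.hard_core)
            e, fmag = lj_pair_energy(rc, params)
            e_lj = float(e.sum())
            fvec = (fmag / r)[:, None] * dr  # force on atom i; -fvec on j
            np.add.at(forces, mi, fvec)
            np.add.at(forces, mj, -fvec)
            off = coords - state.centres[mols]  # lab offset from own centre
            np.add.at(torques, mi,
                      np.cross(off[pairlist.atom_i[keep]], fvec))
            np.add.at(torques, mj,
                      np.cross(off[pairlist.atom_j[keep]], -fvec))
    e_elec = 0.0
    if params.has_electrostatics:
        for i, j in _electrostatic_pairs(state):
            e, f_i, t_i, f_j, t_j = electrostatic_energy(state, i, j)
            e_elec += e
            forces[i] += f_i
            forces[j] += f_j
            torques[i] += t_i
            torques[j] += t_j
    energy = {"lj": e_lj, "elec": e_elec, "total": e_lj + e_elec}
    return energy, forces, torques
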