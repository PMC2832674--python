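"""Initial configurations, synthetic test systems and composition bookkeeping.

Everything the test suite simulates is generated here: random packings at
a target density (with a minimum surface-surface separation between all
neighbors, as used to initialize crowded-cytoplasm runs), hard-sphere
fluids, rigid "bead protein" stand-ins for atomically detailed
structures, and self-avoiding random-coil ensembles standing in for
statistical-coil models of unfolded proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import N_AVOGADRO
from .energy import EnergyModelParams, minimum_image
from .engine import SystemState, random_rotations
from .models import (AtomRecord, EffectiveChargeSet, RigidBodyTemplate,
                     make_template_grids, select_exposed_atoms,
                     stokes_einstein_coefficients)

__all__ = [
    "CompositionSpec",
    "PackingError",
    "random_pack",
    "composition_summary",
    "volume_fraction_from_concentrations",
    "make_sphere_fluid",
    "make_bead_protein",
    "make_unfolded_ensemble",
    "ensemble_rg",
]


class PackingError(RuntimeError):
    pass


@dataclass
class CompositionSpec:
    """Molecule types with copy numbers in a cubic box."""

    entries: list  # of (RigidBodyTemplate, copy_number)
    box_edge: float
    target_concentration: float | None = None  # g/l, optional check

    def __post_init__(self):
        for t, n in self.entries:
            if n < 0:
                raise ValueError(f"negative copy number for {t.name}")

    @property
    def total_copies(self) -> int:
        return sum(n for _, n in self.entries)


# --------------------------------------------------------------------------
# packing
# --------------------------------------------------------------------------

def random_pack(spec: CompositionSpec, min_surface_sep: float = 10.0,
                seed: int = 0, max_attempts: int = 2000,
                params: EnergyModelParams | None = None,
                timestep: float = 2.5) -> SystemState:
    """Place all molecules with random poses at pairwise surface
    separation >= ``min_surface_sep`` under minimum image.

    Sequential insertion with rejection; each molecule gets up to
    ``max_attempts`` trial poses.  Deterministic for a given seed.
    Raises :class:`PackingError` (reporting the achieved fraction) when
    attempts are exhausted.
    """
    rng = np.random.default_rng(seed)
    L = spec.box_edge
    templates = [t for t, _ in spec.entries]
    order = [i for i, (_, n) in enumerate(spec.entries) for _ in range(n)]
    placed_coords = []  # exposed atom coords of placed molecules
    placed_radii = []
    centres, rotations = [], []
    total = len(order)
    for count, t_idx in enumerate(order):
        tmpl = templates[t_idx]
        body = tmpl.exposed_positions
        radii = tmpl.exposed_radii
        ok = False
        for _ in range(max_attempts):
            c = rng.uniform(0, L, size=3)
            R = random_rotations(1, rng)[0]
            lab = c + body @ R.T
            if placed_coords:
                flat = np.concatenate(placed_coords)
                frad = np.concatenate(placed_radii)
                # conservative prefilter by bounding spheres
                reach = (max(radii) + frad.max() + min_surface_sep
                         + np.linalg.norm(body, axis=1).max() if len(body) else 0)
                clash = False
                for a, ra in zip(lab, radii):
                    dr = minimum_image(flat - a, L)
                    surf = np.linalg.norm(dr, axis=1) - frad - ra
                    if np.any(surf < min_surface_sep):
                        clash = True
                        break
                if clash:
                    continue
            centres.append(c)
            rotations.append(R)
            placed_coords.append(lab)
            placed_radii.append(radii)
            ok = True
            break
        if not ok:
            raise PackingError(
                f"packing infeasible: placed {count}/{total} molecules "
                f"({count / total:.0%}) at separation {min_surface_sep} Å")
    template_index = np.array(order, int)
    return SystemState.create(
        box_edge=L, templates=templates, template_index=template_index,
        centres=np.array(centres).reshape(-1, 3),
        rotations=np.array(rotations).reshape(-1, 3, 3),
        params=params or EnergyModelParams(), timestep=timestep, seed=seed)


# --------------------------------------------------------------------------
# composition bookkeeping
# --------------------------------------------------------------------------

def volume_fraction_from_concentrations(concentrations: dict,
                                        specific_volumes) -> float:
    """Volume fraction from per-kind mass concentrations (g/l) and
    specific volumes (ml/g), e.g. protein 0.73 and RNA 0.58 ml/g.

    ``specific_volumes`` may be a dict keyed like ``concentrations`` or a
    single uniform value.
    """
    phi = 0.0
    for kind, conc in concentrations.items():
        if isinstance(specific_volumes, dict):
            if kind not in specific_volumes:
                raise ValueError(f"no specific volume for kind {kind!r}")
            v = specific_volumes[kind]
        else:
            v = float(specific_volumes)
        phi += conc * v / 1000.0  # (g/l)·(ml/g) = ml/l
    return phi


def composition_summary(spec: CompositionSpec, specific_volumes) -> dict:
    """Per-kind mass concentrations (g/l) and the total volume fraction.

    Templates must carry ``mass`` (kDa) and ``kind``.  Returns a dict
    with ``concentration`` (per kind), ``total_concentration`` and
    ``volume_fraction``.
    """
    v_box_l = (spec.box_edge ** 3) * 1e-27  # Å³ -> litres
    conc: dict = {}
    for tmpl, copies in spec.entries:
        if tmpl.mass is None:
            raise ValueError(f"{tmpl.name}: template has no mass")
        grams_per_mol = tmpl.mass * 1000.0  # kDa -> g/mol
        c = copies * grams_per_mol / (N_AVOGADRO * v_box_l)
        conc[tmpl.kind] = conc.get(tmpl.kind, 0.0) + c
    return {
        "concentration": conc,
        "total_concentration": sum(conc.values()),
        "volume_fraction": volume_fraction_from_concentrations(
            conc, specific_volumes),
    }


# --------------------------------------------------------------------------
# synthetic systems
# --------------------------------------------------------------------------

def _sphere_template(name: str, radius: float, charge: float = 0.0,
                     viscosity: float = 0.89) -> RigidBodyTemplate:
    d0t, d0r = stokes_einstein_coefficients(radius, viscosity=viscosity)
    # bead mass from volume at a protein-like specific volume of 0.73 ml/g
    vol = 4.0 / 3.0 * math.pi * radius ** 3  # Å³
    mass_kda = vol * 1e-24 / 0.73 * N_AVOGADRO / 1000.0 * 1e-3
    t = RigidBodyTemplate(
        name=name,
        atoms=[AtomRecord("C", np.zeros(3), radius=radius, charge=charge)],
        effective_charges=EffectiveChargeSet(np.zeros((1, 3)),
                                             np.array([charge])),
        d0_trans=d0t, d0_rot=d0r, hydrodynamic_radius=radius,
        mass=mass_kda, kind="protein")
    return t


def make_sphere_fluid(n: int, radius: float, box_edge: float, seed: int = 0,
                      eps_rep: float = 0.0, timestep: float = 2.5,
                      min_surface_sep: float = 0.0) -> SystemState:
    """n identical neutral spheres in steric mode.

    The hard core and LJ contact are set to 2·radius so the spheres are
    genuinely hard (with ``eps_rep = 0`` the dynamics is free diffusion
    plus hard-core rejection — an equilibrium hard-sphere sampler).  The
    packing fraction n·(4/3)πr³/L³ is stored in ``state.meta``.
    """
    params = EnergyModelParams(
        mode="steric", eps_rep=eps_rep, lj_contact=2.0 * radius,
        cutoff=max(12.0, 2.0 * radius + 6.0), hard_core=2.0 * radius)
    tmpl = _sphere_template("sphere", radius)
    if n == 0:
        state = SystemState.create(
            box_edge=box_edge, templates=[tmpl],
            template_index=np.empty(0, int), centres=np.zeros((0, 3)),
            rotations=np.zeros((0, 3, 3)), params=params,
            timestep=timestep, seed=seed)
    else:
        spec = CompositionSpec(entries=[(tmpl, n)], box_edge=box_edge)
        state = random_pack(spec, min_surface_sep=min_surface_sep, seed=seed,
                            params=params, timestep=timestep)
    state.meta["packing_fraction"] = (
        n * 4.0 / 3.0 * math.pi * radius ** 3 / box_edge ** 3)
    return state


def make_bead_protein(n_beads: int, bead_radius: float = 4.0,
                      geometry: str = "chain", charges=None, seed: int = 0,
                      name: str | None = None, with_grids: bool | None = None,
                      ionic_strength: float = 0.150) -> RigidBodyTemplate:
    """Rigid bead "protein": a touching-bead chain or a compact globule.

    Charges (one per bead, optional) become the effective charges
    directly — exact for the internally generated screened-Coulomb
    grids, which are attached whenever any bead is charged.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if geometry == "chain":
        pos = np.column_stack([2.0 * bead_radius * np.arange(n_beads),
                               np.zeros(n_beads), np.zeros(n_beads)])
    elif geometry == "globule":
        # first n sites of an FCC-like lattice, nearest the origin
        a = 2.0 * bead_radius
        span = int(np.ceil(n_beads ** (1 / 3))) + 1
        grid = np.array([[i, j, k] for i in range(-span, span + 1)
                         for j in range(-span, span + 1)
                         for k in range(-span, span + 1)
                         if (i + j + k) % 2 == 0], float) * (a / math.sqrt(2))
        order = np.argsort(np.linalg.norm(grid, axis=1), kind="stable")
        pos = grid[order[:n_beads]]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    pos = pos - pos.mean(axis=0)
    if charges is None:
        charges = np.zeros(n_beads)
    charges = np.asarray(charges, float)
    if len(charges) != n_beads:
        raise ValueError("need one charge per bead")
    atoms = [AtomRecord(f"C{i}", p, radius=bead_radius, charge=q)
             for i, (p, q) in enumerate(zip(pos, charges))]
    tmpl = RigidBodyTemplate(
        name=name or f"{geometry}{n_beads}", atoms=atoms,
        effective_charges=EffectiveChargeSet(pos.copy(), charges.copy()),
        kind="protein")
    select_exposed_atoms(tmpl, probe_radius=4.0, n_points=240)
    rh = max(bead_radius, 1.29 * tmpl.radius_of_gyration)
    tmpl.hydrodynamic_radius = rh
    tmpl.d0_trans, tmpl.d0_rot = stokes_einstein_coefficients(rh)
    vol = n_beads * 4.0 / 3.0 * math.pi * bead_radius ** 3
    tmpl.mass = vol * 1e-24 / 0.73 * N_AVOGADRO / 1000.0 * 1e-3
    if with_grids is None:
        with_grids = bool(np.any(np.abs(charges) > 1e-12))
    if with_grids:
        make_template_grids(tmpl, ionic_strength=ionic_strength)
    tmpl.validate()
    return tmpl


def make_unfolded_ensemble(n_conformations: int = 1000, n_beads: int = 20,
                           bond_length: float | None = None,
                           bead_radius: float = 4.0, seed: int = 0,
                           max_retries: int = 2000) -> list:
    """Self-avoiding random-walk bead chains modelling unfolded coils.

    Each conformation is a freely jointed chain of ``n_beads`` beads at
    fixed ``bond_length`` (default: touching, 2·bead_radius) whose beads
    never overlap (centre separation >= 2·bead_radius for non-bonded
    pairs); chains failing self-avoidance are regenerated.  Use
    :func:`ensemble_rg` for the radius-of-gyration distribution.
    """
    if n_beads < 2:
        raise ValueError("n_beads must be >= 2")
    if bond_length is None:
        bond_length = 2.0 * bead_radius
    rng = np.random.default_rng(seed)
    min_sep = 2.0 * bead_radius * 0.999  # tolerance for touching bonds
    out = []
    for k in range(n_conformations):
        for _attempt in range(max_retries):
            pos = np.zeros((n_beads, 3))
            failed = False
            for i in range(1, n_beads):
                placed = False
                for _ in range(50):
                    v = rng.normal(size=3)
                    v *= bond_length / np.linalg.norm(v)
                    cand = pos[i - 1] + v
                    d = np.linalg.norm(pos[: max(i - 1, 1)] - cand, axis=1)
                    if i == 1 or np.all(d >= min_sep):
                        pos[i] = cand
                        placed = True
                        break
                if not placed:
                    failed = True
                    break
            if not failed:
                break
        else:
            raise PackingError("self-avoiding chain generation failed")
        pos = pos - pos.mean(axis=0)
        atoms = [AtomRecord(f"C{i}", p, radius=bead_radius, charge=0.0)
                 for i, p in enumerate(pos)]
        tmpl = RigidBodyTemplate(name=f"coil{n_beads}_{k}", atoms=atoms,
                                 effective_charges=EffectiveChargeSet(
                                     np.zeros((1, 3)), np.zeros(1)),
                                 kind="protein")
        rh = max(bead_radius, 1.29 * tmpl.radius_of_gyration)
        tmpl.hydrodynamic_radius = rh
        tmpl.d0_trans, tmpl.d0_rot = stokes_einstein_coefficients(rh)
        vol = n_beads * 4.0 / 3.0 * math.pi * bead_radius ** 3
        tmpl.mass = vol * 1e-24 / 0.73 * N_AVOGADRO / 1000.0 * 1e-3
        out.append(tmpl)
    return out


def ensemble_rg(templates) -> np.ndarray:
    """Radius-of-gyration of each conformation in an ensemble, Å."""
    return np.array([t.radius_of_gyration for t in templates])
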