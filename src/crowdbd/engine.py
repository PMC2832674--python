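"""Rigid-body Brownian dynamics without hydrodynamic interactions.

Each molecule's pose is a centre (wrapped into the periodic box, with an
unwrapped copy accumulated for diffusion analysis) plus a 3x3 rotation
matrix.  One timestep displaces each body by the overdamped drift
(D0/kT) F dt plus an isotropic Gaussian displacement of variance 2 D0 dt
per component, and rotates it by the analogous angular increment about
its centre.  A hard-core constraint (no exposed-atom pair of distinct
molecules below 4.5 Å at the end of a step) is enforced by resampling
the stochastic part of offending molecules' moves, falling back to
reverting them to their previous pose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .constants import kt
from .energy import (EnergyModelParams, build_pair_list, minimum_image,
                     system_energy_forces)
from .models import (RigidBodyTemplate, template_from_dict, template_to_dict)
from .trajio import Trajectory

__all__ = ["SystemState", "bd_step", "enforce_hard_core", "run_simulation",
           "place_tracers", "random_rotations", "save_state", "load_state"]


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rotation matrices uniform over SO(3) (normalized random quaternions)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return Rotation.from_quat(q).as_matrix()


@dataclass
class SystemState:
    """Periodic box of rigid-body molecule instances plus run parameters."""

    box_edge: float
    templates: list
    template_index: np.ndarray  # (M,) into templates
    centres: np.ndarray  # (M, 3) wrapped into [0, L)
    unwrapped: np.ndarray  # (M, 3)
    rotations: np.ndarray  # (M, 3, 3)
    params: EnergyModelParams
    timestep: float = 2.5  # ps
    time: float = 0.0
    rng: np.random.Generator | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)
    _layout: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError("box_edge must be > 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        self.template_index = np.asarray(self.template_index, dtype=int)
        self.centres = np.atleast_2d(np.asarray(self.centres, dtype=float))
        self.unwrapped = np.atleast_2d(np.asarray(self.unwrapped, dtype=float))
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(-1, 3, 3)
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)

    # ------------------------------------------------------------------
    @classmethod
    def create(cls, box_edge, templates, template_index, centres, rotations,
               params=None, timestep=2.5, seed=0):
        centres = np.atleast_2d(np.asarray(centres, dtype=float))
        return cls(box_edge=box_edge, templates=list(templates),
                   template_index=np.asarray(template_index, int),
                   centres=np.mod(centres, box_edge),
                   unwrapped=centres.copy(),
                   rotations=np.asarray(rotations, float).reshape(-1, 3, 3),
                   params=params or EnergyModelParams(),
                   timestep=timestep, seed=seed)

    @property
    def n_molecules(self) -> int:
        return len(self.template_index)

    def template_of(self, m: int) -> RigidBodyTemplate:
        return self.templates[self.template_index[m]]

    @property
    def type_labels(self) -> list:
        return [self.template_of(m).name for m in range(self.n_molecules)]

    def d0_arrays(self):
        d0t = np.array([self.template_of(m).d0_trans
                        for m in range(self.n_molecules)])
        d0r = np.array([self.template_of(m).d0_rot
                        for m in range(self.n_molecules)])
        return d0t, d0r

    def _exposed_layout(self):
        """Flattened body-frame exposed-atom layout, cached across steps
        (shared by copies; invalidated when the composition changes)."""
        if self._layout is None:
            body, mols, radii = [], [], []
            for m in range(self.n_molecules):
                t = self.template_of(m)
                p = t.exposed_positions
                body.append(p)
                mols.append(np.full(len(p), m))
                radii.append(t.exposed_radii)
            if body:
                self._layout = (np.concatenate(body),
                                np.concatenate(mols).astype(int),
                                np.concatenate(radii))
            else:
                self._layout = (np.zeros((0, 3)), np.zeros(0, int),
                                np.zeros(0))
        return self._layout

    def exposed_atom_arrays(self, molecules=None):
        """Lab-frame exposed-atom coordinates.

        Returns (coords (A, 3), mol_index (A,), radii (A,)).  Coordinates
        use the wrapped centres; callers apply minimum image themselves.
        """
        if molecules is not None:
            coords, mols, radii = [], [], []
            for m in molecules:
                t = self.template_of(m)
                p = t.exposed_positions
                coords.append(self.centres[m] + p @ self.rotations[m].T)
                mols.append(np.full(len(p), m))
                radii.append(t.exposed_radii)
            if not coords:
                return (np.zeros((0, 3)), np.zeros(0, int), np.zeros(0))
            return (np.concatenate(coords),
                    np.concatenate(mols).astype(int), np.concatenate(radii))
        body, mols, radii = self._exposed_layout()
        coords = self.centres[mols] + np.einsum(
            "aij,aj->ai", self.rotations[mols], body)
        return coords, mols, radii

    def copy(self) -> "SystemState":
        new = SystemState(box_edge=self.box_edge, templates=self.templates,
                          template_index=self.template_index.copy(),
                          centres=self.centres.copy(),
                          unwrapped=self.unwrapped.copy(),
                          rotations=self.rotations.copy(),
                          params=self.params, timestep=self.timestep,
                          time=self.time, rng=self.rng, seed=self.seed,
                          meta=dict(self.meta))
        new._layout = self._layout
        return new

    def min_pair_distance(self) -> float:
        """Smallest exposed-atom distance between distinct molecules."""
        coords, mols, _ = self.exposed_atom_arrays()
        if len(coords) < 2:
            return np.inf
        wrapped = np.mod(coords, self.box_edge)
        wrapped[wrapped >= self.box_edge] = 0.0
        tree = cKDTree(wrapped, boxsize=self.box_edge)
        best = np.inf
        r = max(self.params.hard_core * 2, 1.0)
        while True:
            pairs = tree.query_pairs(r, output_type="ndarray")
            if len(pairs):
                diff = mols[pairs[:, 0]] != mols[pairs[:, 1]]
                if np.any(diff):
                    dr = minimum_image(wrapped[pairs[diff, 0]]
                                       - wrapped[pairs[diff, 1]], self.box_edge)
                    best = float(np.min(np.linalg.norm(dr, axis=1)))
                    break
            r *= 2
            if r > self.box_edge:
                break
        return best


def _clashing_molecules(state: SystemState, threshold: float) -> np.ndarray:
    """Molecules having an exposed-atom pair below ``threshold``."""
    coords, mols, _ = state.exposed_atom_arrays()
    if len(coords) < 2:
        return np.empty(0, int)
    wrapped = np.mod(coords, state.box_edge)
    wrapped[wrapped >= state.box_edge] = 0.0
    tree = cKDTree(wrapped, boxsize=state.box_edge)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if not len(pairs):
        return np.empty(0, int)
    diff = mols[pairs[:, 0]] != mols[pairs[:, 1]]
    if not np.any(diff):
        return np.empty(0, int)
    return np.unique(np.concatenate([mols[pairs[diff, 0]],
                                     mols[pairs[diff, 1]]]))


def bd_step(state: SystemState, forces: np.ndarray, torques: np.ndarray,
            rng: np.random.Generator | None = None) -> SystemState:
    """One Ermak-McCammon step; returns the (unconstrained) trial state.

    Per molecule: dr = (D0_trans/kT) F dt + S with S Gaussian of variance
    2 D0_trans dt per component; the body rotates by |dw| about dw/|dw|,
    dw = (D0_rot/kT) T dt + Theta, Theta Gaussian of variance 2 D0_rot dt
    per axis.  The drift and noise parts are stored in ``meta`` so the
    hard-core stage can resample the stochastic part alone.
    """
    if not (np.all(np.isfinite(forces)) and np.all(np.isfinite(torques))):
        bad = np.where(~np.all(np.isfinite(forces), axis=-1))[0]
        raise FloatingPointError(
            f"non-finite force/torque at t={state.time} ps, molecules {bad}")
    rng = rng if rng is not None else state.rng
    kT = kt(state.params.temperature)
    dt = state.timestep
    d0t, d0r = state.d0_arrays()
    drift_t = (d0t / kT)[:, None] * forces * dt
    drift_r = (d0r / kT)[:, None] * torques * dt
    sig_t = np.sqrt(2.0 * d0t * dt)[:, None]
    sig_r = np.sqrt(2.0 * d0r * dt)[:, None]
    noise_t = sig_t * rng.normal(size=(state.n_molecules, 3))
    noise_r = sig_r * rng.normal(size=(state.n_molecules, 3))
    disp = drift_t + noise_t
    dw = drift_r + noise_r
    new = state.copy()
    new.unwrapped = state.unwrapped + disp
    new.centres = np.mod(state.centres + disp, state.box_edge)
    new.rotations = np.einsum(
        "mij,mjk->mik", Rotation.from_rotvec(dw).as_matrix(), state.rotations)
    new.time = state.time + dt
    new.meta = dict(state.meta)
    new.meta["_step"] = {"drift_t": drift_t, "drift_r": drift_r,
                         "sig_t": sig_t, "sig_r": sig_r}
    return new


def enforce_hard_core(state_prev: SystemState, state_trial: SystemState,
                      rng: np.random.Generator | None = None,
                      max_retries: int = 100) -> SystemState:
    """Return a state with no exposed-atom pair below the hard core.

    Offending molecules get freshly resampled stochastic displacements
    (keeping the deterministic drift) up to ``max_retries`` times; any
    still offending then revert to their previous pose, iterating until
    the returned configuration is clash-free.
    """
    hc = state_prev.params.hard_core
    if hc <= 0:
        return state_trial
    rng = rng if rng is not None else state_trial.rng
    step = state_trial.meta.get("_step")
    cur = state_trial
    offenders = _clashing_molecules(cur, hc)
    tries = 0
    while len(offenders) and tries < max_retries and step is not None:
        tries += 1
        noise_t = step["sig_t"][offenders] * rng.normal(size=(len(offenders), 3))
        noise_r = step["sig_r"][offenders] * rng.normal(size=(len(offenders), 3))
        disp = step["drift_t"][offenders] + noise_t
        dw = step["drift_r"][offenders] + noise_r
        cur.unwrapped[offenders] = state_prev.unwrapped[offenders] + disp
        cur.centres[offenders] = np.mod(
            state_prev.centres[offenders] + disp, cur.box_edge)
        cur.rotations[offenders] = np.einsum(
            "mij,mjk->mik", Rotation.from_rotvec(dw).as_matrix(),
            state_prev.rotations[offenders])
        offenders = _clashing_molecules(cur, hc)
    # terminal fallback: revert offenders (and any molecule a revert
    # newly brings into conflict) to the clash-free previous pose
    while len(offenders):
        cur.unwrapped[offenders] = state_prev.unwrapped[offenders]
        cur.centres[offenders] = state_prev.centres[offenders]
        cur.rotations[offenders] = state_prev.rotations[offenders]
        remaining = _clashing_molecules(cur, hc)
        grown = np.union1d(offenders, remaining)
        if len(remaining) == 0 or len(grown) == len(offenders):
            break  # clean, or clash predates state_prev — nothing more to do
        offenders = grown
    cur.meta.pop("_step", None)
    return cur


def run_simulation(state: SystemState, n_steps: int,
                   record_every: int = 40, pairlist_refresh: int | None = None,
                   reorthonormalize_every: int = 1000):
    """Propagate ``n_steps`` BD steps, recording poses and energies.

    Returns ``(trajectory, run_log, final_state)`` where ``run_log`` is a
    DataFrame with columns time, e_elec, e_lj, e_total at each recorded
    frame.  Deterministic for a given initial state seed.
    """
    import pandas as pd

    if pairlist_refresh is None:
        pairlist_refresh = state.params.pairlist_refresh
    times, poses, rots, log = [], [], [], []
    cur = state.copy()
    pl = build_pair_list(cur)

    def record(st, energy):
        times.append(st.time)
        poses.append(st.unwrapped.copy())
        rots.append(st.rotations.copy())
        log.append({"time": st.time, "e_elec": energy["elec"],
                    "e_lj": energy["lj"], "e_total": energy["total"]})

    energy, forces, torques = system_energy_forces(cur, pl)
    record(cur, energy)
    for step in range(1, n_steps + 1):
        trial = bd_step(cur, forces, torques)
        cur = enforce_hard_core(cur, trial)
        if step % pairlist_refresh == 0:
            pl = build_pair_list(cur)
        if step % reorthonormalize_every == 0:
            u, _, vt = np.linalg.svd(cur.rotations)
            cur.rotations = np.einsum("mij,mjk->mik", u, vt)
        energy, forces, torques = system_energy_forces(cur, pl)
        if step % record_every == 0:
            record(cur, energy)
    templates = {t.name: t for t in cur.templates}
    traj = Trajectory(np.array(times), np.array(poses), np.array(rots),
                      cur.type_labels, cur.box_edge, templates)
    return traj, pd.DataFrame(log), cur


def place_tracers(state: SystemState, tracer_template: RigidBodyTemplate,
                  n: int = 8, rng: np.random.Generator | None = None
                  ) -> SystemState:
    """Add ``n`` tracer copies; 8 go to the octant centres of the box.

    For n = 8 the tracers sit at (L/4 or 3L/4) per axis — the centres of
    the eight octants — with random orientations; other counts are
    placed uniformly at random.
    """
    rng = rng if rng is not None else state.rng
    L = state.box_edge
    if n == 8:
        centres = np.array([[x, y, z]
                            for x in (L / 4, 3 * L / 4)
                            for y in (L / 4, 3 * L / 4)
                            for z in (L / 4, 3 * L / 4)])
        # canonical first tracer at (L/4, L/4, L/4)
        centres = centres[np.lexsort((centres[:, 2], centres[:, 1],
                                      centres[:, 0]))]
    else:
        centres = rng.uniform(0, L, size=(n, 3))
    rot = random_rotations(n, rng)
    new = state.copy()
    if tracer_template in new.templates:
        t_idx = new.templates.index(tracer_template)
    else:
        new.templates = list(new.templates) + [tracer_template]
        t_idx = len(new.templates) - 1
    new.template_index = np.concatenate(
        [new.template_index, np.full(n, t_idx, int)])
    new.centres = np.vstack([new.centres, centres])
    new.unwrapped = np.vstack([new.unwrapped, centres])
    new.rotations = np.concatenate([new.rotations, rot])
    new._layout = None
    return new


# --------------------------------------------------------------------------
# state serialization (JSON, including the RNG stream for exact restart)
# --------------------------------------------------------------------------

def save_state(state: SystemState, path):
    doc = {
        "format": "crowdbd-state-v1",
        "box_edge": state.box_edge,
        "timestep": state.timestep,
        "time": state.time,
        "seed": state.seed,
        "params": vars(state.params).copy(),
        "templates": [template_to_dict(t) for t in state.templates],
        "template_index": state.template_index.tolist(),
        "centres": state.centres.tolist(),
        "unwrapped": state.unwrapped.tolist(),
        "rotations": state.rotations.tolist(),
        "rng_state": state.rng.bit_generator.state,
        "meta": {k: v for k, v in state.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_state(path) -> SystemState:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "crowdbd-state-v1":
        raise ValueError(f"{path}: not a crowdbd state file")
    state = SystemState(
        box_edge=doc["box_edge"],
        templates=[template_from_dict(d) for d in doc["templates"]],
        template_index=np.array(doc["template_index"], int),
        centres=np.array(doc["centres"]),
        unwrapped=np.array(doc["unwrapped"]),
        rotations=np.array(doc["rotations"]),
        params=EnergyModelParams(**doc["params"]),
        timestep=doc["timestep"], time=doc["time"], seed=doc["seed"],
        meta=doc.get("meta", {}),
    )
    state.rng.bit_generator.state = doc["rng_state"]
    return state
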