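"""Particle-insertion thermodynamics on simulation snapshots.

The transfer free energy of a molecule from dilute solution into the
crowded environment is estimated with Widom's insertion method,

    ΔG = −RT ln < exp(−E_int/RT) >,

averaging over uniformly random trial translations and orientations in
the snapshot box.  Steric scoring is binary — E_int = +∞ on any clash,
0 otherwise, so ΔG = −RT ln(accepted/attempted) — and "full" scoring
evaluates the grid electrostatics + Lennard-Jones interaction energy of
each non-clashing pose (a hard-core clash still scores +∞).

Crowding effects on folding come from inserting the folded structure
and each member of an unfolded ensemble (equal trials per conformation,
pooled Boltzmann average); effects on association come from inserting
the assembled complex versus all components simultaneously (placements
with inter-component clashes are resampled — that interaction belongs to
both legs of the thermodynamic cycle and cancels).  ΔΔG is reported
with the convention positive = the associated/folded form is stabilized
by the crowded environment.  Scaled particle theory provides the
analytic cross-check for hard-sphere fluids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import kt
from .energy import lj_pair_energy, minimum_image
from .engine import SystemState, random_rotations
from .models import RigidBodyTemplate

__all__ = [
    "InsertionResult", "FoldingTarget", "AssociationTarget",
    "insert_species", "insertion_free_energy_smoothed",
    "folding_ddg", "association_ddg", "spt_insertion_free_energy",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class InsertionResult:
    """Outcome of Widom trials for one species on one snapshot."""

    n_attempted: int
    n_accepted: int
    energies: np.ndarray  # finite E_int samples of accepted trials, kcal/mol
    rt: float  # kcal/mol

    def __post_init__(self):
        self.energies = np.asarray(self.energies, float)
        if self.n_accepted > self.n_attempted:
            raise ValueError("accepted cannot exceed attempted")

    @property
    def acceptance(self) -> float:
        return self.n_accepted / self.n_attempted

    @property
    def dg_steric(self) -> float:
        """−RT ln(accepted/attempted); +inf when nothing fits."""
        if self.n_accepted == 0:
            return math.inf
        return -self.rt * math.log(self.acceptance)

    @property
    def boltzmann_sum(self) -> float:
        """Σ exp(−E/RT) over all attempts (clashes contribute 0)."""
        if len(self.energies) == 0:
            return 0.0
        return float(np.sum(np.exp(-self.energies / self.rt)))

    @property
    def dg_full(self) -> float:
        """−RT ln <exp(−E_int/RT)> over ALL attempts."""
        if self.boltzmann_sum == 0.0:
            return math.inf
        return -self.rt * math.log(self.boltzmann_sum / self.n_attempted)

    def standard_error_dg(self) -> float:
        """MC standard error of dg_full via the delta method."""
        w = np.zeros(self.n_attempted)
        w[: len(self.energies)] = np.exp(-self.energies / self.rt)
        mean = w.mean()
        if mean == 0:
            return math.inf
        return float(self.rt * w.std(ddof=1) / (mean *
                                                math.sqrt(self.n_attempted)))


@dataclass
class FoldingTarget:
    """Folded structure vs an ensemble of unfolded conformations."""

    folded: RigidBodyTemplate
    unfolded: list  # of RigidBodyTemplate
    trials_folded: int = 100_000
    trials_per_unfolded_conformation: int = 1_000

    def __post_init__(self):
        if len(self.unfolded) < 1:
            raise ValueError("need at least one unfolded conformation")


@dataclass
class AssociationTarget:
    """Assembled complex vs its separately inserted components."""

    complex: RigidBodyTemplate
    components: list  # of RigidBodyTemplate
    stoichiometry: str = ""
    trials: int = 100_000

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("need at least 2 components")


# --------------------------------------------------------------------------
# insertion machinery
# --------------------------------------------------------------------------

class _Snapshot:
    """KDTree and atom arrays of a frozen configuration."""

    def __init__(self, state: SystemState):
        self.state = state
        self.L = state.box_edge
        coords, mols, radii = state.exposed_atom_arrays()
        self.coords = np.mod(coords, self.L)
        self.coords[self.coords >= self.L] = 0.0
        self.mols = mols
        self.radii = radii
        self.tree = (cKDTree(self.coords, boxsize=self.L)
                     if len(coords) else None)
        self.max_radius = float(radii.max()) if len(radii) else 0.0

    def clashes(self, atoms: np.ndarray, atom_radii: np.ndarray,
                clash_rule: str, clash_distance: float) -> bool:
        if self.tree is None:
            return False
        pts = np.mod(atoms, self.L)
        pts[pts >= self.L] = 0.0
        if clash_rule == "fixed":
            hits = self.tree.query_ball_point(pts, clash_distance)
            return any(len(h) for h in hits)
        # radii rule: clash when centre distance < r_atom + r_snapshot
        search = atom_radii + self.max_radius
        for p, r, s in zip(pts, atom_radii, search):
            for j in self.tree.query_ball_point(p, s):
                d = np.linalg.norm(minimum_image(self.coords[j] - p, self.L))
                if d < r + self.radii[j]:
                    return True
        return False


def _pose_atoms(template, centre, R):
    return centre + template.positions @ R.T


def _interaction_energy(snapshot: _Snapshot, template: RigidBodyTemplate,
                        centre: np.ndarray, R: np.ndarray,
                        params) -> float:
    """Full-model interaction energy of a posed template with the
    snapshot: LJ over exposed-atom pairs within cutoff + symmetrized
    grid electrostatics against every snapshot molecule."""
    from .energy import electrostatic_energy

    state = snapshot.state
    exp_pos = template.exposed_positions
    atoms = centre + exp_pos @ R.T
    pts = np.mod(atoms, snapshot.L)
    pts[pts >= snapshot.L] = 0.0
    e = 0.0
    if snapshot.tree is not None and len(pts):
        hits = snapshot.tree.query_ball_point(pts, params.cutoff)
        for p, h in zip(pts, hits):
            if not h:
                continue
            d = np.linalg.norm(minimum_image(
                snapshot.coords[h] - p, snapshot.L), axis=1)
            d = np.maximum(d, params.hard_core)
            ev, _ = lj_pair_energy(d, params)
            e += float(ev.sum())
    ec = template.effective_charges
    if (params.has_electrostatics and ec is not None
            and np.any(np.abs(ec.magnitudes) > 1e-14)):
        # borrow the pair electrostatics by viewing the inserted molecule
        # as an extra instance of the state
        ghost = state.copy()
        if template in ghost.templates:
            t_idx = ghost.templates.index(template)
        else:
            ghost.templates = list(ghost.templates) + [template]
            t_idx = len(ghost.templates) - 1
        ghost.template_index = np.concatenate(
            [ghost.template_index, [t_idx]])
        ghost.centres = np.vstack([ghost.centres,
                                   np.mod(centre, snapshot.L)])
        ghost.unwrapped = np.vstack([ghost.unwrapped, centre])
        ghost.rotations = np.concatenate([ghost.rotations, R[None]])
        g = ghost.n_molecules - 1
        for j in range(state.n_molecules):
            e += electrostatic_energy(ghost, g, j, with_forces=False)
    return e


def insert_species(snapshot: SystemState, template: RigidBodyTemplate,
                   n_trials: int, scoring: str = "steric", seed: int = 0,
                   clash_rule: str = "fixed", clash_distance: float = 4.5,
                   batch: int = 20_000) -> InsertionResult:
    """Widom insertion of one species into a frozen snapshot.

    Trial translations are uniform in the box, orientations uniform over
    SO(3).  A trial clashes when any template atom comes within
    ``clash_distance`` of a snapshot atom (``clash_rule="fixed"``), or
    within the sum of the two atomic radii (``clash_rule="radii"``, the
    hard-sphere contact used for the scaled-particle-theory check).
    Steric scoring assigns E_int = +∞ to clashes and 0 otherwise; full
    scoring evaluates the energy model for non-clashing poses.
    Deterministic for a given seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    if scoring not in ("steric", "full"):
        raise ValueError(f"unknown scoring {scoring!r}")
    rng = np.random.default_rng(seed)
    snap = snapshot if isinstance(snapshot, _Snapshot) else _Snapshot(snapshot)
    params = snap.state.params
    rt = kt(params.temperature)
    # single-atom species against single-atom snapshots vectorize fully
    simple = (template.n_atoms == 1 and snap.tree is not None)
    accepted = 0
    energies = []
    single_centered = (template.n_atoms == 1
                       and np.allclose(template.positions[0], 0.0))
    done = 0
    while done < n_trials:
        nb = min(batch, n_trials - done)
        centres = rng.uniform(0, snap.L, size=(nb, 3))
        rots = (None if single_centered else random_rotations(nb, rng))
        if simple and single_centered:
            r_atom = template.radii[0]
            if clash_rule == "fixed":
                thr = clash_distance
                counts = snap.tree.query_ball_point(
                    centres, thr, return_length=True)
                ok = counts == 0
            elif np.ptp(snap.radii) < 1e-12:
                # uniform solvent radii: hard-sphere contact is a single
                # distance threshold, fully vectorized
                thr = r_atom + float(snap.radii[0])
                counts = snap.tree.query_ball_point(
                    centres, thr, return_length=True)
                ok = counts == 0
            else:
                thr = r_atom + snap.max_radius
                ok = np.ones(nb, bool)
                hits = snap.tree.query_ball_point(centres, thr)
                for t, h in enumerate(hits):
                    for j in h:
                        d = np.linalg.norm(minimum_image(
                            snap.coords[j] - centres[t], snap.L))
                        if d < r_atom + snap.radii[j]:
                            ok[t] = False
                            break
            idx_ok = np.where(ok)[0]
        else:
            idx_ok = []
            for t in range(nb):
                atoms = _pose_atoms(template, centres[t],
                                    rots[t] if rots is not None else np.eye(3))
                if not snap.clashes(atoms, template.radii, clash_rule,
                                    clash_distance):
                    idx_ok.append(t)
            idx_ok = np.array(idx_ok, int)
        accepted += len(idx_ok)
        if scoring == "full":
            for t in idx_ok:
                R = rots[t] if rots is not None else np.eye(3)
                energies.append(_interaction_energy(
                    snap, template, centres[t], R, params))
        done += nb
    if scoring == "steric":
        energies = np.zeros(accepted)
    return InsertionResult(n_attempted=n_trials, n_accepted=accepted,
                           energies=np.asarray(energies, float), rt=rt)


def insertion_free_energy_smoothed(result: InsertionResult,
                                   n_gaussians: int = 3,
                                   bin_width: float = 0.25) -> float:
    """ΔG from a Gaussian-mixture smoothing of the energy distribution.

    The histogram of finite interaction energies is fitted with a sum of
    ``n_gaussians`` Gaussians; the Boltzmann average is then evaluated
    analytically per component, w_i exp(−μ_i/RT + σ_i²/(2 RT²)), scaled
    by the acceptance fraction.  Falls back to the raw-sample estimator
    (with a warning) if the fit fails or there are too few samples.
    """
    e = result.energies
    rt = result.rt
    if len(e) < 100:
        warnings.warn("too few finite samples for mixture smoothing; "
                      "using raw estimator")
        return result.dg_full
    if np.ptp(e) < bin_width:  # effectively a delta function
        mu = float(e.mean())
        total = result.acceptance * math.exp(-mu / rt)
        return -rt * math.log(total)
    from scipy.optimize import curve_fit

    edges = np.arange(e.min() - bin_width, e.max() + 2 * bin_width, bin_width)
    hist, edges = np.histogram(e, bins=edges, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])

    def mix(xx, *p):
        out = np.zeros_like(xx)
        for i in range(n_gaussians):
            w, mu, sig = p[3 * i: 3 * i + 3]
            out += (abs(w) / (abs(sig) * math.sqrt(2 * math.pi))
                    * np.exp(-0.5 * ((xx - mu) / sig) ** 2))
        return out

    # initialize components from sample quantile groups (weights, means
    # and widths of equal-probability slices of the distribution)
    cuts = np.quantile(e, np.linspace(0, 1, n_gaussians + 1))
    cuts[-1] += 1e-9
    p0 = []
    for i in range(n_gaussians):
        grp = e[(e >= cuts[i]) & (e < cuts[i + 1])]
        if len(grp) < 2:
            grp = e
        p0 += [len(grp) / len(e), float(grp.mean()),
               float(grp.std() + 1e-6)]
    try:
        popt, _ = curve_fit(mix, x, hist, p0=p0, maxfev=50000)
    except RuntimeError:
        warnings.warn("Gaussian-mixture fit did not converge; "
                      "using raw estimator")
        return result.dg_full
    weights = np.abs(popt[0::3])
    mus = popt[1::3]
    sigs = np.abs(popt[2::3])
    weights = weights / weights.sum()
    mean_boltz = float(np.sum(
        weights * np.exp(-mus / rt + sigs ** 2 / (2.0 * rt ** 2))))
    total = result.acceptance * mean_boltz
    if total <= 0:
        warnings.warn("non-positive smoothed Boltzmann average; "
                      "using raw estimator")
        return result.dg_full
    return -rt * math.log(total)


# --------------------------------------------------------------------------
# thermodynamic cycles
# --------------------------------------------------------------------------

def _dg_unfolded(snapshot: _Snapshot, target: FoldingTarget, scoring, seed,
                 clash_rule="fixed", clash_distance=4.5):
    """Pooled unfolded-state insertion free energy (equal trials per
    conformation)."""
    rt = kt(snapshot.state.params.temperature)
    total_boltz = 0.0
    total_trials = 0
    for k, tmpl in enumerate(target.unfolded):
        res = insert_species(snapshot, tmpl,
                             target.trials_per_unfolded_conformation,
                             scoring=scoring, seed=seed + 7919 * (k + 1),
                             clash_rule=clash_rule,
                             clash_distance=clash_distance)
        total_boltz += res.boltzmann_sum
        total_trials += res.n_attempted
    if total_boltz == 0.0:
        raise RuntimeError("no accepted unfolded-state trials "
                           "(undersampled)")
    return -rt * math.log(total_boltz / total_trials)


def folding_ddg(snapshots, target: FoldingTarget, scoring: str = "steric",
                seed: int = 0, clash_rule: str = "fixed",
                clash_distance: float = 4.5):
    """Crowding effect on a folding equilibrium, ΔΔG ± SD (kcal/mol).

    Per snapshot: ΔΔG = −(ΔG_insert(folded) − ΔG_insert(unfolded)),
    positive meaning the folded state is stabilized by the crowded
    environment.  The SD is taken across snapshots (0 for a single one).
    """
    if isinstance(snapshots, SystemState):
        snapshots = [snapshots]
    if len(snapshots) < 1:
        raise ValueError("need at least one snapshot")
    vals = []
    for s_i, snap_state in enumerate(snapshots):
        snap = _Snapshot(snap_state)
        res_f = insert_species(snap, target.folded, target.trials_folded,
                               scoring=scoring, seed=seed + 104729 * s_i,
                               clash_rule=clash_rule,
                               clash_distance=clash_distance)
        if res_f.n_accepted == 0:
            raise RuntimeError("no accepted folded-state trials "
                               "(undersampled)")
        dg_f = res_f.dg_full
        dg_u = _dg_unfolded(snap, target, scoring,
                            seed + 104729 * s_i + 1, clash_rule,
                            clash_distance)
        vals.append(-(dg_f - dg_u))
    vals = np.array(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


def _insert_components_simultaneously(snap: _Snapshot, components,
                                      n_trials, scoring, seed,
                                      clash_rule: str = "fixed",
                                      clash_distance: float = 4.5,
                                      max_resamples: int = 1_000_000):
    """Insert all components at independent random poses; placements with
    inter-component atom pairs closer than the hard-core distance are
    resampled and not counted."""
    rng = np.random.default_rng(seed)
    params = snap.state.params
    rt = kt(params.temperature)
    accepted = 0
    energies = []
    resamples = 0
    for _ in range(n_trials):
        while True:
            poses = []
            for comp in components:
                c = rng.uniform(0, snap.L, size=3)
                R = random_rotations(1, rng)[0]
                poses.append((c, R))
            clash_internal = False
            for a in range(len(components)):
                pa = _pose_atoms(components[a], *poses[a])
                for b in range(a + 1, len(components)):
                    pb = _pose_atoms(components[b], *poses[b])
                    dr = minimum_image(
                        pa[:, None, :] - pb[None, :, :], snap.L)
                    if np.any(np.linalg.norm(dr, axis=-1) < clash_distance):
                        clash_internal = True
                        break
                if clash_internal:
                    break
            if not clash_internal:
                break
            resamples += 1
            if resamples > max_resamples:
                raise RuntimeError("could not place components without "
                                   "inter-component clashes")
        clash = False
        e = 0.0
        for comp, (c, R) in zip(components, poses):
            atoms = _pose_atoms(comp, c, R)
            if snap.clashes(atoms, comp.radii, clash_rule, clash_distance):
                clash = True
                break
        if clash:
            continue
        if scoring == "full":
            for comp, (c, R) in zip(components, poses):
                e += _interaction_energy(snap, comp, c, R, params)
        accepted += 1
        energies.append(e)
    return InsertionResult(n_attempted=n_trials, n_accepted=accepted,
                           energies=np.array(energies), rt=rt)


def association_ddg(snapshots, target: AssociationTarget,
                    scoring: str = "steric", seed: int = 0,
                    clash_rule: str = "fixed",
                    clash_distance: float = 4.5):
    """Crowding effect on an association equilibrium, ΔΔG ± SD.

    ΔΔG = −(ΔG_insert(complex) − ΔG_insert(components simultaneously)),
    positive = the assembled form is stabilized by crowding.
    """
    if isinstance(snapshots, SystemState):
        snapshots = [snapshots]
    vals = []
    for s_i, snap_state in enumerate(snapshots):
        snap = _Snapshot(snap_state)
        res_c = insert_species(snap, target.complex, target.trials,
                               scoring=scoring, seed=seed + 104729 * s_i,
                               clash_rule=clash_rule,
                               clash_distance=clash_distance)
        res_s = _insert_components_simultaneously(
            snap, target.components, target.trials, scoring,
            seed + 104729 * s_i + 1, clash_rule, clash_distance)
        if res_c.boltzmann_sum == 0 or res_s.boltzmann_sum == 0:
            raise RuntimeError("undersampled association insertion")
        vals.append(-(res_c.dg_full - res_s.dg_full))
    vals = np.array(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


# --------------------------------------------------------------------------
# scaled particle theory
# --------------------------------------------------------------------------

def spt_insertion_free_energy(solute_radius: float, solvent_radius: float,
                              packing_fraction: float,
                              temperature: float | None = None) -> float:
    """SPT work (kcal/mol) of inserting a hard sphere into a hard-sphere
    fluid.

    For solute radius r, solvent radius a, packing fraction y and
    x = r/a:

        βW = −ln(1−y) + 3xy/(1−y) + x²[3y/(1−y) + 9y²/(2(1−y)²)]
             + x³ y (1+y+y²)/(1−y)³,

    exact in the point-solute limit, βW(x=0) = −ln(1−y).
    """
    y = packing_fraction
    if not (0.0 <= y < 1.0):
        raise ValueError("packing fraction must be in [0, 1)")
    if solute_radius < 0 or solvent_radius <= 0:
        raise ValueError("radii must be positive")
    rt = kt(temperature) if temperature else kt()
    x = solute_radius / solvent_radius
    omy = 1.0 - y
    beta_w = (-math.log(omy)
              + 3.0 * y * x / omy
              + (3.0 * y / omy + 4.5 * y ** 2 / omy ** 2) * x ** 2
              + y * (1.0 + y + y ** 2) / omy ** 3 * x ** 3)
    return rt * beta_w
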