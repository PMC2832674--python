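"""Rigid-body macromolecule templates, potential grids and effective charges.

A macromolecule type is represented once, in its own body frame, by a
:class:`RigidBodyTemplate`: atom positions/radii/charges, the subset of
solvent-exposed heavy atoms used for short-range interactions, a reduced
set of *effective charges* whose screened-Coulomb field reproduces the
molecule's electrostatic potential outside its surface, two cubic
potential grids (a fine short-range one and a coarse long-range one), and
the infinite-dilution translational and rotational diffusion coefficients
that parameterize its Brownian motion.

Electrostatic potential grids may either be imported from an external
Poisson-Boltzmann solver in OpenDX format, or generated internally from
the atomic charges with Debye-Hückel (screened-Coulomb) electrostatics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .constants import COULOMB, TEMPERATURE, debye_kappa

__all__ = [
    "AtomRecord",
    "PotentialGrid",
    "EffectiveChargeSet",
    "RigidBodyTemplate",
    "PQRParseError",
    "read_pqr",
    "write_pqr",
    "select_exposed_atoms",
    "stokes_einstein_coefficients",
    "generate_screened_coulomb_grid",
    "read_dx_grid",
    "write_dx_grid",
    "fit_effective_charges",
    "save_template",
    "load_template",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom of a rigid body, in the body frame.

    position in Å, radius in Å (> 0), charge in elementary charges.
    """

    name: str
    position: np.ndarray
    radius: float
    charge: float
    exposed: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (self.radius > 0):
            raise ValueError(f"atom {self.name}: radius must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        # PQR names put the element first (possibly after a digit, e.g. 1HB)
        stripped = self.name.lstrip("0123456789")
        return stripped[:1].upper() == "H"


@dataclass
class PotentialGrid:
    """Regular scalar grid of electrostatic potential, kcal/(mol·e).

    ``values[i, j, k]`` lives at ``origin + (i, j, k) * spacing`` in the
    body frame of the owning molecule.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    resolution_class: str = "fine"

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent(self) -> np.ndarray:
        """Edge lengths of the grid box, Å."""
        return (np.array(self.dims) - 1) * self.spacing

    @property
    def max_reach(self) -> float:
        """Largest distance from the body origin still inside the grid."""
        lo = self.origin
        hi = self.origin + self.extent
        corners = np.array([[x, y, z] for x in (lo[0], hi[0])
                            for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
        return float(np.max(np.linalg.norm(corners, axis=1)))

    def interpolate(self, points: np.ndarray,
                    gradient: bool = False):
        """Trilinear interpolation at body-frame ``points`` (n, 3).

        Points outside the grid get value 0 (and zero gradient).  Returns
        ``values`` or ``(values, gradients, inside_mask)``.  The gradient
        is the exact analytic gradient of the trilinear interpolant.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - self.origin) / self.spacing
        nd = np.array(self.dims)
        inside = np.all((local >= 0.0) & (local <= nd - 1), axis=1)
        vals = np.zeros(len(pts))
        grads = np.zeros((len(pts), 3)) if gradient else None
        if np.any(inside):
            loc = local[inside]
            i0 = np.clip(np.floor(loc).astype(int), 0, nd - 2)
            f = loc - i0
            ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
            c = self.values
            c000 = c[ix, iy, iz]
            c100 = c[ix + 1, iy, iz]
            c010 = c[ix, iy + 1, iz]
            c110 = c[ix + 1, iy + 1, iz]
            c001 = c[ix, iy, iz + 1]
            c101 = c[ix + 1, iy, iz + 1]
            c011 = c[ix, iy + 1, iz + 1]
            c111 = c[ix + 1, iy + 1, iz + 1]
            fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
            # interpolate along x, then y, then z
            c00 = c000 * (1 - fx) + c100 * fx
            c10 = c010 * (1 - fx) + c110 * fx
            c01 = c001 * (1 - fx) + c101 * fx
            c11 = c011 * (1 - fx) + c111 * fx
            c0 = c00 * (1 - fy) + c10 * fy
            c1 = c01 * (1 - fy) + c11 * fy
            vals[inside] = c0 * (1 - fz) + c1 * fz
            if gradient:
                dx00 = c100 - c000
                dx10 = c110 - c010
                dx01 = c101 - c001
                dx11 = c111 - c011
                dx0 = dx00 * (1 - fy) + dx10 * fy
                dx1 = dx01 * (1 - fy) + dx11 * fy
                gx = dx0 * (1 - fz) + dx1 * fz
                dy0 = c10 - c00
                dy1 = c11 - c01
                gy = dy0 * (1 - fz) + dy1 * fz
                gz = c1 - c0
                grads[inside, 0] = gx / self.spacing
                grads[inside, 1] = gy / self.spacing
                grads[inside, 2] = gz / self.spacing
        if gradient:
            return vals, grads, inside
        return vals


@dataclass
class EffectiveChargeSet:
    """Reduced point charges reproducing the molecule's far field."""

    positions: np.ndarray  # (n, 3) body frame, Å
    magnitudes: np.ndarray  # (n,) elementary charges
    residual: float = 0.0  # relative RMS misfit over the fit shell

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.magnitudes = np.atleast_1d(np.asarray(self.magnitudes, dtype=float))
        if len(self.positions) != len(self.magnitudes):
            raise ValueError("positions and magnitudes must have the same length")
        if not np.all(np.isfinite(self.magnitudes)):
            raise ValueError("effective charges must be finite")

    def __len__(self) -> int:
        return len(self.magnitudes)

    @property
    def total_charge(self) -> float:
        return float(self.magnitudes.sum())


@dataclass
class RigidBodyTemplate:
    """One macromolecule type: geometry, charges, grids, diffusion inputs.

    ``d0_trans`` (Å²/ps) and ``d0_rot`` (rad²/ps) are the isotropic
    infinite-dilution diffusion coefficients — *inputs* to the dynamics,
    typically from Stokes-Einstein on a hydrodynamic radius.
    """

    name: str
    atoms: list[AtomRecord]
    effective_charges: EffectiveChargeSet | None = None
    fine_grid: PotentialGrid | None = None
    coarse_grid: PotentialGrid | None = None
    d0_trans: float | None = None
    d0_rot: float | None = None
    hydrodynamic_radius: float | None = None
    mass: float | None = None  # kDa
    kind: str = "protein"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- cached array views ------------------------------------------------
    def _arrays(self):
        if "pos" not in self._cache:
            self._cache["pos"] = np.array([a.position for a in self.atoms])
            self._cache["rad"] = np.array([a.radius for a in self.atoms])
            self._cache["chg"] = np.array([a.charge for a in self.atoms])
            self._cache["exp"] = np.array([a.exposed for a in self.atoms], bool)
        return self._cache

    def invalidate_cache(self):
        self._cache.clear()

    @property
    def positions(self) -> np.ndarray:
        return self._arrays()["pos"]

    @property
    def radii(self) -> np.ndarray:
        return self._arrays()["rad"]

    @property
    def charges(self) -> np.ndarray:
        return self._arrays()["chg"]

    @property
    def exposed_mask(self) -> np.ndarray:
        return self._arrays()["exp"]

    @property
    def exposed_positions(self) -> np.ndarray:
        a = self._arrays()
        return a["pos"][a["exp"]]

    @property
    def exposed_radii(self) -> np.ndarray:
        a = self._arrays()
        return a["rad"][a["exp"]]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def radius_of_gyration(self) -> float:
        p = self.positions
        c = p.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((p - c) ** 2, axis=1))))

    @property
    def bounding_radius(self) -> float:
        """Distance from body origin to the outermost atom surface, Å."""
        p = self.positions
        return float(np.max(np.linalg.norm(p, axis=1) + self.radii))

    def validate(self, full: bool = True):
        """Check template invariants; raise ``ValueError`` on violation."""
        if self.n_atoms == 0:
            raise ValueError(f"{self.name}: template has no atoms")
        if not np.any(self.exposed_mask):
            raise ValueError(f"{self.name}: no exposed atoms")
        if full:
            if self.d0_trans is None or not self.d0_trans > 0:
                raise ValueError(f"{self.name}: d0_trans must be > 0")
            if self.d0_rot is None or not self.d0_rot > 0:
                raise ValueError(f"{self.name}: d0_rot must be > 0")
        return self


# --------------------------------------------------------------------------
# PQR I/O
# --------------------------------------------------------------------------

class PQRParseError(ValueError):
    pass


def read_pqr(path) -> RigidBodyTemplate:
    """Read a PQR structure file into a (partial) template.

    Accepts the whitespace-separated PQR dialect: every ``ATOM``/``HETATM``
    record carries x, y, z, charge, radius as its last five fields.
    Coordinates are recentred on the geometric centre of the atoms, which
    becomes the body-frame origin.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 8:
                raise PQRParseError(f"{path.name}:{lineno}: too few fields in record")
            try:
                x, y, z, q, r = (float(v) for v in rec[-5:])
            except ValueError as exc:
                raise PQRParseError(f"{path.name}:{lineno}: {exc}") from None
            name = rec[2] if len(rec) > 2 else "X"
            try:
                atoms.append(AtomRecord(name, (x, y, z), radius=r, charge=q))
            except ValueError as exc:
                raise PQRParseError(f"{path.name}:{lineno}: {exc}") from None
    if not atoms:
        raise PQRParseError(f"{path.name}: no ATOM/HETATM records found")
    centre = np.mean([a.position for a in atoms], axis=0)
    for a in atoms:
        a.position = a.position - centre
    return RigidBodyTemplate(name=path.stem, atoms=atoms)


def write_pqr(template: RigidBodyTemplate, path, resname: str = "MOL"):
    """Write a template's atoms as a whitespace-separated PQR file."""
    with open(path, "w") as fh:
        fh.write("REMARK generated by crowdbd\n")
        for i, a in enumerate(template.atoms, start=1):
            x, y, z = a.position
            fh.write(
                f"ATOM {i:6d} {a.name:<4s} {resname:<4s} {1:4d} "
                f"{x:10.3f} {y:10.3f} {z:10.3f} {a.charge:8.4f} {a.radius:7.4f}\n"
            )


# --------------------------------------------------------------------------
# solvent exposure
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit vectors (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def select_exposed_atoms(template: RigidBodyTemplate,
                         probe_radius: float = 4.0,
                         n_points: int = 960) -> RigidBodyTemplate:
    """Flag solvent-exposed heavy atoms by probe-inflated surface sampling.

    An atom is exposed iff at least one of ``n_points`` sample points on
    its probe-inflated sphere (radius + probe) lies outside every other
    atom's inflated sphere, i.e. its solvent-accessible surface area is
    nonzero at the sampling resolution.  Hydrogens are never flagged.
    Returns the same template with ``exposed`` flags updated in place.
    """
    if template.n_atoms == 0:
        raise ValueError("template has no atoms")
    pos = template.positions
    rad = template.radii + probe_radius
    heavy = np.array([not a.is_hydrogen for a in template.atoms])
    sphere = _fibonacci_sphere(n_points)
    for i, atom in enumerate(template.atoms):
        if not heavy[i]:
            atom.exposed = False
            continue
        pts = pos[i] + rad[i] * sphere
        # only neighbors whose inflated sphere can reach atom i's surface
        d = np.linalg.norm(pos - pos[i], axis=1)
        nb = (d < rad + rad[i]) & (np.arange(len(pos)) != i) & heavy
        if not np.any(nb):
            atom.exposed = True
            continue
        covered = np.zeros(n_points, dtype=bool)
        for j in np.where(nb)[0]:
            covered |= np.einsum("ij,ij->i", pts - pos[j], pts - pos[j]) < rad[j] ** 2
            if covered.all():
                break
        atom.exposed = not covered.all()
    template.invalidate_cache()
    return template


# --------------------------------------------------------------------------
# Stokes-Einstein diffusion coefficients
# --------------------------------------------------------------------------

def stokes_einstein_coefficients(hydrodynamic_radius: float,
                                 temperature: float = TEMPERATURE,
                                 viscosity: float = 0.89):
    """Infinite-dilution (d0_trans [Å²/ps], d0_rot [rad²/ps]) of a sphere.

    d0_trans = kT / (6 π η R), d0_rot = kT / (8 π η R³), for a sphere of
    hydrodynamic radius R (Å) in a solvent of viscosity η (cP) at T (K).
    """
    if hydrodynamic_radius <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("radius, temperature and viscosity must all be > 0")
    kb_si = 1.380649e-23  # J/K
    eta = viscosity * 1e-3  # Pa·s
    r = hydrodynamic_radius * 1e-10  # m
    d_trans = kb_si * temperature / (6.0 * math.pi * eta * r)  # m²/s
    d_rot = kb_si * temperature / (8.0 * math.pi * eta * r ** 3)  # 1/s
    return d_trans * 1e8, d_rot * 1e-12  # Å²/ps, rad²/ps


# --------------------------------------------------------------------------
# grids
# --------------------------------------------------------------------------

def _screened_coulomb_potential(nodes: np.ndarray, charge_pos: np.ndarray,
                                charges: np.ndarray, radii: np.ndarray,
                                kappa: float, solvent_dielectric: float
                                ) -> np.ndarray:
    """Debye-Hückel potential of point charges at ``nodes``, kcal/(mol·e).

    Distances are clamped below at each source atom's radius so that the
    potential stays finite on nodes that fall inside the molecule.
    """
    out = np.zeros(len(nodes))
    chunk = 200_000 // max(1, len(charge_pos))
    for start in range(0, len(nodes), max(1, chunk)):
        sl = slice(start, start + max(1, chunk))
        d = np.linalg.norm(nodes[sl, None, :] - charge_pos[None, :, :], axis=2)
        d = np.maximum(d, radii[None, :])
        out[sl] = np.sum(charges * COULOMB * np.exp(-kappa * d)
                         / (solvent_dielectric * d), axis=1)
    return out


def generate_screened_coulomb_grid(template: RigidBodyTemplate,
                                   spacing: float = 2.0,
                                   margin: float = 20.0,
                                   ionic_strength: float = 0.150,
                                   solvent_dielectric: float = 78.0,
                                   temperature: float = TEMPERATURE,
                                   resolution_class: str = "fine"
                                   ) -> PotentialGrid:
    """Build a potential grid from the atomic charges with DH screening.

    The grid box covers the atoms' bounding box inflated by ``margin`` Å
    per side (default 20 Å — a 20 Å shell beyond the molecular surface
    when the margin accounts for atom radii) and is centred on the body
    frame.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    pos = template.positions
    rad = template.radii
    lo = (pos - rad[:, None]).min(axis=0) - margin
    hi = (pos + rad[:, None]).max(axis=0) + margin
    centre = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo)
    n = np.maximum(2, np.ceil(2 * half / spacing).astype(int) + 1)
    origin = centre - (n - 1) * spacing / 2.0
    kappa = debye_kappa(ionic_strength, solvent_dielectric, temperature)
    ax = [origin[k] + spacing * np.arange(n[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    sel = np.abs(template.charges) > 1e-12
    if np.any(sel):
        vals = _screened_coulomb_potential(
            nodes, pos[sel], template.charges[sel], rad[sel],
            kappa, solvent_dielectric)
    else:
        vals = np.zeros(len(nodes))
    return PotentialGrid(origin=origin, spacing=spacing,
                         values=vals.reshape(tuple(n)),
                         resolution_class=resolution_class)


def make_template_grids(template: RigidBodyTemplate,
                        fine_spacing: float = 2.0,
                        coarse_spacing: float = 4.0,
                        shell: float = 20.0,
                        ionic_strength: float = 0.150,
                        solvent_dielectric: float = 78.0,
                        temperature: float = TEMPERATURE) -> RigidBodyTemplate:
    """Attach internally generated fine and coarse grids to a template.

    The fine grid covers a ``shell`` Å shell beyond the surface; the
    coarse grid extends at least 50% further per axis.
    """
    pos, rad = template.positions, template.radii
    ext = (pos + rad[:, None]).max(axis=0) - (pos - rad[:, None]).min(axis=0)
    template.fine_grid = generate_screened_coulomb_grid(
        template, fine_spacing, shell, ionic_strength, solvent_dielectric,
        temperature, "fine")
    coarse_margin = 1.5 * shell + 0.25 * float(ext.max())
    template.coarse_grid = generate_screened_coulomb_grid(
        template, coarse_spacing, coarse_margin, ionic_strength,
        solvent_dielectric, temperature, "coarse")
    return template


def read_dx_grid(path, resolution_class: str = "fine") -> PotentialGrid:
    """Read an OpenDX regular scalar grid."""
    from gridData import Grid
    try:
        g = Grid(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read OpenDX grid {path}: {exc}") from exc
    deltas = np.asarray(g.delta, dtype=float)
    if deltas.ndim == 2:
        deltas = np.diag(deltas)
    if not np.allclose(deltas, deltas[0]):
        raise ValueError("only grids with uniform spacing are supported")
    return PotentialGrid(origin=np.asarray(g.origin, dtype=float),
                         spacing=float(deltas[0]),
                         values=np.asarray(g.grid, dtype=float),
                         resolution_class=resolution_class)


def write_dx_grid(grid: PotentialGrid, path):
    """Write a grid in OpenDX format."""
    from gridData import Grid
    g = Grid(grid.values, origin=np.asarray(grid.origin),
             delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx")


# --------------------------------------------------------------------------
# effective charges
# --------------------------------------------------------------------------

def fit_effective_charges(template: RigidBodyTemplate,
                          grid: PotentialGrid,
                          shell_inner: float = 3.0,
                          shell_outer: float = 11.0,
                          n_sites: int | None = None,
                          ionic_strength: float = 0.150,
                          solvent_dielectric: float = 78.0,
                          temperature: float = TEMPERATURE,
                          seed: int = 0) -> EffectiveChargeSet:
    """Fit reduced charges whose screened-Coulomb field matches ``grid``.

    Grid nodes whose distance to the nearest atom *surface* falls in
    ``[shell_inner, shell_outer]`` are the fit points; charge sites are
    the charged-atom positions (or ``n_sites`` k-means centroids of them).
    A linear least-squares problem in the magnitudes minimizes the summed
    squared potential misfit over the shell; the relative RMS residual is
    stored on the returned set.
    """
    pos, rad = template.positions, template.radii
    charged = np.abs(template.charges) > 1e-12
    if not np.any(charged):
        return EffectiveChargeSet(positions=np.zeros((1, 3)),
                                  magnitudes=np.zeros(1), residual=0.0)
    sites = pos[charged]
    if n_sites is not None and n_sites < len(sites):
        from scipy.cluster.vq import kmeans2
        sites, _ = kmeans2(sites, n_sites, seed=seed, minit="++")
    # shell sample points from grid nodes
    n = np.array(grid.dims)
    ax = [grid.origin[k] + grid.spacing * np.arange(n[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    from scipy.spatial import cKDTree
    # distance to nearest atom surface, approximated via nearest centre
    tree = cKDTree(pos)
    k = min(8, len(pos))
    dists, idx = tree.query(nodes, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    surf = np.min(dists - rad[idx], axis=1)
    mask = (surf >= shell_inner) & (surf <= shell_outer)
    if not np.any(mask):
        raise ValueError("grid does not cover the requested fit shell")
    pts = nodes[mask]
    target = grid.values.ravel()[mask]
    kappa = debye_kappa(ionic_strength, solvent_dielectric, temperature)
    d = np.linalg.norm(pts[:, None, :] - sites[None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    design = COULOMB * np.exp(-kappa * d) / (solvent_dielectric * d)
    sol, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("singular effective-charge system; using regularized solve")
        lam = 1e-8 * np.trace(design.T @ design) / design.shape[1]
        sol = np.linalg.solve(design.T @ design + lam * np.eye(design.shape[1]),
                              design.T @ target)
    resid = design @ sol - target
    scale = float(np.sqrt(np.mean(target ** 2)))
    rel = float(np.sqrt(np.mean(resid ** 2)) / scale) if scale > 0 else 0.0
    return EffectiveChargeSet(positions=sites, magnitudes=sol, residual=rel)


# --------------------------------------------------------------------------
# template serialization (self-describing JSON archive)
# --------------------------------------------------------------------------

def _grid_to_dict(g: PotentialGrid | None):
    if g is None:
        return None
    return {"origin": g.origin.tolist(), "spacing": g.spacing,
            "dims": list(g.dims), "values": g.values.ravel().tolist(),
            "resolution_class": g.resolution_class}


def _grid_from_dict(d):
    if d is None:
        return None
    return PotentialGrid(origin=np.array(d["origin"]), spacing=d["spacing"],
                         values=np.array(d["values"]).reshape(d["dims"]),
                         resolution_class=d["resolution_class"])


def template_to_dict(t: RigidBodyTemplate) -> dict:
    return {
        "format": "crowdbd-template-v1",
        "name": t.name,
        "kind": t.kind,
        "mass": t.mass,
        "hydrodynamic_radius": t.hydrodynamic_radius,
        "d0_trans": t.d0_trans,
        "d0_rot": t.d0_rot,
        "atoms": [{"name": a.name, "position": a.position.tolist(),
                   "radius": a.radius, "charge": a.charge,
                   "exposed": bool(a.exposed)} for a in t.atoms],
        "effective_charges": None if t.effective_charges is None else {
            "positions": t.effective_charges.positions.tolist(),
            "magnitudes": t.effective_charges.magnitudes.tolist(),
            "residual": t.effective_charges.residual},
        "fine_grid": _grid_to_dict(t.fine_grid),
        "coarse_grid": _grid_to_dict(t.coarse_grid),
    }


def template_from_dict(d: dict) -> RigidBodyTemplate:
    ec = d.get("effective_charges")
    return RigidBodyTemplate(
        name=d["name"], kind=d.get("kind", "protein"), mass=d.get("mass"),
        hydrodynamic_radius=d.get("hydrodynamic_radius"),
        d0_trans=d.get("d0_trans"), d0_rot=d.get("d0_rot"),
        atoms=[AtomRecord(a["name"], np.array(a["position"]), a["radius"],
                          a["charge"], a["exposed"]) for a in d["atoms"]],
        effective_charges=None if ec is None else EffectiveChargeSet(
            positions=np.array(ec["positions"]),
            magnitudes=np.array(ec["magnitudes"]),
            residual=ec.get("residual", 0.0)),
        fine_grid=_grid_from_dict(d.get("fine_grid")),
        coarse_grid=_grid_from_dict(d.get("coarse_grid")),
    )


def save_template(t: RigidBodyTemplate, path):
    with open(path, "w") as fh:
        json.dump(template_to_dict(t), fh)


def load_template(path) -> RigidBodyTemplate:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "crowdbd-template-v1":
        raise ValueError(f"{path}: not a crowdbd template archive")
    return template_from_dict(d)
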