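"""Continuum electrostatics of ion insertion along a channel pore.

A finite-difference solver for the linearized Poisson-Boltzmann (LPB)
equation

    div( eps(r) grad(phi) ) - kbar^2(r) phi = -rho_f(r) / eps0

on a uniform cubic grid, with an implicit membrane modelled as a
low-dielectric slab, protein atoms carving a low-dielectric,
ion-excluded cavity, and Dirichlet boundary values from the
Debye-screened Coulomb potential of the fixed charges.  The potential
is solved in thermal units u = e*phi/kT; electrostatic energies are
(1/2) * sum_i q_i u(r_i) in kT.

Ion-insertion energies use a three-state thermodynamic cycle evaluated
on the identical grid so that the (grid-dependent) self-energy of the
probe charge cancels:

    dG(z) = E[protein + probe at z] - E[protein] - E[probe in bulk water]

with the bulk reference placed at the same grid-fractional position in
a uniform-water system.  The probe ion is a point charge whose Born
radius carves its own dielectric cavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .constants import E_CHARGE, EPS0, K_BOLTZMANN, N_AVOGADRO

__all__ = [
    "PQRAtom",
    "GridSpec",
    "ProbeIon",
    "EnergyProfile",
    "read_pqr",
    "write_pqr",
    "build_dielectric_map",
    "solve_lpb",
    "grid_energy",
    "insertion_energy",
    "InsertionEnergy",
    "pore_profile",
    "write_dx",
    "SolverError",
]


class SolverError(RuntimeError):
    """LPB iteration failed to reach tolerance; carries residual info."""


@dataclass(frozen=True)
class PQRAtom:
    """An atom with partial charge (e) and radius (ångström)."""

    xyz: tuple[float, float, float]
    charge: float
    radius: float
    name: str = "X"
    residue_name: str = "UNK"
    residue_number: int = 1
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not all(math.isfinite(c) for c in self.xyz) or not math.isfinite(self.charge):
            raise ValueError("coordinates and charge must be finite")


@dataclass(frozen=True)
class GridSpec:
    """Grid, slab and medium parameters for the LPB calculation.

    Defaults follow the standard implicit-membrane protocol for a
    channel embedded in a 40 Å hydrophobic slab: 300 Å box, 97 grid
    points per axis, slab from z = -25 to +15 Å, dielectrics 2/2/80 for
    protein/membrane/water, 100 mM symmetric monovalent mobile ions of
    radius 2.0 Å, water probe radius 1.4 Å.
    """

    box_edge: float = 300.0
    points_per_axis: int = 97
    slab_z: tuple[float, float] | None = (-25.0, 15.0)
    slab_exclusion_radius: float | None = None  # water channel through the slab
    eps_protein: float = 2.0
    eps_membrane: float = 2.0
    eps_water: float = 80.0
    ionic_strength: float = 0.1  # molar
    mobile_ion_charge: int = 1
    mobile_ion_radius: float = 2.0
    probe_radius: float = 1.4  # water probe, inflates atom cavities
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.points_per_axis < 9 or self.points_per_axis % 2 == 0:
            raise ValueError("points_per_axis must be >= 9 and odd")
        if self.slab_z is not None and self.slab_z[0] >= self.slab_z[1]:
            raise ValueError("slab lower bound must be below upper bound")
        if min(self.eps_protein, self.eps_membrane, self.eps_water) <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def h(self) -> float:
        """Grid spacing, ångström."""
        return self.box_edge / (self.points_per_axis - 1)

    @property
    def axis(self) -> np.ndarray:
        """Node coordinates along one axis (box centred on the origin)."""
        n = self.points_per_axis
        return -0.5 * self.box_edge + self.h * np.arange(n)

    @property
    def coulomb_scale(self) -> float:
        """e^2/(eps0 kT) in ångström (vacuum Bjerrum length times 4*pi)."""
        return (E_CHARGE**2 / (EPS0 * K_BOLTZMANN * self.temperature)) * 1e10

    @property
    def kappa2_water(self) -> float:
        """Debye screening kappa^2 in water, ångström^-2."""
        if self.ionic_strength == 0:
            return 0.0
        kappa2_si = (2000.0 * N_AVOGADRO * E_CHARGE**2 * self.ionic_strength
                     / (EPS0 * self.eps_water * K_BOLTZMANN * self.temperature))
        return kappa2_si * 1e-20


@dataclass(frozen=True)
class ProbeIon:
    """Point-charge probe with a Born-radius dielectric cavity."""

    name: str
    charge: int
    born_radius: float  # ångström

    def __post_init__(self) -> None:
        if self.charge not in (1, 2):
            raise ValueError("probe charge must be +1 or +2")
        if self.born_radius <= 0:
            raise ValueError("Born radius must be positive")


@dataclass
class EnergyProfile:
    """z-resolved ion-insertion energies, one series per probe."""

    z_positions: np.ndarray  # ångström
    energies: dict[str, np.ndarray]  # probe name -> kT
    units: str = "kT"
    temperature: float = 298.15

    def to_frame(self):
        import pandas as pd

        rows = []
        for probe, e in self.energies.items():
            for z, val in zip(self.z_positions, e):
                rows.append({"z": z, "probe": probe, "energy": val})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# PQR I/O (whitespace dialect)
# --------------------------------------------------------------------------

def read_pqr(path: str | Path) -> list[PQRAtom]:
    """Read a whitespace-delimited PQR file.

    Accepts both the chain-bearing and chain-less dialects: the last two
    fields of an ATOM/HETATM record are charge and radius, the three
    fields before them are x, y, z.
    """
    atoms: list[PQRAtom] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            x, y, z, q, r = (float(v) for v in tok[-5:])
            name = tok[2] if len(tok) > 2 else "X"
            resname = tok[3] if len(tok) > 3 else "UNK"
            has_chain = len(tok) >= 11
            chain = tok[4] if has_chain else "A"
            try:
                resnum = int(tok[5] if has_chain else tok[4])
            except (ValueError, IndexError):
                resnum = 1
            atoms.append(PQRAtom(xyz=(x, y, z), charge=q, radius=r, name=name,
                                 residue_name=resname, residue_number=resnum,
                                 chain=chain))
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return atoms


def write_pqr(atoms: Sequence[PQRAtom], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            fh.write(
                f"ATOM  {i:5d} {a.name:<4s} {a.residue_name:<4s}{a.chain:1s} "
                f"{a.residue_number:4d}    "
                f"{a.xyz[0]:10.4f} {a.xyz[1]:10.4f} {a.xyz[2]:10.4f} "
                f"{a.charge:8.4f} {a.radius:7.4f}\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# Volume construction
# --------------------------------------------------------------------------

def _mark_spheres(mask: np.ndarray, axis: np.ndarray, centers: np.ndarray,
                  radii: np.ndarray) -> None:
    """Set mask True inside each sphere (in place, per-atom local boxes)."""
    h = axis[1] - axis[0]
    lo = axis[0]
    n = axis.size
    for c, r in zip(centers, radii):
        if r <= 0:
            continue
        i0 = np.maximum(np.floor((c - r - lo) / h).astype(int), 0)
        i1 = np.minimum(np.ceil((c + r - lo) / h).astype(int) + 1, n)
        if np.any(i0 >= i1):
            continue
        ax = axis[i0[0]:i1[0]][:, None, None] - c[0]
        ay = axis[i0[1]:i1[1]][None, :, None] - c[1]
        az = axis[i0[2]:i1[2]][None, None, :] - c[2]
        local = ax**2 + ay**2 + az**2 <= r * r
        mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= local


def build_dielectric_map(
    atoms: Sequence[PQRAtom],
    grid: GridSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the dielectric, screening and hard-core volumes.

    Returns ``(eps, kappa2, core)``:

    - ``eps``: relative dielectric per node -- eps_protein inside any
      atom inflated by the water probe radius; eps_membrane in the slab
      outside the protein; eps_water elsewhere.
    - ``kappa2``: modified screening coefficient (eps_water * kappa_D^2,
      Å^-2), zero inside atoms inflated by the mobile-ion radius and
      inside the slab.
    - ``core``: boolean mask of nodes inside a bare (uninflated) atom
      radius, used to flag probe positions inside a hard core.
    """
    n = grid.points_per_axis
    axis = grid.axis
    eps = np.full((n, n, n), grid.eps_water)
    kappa2 = np.full((n, n, n), grid.eps_water * grid.kappa2_water)
    core = np.zeros((n, n, n), dtype=bool)

    if grid.slab_z is not None:
        zlo, zhi = grid.slab_z
        slab = (axis >= zlo) & (axis <= zhi)
        if grid.slab_exclusion_radius is None:
            eps[:, :, slab] = grid.eps_membrane
            kappa2[:, :, slab] = 0.0
        else:
            # aqueous channel through the slab around the pore (z) axis
            rho2 = axis[:, None] ** 2 + axis[None, :] ** 2
            outside = rho2 > grid.slab_exclusion_radius**2
            region = outside[:, :, None] & slab[None, None, :]
            eps[region] = grid.eps_membrane
            kappa2[:, :, slab] = 0.0  # no mobile ions inside the membrane span

    if atoms:
        centers = np.array([a.xyz for a in atoms], dtype=float)
        radii = np.array([a.radius for a in atoms], dtype=float)
        half = grid.box_edge / 2
        if np.any(np.abs(centers) > half):
            raise ValueError("atoms lie outside the grid box")
        prot = np.zeros((n, n, n), dtype=bool)
        _mark_spheres(prot, axis, centers, radii + grid.probe_radius)
        eps[prot] = grid.eps_protein
        excl = np.zeros((n, n, n), dtype=bool)
        _mark_spheres(excl, axis, centers, radii + grid.mobile_ion_radius)
        kappa2[excl] = 0.0
        _mark_spheres(core, axis, centers, radii)
    return eps, kappa2, core


# --------------------------------------------------------------------------
# Charge spreading / interpolation
# --------------------------------------------------------------------------

def _trilinear_weights(grid: GridSpec, xyz: np.ndarray):
    """Cell index and 8 trilinear (index, weight) pairs for a point."""
    h = grid.h
    lo = -0.5 * grid.box_edge
    f = (np.asarray(xyz, dtype=float) - lo) / h
    i0 = np.floor(f).astype(int)
    i0 = np.clip(i0, 0, grid.points_per_axis - 2)
    d = f - i0
    out = []
    for dx in (0, 1):
        wx = d[0] if dx else 1 - d[0]
        for dy in (0, 1):
            wy = d[1] if dy else 1 - d[1]
            for dz in (0, 1):
                wz = d[2] if dz else 1 - d[2]
                out.append(((i0[0] + dx, i0[1] + dy, i0[2] + dz), wx * wy * wz))
    return out


def _spread_charges(grid: GridSpec,
                    charges: Sequence[tuple[np.ndarray, float]]) -> np.ndarray:
    n = grid.points_per_axis
    q = np.zeros((n, n, n))
    for xyz, qval in charges:
        if qval == 0:
            continue
        for (i, j, k), w in _trilinear_weights(grid, np.asarray(xyz)):
            q[i, j, k] += qval * w
    return q


def _interpolate(volume: np.ndarray, grid: GridSpec, xyz) -> float:
    return float(sum(w * volume[i, j, k]
                     for (i, j, k), w in _trilinear_weights(grid, np.asarray(xyz))))


# --------------------------------------------------------------------------
# LPB solve
# --------------------------------------------------------------------------

def _boundary_potential(grid: GridSpec,
                        charges: Sequence[tuple[np.ndarray, float]]) -> np.ndarray:
    """Dirichlet values: Debye-screened Coulomb in bulk water (thermal units)."""
    n = grid.points_per_axis
    axis = grid.axis
    u = np.zeros((n, n, n))
    kd = math.sqrt(grid.kappa2_water)
    pref = grid.coulomb_scale / (4.0 * math.pi * grid.eps_water)
    faces = []  # (index expression, meshgrid coords)
    X, Y = np.meshgrid(axis, axis, indexing="ij")
    for fixed_axis in range(3):
        for side in (0, n - 1):
            coords = np.empty((n, n, 3))
            other = [a for a in range(3) if a != fixed_axis]
            coords[..., fixed_axis] = axis[side]
            coords[..., other[0]] = X
            coords[..., other[1]] = Y
            faces.append((fixed_axis, side, coords))
    for xyz, q in charges:
        if q == 0:
            continue
        p = np.asarray(xyz, dtype=float)
        for fixed_axis, side, coords in faces:
            r = np.linalg.norm(coords - p, axis=-1)
            r = np.maximum(r, 1e-6)
            vals = pref * q * np.exp(-kd * r) / r
            idx = [slice(None)] * 3
            idx[fixed_axis] = side
            u[tuple(idx)] += vals
    return u


def solve_lpb(
    eps: np.ndarray,
    kappa2: np.ndarray,
    charges: Sequence[tuple[np.ndarray, float]],
    grid: GridSpec,
    tolerance: float = 1e-6,
    max_iter: int = 20000,
) -> np.ndarray:
    """Solve the LPB equation; returns the potential u in kT/e units.

    Finite-difference 7-point discretisation with harmonic-mean face
    dielectrics, trilinear charge spreading and Dirichlet boundary values
    from the screened-Coulomb bulk solution.  The symmetric
    positive-definite system is solved by preconditioned conjugate
    gradients to a relative residual of ``tolerance``; non-convergence
    raises :class:`SolverError`.
    """
    n = grid.points_per_axis
    if eps.shape != (n, n, n) or kappa2.shape != (n, n, n):
        raise ValueError("volume shapes do not match the grid")
    h = grid.h
    m = n - 2  # interior nodes per axis

    # harmonic-mean face dielectrics
    fx = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    fy = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    fz = 2.0 * eps[..., :-1] * eps[..., 1:] / (eps[..., :-1] + eps[..., 1:])

    sl = slice(1, n - 1)
    eW, eE = fx[0:m, sl, sl], fx[1:m + 1, sl, sl]
    eS, eN = fy[sl, 0:m, sl], fy[sl, 1:m + 1, sl]
    eD, eU = fz[sl, sl, 0:m], fz[sl, sl, 1:m + 1]

    diag = (eW + eE + eS + eN + eD + eU + h * h * kappa2[sl, sl, sl]).ravel()

    idx = np.arange(m**3).reshape(m, m, m)
    rows, cols, vals = [], [], []
    # +x neighbour
    rows.append(idx[:-1].ravel()); cols.append(idx[1:].ravel())
    vals.append(-eE[:-1].ravel())
    # +y neighbour
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel())
    vals.append(-eN[:, :-1].ravel())
    # +z neighbour
    rows.append(idx[..., :-1].ravel()); cols.append(idx[..., 1:].ravel())
    vals.append(-eU[..., :-1].ravel())
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    upper = sparse.coo_matrix((vals, (rows, cols)), shape=(m**3, m**3))
    A = (upper + upper.T + sparse.diags(diag)).tocsr()

    qvol = _spread_charges(grid, charges)
    ub = _boundary_potential(grid, charges)
    b = (grid.coulomb_scale / h) * qvol[sl, sl, sl]
    # boundary couplings move to the right-hand side
    b[0] += eW[0] * ub[0, sl, sl]
    b[-1] += eE[-1] * ub[n - 1, sl, sl]
    b[:, 0] += eS[:, 0] * ub[sl, 0, sl]
    b[:, -1] += eN[:, -1] * ub[sl, n - 1, sl]
    b[..., 0] += eD[..., 0] * ub[sl, sl, 0]
    b[..., -1] += eU[..., -1] * ub[sl, sl, n - 1]
    b = b.ravel()

    precond = sparse.diags(1.0 / diag)
    x, info = cg(A, b, rtol=tolerance, atol=0.0, maxiter=max_iter, M=precond)
    if info != 0:
        res = float(np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1e-300))
        raise SolverError(
            f"CG did not converge (info={info}); relative residual {res:.2e}")
    u = ub.copy()
    u[sl, sl, sl] = x.reshape(m, m, m)
    return u


def grid_energy(u: np.ndarray, grid: GridSpec,
                charges: Sequence[tuple[np.ndarray, float]]) -> float:
    """Electrostatic energy (kT) of the fixed charges in potential u."""
    return 0.5 * sum(q * _interpolate(u, grid, xyz) for xyz, q in charges if q)


# --------------------------------------------------------------------------
# Insertion energies and pore profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertionEnergy:
    energy_kT: float
    inside_core: bool  # probe centre within a bare atom radius

    def __float__(self) -> float:
        return self.energy_kT


def _system_energy(atoms: Sequence[PQRAtom], grid: GridSpec,
                   tolerance: float) -> float:
    eps, kappa2, _ = build_dielectric_map(atoms, grid)
    charges = [(np.asarray(a.xyz), a.charge) for a in atoms]
    u = solve_lpb(eps, kappa2, charges, grid, tolerance=tolerance)
    return grid_energy(u, grid, charges)


def insertion_energy(
    atoms: Sequence[PQRAtom],
    grid: GridSpec,
    probe: ProbeIon,
    position: Sequence[float],
    tolerance: float = 1e-8,
    _protein_energy: float | None = None,
    _bulk_cache: dict | None = None,
) -> InsertionEnergy:
    """Ion-insertion energy dG at ``position`` (kT), three-state cycle.

    All three states are computed on the identical grid; the bulk
    reference places the probe at the same fractional grid offset in a
    uniform-water system so that the probe's grid self-energy cancels
    exactly.  A probe inside a bare atom radius is flagged (the energy
    is still returned).
    """
    pos = np.asarray(position, dtype=float)
    if np.any(np.abs(pos) > grid.box_edge / 2):
        raise ValueError("probe position outside the grid box")
    if probe.charge == 0:
        return InsertionEnergy(0.0, False)

    probe_atom = PQRAtom(xyz=tuple(pos), charge=float(probe.charge),
                         radius=probe.born_radius, name=probe.name)
    _, _, core = build_dielectric_map(list(atoms), grid)
    inside = bool(_interpolate(core.astype(float), grid, pos) > 0.5)

    e_complex = _system_energy(list(atoms) + [probe_atom], grid, tolerance)
    e_protein = (_protein_energy if _protein_energy is not None
                 else _system_energy(list(atoms), grid, tolerance))

    bulk_grid = GridSpec(
        box_edge=grid.box_edge, points_per_axis=grid.points_per_axis,
        slab_z=None, eps_protein=grid.eps_protein,
        eps_membrane=grid.eps_membrane, eps_water=grid.eps_water,
        ionic_strength=grid.ionic_strength,
        mobile_ion_charge=grid.mobile_ion_charge,
        mobile_ion_radius=grid.mobile_ion_radius,
        probe_radius=grid.probe_radius, temperature=grid.temperature)
    frac = tuple(np.round((pos + grid.box_edge / 2) / grid.h % 1.0, 9))
    key = (probe.name, probe.charge, probe.born_radius, frac)
    if _bulk_cache is not None and key in _bulk_cache:
        e_bulk = _bulk_cache[key]
    else:
        e_bulk = _system_energy([probe_atom], bulk_grid, tolerance)
        if _bulk_cache is not None:
            _bulk_cache[key] = e_bulk
    return InsertionEnergy(float(e_complex - e_protein - e_bulk), inside)


def pore_profile(
    atoms: Sequence[PQRAtom],
    grid: GridSpec,
    probes: Sequence[ProbeIon],
    z_range: tuple[float, float],
    spacing: float = 3.0,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    tolerance: float = 1e-8,
) -> EnergyProfile:
    """Insertion-energy profile along the pore (z) axis, 3 Å default steps.

    The pore must already be oriented with its symmetry axis on z;
    ``axis_xy`` shifts the sampling line off-centre if needed.  The
    protein-only solve is shared across positions and probes, and bulk
    references are cached per grid offset.
    """
    z = np.arange(z_range[0], z_range[1] + 0.5 * spacing, spacing)
    e_protein = _system_energy(list(atoms), grid, tolerance) if list(atoms) else 0.0
    cache: dict = {}
    energies = {}
    for probe in probes:
        vals = np.empty(z.size)
        for i, zi in enumerate(z):
            res = insertion_energy(atoms, grid, probe,
                                   (axis_xy[0], axis_xy[1], zi),
                                   tolerance=tolerance,
                                   _protein_energy=e_protein,
                                   _bulk_cache=cache)
            vals[i] = res.energy_kT
        energies[probe.name] = vals
    return EnergyProfile(z_positions=z, energies=energies,
                         temperature=grid.temperature)


# --------------------------------------------------------------------------
# OpenDX output
# --------------------------------------------------------------------------

def write_dx(volume: np.ndarray, grid: GridSpec, path: str | Path,
             comment: str = "scalar grid") -> None:
    """Dump a scalar grid in OpenDX format (APBS-style ordering)."""
    n = grid.points_per_axis
    lo = -0.5 * grid.box_edge
    h = grid.h
    flat = volume.ravel()  # x fastest-varying last, matching DX z-major? use C order
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {lo:.6e} {lo:.6e} {lo:.6e}\n")
        fh.write(f"delta {h:.6e} 0.0 0.0\n")
        fh.write(f"delta 0.0 {h:.6e} 0.0\n")
        fh.write(f"delta 0.0 0.0 {h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(f"object 3 class array type double rank 0 items {flat.size} "
                 "data follows\n")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
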