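"""Synthetic patch-clamp families and toy pore structures.

The generators provide the statistical structure the analysis modules
assume, so the whole pipeline is testable without recordings or
deposited coordinates:

- voltage-clamp I-V families with a Boltzmann activation gate, a
  reversal potential derived from the GHK voltage equation (divalent
  conditions invert the Lewis-type relation), additive ohmic leak,
  linear rundown in time and Gaussian noise on peak currents;
- exactly n-fold-symmetric toy pores -- rings of partial charges around
  the z axis with axial ion sites and intervening waters -- emitted as
  matched PDB and PQR fixtures.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .constants import VALENCE
from .electrostatics import PQRAtom, write_pqr
from .iv_analysis import IVDataset
from .permeability import (
    Environment,
    ghk_reversal_potential,
    invert_divalent_ratio,
    species_from_saline,
)
from .structure import AtomRecord, StructureModel, write_pdb

__all__ = [
    "SyntheticRecipe",
    "SyntheticCondition",
    "SyntheticIV",
    "generate_iv_family",
    "ToyPoreSpec",
    "generate_toy_pore",
    "generate_block_timecourse",
]


# --------------------------------------------------------------------------
# Patch-clamp families
# --------------------------------------------------------------------------

def _default_conditions() -> dict[str, dict]:
    # 150 mM test-cation chloride outside; 30 mM Na + 90 mM NMDG inside
    ext = lambda ion, mM=150.0: {ion: mM}
    internal = {"Na": 30.0, "NMDG": 90.0}
    return {ion: {"external": ext(ion), "internal": dict(internal)}
            for ion in ("Na", "K", "Li")}


@dataclass
class SyntheticRecipe:
    """Full generative specification for fake patch-clamp data.

    ``conditions`` maps a condition label to its saline composition,
    ``{"external": {ion: mM}, "internal": {ion: mM}}``.  True
    permeability ratios P_x/P_Na drive the reversal potential of each
    condition through the GHK voltage equation (monovalent test ions)
    or the inverted Lewis-type relation (divalent test ions).
    """

    conditions: dict = field(default_factory=_default_conditions)
    permeabilities: dict = field(default_factory=lambda: {"Na": 1.0, "K": 0.4,
                                                          "Li": 0.7})
    v_half: float = -100.0  # mV
    slope_k: float = -8.0  # mV (negative: gate opens with depolarisation)
    g_max: float = 2.0  # pA/mV
    leak_conductance: float = 0.5  # pA/mV
    rundown_rate: float = 0.03  # fraction/min of the peak inward current
    noise_sigma: float = 5.0  # pA
    voltages: np.ndarray = field(
        default_factory=lambda: np.arange(-180.0, 61.0, 10.0))
    sweep_interval_s: float = 2.0
    t_start_s: float = 30.0
    temperature: float = 295.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        self.voltages = np.asarray(self.voltages, dtype=float)


@dataclass
class SyntheticIV:
    """One generated condition with its ground truth attached."""

    dataset: IVDataset  # raw: gated + leak + rundown + noise
    sub_currents: np.ndarray  # (n, 4) P/4 sub-sweep responses
    true_erev: float  # mV
    gated_truth: np.ndarray  # noise-free gated component, pA


def _side_ionic_strength(side: Mapping[str, float]) -> float:
    # each cation with its chloride counter-ion: I contribution c*z(z+1)/2
    return sum((mM / 1000.0) * VALENCE.get(ion, 1) * (VALENCE.get(ion, 1) + 1) / 2
               for ion, mM in side.items())


def _condition_erev(cond: Mapping, permeabilities: Mapping[str, float],
                    env: Environment) -> float:
    ext, internal = cond["external"], cond["internal"]
    i_ext = _side_ionic_strength(ext)
    i_int = _side_ionic_strength(internal)
    act = lambda side, istr: {
        ion: species_from_saline(ion, mM / 1000.0, ionic_strength=istr,
                                 env=env).alpha
        for ion, mM in side.items()}
    a_ext, a_int = act(ext, i_ext), act(internal, i_int)
    divalent_ext = [ion for ion in ext
                    if VALENCE.get(ion, 1) == 2 and permeabilities.get(ion, 0) > 0]
    if divalent_ext:
        ion = divalent_ext[0]
        return invert_divalent_ratio(permeabilities[ion], a_int["Na"],
                                     a_ext[ion], env=env)
    return ghk_reversal_potential(permeabilities, a_ext, a_int, env=env)


def generate_iv_family(recipe: SyntheticRecipe) -> dict[str, SyntheticIV]:
    """Generate one peak-current I-V family per condition.

    I(V, t) = rundown(t) * g_max (V - E_rev) / (1 + exp[(V - V_1/2)/k])
              + g_leak V + noise

    Rundown multiplies the gated (channel) component by the linear
    factor 1 - rundown_rate * t/60 -- conductance is lost over time, so
    the peak current decays linearly while the reversal potential is
    untouched, as in recordings.  P/4 sub-sweeps are delivered from a
    hyperpolarised holding where the gate stays shut, so they carry
    only the linear leak (plus noise).
    """
    if not recipe.conditions:
        raise ValueError("recipe declares no conditions")
    for label, cond in recipe.conditions.items():
        if not cond.get("external") or not cond.get("internal"):
            raise ValueError(f"condition {label!r} has an empty composition")
    env = Environment(temperature=recipe.temperature)
    rng = np.random.default_rng(recipe.seed)
    v = recipe.voltages
    out: dict[str, SyntheticIV] = {}
    for label, cond in recipe.conditions.items():
        erev = _condition_erev(cond, recipe.permeabilities, env)
        gate = 1.0 / (1.0 + np.exp(np.clip((v - recipe.v_half) / recipe.slope_k,
                                           -500, 500)))
        gated = recipe.g_max * (v - erev) * gate
        leak = recipe.leak_conductance * v
        t = recipe.t_start_s + recipe.sweep_interval_s * np.arange(v.size)
        rundown = 1.0 - recipe.rundown_rate * t / 60.0
        noise = rng.normal(0.0, recipe.noise_sigma, size=v.size)
        currents = rundown * gated + leak + noise
        sub = np.empty((v.size, 4))
        for j in range(4):
            sub[:, j] = (recipe.leak_conductance * v / 4.0
                         + rng.normal(0.0, recipe.noise_sigma / 4.0, size=v.size))
        out[label] = SyntheticIV(
            dataset=IVDataset(condition=label, voltages=v.copy(),
                              currents=currents, times=t),
            sub_currents=sub, true_erev=float(erev), gated_truth=gated)
    return out


# --------------------------------------------------------------------------
# Toy pore structures
# --------------------------------------------------------------------------

@dataclass
class ToyPoreSpec:
    """An exactly n-fold-symmetric toy selectivity filter.

    ``ring_charges`` lists (partial charge e, z position Å) rings of
    ``n_fold`` oxygen-like atoms at ``ring_radius`` from the z axis;
    ``ion_positions`` are axial z positions of sodium ions and
    ``water_positions`` axial z positions (or xyz triples) of waters.
    """

    ring_radius: float = 4.0
    ring_charges: Sequence[tuple[float, float]] = ((-0.76, 8.0),)
    n_fold: int = 4
    ion_positions: Sequence[float] = (10.0, 7.2, 1.6)
    water_positions: Sequence = ()
    atom_radius: float = 1.5  # carved dielectric radius of ring atoms, Å
    phase_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fold < 3:
            raise ValueError("n_fold symmetry must be >= 3")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")


def generate_toy_pore(
    spec: ToyPoreSpec,
    pdb_path: str | Path | None = None,
    pqr_path: str | Path | None = None,
) -> tuple[StructureModel, list[PQRAtom]]:
    """Build the toy pore; optionally write matched PDB and PQR files.

    Ring atoms are assigned to chains A, B, ... (one chain per symmetry
    position) so the structure is exactly ``n_fold``-symmetric about z.
    The PQR carries the ring atoms only (fixed charges for the
    electrostaics of the empty pore); ions and waters appear in the PDB.
    Atoms closer than 0.5 Å raise an error.
    """
    chains = [chr(ord("A") + i) for i in range(spec.n_fold)]
    atoms: list[AtomRecord] = []
    pqr: list[PQRAtom] = []
    serial = 0
    for ring_idx, (charge, z) in enumerate(spec.ring_charges):
        resnum = 178 + ring_idx
        for i, chain in enumerate(chains):
            theta = math.radians(spec.phase_offset_deg) + 2.0 * math.pi * i / spec.n_fold
            x = spec.ring_radius * math.cos(theta)
            y = spec.ring_radius * math.sin(theta)
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name="OE1", element="O", residue_name="GLU",
                residue_number=resnum, chain=chain, xyz=np.array([x, y, z]),
                occupancy=1.0, b_factor=20.0))
            pqr.append(PQRAtom(xyz=(x, y, z), charge=charge,
                               radius=spec.atom_radius, name="OE1",
                               residue_name="GLU", residue_number=resnum,
                               chain=chain))
    for i, z in enumerate(spec.ion_positions):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="NA", element="NA", residue_name="NA",
            residue_number=500 + i, chain="S", xyz=np.array([0.0, 0.0, float(z)]),
            occupancy=1.0, b_factor=25.0, is_hetero=True))
    for i, w in enumerate(spec.water_positions):
        xyz = (np.array([0.0, 0.0, float(w)]) if np.isscalar(w)
               else np.asarray(w, dtype=float))
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="O", element="O", residue_name="HOH",
            residue_number=600 + i, chain="W", xyz=xyz,
            occupancy=1.0, b_factor=30.0, is_hetero=True))

    xyz = np.vstack([a.xyz for a in atoms])
    if len(atoms) > 1:
        d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.5:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"overlapping atoms {atoms[i].serial} and {atoms[j].serial} "
                f"({d.min():.2f} Å apart)")

    model = StructureModel(
        atoms=atoms, name="toy_pore",
        tetramer_groups={"ALL": {a.chain for a in atoms}})
    if pdb_path is not None:
        write_pdb(model, pdb_path)
    if pqr_path is not None:
        write_pqr(pqr, pqr_path)
    return model, pqr


# --------------------------------------------------------------------------
# Block timecourses
# --------------------------------------------------------------------------

def generate_block_timecourse(
    rundown_rate: float = 0.03,  # fraction/min
    block_fraction: float = 0.5,
    t_apply: float = 120.0,  # s
    seed: int = 0,
    i0: float = -200.0,  # pA
    duration: float = 240.0,  # s
    dt: float = 5.0,  # s
    noise_sigma: float = 0.0,  # pA
) -> tuple[np.ndarray, np.ndarray]:
    """Sodium-current timecourse with linear rundown and a block step.

    I(t) = i0 (1 - rundown_rate * t/60) before ``t_apply`` and the same
    times (1 - block_fraction) afterwards, plus Gaussian noise.
    """
    if not np.isfinite(rundown_rate) or not np.isfinite(block_fraction):
        raise ValueError("rates must be finite")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    i = i0 * (1.0 - rundown_rate * t / 60.0)
    i[t >= t_apply] *= (1.0 - block_fraction)
    if noise_sigma > 0:
        i = i + rng.normal(0.0, noise_sigma, size=t.size)
    return t, i
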