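"""Selectivity-filter geometry and tetramer superposition.

Parses channel coordinate files (PDB), completes tetramers from crystal
symmetry where the asymmetric unit holds half-tetramers, superposes
tetramers/structures by least squares (Kabsch) and measures the
geometry of the axial sodium sites: inter-ion distances, nearest
protein atoms, coordination-sphere censuses and waters near each site.

Sodium sites are labelled Na_I, Na_II, ... from the extracellular side
inward, by descending axial coordinate after aligning the pore axis
(the tetramer's unique principal axis) with z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import gemmi

__all__ = [
    "AtomRecord",
    "StructureModel",
    "IonSite",
    "IonSiteSet",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "apply_symmetry",
    "parse_selection",
    "superpose",
    "transform_points",
    "ion_site_geometry",
    "compare_sites",
]

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}
_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: np.ndarray  # ångström, shape (3,)
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in _WATER_NAMES

    @property
    def is_sodium(self) -> bool:
        return self.element.upper() == "NA" or (
            self.is_hetero and self.residue_name.strip() == "NA")

    @property
    def is_protein(self) -> bool:
        return not self.is_hetero and not self.is_water


@dataclass
class StructureModel:
    """Flat atom list plus tetramer grouping and symmetry operators."""

    atoms: list[AtomRecord]
    name: str = ""
    tetramer_groups: dict[str, set[str]] = field(default_factory=dict)
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        chains = self.chains
        for gid, members in self.tetramer_groups.items():
            missing = set(members) - chains
            if missing:
                raise ValueError(f"tetramer group {gid} references absent "
                                 f"chains {sorted(missing)}")
        for R, _ in self.symmetry_ops:
            if abs(np.linalg.det(R) - 1.0) > 1e-6:
                raise ValueError("symmetry rotation must be proper (det=+1)")

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def coords(self, predicate: Callable[[AtomRecord], bool] | None = None) -> np.ndarray:
        sel = self.atoms if predicate is None else [a for a in self.atoms if predicate(a)]
        if not sel:
            return np.empty((0, 3))
        return np.vstack([a.xyz for a in sel])

    def select(self, predicate: Callable[[AtomRecord], bool]) -> list[AtomRecord]:
        return [a for a in self.atoms if predicate(a)]

    def group_chains(self, tetramer_id: str | None) -> set[str]:
        if tetramer_id is None:
            return self.chains
        try:
            return set(self.tetramer_groups[tetramer_id])
        except KeyError:
            raise KeyError(
                f"unknown tetramer {tetramer_id!r}; have "
                f"{sorted(self.tetramer_groups)}") from None


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def _default_groups(chains: set[str]) -> dict[str, set[str]]:
    if {"A", "B", "C", "D"} <= chains:
        return {"AB": {"A", "B"}, "CD": {"C", "D"}}
    return {"ALL": set(chains)}


def read_structure(path: str | Path, keep_waters: bool = True,
                   expand_symmetry: bool = False) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer.
    Crystal symmetry operators (from the space group in CRYST1) are
    converted to orthogonal-frame (R, t) pairs and stored on the model;
    with ``expand_symmetry`` all non-identity operators are applied
    immediately (for entries deposited as half-tetramers).
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    atoms: list[AtomRecord] = []
    model = st[0]
    for chain in model:
        for res in chain:
            # resolve altlocs: keep the highest-occupancy copy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            het = res.het_flag == "H"
            if not keep_waters and res.name in _WATER_NAMES:
                continue
            for at in best.values():
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain=chain.name,
                    xyz=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    b_factor=at.b_iso,
                    is_hetero=het,
                ))
    if not atoms:
        raise ValueError(f"{path}: no atoms parsed")

    ops = _crystal_ops(st)
    mdl = StructureModel(atoms=atoms, name=path.stem,
                         tetramer_groups=_default_groups({a.chain for a in atoms}),
                         symmetry_ops=ops)
    if expand_symmetry:
        for idx in range(1, len(ops)):
            mdl = apply_symmetry(mdl, idx)
    return mdl


def _crystal_ops(st: gemmi.Structure) -> list[tuple[np.ndarray, np.ndarray]]:
    sg = st.find_spacegroup()
    if sg is None or st.cell.volume <= 0:
        return [(np.eye(3), np.zeros(3))]
    M = np.array(st.cell.orth.mat.tolist())
    Minv = np.linalg.inv(M)
    ops = []
    for op in sg.operations():
        R_frac = np.array(op.rot, dtype=float) / op.DEN
        t_frac = np.array(op.tran, dtype=float) / op.DEN
        ops.append((M @ R_frac @ Minv, M @ t_frac))
    return ops


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column classic PDB (one MODEL, no altlocs)."""
    st = gemmi.Structure()
    st.name = model.name or "model"
    md = gemmi.Model("1")
    by_chain: dict[str, list[AtomRecord]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain, []).append(a)
    for cname, recs in by_chain.items():
        ch = gemmi.Chain(cname)
        current_res = None
        res = None
        for a in recs:
            key = (a.residue_number, a.residue_name)
            if key != current_res:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                res.het_flag = "H" if a.is_hetero else "A"
                ch.add_residue(res)
                current_res = key
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.xyz)
            at.occ = a.occupancy
            at.b_iso = a.b_factor
            ch[-1].add_atom(at)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# --------------------------------------------------------------------------
# Symmetry
# --------------------------------------------------------------------------

def apply_symmetry(model: StructureModel,
                   op: int | tuple[np.ndarray, np.ndarray]) -> StructureModel:
    """Append symmetry-generated copies of all chains under new labels.

    ``op`` is an index into ``model.symmetry_ops`` or an explicit
    (rotation, translation) pair in the orthogonal frame.  Intra-chain
    distances are preserved exactly (rigid transform).
    """
    if isinstance(op, int):
        try:
            R, t = model.symmetry_ops[op]
        except IndexError:
            raise IndexError(
                f"symmetry operator {op} not present "
                f"({len(model.symmetry_ops)} available)") from None
    else:
        R, t = np.asarray(op[0], dtype=float), np.asarray(op[1], dtype=float)
    if abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("operator rotation must be proper (det=+1)")

    used = {a.chain for a in model.atoms}
    alphabet = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"]
    fresh = iter([c for c in alphabet if c not in used])
    relabel: dict[str, str] = {}
    new_atoms = list(model.atoms)
    serial = max(a.serial for a in model.atoms)
    for a in model.atoms:
        if a.chain not in relabel:
            try:
                relabel[a.chain] = next(fresh)
            except StopIteration:
                relabel[a.chain] = a.chain + "'"
        serial += 1
        new_atoms.append(AtomRecord(
            serial=serial, name=a.name, element=a.element,
            residue_name=a.residue_name, residue_number=a.residue_number,
            chain=relabel[a.chain], xyz=R @ a.xyz + t,
            occupancy=a.occupancy, b_factor=a.b_factor, is_hetero=a.is_hetero))
    groups = {gid: set(m) for gid, m in model.tetramer_groups.items()}
    return StructureModel(atoms=new_atoms, name=model.name,
                          tetramer_groups=groups,
                          symmetry_ops=list(model.symmetry_ops))


# --------------------------------------------------------------------------
# Selections
# --------------------------------------------------------------------------

def parse_selection(spec) -> Callable[[AtomRecord], bool]:
    """Turn a selection spec into an atom predicate.

    Accepts a callable (returned unchanged) or a string of
    ``and``-joined clauses: ``all``, ``protein``, ``ions``, ``waters``,
    ``resi A-B``, ``name CA``, ``chain A`` (comma lists allowed for
    name/chain).  Hydrogens are never excluded here; deposited crystal
    structures carry none.
    """
    if callable(spec):
        return spec
    clauses = [c.strip() for c in str(spec).split(" and ") if c.strip()]

    def predicate(a: AtomRecord) -> bool:
        for clause in clauses:
            parts = clause.split()
            kw = parts[0].lower()
            if kw == "all":
                continue
            if kw == "protein":
                if not a.is_protein:
                    return False
            elif kw == "ions":
                if not (a.is_hetero and not a.is_water):
                    return False
            elif kw == "waters":
                if not a.is_water:
                    return False
            elif kw == "resi":
                lo, _, hi = parts[1].partition("-")
                lo_i = int(lo)
                hi_i = int(hi) if hi else lo_i
                if not (lo_i <= a.residue_number <= hi_i):
                    return False
            elif kw == "name":
                if a.name not in {n.strip() for n in parts[1].split(",")}:
                    return False
            elif kw == "chain":
                if a.chain not in {n.strip() for n in parts[1].split(",")}:
                    return False
            else:
                raise ValueError(f"unknown selection keyword {kw!r}")
        return True

    return predicate


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping the moving model onto the reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # ångström
    rmsd: float  # ångström, over the scoring selection
    n_atoms: int
    selection_spec: str

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return transform_points(xyz, self.rotation, self.translation)


def transform_points(xyz: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    return xyz @ np.asarray(R).T + np.asarray(t)


def _paired_coords(model_a: StructureModel, model_b: StructureModel,
                   predicate, chain_map: dict[str, str] | None):
    """Pair atoms by (chain, residue number, atom name)."""
    chain_map = chain_map or {}
    index_b = {(a.chain, a.residue_number, a.name): a
               for a in model_b.atoms if predicate(a)}
    pa, pb, unpaired = [], [], []
    for a in model_a.atoms:
        if not predicate(a):
            continue
        key = (chain_map.get(a.chain, a.chain), a.residue_number, a.name)
        b = index_b.get(key)
        if b is None:
            unpaired.append(a)
        else:
            pa.append(a.xyz)
            pb.append(b.xyz)
    return pa, pb, unpaired


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    selection="protein",
    score_selection=None,
    chain_map: dict[str, str] | None = None,
    strict: bool = False,
) -> SuperpositionResult:
    """Optimal least-squares (Kabsch) superposition of b onto a.

    Atoms are paired by chain / residue number / atom name within the
    fit ``selection`` (so e.g. side-chain atoms absent from one model --
    a mutated residue -- drop out of the pairing automatically);
    ``chain_map`` renames a-chains to b-chains for cross-tetramer
    comparisons.  The reported RMSD is evaluated over
    ``score_selection`` (default: the fit selection) after applying the
    fitted transform, supporting superpose-on-X / score-on-Y.
    """
    pred_fit = parse_selection(selection)
    pa, pb, unpaired = _paired_coords(model_a, model_b, pred_fit, chain_map)
    if not pa:
        raise ValueError(
            "empty atom pairing for selection "
            f"{selection!r}; {len(unpaired)} reference atoms unmatched")
    if unpaired:
        msg = (f"{len(unpaired)} reference atoms unmatched in pairing, e.g. "
               + ", ".join(f"{a.chain}/{a.residue_number}/{a.name}"
                           for a in unpaired[:5]))
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    A = np.vstack(pa)
    B = np.vstack(pb)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, _ = Rotation.align_vectors(A - ca, B - cb)
    R = rot.as_matrix()
    t = ca - R @ cb

    if score_selection is None:
        scored = transform_points(B, R, t)
        rmsd = float(np.sqrt(np.mean(np.sum((scored - A) ** 2, axis=1))))
        n = A.shape[0]
    else:
        pred_score = parse_selection(score_selection)
        sa, sb, _ = _paired_coords(model_a, model_b, pred_score, chain_map)
        if not sa:
            raise ValueError("empty pairing for scoring selection")
        SA, SB = np.vstack(sa), np.vstack(sb)
        rmsd = float(np.sqrt(np.mean(
            np.sum((transform_points(SB, R, t) - SA) ** 2, axis=1))))
        n = SA.shape[0]
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_atoms=n, selection_spec=str(selection))


# --------------------------------------------------------------------------
# Ion-site geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IonSite:
    label: str
    xyz: np.ndarray  # original frame, ångström
    z_axial: float  # pore-axis coordinate, ångström
    b_factor: float
    tetramer_id: str | None


@dataclass
class IonSiteSet:
    sites: list[IonSite]  # ordered extracellular -> intracellular
    waters: np.ndarray  # (n, 3) original-frame coordinates
    tetramer_id: str | None = None


def pore_axis_frame(coords: np.ndarray) -> np.ndarray:
    """Rotation matrix sending the pore (unique principal) axis to +z.

    The unique axis is the principal axis whose covariance eigenvalue is
    most separated from the other two (a ~4-fold-symmetric tetramer has
    two nearly degenerate in-plane eigenvalues).  The axis is oriented
    to keep a positive projection on the input +z so that extracellular
    stays 'up' for membrane-aligned depositions.
    """
    X = coords - coords.mean(axis=0)
    evals, evecs = np.linalg.eigh(np.cov(X.T))
    sep = [min(abs(evals[i] - evals[j]) for j in range(3) if j != i)
           for i in range(3)]
    axis = evecs[:, int(np.argmax(sep))]
    if axis[2] < 0:
        axis = -axis
    # complete a right-handed orthonormal frame with axis as new z
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, axis)
    x /= np.linalg.norm(x)
    y = np.cross(axis, x)
    return np.vstack([x, y, axis])  # rows: new basis


def ion_site_geometry(
    model: StructureModel,
    tetramer_id: str | None = None,
    coordination_cutoff: float = 3.5,
) -> tuple[IonSiteSet, dict]:
    """Locate the axial sodium sites and report their environment.

    Returns the ordered :class:`IonSiteSet` and a report dict with
    ``inter_site`` (consecutive-pair 3D distances and axial separations),
    per-site ``nearest_protein_atom``, ``coordination_count`` (protein
    atoms within ``coordination_cutoff``, default 3.5 Å, the outer limit
    of a sodium coordination sphere) and ``waters_within_cutoff``.
    """
    chains = model.group_chains(tetramer_id)
    protein = [a for a in model.atoms if a.is_protein and a.chain in chains]
    ions = [a for a in model.atoms if a.is_sodium and a.chain in chains]
    if not ions:  # ions may live in their own chain outside the group
        ions = [a for a in model.atoms if a.is_sodium]
    waters = [a for a in model.atoms if a.is_water and a.chain in chains]
    if not waters:
        waters = [a for a in model.atoms if a.is_water]

    if not ions:
        warnings.warn("no sodium ions found; returning empty site set",
                      stacklevel=2)
        return (IonSiteSet(sites=[], waters=np.empty((0, 3)),
                           tetramer_id=tetramer_id),
                {"inter_site": [], "sites": []})

    if len(protein) >= 3:
        frame = pore_axis_frame(np.vstack([a.xyz for a in protein]))
    else:  # too few atoms to define a principal axis; keep the input frame
        frame = np.eye(3)
    z_of = lambda a: float((frame @ a.xyz)[2])
    ions_sorted = sorted(ions, key=z_of, reverse=True)  # extracellular first

    sites = [IonSite(label=f"Na_{_ROMAN[i] if i < len(_ROMAN) else i + 1}",
                     xyz=a.xyz, z_axial=z_of(a), b_factor=a.b_factor,
                     tetramer_id=tetramer_id)
             for i, a in enumerate(ions_sorted)]
    wxyz = (np.vstack([a.xyz for a in waters]) if waters else np.empty((0, 3)))

    pxyz = (np.vstack([a.xyz for a in protein]) if protein else np.empty((0, 3)))
    report_sites = []
    for s in sites:
        entry: dict = {"label": s.label, "z_axial": s.z_axial}
        if len(pxyz):
            d = np.linalg.norm(pxyz - s.xyz, axis=1)
            j = int(np.argmin(d))
            a = protein[j]
            entry["nearest_protein_atom"] = {
                "name": a.name, "residue_name": a.residue_name,
                "residue_number": a.residue_number, "chain": a.chain,
                "distance": float(d[j]),
            }
            entry["coordination_count"] = int(np.sum(d <= coordination_cutoff))
        else:
            entry["nearest_protein_atom"] = None
            entry["coordination_count"] = 0
        if len(wxyz):
            dw = np.linalg.norm(wxyz - s.xyz, axis=1)
            entry["waters_within_cutoff"] = int(np.sum(dw <= coordination_cutoff))
        else:
            entry["waters_within_cutoff"] = 0
        report_sites.append(entry)

    inter = []
    for s1, s2 in zip(sites, sites[1:]):
        inter.append({
            "pair": (s1.label, s2.label),
            "distance": float(np.linalg.norm(s1.xyz - s2.xyz)),
            "axial_separation": float(s1.z_axial - s2.z_axial),
        })
    report = {"sites": report_sites, "inter_site": inter,
              "coordination_cutoff": coordination_cutoff}
    return IonSiteSet(sites=sites, waters=wxyz, tetramer_id=tetramer_id), report


def compare_sites(set_a: IonSiteSet, set_b: IonSiteSet,
                  superposition: SuperpositionResult | None = None) -> pd.DataFrame:
    """Per-label site displacements after mapping set_b into set_a's frame.

    Labels present in only one set appear with NaN displacement (e.g. a
    site abolished by a mutation).
    """
    pos_a = {s.label: s.xyz for s in set_a.sites}
    pos_b = {s.label: (superposition.apply(s.xyz)[0] if superposition else s.xyz)
             for s in set_b.sites}
    rows = []
    for label in sorted(set(pos_a) | set(pos_b)):
        a, b = pos_a.get(label), pos_b.get(label)
        rows.append({
            "label": label,
            "in_a": a is not None,
            "in_b": b is not None,
            "displacement": (float(np.linalg.norm(a - b))
                             if a is not None and b is not None else np.nan),
        })
    return pd.DataFrame(rows)
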