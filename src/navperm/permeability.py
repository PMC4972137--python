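"""Relative ion permeabilities from bi-ionic reversal potentials.

Under bi-ionic conditions (test cation X dominant outside, Na inside and
outside in the reference condition) the shift of the reversal potential
between the X and Na conditions encodes the permeability ratio P_X/P_Na
through the GHK voltage equation.  This module implements the two
reductions used for whole-cell recordings:

monovalent X (charge +1)::

    P_X/P_Na = (alpha_Na,e / alpha_X,e) * exp(dE_rev * F / (R*T))
    dE_rev   = E_rev,X - E_rev,Na

divalent X (charge +2, Lewis-type relation, internal Na as reference)::

    P_X/P_Na = alpha_Na,i * e^x * (e^x + 1) / (4 * alpha_X,e),
    x = E_rev,X * F / (R*T)

where alpha = gamma * [X] is the effective activity and gamma comes from
the extended Debye-Hueckel equation.  The grouping of the exponential
terms in the divalent relation is ambiguous in the literature this
follows; both readings are implemented (see :func:`divalent_ratio`).

Conditions in which no voltage-gated inward current is activated only
bound the ratio from above: a detection floor replaces the computed
ratio and the result is flagged as an upper bound.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

from .constants import (
    DEFAULT_TEMPERATURE_K,
    DH_A,
    DH_B,
    FARADAY,
    KIELLAND_SIZE_A,
    R_GAS,
    VALENCE,
    rt_over_f_mv,
)

__all__ = [
    "Environment",
    "IonSpecies",
    "PermeabilityResult",
    "debye_huckel_gamma",
    "effective_activity",
    "ionic_strength_single_salt",
    "monovalent_ratio",
    "divalent_ratio",
    "apply_detection_floor",
    "ghk_reversal_potential",
    "invert_monovalent_ratio",
    "invert_divalent_ratio",
    "species_from_saline",
    "analyze_reversal_table",
    "load_salines",
    "results_to_frame",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Environment:
    """Thermodynamic context for the permeability equations.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin.
    dh_A, dh_B : float
        Extended Debye-Hueckel coefficients (M^-1/2 and A^-1 M^-1/2).
    ionic_strength : float
        Default ionic strength (molar) for activity-coefficient
        evaluation when a species does not carry its own.
    """

    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = R_GAS
    faraday: float = FARADAY
    dh_A: float = DH_A
    dh_B: float = DH_B
    ionic_strength: float = 0.15

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def rt_over_f_mv(self) -> float:
        """Thermal voltage RT/F in mV (positive)."""
        return 1000.0 * self.gas_constant * self.temperature / self.faraday


@dataclass
class IonSpecies:
    """A cation with its concentration and activity bookkeeping.

    ``gamma`` (activity coefficient) and ``alpha = gamma * concentration``
    (effective activity, molar) are derived; call
    :func:`debye_huckel_gamma` / :func:`effective_activity` or build the
    species with :func:`species_from_saline` to populate them.
    """

    name: str
    z: int
    concentration: float  # molar
    side: Literal["internal", "external"] = "external"
    size_param_a: float | None = None  # ångström
    born_radius: float | None = None  # ångström
    gamma: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.z not in (1, 2):
            raise ValueError(f"valence must be +1 or +2, got {self.z}")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.size_param_a is None:
            self.size_param_a = KIELLAND_SIZE_A.get(self.name, 4.0)


@dataclass(frozen=True)
class PermeabilityResult:
    """A relative permeability P_X/P_Na with provenance."""

    ion: str
    ratio: float
    method: Literal["monovalent", "divalent"]
    is_upper_bound: bool = False
    erev_used: float | None = None  # mV, junction-corrected
    erev_na_used: float | None = None  # mV


# --------------------------------------------------------------------------
# Activity coefficients
# --------------------------------------------------------------------------

def debye_huckel_gamma(
    z: int,
    ionic_strength: float,
    size_param_a: float,
    env: Environment | None = None,
) -> float:
    """Extended Debye-Hueckel activity coefficient.

    log10(gamma) = -A z^2 sqrt(I) / (1 + B å sqrt(I))

    Parameters
    ----------
    z : int
        Ion valence.
    ionic_strength : float
        Ionic strength I in molar.
    size_param_a : float
        Kielland ion-size parameter å in ångström.
    env : Environment, optional
        Supplies the A and B coefficients (defaults: 0.509 / 0.328,
        water at 25 C).

    Returns
    -------
    float
        gamma in (0, 1].
    """
    if ionic_strength < 0:
        raise ValueError(f"ionic strength must be >= 0, got {ionic_strength}")
    if size_param_a <= 0:
        raise ValueError(f"ion-size parameter must be > 0, got {size_param_a}")
    env = env or Environment()
    sqrt_i = math.sqrt(ionic_strength)
    log10_gamma = -env.dh_A * z * z * sqrt_i / (1.0 + env.dh_B * size_param_a * sqrt_i)
    return 10.0 ** log10_gamma


def effective_activity(species: IonSpecies) -> float:
    """Effective activity alpha = gamma * [X] in molar.

    Also stores the result on ``species.alpha``.
    """
    if species.gamma is None:
        raise ValueError(
            f"gamma is not set for {species.name}; compute it with "
            "debye_huckel_gamma first"
        )
    species.alpha = species.gamma * species.concentration
    return species.alpha


def ionic_strength_single_salt(concentration: float, z_cation: int) -> float:
    """Ionic strength (molar) of a single fully dissociated chloride salt.

    X-Cl at concentration c gives I = c; X-Cl2 gives I = 3c.  Buffer
    species (HEPES, EGTA, trace Ca) are deliberately ignored; they
    contribute < 10 mM under the saline recipes this models.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return 0.5 * (concentration * z_cation**2 + z_cation * concentration)


def species_from_saline(
    name: str,
    concentration: float,
    side: Literal["internal", "external"] = "external",
    z: int | None = None,
    size_param_a: float | None = None,
    ionic_strength: float | None = None,
    env: Environment | None = None,
) -> IonSpecies:
    """Build an :class:`IonSpecies` with gamma and alpha populated.

    If ``ionic_strength`` is omitted it is derived from the species' own
    chloride salt via :func:`ionic_strength_single_salt`.
    """
    if z is None:
        try:
            z = VALENCE[name]
        except KeyError:
            raise ValueError(f"unknown ion {name!r}: pass z explicitly") from None
    sp = IonSpecies(name=name, z=z, concentration=concentration, side=side,
                    size_param_a=size_param_a)
    if ionic_strength is None:
        ionic_strength = ionic_strength_single_salt(concentration, z)
    sp.gamma = debye_huckel_gamma(z, ionic_strength, sp.size_param_a, env)
    effective_activity(sp)
    return sp


# --------------------------------------------------------------------------
# Permeability ratios
# --------------------------------------------------------------------------

def monovalent_ratio(
    erev_x: float,
    erev_na: float,
    alpha_x_ext: float,
    alpha_na_ext: float,
    env: Environment | None = None,
    ion: str = "X",
) -> PermeabilityResult:
    """P_X/P_Na for a monovalent test cation from the E_rev shift.

    P_X/P_Na = (alpha_Na,e / alpha_X,e) * exp((E_rev,X - E_rev,Na) / (RT/F))

    Voltages in mV, activities in molar (units cancel in the ratio).
    """
    if alpha_x_ext <= 0 or alpha_na_ext <= 0:
        raise ValueError("effective activities must be positive")
    env = env or Environment()
    vt = env.rt_over_f_mv
    ratio = (alpha_na_ext / alpha_x_ext) * math.exp((erev_x - erev_na) / vt)
    return PermeabilityResult(
        ion=ion, ratio=ratio, method="monovalent",
        erev_used=erev_x, erev_na_used=erev_na,
    )


def divalent_ratio(
    erev_x: float,
    alpha_na_int: float,
    alpha_x_ext: float,
    env: Environment | None = None,
    ion: str = "X",
    grouping: Literal["product", "quotient"] = "product",
) -> PermeabilityResult:
    """P_X/P_Na for a divalent test cation (Lewis-type relation).

    With x = E_rev / (RT/F):

    - ``grouping="product"`` (default, the Fatt-Ginsborg / Lewis form)::

          P_X/P_Na = alpha_Na,i * e^x * (e^x + 1) / (4 * alpha_X,e)

    - ``grouping="quotient"`` (alternative reading of the same relation)::

          P_X/P_Na = alpha_Na,i * e^x / ((e^x + 1) * 4 * alpha_X,e)

    The internal sodium activity is the reference because the external
    saline contains only the divalent test cation.
    """
    if alpha_na_int <= 0 or alpha_x_ext <= 0:
        raise ValueError("effective activities must be positive")
    env = env or Environment()
    ex = math.exp(erev_x / env.rt_over_f_mv)
    if grouping == "product":
        ratio = alpha_na_int * ex * (ex + 1.0) / (4.0 * alpha_x_ext)
    elif grouping == "quotient":
        ratio = alpha_na_int * ex / ((ex + 1.0) * 4.0 * alpha_x_ext)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return PermeabilityResult(ion=ion, ratio=ratio, method="divalent",
                              erev_used=erev_x)


def apply_detection_floor(
    result: PermeabilityResult,
    erev_x: float,
    floor: float = 0.1,
    erev_threshold: float = -4.0,
) -> PermeabilityResult:
    """Clamp a ratio to the detection floor for unmeasurable currents.

    When the test condition shows no activatable inward current the
    apparent E_rev collapses toward the endogenous-leak reversal; an
    apparent E_rev at or below ``erev_threshold`` (default -4 mV,
    inclusive) only bounds P_X/P_Na from above.  The result is then
    flagged ``is_upper_bound`` with ``ratio`` set to ``floor``.
    """
    if floor <= 0:
        raise ValueError("detection floor must be positive")
    if erev_x <= erev_threshold:
        return replace(result, ratio=floor, is_upper_bound=True)
    return result


# --------------------------------------------------------------------------
# GHK forward model and inversions (used by the synthetic generator and
# for round-trip checks)
# --------------------------------------------------------------------------

def ghk_reversal_potential(
    permeabilities: Mapping[str, float],
    external: Mapping[str, float],
    internal: Mapping[str, float],
    env: Environment | None = None,
) -> float:
    """GHK voltage equation for monovalent cations (mV).

    E_rev = (RT/F) * ln( sum_x P_x alpha_x,e / sum_x P_x alpha_x,i )

    ``external`` / ``internal`` map ion name -> effective activity
    (molar); ``permeabilities`` map ion name -> P_x/P_Na (Na = 1).
    Ions absent from a side contribute zero.  Anions and impermeant
    cations (NMDG) are omitted by simply not listing them.
    """
    env = env or Environment()
    num = sum(permeabilities.get(ion, 0.0) * a for ion, a in external.items())
    den = sum(permeabilities.get(ion, 0.0) * a for ion, a in internal.items())
    if num <= 0 or den <= 0:
        raise ValueError("both sides need at least one permeant ion with "
                         "positive activity")
    return env.rt_over_f_mv * math.log(num / den)


def invert_monovalent_ratio(
    ratio: float,
    erev_na: float,
    alpha_x_ext: float,
    alpha_na_ext: float,
    env: Environment | None = None,
) -> float:
    """E_rev,X (mV) that the monovalent relation maps to ``ratio``."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    env = env or Environment()
    return erev_na + env.rt_over_f_mv * math.log(ratio * alpha_x_ext / alpha_na_ext)


def invert_divalent_ratio(
    ratio: float,
    alpha_na_int: float,
    alpha_x_ext: float,
    env: Environment | None = None,
    grouping: Literal["product", "quotient"] = "product",
) -> float:
    """E_rev,X (mV) that the divalent relation maps to ``ratio``.

    For the product grouping this solves the quadratic
    u^2 + u = 4 * ratio * alpha_X,e / alpha_Na,i in u = e^x.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    env = env or Environment()
    c = 4.0 * ratio * alpha_x_ext / alpha_na_int
    if grouping == "product":
        u = 0.5 * (-1.0 + math.sqrt(1.0 + 4.0 * c))
    elif grouping == "quotient":
        if c >= 1.0:
            raise ValueError("quotient grouping saturates below ratio "
                             f"alpha_Na,i/(4 alpha_X,e); got c={c:.3g}")
        u = c / (1.0 - c)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return env.rt_over_f_mv * math.log(u)


# --------------------------------------------------------------------------
# Tabular front end
# --------------------------------------------------------------------------

def load_salines(path: str | Path) -> dict:
    """Load a saline-composition declaration from JSON.

    Expected shape::

        {"conditions": {"K": {"external": [{"ion": "K", "mM": 150}],
                              "internal": [{"ion": "Na", "mM": 30}]}, ...}}
    """
    with open(path) as fh:
        return json.load(fh)


def analyze_reversal_table(
    table: pd.DataFrame,
    env: Environment | None = None,
    floor: float = 0.1,
    erev_threshold: float = -4.0,
    internal_na_mM: float = 30.0,
    internal_ionic_strength: float | None = None,
    grouping: Literal["product", "quotient"] = "product",
    reference_ion: str = "Na",
) -> list[PermeabilityResult]:
    """Compute P_X/P_Na for every condition of a reversal-potential table.

    ``table`` columns: ``condition``, ``ion``, ``concentration_mM``
    (external test-cation concentration), ``erev_mV``; optional
    ``jp_mV`` (liquid junction potential, subtracted from E_rev when
    present) and ``z``.  One row must carry the reference ion (Na).

    Monovalent test ions use the E_rev shift against the Na condition;
    divalent ions use the Lewis-type relation with the internal Na
    activity (``internal_na_mM``, gamma evaluated at the internal ionic
    strength, by default that of the Na-condition bath).
    """
    env = env or Environment()
    df = table.copy()
    if "jp_mV" in df.columns:
        df["erev_corr"] = df["erev_mV"] - df["jp_mV"].fillna(0.0)
    else:
        df["erev_corr"] = df["erev_mV"]

    ref_rows = df[df["ion"] == reference_ion]
    if ref_rows.empty:
        raise ValueError(f"table has no {reference_ion} reference condition")
    ref = ref_rows.iloc[0]
    na_ext = species_from_saline(reference_ion, ref["concentration_mM"] / 1000.0,
                                 env=env)
    erev_na = float(ref["erev_corr"])

    na_int = species_from_saline(
        reference_ion, internal_na_mM / 1000.0, side="internal",
        ionic_strength=internal_ionic_strength
        if internal_ionic_strength is not None
        else ionic_strength_single_salt(ref["concentration_mM"] / 1000.0, 1),
        env=env,
    )

    results = []
    for _, row in df.iterrows():
        ion = row["ion"]
        z = int(row["z"]) if "z" in df.columns and not pd.isna(row.get("z")) \
            else VALENCE.get(ion, 1)
        sp = species_from_saline(ion, row["concentration_mM"] / 1000.0, z=z,
                                 env=env)
        erev_x = float(row["erev_corr"])
        if z == 1:
            res = monovalent_ratio(erev_x, erev_na, sp.alpha, na_ext.alpha,
                                   env=env, ion=ion)
        else:
            res = divalent_ratio(erev_x, na_int.alpha, sp.alpha, env=env,
                                 ion=ion, grouping=grouping)
        res = apply_detection_floor(res, erev_x, floor=floor,
                                    erev_threshold=erev_threshold)
        results.append(res)
    return results


def results_to_frame(results: Sequence[PermeabilityResult]) -> pd.DataFrame:
    """Flatten results to a DataFrame (CSV/JSON-ready)."""
    return pd.DataFrame(
        {
            "ion": r.ion,
            "ratio": r.ratio,
            "method": r.method,
            "is_upper_bound": r.is_upper_bound,
            "erev_used_mV": r.erev_used,
            "erev_na_used_mV": r.erev_na_used,
        }
        for r in results
    )
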