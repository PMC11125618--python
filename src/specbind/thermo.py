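"""Van't Hoff thermodynamics, binding-force classification, ligand efficiency.

The temperature dependence of the apparent binding constant gives the binding
enthalpy via the van't Hoff relation; for two temperatures

    ln(K2/K1) = dH (1/T1 - 1/T2) / R

and for more, dH = -R * slope of ln Ka vs 1/T. Gibbs energy follows either
from the constant itself (dG = -R T ln Ka) or from dG = dH - T dS. The signs
of dH and dS diagnose the dominant binding force for protein-ligand systems:
(+, +) hydrophobic, (-, -) hydrogen bonding / van der Waals, (-, +)
electrostatic attraction.

Ligand efficiency normalises a docking binding energy by the ligand's
non-hydrogen atom count: LE = |dG_binding| / N_heavy, kcal/mol per heavy
atom, reported as a positive magnitude.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParseError, ValidationError

__all__ = [
    "R_GAS",
    "ForceClass",
    "ThermoResult",
    "LigandRecord",
    "vant_hoff_enthalpy",
    "vant_hoff_analysis",
    "gibbs_from_Ka",
    "gibbs_from_HS",
    "classify_forces",
    "heavy_atom_count",
    "ligand_efficiency",
]

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

_ZERO_BAND = 1.0e-9


class ForceClass(str, enum.Enum):
    HYDROPHOBIC = "hydrophobic"
    HYDROGEN_BOND_VDW = "hydrogen_bond_vdW"
    ELECTROSTATIC = "electrostatic"
    UNCLASSIFIED = "unclassified"


@dataclass
class ThermoResult:
    """Van't Hoff outputs in the conventional unit mix: dH, dG in kJ/mol, dS in J/(mol K).

    ``delta_G_kJ_by_T`` is computed from (dH, dS) via dG = dH - T dS, so the
    identity holds exactly for every stored temperature.
    """

    delta_H_kJ: float
    delta_S_J: float
    delta_G_kJ_by_T: dict[float, float] = field(default_factory=dict)
    force_class: ForceClass = ForceClass.UNCLASSIFIED
    R_gas: float = R_GAS


@dataclass
class LigandRecord:
    name: str
    formula: str
    binding_energy_kcal: float
    n_heavy: int = 0
    LE: float = 0.0

    def __post_init__(self):
        expected = heavy_atom_count(self.formula)
        if self.n_heavy == 0:
            self.n_heavy = expected
        elif self.n_heavy != expected:
            raise ValidationError(
                f"n_heavy = {self.n_heavy} does not match formula {self.formula} ({expected})"
            )
        self.LE = ligand_efficiency(self.binding_energy_kcal, self.n_heavy)


def _validate_ka_map(Ka_by_T) -> tuple[np.ndarray, np.ndarray]:
    """Accept a {T: Ka} mapping or an iterable of (T, Ka) pairs."""
    pairs = list(Ka_by_T.items()) if hasattr(Ka_by_T, "items") else [tuple(p) for p in Ka_by_T]
    temps = np.array([float(t) for t, _ in pairs])
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures in Ka data")
    if temps.size < 2:
        raise ValidationError("van't Hoff analysis needs Ka at >= 2 distinct temperatures")
    order = np.argsort(temps)
    temps = temps[order]
    kas = np.array([float(k) for _, k in pairs])[order]
    if np.any(kas <= 0) or np.any(temps <= 0):
        raise ValidationError("all Ka and T values must be positive")
    return temps, kas


def vant_hoff_enthalpy(Ka_by_T: dict[float, float]) -> float:
    """Binding enthalpy dH in kJ/mol from Ka at two or more temperatures.

    Two points use the closed form; more points use the slope of the
    regression of ln Ka on 1/T (which reduces to the closed form at 2).
    """
    temps, kas = _validate_ka_map(Ka_by_T)
    if temps.size == 2:
        (t1, t2), (k1, k2) = temps, kas
        dh_J = R_GAS * np.log(k2 / k1) / (1.0 / t1 - 1.0 / t2)
    else:
        slope = stats.linregress(1.0 / temps, np.log(kas)).slope
        dh_J = -slope * R_GAS
    return float(dh_J / 1000.0)


def vant_hoff_analysis(Ka_by_T: dict[float, float]) -> ThermoResult:
    """Full van't Hoff treatment: dH, dS, per-temperature dG, force class.

    dS comes from the intercept of ln Ka = -dH/(R T) + dS/R; the stored dG
    map is evaluated from (dH, dS) so the Gibbs identity is exact.
    """
    temps, kas = _validate_ka_map(Ka_by_T)
    dh_kJ = vant_hoff_enthalpy(Ka_by_T)
    # intercept of ln Ka vs 1/T equals dS/R
    if temps.size == 2:
        intercept = np.log(kas[0]) + dh_kJ * 1000.0 / (R_GAS * temps[0])
    else:
        intercept = stats.linregress(1.0 / temps, np.log(kas)).intercept
    ds_J = float(intercept * R_GAS)
    dg_map = {float(t): gibbs_from_HS(dh_kJ, ds_J, float(t)) for t in temps}
    return ThermoResult(
        delta_H_kJ=dh_kJ,
        delta_S_J=ds_J,
        delta_G_kJ_by_T=dg_map,
        force_class=classify_forces(dh_kJ, ds_J),
    )


def gibbs_from_Ka(Ka: float, T: float) -> float:
    """dG = -R T ln Ka, kJ/mol."""
    if Ka <= 0:
        raise ValidationError("Ka must be positive")
    if T <= 0:
        raise ValidationError("T must be positive")
    return float(-R_GAS * T * np.log(Ka) / 1000.0)


def gibbs_from_HS(delta_H_kJ: float, delta_S_J: float, T: float) -> float:
    """dG = dH - T dS, with dH in kJ/mol and dS in J/(mol K)."""
    if T <= 0:
        raise ValidationError("T must be positive")
    return float(delta_H_kJ - T * delta_S_J / 1000.0)


def classify_forces(delta_H_kJ: float, delta_S_J: float) -> ForceClass:
    """Sign-based force diagnosis; values within 1e-9 of zero are unclassifiable."""
    if abs(delta_H_kJ) <= _ZERO_BAND or abs(delta_S_J) <= _ZERO_BAND:
        warnings.warn("dH or dS indistinguishable from zero; force class unclassified",
                      stacklevel=2)
        return ForceClass.UNCLASSIFIED
    if delta_H_kJ > 0 and delta_S_J > 0:
        return ForceClass.HYDROPHOBIC
    if delta_H_kJ < 0 and delta_S_J < 0:
        return ForceClass.HYDROGEN_BOND_VDW
    if delta_H_kJ < 0 and delta_S_J > 0:
        return ForceClass.ELECTROSTATIC
    return ForceClass.UNCLASSIFIED


# all IUPAC element symbols, for formula validation
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn "
    "Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe Cs Ba La "
    "Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po "
    "At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg "
    "Cn Nh Fl Mc Lv Ts Og".split()
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def heavy_atom_count(formula: str) -> int:
    """Number of non-hydrogen atoms in a Hill-style molecular formula.

    Supply the anion formula for salts (e.g. C4F9O3S, not C4F9KO3S) so the
    counter-ion does not inflate the count.
    """
    formula = formula.strip()
    if not formula:
        raise ParseError("empty molecular formula")
    pos, total = 0, 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m or not m.group(1):
            raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, count = m.group(1), int(m.group(2) or 1)
        if symbol not in _ELEMENTS:
            raise ParseError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        if symbol != "H":
            total += count
        pos = m.end()
    return total


def ligand_efficiency(binding_energy_kcal: float, n_heavy: int) -> float:
    """LE = |binding energy| / heavy-atom count, kcal/mol per heavy atom."""
    if n_heavy < 1:
        raise ValidationError("n_heavy must be >= 1")
    return abs(binding_energy_kcal) / n_heavy
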