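"""Model structure: components, processes, parameters, and the Gujer matrix.

The model describes anaerobic digestion of a salt-accumulating plant biomass
in COD units, extended beyond standard ADM1 with an oxalate degradation
pathway and eight sulfate-reducing guilds that compete with the methanogenic
food web for fermentation products.  All organic state variables are carried
in kgCOD m^-3 (numerically equal to g L^-1); hydrogen sulfide and sulfate
are carried in kmol m^-3 and interconverted at 64 kgCOD per kmol of sulfide.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "COD_PER_KMOL_H2S",
    "ComponentRegistry",
    "ProcessDef",
    "RateKind",
    "ParameterSet",
    "StoichiometryMatrix",
    "build_model",
    "build_registry",
    "build_processes",
    "assemble_matrix",
    "validate_cod_balance",
    "PRESETS",
]

#: COD equivalent of one kmol of hydrogen sulfide (kgCOD kmol^-1).
COD_PER_KMOL_H2S = 64.0

# ---------------------------------------------------------------------------
# Components
# ---------------------------------------------------------------------------

_SOLUBLE = [
    # (code, unit)
    ("S_su", "kgCOD/m3"),
    ("S_aa", "kgCOD/m3"),
    ("S_fa", "kgCOD/m3"),
    ("S_va", "kgCOD/m3"),
    ("S_bu", "kgCOD/m3"),
    ("S_pro", "kgCOD/m3"),
    ("S_ac", "kgCOD/m3"),
    ("S_ox", "kgCOD/m3"),
    ("S_h2", "kgCOD/m3"),
    ("S_ch4", "kgCOD/m3"),
    ("S_h2s", "kmol/m3"),
    ("S_SO4", "kmol/m3"),
    ("S_I", "kgCOD/m3"),
]

_PARTICULATE = [
    "X_C", "X_ch", "X_pr", "X_li", "X_I",
    "X_ox", "X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2",
    "X_mSRB", "X_aaSRB", "X_LSRB", "X_vSRB", "X_bSRB", "X_pSRB",
    "X_aSRB", "X_hSRB",
]

#: The 16 active biomass guilds (8 methanogenic-chain degraders + 8 SRB).
BIOMASS_CODES = tuple(_PARTICULATE[5:])

#: Soluble substrates counted as biodegradable in COD balances.
BIODEGRADABLE_SOLUBLE = ("S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro",
                         "S_ac", "S_ox", "S_h2")

#: Biodegradable particulate pools (feed composite and hydrolysis backlog).
BIODEGRADABLE_PARTICULATE = ("X_C", "X_ch", "X_pr", "X_li")


@dataclass(frozen=True)
class Component:
    index: int          # 1-based position in the matrix
    code: str
    phase: str          # "soluble" | "particulate"
    unit: str
    is_biomass: bool


class ComponentRegistry:
    """Ordered registry of the 34 model state variables.

    13 soluble components precede 21 particulates; sulfide and sulfate are
    the only molar-unit entries, everything else is COD-based.
    """

    def __init__(self) -> None:
        entries: List[Component] = []
        for i, (code, unit) in enumerate(_SOLUBLE, start=1):
            entries.append(Component(i, code, "soluble", unit, False))
        for j, code in enumerate(_PARTICULATE, start=14):
            entries.append(
                Component(j, code, "particulate", "kgCOD/m3",
                          code in BIOMASS_CODES))
        self.entries = entries
        self._by_code = {c.code: c for c in entries}
        self._validate()

    def _validate(self) -> None:
        sol = [c for c in self.entries if c.phase == "soluble"]
        par = [c for c in self.entries if c.phase == "particulate"]
        if len(sol) != 13 or len(par) != 21:
            raise ValueError("registry must hold 13 soluble and 21 "
                             "particulate components")
        if sorted(c.index for c in self.entries) != list(range(1, 35)):
            raise ValueError("component indices must be a permutation of 1..34")
        if sum(c.is_biomass for c in self.entries) != 16:
            raise ValueError("expected 16 active biomass guilds")
        molar = [c.code for c in self.entries if c.unit == "kmol/m3"]
        if sorted(molar) != ["S_SO4", "S_h2s"]:
            raise ValueError("only S_h2s and S_SO4 carry molar units")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, code: str) -> Component:
        return self._by_code[code]

    def idx(self, code: str) -> int:
        """0-based column index of a component code."""
        return self._by_code[code].index - 1

    @property
    def codes(self) -> List[str]:
        return [c.code for c in self.entries]

    def cod_equivalents(self) -> np.ndarray:
        """Per-component factor mapping state units to kgCOD m^-3.

        1 for COD-based components, 64 for sulfide (kgCOD kmol^-1) and 0
        for sulfate, which carries no COD.
        """
        eq = np.ones(len(self.entries))
        eq[self.idx("S_h2s")] = COD_PER_KMOL_H2S
        eq[self.idx("S_SO4")] = 0.0
        return eq


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class RateKind(enum.Enum):
    FIRST_ORDER = "first_order"
    MONOD = "monod"
    MONOD_INHIBITED = "monod_inhibited"
    DECAY = "decay"


#: guild order for the 17 degraders (oxalate + 7 methanogenic chain + ... )
GUILDS = ("ox", "su", "aa", "fa", "va", "bu", "pro", "ac", "h2",
          "mSRB", "aaSRB", "LSRB", "vSRB", "bSRB", "pSRB", "aSRB", "hSRB")


@dataclass
class ParameterSet:
    """Kinetic constants, yields and product fractions of the model.

    Rates are d^-1, half-saturation constants kgCOD m^-3 and yields
    gCOD-biomass per gCOD-substrate.  ``km``/``ks``/``b`` are keyed by the
    substrate handled (``va`` and ``bu`` share one biomass guild, X_c4, but
    keep separate uptake kinetics).
    """

    name: str = "default"
    # disintegration / hydrolysis (first order, d^-1)
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0
    # uptake kinetics per substrate
    km: Dict[str, float] = field(default_factory=dict)
    ks: Dict[str, float] = field(default_factory=dict)
    b: Dict[str, float] = field(default_factory=dict)
    # yields per guild
    Y: Dict[str, float] = field(default_factory=dict)
    # propionate inhibition
    K_I_pp: float = 1e6
    K_I_pa: float = 1e6
    K_I_ph: float = 1e6
    n: float = 1.0
    # optional per-process inhibition exponents; fall back to n when None
    n_pa: Optional[float] = None
    n_ph: Optional[float] = None
    # sulfate half-saturation for SRB uptake (kmol m^-3); keeps sulfate
    # consumption bounded by availability
    K_SO4: float = 1e-4
    # disintegration fractions
    f_ch_xc: float = 0.60
    f_pr_xc: float = 0.108
    f_li_xc: float = 0.001
    f_ox_xc: float = 0.011
    f_xI_xc: float = 0.27
    f_sI_xc: float = 0.01
    # lipid hydrolysis split
    f_fa_li: float = 0.95
    # sugar fermentation products
    f_h2_su: float = 0.33
    f_bu_su: float = 0.0
    f_pro_su: float = 0.0
    # amino acid fermentation products
    f_va_aa: float = 0.26
    f_bu_aa: float = 0.27
    f_pro_aa: float = 0.07
    f_ac_aa: float = 0.33
    # LCFA oxidation acetate share
    f_ac_L: float = 0.7
    # valerate oxidation splits (methanogenic chain)
    f_pro_va: float = 0.54
    f_ac_va: float = 0.31
    f_h2_va: float = 0.15
    # butyrate oxidation splits
    f_ac_bu: float = 0.8
    f_h2_bu: float = 0.2
    # propionate oxidation splits
    f_ac_pro: float = 0.57
    f_h2_pro: float = 0.43
    # LCFA (methanogenic) splits
    f_ac_fa: float = 0.7
    f_h2_fa: float = 0.3
    # SRB valerate split (acetate / sulfide), as printed
    f_ac_va_srb: float = 0.84

    @property
    def f_ac_su(self) -> float:
        return 1.0 - self.f_h2_su - self.f_bu_su - self.f_pro_su

    @property
    def f_h2_aa(self) -> float:
        return 1.0 - self.f_va_aa - self.f_bu_aa - self.f_pro_aa - self.f_ac_aa

    def copy(self, **overrides) -> "ParameterSet":
        new = replace(self)
        new.km = dict(self.km)
        new.ks = dict(self.ks)
        new.b = dict(self.b)
        new.Y = dict(self.Y)
        for key, val in overrides.items():
            self_has = hasattr(new, key)
            if not self_has:
                raise KeyError(f"unknown parameter {key!r}")
            setattr(new, key, val)
        return new

    # -- flat access used by config files and the calibration layer -------
    _ALIASES = {"KI_pp": "K_I_pp", "KI_pa": "K_I_pa", "KI_ph": "K_I_ph"}

    def get_flat(self, key: str) -> float:
        holder, sub = self._locate(key)
        return getattr(self, sub) if holder is None else holder[sub]

    def set_flat(self, key: str, value: float) -> None:
        holder, sub = self._locate(key)
        if holder is None:
            setattr(self, sub, float(value))
        else:
            holder[sub] = float(value)

    def _locate(self, key: str):
        """Resolve a flat config key to (dict, subkey) or (None, attr)."""
        for prefix, holder in (("km_", self.km), ("KS_", self.ks),
                               ("b_", self.b), ("Y_", self.Y)):
            if key.startswith(prefix) and key[len(prefix):] in holder:
                return holder, key[len(prefix):]
        key = self._ALIASES.get(key, key)
        if hasattr(self, key) and not key.startswith("_"):
            return None, key
        raise KeyError(f"unknown parameter {key!r}")

    def flat_names(self) -> List[str]:
        names = [f.name for f in fields(self)
                 if f.name not in ("name", "km", "ks", "b", "Y")]
        names += [f"km_{g}" for g in self.km]
        names += [f"KS_{g}" for g in self.ks]
        names += [f"b_{g}" for g in self.b]
        names += [f"Y_{g}" for g in self.Y]
        return names

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        dis = (self.f_ch_xc + self.f_pr_xc + self.f_li_xc + self.f_ox_xc
               + self.f_xI_xc + self.f_sI_xc)
        if abs(dis - 1.0) > 1e-9:
            raise ValueError(
                f"disintegration fractions sum to {dis!r}, expected 1")
        if self.f_ac_su < 0 or self.f_h2_aa < 0:
            raise ValueError("derived product fraction is negative "
                             "(f_ac_su or f_h2_aa)")
        product_sets = {
            "sugar uptake": self.f_h2_su + self.f_bu_su + self.f_pro_su
            + self.f_ac_su,
            "amino acid uptake": self.f_va_aa + self.f_bu_aa + self.f_pro_aa
            + self.f_ac_aa + self.f_h2_aa,
            "valerate uptake": self.f_pro_va + self.f_ac_va + self.f_h2_va,
            "butyrate uptake": self.f_ac_bu + self.f_h2_bu,
            "propionate uptake": self.f_ac_pro + self.f_h2_pro,
            "LCFA uptake": self.f_ac_fa + self.f_h2_fa,
        }
        for label, total in product_sets.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"product fractions for {label} sum to {total!r}")
        for d, label in ((self.km, "km"), (self.ks, "ks"), (self.b, "b"),
                         (self.Y, "Y")):
            for g, v in d.items():
                if v < 0:
                    raise ValueError(f"{label}[{g}] is negative")
        for g, y in self.Y.items():
            if y >= 1:
                raise ValueError(f"yield Y[{g}] must be < 1")
        if self.n < 1:
            raise ValueError("inhibition exponent n must be >= 1")
        if self.k_dis < 0 or min(self.k_hyd_ch, self.k_hyd_pr,
                                 self.k_hyd_li) < 0:
            raise ValueError("first-order rates must be nonnegative")


def _base_parameters() -> ParameterSet:
    """Common structure shared by all presets (yields, fractions)."""
    p = ParameterSet()
    p.Y = {
        "ox": 0.04, "su": 0.18, "aa": 0.18, "fa": 0.06, "c4": 0.04,
        "pro": 0.04, "ac": 0.05, "h2": 0.04,
        # SRB yields mirror their methanogenic-chain counterparts
        "mSRB": 0.18, "aaSRB": 0.18, "LSRB": 0.06, "vSRB": 0.04,
        "bSRB": 0.04, "pSRB": 0.04, "aSRB": 0.05, "hSRB": 0.04,
    }
    return p


def _saline_kinetics(p: ParameterSet) -> None:
    """Calibrated uptake kinetics shared by both salt systems (kg-COD units)."""
    p.k_dis = 1.2
    p.k_hyd_ch = p.k_hyd_pr = p.k_hyd_li = 10.0
    p.km = {"ox": 4.0, "su": 4.0, "aa": 4.0, "fa": 1.0, "va": 2.0,
            "bu": 2.0, "pro": 0.039, "ac": 4.0, "h2": 1.5}
    p.ks = {"ox": 0.010, "su": 0.010, "aa": 0.010, "fa": 0.040, "va": 0.010,
            "bu": 0.010, "pro": 0.005, "ac": 0.015, "h2": 7e-9}
    # decay: 0.06 d^-1 for every guild with a tabulated value; the acetate
    # and hydrogen methanogens have no tabulated decay and are treated as
    # decay-free — with any appreciable decay the methanogenic community is
    # nonviable at the reported operating points (see docs/methods.md)
    p.b = {"ox": 0.06, "su": 0.06, "aa": 0.06, "fa": 0.06, "c4": 0.06,
           "pro": 0.06, "ac": 0.0, "h2": 0.0,
           "mSRB": 0.06, "aaSRB": 0.06, "LSRB": 0.06, "vSRB": 0.06,
           "bSRB": 0.06, "pSRB": 0.06, "aSRB": 0.06, "hSRB": 0.06}
    p.K_I_pp = 0.8
    p.K_I_pa = 0.5
    p.K_I_ph = 0.5
    # the sharpened threshold exponent is tabulated within the propionate-
    # degrader block and binds to its self-inhibition; the acetate and
    # hydrogen degraders use the plain first-order threshold
    p.n = 5.0
    p.n_pa = 1.0
    p.n_ph = 1.0


def _srb_off(p: ParameterSet) -> None:
    p.km.update({"mSRB": 0.0, "aaSRB": 0.0, "LSRB": 0.0, "vSRB": 0.0,
                 "bSRB": 0.0, "pSRB": 0.0, "aSRB": 0.0, "hSRB": 0.0})
    p.ks.update({g: 1e-4 for g in ("mSRB", "aaSRB", "LSRB", "vSRB",
                                   "bSRB", "pSRB", "aSRB", "hSRB")})


def _nacl_preset() -> ParameterSet:
    p = _base_parameters()
    _saline_kinetics(p)
    _srb_off(p)
    p.name = "NaCl"
    return p


def _sulfate_preset() -> ParameterSet:
    p = _base_parameters()
    _saline_kinetics(p)
    p.name = "Na2SO4_NaHCO3"
    p.km["pro"] = 2.0
    p.km.update({"mSRB": 2.0, "aaSRB": 2.0, "LSRB": 1.0, "vSRB": 2.0,
                 "bSRB": 2.0, "pSRB": 2.0, "aSRB": 2.0, "hSRB": 8.0})
    p.ks.update({g: 1e-4 for g in ("mSRB", "aaSRB", "LSRB", "vSRB",
                                   "bSRB", "pSRB", "aSRB", "hSRB")})
    return p


def _default_preset() -> ParameterSet:
    """Non-saline reference kinetics (standard solid-waste values)."""
    p = _base_parameters()
    p.name = "default"
    p.k_dis = 0.5
    p.km = {"ox": 4.0, "su": 30.0, "aa": 50.0, "fa": 6.0, "va": 20.0,
            "bu": 20.0, "pro": 13.0, "ac": 8.0, "h2": 35.0}
    p.ks = {"ox": 0.010, "su": 0.5, "aa": 0.3, "fa": 0.4, "va": 0.2,
            "bu": 0.2, "pro": 0.1, "ac": 0.15, "h2": 7e-9}
    p.b = {g: 0.02 for g in ("ox", "su", "aa", "fa", "c4", "pro", "ac", "h2",
                             "mSRB", "aaSRB", "LSRB", "vSRB", "bSRB",
                             "pSRB", "aSRB", "hSRB")}
    _srb_off(p)
    return p


PRESETS = {
    "default": _default_preset,
    "NaCl": _nacl_preset,
    "Na2SO4_NaHCO3": _sulfate_preset,
}


# ---------------------------------------------------------------------------
# Processes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessDef:
    j: int
    name: str
    rate_kind: RateKind
    substrate: Optional[str]    # component code consumed in the rate law
    biomass: Optional[str]      # guild component code for Monod/decay rates
    guild: Optional[str]        # kinetic key into km/ks/b
    stoich: Dict[str, float]    # component code -> coefficient


#: (j, substrate, biomass component, kinetic key) for Monod uptakes 5..21
_UPTAKES: List[Tuple[int, str, str, str]] = [
    (5, "S_ox", "X_ox", "ox"),
    (6, "S_su", "X_su", "su"),
    (7, "S_aa", "X_aa", "aa"),
    (8, "S_fa", "X_fa", "fa"),
    (9, "S_va", "X_c4", "va"),
    (10, "S_bu", "X_c4", "bu"),
    (11, "S_pro", "X_pro", "pro"),
    (12, "S_ac", "X_ac", "ac"),
    (13, "S_h2", "X_h2", "h2"),
    (14, "S_su", "X_mSRB", "mSRB"),
    (15, "S_aa", "X_aaSRB", "aaSRB"),
    (16, "S_fa", "X_LSRB", "LSRB"),
    (17, "S_va", "X_vSRB", "vSRB"),
    (18, "S_bu", "X_bSRB", "bSRB"),
    (19, "S_pro", "X_pSRB", "pSRB"),
    (20, "S_ac", "X_aSRB", "aSRB"),
    (21, "S_h2", "X_hSRB", "hSRB"),
]

#: biomass guild decayed by processes 22..37, with kinetic key
_DECAYS: List[Tuple[int, str, str]] = [
    (22, "X_ox", "ox"), (23, "X_su", "su"), (24, "X_aa", "aa"),
    (25, "X_fa", "fa"), (26, "X_c4", "c4"), (27, "X_pro", "pro"),
    (28, "X_ac", "ac"), (29, "X_h2", "h2"),
    (30, "X_mSRB", "mSRB"), (31, "X_aaSRB", "aaSRB"),
    (32, "X_LSRB", "LSRB"), (33, "X_vSRB", "vSRB"),
    (34, "X_bSRB", "bSRB"), (35, "X_pSRB", "pSRB"),
    (36, "X_aSRB", "aSRB"), (37, "X_hSRB", "hSRB"),
]

SRB_PROCESSES = tuple(range(14, 22))


def _srb_row(sub: str, bio: str, Y: float,
             products: Dict[str, float], f_h2s: float) -> Dict[str, float]:
    """Stoichiometric row for an SRB uptake.

    ``products`` maps soluble COD products to their fraction of (1-Y);
    ``f_h2s`` is the fraction routed to sulfide, entered mole-for-mole
    against sulfate at 64 kgCOD per kmol.
    """
    row = {sub: -1.0, bio: Y}
    for code, f in products.items():
        if f:
            row[code] = row.get(code, 0.0) + (1.0 - Y) * f
    mol = (1.0 - Y) * f_h2s / COD_PER_KMOL_H2S
    row["S_h2s"] = mol
    row["S_SO4"] = -mol
    return row


def build_processes(params: ParameterSet) -> List[ProcessDef]:
    """Instantiate the 37 process definitions with numeric stoichiometry."""
    p = params
    Y = p.Y
    procs: List[ProcessDef] = []

    def add(j, name, kind, sub, bio, guild, stoich):
        procs.append(ProcessDef(j, name, kind, sub, bio, guild, dict(stoich)))

    add(1, "disintegration", RateKind.FIRST_ORDER, "X_C", None, None, {
        "X_C": -1.0, "X_ch": p.f_ch_xc, "X_pr": p.f_pr_xc,
        "X_li": p.f_li_xc, "X_I": p.f_xI_xc, "S_I": p.f_sI_xc,
        "S_ox": p.f_ox_xc})
    add(2, "hydrolysis of carbohydrates", RateKind.FIRST_ORDER, "X_ch",
        None, None, {"X_ch": -1.0, "S_su": 1.0})
    add(3, "hydrolysis of proteins", RateKind.FIRST_ORDER, "X_pr",
        None, None, {"X_pr": -1.0, "S_aa": 1.0})
    add(4, "hydrolysis of lipids", RateKind.FIRST_ORDER, "X_li",
        None, None, {"X_li": -1.0, "S_su": 1.0 - p.f_fa_li,
                     "S_fa": p.f_fa_li})

    add(5, "uptake of oxalate", RateKind.MONOD, "S_ox", "X_ox", "ox", {
        "S_ox": -1.0, "S_h2": 1.0 - Y["ox"], "X_ox": Y["ox"]})
    add(6, "uptake of monosaccharides", RateKind.MONOD, "S_su", "X_su",
        "su", {
            "S_su": -1.0, "X_su": Y["su"],
            "S_bu": (1 - Y["su"]) * p.f_bu_su,
            "S_pro": (1 - Y["su"]) * p.f_pro_su,
            "S_ac": (1 - Y["su"]) * p.f_ac_su,
            "S_h2": (1 - Y["su"]) * p.f_h2_su})
    add(7, "uptake of amino acids", RateKind.MONOD, "S_aa", "X_aa", "aa", {
        "S_aa": -1.0, "X_aa": Y["aa"],
        "S_va": (1 - Y["aa"]) * p.f_va_aa,
        "S_bu": (1 - Y["aa"]) * p.f_bu_aa,
        "S_pro": (1 - Y["aa"]) * p.f_pro_aa,
        "S_ac": (1 - Y["aa"]) * p.f_ac_aa,
        "S_h2": (1 - Y["aa"]) * p.f_h2_aa})
    add(8, "uptake of LCFA", RateKind.MONOD, "S_fa", "X_fa", "fa", {
        "S_fa": -1.0, "X_fa": Y["fa"],
        "S_ac": (1 - Y["fa"]) * p.f_ac_fa,
        "S_h2": (1 - Y["fa"]) * p.f_h2_fa})
    add(9, "uptake of valerate", RateKind.MONOD, "S_va", "X_c4", "va", {
        "S_va": -1.0, "X_c4": Y["c4"],
        "S_pro": (1 - Y["c4"]) * p.f_pro_va,
        "S_ac": (1 - Y["c4"]) * p.f_ac_va,
        "S_h2": (1 - Y["c4"]) * p.f_h2_va})
    add(10, "uptake of butyrate", RateKind.MONOD, "S_bu", "X_c4", "bu", {
        "S_bu": -1.0, "X_c4": Y["c4"],
        "S_ac": (1 - Y["c4"]) * p.f_ac_bu,
        "S_h2": (1 - Y["c4"]) * p.f_h2_bu})
    add(11, "uptake of propionate", RateKind.MONOD_INHIBITED, "S_pro",
        "X_pro", "pro", {
            "S_pro": -1.0, "X_pro": Y["pro"],
            "S_ac": (1 - Y["pro"]) * p.f_ac_pro,
            "S_h2": (1 - Y["pro"]) * p.f_h2_pro})
    add(12, "uptake of acetate", RateKind.MONOD_INHIBITED, "S_ac", "X_ac",
        "ac", {"S_ac": -1.0, "X_ac": Y["ac"], "S_ch4": 1 - Y["ac"]})
    add(13, "uptake of hydrogen", RateKind.MONOD_INHIBITED, "S_h2", "X_h2",
        "h2", {"S_h2": -1.0, "X_h2": Y["h2"], "S_ch4": 1 - Y["h2"]})

    # SRB uptakes: soluble product split mirrors the methanogenic chain,
    # with the hydrogen share replaced by sulfide.
    add(14, "uptake of monosaccharides by SRB", RateKind.MONOD, "S_su",
        "X_mSRB", "mSRB",
        _srb_row("S_su", "X_mSRB", Y["mSRB"],
                 {"S_bu": p.f_bu_su, "S_pro": p.f_pro_su,
                  "S_ac": p.f_ac_su}, p.f_h2_su))
    add(15, "uptake of amino acids by SRB", RateKind.MONOD, "S_aa",
        "X_aaSRB", "aaSRB",
        _srb_row("S_aa", "X_aaSRB", Y["aaSRB"],
                 {"S_va": p.f_va_aa, "S_bu": p.f_bu_aa,
                  "S_pro": p.f_pro_aa, "S_ac": p.f_ac_aa}, p.f_h2_aa))
    add(16, "uptake of LCFA by SRB", RateKind.MONOD, "S_fa", "X_LSRB",
        "LSRB",
        _srb_row("S_fa", "X_LSRB", Y["LSRB"],
                 {"S_ac": p.f_ac_L}, 1.0 - p.f_ac_L))
    add(17, "uptake of valerate by SRB", RateKind.MONOD, "S_va", "X_vSRB",
        "vSRB",
        _srb_row("S_va", "X_vSRB", Y["vSRB"],
                 {"S_ac": p.f_ac_va_srb}, 1.0 - p.f_ac_va_srb))
    add(18, "uptake of butyrate by SRB", RateKind.MONOD, "S_bu", "X_bSRB",
        "bSRB",
        _srb_row("S_bu", "X_bSRB", Y["bSRB"],
                 {"S_ac": p.f_ac_bu}, p.f_h2_bu))
    add(19, "uptake of propionate by SRB", RateKind.MONOD, "S_pro",
        "X_pSRB", "pSRB",
        _srb_row("S_pro", "X_pSRB", Y["pSRB"],
                 {"S_ac": p.f_ac_pro}, p.f_h2_pro))
    add(20, "uptake of acetate by SRB", RateKind.MONOD, "S_ac", "X_aSRB",
        "aSRB", _srb_row("S_ac", "X_aSRB", Y["aSRB"], {}, 1.0))
    add(21, "uptake of hydrogen by SRB", RateKind.MONOD, "S_h2", "X_hSRB",
        "hSRB", _srb_row("S_h2", "X_hSRB", Y["hSRB"], {}, 1.0))

    for j, bio, guild in _DECAYS:
        add(j, f"decay of {bio}", RateKind.DECAY, None, bio, guild,
            {bio: -1.0, "X_C": 1.0})

    return procs


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

@dataclass
class StoichiometryMatrix:
    matrix: np.ndarray          # 37 x 34
    cod_equivalents: np.ndarray  # length 34
    registry: ComponentRegistry
    processes: List[ProcessDef]

    def row(self, j: int) -> np.ndarray:
        """1-based process row."""
        return self.matrix[j - 1]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.matrix,
                            index=[p.name for p in self.processes],
                            columns=self.registry.codes)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def assemble_matrix(processes: List[ProcessDef],
                    params: ParameterSet,
                    registry: Optional[ComponentRegistry] = None,
                    ) -> StoichiometryMatrix:
    """Build the numeric 37x34 Gujer matrix from process definitions.

    Raises ``ValueError`` naming the offending process if a product-fraction
    set fails to close, surfacing as a COD-conservation violation.
    """
    params.validate()
    reg = registry or ComponentRegistry()
    mat = np.zeros((len(processes), len(reg)))
    for p in processes:
        for code, coeff in p.stoich.items():
            mat[p.j - 1, reg.idx(code)] = coeff
    sm = StoichiometryMatrix(mat, reg.cod_equivalents(), reg, list(processes))
    residuals = validate_cod_balance(sm)
    bad = [p.name for p, r in zip(processes, residuals) if abs(r) > 1e-8]
    if bad:
        raise ValueError(f"COD not conserved in process(es): {', '.join(bad)}")
    return sm


def validate_cod_balance(m: StoichiometryMatrix) -> np.ndarray:
    """Per-process COD residual (kgCOD per unit of process rate).

    Sulfide counts at 64 kgCOD kmol^-1 and sulfate carries no COD; a valid
    matrix returns 37 zeros (|residual| <= 1e-8).
    """
    return m.matrix @ m.cod_equivalents


def build_model(scenario_name: str = "default"):
    """Return ``(registry, processes, params)`` for a named preset.

    ``NaCl`` carries the saline calibration with dormant SRB guilds
    (km = 0, no sulfate fed); ``Na2SO4_NaHCO3`` activates the eight SRB
    guilds; ``default`` is the non-saline reference.
    """
    try:
        params = PRESETS[scenario_name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario_name!r}; expected one of "
            f"{sorted(PRESETS)}") from None
    params.validate()
    registry = build_registry()
    processes = build_processes(params)
    return registry, processes, params


def build_registry() -> ComponentRegistry:
    return ComponentRegistry()
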