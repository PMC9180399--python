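"""Feed composition handling and COD unit conversions.

The feed is a dried fodder-grass concentrate whose COD splits, on
disintegration, into carbohydrate, protein, lipid, oxalate and inert pools.
Measured solids and dissolved-carbon signals are converted to COD with the
factors used throughout the study: 1.19 gCOD per g VSS for particulates
(complete oxidation of (C6H10O5)n) and per-substance COD/DOC ratios for
solubles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = ["FeedComposition", "feed_from_fractions", "cod_from_vss",
           "vss_from_cod", "cod_from_soluble_toc", "cod_per_doc",
           "COD_PER_VSS", "COD_PER_TOC_SOLUBLE", "COD_PER_DOC"]

#: gCOD of particulate matter per g of volatile suspended solids
COD_PER_VSS = 1.19
#: gCOD of soluble matter per g of soluble TOC (32 g-O2 per 12 g-C)
COD_PER_TOC_SOLUBLE = 2.67
#: COD/DOC ratios by substance, from the assumed elemental compositions
#: (CH2O)n, (C4H9O2N)n and (C31H34O11)n
COD_PER_DOC = {"carbohydrate": 2.67, "protein": 3.00, "lignin": 2.92}


@dataclass
class FeedComposition:
    """Feed COD fractionation plus the salt-system metadata of a scenario."""

    total_cod: float                      # kgCOD m^-3 of feed concentrate
    f_ch_xc: float
    f_pr_xc: float
    f_li_xc: float
    f_ox_xc: float
    f_xI_xc: float
    f_sI_xc: float
    salt_system: str = "NaCl"             # "NaCl" | "Na2SO4_NaHCO3"
    na_conc: Optional[float] = None       # g-Na+ per L, metadata
    osmotic_pressure_atm: Optional[float] = None  # metadata only

    def __post_init__(self) -> None:
        fr = self.fractions
        if min(fr) < 0:
            raise ValueError("feed fractions must be nonnegative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"feed fractions sum to {sum(fr)!r}, expected 1")

    @property
    def fractions(self) -> Tuple[float, ...]:
        return (self.f_ch_xc, self.f_pr_xc, self.f_li_xc, self.f_ox_xc,
                self.f_xI_xc, self.f_sI_xc)


def feed_from_fractions(percentages: Sequence[float], total_cod: float,
                        soluble_inert_carveout: float = 1.0,
                        **metadata) -> FeedComposition:
    """Build a feed from measured percentages of the five analysed pools.

    ``percentages`` lists (carbohydrate, protein, lipid, oxalate, inert) in
    percent of total COD; a soluble-inert carve-out (percent, default 1)
    is subtracted from the carbohydrate pool, reflecting soluble lignin
    compounds detected in the digestate.
    """
    if len(percentages) != 5:
        raise ValueError("expected 5 pool percentages "
                         "(carbohydrate, protein, lipid, oxalate, inert)")
    total = sum(percentages)
    if abs(total - 100.0) > 0.5:
        raise ValueError(f"pool percentages sum to {total}, expected 100")
    ch, pr, li, ox, xi = (x / total for x in percentages)
    si = soluble_inert_carveout / 100.0
    if si > ch:
        raise ValueError("soluble-inert carve-out exceeds carbohydrate pool")
    return FeedComposition(total_cod, ch - si, pr, li, ox, xi, si, **metadata)


def cod_from_vss(vss: float) -> float:
    """Particulate COD (kgCOD m^-3) from a VSS concentration (g L^-1)."""
    if vss < 0:
        raise ValueError("VSS must be nonnegative")
    return COD_PER_VSS * vss


def vss_from_cod(cod: float) -> float:
    """Inverse of :func:`cod_from_vss` (MLSS approximated by VSS)."""
    if cod < 0:
        raise ValueError("COD must be nonnegative")
    return cod / COD_PER_VSS


def cod_from_soluble_toc(toc: float) -> float:
    """Soluble COD (kgCOD m^-3) from soluble TOC (g-C L^-1)."""
    if toc < 0:
        raise ValueError("TOC must be nonnegative")
    return COD_PER_TOC_SOLUBLE * toc


def cod_per_doc(substance: str) -> float:
    """COD/DOC factor for carbohydrate, protein or lignin."""
    try:
        return COD_PER_DOC[substance]
    except KeyError:
        raise ValueError(
            f"unknown substance {substance!r}; expected one of "
            f"{sorted(COD_PER_DOC)}") from None
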