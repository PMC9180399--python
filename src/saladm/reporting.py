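"""Steady-state COD accounting and with/without-SRB comparisons.

Every outflow pathway of the reactor — methane gas, sulfide (at 64 kgCOD
per kmol), wasted inerts, wasted biomass and wasted biodegradables — is
expressed as a fraction of the COD feeding rate, mirroring how conversion
efficiencies are reported for the two salt systems.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .model_core import (BIODEGRADABLE_PARTICULATE, BIODEGRADABLE_SOLUBLE,
                         BIOMASS_CODES, COD_PER_KMOL_H2S)

__all__ = ["CODBalance", "cod_balance", "sulfide_to_cod", "srb_share",
           "compare_srb", "degradable_fraction"]


@dataclass
class CODBalance:
    """Fractions of fed COD leaving the reactor by pathway at steady state."""

    methane: float
    sulfide_cod: float
    particulate_inert: float
    soluble_inert: float
    biomass: float
    residual_biodegradable_soluble: float
    residual_biodegradable_particulate: float

    def total(self) -> float:
        return sum(asdict(self).values())

    def as_dict(self) -> dict:
        return asdict(self)

    def as_percent(self) -> dict:
        """Rounded presentation copy (integer percent, raw kept elsewhere)."""
        return {k: round(100.0 * v) for k, v in asdict(self).items()}

    def validate(self, tol: float = 0.01) -> None:
        vals = asdict(self)
        bad = [k for k, v in vals.items() if v < -1e-12]
        if bad:
            raise ValueError(f"negative balance fractions: {bad}")
        if abs(self.total() - 1.0) > tol:
            raise ValueError(
                f"COD balance fractions sum to {self.total():.4f}, "
                f"expected 1 within {tol}")


def cod_balance(steady, schedule) -> CODBalance:
    """COD balance of a converged reactor state.

    Output fluxes are instantaneous at the converged state: gas production
    from the process rates, washout as concentration / SRT.  Requires a
    state produced by the steady-state solver.
    """
    if not getattr(steady, "converged", False):
        raise ValueError("cod_balance requires a converged steady state")
    cm = steady.model
    olr = steady.olr if steady.olr is not None else schedule.olr(0.0)
    if olr <= 0:
        raise ValueError("cod_balance needs a positive feeding rate")
    c = steady.concentrations
    rho = cm.evaluator(c)
    p_ch4 = float(cm.ch4_row @ rho)
    p_h2s = float(cm.h2s_row @ rho)
    kw = 1.0 / schedule.srt
    idx = cm.registry.idx

    def washout(codes) -> float:
        return float(sum(c[idx(k)] for k in codes)) * kw / olr

    bal = CODBalance(
        methane=p_ch4 / olr,
        sulfide_cod=COD_PER_KMOL_H2S * p_h2s / olr,
        particulate_inert=washout(["X_I"]),
        soluble_inert=washout(["S_I"]),
        biomass=washout(BIOMASS_CODES),
        residual_biodegradable_soluble=washout(BIODEGRADABLE_SOLUBLE),
        residual_biodegradable_particulate=washout(BIODEGRADABLE_PARTICULATE),
    )
    bal.validate(tol=0.011)
    return bal


def sulfide_to_cod(s_h2s: float) -> float:
    """Sulfide (kmol m^-3) to its COD equivalent (kgCOD m^-3), x64."""
    if s_h2s < 0:
        raise ValueError("sulfide amount must be nonnegative")
    return COD_PER_KMOL_H2S * s_h2s


def degradable_fraction(params) -> float:
    """Fraction of fed COD that is biodegradable (excludes both inert
    disintegration products)."""
    return 1.0 - params.f_xI_xc - params.f_sI_xc


def srb_share(result_with, result_without=None, t: Optional[float] = None
              ) -> float:
    """Share of degradable fed COD routed through the SRB uptake processes.

    Electron-donor COD consumed by the eight SRB uptakes (cumulative), over
    cumulative degradable COD fed (fed COD times one minus the inert
    fractions) at day ``t`` (default: end of run).  Each donor molecule is
    counted once, at uptake.  When a paired SRB-free run is supplied its
    schedule must match.
    """
    if result_without is not None:
        a, b = result_with.schedule, result_without.schedule
        if (a.segments != b.segments or a.srt != b.srt
                or a.feed_cod != b.feed_cod):
            raise ValueError("with/without-SRB runs must share a schedule")
    cm = result_with.model
    t = result_with.times[-1] if t is None else t
    i = int(np.argmin(np.abs(result_with.times - t)))
    led = result_with.states[i, cm.n_comp:]
    fed, donor = led[2], led[5]
    degradable = fed * degradable_fraction(cm.params)
    if degradable <= 0:
        return 0.0
    return float(donor / degradable)


def compare_srb(model_factory, schedule, t: float, **simulate_kw) -> dict:
    """Run a schedule with and without the SRB guilds and compare.

    ``model_factory(active_srb: bool)`` must return a model tuple; the
    SRB-free run also starts with zero SRB biomass.  Returns the methane
    production rates at day ``t`` and the SRB share of degradable COD.
    """
    from .reactor import compile_model, default_initial_state, simulate

    res = {}
    for active in (True, False):
        cm = compile_model(model_factory(active))
        c0 = default_initial_state(cm)
        if not active:
            for code in BIOMASS_CODES:
                if "SRB" in code:
                    c0[cm.registry.idx(code)] = 0.0
        res[active] = simulate(cm, schedule, initial_state=c0, **simulate_kw)

    def mpr_at(sim):
        i = int(np.argmin(np.abs(sim.times - t)))
        return float(sim.mpr[i])

    return {
        "mpr_with_srb": mpr_at(res[True]),
        "mpr_without_srb": mpr_at(res[False]),
        "srb_share": srb_share(res[True], res[False], t=t),
        "result_with": res[True],
        "result_without": res[False],
    }
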