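"""Rate laws and evaluation of the 37-process rate vector.

Four rate forms cover the whole network: first-order disintegration and
hydrolysis, Monod uptake, Monod uptake throttled by a threshold-type
propionate inhibition factor, and first-order biomass decay.  Uptake rates
are expressed in COD of the electron donor (kgCOD m^-3 d^-1); SRB uptakes
additionally require sulfate, whose availability enters as a saturation
factor so that reduction never outruns the sulfate supply.
"""

from __future__ import annotations

from typing import List

import numpy as np

from .model_core import (ComponentRegistry, ParameterSet, ProcessDef,
                         RateKind, SRB_PROCESSES)

__all__ = ["first_order_rate", "monod_rate", "propionate_inhibition",
           "RateEvaluator", "process_rates"]

#: states more negative than this abort a public rate evaluation; less
#: negative excursions are integrator noise and are clamped to zero
NEGATIVITY_ABORT = -1e-8

#: inside the integrator states are clamped without aborting: internal
#: stages of a stiff solver may undershoot zero arbitrarily during Newton
#: iteration, and the clamped dynamics are always restoring
SOLVER_NEGATIVITY_ABORT = -np.inf


def first_order_rate(k: float, X: float) -> float:
    """First-order conversion rate k*X for disintegration and hydrolysis."""
    if k < 0 or X < 0:
        raise ValueError("first-order rate requires k >= 0 and X >= 0")
    return k * X


def monod_rate(k_m: float, S: float, K_S: float, X_B: float) -> float:
    """Monod uptake k_m * S/(K_S+S) * X_B, bounded by k_m*X_B."""
    if min(k_m, S, X_B) < 0 or K_S < 0:
        raise ValueError("Monod rate requires nonnegative arguments")
    if K_S == 0.0 and S == 0.0:
        raise ValueError("K_S = 0 with S = 0 leaves the rate undefined")
    return k_m * S / (K_S + S) * X_B


def propionate_inhibition(S_pro: float, K_I: float, n: float) -> float:
    """Threshold inhibition factor K_I^n / (K_I^n + S_pro^n) in (0, 1].

    Equals 1 with no propionate and 1/2 at S_pro = K_I; the exponent n >= 1
    sharpens the switch around the threshold K_I.
    """
    if S_pro < 0:
        raise ValueError("S_pro must be nonnegative")
    if K_I <= 0:
        raise ValueError("K_I must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    # work with the ratio to stay overflow-safe for large S_pro or K_I
    r = (S_pro / K_I) ** n
    return 1.0 / (1.0 + r)


class RateEvaluator:
    """Vectorized evaluation of the 37 process rates for a model.

    Precomputes index arrays so the hot path is pure numpy; used by the
    reactor integrator.
    """

    def __init__(self, registry: ComponentRegistry,
                 processes: List[ProcessDef], params: ParameterSet,
                 negativity_floor: float = SOLVER_NEGATIVITY_ABORT) -> None:
        self.registry = registry
        self.processes = processes
        self.params = params
        self.n_proc = len(processes)
        self.negativity_floor = negativity_floor

        idx = registry.idx
        self._i_pro = idx("S_pro")
        self._i_so4 = idx("S_SO4")

        first = [p for p in processes if p.rate_kind == RateKind.FIRST_ORDER]
        self._fo_rows = np.array([p.j - 1 for p in first])
        self._fo_sub = np.array([idx(p.substrate) for p in first])
        self._fo_k = np.array([params.k_dis, params.k_hyd_ch,
                               params.k_hyd_pr, params.k_hyd_li])

        monod = [p for p in processes
                 if p.rate_kind in (RateKind.MONOD, RateKind.MONOD_INHIBITED)]
        self._m_rows = np.array([p.j - 1 for p in monod])
        self._m_sub = np.array([idx(p.substrate) for p in monod])
        self._m_bio = np.array([idx(p.biomass) for p in monod])
        self._m_km = np.array([params.km[p.guild] for p in monod])
        self._m_ks = np.array([params.ks[p.guild] for p in monod])
        self._m_srb = np.array([p.j in SRB_PROCESSES for p in monod])
        self._m_j = np.array([p.j for p in monod])

        decay = [p for p in processes if p.rate_kind == RateKind.DECAY]
        self._d_rows = np.array([p.j - 1 for p in decay])
        self._d_bio = np.array([idx(p.biomass) for p in decay])
        self._d_b = np.array([params.b[p.guild] for p in decay])

    def __call__(self, state: np.ndarray) -> np.ndarray:
        """Return the 37-vector of process rates for a 34-state vector."""
        if state.shape[0] != len(self.registry):
            raise ValueError(
                f"state must have {len(self.registry)} components, "
                f"got {state.shape[0]}")
        if state.min() < self.negativity_floor:
            worst = self.registry.codes[int(np.argmin(state))]
            raise ValueError(
                f"state component {worst} is negative beyond tolerance: "
                f"{state.min():.3e}")
        c = np.maximum(state, 0.0)
        p = self.params

        rho = np.empty(self.n_proc)
        rho[self._fo_rows] = self._fo_k * c[self._fo_sub]

        s = c[self._m_sub]
        m = self._m_km * s / (self._m_ks + s) * c[self._m_bio]
        # sulfate saturation caps all SRB uptakes
        if self._m_srb.any():
            so4 = c[self._i_so4]
            m = np.where(self._m_srb, m * so4 / (p.K_SO4 + so4), m)
        # propionate inhibition on propionate, acetate, hydrogen uptake
        s_pro = c[self._i_pro]
        inhibited = ((11, p.K_I_pp, p.n),
                     (12, p.K_I_pa, p.n_pa if p.n_pa is not None else p.n),
                     (13, p.K_I_ph, p.n_ph if p.n_ph is not None else p.n))
        for j, K_I, n in inhibited:
            pos = np.nonzero(self._m_j == j)[0][0]
            m[pos] *= propionate_inhibition(s_pro, K_I, n)
        rho[self._m_rows] = m

        rho[self._d_rows] = self._d_b * c[self._d_bio]
        return rho


def process_rates(state, model) -> np.ndarray:
    """Evaluate all 37 process rates for ``model = (registry, processes,
    params)`` at a 34-component state."""
    registry, processes, params = model
    ev = RateEvaluator(registry, processes, params,
                       negativity_floor=NEGATIVITY_ABORT)
    return ev(np.asarray(state, dtype=float))
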