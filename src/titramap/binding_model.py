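"""Two-state (optionally two-site) fast-exchange binding forward model.

Populations come from the exact single-site mass balance with ligand
depletion (the titrations of interest are near-stoichiometric, 0.5–2
ligand equivalents on a 50 μM protein, where the L≫P approximation is
badly wrong):

    f = [ (P + L + Kd) − sqrt((P + L + Kd)² − 4·P·L) ] / (2·P)

In fast exchange a residue shows one population-averaged peak,

    δ_obs = δ_free + f·Δδ_sat,

and its transverse relaxation gains both a size term and an exchange term

    ΔR₂ = f·(R₂,bound − R₂,free)  +  f·(1−f)·Δω²/k_ex      (contact residues)

with Δω the compound free→bound shift difference in rad/s at the declared
¹H field.  Peak height decays as exp(−ΔR₂·t_relax) with a single effective
relaxation time.  The exchange term is maximal at f = ½ and vanishes at the
endpoints — the mechanism by which contact residues broaden (I/I₀ < 1) or
disappear mid-titration.

``fit_kd`` inverts the model: a single global Kd and per-residue saturation
CSPs are least-squares fitted to CSP-vs-ligand curves (separable linear
subproblem for the Δδ_max values, 1-D search over log Kd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .csp_core import DEFAULT_ALPHA_N
from .errors import FitError, ParameterError

#: gyromagnetic-ratio magnitude of ¹⁵N relative to ¹H
GAMMA_N_OVER_H = 0.101329118

#: default ¹H spectrometer frequency, MHz
DEFAULT_FIELD_MHZ = 800.0


@dataclass
class BindingParams:
    """Thermodynamic and relaxation parameters of a simulated titration.

    Concentrations share one unit (μM by convention); ``kd2`` enables a
    sequential, non-cooperative second (weak) site.  ``t_relax`` is the
    effective signal-decay time converting a rate excess into a peak-height
    attenuation.
    """

    kd1: float = 5.0
    kd2: float | None = None
    p_total: float = 50.0
    ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    r2_free: float = 15.0
    r2_bound: float = 25.0
    kex: float = 10000.0
    t_relax: float = 0.05
    field_mhz: float = DEFAULT_FIELD_MHZ

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or self.p_total <= 0:
            raise ParameterError("kd1 and p_total must be positive")
        if self.kd2 is not None and self.kd2 <= 0:
            raise ParameterError("kd2 must be positive when given")
        if any(r < 0 for r in self.ratios):
            raise ParameterError("molar ratios must be >= 0")
        if self.kex <= 0:
            raise ParameterError("kex must be positive")
        if not (self.r2_bound >= self.r2_free >= 0):
            raise ParameterError("need r2_bound >= r2_free >= 0")


@dataclass
class ResidueResponse:
    """Saturation shift changes of one residue, per binding site.

    Non-contact residues have zero Δδ; ``contact`` switches the exchange
    (Rex) broadening term on.
    """

    residue_index: int
    ddh: float = 0.0
    ddn: float = 0.0
    ddh2: float = 0.0
    ddn2: float = 0.0
    contact: bool = False

    def __post_init__(self) -> None:
        for v in (self.ddh, self.ddn, self.ddh2, self.ddn2):
            if not math.isfinite(v):
                raise ParameterError("shift responses must be finite")


def fraction_bound(p_total: float, l_total, kd: float):
    """Exact bound fraction of protein from the single-site mass balance.

    Vectorized over ``l_total``.  ``kd == 0`` gives the stoichiometric limit
    min(L/P, 1).
    """
    l_total = np.asarray(l_total, dtype=float)
    if p_total <= 0:
        raise ParameterError("p_total must be positive")
    if np.any(l_total < 0) or kd < 0:
        raise ParameterError("l_total and kd must be >= 0")
    if kd == 0:
        f = np.minimum(l_total / p_total, 1.0)
    else:
        s = p_total + l_total + kd
        disc = s * s - 4.0 * p_total * l_total
        f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p_total)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def compound_domega(ddh: float, ddn: float, field_mhz: float = DEFAULT_FIELD_MHZ) -> float:
    """Compound free→bound shift difference in rad/s at the given ¹H field."""
    wh = ddh * field_mhz * 1e6 * 2.0 * math.pi * 1e-6  # ppm -> Hz -> rad/s
    wn = ddn * field_mhz * GAMMA_N_OVER_H * 1e6 * 2.0 * math.pi * 1e-6
    return math.hypot(wh, wn)


def observed_peak(
    resp: ResidueResponse,
    f: float,
    free_h: float,
    free_n: float,
    params: BindingParams | None = None,
    f2: float = 0.0,
):
    """Population-averaged peak position and relative height at bound fraction ``f``.

    Returns ``(shift_h, shift_n, relative_intensity)``; intensity is 1 at
    f = 0.  ``f2`` is the second-site bound fraction (shifts additive; its
    exchange contribution is computed with the site-2 Δω).
    """
    params = params or BindingParams()
    if not (0.0 <= f <= 1.0) or not (0.0 <= f2 <= 1.0):
        raise ParameterError("bound fractions must lie in [0, 1]")
    dh = f * resp.ddh + f2 * resp.ddh2
    dn = f * resp.ddn + f2 * resp.ddn2
    delta_r2 = f * (params.r2_bound - params.r2_free)
    if resp.contact:
        dw1 = compound_domega(resp.ddh, resp.ddn, params.field_mhz)
        delta_r2 += f * (1.0 - f) * dw1 * dw1 / params.kex
        if f2 > 0.0:
            dw2 = compound_domega(resp.ddh2, resp.ddn2, params.field_mhz)
            delta_r2 += f2 * (1.0 - f2) * dw2 * dw2 / params.kex
    intensity = math.exp(-delta_r2 * params.t_relax)
    return free_h + dh, free_n + dn, intensity


def fit_kd(
    l_totals,
    csp_matrix,
    p_total: float,
    noise_sd: float = 0.0,
    kd_bounds: tuple[float, float] | None = None,
):
    """Global-Kd least-squares fit of CSP titration curves.

    ``csp_matrix`` is (n_residues, n_points) of compound CSPs measured at
    total ligand concentrations ``l_totals`` (same units as ``p_total``).
    The model is Δδ(i, L) = Δδ_max(i)·f(P, L, Kd) with one shared Kd; for a
    fixed Kd the optimal Δδ_max values are closed-form, so the fit is a 1-D
    minimization over log₁₀ Kd.

    Returns ``(kd_estimate, ddmax_array, residual_matrix)``.  Raises
    :class:`FitError` when no residue responds above ``5·noise_sd`` (or
    responds at all when noise_sd is 0).
    """
    l_totals = np.asarray(l_totals, dtype=float)
    Y = np.atleast_2d(np.asarray(csp_matrix, dtype=float))
    if Y.shape[1] != l_totals.size:
        raise ParameterError("csp_matrix columns must match l_totals")
    if l_totals.size < 3:
        raise FitError("need at least 3 titration points to fit Kd")
    resp_floor = 5.0 * noise_sd
    responsive = np.nanmax(Y, axis=1) > resp_floor
    if not np.any(responsive) or np.nanmax(Y) <= 0:
        raise FitError("no responsive residues: all CSP curves are flat")
    Yr = np.nan_to_num(Y[responsive], nan=0.0)

    def sse_at(log10_kd: float) -> float:
        f = fraction_bound(p_total, l_totals, 10.0 ** log10_kd)
        denom = float(f @ f)
        if denom == 0.0:
            return float(np.sum(Yr * Yr))
        ddmax = (Yr @ f) / denom
        resid = Yr - np.outer(ddmax, f)
        return float(np.sum(resid * resid))

    lo, hi = kd_bounds or (1e-3 * p_total, 1e3 * p_total)
    # coarse log-grid scan then local refinement: the SSE can be flat/multimodal
    grid = np.linspace(math.log10(lo), math.log10(hi), 200)
    best = min(grid, key=sse_at)
    span = grid[1] - grid[0]
    res = minimize_scalar(sse_at, bounds=(best - 2 * span, best + 2 * span), method="bounded")
    kd = float(10.0 ** res.x)
    f = fraction_bound(p_total, l_totals, kd)
    denom = float(f @ f)
    ddmax_full = np.zeros(Y.shape[0])
    Yfull = np.nan_to_num(Y, nan=0.0)
    ddmax_full = (Yfull @ f) / denom
    resid = Yfull - np.outer(ddmax_full, f)
    return kd, ddmax_full, resid
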