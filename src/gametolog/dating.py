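"""Dating gametolog divergence under male-biased mutation rates.

Silent sites on the X and Y evolve at different rates because the male germ
line contributes more replications (and hence mutations) per year than the
female germ line.  With a 1:1 sex ratio the X spends two-thirds of its time
in females and one-third in males, the Y is male-limited, and autosomes
split time evenly, so with female rate m_f and male rate m_m = alpha * m_f:

    m_A  = (m_m + m_f) / 2
    m_X  = (2/3) m_f + (1/3) m_m
    m_Y  = m_m
    m_XY = m_X + m_Y        (per-year divergence rate of an X/Y pair)

The autosomal rate is calibrated from a neutral divergence K between two
species with a known split-time window [T_lo, T_hi]: m_A = K / (2 T).  A
gametolog pair's synonymous divergence K_S then dates recombination arrest
at T = K_S / m_XY, the faster rate bound giving the younger age.

Two rounding modes are provided.  ``full-precision`` carries every quantity
exactly; ``printed-chain`` rounds each intermediate rate to 3 significant
figures before it enters the next step, which is how chained estimates are
conventionally reported (and is required to reproduce published chains in
which, e.g., 2.38 + 3.57 = 5.95 holds at 3 figures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

YEAR_PER_MYR = 1_000_000.0

RoundingMode = Literal["printed-chain", "full-precision"]


class DatingError(ValueError):
    pass


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def autosomal_rate(K: float, T_lo: float, T_hi: float,
                   rounding: RoundingMode = "printed-chain") -> tuple[float, float]:
    """Autosomal substitution rate bounds (per site per year) from a
    calibration divergence K and a species split-time window in years.

    Returns ``(m_A_hi, m_A_lo)``: the younger bound T_lo gives the higher
    rate.  In printed-chain mode rates are rounded to 3 significant figures.
    """
    if K <= 0 or T_lo <= 0 or T_hi <= T_lo:
        raise DatingError("require K > 0 and 0 < T_lo < T_hi")
    m_hi = K / (2.0 * T_lo)
    m_lo = K / (2.0 * T_hi)
    if rounding == "printed-chain":
        m_hi, m_lo = _round_sig(m_hi), _round_sig(m_lo)
    return m_hi, m_lo


@dataclass(frozen=True)
class RateModel:
    """Sex-chromosome substitution-rate bounds derived from m_A and alpha."""

    alpha: float
    m_A_lo: float
    m_A_hi: float
    m_f_lo: float
    m_f_hi: float
    m_m_lo: float
    m_m_hi: float
    m_X_lo: float
    m_X_hi: float
    m_Y_lo: float
    m_Y_hi: float
    m_XY_lo: float
    m_XY_hi: float
    rounding_mode: RoundingMode


def build_rate_model(m_A_lo: float, m_A_hi: float, alpha: float = 2.0,
                     rounding: RoundingMode = "printed-chain") -> RateModel:
    """Derive m_f, m_m, m_X, m_Y and m_XY bounds from autosomal-rate bounds.

    alpha = m_m / m_f is the male-driven-evolution factor (2 is the
    conservative mammalian estimate).  In printed-chain mode m_X and m_Y
    are rounded to 3 significant figures before summing into m_XY.
    """
    if alpha <= 0:
        raise DatingError("alpha must be > 0")
    if m_A_lo <= 0 or m_A_hi < m_A_lo:
        raise DatingError("require 0 < m_A_lo <= m_A_hi")

    def chain(m_A: float) -> tuple[float, float, float, float, float]:
        m_f = 2.0 * m_A / (1.0 + alpha)
        m_m = alpha * m_f
        m_X = (2.0 / 3.0) * m_f + (1.0 / 3.0) * m_m
        m_Y = m_m
        if rounding == "printed-chain":
            m_X, m_Y = _round_sig(m_X), _round_sig(m_Y)
        return m_f, m_m, m_X, m_Y, m_X + m_Y

    f_lo, m_lo, X_lo, Y_lo, XY_lo = chain(m_A_lo)
    f_hi, m_hi, X_hi, Y_hi, XY_hi = chain(m_A_hi)
    return RateModel(alpha=alpha, m_A_lo=m_A_lo, m_A_hi=m_A_hi,
                     m_f_lo=f_lo, m_f_hi=f_hi, m_m_lo=m_lo, m_m_hi=m_hi,
                     m_X_lo=X_lo, m_X_hi=X_hi, m_Y_lo=Y_lo, m_Y_hi=Y_hi,
                     m_XY_lo=XY_lo, m_XY_hi=XY_hi, rounding_mode=rounding)


@dataclass(frozen=True)
class DatingEstimate:
    """Divergence-time window in million years (T_lo = young, T_hi = old)."""

    KS_input: float
    T_lo: float
    T_hi: float
    T_lo_years: float
    T_hi_years: float


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def date_divergence(KS: float, model: RateModel) -> DatingEstimate:
    """T = K_S / m_XY; the faster rate gives the younger bound.

    Bounds are reported in million years, rounded half-up to the nearest
    integer Myr in printed-chain mode.
    """
    if KS <= 0:
        raise DatingError("KS must be > 0")
    t_young = KS / model.m_XY_hi
    t_old = KS / model.m_XY_lo
    lo, hi = t_young / YEAR_PER_MYR, t_old / YEAR_PER_MYR
    if model.rounding_mode == "printed-chain":
        lo, hi = _round_half_up(lo), _round_half_up(hi)
    return DatingEstimate(KS_input=KS, T_lo=lo, T_hi=hi,
                          T_lo_years=t_young, T_hi_years=t_old)


def date_with_se(KS: float, se_KS: float, m_XY: float) -> tuple[float, float]:
    """Point estimate and delta-method SE of T (years) at a single rate."""
    if KS <= 0 or m_XY <= 0:
        raise DatingError("KS and m_XY must be > 0")
    return KS / m_XY, se_KS / m_XY
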