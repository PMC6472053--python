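"""Fatty-acid composition from the ten named signal integrals.

All percentages are mole % of acyl chains: the chain count is the total
methyl integral divided by three (I_TL = I0.88 + I0.95, three methyl
protons per chain), and each species percentage divides its diagnostic
integral by its proton count:

    alpha-linolenic = 100 * 3 I2.81 / (4 I_TL)      (4 bis-allylic H)
    linoleic        = 100 * 3 I2.77 / (2 I_TL)      (2 bis-allylic H)
    CLA ct          = 100 * 3 I6.28 / I_TL          (1 olefinic H at 6.28)
    CLA tt          = 100 * 3 I5.99 / (2 I_TL)      (H10 + H11)
    caproleic       = 100 * 3 I5.80 / I_TL  or  100 * 3 I4.99 / I_TL

Total unsaturation uses the allylic integral D (2.02 ppm) against the
alpha-carbonyl integral C (2.33 ppm). Every non-terminal unsaturated chain
carries 4 allylic protons; caproleic acid, the only milk MUFA with a
terminal double bond, carries only 2 allylic protons plus 1 terminal
vinyl proton in I4.99, while every chain carries 2 protons in C:

    UFA = 100 * (D + 2 I4.99) / (2 C),    SFA = 100 - UFA,
    MUFA = UFA - linoleic - alpha-linolenic - CLA ct - CLA tt.

The pure-caproleic limit (D = 2n, I4.99 = n, C = 2n -> 100%) validates the
terminal-double-bond correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntegralSet",
    "CompositionReport",
    "pct_alpha_linolenic",
    "pct_linoleic",
    "pct_cla_ct",
    "pct_cla_tt",
    "pct_caproleic",
    "pct_ufa",
    "pct_sfa",
    "pct_mufa",
    "omega_ratio",
    "quantify",
    "precision_stats",
    "relative_deviation",
]

log = logging.getLogger(__name__)


@dataclass
class IntegralSet:
    """The ten signal integrals (intensity x ppm) feeding the equations.

    ``d`` is I2.02 (allylic), ``c`` is I2.33 (alpha-carbonyl). Negative
    integrals (possible from noise) are floored at zero with a warning.
    """

    i088: float
    i095: float
    d: float
    c: float
    i277: float
    i281: float
    i499: float
    i580: float
    i599: float
    i628: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("i088", "i095", "d", "c", "i277", "i281",
                     "i499", "i580", "i599", "i628"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"integral {name} is not finite")
            if v < 0:
                log.warning("negative integral %s=%.3g floored at 0", name, v)
                v = 0.0
            setattr(self, name, v)

    @property
    def itl(self) -> float:
        """Total methyl integral I0.88 + I0.95 (three protons per chain)."""
        return self.i088 + self.i095

    def scaled(self, k: float) -> "IntegralSet":
        return IntegralSet(*(k * v for v in (
            self.i088, self.i095, self.d, self.c, self.i277, self.i281,
            self.i499, self.i580, self.i599, self.i628)), meta=dict(self.meta))


def _require_itl(I: IntegralSet) -> float:
    if I.itl <= 0:
        raise ValueError("total methyl integral I_TL must be positive")
    return I.itl


def pct_alpha_linolenic(I: IntegralSet) -> float:
    """alpha-linolenic acid, mol % of chains (bis-allylic 2.81 ppm, 4H)."""
    return 100.0 * 3.0 * I.i281 / (4.0 * _require_itl(I))


def pct_linoleic(I: IntegralSet) -> float:
    """Linoleic acid, mol % of chains (bis-allylic 2.77 ppm, 2H)."""
    return 100.0 * 3.0 * I.i277 / (2.0 * _require_itl(I))


def pct_cla_ct(I: IntegralSet) -> float:
    """Cis/trans conjugated 18:2 pool, mol % (one olefinic H at 6.28 ppm)."""
    return 100.0 * 3.0 * I.i628 / _require_itl(I)


def pct_cla_tt(I: IntegralSet) -> float:
    """(9t,11t) conjugated 18:2, mol % (H10 + H11 at 5.99 ppm)."""
    return 100.0 * 3.0 * I.i599 / (2.0 * _require_itl(I))


def pct_caproleic(I: IntegralSet) -> tuple[float, float]:
    """Caproleic acid, mol %, estimated from H9 (5.80) and from H10a (4.99).

    Returns both one-proton estimates; they should agree, and a relative
    disagreement above 10% is logged as a warning.
    """
    itl = _require_itl(I)
    from_h9 = 100.0 * 3.0 * I.i580 / itl
    from_h10a = 100.0 * 3.0 * I.i499 / itl
    ref = max(abs(from_h9), abs(from_h10a))
    if ref > 0 and abs(from_h9 - from_h10a) / ref > 0.10:
        log.warning("caproleic estimates disagree: H9 %.3f%% vs H10a %.3f%%",
                    from_h9, from_h10a)
    return from_h9, from_h10a


def pct_ufa(I: IntegralSet) -> float:
    """Total unsaturated fatty acids, mol % (terminal-bond-corrected)."""
    if I.c <= 0:
        raise ValueError("alpha-carbonyl integral C must be positive")
    d = I.d
    if d < 2.0 * I.i499:
        log.warning("allylic integral D=%.3g below caproleic floor 2*I499=%.3g; "
                    "clipping", d, 2.0 * I.i499)
        d = 2.0 * I.i499
    return 100.0 * (d + 2.0 * I.i499) / (2.0 * I.c)


def pct_sfa(I: IntegralSet) -> float:
    """Saturated fatty acids, mol %: complement of the UFA percentage."""
    return 100.0 - pct_ufa(I)


def pct_mufa(I: IntegralSet) -> float:
    """Monounsaturated fatty acids, mol %: UFA minus the named PUFA/CLA."""
    mufa = (pct_ufa(I) - pct_linoleic(I) - pct_alpha_linolenic(I)
            - pct_cla_ct(I) - pct_cla_tt(I))
    if mufa < 0:
        log.warning("negative MUFA %.3f%% clipped at 0", mufa)
        mufa = 0.0
    return mufa


def omega_ratio(I: IntegralSet) -> float:
    """omega-6 : omega-3 ratio, linoleic over alpha-linolenic (= 2 I2.77/I2.81)."""
    if I.i281 <= 0:
        raise ValueError("omega ratio undefined: I2.81 is zero")
    return pct_linoleic(I) / pct_alpha_linolenic(I)


@dataclass
class CompositionReport:
    """Per-sample fatty-acid composition, mol % of acyl chains."""

    alpha_linolenic: float
    linoleic: float
    cla_ct: float
    cla_tt: float
    caproleic: float
    caproleic_alt: float
    ufa: float
    mufa: float
    sfa: float
    omega_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


def quantify(I: IntegralSet) -> CompositionReport:
    """Apply the full set of composition equations to one integral set."""
    cap_h9, cap_h10a = pct_caproleic(I)
    try:
        omega = omega_ratio(I)
    except ValueError:
        omega = float("nan")
    return CompositionReport(
        alpha_linolenic=pct_alpha_linolenic(I),
        linoleic=pct_linoleic(I),
        cla_ct=pct_cla_ct(I),
        cla_tt=pct_cla_tt(I),
        caproleic=cap_h9,
        caproleic_alt=cap_h10a,
        ufa=pct_ufa(I),
        mufa=pct_mufa(I),
        sfa=pct_sfa(I),
        omega_ratio=omega,
    )


def precision_stats(replicates) -> tuple[float, float]:
    """Coefficient of variation (%) and precision 1 - rsd over replicates.

    Uses the sample standard deviation (ddof=1); requires at least two
    replicate values and a non-zero mean.
    """
    vals = np.asarray(list(replicates), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicate values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("replicate mean is zero")
    rsd = vals.std(ddof=1) / abs(mean)
    return 100.0 * rsd, 1.0 - rsd


def relative_deviation(test_value: float, reference_value: float) -> float:
    """Percent relative deviation of a test value from a reference value."""
    if reference_value == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (test_value - reference_value) / reference_value
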