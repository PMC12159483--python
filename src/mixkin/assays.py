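"""Closed-form assay conversions from raw instrument readings.

These are the arithmetic conversions used to express raw weights,
absorbances and titres in the quality-index units the rest of the package
consumes: water-holding capacity and syneresis (mass %), DPPH radical
inhibition (%), total monomeric anthocyanin (umol/100 g), TBA reactive
substances and free fatty acids.

The water-holding formula computes the non-sediment mass fraction as the
source protocol states it; ``convention="sediment"`` gives the more common
sediment-mass variant.
"""

from __future__ import annotations

import warnings

from .errors import DomainError

__all__ = [
    "whc_percent",
    "syneresis_percent",
    "dpph_inhibition",
    "anthocyanin_umol",
    "tba_value",
    "ffa_value",
]

#: equivalent weight of KOH used in the free-fatty-acid titration
KOH_EQUIVALENT_WEIGHT = 56.1


def whc_percent(w_sample: float, w_sediment: float, convention: str = "supernatant") -> float:
    """Water-holding capacity (%) from sample and sediment weights (g).

    ``convention="supernatant"`` (default) returns the non-sediment fraction
    (sample - sediment)/sample x 100; ``"sediment"`` returns
    sediment/sample x 100.
    """
    if w_sample <= 0:
        raise DomainError("sample weight must be > 0")
    if not 0 <= w_sediment <= w_sample:
        raise DomainError("sediment weight must lie in [0, sample weight]")
    if convention == "supernatant":
        return (w_sample - w_sediment) / w_sample * 100.0
    if convention == "sediment":
        return w_sediment / w_sample * 100.0
    raise DomainError("convention must be 'supernatant' or 'sediment'")


def syneresis_percent(w_supernatant: float, w_sample: float) -> float:
    """Spontaneous whey separation (%) from supernatant and sample weights (g)."""
    if w_sample <= 0:
        raise DomainError("sample weight must be > 0")
    if not 0 <= w_supernatant <= w_sample:
        raise DomainError("supernatant weight must lie in [0, sample weight]")
    return w_supernatant / w_sample * 100.0


def dpph_inhibition(abs_control: float, abs_sample: float) -> float:
    """DPPH radical scavenging (%); negative (pro-oxidant) values pass with a warning."""
    if abs_control <= 0:
        raise DomainError("control absorbance must be > 0")
    pct = (abs_control - abs_sample) / abs_control * 100.0
    if pct < 0:
        warnings.warn("negative DPPH inhibition (pro-oxidant reading)", stacklevel=2)
    return pct


def anthocyanin_umol(abs534: float, abs643: float, abs661: float) -> float:
    """Total monomeric anthocyanin (umol/100 g) from three absorbances.

    (0.0821 A534 - 0.00687 A643 - 0.002426 A661) x 5, the x5 applying to the
    whole bracket.
    """
    if min(abs534, abs643, abs661) < 0:
        raise DomainError("absorbances must be >= 0")
    return (0.0821 * abs534 - 0.00687 * abs643 - 0.002426 * abs661) * 5.0


def tba_value(abs532: float) -> float:
    """TBA reactive substances from the 532 nm absorbance (7.8 x A532).

    The output scale follows the 7.8 molar factor; the storage fixtures
    report it as mg MDA/kg.
    """
    if abs532 < 0:
        raise DomainError("absorbance must be >= 0")
    return 7.8 * abs532


def ffa_value(titre_ml: float, normality: float, w_sample: float) -> float:
    """Free fatty acid value: titre x N(KOH) x 56.1 / sample weight (g)."""
    if w_sample <= 0:
        raise DomainError("sample weight must be > 0")
    if titre_ml < 0 or normality < 0:
        raise DomainError("titre and normality must be >= 0")
    return titre_ml * normality * KOH_EQUIVALENT_WEIGHT / w_sample
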