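"""Equilibrium size-spectrum comparative statics.

In the static size-spectrum framework the community-wide mean PPMR sets how
many trophic steps separate two body masses: each factor of PPMR in mass is
one trophic level.  The relative trophic level of a predator of mass ``target``
against a baseline mass ``ref`` is therefore log10(target/ref)/log10(PPMR).

Dynamic size-spectrum work suggests the *preferred* PPMR (the mode of the
log-normal feeding kernel under equal prey availability) is roughly 60% of
the mean *realized* PPMR measured from stomach contents; the helper below
applies that offset.
"""

from __future__ import annotations

import math

from .errors import InvalidMeasurementError, InvalidPPMRError

HARTVIG_PREFERRED_FACTOR = 0.60


def relative_trophic_level(target_mass: float, ref_mass: float, ppmr: float) -> float:
    """Trophic-level offset of ``target_mass`` relative to ``ref_mass``.

    Strictly decreasing in PPMR for target > ref, and additive over mass
    ratios: TL(a->c) = TL(a->b) + TL(b->c).
    """
    if ppmr <= 1:
        raise InvalidPPMRError(f"ppmr must exceed 1, got {ppmr}")
    if target_mass <= 0 or ref_mass <= 0:
        raise InvalidMeasurementError("masses must be positive")
    return math.log10(target_mass / ref_mass) / math.log10(ppmr)


def preferred_from_realized(
    realized_ppmr: float, factor: float = HARTVIG_PREFERRED_FACTOR
) -> float:
    """Approximate preferred PPMR as a fixed fraction of realized PPMR."""
    if realized_ppmr <= 0:
        raise InvalidMeasurementError("realized PPMR must be positive")
    return factor * realized_ppmr
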