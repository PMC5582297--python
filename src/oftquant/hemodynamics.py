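"""Outflow-tract band tightness.

Band tightness quantifies the severity of a suture constriction of the
embryonic outflow tract as the relative reduction of its maximum external
diameter at the band site:

    tightness = 1 - d_after / d_before

where ``d_before`` is the diameter at (approximately) the band location
before banding and ``d_after`` the diameter at the band site afterwards.
Experiments in this line of work restrict analysis to a 30-45% constriction
window, within which the induced wall-shear and pressure changes are
approximately constant; ``in_study_range`` screens measurements against
that window.
"""

from __future__ import annotations

from dataclasses import dataclass

STUDY_RANGE: tuple[float, float] = (0.30, 0.45)


@dataclass(frozen=True)
class DiameterPair:
    """Outflow-tract external diameters (μm) after/before banding."""

    d_after: float
    d_before: float

    def __post_init__(self) -> None:
        if self.d_before <= 0:
            raise ValueError("pre-band diameter must be positive")
        if self.d_after < 0:
            raise ValueError("post-band diameter must be non-negative")


def band_tightness(pair: DiameterPair) -> float:
    """Fractional constriction 1 - d_after/d_before (dimensionless)."""
    return 1.0 - pair.d_after / pair.d_before


def in_study_range(
    bt: float, lo: float = STUDY_RANGE[0], hi: float = STUDY_RANGE[1]
) -> bool:
    """True iff tightness lies in the inclusive [lo, hi] screening window."""
    if not 0.0 <= bt <= 1.0:
        raise ValueError("band tightness must lie in [0, 1]")
    return lo <= bt <= hi
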