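"""Frequency-band catalogue.

The analysis is run independently in six canonical bands of interest (BoIs):
theta, alpha, beta and three overlapping sub-bands of the gamma range. This
module is the single source of truth for band edges; nothing else in the
package hard-codes them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band of interest.

    Parameters
    ----------
    name : str
        Band label (e.g. ``"alpha"``).
    lo, hi : float
        Band edges in Hz, ``0 < lo < hi``.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"invalid band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )

    def validate_against_fs(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.hi} Hz >= Nyquist ({fs / 2} Hz)"
            )


#: Broadband range used for preprocessing and broadband covariance (Hz).
BROADBAND = BandDefinition("broadband", 1.0, 150.0)


def band_catalog() -> list[BandDefinition]:
    """Return the six bands of interest, in canonical order.

    theta (4-8), alpha (8-12), beta (13-30), gamma1 (30-40), gamma2 (35-45),
    gamma3 (40-48) Hz.
    """
    return [
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma1", 30.0, 40.0),
        BandDefinition("gamma2", 35.0, 45.0),
        BandDefinition("gamma3", 40.0, 48.0),
    ]


def get_band(name: str) -> BandDefinition:
    """Look up a catalogue band (or ``"broadband"``) by name."""
    if name == BROADBAND.name:
        return BROADBAND
    for b in band_catalog():
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")
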