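"""Spectral species and frequency-axis conventions for [1-13C]pyruvate MRSI.

The carbonyl region of the hyperpolarized [1-13C]pyruvate spectrum contains
pyruvate (Pyr) and its downstream products lactate (Lac, via LDH), 13C
bicarbonate (Bic, via PDH-mediated decarboxylation) and alanine (Ala, via
ALT), plus the pyruvate-hydrate side resonance.  Chemical shifts are the
standard in vivo assignments; the RF carrier is placed on the pyruvate
resonance so pyruvate appears at 0 Hz offset.
"""

from __future__ import annotations

from dataclasses import dataclass

PPM_MIN = 150.0
PPM_MAX = 195.0

#: carrier frequency position (on pyruvate), ppm
CARRIER_PPM = 171.0

#: 13C Larmor frequency at 3 T, MHz (1 ppm = 32.13 Hz)
DEFAULT_F0_MHZ = 32.13

_ALLOWED_NAMES = frozenset(
    {"pyruvate", "lactate", "bicarbonate", "alanine", "pyruvate_hydrate"}
)


@dataclass(frozen=True)
class MetabolitePeak:
    """A single 13C resonance.

    Parameters
    ----------
    name
        One of ``pyruvate``, ``lactate``, ``bicarbonate``, ``alanine``,
        ``pyruvate_hydrate``.
    chemical_shift
        Position in ppm (carbonyl region, 150-195 ppm).
    t2star
        Apparent transverse decay time in seconds; the in vivo linewidth is
        1/(pi*t2star), about 20 Hz at the 0.016 s default.
    """

    name: str
    chemical_shift: float
    t2star: float = 0.016

    def __post_init__(self) -> None:
        if self.name not in _ALLOWED_NAMES:
            raise ValueError(f"unknown metabolite name {self.name!r}")
        if not (PPM_MIN <= self.chemical_shift <= PPM_MAX):
            raise ValueError(
                f"chemical shift {self.chemical_shift} ppm outside "
                f"[{PPM_MIN}, {PPM_MAX}] ppm"
            )
        if self.t2star <= 0:
            raise ValueError("t2star must be positive")


PYRUVATE = MetabolitePeak("pyruvate", 171.0)
LACTATE = MetabolitePeak("lactate", 183.2)
BICARBONATE = MetabolitePeak("bicarbonate", 161.1)
ALANINE = MetabolitePeak("alanine", 176.5)
PYRUVATE_HYDRATE = MetabolitePeak("pyruvate_hydrate", 179.5)

#: the four quantified species, in the order used throughout the package
DEFAULT_PEAKS = (PYRUVATE, LACTATE, BICARBONATE, ALANINE)

#: kinetic pool order used by :mod:`hpcsi.kinetics`
METABOLITES = ("pyruvate", "lactate", "bicarbonate", "alanine")


def offset_hz(
    peak: MetabolitePeak,
    f0_mhz: float = DEFAULT_F0_MHZ,
    carrier_ppm: float = CARRIER_PPM,
) -> float:
    """Resonance offset of *peak* from the carrier, in Hz."""
    return (peak.chemical_shift - carrier_ppm) * f0_mhz


def hz_to_ppm(
    freq_hz,
    f0_mhz: float = DEFAULT_F0_MHZ,
    carrier_ppm: float = CARRIER_PPM,
):
    """Convert a frequency-offset axis (Hz from carrier) to ppm."""
    return carrier_ppm + freq_hz / f0_mhz
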