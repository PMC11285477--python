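"""Prey body-mass bookkeeping for the two wolf populations.

Mean prey body masses are diet-weighted means over the reported prey spectra
of the Alaskan and Swedish populations; the species masses and the weighted
means are carried as study inputs.
"""

from __future__ import annotations

#: prey species body masses (kg) and the diet-weighted mean per population
PREY_BODY_MASS = {
    "Alaska": {
        "moose": 360.0,
        "caribou": 120.0,
        "beaver": 20.0,
        "snow hare": 5.0,
        "muskrat": 1.5,
        "rodents": 1.0,
    },
    "Sweden": {
        "moose": 360.0,
        "Cervidae": 50.0,
        "roe deer": 30.0,
        "beaver": 20.0,
        "rodents": 1.0,
        "birds": 1.0,
    },
}

#: diet-weighted mean prey body mass (kg) per population
MEAN_PREY_MASS = {"Alaska": 196.36, "Sweden": 253.30}


def relative_mass_difference(mass_large: float, mass_small: float) -> float:
    """How much larger (in %) the larger mean prey mass is, relative to itself.

    The convention expresses the gap as a fraction of the larger mean:
    100 × (m_large − m_small) / m_large.
    """
    if mass_large <= 0:
        raise ValueError("masses must be positive")
    return 100.0 * (mass_large - mass_small) / mass_large


def prey_size_gap() -> float:
    """Percent by which Swedish wolves' mean prey mass exceeds the Alaskan one."""
    return relative_mass_difference(MEAN_PREY_MASS["Sweden"], MEAN_PREY_MASS["Alaska"])
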