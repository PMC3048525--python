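"""Volumes and molecule-count/concentration conversions.

Signaling reactions occur cell-wide and use the cellular volume; the
transcription factors Gal4p and Gal4-80p act in the nucleus and are
converted at the nuclear volume when handed to the promoter model.
"""

AVOGADRO = 6.022e23

#: Cellular volume, liters (haploid budding yeast).
CELL_VOLUME_L = 23e-15

#: Nuclear volume, liters.
NUCLEAR_VOLUME_L = 1.66e-15


def counts_to_molar(count: float, volume_l: float = CELL_VOLUME_L) -> float:
    """Molecule count -> molar concentration at the given volume."""
    return count / (AVOGADRO * volume_l)


def molar_to_counts(conc: float, volume_l: float = CELL_VOLUME_L) -> float:
    return conc * AVOGADRO * volume_l


def counts_to_nanomolar(count: float, volume_l: float = CELL_VOLUME_L) -> float:
    return counts_to_molar(count, volume_l) * 1e9
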