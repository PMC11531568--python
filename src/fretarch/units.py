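"""Central length-unit conversions.

FRET-side modules (photophysics, trace processing, PDA, discrimination)
work in nanometres; structure-side modules (AV engine, structural metrics)
work in Ångström, matching PDB coordinates.
"""

ANGSTROM_PER_NM = 10.0


def nm_to_angstrom(x: float) -> float:
    return x * ANGSTROM_PER_NM


def angstrom_to_nm(x: float) -> float:
    return x / ANGSTROM_PER_NM
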