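"""Shared physical constants."""

#: Molecules per (nM * µm^3): Avogadro constant scaled so that
#: concentration [nmol/L] * volume [µm^3] * NA_NM_UM3 = molecule count.
NA_NM_UM3 = 0.602214086
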