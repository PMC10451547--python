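"""Physical constants (SI)."""

R_GAS = 8.314  # J mol^-1 K^-1
FARADAY = 96485.0  # C mol^-1

#: Default generation-cell temperature (37 degC reaction vessel).
T_GENERATION = 310.15  # K
#: Default mediator-cell temperature (25 degC ferri/ferrocyanide cell).
T_MEDIATOR = 298.15  # K


def nernst_slope(temperature: float, natural: bool = True) -> float:
    """RT/F in volts per natural-log unit (or per decade if ``natural=False``)."""
    s = R_GAS * temperature / FARADAY
    return s if natural else s * 2.302585092994046
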