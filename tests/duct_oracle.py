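"""Independent test oracle: exact rectangular-duct resistance.

The production code approximates the friction of a shallow rectangular
channel with a one-term expression.  This oracle evaluates the full
double-series solution of pressure-driven flow in a rectangular duct of
width w >= height h:

    R = 12 eta L / (w h^3 * [1 - sum_{n odd} (192/pi^5) (h/w) n^-5
                                 tanh(n pi w / (2 h))])

Used only in tests, never by the package itself.
"""

import math


def exact_rect_duct_resistance(
    width: float, height: float, length: float, viscosity: float, n_terms: int = 101
) -> float:
    if height > width:
        raise ValueError("oracle expects h <= w")
    h_over_w = height / width
    series = sum(
        math.tanh(n * math.pi * width / (2.0 * height)) / n**5
        for n in range(1, n_terms, 2)
    )
    bracket = 1.0 - (192.0 / math.pi**5) * h_over_w * series
    return 12.0 * viscosity * length / (width * height**3 * bracket)
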