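"""Reference constants for water stable-isotope arithmetic.

Delta values (δ²H, δ¹⁸O) are expressed in per mil (‰) against VSMOW,
the Vienna Standard Mean Ocean Water reference. The absolute isotope
amount ratios of VSMOW used to convert delta values to atom percent are
the community reference values; they can be overridden per analysis via
:class:`IsotopeConstants`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: ²H/¹H isotope amount ratio of VSMOW.
R_VSMOW_2H = 1.5576e-4
#: ¹⁸O/¹⁶O isotope amount ratio of VSMOW.
R_VSMOW_18O = 2.0052e-3

#: Global meteoric water line: δ²H = 8·δ¹⁸O + 10‰.
GMWL_SLOPE = 8.0
GMWL_INTERCEPT = 10.0


@dataclass(frozen=True)
class IsotopeConstants:
    """Bundle of reference constants used throughout the isotope stage."""

    r_standard_2h: float = R_VSMOW_2H
    r_standard_18o: float = R_VSMOW_18O
    gmwl_slope: float = GMWL_SLOPE
    gmwl_intercept: float = GMWL_INTERCEPT

    def __post_init__(self) -> None:
        if self.r_standard_2h <= 0 or self.r_standard_18o <= 0:
            raise ValueError("isotope reference ratios must be strictly positive")


DEFAULT_CONSTANTS = IsotopeConstants()
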