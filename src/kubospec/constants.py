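"""Physical constants and unit conversions.

All user-facing frequencies are wavenumbers (cm^-1) and all times are
picoseconds, the units in which carbonyl-band parameters are conventionally
reported.  Internally the line-broadening function needs angular frequencies
in rad/ps, hence the single conversion factor below.
"""

import math

#: Speed of light in cm/ps.
C_CM_PER_PS = 0.0299792458

#: Multiply a wavenumber in cm^-1 by this to get an angular frequency in
#: rad/ps (2*pi*c with c in cm/ps, ~0.18837 rad/ps per cm^-1).
CM1_TO_RADPS = 2.0 * math.pi * C_CM_PER_PS
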