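"""Default study conditions for simulations and benchmarks.

These are the conditions the validation simulations emulate: a membrane
receptor tracked at video rate with sub-diffraction localization error.
The spring constant 0.3 pN/um is the experimental-scale value for the
toxin-receptor system the method was developed on; the quartic strength is
chosen so the quartic well's stationary per-axis variance matches the
spring case, making the two confinement models directly comparable.
"""

from __future__ import annotations

from .models import (
    KT_310,
    quartic_strength_matching_spring,
    spring_constant_to_kT,
)

#: diffusion coefficient, um^2/s
D = 0.1
#: acquisition interval, s
DT = 0.05
#: static localization noise, um
SIGMA = 0.03
#: spring constant, pN/um
K_PN = 0.3
#: spring constant in thermal units, kBT/um^2 (~70.1 at 310 K)
K_KT = spring_constant_to_kT(K_PN, KT_310)
#: quartic strength, kBT/um^4, matched to the spring's stationary variance
U_KT = quartic_strength_matching_spring(K_KT)
#: sliding-window size, frames
WINDOW = 51
#: low-pass persistence, window positions
PERSISTENCE = 3
#: minimum zone duration, central frames (half a window)
MIN_ZONE = 25
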