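"""Physical constants and unit conventions.

Internally everything runs in a single unit system:

* lengths in nm (MDAnalysis positions, reported in Angstrom, are divided
  by 10 on read),
* DRID moments in nm^-1,
* times in ps, rates in ps^-1,
* free energies in units of k_B T.
"""

from scipy.constants import Boltzmann as K_B  # J/K
from scipy.constants import Planck as H  # J s

import numpy as np

#: picoseconds per second
PS_PER_S = 1e12

#: Angstrom per nm (MDAnalysis native length unit is Angstrom)
ANGSTROM_PER_NM = 10.0


def eyring_prefactor(temperature: float) -> float:
    """k_B T / h expressed in ps^-1 (the attempt frequency of Eyring theory)."""
    return K_B * temperature / H / PS_PER_S


def log_eyring_prefactor(temperature: float) -> float:
    """ln(k_B T / h * 1 ps): the dimensionless barrier offset for rates in ps^-1.

    At 310 K this evaluates to about 1.8655.
    """
    return float(np.log(eyring_prefactor(temperature)))
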