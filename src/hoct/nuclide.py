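"""Physical constants for ¹⁶⁶Ho and the holmium compounds used in phantoms.

¹⁶⁶Ho decays to stable ¹⁶⁶Er with a 26.82 h half-life, emitting two
high-energy beta branches (endpoint 1.77 MeV at 49.9%/decay and 1.85 MeV at
48.8%/decay), a low-yield 0.08 MeV gamma line (6.6%/decay) that keeps
patient quarantine short, and a small low-energy conversion-electron /
Auger / x-ray component whose sub-voxel ranges make it effectively a local
deposit.
"""

from __future__ import annotations

import numpy as np

#: ¹⁶⁶Ho physical half-life in hours.
HALF_LIFE_H: float = 26.82

#: ¹⁶⁶Ho physical half-life in seconds.
HALF_LIFE_S: float = HALF_LIFE_H * 3600.0

#: Decay constant λ = ln2 / t½ in s⁻¹ (≈ 7.18 × 10⁻⁶).
DECAY_CONSTANT_PER_S: float = float(np.log(2) / HALF_LIFE_S)

#: Beta branches as (endpoint energy MeV, yield per decay).
BETA_BRANCHES: tuple[tuple[float, float], ...] = ((1.77, 0.499), (1.85, 0.488))

#: Gamma lines as (energy MeV, yield per decay).
PHOTON_LINES: tuple[tuple[float, float], ...] = ((0.08, 0.066),)

#: Lumped conversion-electron/Auger/x-ray component (mean MeV, yield per
#: decay); deposited locally at the source voxel since its range is
#: sub-voxel on millimetre grids.
LOCAL_COMPONENT: tuple[float, float] = (0.030, 0.15)

#: Transport cutoff in keV; particles below it deposit locally.
ENERGY_CUTOFF_KEV: float = 1.0

#: Mass fraction of elemental Ho in the Ho-PLLA microspheres (19.7%).
HO_MS_CONTENT_FRACTION: float = 0.197

# Standard atomic weights (IUPAC 2021, u)
_M_HO = 164.930329
_M_CL = 35.45
_M_H = 1.008
_M_O = 15.999


def hocl3_hexahydrate_ho_fraction() -> float:
    """Mass fraction of elemental Ho in HoCl₃·6H₂O (≈ 0.43).

    Computed from standard atomic weights; the calibration phantom stock
    solution is prepared from this salt, so its Ho content fixes the
    concentration scale.
    """
    m_total = _M_HO + 3 * _M_CL + 6 * (2 * _M_H + _M_O)
    return _M_HO / m_total
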