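"""Physical constants and unit conventions.

Internal unit system (the standard membrane-model convention):

==============  ==========
quantity        unit
==============  ==========
voltage         mV
time            ms
conductance     mS/cm^2
current         uA/cm^2
concentration   mM
length          um
capacitance     uF/cm^2
==============  ==========

Pump and exchanger densities are quoted in the literature in mA/cm^2 and are
converted (x1000) to uA/cm^2 at load.
"""

import math

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

#: Model temperature, degrees C.
TEMP_C = 36.0
TEMP_K = TEMP_C + 273.15

#: RT/F at model temperature, in mV.
RTF_MV = 1000.0 * GAS_CONSTANT * TEMP_K / FARADAY

#: Q10 factor 3^((T-37)/10) applied to most dendritic channel kinetics.
MT_37 = 3.0 ** ((TEMP_C - 37.0) / 10.0)
#: Q10 factor for the Kv1.2 current, referenced to 22 C.
MT_22 = 3.0 ** ((TEMP_C - 22.0) / 10.0)
#: Q10 factor 2.3^((T-36)/10) for the M-type current (unity at 36 C).
FT_36 = 2.3 ** ((TEMP_C - 36.0) / 10.0)

#: Fixed reversal potential for dendritic Ca currents, mV.
E_CA_DEND = 135.0

#: GHK flux constants for the somatic P-type Ca current (fixed, not coupled to
#: the shell Ca pool): permeability cm/s, concentrations mM, temperature K.
GHK_P_CA = 5e-5
GHK_CA_I = 1e-4  # 100 nM
GHK_CA_O = 2.0
GHK_TEMP_K = 295.0

#: Extracellular Na, mM (fixed); with [Na]_i = 10 mM gives E_Na = +70.3 mV.
NA_OUT = 140.0

#: Default fixed intracellular K (mM) closing the dendritic Nernst relation.
K_IN_DEND = 45.0


def nernst(c_out: float, c_in: float, z: int = 1) -> float:
    """Nernst potential in mV at the model temperature."""
    return RTF_MV / z * math.log(c_out / c_in)
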