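"""Physical constants and shared conventions.

All frequency offsets in this package are reported in MHz relative to the
observer carrier (carrier at 0 MHz); absolute microwave frequencies are in
GHz, magnetic fields in mT, pulse lengths and inter-pulse delays in ns
(centre-to-centre), decay times in us unless stated otherwise.
"""

#: Dipolar constant of a nitroxide spin-label pair, MHz nm^3.
#: The perpendicular dipolar frequency of a pair at distance r is D / r^3.
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04

#: Nominal gyromagnetic ratio of a nitroxide radical (g ~ 2.0059), MHz/mT.
#: Used only as the a-priori field <-> frequency conversion before the
#: echo-detected field sweep refines it.
GAMMA_NITROXIDE_MHZ_PER_MT = 28.079

#: Safety margin applied to the Nyquist sampling criterion when converting a
#: pump-pulse time step into a minimum detectable distance.
NYQUIST_SAFETY = 0.85

#: The Pake pattern has shoulders at twice the perpendicular dipolar
#: frequency, so the sampling rule uses a factor of 4 instead of 2.
PAKE_SHOULDER_FACTOR = 4.0
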