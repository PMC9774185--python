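"""Physical constants and package-wide unit conventions.

Internal units: time ms, current pA, concentration uM (ligand) or mM (bulk
ions), voltage mV (membrane convention, intracellular minus extracellular),
temperature K.
"""

GAS_CONSTANT_J = 8.314462618  # J / (mol K)
GAS_CONSTANT_KCAL = 1.987204258e-3  # kcal / (mol K)
FARADAY = 96485.33212  # C / mol

ROOM_TEMPERATURE_K = 295.15  # 22 C, the recording temperature default

#: Gaussian low-pass filter: -3 dB cutoff f_c corresponds to a time-domain
#: standard deviation of 0.1325/f_c, and the shortest event still reaching
#: half amplitude (the dead time) is 0.179/f_c.
GAUSSIAN_SIGMA_FACTOR = 0.13252
DEAD_TIME_FACTOR = 0.179
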