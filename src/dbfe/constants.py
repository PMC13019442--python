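"""Repo-wide unit conventions.

Lengths in angstrom, energies in kcal/mol, temperatures in Kelvin.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Standard-state volume per molecule at 1 M, cubic angstrom.
V_STANDARD = 1660.0

#: Surface volume of the unit quaternion sphere S^3 (the uniform rotational
#: reference measure; antipodal double cover used consistently everywhere).
import math

S3_VOLUME = 2.0 * math.pi**2

#: Default temperature (K) matching the simulation protocol conventions.
DEFAULT_TEMPERATURE = 300.0
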