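"""Unit conversion constants.

Internal unit system: lengths in mm, time in s, pressure in mmHg, blood
viscosity in mPa s.  Stresses are reported in dyn cm^-2.
"""

import zlib

import numpy as np

#: 1 mmHg in Pa.
MMHG_TO_PA = 133.322387415

#: 1 mmHg in dyn cm^-2 (1 dyn cm^-2 = 0.1 Pa).
MMHG_TO_DYN_CM2 = MMHG_TO_PA * 10.0

#: Poiseuille conductance conversion: with D and L in mm and mu in mPa s,
#: g = pi D^4 / (128 mu L) * POISEUILLE_UNIT_FACTOR gives flow in mm^3 s^-1
#: per mmHg of pressure drop.
POISEUILLE_UNIT_FACTOR = MMHG_TO_PA * 1.0e3

#: 32 mu Q / (pi D^3) with mu in mPa s, Q in mm^3 s^-1, D in mm yields a
#: stress in mPa; multiply by this to obtain dyn cm^-2.
MPA_TO_DYN_CM2 = 1.0e-2

#: ... and by this to obtain mmHg.
MPA_TO_MMHG = 1.0e-3 / MMHG_TO_PA


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, independent RNG stream from a single run seed.

    Each consumer (scenario generation, migration, branching, ...) pulls
    from its own stream so that adding draws to one stage does not perturb
    the others.  The mapping is stable across runs and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
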