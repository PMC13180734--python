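"""neobag: apnoea of prematurity and EEG brain-age-gap analysis.

Tools for linking the apnoea rate of moderate-to-late preterm infants
(from impedance pneumography) to the maturity of their brain activity
(an EEG-derived brain age relative to postmenstrual age), including a
synthetic cohort generator, inter-breath-interval density functions,
and the mixed-model / bootstrap / E-value statistics.
"""

from . import (densities, desaturation, evoked, gap, resting, respiration,
               stats, synthetic)

__all__ = ["densities", "desaturation", "evoked", "gap", "resting",
           "respiration", "stats", "synthetic", "pipeline"]
__version__ = "0.1.0"


def __getattr__(name):
    if name == "pipeline":
        from . import pipeline
        return pipeline
    raise AttributeError(name)
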