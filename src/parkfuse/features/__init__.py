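"""Hand-crafted baseline representations.

Speech: articulation (488), phonation (28) and prosody (103) descriptors;
video: 255-dimensional local-binary-pattern lip-texture histograms.
"""

import numpy as np

from .articulation import ARTICULATION_DIM, articulation_feature_names, articulation_features
from .functionals import FUNCTIONAL_NAMES, functionals
from .lbp import LBP_DIM, lbp_code, lbp_features, lbp_histogram, lbp_image
from .phonation import PHONATION_DIM, jitter_shimmer, phonation_feature_names, phonation_features
from .prosody import PROSODY_DIM, prosody_feature_names, prosody_features
from .voicing import F0Contour, TransitionSet, detect_transitions, f0_contour, voiced_runs

SPEECH_FULL_DIM = ARTICULATION_DIM + PHONATION_DIM + PROSODY_DIM  # 619


def speech_features(samples, rate: int = 48_000) -> np.ndarray:
    """Concatenated articulation + phonation + prosody vector (619 values)."""
    return np.concatenate(
        [
            articulation_features(samples, rate),
            phonation_features(samples, rate),
            prosody_features(samples, rate),
        ]
    )


__all__ = [
    "ARTICULATION_DIM",
    "PHONATION_DIM",
    "PROSODY_DIM",
    "LBP_DIM",
    "SPEECH_FULL_DIM",
    "FUNCTIONAL_NAMES",
    "functionals",
    "f0_contour",
    "detect_transitions",
    "voiced_runs",
    "F0Contour",
    "TransitionSet",
    "jitter_shimmer",
    "phonation_features",
    "articulation_features",
    "prosody_features",
    "speech_features",
    "lbp_code",
    "lbp_image",
    "lbp_histogram",
    "lbp_features",
    "phonation_feature_names",
    "articulation_feature_names",
    "prosody_feature_names",
]
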