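"""Reference confusion matrices from the published sheep-lameness study.

Leave-one-out QDA confusion matrices for the three accelerometer
deployments (ear, collar, leg), as reported for the two analysis variants:
Analysis I keeps lame grazing alongside lame walking and the sound
behaviours; Analysis II drops lame grazing.  Rows are predicted behaviours,
columns observed behaviours (the orientation used throughout this package).
These tables are inputs for exercising the performance-metric arithmetic
(sensitivity, specificity, accuracy, precision, per-class prediction
accuracy) against the values reported alongside them; they are not outputs
of this package's classifier.
"""

from __future__ import annotations

import numpy as np

from .validation import ConfusionMatrix

_A2_CLASSES_4 = ["sound_grazing", "sound_standing", "sound_walking", "lame_walking"]
_A2_CLASSES_5 = ["sound_grazing", "sound_standing", "sound_walking", "sound_lying",
                 "lame_walking"]
_A1_CLASSES_5 = ["sound_grazing", "sound_standing", "sound_walking",
                 "lame_walking", "lame_grazing"]
_A1_CLASSES_6 = ["sound_grazing", "sound_standing", "sound_walking", "sound_lying",
                 "lame_walking", "lame_grazing"]

# Analysis II (no lame grazing); rows predicted, columns observed.
_ANALYSIS_II = {
    "ear": (_A2_CLASSES_4, [
        [321, 26, 1, 6],
        [15, 830, 1, 3],
        [2, 5, 262, 9],
        [4, 0, 9, 80],
    ]),
    "collar": (_A2_CLASSES_5, [
        [283, 26, 2, 0, 0],
        [13, 53, 10, 12, 9],
        [2, 15, 60, 8, 42],
        [0, 12, 23, 18, 6],
        [0, 0, 0, 2, 31],
    ]),
    "leg": (_A2_CLASSES_5, [
        [266, 44, 0, 0, 3],
        [26, 61, 0, 0, 6],
        [0, 0, 60, 0, 3],
        [0, 0, 0, 46, 0],
        [6, 1, 34, 0, 81],
    ]),
}

# Analysis I (lame grazing retained); rows predicted, columns observed.
_ANALYSIS_I = {
    "ear": (_A1_CLASSES_5, [
        [287, 42, 5, 6, 131],
        [44, 812, 2, 3, 11],
        [1, 4, 241, 9, 3],
        [0, 0, 14, 78, 3],
        [10, 3, 11, 2, 34],
    ]),
    "collar": (_A1_CLASSES_6, [
        [281, 26, 0, 0, 0, 39],
        [12, 53, 12, 3, 29, 14],
        [0, 22, 77, 13, 13, 2],
        [2, 5, 5, 22, 4, 4],
        [0, 0, 0, 1, 11, 4],
        [3, 0, 0, 0, 20, 108],
    ]),
    "leg": (_A1_CLASSES_6, [
        [262, 34, 0, 0, 5, 55],
        [33, 71, 0, 0, 6, 105],
        [0, 0, 81, 0, 2, 0],
        [2, 0, 0, 46, 0, 8],
        [1, 0, 13, 0, 80, 6],
        [0, 1, 0, 0, 0, 7],
    ]),
}


def reference_confusion_matrix(deployment: str, analysis: str = "II") -> ConfusionMatrix:
    """Published LOOCV confusion matrix for one deployment and analysis.

    Parameters
    ----------
    deployment : {'ear', 'collar', 'leg'}
    analysis : {'I', 'II'}
        'I' includes lame grazing; 'II' excludes it.
    """
    table = {"I": _ANALYSIS_I, "II": _ANALYSIS_II}.get(analysis)
    if table is None:
        raise ValueError("analysis must be 'I' or 'II'")
    if deployment not in table:
        raise ValueError("deployment must be one of 'ear', 'collar', 'leg'")
    classes, counts = table[deployment]
    return ConfusionMatrix(classes=list(classes), counts=np.array(counts))


def reference_confusion_matrices(analysis: str = "II") -> dict[str, ConfusionMatrix]:
    """All three deployments' published matrices for one analysis."""
    return {d: reference_confusion_matrix(d, analysis) for d in ("ear", "collar", "leg")}
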