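"""Per-epoch movement metrics for tri-axial acceleration.

Fourteen features per 10 s epoch, computed on raw gravity-inclusive samples
in g:

* ``Ax``, ``Ay``, ``Az`` — mean acceleration per axis.
* ``MV`` (movement variation) — mean absolute sample-to-sample difference
  summed over the three axes: (1/T) * (sum|dx| + sum|dy| + sum|dz|).
* ``SMA`` (signal magnitude area) — (1/T) * (sum|x| + sum|y| + sum|z|).
* ``AI`` (average intensity) — mean instantaneous vector magnitude
  (1/T) * sum sqrt(x^2 + y^2 + z^2).
* ``Entropy`` — (1/T) * sum (1 + Ts_i) ln(1 + Ts_i) with Ts_i = x_i + y_i + z_i.
* ``Energy`` — (1/T) * sum (TSS_i)^2 with TSS_i = x_i^2 + y_i^2 + z_i^2.
* ``MaxX/Y/Z``, ``MinX/Y/Z`` — per-axis epoch extrema.

The entropy sum is defined for (1 + Ts) > 0; since axes can be negative in
g, the default guard evaluates a non-positive term as (1+Ts)·ln|1+Ts| (0 at
Ts = -1) and emits a warning; set ``entropy_guard='reject'`` to refuse such
epochs instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import BEHAVIOURS, AnnotatedEpoch

FEATURE_NAMES = (
    "Ax", "Ay", "Az", "MV", "SMA", "AI", "Entropy", "Energy",
    "MaxX", "MaxY", "MaxZ", "MinX", "MinY", "MinZ",
)

#: Class sets for the two analyses: the first keeps lame walking and lame
#: grazing alongside the sound behaviours; the second drops lame grazing,
#: which is heavily confused with sound grazing.  Lame standing and lame
#: lying are excluded from both (indistinguishable from their sound
#: counterparts).
ANALYSIS_CLASSES = {
    "I": ("sound_grazing", "sound_standing", "sound_walking", "sound_lying",
          "lame_walking", "lame_grazing"),
    "II": ("sound_grazing", "sound_standing", "sound_walking", "sound_lying",
           "lame_walking"),
}


def compute_features(epoch: AnnotatedEpoch, entropy_guard: str = "warn") -> dict[str, float]:
    """Compute the fourteen movement metrics for one epoch.

    Parameters
    ----------
    epoch : AnnotatedEpoch
        Window of T >= 2 samples, shape (T, 3), finite.
    entropy_guard : {'warn', 'reject'}
        Handling of entropy terms with (1 + x+y+z) <= 0.

    Returns
    -------
    dict mapping each of ``FEATURE_NAMES`` to a float.
    """
    s = epoch.samples
    if s.shape[0] < 2:
        raise ValueError("epoch must contain at least 2 samples")
    if not np.all(np.isfinite(s)):
        raise ValueError("epoch contains non-finite samples")
    if entropy_guard not in ("warn", "reject"):
        raise ValueError("entropy_guard must be 'warn' or 'reject'")
    T = s.shape[0]
    x, y, z = s[:, 0], s[:, 1], s[:, 2]

    means = s.mean(axis=0)
    mv = np.sum(np.abs(np.diff(s, axis=0))) / T
    sma = np.sum(np.abs(s)) / T
    ai = np.mean(np.sqrt(np.sum(s * s, axis=1)))

    one_plus_ts = 1.0 + (x + y + z)
    if np.any(one_plus_ts <= 0):
        if entropy_guard == "reject":
            raise ValueError(
                "entropy undefined: some samples have 1 + x + y + z <= 0")
        warnings.warn(
            "entropy terms with 1 + x + y + z <= 0 evaluated as "
            "(1+Ts)*ln|1+Ts|", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_terms = np.where(
            one_plus_ts != 0.0,
            one_plus_ts * np.log(np.abs(one_plus_ts)),
            0.0,
        )
    entropy = float(np.sum(log_terms) / T)

    tss = np.sum(s * s, axis=1)
    energy = float(np.sum(tss * tss) / T)

    maxs = s.max(axis=0)
    mins = s.min(axis=0)
    return {
        "Ax": float(means[0]), "Ay": float(means[1]), "Az": float(means[2]),
        "MV": float(mv), "SMA": float(sma), "AI": float(ai),
        "Entropy": entropy, "Energy": energy,
        "MaxX": float(maxs[0]), "MaxY": float(maxs[1]), "MaxZ": float(maxs[2]),
        "MinX": float(mins[0]), "MinY": float(mins[1]), "MinZ": float(mins[2]),
    }


def build_feature_matrix(epochs: list[AnnotatedEpoch], analysis: str | None = None,
                         entropy_guard: str = "warn") -> pd.DataFrame:
    """Stack per-epoch features into one labelled matrix.

    One row per epoch in stable (animal_id, start_time) order, with the 14
    feature columns plus ``behaviour``, ``animal_id``, ``deployment`` and
    ``start_time``.  All epochs must share a deployment.  ``analysis`` of
    'I' or 'II' restricts rows to that analysis' class set; None keeps all
    behaviours.
    """
    if not epochs:
        raise ValueError("no epochs provided")
    deployments = {e.deployment for e in epochs}
    if len(deployments) > 1:
        raise ValueError(
            f"epochs mix deployments {sorted(deployments)}; build one matrix "
            "per deployment")
    if analysis is not None:
        if analysis not in ANALYSIS_CLASSES:
            raise ValueError("analysis must be 'I', 'II', or None")
        keep = set(ANALYSIS_CLASSES[analysis])
        epochs = [e for e in epochs if e.behaviour in keep]
        if not epochs:
            raise ValueError(f"no epochs left after Analysis {analysis} class filter")
    epochs = sorted(epochs, key=lambda e: (e.animal_id, e.start_time))
    rows = []
    for e in epochs:
        row = compute_features(e, entropy_guard=entropy_guard)
        row["behaviour"] = e.behaviour
        row["animal_id"] = e.animal_id
        row["deployment"] = e.deployment
        row["start_time"] = e.start_time
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES)
                        + ["behaviour", "animal_id", "deployment", "start_time"])


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    return df


class EpochFeatureExtractor:
    """Transformer turning annotated epochs into a labelled feature matrix.

    Stateless aside from its parameters; ``fit`` is a no-op so the extractor
    slots into scikit-learn style pipelines.
    """

    def __init__(self, analysis: str | None = None, entropy_guard: str = "warn"):
        self.analysis = analysis
        self.entropy_guard = entropy_guard

    def get_params(self, deep: bool = True) -> dict:
        return {"analysis": self.analysis, "entropy_guard": self.entropy_guard}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("analysis", "entropy_guard"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, epochs, y=None):
        return self

    def transform(self, epochs) -> pd.DataFrame:
        return build_feature_matrix(epochs, analysis=self.analysis,
                                    entropy_guard=self.entropy_guard)

    def fit_transform(self, epochs, y=None) -> pd.DataFrame:
        return self.fit(epochs).transform(epochs)
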