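"""Synthetic tri-axial gait-signal generator for sheep behaviour studies.

Generates labelled accelerometer records with the statistical structure the
classification pipeline assumes, so the whole analysis can be exercised
without field data.  The signal model per behaviour is

    a_axis(t) = gravity_axis
              + amp_axis * [ sin(2*pi*f*t + phi_axis)
                             + asymmetry * sin(4*pi*f*t + 2*phi_axis) ]
              + white Gaussian noise (sd = noise_sd)

i.e. a gravity offset, a stride/head-swing oscillation with an
asymmetry-weighted second harmonic, and sensor noise, in units of g.
Static postures (standing, lying) have zero oscillation.  Lameness is
encoded on walking as an amplitude multiplier plus second-harmonic
distortion — the sensor sees a larger, asymmetric swing from the head-bob of
an animal avoiding weight on one foreleg — and on grazing as a reduced
step component that deliberately overlaps the sound-grazing signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .io import (
    BEHAVIOURS,
    DEPLOYMENTS,
    AccelSeries,
    Annotation,
    phase_of,
    write_accel_csv,
    write_annotations,
)

#: Fixed per-axis phase offsets of the oscillation (radians).
AXIS_PHASES = (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)

#: Lame walking amplitude multiplier relative to sound walking.
LAME_WALK_AMP_FACTOR = 1.8
#: Second-harmonic distortion coefficient for lame walking.
LAME_WALK_ASYMMETRY = 0.4
#: Lame grazing step-component multiplier relative to sound grazing.
LAME_GRAZE_AMP_FACTOR = 0.6


@dataclass
class BehaviourParams:
    """Signal-model parameters for one behaviour.

    Attributes
    ----------
    behaviour : str
        One of the eight sound/lame behaviour labels.
    gravity_orientation : ndarray, shape (3,)
        Unit vector of the static gravity component (g).
    osc_freq_hz : float
        Stride or head-swing fundamental frequency; 0 for static states.
    osc_amp : ndarray, shape (3,)
        Per-axis oscillation amplitude (g), >= 0.
    asymmetry : float
        Second-harmonic distortion coefficient in [0, 1].
    noise_sd : float
        White-noise standard deviation (g), >= 0.
    """

    behaviour: str
    gravity_orientation: np.ndarray
    osc_freq_hz: float = 0.0
    osc_amp: np.ndarray = field(default_factory=lambda: np.zeros(3))
    asymmetry: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.gravity_orientation = np.asarray(self.gravity_orientation, dtype=float)
        self.osc_amp = np.asarray(self.osc_amp, dtype=float)
        if self.gravity_orientation.shape != (3,) or self.osc_amp.shape != (3,):
            raise ValueError("gravity_orientation and osc_amp must be 3-vectors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.osc_amp < 0):
            raise ValueError("osc_amp must be >= 0 componentwise")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.osc_freq_hz < 0:
            raise ValueError("osc_freq_hz must be >= 0")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def default_behaviour_params() -> dict[str, BehaviourParams]:
    """Default signal parameters per behaviour.

    Sound walking carries a 1.5 Hz stride oscillation; lame walking has the
    same stride frequency but 1.8x the amplitude plus a 0.4 second-harmonic
    distortion.  Grazing is a slower head swing with the head-down gravity
    orientation; lame grazing keeps that posture with a reduced (0.6x) step
    component so that it overlaps sound grazing.  Standing and lying are
    static with distinct sensor orientations.  All values are in g; sensor
    noise sd is 0.03 g.
    """
    noise = 0.03
    upright = _unit([0.95, 0.1, 0.3])
    head_down = _unit([0.5, 0.2, 0.84])
    recumbent = _unit([0.15, 0.95, 0.27])
    walk_amp = np.array([0.30, 0.18, 0.24])
    graze_amp = np.array([0.10, 0.07, 0.08])
    return {
        "sound_standing": BehaviourParams(
            "sound_standing", upright, 0.0, np.zeros(3), 0.0, noise),
        "sound_lying": BehaviourParams(
            "sound_lying", recumbent, 0.0, np.zeros(3), 0.0, noise),
        "sound_grazing": BehaviourParams(
            "sound_grazing", head_down, 0.8, graze_amp, 0.0, noise),
        "sound_walking": BehaviourParams(
            "sound_walking", upright, 1.5, walk_amp, 0.0, noise),
        "lame_walking": BehaviourParams(
            "lame_walking", upright, 1.5, LAME_WALK_AMP_FACTOR * walk_amp,
            LAME_WALK_ASYMMETRY, noise),
        "lame_grazing": BehaviourParams(
            "lame_grazing", head_down, 0.8, LAME_GRAZE_AMP_FACTOR * graze_amp,
            0.0, noise),
        "lame_standing": BehaviourParams(
            "lame_standing", upright, 0.0, np.zeros(3), 0.0, noise),
        "lame_lying": BehaviourParams(
            "lame_lying", recumbent, 0.0, np.zeros(3), 0.0, noise),
    }


#: Epochs per behaviour for each deployment in the default study shape
#: (totals across animals).
DEFAULT_EPOCH_COUNTS: dict[str, dict[str, int]] = {
    "collar": {
        "sound_walking": 95, "sound_standing": 106, "sound_grazing": 298,
        "sound_lying": 40, "lame_walking": 88, "lame_standing": 62,
        "lame_grazing": 171, "lame_lying": 236,
    },
    "leg": {
        "sound_walking": 94, "sound_standing": 106, "sound_grazing": 298,
        "sound_lying": 46, "lame_walking": 92, "lame_standing": 93,
        "lame_grazing": 181, "lame_lying": 279,
    },
    "ear": {
        "sound_walking": 274, "sound_standing": 862, "sound_grazing": 342,
        "sound_lying": 0, "lame_walking": 98, "lame_standing": 97,
        "lame_grazing": 182, "lame_lying": 279,
    },
}


@dataclass
class StudyConfig:
    """Shape and randomness of a synthetic deployment study.

    ``epoch_counts`` maps behaviour label to the total number of complete
    10 s epochs the study should yield per deployment (split near-evenly
    across animals).  ``per_animal_sd`` is the sigma of the multiplicative
    log-normal perturbation applied to each animal's oscillation amplitudes,
    so that cross-validation cannot memorise a single waveform.
    """

    animals: int = 5
    sample_rate_hz: float = 12.0
    epoch_s: float = 10.0
    epoch_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EPOCH_COUNTS["ear"]))
    deployments: tuple[str, ...] = ("ear",)
    seed: int = 0
    per_animal_sd: float = 0.15
    behaviour_params: dict[str, BehaviourParams] = field(
        default_factory=default_behaviour_params)

    def __post_init__(self) -> None:
        if self.animals < 1:
            raise ValueError("animals must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for b, c in self.epoch_counts.items():
            if b not in BEHAVIOURS:
                raise ValueError(f"unknown behaviour {b!r} in epoch_counts")
            if c < 0:
                raise ValueError("epoch_counts values must be >= 0")
        for d in self.deployments:
            if d not in DEPLOYMENTS:
                raise ValueError(f"unknown deployment {d!r}")


def default_study_config(deployment: str = "ear", seed: int = 0,
                         animals: int = 5, **kwargs) -> StudyConfig:
    """Study config whose epoch counts mirror the default study shape."""
    if deployment not in DEFAULT_EPOCH_COUNTS:
        raise ValueError(f"unknown deployment {deployment!r}")
    return StudyConfig(
        animals=animals,
        epoch_counts=dict(DEFAULT_EPOCH_COUNTS[deployment]),
        deployments=(deployment,),
        seed=seed,
        **kwargs,
    )


def generate_behaviour_signal(params: BehaviourParams, duration_s: float,
                              rate_hz: float, seed: int,
                              animal_id: str = "sim",
                              deployment: str = "ear",
                              t0: float = 0.0) -> AccelSeries:
    """Generate one behaviour's tri-axial signal.

    Returns ``floor(duration_s * rate_hz)`` samples of
    gravity + oscillation + Gaussian noise.  Identical ``(params, seed)``
    give identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n = int(math.floor(duration_s * rate_hz + 1e-9))
    if n == 0:
        raise ValueError("duration too short for one sample at this rate")
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)
    xyz = np.empty((n, 3))
    for axis in range(3):
        sig = np.full(n, params.gravity_orientation[axis])
        if params.osc_freq_hz > 0 and params.osc_amp[axis] > 0:
            w = 2.0 * math.pi * params.osc_freq_hz
            phi = AXIS_PHASES[axis]
            sig = sig + params.osc_amp[axis] * (
                np.sin(w * t + phi)
                + params.asymmetry * np.sin(2.0 * w * t + 2.0 * phi)
            )
        xyz[:, axis] = sig
    if params.noise_sd > 0:
        xyz += rng.normal(0.0, params.noise_sd, size=(n, 3))
    return AccelSeries(
        times=t0 + t, x=xyz[:, 0], y=xyz[:, 1], z=xyz[:, 2],
        rate_hz=rate_hz, animal_id=animal_id, deployment=deployment,
    )


def _animal_counts(total: int, animals: int) -> list[int]:
    base, rem = divmod(total, animals)
    return [base + (1 if i < rem else 0) for i in range(animals)]


def _perturb(params: BehaviourParams, factors: np.ndarray) -> BehaviourParams:
    return replace(params, osc_amp=params.osc_amp * factors)


def generate_study(config: StudyConfig
                   ) -> dict[tuple[str, str], tuple[AccelSeries, list[Annotation]]]:
    """Generate a full labelled study: one record per animal x deployment.

    Each record concatenates one contiguous block per behaviour (epoch-count
    multiples of 10 s) separated by 10 s 'transition' gaps, so downstream
    segmentation recovers exactly ``epoch_counts`` complete epochs per
    behaviour per deployment.  Per-animal log-normal amplitude factors are
    shared across deployments.  Fully reproducible under ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    animal_ss, stream_ss = ss.spawn(2)
    animal_rngs = animal_ss.spawn(config.animals)
    # Per-animal amplitude factors, shared across deployments.
    factors = {}
    for i, child in enumerate(animal_rngs):
        rng = np.random.default_rng(child)
        factors[i] = {
            b: np.exp(rng.normal(0.0, config.per_animal_sd, size=3))
            for b in BEHAVIOURS
        }

    behaviours = [b for b in BEHAVIOURS if config.epoch_counts.get(b, 0) > 0]
    per_animal = {
        b: _animal_counts(config.epoch_counts[b], config.animals)
        for b in behaviours
    }
    transition_params = BehaviourParams(
        "sound_standing",
        default_behaviour_params()["sound_standing"].gravity_orientation,
        noise_sd=config.behaviour_params["sound_standing"].noise_sd,
    )

    study: dict[tuple[str, str], tuple[AccelSeries, list[Annotation]]] = {}
    seed_rng = np.random.default_rng(stream_ss)
    for i in range(config.animals):
        animal_id = f"animal{i + 1:02d}"
        for deployment in config.deployments:
            segments: list[AccelSeries] = []
            annotations: list[Annotation] = []
            t0 = 0.0
            blocks = [b for b in behaviours if per_animal[b][i] > 0]
            for j, b in enumerate(blocks):
                if j > 0:  # 10 s transition gap, excluded downstream
                    seg = generate_behaviour_signal(
                        transition_params, config.epoch_s, config.sample_rate_hz,
                        seed=int(seed_rng.integers(2**31)),
                        animal_id=animal_id, deployment=deployment, t0=t0)
                    segments.append(seg)
                    annotations.append(Annotation(
                        t0, t0 + config.epoch_s, "transition",
                        animal_id, "reserved", deployment))
                    t0 += config.epoch_s
                dur = per_animal[b][i] * config.epoch_s
                params = _perturb(config.behaviour_params[b], factors[i][b])
                seg = generate_behaviour_signal(
                    params, dur, config.sample_rate_hz,
                    seed=int(seed_rng.integers(2**31)),
                    animal_id=animal_id, deployment=deployment, t0=t0)
                segments.append(seg)
                annotations.append(Annotation(
                    t0, t0 + dur, b, animal_id, phase_of(b), deployment))
                t0 += dur
            series = AccelSeries(
                times=np.concatenate([s.times for s in segments]),
                x=np.concatenate([s.x for s in segments]),
                y=np.concatenate([s.y for s in segments]),
                z=np.concatenate([s.z for s in segments]),
                rate_hz=config.sample_rate_hz,
                animal_id=animal_id, deployment=deployment,
            )
            study[(animal_id, deployment)] = (series, annotations)
    return study


def write_study(study, outdir, config: StudyConfig | None = None) -> None:
    """Write one accel/annotation CSV pair per animal x deployment."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (animal_id, deployment), (series, annotations) in sorted(study.items()):
        write_accel_csv(series, outdir / f"{animal_id}_{deployment}_accel.csv")
        write_annotations(annotations, outdir / f"{animal_id}_{deployment}_annotations.csv")
    if config is not None:
        write_config(config, outdir / "study_config.yaml")


def write_config(config: StudyConfig, path) -> None:
    doc = {
        "animals": config.animals,
        "sample_rate_hz": config.sample_rate_hz,
        "epoch_s": config.epoch_s,
        "epoch_counts": dict(config.epoch_counts),
        "deployments": list(config.deployments),
        "seed": config.seed,
        "per_animal_sd": config.per_animal_sd,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_config(path) -> StudyConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return StudyConfig(
        animals=doc.get("animals", 5),
        sample_rate_hz=doc.get("sample_rate_hz", 12.0),
        epoch_s=doc.get("epoch_s", 10.0),
        epoch_counts=doc.get("epoch_counts", dict(DEFAULT_EPOCH_COUNTS["ear"])),
        deployments=tuple(doc.get("deployments", ("ear",))),
        seed=doc.get("seed", 0),
        per_animal_sd=doc.get("per_animal_sd", 0.15),
    )
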