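import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20180112)


def make_epoch(samples, behaviour="sound_standing", animal_id="a1",
               deployment="ear", start_time=0.0):
    from lamegait.io import AnnotatedEpoch

    return AnnotatedEpoch(
        samples=np.asarray(samples, dtype=float), behaviour=behaviour,
        animal_id=animal_id, deployment=deployment, start_time=start_time)


def random_epoch(rng, n=120, scale=1.0, behaviour="sound_walking", **kw):
    return make_epoch(rng.normal(0.0, scale, size=(n, 3)), behaviour=behaviour, **kw)


def naive_features(samples):
    """Per-sample loop evaluation of the 14 metric formulas (test oracle)."""
    import math

    s = np.asarray(samples, dtype=float)
    T = s.shape[0]
    x, y, z = s[:, 0], s[:, 1], s[:, 2]
    out = {}
    out["Ax"] = sum(x) / T
    out["Ay"] = sum(y) / T
    out["Az"] = sum(z) / T
    mv = 0.0
    for i in range(T - 1):
        mv += abs(x[i + 1] - x[i]) + abs(y[i + 1] - y[i]) + abs(z[i + 1] - z[i])
    out["MV"] = mv / T
    out["SMA"] = (sum(abs(v) for v in x) + sum(abs(v) for v in y)
                  + sum(abs(v) for v in z)) / T
    out["AI"] = sum(math.sqrt(x[i] ** 2 + y[i] ** 2 + z[i] ** 2)
                    for i in range(T)) / T
    ent = 0.0
    for i in range(T):
        u = 1.0 + x[i] + y[i] + z[i]
        if u != 0.0:
            ent += u * math.log(abs(u))
    out["Entropy"] = ent / T
    out["Energy"] = sum((x[i] ** 2 + y[i] ** 2 + z[i] ** 2) ** 2
                        for i in range(T)) / T
    out["MaxX"], out["MaxY"], out["MaxZ"] = max(x), max(y), max(z)
    out["MinX"], out["MinY"], out["MinZ"] = min(x), min(y), min(z)
    return out
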