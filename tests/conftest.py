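import numpy as np
import pytest

from icgperf import (FluorescenceVideo, KineticParams, default_pouch_layout,
                     make_gain_field, render_video)
from icgperf.io import BackgroundStats, PerfusionCurve


@pytest.fixture
def std_params():
    """Reference bolus kinetics: baseline 5, amplitude 100, arrival 10 s,
    time-to-peak 8 s, shape 2 (noiseless)."""
    return KineticParams(baseline=5.0, amplitude=100.0, t_arrival=10.0,
                         time_to_peak=8.0, shape=2.0, noise_sd=0.0)


@pytest.fixture
def noiseless_video(std_params):
    layout = default_pouch_layout(body=std_params, apex=std_params,
                                  height=16, width=32)
    video, truth = render_video(layout, duration=120.0, frame_rate=4.0, seed=0)
    return video, truth, layout


@pytest.fixture
def textured_noisy_video():
    body = KineticParams(5.0, 100.0, 10.0, 8.0, 2.0, 0.5)
    apex = KineticParams(6.0, 80.0, 11.0, 9.0, 2.2, 0.5)
    layout = default_pouch_layout(body=body, apex=apex,
                                  gain=make_gain_field((36, 48), seed=53))
    video, truth = render_video(layout, duration=120.0, frame_rate=4.0, seed=3)
    return video, truth, layout


@pytest.fixture
def quiet_bg():
    """Zero-noise background stats (noiseless recordings)."""
    return BackgroundStats(mean=5.0, sd=0.0, slope_sd=0.0, n_pixels=25)


def make_curve(params: KineticParams, frame_rate: float = 4.0,
               duration: float = 120.0) -> PerfusionCurve:
    """Noiseless analytic perfusion curve sampled on the frame grid."""
    from icgperf import gamma_variate_curve

    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    return PerfusionCurve(roi_id=1, location="body", t=t,
                          intensity=np.asarray(gamma_variate_curve(params, t)))


def dense_grid_features(params: KineticParams, duration: float = 120.0,
                        dt: float = 1e-4) -> dict:
    """Brute-force oracle: perfusion indicators from a dense-grid
    finite-difference evaluation of the analytic curve (independent of the
    closed forms used by the package)."""
    from icgperf import gamma_variate_curve

    t = np.arange(0.0, duration, dt)
    y = np.asarray(gamma_variate_curve(params, t))
    s = np.gradient(y, dt)
    i_peak = int(np.argmax(y))
    t_max = t[i_peak]
    t_begin = t[np.argmax(s > 0)]
    rise = (t >= t_begin) & (t <= t_max)
    egress_val = (np.interp(t_max + 5.0, t, y) - y[i_peak]) / 5.0
    return {
        "t_ingress_begin": t_begin,
        "t_max": t_max,
        "i_max": y[i_peak],
        "ingress": (y[i_peak] - np.interp(t_begin, t, y)) / (t_max - t_begin),
        "max_ingress": float(s[rise].max()),
        "egress": egress_val,
        "max_egress": float(s[t > t_max].min()),
    }
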