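import numpy as np
import pytest

from organoid_quant.core_io import Image2D, ImageStack3D, Movie


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bimodal_image(rng):
    """Two-population intensity image with known labels (low/high modes)."""
    labels = rng.random((64, 64)) < 0.3
    pixels = np.where(labels, rng.normal(0.8, 0.05, (64, 64)), rng.normal(0.2, 0.05, (64, 64)))
    return Image2D(np.clip(pixels, 0, 1)), labels


@pytest.fixture
def cylinder_and_sphere_stack():
    """One straight tube plus one solid sphere of the same radius, zero background."""
    shape = (24, 96, 96)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    radius = 3
    tube = ((zz - 12) ** 2 + (yy - 30) ** 2) <= radius**2  # runs along x
    sphere = ((zz - 12) ** 2 + (yy - 70) ** 2 + (xx - 48) ** 2) <= radius**2
    vol = np.where(tube | sphere, 1.0, 0.0)
    return ImageStack3D(vol, voxel_size_um=(0.2, 0.133, 0.133)), tube, sphere


def make_trace_from_kernel(
    tau_r=0.5, tau_d=2.0, amp=0.05, onset_s=10.0, duration_s=40.0, rate=4.0, noise_sd=0.0, seed=0
):
    """Build a DffTrace holding one (or zero, if amp=0) rise×decay transient."""
    from organoid_quant.calcium_activity import DffTrace, kernel_peak_factor
    from scipy import ndimage as ndi

    t = np.arange(int(duration_s * rate)) / rate
    dt = np.clip(t - onset_s, 0, None)
    v = amp / kernel_peak_factor(tau_r, tau_d) * (1 - np.exp(-dt / tau_r)) * np.exp(-dt / tau_d)
    v[t < onset_s] = 0.0
    if noise_sd:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, len(v))
    smoothed = ndi.uniform_filter1d(v, size=3, mode="nearest")
    return DffTrace(
        values=smoothed,
        f0=np.ones_like(v),
        frame_rate_hz=rate,
        smooth_window_frames=3,
        raw_values=v,
    )
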