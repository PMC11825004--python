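"""Shared fixtures: small rendered scenes and matching platform configs.

Scenes are rendered once per session; tests that need variants build
them locally from the same specs via ``dataclasses.replace``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import pillartrack as pt


@pytest.fixture(scope="session")
def clean_spec() -> pt.SceneSpec:
    """Small, artifact-free circular-pillar scene (fast to render)."""
    return pt.SceneSpec(
        pillar_kind="circle", frame_shape=(100, 240), fps=100.0,
        duration_s=0.6, waveform="sine", freq_hz=2.0, amp_px=8.0,
        gap0_px=120.0, circle_radius_px=12.0, tissue_axes_px=(95.0, 36.0),
        noise_sigma=0.0, rng_seed=5)


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    stack, truth = pt.render_video(clean_spec)
    return clean_spec, stack, truth, pt.platform_for(clean_spec)


@pytest.fixture(scope="session")
def rect_spec() -> pt.SceneSpec:
    """Small rectangular-pillar scene with V-wedge, noise and bubbles."""
    return pt.SceneSpec(
        pillar_kind="rectangle", frame_shape=(100, 240), fps=100.0,
        duration_s=0.6, waveform="pulse", freq_hz=2.0, amp_px=8.0,
        gap0_px=120.0, rect_dims_px=(26.0, 16.0),
        tissue_axes_px=(95.0, 36.0), v_wedge_area_px2=150.0,
        noise_sigma=5.0, n_bubbles=3, shadow_strength=0.1, rng_seed=7)


@pytest.fixture(scope="session")
def rect_scene(rect_spec):
    stack, truth = pt.render_video(rect_spec)
    return rect_spec, stack, truth, pt.platform_for(rect_spec)


@pytest.fixture(scope="session")
def clean_tracked(clean_scene):
    spec, stack, truth, cfg = clean_scene
    return pt.track(stack, cfg)


@pytest.fixture(scope="session")
def circle_config() -> pt.PlatformConfig:
    """Generic circular platform at 1 µm/px for hand-built fixtures."""
    return pt.PlatformConfig(pillar_kind="circle", E=1e6, L=300.0, a=250.0,
                             diameter_um=24.0, um_per_px=1.0, fps=100.0)


def respec(spec: pt.SceneSpec, **kw) -> pt.SceneSpec:
    return dataclasses.replace(spec, **kw)


def render_disk(shape: tuple[int, int], center: tuple[float, float],
                radius: float, ss: int = 8) -> np.ndarray:
    """Anti-aliased boolean disk (coverage >= 0.5) for oracle fixtures."""
    rr = (np.arange(shape[0] * ss) + 0.5) / ss - 0.5
    cc = (np.arange(shape[1] * ss) + 0.5) / ss - 0.5
    d2 = (rr[:, None] - center[0]) ** 2 + (cc[None, :] - center[1]) ** 2
    cov = (d2 <= radius ** 2).astype(float)
    cov = cov.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))
    return cov >= 0.5
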