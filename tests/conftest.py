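"""Shared fixtures: small synthetic profiles, scenes, and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import thermomimic as tm
from thermomimic import evaluate as ev
from thermomimic import synthetic


@pytest.fixture(scope="session")
def small_shape():
    return (16, 16)


@pytest.fixture(scope="session")
def quiet_profile(small_shape):
    """Noiseless camera: identity PSF, no β, no temporal noise."""
    return tm.CameraProfile(name="quiet", fps=10.0, fpa=small_shape, psf=None)


@pytest.fixture(scope="session")
def noisy_profile(small_shape):
    """Fully characterized synthetic low-cost camera at 16x16."""
    return synthetic.make_camera_profile(
        "noisy",
        fps=5.0,
        shape=small_shape,
        sigma_hf_C=0.07,
        drift_amplitude_C=0.3,
        drift_period_s=60.0,
        psf_sigma_px=1.2,
        beta_rms_C=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_shape):
    return synthetic.SkinSceneConfig(
        shape=small_shape,
        fps_truth=10.0,
        duration_s=90.0,
        lesion_radius_px=4.0,
        seed=3,
    )


def _cohort_scene(shape, seed):
    return synthetic.SkinSceneConfig(
        shape=shape,
        fps_truth=2.0,
        duration_s=90.0,
        lesion_radius_px=4.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort_summaries():
    """Per-record summaries for a small planted-offset cohort.

    10 benign and 10 malignant lesions (mixed subclasses) rendered
    noiselessly at 12x12, 2 fps, 90 s — enough separation for the
    classifier sanity checks and cheap enough for the default run.
    """
    shape = (12, 12)
    labels = ["benign"] * 10 + ["MM", "MM", "BCC", "BCC", "BCC", "BCC", "SCC", "SCC", "BCC", "MM"]
    summaries = []
    for idx, label in enumerate(labels):
        record = synthetic.generate_acquisition(_cohort_scene(shape, seed=100 + idx), label)
        summaries.append(ev.prepare_record_summary(record, p=0.02))
    return summaries


@pytest.fixture(scope="session")
def separable_summaries():
    """Cohort in the separable limit: planted θ offset ≫ spread (spreads /10)."""
    shape = (12, 12)
    labels = ["benign"] * 8 + ["MM", "MM", "BCC", "BCC", "SCC", "SCC", "BCC", "BCC"]

    def tighten(dist):
        return synthetic.ThetaDistribution(mean=dist.mean.copy(), sd=dist.sd / 10.0)

    summaries = []
    for idx, label in enumerate(labels):
        base = _cohort_scene(shape, seed=500 + idx)
        scene = synthetic.SkinSceneConfig(
            shape=shape,
            fps_truth=base.fps_truth,
            duration_s=base.duration_s,
            lesion_radius_px=base.lesion_radius_px,
            theta_benign=tighten(base.theta_benign),
            theta_lesion_benign=tighten(base.theta_lesion_benign),
            theta_lesion_malignant=tighten(base.theta_lesion_malignant),
            seed=base.seed,
        )
        record = synthetic.generate_acquisition(scene, label)
        summaries.append(ev.prepare_record_summary(record, p=0.02))
    return summaries
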