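"""Shared fixtures and geometry helpers for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from phenocloud import PlantSpec, generate_plant, train_from_cloud

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def cylinder_points(P, a, r, length, n, sigma=0.0, rng=None):
    """Sample n points on (or near) a cylinder coat; independent of the
    package's own generator."""
    rng = rng or np.random.default_rng(0)
    a = np.asarray(a, float)
    a = a / np.linalg.norm(a)
    ref = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    t = rng.uniform(0, length, n)
    ph = rng.uniform(0, 2 * np.pi, n)
    pts = (np.asarray(P, float) + t[:, None] * a
           + r * (np.cos(ph)[:, None] * e1 + np.sin(ph)[:, None] * e2))
    if sigma > 0:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return pts


def tilted_axis(tilt_deg, az_deg=0.0):
    t, az = np.radians(tilt_deg), np.radians(az_deg)
    return np.array([np.sin(t) * np.cos(az), np.sin(t) * np.sin(az), np.cos(t)])


TRAIN_SPEC = PlantSpec(n_stems=3, stem_radius=[1.5, 2.0, 2.5],
                       stem_length=[100, 120, 90], n_leaves=7,
                       leaf_length=55, leaf_width=8, seed=42)


@pytest.fixture(scope="session")
def training_plant():
    return generate_plant(TRAIN_SPEC)


@pytest.fixture(scope="session")
def trained_model(training_plant):
    cloud, _ = training_plant
    return train_from_cloud(cloud)
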