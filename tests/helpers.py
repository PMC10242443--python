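"""Shared synthetic point-cloud factories for the shape-analysis tests."""

import numpy as np


def make_straight_cloud(rng, n=60, sigma=0.02, length=1.0, angle=0.0):
    """Noisy points along a straight segment of given length and angle."""
    t = rng.uniform(0.0, length, n)
    pts = np.column_stack([t, np.zeros(n)])
    c, s = np.cos(angle), np.sin(angle)
    pts = pts @ np.array([[c, s], [-s, c]])
    return pts + rng.normal(0.0, sigma, (n, 2))


def make_l_cloud(rng, n=80, sigma=0.02, arm=1.0):
    """Noisy points on two orthogonal arms meeting at (arm, 0)."""
    u = rng.uniform(0.0, arm, n)
    on_first = rng.random(n) < 0.5
    pts = np.where(
        on_first[:, None],
        np.column_stack([u, np.zeros(n)]),
        np.column_stack([np.full(n, arm), u]),
    )
    return pts + rng.normal(0.0, sigma, (n, 2))
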