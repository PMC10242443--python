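"""Point/segment/polyline distance primitives used by the simulator and the
polyline fitter."""

from __future__ import annotations

import numpy as np

__all__ = ["segment_distances", "polyline_distances", "nearest_point_on_polyline"]


def segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to each segment [a_j, b_j].

    Parameters
    ----------
    points : (N, 2)
    a, b : (K, 2) segment endpoints.

    Returns
    -------
    (N, K) distance matrix.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom == 0.0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]
    t = np.clip((ap * ab[None, :, :]).sum(axis=-1) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - proj, axis=-1)


def polyline_distances(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest point of an open polyline."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[0] < 2:
        return np.linalg.norm(np.atleast_2d(points) - vertices[0], axis=-1)
    return segment_distances(points, vertices[:-1], vertices[1:]).min(axis=1)


def nearest_point_on_polyline(p: np.ndarray, vertices: np.ndarray) -> tuple[np.ndarray, float]:
    """Nearest point on an open polyline to a single 2D point, and its distance."""
    p = np.asarray(p, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    if vertices.shape[0] < 2:
        return vertices[0], float(np.linalg.norm(p - vertices[0]))
    a, b = vertices[:-1], vertices[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(p - proj, axis=1)
    j = int(np.argmin(d))
    return proj[j], float(d[j])
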