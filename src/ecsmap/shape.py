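"""Point-cloud shape analysis of tracer-covered areas.

Each tracked particle explores a cloud of localizations.  Clouds are first
fitted to ellipses (covariance eigen-decomposition); clouds whose
long-to-short axis ratio is below sqrt(2) are classed "0D" (punctate) and
assigned zero length.  Elongated ("1D") clouds are summarized by a polyline
whose segments are constrained to equal length, fitted by minimizing

    J = mean_i dist(p_i, polyline)^2 + lambda * (k * s)

where k*s is the total polyline length and lambda (um) a length penalty.  The
equal-length constraint is enforced exactly by the parameterization (start
vertex, common segment length s, per-segment headings), optimized by
derivative-free multi-start local search.  The segment count k is selected by
repeated 2-fold cross-validation on held-out mean squared point-to-polyline
distance, ties broken toward smaller k.

Estimators follow scikit-learn conventions (``fit(X)``, trailing-underscore
fitted attributes, ``get_params``/``set_params``); the module-level functions
are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .datatypes import SegmentSet
from .geometry import polyline_distances

__all__ = [
    "PointCloud",
    "EllipseFit",
    "ShapeClass",
    "PolylineFit",
    "EllipseShapeClassifier",
    "EqualLengthPolyline",
    "PolylineSegmentCV",
    "fit_ellipse",
    "classify_shape",
    "fit_polyline",
    "select_segment_count",
    "extract_segments",
    "default_penalty",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class PointCloud:
    """>= 3 2D localizations (um) belonging to one tracer-covered area."""

    points: np.ndarray
    area_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 3 or self.points.shape[1] != 2:
            raise ValueError("point cloud needs >= 3 2D points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates in point cloud")
        if np.allclose(self.points, self.points[0]):
            raise ValueError("all points identical; cloud has no shape")


@dataclass
class EllipseFit:
    centroid: np.ndarray
    a: float  # long half-axis scale (2*sqrt of larger covariance eigenvalue)
    b: float  # short half-axis scale
    orientation: float  # long-axis angle, radians in [0, pi)

    @property
    def ratio(self) -> float:
        return self.a / self.b if self.b > 0 else float("inf")


@dataclass
class ShapeClass:
    label: str  # "0D" or "1D"
    length: float = 0.0  # um; 0 for 0D, total polyline length for 1D


@dataclass
class PolylineFit:
    vertices: np.ndarray  # (k+1, 2)
    segment_length: float
    headings: np.ndarray  # (k,)
    mse: float  # mean squared point-to-polyline distance (training)
    penalty: float  # lambda used
    objective: float  # mse + penalty * k * segment_length
    cv_errors: dict[int, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return int(self.headings.size)

    @property
    def total_length(self) -> float:
        return self.k * self.segment_length


# ---------------------------------------------------------------------------
# ellipse classification


def _as_points(cloud) -> np.ndarray:
    return cloud.points if isinstance(cloud, PointCloud) else PointCloud(cloud).points


def fit_ellipse(cloud) -> EllipseFit:
    """Ellipse summary of a cloud from its sample-covariance eigenstructure.

    Axis scales are 2*sqrt(eigenvalue); only the ratio and the long-axis
    orientation are consumed downstream, so the scale constant is a
    convention.  Collinear clouds give b = 0 (ratio = inf).
    """
    pts = _as_points(cloud)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    major = evecs[:, 1]
    return EllipseFit(
        centroid=centroid,
        a=2.0 * math.sqrt(evals[1]),
        b=2.0 * math.sqrt(evals[0]),
        orientation=float(np.mod(math.atan2(major[1], major[0]), np.pi)),
    )


def classify_shape(ellipse: EllipseFit, threshold: float = SQRT2) -> ShapeClass:
    """0D if long/short axis ratio < threshold (default sqrt(2)), else 1D."""
    if ellipse.b == 0.0 or ellipse.ratio >= threshold:
        return ShapeClass("1D")
    return ShapeClass("0D", length=0.0)


class EllipseShapeClassifier(BaseEstimator):
    """Classify a localization cloud as punctate ("0D") or elongated ("1D").

    Parameters
    ----------
    threshold : float, default sqrt(2)
        Long/short axis-ratio cut below which the cloud is 0D.
    """

    def __init__(self, threshold: float = SQRT2):
        self.threshold = threshold

    def fit(self, X, y=None):
        e = fit_ellipse(np.asarray(X))
        self.centroid_ = e.centroid
        self.a_ = e.a
        self.b_ = e.b
        self.ratio_ = e.ratio
        self.orientation_ = e.orientation
        self.label_ = classify_shape(e, self.threshold).label
        return self

    def predict(self, X=None) -> str:
        return self.label_


# ---------------------------------------------------------------------------
# equal-length polyline fitting


def default_penalty(points: np.ndarray) -> float:
    """Scale-aware default length penalty: 0.1 x mean nearest-neighbor
    distance of the cloud (um)."""
    pts = np.atleast_2d(points)
    if pts.shape[0] < 2:
        return 0.0
    d, _ = cKDTree(pts).query(pts, k=2)
    return 0.1 * float(d[:, 1].mean())


def _mean_sq_dist(pts: np.ndarray, vertices: np.ndarray) -> float:
    """Mean squared point-to-polyline distance (allocation-lean hot path)."""
    a = vertices[:-1]
    ab = vertices[1:] - a
    denom = (ab * ab).sum(axis=1)
    np.copyto(denom, 1.0, where=denom == 0.0)
    ap = pts[:, None, :] - a
    t = np.clip((ap * ab).sum(axis=-1) / denom, 0.0, 1.0)
    resid = ap - t[..., None] * ab
    return float((resid * resid).sum(axis=-1).min(axis=1).mean())


def _vertices_from_params(params: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    s = abs(float(params[2]))
    headings = params[3 : 3 + k]
    steps = s * np.column_stack([np.cos(headings), np.sin(headings)])
    vertices = np.empty((k + 1, 2))
    vertices[0] = params[:2]
    vertices[1:] = params[:2] + np.cumsum(steps, axis=0)
    return vertices, s


def _pca_frame(pts: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(centroid, principal angle, projected span) of the cloud."""
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T, ddof=1)
    _, evecs = np.linalg.eigh(cov)
    u = evecs[:, 1]
    alpha = math.atan2(u[1], u[0])
    proj = (pts - centroid) @ u
    return centroid, alpha, float(proj.max() - proj.min())


class EqualLengthPolyline(BaseEstimator):
    """Length-penalized polyline of ``n_segments`` equal-length segments.

    Parameters
    ----------
    n_segments : int
        Number of segments k (>= 1).
    penalty : float or None
        Length penalty lambda (um); None selects the scale-aware default
        0.1 x mean nearest-neighbor distance at fit time.
    n_starts : int
        Multi-start count (principal-axis-aligned forward/backward starts
        plus random heading perturbations).
    random_state : int or None
        Seed for the random starts; fits are deterministic given the seed.

    Fitted attributes: ``vertices_`` (k+1, 2), ``segment_length_``,
    ``headings_``, ``mse_``, ``objective_``, ``penalty_``.
    """

    def __init__(
        self,
        n_segments: int = 1,
        penalty: float | None = None,
        n_starts: int = 8,
        random_state: int | None = None,
        maxfev_per_param: int = 120,
    ):
        self.n_segments = n_segments
        self.penalty = penalty
        self.n_starts = n_starts
        self.random_state = random_state
        self.maxfev_per_param = maxfev_per_param

    def _starts(self, pts: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
        k = self.n_segments
        centroid, alpha, span = _pca_frame(pts)
        span = max(span, 1e-6)
        u = np.array([math.cos(alpha), math.sin(alpha)])
        s0 = span / k
        ends = [centroid - u * span / 2.0, centroid + u * span / 2.0]
        starts = [
            np.concatenate([ends[0], [s0], np.full(k, alpha)]),
            np.concatenate([ends[1], [s0], np.full(k, alpha + math.pi)]),
        ]
        while len(starts) < self.n_starts:
            base = starts[len(starts) % 2]
            jitter = np.concatenate(
                [
                    rng.normal(0.0, 0.1 * span, 2),
                    [s0 * rng.uniform(0.5, 1.5)],
                    rng.normal(0.0, 0.7, k),
                ]
            )
            starts.append(base + jitter)
        return starts[: self.n_starts]

    def fit(self, X, y=None):
        pts = np.atleast_2d(np.asarray(X, dtype=float))
        if pts.shape[0] < 2:
            raise ValueError("need at least 2 points to fit a polyline")
        k = int(self.n_segments)
        if k < 1:
            raise ValueError("n_segments must be >= 1")
        lam = default_penalty(pts) if self.penalty is None else float(self.penalty)
        rng = np.random.default_rng(self.random_state)

        def objective(params: np.ndarray) -> float:
            vertices, s = _vertices_from_params(params, k)
            return _mean_sq_dist(pts, vertices) + lam * k * s

        best = None
        maxfev = self.maxfev_per_param * (k + 3)
        for x0 in self._starts(pts, rng):
            res = minimize(
                objective,
                x0,
                method="Powell",
                options={"maxfev": maxfev, "xtol": 1e-5, "ftol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("polyline optimization failed to converge from any start")
        vertices, s = _vertices_from_params(best.x, k)
        self.vertices_ = vertices
        self.segment_length_ = s
        self.headings_ = np.mod(
            np.arctan2(np.diff(vertices[:, 1]), np.diff(vertices[:, 0])), 2 * np.pi
        )
        d = polyline_distances(pts, vertices)
        self.mse_ = float(np.mean(d**2))
        self.penalty_ = lam
        self.objective_ = float(best.fun)
        return self

    def transform(self, X) -> np.ndarray:
        """Distance of each point to the fitted polyline (um)."""
        return polyline_distances(np.atleast_2d(np.asarray(X, dtype=float)), self.vertices_)

    def score(self, X, y=None) -> float:
        return -float(np.mean(self.transform(X) ** 2))

    def to_result(self, cv_errors: dict[int, float] | None = None) -> PolylineFit:
        return PolylineFit(
            vertices=self.vertices_,
            segment_length=self.segment_length_,
            headings=self.headings_,
            mse=self.mse_,
            penalty=self.penalty_,
            objective=self.objective_,
            cv_errors=dict(cv_errors or {}),
        )


class PolylineSegmentCV(BaseEstimator):
    """Select the polyline segment count by repeated 2-fold cross-validation.

    For each candidate k the points are split at random into two halves; a
    polyline is fitted on each half and scored by the mean squared
    point-to-polyline distance on the held-out half; CV(k) averages the two
    folds over ``n_repeats`` random splits.  The final model is refitted on
    all points at the selected k.

    CV estimates are noisy, so "ties toward smaller k" is realized by the
    one-standard-error parsimony rule: the smallest k whose CV error lies
    within one standard error (over folds) of the minimum is selected
    (``se_rule=False`` reverts to the strict argmin).

    ``split="time_block"`` replaces the random split by first-half/second-half
    of the point order (localization order is acquisition order).
    """

    def __init__(
        self,
        k_min: int = 1,
        k_max: int = 10,
        penalty: float | None = None,
        n_repeats: int = 5,
        cv_starts: int = 2,
        final_starts: int = 8,
        split: str = "random",
        se_rule: bool = True,
        random_state: int | None = None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.penalty = penalty
        self.n_repeats = n_repeats
        self.cv_starts = cv_starts
        self.final_starts = final_starts
        self.split = split
        self.se_rule = se_rule
        self.random_state = random_state

    def fit(self, X, y=None):
        pts = np.atleast_2d(np.asarray(X, dtype=float))
        n = pts.shape[0]
        if n < 8:
            raise ValueError("cross-validated selection needs >= 8 points")
        ks = list(range(int(self.k_min), int(self.k_max) + 1))
        if not ks:
            raise ValueError("empty segment-count range")
        lam = default_penalty(pts) if self.penalty is None else float(self.penalty)
        ss = np.random.SeedSequence(self.random_state)
        split_rng = np.random.default_rng(ss.spawn(1)[0])
        fit_seeds = iter(ss.spawn(2 * len(ks) * self.n_repeats))
        splits = []
        for _ in range(self.n_repeats):
            if self.split == "time_block":
                order = np.arange(n)
            else:
                order = split_rng.permutation(n)
            half = n // 2
            splits.append((order[:half], order[half:]))
            if self.split == "time_block":
                break  # deterministic split: repeats are identical
        cv: dict[int, float] = {}
        cv_se: dict[int, float] = {}
        for k in ks:
            errs = []
            for train_idx, test_idx in splits:
                for tr, te in ((train_idx, test_idx), (test_idx, train_idx)):
                    est = EqualLengthPolyline(
                        n_segments=k,
                        penalty=lam,
                        n_starts=self.cv_starts,
                        random_state=int(next(fit_seeds).generate_state(1)[0] % (2**31)),
                    ).fit(pts[tr])
                    errs.append(float(np.mean(est.transform(pts[te]) ** 2)))
            cv[k] = float(np.mean(errs))
            cv_se[k] = (
                float(np.std(errs, ddof=1) / math.sqrt(len(errs))) if len(errs) > 1 else 0.0
            )
        k_star = min(ks, key=lambda k: (cv[k], k))
        if self.se_rule:
            cut = cv[k_star] + cv_se[k_star]
            best_k = min(k for k in ks if cv[k] <= cut)
        else:
            best_k = k_star
        final_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        self.estimator_ = EqualLengthPolyline(
            n_segments=best_k,
            penalty=lam,
            n_starts=self.final_starts,
            random_state=final_seed,
        ).fit(pts)
        self.best_k_ = best_k
        self.cv_errors_ = cv
        self.cv_se_ = cv_se
        self.penalty_ = lam
        self.vertices_ = self.estimator_.vertices_
        self.segment_length_ = self.estimator_.segment_length_
        self.headings_ = self.estimator_.headings_
        self.mse_ = self.estimator_.mse_
        return self

    def transform(self, X) -> np.ndarray:
        return self.estimator_.transform(X)

    def to_result(self) -> PolylineFit:
        return self.estimator_.to_result(cv_errors=self.cv_errors_)


# ---------------------------------------------------------------------------
# functional wrappers


def fit_polyline(
    cloud,
    k: int,
    penalty: float | None = None,
    n_starts: int = 8,
    seed: int | None = None,
) -> PolylineFit:
    est = EqualLengthPolyline(
        n_segments=k, penalty=penalty, n_starts=n_starts, random_state=seed
    ).fit(_as_points(cloud) if not isinstance(cloud, np.ndarray) else cloud)
    return est.to_result()


def select_segment_count(
    cloud,
    k_range: range | tuple[int, int] = (1, 10),
    penalty: float | None = None,
    n_repeats: int = 5,
    seed: int | None = None,
    split: str = "random",
) -> PolylineFit:
    if isinstance(k_range, range):
        k_min, k_max = k_range.start, k_range.stop - 1
    else:
        k_min, k_max = k_range
    est = PolylineSegmentCV(
        k_min=k_min,
        k_max=k_max,
        penalty=penalty,
        n_repeats=n_repeats,
        split=split,
        random_state=seed,
    ).fit(_as_points(cloud) if not isinstance(cloud, np.ndarray) else cloud)
    return est.to_result()


def extract_segments(fit: PolylineFit, owner: str = "") -> SegmentSet:
    """Break a polyline into (axial orientation, length) segment pairs."""
    return SegmentSet(
        orientations=np.mod(fit.headings, np.pi),
        lengths=np.full(fit.k, fit.segment_length),
        owner=owner,
    )
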