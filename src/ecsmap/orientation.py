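"""Length-weighted axial orientation statistics and AIC model selection.

Segment orientations are axial (period pi).  Before fitting, angles are
doubled (phi = 2*theta on [0, 2pi)) so that axial data become ordinary
circular data; the circular normal (von Mises) law is then well defined.
Segment lengths enter the likelihood as fractional counts renormalized to the
number of segments (effective n), which keeps AIC values comparable across
segment sets with different total lengths.

Three candidate models are fitted to each set:

* uniform on the circle: logL = -n_eff * log(2*pi), 0 free parameters;
* one circular normal: weighted maximum likelihood (mean direction from the
  weighted circular mean, concentration by inverting the Bessel-function
  ratio A1(kappa) = I1/I0, capped at 500), 2 parameters (mu, kappa);
* a two-component circular-normal mixture whose centers differ by pi in
  doubled space (orthogonal orientations), free kappa1, kappa2 and weight,
  fitted by multi-start expectation-maximization, 4 parameters.

The best model is the one minimizing AIC = 2p - 2*logL, ties broken toward
fewer parameters.  A uniform winner means "no preferred orientation"; either
concentrated model means a preferred orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e, logsumexp
from sklearn.base import BaseEstimator

from .datatypes import SegmentSet

__all__ = [
    "OrientationModelFit",
    "orientation_histogram",
    "fit_orientation_models",
    "select_model",
    "AxialOrientationModelSelector",
    "KAPPA_CAP",
]

KAPPA_CAP = 500.0


@dataclass
class OrientationModelFit:
    model: str  # "uniform" | "vonmises" | "orthogonal_mixture"
    mu: float = 0.0  # mean orientation, [0, pi)
    kappa1: float = 0.0
    kappa2: float = 0.0
    weight: float = 1.0  # mixture weight of the component at mu
    loglik: float = 0.0
    n_params: int = 0
    aic: float = 0.0
    converged: bool = True

    @property
    def preferred_orientation(self) -> bool:
        """Maps the selected model onto the no-preference/preference dichotomy."""
        return self.model != "uniform"


def orientation_histogram(
    segs: SegmentSet, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Length-weighted histogram over [0, pi) with half-open bins.

    Returns (bin_edges, bin_mass); total mass equals the total segment length.
    """
    if segs.n < 1:
        raise ValueError("need at least one segment")
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    mass, _ = np.histogram(segs.orientations, bins=edges, weights=segs.lengths)
    return edges, mass


# ---------------------------------------------------------------------------
# circular-normal machinery (doubled angles)


def _log_bessel_i0(kappa: float) -> float:
    return kappa + math.log(i0e(kappa))


def _a1(kappa: float) -> float:
    return i1e(kappa) / i0e(kappa)


def _a1_inv(r: float) -> float:
    """Invert the mean-resultant-length equation A1(kappa) = r, capped."""
    if r <= 0.0:
        return 0.0
    if r >= _a1(KAPPA_CAP):
        return KAPPA_CAP
    return float(brentq(lambda k: _a1(k) - r, 1e-9, KAPPA_CAP, xtol=1e-10))


def _doubled(segs: SegmentSet) -> tuple[np.ndarray, np.ndarray, float]:
    """(phi, normalized weights, n_eff) with phi = 2*theta on [0, 2pi)."""
    phi = np.mod(2.0 * segs.orientations, 2.0 * np.pi)
    n_eff = float(segs.n)
    w = segs.lengths * (n_eff / segs.lengths.sum())
    return phi, w, n_eff


def _fit_uniform(n_eff: float) -> OrientationModelFit:
    ll = -n_eff * math.log(2.0 * math.pi)
    return OrientationModelFit("uniform", loglik=ll, n_params=0, aic=-2.0 * ll)


def _fit_vonmises(phi: np.ndarray, w: np.ndarray) -> OrientationModelFit:
    z = np.sum(w * np.exp(1j * phi))
    mu2 = float(np.angle(z)) % (2.0 * math.pi)
    rbar = abs(z) / w.sum()
    kappa = _a1_inv(rbar)
    ll = float(np.sum(w * (kappa * np.cos(phi - mu2))) - w.sum() * _log_bessel_i0(kappa)
               - w.sum() * math.log(2.0 * math.pi))
    return OrientationModelFit(
        "vonmises",
        mu=(mu2 / 2.0) % math.pi,
        kappa1=kappa,
        loglik=ll,
        n_params=2,
        aic=4.0 - 2.0 * ll,
    )


def _mixture_loglik(
    phi: np.ndarray, w: np.ndarray, mu2: float, k1: float, k2: float, wt: float
) -> tuple[float, np.ndarray]:
    """Weighted log-likelihood and responsibilities of component 1."""
    log_c = math.log(2.0 * math.pi)
    l1 = math.log(wt) + k1 * np.cos(phi - mu2) - _log_bessel_i0(k1) - log_c
    l2 = math.log1p(-wt) + k2 * np.cos(phi - mu2 - math.pi) - _log_bessel_i0(k2) - log_c
    stacked = np.vstack([l1, l2])
    tot = logsumexp(stacked, axis=0)
    return float(np.sum(w * tot)), np.exp(l1 - tot)


def _fit_mixture(
    phi: np.ndarray,
    w: np.ndarray,
    n_starts: int = 4,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> OrientationModelFit:
    """EM for the orthogonal two-component circular-normal mixture."""
    w_sum = w.sum()
    best: tuple[float, tuple[float, float, float, float]] | None = None
    converged_any = False
    for j in range(n_starts):
        mu2 = j * math.pi / n_starts * 2.0  # starts spread over doubled space
        k1 = k2 = 2.0
        wt = 0.5
        ll_old = -np.inf
        converged = False
        for _ in range(max_iter):
            ll, r1 = _mixture_loglik(phi, w, mu2, k1, k2, wt)
            r2 = 1.0 - r1
            m1 = np.sum(w * r1)
            m2 = np.sum(w * r2)
            wt = float(np.clip(m1 / w_sum, 1e-6, 1.0 - 1e-6))
            z1 = np.sum(w * r1 * np.exp(1j * phi))
            z2 = -np.sum(w * r2 * np.exp(1j * phi))  # e^{i(phi - pi)} = -e^{i phi}
            mu2 = float(np.angle(k1 * z1 + k2 * z2)) % (2.0 * math.pi)
            e = np.exp(-1j * mu2)
            r1bar = max((z1 * e).real, 0.0) / m1 if m1 > 0 else 0.0
            r2bar = max((z2 * e).real, 0.0) / m2 if m2 > 0 else 0.0
            k1 = _a1_inv(min(r1bar, 1.0))
            k2 = _a1_inv(min(r2bar, 1.0))
            if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
                converged = True
                break
            ll_old = ll
        ll, _ = _mixture_loglik(phi, w, mu2, k1, k2, wt)
        converged_any = converged_any or converged
        if best is None or ll > best[0]:
            best = (ll, (mu2, k1, k2, wt))
    ll, (mu2, k1, k2, wt) = best  # type: ignore[misc]
    return OrientationModelFit(
        "orthogonal_mixture",
        mu=(mu2 / 2.0) % math.pi,
        kappa1=k1,
        kappa2=k2,
        weight=wt,
        loglik=ll,
        n_params=4,
        aic=8.0 - 2.0 * ll,
        converged=converged_any,
    )


def fit_orientation_models(
    segs: SegmentSet, em_starts: int = 4, doubled: bool = True
) -> list[OrientationModelFit]:
    """Fit the three candidate orientation models to one segment set.

    The mixture needs >= 3 segments; with fewer it is skipped.  With
    ``doubled=False`` the circular fits run on raw orientations in [0, pi)
    mapped to the circle without doubling (comparison mode only).
    """
    if segs.n < 1:
        raise ValueError("need at least one segment")
    if doubled:
        phi, w, n_eff = _doubled(segs)
    else:
        phi = np.mod(segs.orientations, 2.0 * np.pi)
        n_eff = float(segs.n)
        w = segs.lengths * (n_eff / segs.lengths.sum())
    fits = [_fit_uniform(n_eff), _fit_vonmises(phi, w)]
    if segs.n >= 3:
        fits.append(_fit_mixture(phi, w, n_starts=em_starts))
    return fits


def select_model(fits: list[OrientationModelFit]) -> OrientationModelFit:
    """Minimum-AIC fit; ties broken toward fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to select among")
    return min(fits, key=lambda f: (f.aic, f.n_params))


class AxialOrientationModelSelector(BaseEstimator):
    """AIC selection among uniform / circular-normal / orthogonal-mixture
    axial orientation models.

    ``fit(theta, sample_weight=lengths)`` accepts orientations in radians
    (reduced mod pi) with optional positive length weights.

    Fitted attributes: ``fits_`` (the three candidate fits), ``best_``
    (selected :class:`OrientationModelFit`), ``model_``, ``mu_``, ``aic_``.
    """

    def __init__(self, em_starts: int = 4, doubled: bool = True):
        self.em_starts = em_starts
        self.doubled = doubled

    def fit(self, theta, sample_weight=None):
        theta = np.asarray(theta, dtype=float)
        if sample_weight is None:
            sample_weight = np.ones_like(theta)
        segs = SegmentSet(theta, np.asarray(sample_weight, dtype=float))
        self.fits_ = fit_orientation_models(
            segs, em_starts=self.em_starts, doubled=self.doubled
        )
        self.best_ = select_model(self.fits_)
        self.model_ = self.best_.model
        self.mu_ = self.best_.mu
        self.aic_ = self.best_.aic
        return self

    def predict(self, X=None) -> str:
        return self.model_
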