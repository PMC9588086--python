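"""Fluorescence correlation spectroscopy: triplet-model fitting and diffusivity.

FCS infers the diffusion time ``tau_D`` of a fluorophore through a confocal
volume from the autocorrelation of its intensity fluctuations.  For a 3-D
Gaussian focus with a reversible dark (triplet) state, the model is

    G(tau) = (1/N) * 1/(1 + tau/tau_D) * 1/sqrt(1 + p^2 (tau/tau_D))
             * (1 + T/(1-T) * exp(-tau/tau_T)),

with ``N`` the mean particle number in the volume, ``p = r0/z0`` the
instrumental aspect constant, ``T`` the triplet amplitude and ``tau_T`` the
triplet lifetime.  The second (axial) factor is implemented with ``p^2``, the
standard 3-D Gaussian form; some write-ups print a bare ``p`` there, and that
variant is available via ``p_squared=False``.

Once the focal radius ``r0`` is calibrated against a dye of known diffusivity
(``r0 = sqrt(4 D tau_D)``), a fitted diffusion time converts to a diffusion
coefficient via ``D = r0^2 / (4 tau_D)``.

The fitting surface follows the Model/Results idiom: build a
:class:`TripletModel` from a curve, call :meth:`~TripletModel.fit`, inspect
the returned :class:`TripletFitResults` (estimates, standard errors,
``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import lmfit
import numpy as np

from chipscreen.exceptions import FitError, InvalidInputError

_PARAM_NAMES = ("n_particles", "tau_d", "p", "triplet_amp", "tau_t")


@dataclass(frozen=True)
class FcsParams:
    """Triplet-model parameters.

    ``n_particles`` > 0, ``tau_d`` > 0 (s), ``p`` = r0/z0 > 0,
    ``triplet_amp`` in [0, 1), ``tau_t`` > 0 (s).
    """

    n_particles: float
    tau_d: float
    p: float
    triplet_amp: float = 0.0
    tau_t: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.n_particles > 0):
            raise InvalidInputError(f"n_particles must be > 0, got {self.n_particles}")
        if not (self.tau_d > 0):
            raise InvalidInputError(f"tau_d must be > 0, got {self.tau_d}")
        if not (self.p > 0):
            raise InvalidInputError(f"p must be > 0, got {self.p}")
        if not (0.0 <= self.triplet_amp < 1.0):
            raise InvalidInputError(
                f"triplet_amp must be in [0, 1), got {self.triplet_amp}"
            )
        if not (self.tau_t > 0):
            raise InvalidInputError(f"tau_t must be > 0, got {self.tau_t}")


@dataclass(frozen=True)
class FcsInstrument:
    """Confocal volume geometry: focal radius r0 and axial half-length z0 (m)."""

    r0: float
    z0: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0 and self.z0 > 0):
            raise InvalidInputError("r0 and z0 must be > 0")

    @property
    def p(self) -> float:
        return self.r0 / self.z0


@dataclass(frozen=True)
class FcsCurve:
    """An autocorrelation curve: strictly increasing lags (s) and G values."""

    lags: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape or lags.ndim != 1:
            raise InvalidInputError("lags and g must be equal-length 1-D arrays")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise InvalidInputError("lags must be positive and strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)

    @property
    def n(self) -> int:
        return int(self.lags.size)


def autocorrelation(tau, params: FcsParams, p_squared: bool = True):
    """Triplet-model G(tau); accepts scalar or array lag times (s).

    ``p_squared=False`` selects the variant with a bare ``p`` in the axial
    factor instead of the standard ``p^2``.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidInputError("tau must be >= 0")
    x = tau / params.tau_d
    q = params.p**2 if p_squared else params.p
    diff = 1.0 / ((1.0 + x) * np.sqrt(1.0 + q * x))
    trip = 1.0 + (params.triplet_amp / (1.0 - params.triplet_amp)) * np.exp(
        -tau / params.tau_t
    )
    out = (1.0 / params.n_particles) * diff * trip
    return out if out.ndim else float(out)


def normalize_curve(curve: FcsCurve) -> FcsCurve:
    """Divide the whole curve by its value at the first lag.

    The normalized curve starts at exactly 1 and is independent of the
    particle number N (the amplitude cancels in the ratio).
    """
    if curve.n == 0:
        raise InvalidInputError("cannot normalize an empty curve")
    g0 = curve.g[0]
    if g0 == 0:
        raise InvalidInputError("G at the first lag is zero; normalization undefined")
    return FcsCurve(lags=curve.lags, g=curve.g / g0)


class TripletModel:
    """Nonlinear least-squares triplet model for one autocorrelation curve.

    Parameters
    ----------
    curve : FcsCurve
        Measured (lag, G) pairs; at least 10 points spanning two decades.
    p_squared : bool
        Axial-factor convention (see :func:`autocorrelation`).
    weights : array-like, optional
        Per-point weights for the residual; ``None`` (default) is unweighted.
        ``"inverse_g2"`` applies 1/G^2 weighting.
    """

    def __init__(self, curve: FcsCurve, p_squared: bool = True, weights=None):
        if curve.n < 10:
            raise InvalidInputError(f"fit needs >= 10 points, got {curve.n}")
        span = curve.lags[-1] / curve.lags[0]
        if span < 100:
            raise InvalidInputError(
                f"lags must span >= 2 decades, got {np.log10(span):.2f}"
            )
        self.curve = curve
        self.p_squared = p_squared
        if isinstance(weights, str):
            if weights != "inverse_g2":
                raise InvalidInputError(f"unknown weighting {weights!r}")
            weights = 1.0 / np.maximum(curve.g, 1e-30) ** 2
        self.weights = None if weights is None else np.asarray(weights, dtype=float)

    def _residual(self, lm_params: lmfit.Parameters) -> np.ndarray:
        p = FcsParams(**{k: lm_params[k].value for k in _PARAM_NAMES})
        res = autocorrelation(self.curve.lags, p, self.p_squared) - self.curve.g
        return res if self.weights is None else res * self.weights

    def fit(
        self,
        init: FcsParams,
        fixed: Iterable[str] = (),
        max_nfev: int = 10000,
    ) -> "TripletFitResults":
        """Fit the model; ``fixed`` names parameters held at their init value.

        Bounds enforce the parameter invariants (positivity, T in [0, 1)).
        """
        fixed = set(fixed)
        unknown = fixed - set(_PARAM_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown fixed parameters: {sorted(unknown)}")
        pars = lmfit.Parameters()
        pars.add("n_particles", value=init.n_particles, min=1e-12, vary="n_particles" not in fixed)
        pars.add("tau_d", value=init.tau_d, min=1e-15, vary="tau_d" not in fixed)
        pars.add("p", value=init.p, min=1e-6, vary="p" not in fixed)
        pars.add(
            "triplet_amp",
            value=init.triplet_amp,
            min=0.0,
            max=1.0 - 1e-9,
            vary="triplet_amp" not in fixed,
        )
        pars.add("tau_t", value=init.tau_t, min=1e-15, vary="tau_t" not in fixed)
        result = lmfit.minimize(
            self._residual, pars, method="least_squares", max_nfev=max_nfev
        )
        if not result.success:
            raise FitError(f"triplet fit did not converge: {result.message}")
        fitted = FcsParams(**{k: result.params[k].value for k in _PARAM_NAMES})
        stderr = {
            k: (result.params[k].stderr if result.params[k].stderr is not None else np.nan)
            for k in _PARAM_NAMES
        }
        return TripletFitResults(
            model=self, params=fitted, stderr=stderr, minimizer_result=result
        )


@dataclass
class TripletFitResults:
    """Fitted triplet-model parameters with uncertainties and diagnostics."""

    model: TripletModel
    params: FcsParams
    stderr: Mapping[str, float]
    minimizer_result: lmfit.minimizer.MinimizerResult

    @property
    def residual_norm(self) -> float:
        return float(np.sqrt(self.minimizer_result.chisqr))

    @property
    def r_squared(self) -> float:
        g = self.model.curve.g
        ss_res = float(np.sum((g - self.predict()) ** 2))
        ss_tot = float(np.sum((g - g.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    def predict(self, lags=None) -> np.ndarray:
        if lags is None:
            lags = self.model.curve.lags
        return autocorrelation(lags, self.params, self.model.p_squared)

    def diffusivity(self, instrument: FcsInstrument) -> float:
        return diffusivity_from_tau(instrument, self.params.tau_d)

    def summary(self) -> str:
        lines = [
            "Triplet-model FCS fit",
            f"  points: {self.model.curve.n}   axial factor: "
            + ("p^2 (standard)" if self.model.p_squared else "p (literal)"),
            f"  residual norm: {self.residual_norm:.4g}   R^2: {self.r_squared:.5f}",
            "  parameter       value        stderr",
        ]
        for k in _PARAM_NAMES:
            lines.append(
                f"  {k:<14}{getattr(self.params, k):>12.5g}  {self.stderr[k]:>12.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": {k: getattr(self.params, k) for k in _PARAM_NAMES},
            "stderr": {k: float(self.stderr[k]) for k in _PARAM_NAMES},
            "residual_norm": self.residual_norm,
            "r_squared": self.r_squared,
            "p_squared": self.model.p_squared,
        }


def fit_fcs(
    curve: FcsCurve,
    init: FcsParams,
    fixed: Iterable[str] = (),
    p_squared: bool = True,
    weights=None,
) -> TripletFitResults:
    """Convenience wrapper: ``TripletModel(curve, ...).fit(init, fixed)``."""
    return TripletModel(curve, p_squared=p_squared, weights=weights).fit(init, fixed)


def diffusivity_from_tau(instrument: FcsInstrument, tau_d: float) -> float:
    """D = r0^2 / (4 tau_D), m^2/s."""
    if not (tau_d > 0):
        raise InvalidInputError(f"tau_d must be > 0, got {tau_d}")
    return instrument.r0**2 / (4.0 * tau_d)


def calibrate_confocal_volume(known_d: float, fitted_tau_d: float) -> float:
    """Focal radius r0 = sqrt(4 D tau_D) from a calibration dye of known D."""
    if not (known_d > 0 and fitted_tau_d > 0):
        raise InvalidInputError("known_d and fitted_tau_d must be > 0")
    return float(np.sqrt(4.0 * known_d * fitted_tau_d))


def pure_diffusion_params(params: FcsParams) -> FcsParams:
    """The same parameters with the triplet branch switched off (T = 0)."""
    return replace(params, triplet_amp=0.0)
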