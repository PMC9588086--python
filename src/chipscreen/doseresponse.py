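"""Live/dead viability and sigmoidal dose-response (EC50) analysis.

Viability is the live fraction of counted cells,

    viability (%) = 100 * N_L / (N_L + N_D),

and a drug's potency is summarized by fitting viability against dose with a
Hill-type sigmoid on linear concentration,

    V(c) = bottom + (top - bottom) / (1 + (c / EC50)^hill),

so a true zero-dose control is handled exactly (V(0) = top for hill > 0).
EC50 here is the dose at the midpoint between the fitted plateaus.  A
log-dose (4PL-style) mode is available for assays without a zero dose.

Fitting follows the Model/Results idiom: :class:`DoseResponseModel` wraps the
data, ``fit()`` returns :class:`DoseResponseResults` with estimates,
standard errors, R^2 and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from chipscreen.exceptions import FitError, InvalidInputError, UndefinedIndexError

_FIT_PARAMS = ("top", "bottom", "ec50", "hill")


@dataclass(frozen=True)
class ViabilityCount:
    """Live/dead cell counts from one field of view."""

    n_live: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise InvalidInputError("counts must be >= 0")


def viability(count: ViabilityCount) -> float:
    """Percent viability 100 N_L / (N_L + N_D)."""
    total = count.n_live + count.n_dead
    if total == 0:
        raise UndefinedIndexError("viability undefined: no cells counted")
    return 100.0 * count.n_live / total


@dataclass(frozen=True)
class DoseResponseData:
    """Dose-viability observations (doses in drug units, viability in %)."""

    concentrations: np.ndarray
    viabilities: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        v = np.asarray(self.viabilities, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise InvalidInputError("doses and viabilities must be equal-length 1-D arrays")
        if np.any(c < 0):
            raise InvalidInputError("doses must be >= 0")
        if np.any((v < 0) | (v > 100)):
            raise InvalidInputError("viabilities must be in [0, 100] %")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "viabilities", v)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, dose_col: str = "dose", viability_col: str = "viability"
    ) -> "DoseResponseData":
        return cls(frame[dose_col].to_numpy(), frame[viability_col].to_numpy())


def hill_curve(c, top: float, bottom: float, ec50: float, hill: float):
    """Descending Hill sigmoid on linear concentration; V(0) = top."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0)
    out = bottom + (top - bottom) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted sigmoid parameters: plateaus, EC50 (dose units), Hill slope, R^2."""

    top: float
    bottom: float
    ec50: float
    hill: float
    r2: float

    def __post_init__(self) -> None:
        if self.bottom > self.top:
            raise InvalidInputError("bottom must not exceed top")
        if not (self.ec50 > 0):
            raise InvalidInputError(f"ec50 must be > 0, got {self.ec50}")


class DoseResponseModel:
    """Hill-type dose-response model for one viability series.

    Parameters
    ----------
    data : DoseResponseData
        At least 4 dose levels (4 free parameters), including a zero-dose
        control in the default linear-dose mode.
    log_dose : bool
        Fit on log10 dose (classic 4PL); requires strictly positive doses.
    bounds : mapping, optional
        Per-parameter (min, max) overrides.  Defaults keep viability
        physical: 0 <= bottom, top <= 100, hill > 0.
    """

    def __init__(
        self,
        data: DoseResponseData,
        log_dose: bool = False,
        bounds: Mapping[str, tuple[float, float]] | None = None,
    ):
        if np.unique(data.concentrations).size < 4:
            raise InvalidInputError("need >= 4 distinct dose levels for a 4-parameter fit")
        if log_dose and np.any(data.concentrations <= 0):
            raise InvalidInputError("log-dose mode requires strictly positive doses")
        self.data = data
        self.log_dose = log_dose
        self.bounds = {
            "top": (0.0, 100.0),
            "bottom": (0.0, 100.0),
            "ec50": (1e-12, np.inf),
            "hill": (1e-3, 50.0),
        }
        if bounds:
            self.bounds.update(bounds)

    def _initial_guess(self) -> dict[str, float]:
        c, v = self.data.concentrations, self.data.viabilities
        top = float(v[np.argmin(c)])
        bottom = float(v.min())
        mid = 0.5 * (top + bottom)
        pos = c[c > 0]
        # dose whose viability is nearest the midpoint, as an EC50 seed
        if pos.size:
            ec50 = float(pos[np.argmin(np.abs(v[c > 0] - mid))])
        else:  # pragma: no cover - guarded by >=4 distinct doses
            ec50 = 1.0
        return {"top": max(top, bottom + 1e-3), "bottom": bottom, "ec50": ec50, "hill": 1.5}

    def _predict(self, pars, c):
        if self.log_dose:
            logc = np.log10(np.asarray(c, dtype=float))
            return pars["bottom"] + (pars["top"] - pars["bottom"]) / (
                1.0 + 10.0 ** (pars["hill"] * (logc - np.log10(pars["ec50"])))
            )
        return hill_curve(c, pars["top"], pars["bottom"], pars["ec50"], pars["hill"])

    def fit(self, init: Mapping[str, float] | None = None) -> "DoseResponseResults":
        """Least-squares fit; returns results with a monotonicity warning flag.

        A series whose viability increases with dose is still fitted, but the
        result is flagged (``monotone_warning``).
        """
        guess = self._initial_guess()
        if init:
            guess.update(init)
        pars = lmfit.Parameters()
        for name in _FIT_PARAMS:
            lo, hi = self.bounds[name]
            pars.add(name, value=float(np.clip(guess[name], lo, hi)), min=lo, max=hi)

        def residual(p):
            vals = {k: p[k].value for k in _FIT_PARAMS}
            return self._predict(vals, self.data.concentrations) - self.data.viabilities

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = lmfit.minimize(residual, pars, method="least_squares", max_nfev=10000)
        if not result.success:
            raise FitError(f"dose-response fit did not converge: {result.message}")
        vals = {k: float(result.params[k].value) for k in _FIT_PARAMS}
        if vals["bottom"] > vals["top"]:  # pragma: no cover - bounds make this rare
            vals["top"], vals["bottom"] = vals["bottom"], vals["top"]
        v = self.data.viabilities
        ss_res = float(np.sum((self._predict(vals, self.data.concentrations) - v) ** 2))
        ss_tot = float(np.sum((v - v.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        fit = DoseResponseFit(
            top=vals["top"], bottom=vals["bottom"], ec50=vals["ec50"], hill=vals["hill"],
            r2=float(np.clip(r2, 0.0, 1.0)) if np.isfinite(r2) else r2,
        )
        stderr = {
            k: (result.params[k].stderr if result.params[k].stderr is not None else np.nan)
            for k in _FIT_PARAMS
        }
        # rising viability with dose means the drug axis is inverted or inactive
        order = np.argsort(self.data.concentrations)
        slope = np.polyfit(self.data.concentrations[order], v[order], 1)[0]
        return DoseResponseResults(
            model=self, fit=fit, stderr=stderr, monotone_warning=bool(slope > 0),
            minimizer_result=result,
        )


@dataclass
class DoseResponseResults:
    """Fitted dose-response curve with uncertainties and diagnostics."""

    model: DoseResponseModel
    fit: DoseResponseFit
    stderr: Mapping[str, float]
    monotone_warning: bool
    minimizer_result: lmfit.minimizer.MinimizerResult

    def predict(self, concentrations) -> np.ndarray:
        vals = {k: getattr(self.fit, k) for k in _FIT_PARAMS}
        return self.model._predict(vals, concentrations)

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit"
            + (" (log-dose)" if self.model.log_dose else " (linear dose)"),
            f"  doses: {self.model.data.concentrations.size}   R^2: {self.fit.r2:.4f}"
            + ("   WARNING: viability rises with dose" if self.monotone_warning else ""),
            "  parameter   value        stderr",
        ]
        for k in _FIT_PARAMS:
            lines.append(f"  {k:<10}{getattr(self.fit, k):>10.4g}  {self.stderr[k]:>10.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fit": {k: getattr(self.fit, k) for k in _FIT_PARAMS} | {"r2": self.fit.r2},
            "stderr": {k: float(self.stderr[k]) for k in _FIT_PARAMS},
            "monotone_warning": self.monotone_warning,
            "log_dose": self.model.log_dose,
        }


def fit_dose_response(
    data: DoseResponseData,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    log_dose: bool = False,
    init: Mapping[str, float] | None = None,
) -> DoseResponseResults:
    """Convenience wrapper: ``DoseResponseModel(data, ...).fit(init)``."""
    return DoseResponseModel(data, log_dose=log_dose, bounds=bounds).fit(init)


def ec50_comparison(
    fits: Sequence[DoseResponseFit], labels: Sequence[str]
) -> pd.DataFrame:
    """Comparison table of fitted curves, sorted by EC50 (ascending potency loss).

    Adds the EC50 ratio of each row to the most potent (smallest-EC50) fit.
    """
    if len(fits) < 2:
        raise InvalidInputError("comparison needs >= 2 fits")
    if len(fits) != len(labels):
        raise InvalidInputError("fits and labels must have equal length")
    frame = pd.DataFrame(
        {
            "label": list(labels),
            "ec50": [f.ec50 for f in fits],
            "hill": [f.hill for f in fits],
            "r2": [f.r2 for f in fits],
        }
    ).sort_values("ec50", kind="stable", ignore_index=True)
    frame["ec50_ratio"] = frame["ec50"] / frame["ec50"].iloc[0]
    return frame
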