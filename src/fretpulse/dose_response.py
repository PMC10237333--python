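"""Saturation-kinetics dose-response fitting of final normalized FRET.

The model is a single-site binding curve in the ligand concentration c (mM):

    response - 1 = max_response * c / (K05 + c)

so the fitted curve passes through response 1 at zero dose, ``max_response``
is the maximal change in normalized FRET, and ``K05`` the concentration
giving half of it.  The default fit operates on per-concentration mean
responses; a per-cell fit is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "saturation_response",
    "aggregate_final",
    "DoseResponseModel",
    "DoseResponseResults",
    "fit_dose_response",
    "predict_response",
]


def saturation_response(concentration, max_response: float, k05: float):
    """Predicted normalized FRET: 1 + max * c / (K05 + c)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = 1.0 + max_response * c / (k05 + c)
    return float(out) if out.ndim == 0 else out


def aggregate_final(points: pd.DataFrame) -> pd.DataFrame:
    """Per-concentration mean, sample SD, and n of final normalized FRET.

    Expects columns ``concentration`` and ``final_norm_fret``; SD is NaN
    for single-cell concentrations.
    """
    if points.empty:
        raise ValueError("no dose-response points to aggregate")
    g = points.groupby("concentration")["final_norm_fret"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out.sort_values("concentration").reset_index(drop=True)


class DoseResponseModel:
    """Nonlinear least-squares model for the saturation dose response.

    Parameters
    ----------
    concentration, response :
        Ligand concentrations (mM) and final normalized FRET values,
        either per cell or already aggregated.
    aggregate :
        ``"mean"`` (default) fits per-concentration mean responses, as in
        population dose-response plots; ``"cells"`` fits every point.
    """

    def __init__(self, concentration, response, aggregate: str = "mean"):
        c = np.asarray(concentration, dtype=float)
        r = np.asarray(response, dtype=float)
        if c.size != r.size:
            raise ValueError("concentration and response must have equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if aggregate not in ("mean", "cells"):
            raise ValueError("aggregate must be 'mean' or 'cells'")
        self.points = pd.DataFrame({"concentration": c, "final_norm_fret": r})
        self.aggregate = aggregate
        self.per_concentration = aggregate_final(self.points)
        if self.per_concentration.shape[0] < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if not (self.per_concentration["concentration"] > 0).any():
            raise ValueError("need at least one positive concentration")
        if aggregate == "mean":
            self._c = self.per_concentration["concentration"].to_numpy()
            self._r = self.per_concentration["mean"].to_numpy()
        else:
            self._c, self._r = c, r

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        concentration: str = "concentration",
        response: str = "final_norm_fret",
        aggregate: str = "mean",
    ) -> "DoseResponseModel":
        return cls(data[concentration], data[response], aggregate=aggregate)

    def _objective(self, max_response: float, k05: float) -> float:
        resid = self._r - saturation_response(self._c, max_response, k05)
        return float((resid**2).sum())

    def fit(self, transform: str = "log") -> "DoseResponseResults":
        """Least-squares fit of (max_response, K05).

        ``transform="log"`` (default) optimizes log-parameters, keeping
        both positive; ``transform="none"`` runs an unconstrained fit
        (useful for cross-checking against naive optimizers).  Starting
        values: max0 = max(mean response) - 1, K0 = median positive
        concentration.
        """
        max0 = float(self._r.max() - 1.0)
        k0 = float(np.median(self._c[self._c > 0]))
        identifiable = True
        if max0 <= 1e-8:  # flat/declining responses: amplitude pinned near zero
            identifiable = False
            max0 = 1e-8

        if transform == "log":
            def resid(theta):
                return self._r - saturation_response(
                    self._c, np.exp(theta[0]), np.exp(theta[1])
                )

            sol = least_squares(resid, x0=[np.log(max0), np.log(k0)], method="lm")
            max_hat, k_hat = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
        elif transform == "none":
            def resid(theta):
                return self._r - (1.0 + theta[0] * self._c / (theta[1] + self._c))

            sol = least_squares(resid, x0=[max0, k0], method="lm")
            max_hat, k_hat = float(sol.x[0]), float(sol.x[1])
        else:
            raise ValueError("transform must be 'log' or 'none'")
        if not sol.success:
            raise RuntimeError(
                f"dose-response fit did not converge: {sol.message} "
                f"(start max0={max0:.4g}, K0={k0:.4g}, nfev={sol.nfev})"
            )
        if abs(max_hat) < 1e-6:
            identifiable = False
        return DoseResponseResults(
            model=self,
            max_response=max_hat,
            k05=k_hat,
            rss=self._objective(max_hat, k_hat),
            k05_identifiable=identifiable,
            nfev=int(sol.nfev),
        )


@dataclass
class DoseResponseResults:
    """Fitted saturation-curve parameters and per-concentration summaries."""

    model: DoseResponseModel
    max_response: float
    k05: float
    rss: float
    k05_identifiable: bool = True
    nfev: int = 0

    @property
    def per_concentration(self) -> pd.DataFrame:
        return self.model.per_concentration

    def predict(self, concentration):
        """Predicted normalized FRET at the given concentrations."""
        return saturation_response(concentration, self.max_response, self.k05)

    def summary(self) -> str:
        lines = [
            "Saturation dose-response fit (response - 1 = max*c/(K05 + c))",
            f"  max_response : {self.max_response:10.4f}",
            f"  K05 (mM)     : {self.k05:10.4f}"
            + ("" if self.k05_identifiable else "   [unidentifiable: flat response]"),
            f"  RSS          : {self.rss:10.3e}   ({self.model.aggregate} fit)",
            "",
            self.per_concentration.to_string(index=False),
        ]
        return "\n".join(lines)


def fit_dose_response(
    points: pd.DataFrame, aggregate: str = "mean", transform: str = "log"
) -> DoseResponseResults:
    """Fit the saturation curve to a (concentration, final_norm_fret) table."""
    return DoseResponseModel.from_dataframe(points, aggregate=aggregate).fit(transform)


def predict_response(result: DoseResponseResults, concentration):
    """Evaluate a fitted dose-response curve (module-level convenience)."""
    return result.predict(concentration)
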