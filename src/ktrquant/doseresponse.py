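"""Concentration-response curves from per-cell AUCs: averaging and 4PL fit.

The response at each concentration is the grand mean of per-replicate mean
AUCs (each biological replicate contributes equally regardless of its cell
count). The curve is the four-parameter logistic in its log-logistic form

    y(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with slope b, lower asymptote c, upper asymptote d and inflection
(EC50) e. The negative-control response enters the fit at a small pseudo
concentration, since log of zero is undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DoseResponseFit:
    """4PL fit result; ``e`` is the EC50 in the concentration units of the input."""

    b: float
    c: float
    d: float
    e: float
    residual_ss: float
    converged: bool
    degenerate: bool = False

    @property
    def ec50(self) -> float:
        return self.e

    def predict(self, x):
        return four_param_logistic(np.asarray(x, dtype=float),
                                   self.b, self.c, self.d, self.e)


def four_param_logistic(x, b, c, d, e):
    """y = c + (d - c) / (1 + exp(b (ln x - ln e)))."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def replicate_average(auc_table: pd.DataFrame, value_col: str = "auc_erk",
                      conc_col: str = "concentration",
                      rep_col: str = "replicate") -> pd.DataFrame:
    """Two-stage mean: cells -> replicate mean, replicates -> grand mean.

    Returns per-concentration rows with the grand mean ('response') and the
    per-replicate means kept long in 'replicate_means'. Concentrations with
    zero cells are dropped with a warning.
    """
    if rep_col not in auc_table.columns:
        auc_table = auc_table.assign(**{rep_col: 1})
    stage1 = (auc_table.groupby([conc_col, rep_col])[value_col]
              .mean().rename("replicate_mean").reset_index())
    if stage1.empty:
        warnings.warn("no cells in any concentration", stacklevel=2)
    grand = (stage1.groupby(conc_col)["replicate_mean"].agg(list)
             .rename("replicate_means").reset_index())
    grand["response"] = grand["replicate_means"].map(np.mean)
    grand["n_replicates"] = grand["replicate_means"].map(len)
    return grand.sort_values(conc_col).reset_index(drop=True)


def fit_4pl(concentrations, responses, control_response: float | None = None,
            control_conc_factor: float = 1e-4) -> DoseResponseFit:
    """Unweighted least-squares 4PL fit of responses against concentration.

    ``control_response`` (response with no ligand) is appended at the pseudo
    concentration ``control_conc_factor`` times the lowest tested
    concentration. Requires >= 4 distinct concentrations after insertion.
    Non-convergence returns a flagged fit rather than raising; an all-flat
    response is flagged degenerate.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentrations must be > 0")
    if control_response is not None:
        x = np.append(x, control_conc_factor * x.min())
        y = np.append(y, control_response)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")

    span = float(y.max() - y.min())
    if span == 0:
        return DoseResponseFit(b=0.0, c=float(y[0]), d=float(y[0]),
                               e=float(np.sqrt(x.min() * x.max())),
                               residual_ss=0.0, converged=True, degenerate=True)

    # quartile-based initialisation: asymptotes from the data range, EC50
    # from the concentration whose response is nearest the midpoint
    c0, d0 = float(y.min()), float(y.max())
    mid = 0.5 * (c0 + d0)
    e0 = float(x[np.argmin(np.abs(y - mid))])
    e0 = float(np.clip(e0, x.min(), x.max()))
    increasing = np.corrcoef(np.log(x), y)[0, 1] >= 0
    b0 = -1.0 if increasing else 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_param_logistic, x, y, p0=[b0, c0, d0, e0],
                bounds=([-np.inf, -np.inf, -np.inf, x.min() * 1e-8],
                        [np.inf, np.inf, np.inf, x.max() * 1e8]),
                maxfev=20000)
        converged = True
    except RuntimeError:
        popt = [b0, c0, d0, e0]
        converged = False
    resid = y - four_param_logistic(x, *popt)
    return DoseResponseFit(b=float(popt[0]), c=float(popt[1]), d=float(popt[2]),
                           e=float(popt[3]), residual_ss=float(resid @ resid),
                           converged=converged)


def fit_dose_response(auc_table: pd.DataFrame, value_col: str = "auc_erk",
                      control_response: float | None = None) -> DoseResponseFit:
    """Convenience: replicate-average an AUC table and fit the 4PL."""
    avg = replicate_average(auc_table, value_col=value_col)
    return fit_4pl(avg["concentration"].to_numpy(), avg["response"].to_numpy(),
                   control_response=control_response)
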