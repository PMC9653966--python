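"""First-order plasma-degradation kinetics.

Below the Michaelis–Menten constant, enzymatic hydrolysis in plasma is
pseudo-first-order: C(t) = C0·exp(k·t) with k < 0 for a substrate. The
rate constant is the slope of an ordinary least-squares fit of
ln(concentration) against incubation time, replicates pooled into one
regression. The half-life follows as t1/2 = ln 2 / |k|.

Incubations here stop at 120 min, so slow rates cannot be resolved from
measurement noise: compounds with |k| below 0.006 ln(µM)/min are reported
as stable with a censored half-life of ">120 min".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: |k| (per minute) below which a compound is reported as stable (">120 min").
K_CENSOR_THRESHOLD = 0.006

#: Longest incubation time (minutes); censored half-lives are capped here.
T_MAX = 120.0


@dataclass
class DegradationFit:
    compound_id: str
    k: float            # signed slope, ln(concentration) per minute
    k_sd: float         # standard error of the slope
    t_half: float       # minutes; equals T_MAX when censored
    censored: bool      # True -> report half-life as ">120 min"
    r2: float
    n_points: int

    def t_half_text(self) -> str:
        return f">{T_MAX:g} min" if self.censored else f"{self.t_half:.1f} min"


def fit_degradation(
    times, concentrations, compound_id: str = ""
) -> DegradationFit:
    """Fit ln(concentration) vs time by OLS; pooled replicate points allowed.

    ``times`` and ``concentrations`` are flat, equal-length sequences; a
    time value repeated across replicates simply appears multiple times.
    """
    t = np.asarray(times, dtype=float).ravel()
    c = np.asarray(concentrations, dtype=float).ravel()
    if t.shape != c.shape:
        raise ValueError("times and concentrations must have equal length")
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 distinct time points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (log-linear fit)")

    fit = stats.linregress(t, np.log(c))
    k = float(fit.slope)
    censored = abs(k) < K_CENSOR_THRESHOLD
    t_half = T_MAX if censored else min(float(np.log(2) / abs(k)), T_MAX)
    return DegradationFit(
        compound_id=compound_id,
        k=k,
        k_sd=float(fit.stderr),
        t_half=t_half,
        censored=censored,
        r2=float(fit.rvalue**2),
        n_points=len(t),
    )


def compare_fits(a: DegradationFit, b: DegradationFit) -> bool:
    """Whether two rate constants agree within their k ± 2·SD intervals.

    Used to test e.g. whether a co-incubated stable isomer changes the
    substrate's degradation rate. Raises if exactly one fit is censored —
    a resolved rate and a detection bound are not comparable.
    """
    if a.censored != b.censored:
        raise ValueError(
            "cannot compare a censored (stable) fit with an uncensored one"
        )
    if a.censored:
        return True  # both below the resolvable-rate threshold
    lo_a, hi_a = a.k - 2 * a.k_sd, a.k + 2 * a.k_sd
    lo_b, hi_b = b.k - 2 * b.k_sd, b.k + 2 * b.k_sd
    return lo_a <= hi_b and lo_b <= hi_a
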