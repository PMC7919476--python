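"""Association constant and binding stoichiometry from the double-log Hill plot.

For static quenching the titration obeys

    log10[(F0 - F) / F] = log10 K_A + n log10 [Q]

so an ordinary least-squares line through the double-logarithm points yields
the Hill coefficient n (slope; the apparent number of binding sites per
protein) and the association constant K_A (L/mol) as the antilog of the
intercept.  Points with F >= F0 (fluorescence enhancement, seen at the first
titration points of some complexes) have no defined transform and are
excluded, with the exclusion recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quenching import quench_ratios
from .spectra import SpectraError, TitrationSeries

__all__ = ["BindingResult", "HillModel", "hill_transform", "hill_fit"]


def hill_transform(
    series_or_ratios,
    F0: float | None = None,
    policy: str = "fixed",
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Transform a titration to double-logarithm coordinates.

    Returns ``(log10_Q, log10_y, dropped)`` where ``y = (F0 - F)/F`` and
    ``dropped`` lists the indices of titration points excluded because
    [Q] = 0 or F >= F0 (enhancement / no quenching).

    Accepts a :class:`~albind.spectra.TitrationSeries` or a precomputed
    ``(Q, F0/F)`` pair.
    """
    if isinstance(series_or_ratios, TitrationSeries):
        Q, r = quench_ratios(series_or_ratios, policy=policy, F0=F0)
    else:
        Q, r = (np.asarray(a, dtype=float) for a in series_or_ratios)
    y = r - 1.0  # (F0 - F)/F = F0/F - 1
    usable = (Q > 0) & (y > 0)
    dropped = tuple(int(i) for i in np.flatnonzero(~usable))
    if usable.sum() < 3:
        raise SpectraError(
            f"only {int(usable.sum())} usable titration points after excluding "
            "[Q]=0 and F>=F0 points; >= 3 required"
        )
    return np.log10(Q[usable]), np.log10(y[usable]), dropped


@dataclass(frozen=True)
class BindingResult:
    """Hill double-log fit at one temperature."""

    K_A: float  # L/mol, antilog of the intercept
    n: float  # Hill slope (binding-site number)
    temperature_K: float
    r_squared: float
    points_used: tuple[int, ...]
    points_dropped: tuple[int, ...] = ()

    def __post_init__(self):
        if self.K_A <= 0:
            raise ValueError("K_A must be positive")


class HillModel:
    """Double-logarithm Hill regression model for one titration.

    Built from a titration series (or a precomputed ``(Q, F0/F)`` pair plus
    a temperature); ``fit()`` returns a :class:`BindingResult` carrying
    K_A = 10**intercept, n = slope, the fit quality and the point filter
    actually applied.
    """

    def __init__(
        self,
        series_or_ratios,
        temperature_K: float | None = None,
        F0: float | None = None,
        policy: str = "fixed",
    ):
        if isinstance(series_or_ratios, TitrationSeries):
            self.temperature_K = series_or_ratios.temperature_K
            n_points = series_or_ratios.quencher_conc_M.size
        else:
            if temperature_K is None:
                raise ValueError("temperature_K is required with raw ratios")
            self.temperature_K = float(temperature_K)
            n_points = np.asarray(series_or_ratios[0]).size
        self.logQ, self.logy, self.dropped = hill_transform(
            series_or_ratios, F0=F0, policy=policy
        )
        self.points_used = tuple(
            i for i in range(n_points) if i not in self.dropped
        )

    def fit(self) -> BindingResult:
        """OLS of log10[(F0-F)/F] on log10[Q]."""
        if np.ptp(self.logQ) == 0:
            raise ValueError("degenerate concentration range: all [Q] equal")
        res = stats.linregress(self.logQ, self.logy)
        return BindingResult(
            K_A=float(10.0**res.intercept),
            n=float(res.slope),
            temperature_K=self.temperature_K,
            r_squared=float(res.rvalue**2),
            points_used=self.points_used,
            points_dropped=self.dropped,
        )


def hill_fit(
    transformed_or_series,
    temperature_K: float = np.nan,
) -> BindingResult:
    """Fit the Hill line; accepts a series or pre-transformed (logQ, logy).

    When given pre-transformed coordinates the point bookkeeping reflects
    the transformed points only.
    """
    if isinstance(transformed_or_series, TitrationSeries):
        return HillModel(transformed_or_series).fit()
    logQ, logy = (np.asarray(a, dtype=float) for a in transformed_or_series)
    if logQ.size < 3:
        raise ValueError("Hill fit needs >= 3 points")
    if np.ptp(logQ) == 0:
        raise ValueError("degenerate concentration range: all [Q] equal")
    res = stats.linregress(logQ, logy)
    return BindingResult(
        K_A=float(10.0**res.intercept),
        n=float(res.slope),
        temperature_K=float(temperature_K),
        r_squared=float(res.rvalue**2),
        points_used=tuple(range(logQ.size)),
    )
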