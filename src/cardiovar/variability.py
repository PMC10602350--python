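"""Poincaré-plot variability indices for beat-to-beat series.

A Poincaré plot scatters consecutive values of a per-cycle quantity against
each other: each point is ``(x_i, x_{i+1})``.  Its dispersion is summarised by
two standard deviations measured in the frame rotated 45 degrees onto the line
of identity ``y = x``:

* ``SD1`` — dispersion perpendicular to the identity line, i.e. the population
  standard deviation of ``d_i = (x_{i+1} - x_i) / sqrt(2)``.  It captures
  beat-to-beat (short-term) variability.
* ``SD2`` — dispersion along the identity line, the population standard
  deviation of ``s_i = (x_{i+1} + x_i) / sqrt(2)``.  It captures slower
  (long-term) variability.

Both indices carry the unit of the input series (ms for cycle duration,
μl for stroke volume).  Standard deviations use the population convention
(``ddof=0``) over the ``n - 1`` consecutive pairs, which makes small worked
examples exact.

For a stationary AR(1) series with lag-1 autocorrelation ``a`` and innovation
SD ``σ``, the indices converge to ``SD1 = σ/sqrt(1+a)`` and
``SD2 = σ/sqrt(1-a)`` — the link exploited by the circulation model in
:mod:`cardiovar.frank_starling`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PoincareIndices", "poincare_points", "poincare_indices", "indices_table"]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class PoincareIndices:
    """SD1/SD2 summary of one beat-to-beat series."""

    sd1: float
    sd2: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("SD1 and SD2 must be non-negative")


def _as_series(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("beat series contains non-finite values")
    return x


def poincare_points(values) -> np.ndarray:
    """Return the ``(n-1, 2)`` array of consecutive pairs ``(x_i, x_{i+1})``.

    The first coordinate (abscissa) is the earlier beat; this is the
    conventional orientation, and SD1/SD2 are invariant to swapping the axes.
    """
    x = _as_series(values)
    if x.size < 2:
        raise ValueError("need at least 2 values to form Poincaré pairs")
    return np.column_stack([x[:-1], x[1:]])


def poincare_indices(values) -> PoincareIndices:
    """Compute SD1 and SD2 of a beat-to-beat series (n >= 3)."""
    x = _as_series(values)
    if x.size < 3:
        raise ValueError("need at least 3 values for Poincaré indices")
    d = (x[1:] - x[:-1]) / _SQRT2
    s = (x[1:] + x[:-1]) / _SQRT2
    return PoincareIndices(
        sd1=float(np.std(d)),  # ddof=0 over the n-1 pairs
        sd2=float(np.std(s)),
        n_pairs=x.size - 1,
    )


def indices_table(series_by_key: dict[tuple[str, str], "np.ndarray"]) -> pd.DataFrame:
    """Tidy table of indices for many labelled series.

    Parameters
    ----------
    series_by_key
        Mapping ``(animal_id, quantity) -> series``.

    Returns
    -------
    DataFrame with columns ``animal_id, quantity, SD1, SD2, n_pairs``.
    """
    rows = []
    for (animal_id, quantity), series in series_by_key.items():
        idx = poincare_indices(series)
        rows.append(
            {"animal_id": animal_id, "quantity": quantity,
             "SD1": idx.sd1, "SD2": idx.sd2, "n_pairs": idx.n_pairs}
        )
    return pd.DataFrame(rows, columns=["animal_id", "quantity", "SD1", "SD2", "n_pairs"])


def plot_poincare(values, ax=None, **scatter_kws):
    """Scatter the Poincaré pairs with the identity line (cosmetic helper)."""
    import matplotlib.pyplot as plt

    pts = poincare_points(values)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pts[:, 0], pts[:, 1], **scatter_kws)
    lo, hi = pts.min(), pts.max()
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8)
    ax.set_xlabel("value at beat i")
    ax.set_ylabel("value at beat i+1")
    return ax
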