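"""Closed-system Rayleigh fractionation estimators.

Two processes are modelled with the same ln-linear algebra:

* **Uptake from the hydroponic reservoir.** As plants remove Cd from a
  finite solution, the residual solution evolves along
  ``delta_final - delta_init = eps_uptake * ln f`` where f is the fraction
  of Cd remaining. ``uptake_epsilon`` inverts this for eps.

* **Within-plant sequestration vs mobilisation.** Light Cd is retained in
  the roots while heavier Cd moves unidirectionally to the sink (leaves or
  whole shoot): ``Delta_sink-tot = eps_seq_mob * ln f_sink``.
  ``seq_mob_epsilon_single`` evaluates one plant; ``fit_rayleigh`` pools
  plants with a least-squares line forced through (f = 1, Delta = 0), since
  a sink holding all the Cd cannot differ from the source.

Sign convention: a sink isotopically heavier than the source (positive
Delta) at f < 1 yields a negative epsilon. Reported magnitudes are exposed
alongside the signed value because uptake fractionations are conventionally
quoted as magnitudes.

``accumulated_product_delta`` gives the exact accumulated-removal
composition implied by mass balance, used by the synthetic generator and the
reservoir-effect consistency check; the pooled fit deliberately uses the
instantaneous ln-linear form for the accumulated sink, matching how such
fits are reported in plant isotope studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "RayleighFit",
    "uptake_epsilon",
    "seq_mob_epsilon_single",
    "fit_rayleigh",
    "accumulated_product_delta",
]


def _check_fraction(f: float, allow_one: bool = False) -> None:
    hi_ok = f <= 1.0 if allow_one else f < 1.0
    if not (0.0 < f and hi_ok):
        hi = "1]" if allow_one else "1)"
        raise ValueError(f"fraction must lie in (0, {hi}, got {f}")


def uptake_epsilon(delta_init: float, delta_final: float, f_remaining: float) -> float:
    """Fractionation factor (permil) of reservoir depletion.

    eps = (delta_final - delta_init) / ln f; the signed value is returned
    (negative when the removed Cd is isotopically light, as for plant uptake).
    """
    _check_fraction(f_remaining)
    return (delta_final - delta_init) / math.log(f_remaining)


def seq_mob_epsilon_single(delta_sink_minus_tot: float, f_sink: float) -> float | None:
    """Per-plant sequestration-mobilisation epsilon (permil).

    eps = Delta_sink-tot / ln f_sink. At f_sink = 1 the expression is
    indeterminate: Delta = 0 there is consistent with any epsilon (returns
    None), a nonzero Delta is a contradiction (raises).
    """
    _check_fraction(f_sink, allow_one=True)
    if f_sink == 1.0:
        if delta_sink_minus_tot != 0.0:
            raise ValueError(
                "inconsistent point: the sink holds all the Cd (f = 1) "
                f"yet differs from the source by {delta_sink_minus_tot} permil"
            )
        return None
    return delta_sink_minus_tot / math.log(f_sink)


@dataclass(frozen=True)
class RayleighFit:
    """Forced-origin least-squares fit of Delta_sink-tot against ln f_sink."""

    epsilon: float  # permil, signed
    sink: str
    n_points: int
    residual_sd: float  # permil
    per_point_epsilons: tuple[float, ...]

    @property
    def epsilon_magnitude(self) -> float:
        return abs(self.epsilon)

    def predict(self, f_sink: np.ndarray) -> np.ndarray:
        """Model Delta at given sink fractions (the fitted curve)."""
        f = np.asarray(f_sink, dtype=float)
        return self.epsilon * np.log(f)


def fit_rayleigh(
    points: Sequence[tuple[float, float]],
    sink: str = "leaf",
    weights: Sequence[float] | None = None,
) -> RayleighFit:
    """Pool (f_sink, Delta_sink-tot) points into one fractionation factor.

    Least squares of Delta on x = ln f with zero intercept — the line is
    forced through (f = 1, Delta = 0):

        eps = sum(w x y) / sum(w x^2)

    Weights default to 1 (plain OLS); pass inverse variances to weight by
    analytical precision. Points at exactly f = 1 carry x = 0 and therefore
    do not constrain the slope (all points at f = 1 is a singular design).
    """
    if len(points) < 1:
        raise ValueError("at least one point is required")
    f = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("all sink fractions must lie in (0, 1]")
    x = np.log(f)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative and match the points")
    sxx = float(np.dot(w, x * x))
    if sxx == 0.0:
        raise ValueError("singular design: every point sits at f_sink = 1")
    eps = float(np.dot(w, x * y) / sxx)
    resid = y - eps * x
    dof = max(len(points) - 1, 1)
    per_point = tuple(
        float(yi / xi) if xi != 0.0 else float("nan") for xi, yi in zip(x, y)
    )
    return RayleighFit(
        epsilon=eps,
        sink=sink,
        n_points=len(points),
        residual_sd=float(np.sqrt(np.dot(w, resid**2) / (w.sum() / len(w)) / dof)),
        per_point_epsilons=per_point,
    )


def accumulated_product_delta(delta_init: float, epsilon: float, f: float) -> float:
    """Composition of the accumulated removed pool of a Rayleigh process.

    For a reservoir starting at ``delta_init`` and depleted to fraction
    ``f`` with fractionation ``epsilon``, the residue sits at
    ``delta_init + eps*ln f`` and exact mass balance puts the accumulated
    product at::

        delta_init - eps * f * ln f / (1 - f)

    As f -> 1 this tends to ``delta_init + eps`` (the instantaneous offset).
    """
    _check_fraction(f)
    return delta_init - epsilon * f * math.log(f) / (1.0 - f)
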