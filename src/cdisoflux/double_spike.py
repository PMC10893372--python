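"""Double-spike data reduction for Cd isotope-ratio measurements.

A sample of natural Cd is mixed with a 111Cd-113Cd double spike before
purification, and the spiked mixture is measured by MC-ICP-MS. Three measured
isotope ratios (111/110, 113/110, 114/110) over-determine nothing and exactly
determine three unknowns:

* ``p``     — molar fraction of the denominator isotope (110Cd) contributed
              by the spike,
* ``alpha`` — natural mass-dependent fractionation exponent relating the
              sample to the reference standard (exponential law),
* ``beta``  — instrumental mass-bias exponent (exponential law).

The exponential law writes a fractionated ratio as ``R_i * (m_i/m_110)^x``
where ``m_i`` are the isotope atomic masses. The natural delta value follows
from ``alpha`` alone::

    delta114 (permil) = ((m114/m110)**alpha - 1) * 1000

and the sample's Cd amount follows from ``p`` by isotope dilution.

The inversion is a damped Newton iteration on the three mixing equations with
an analytic Jacobian.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "IsotopeSystem",
    "SpikeMixture",
    "SpikePlan",
    "DoubleSpikeError",
    "ConvergenceError",
    "forward_mix",
    "invert_double_spike",
    "isotope_dilution_conc",
    "plan_spike",
    "alpha_from_delta",
    "delta_from_alpha",
]


class DoubleSpikeError(ValueError):
    """Invalid isotope-system configuration or unusable input."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the final residual vector."""

    def __init__(self, message: str, residuals: np.ndarray, iterations: int):
        super().__init__(message)
        self.residuals = residuals
        self.iterations = iterations


@dataclass(frozen=True)
class IsotopeSystem:
    """Reference and spike Cd isotope compositions for the 110/111/113/114 set.

    Ratios are (111/110, 113/110, 114/110). The shipped default composition
    (``IsotopeSystem.default()``) carries natural-abundance reference ratios
    and an illustrative 111-113 double spike; these are editable placeholder
    values, not certified compositions.

    Parameters
    ----------
    isotope_masses
        Atomic masses (u) of 110Cd, 111Cd, 113Cd, 114Cd, strictly increasing.
    reference_ratios
        Natural-standard ratios of the bracketing isotope standard.
    spike_ratios
        The same three ratios for the double spike.
    spike_conc_ng_per_g
        Cd amount per mass of spike solution (ng/g).
    """

    isotope_masses: tuple[float, float, float, float]
    reference_ratios: tuple[float, float, float]
    spike_ratios: tuple[float, float, float]
    spike_conc_ng_per_g: float = 100.0

    def __post_init__(self) -> None:
        masses = np.asarray(self.isotope_masses, dtype=float)
        if masses.shape != (4,) or not np.all(np.diff(masses) > 0):
            raise DoubleSpikeError("isotope_masses must be four strictly increasing values")
        for name in ("reference_ratios", "spike_ratios"):
            r = np.asarray(getattr(self, name), dtype=float)
            if r.shape != (3,) or not np.all(r > 0):
                raise DoubleSpikeError(f"{name} must be three strictly positive ratios")
        if self.spike_conc_ng_per_g <= 0:
            raise DoubleSpikeError("spike_conc_ng_per_g must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def mass_ratios(self) -> np.ndarray:
        """(m111/m110, m113/m110, m114/m110)."""
        m = np.asarray(self.isotope_masses)
        return m[1:] / m[0]

    def check_invertible(self) -> None:
        """Raise unless spike and reference differ in >= 2 of 3 ratios.

        A spike too close to the reference makes the three mixing equations
        singular in (p, alpha, beta).
        """
        ref = np.asarray(self.reference_ratios)
        spk = np.asarray(self.spike_ratios)
        distinct = np.sum(np.abs(spk - ref) / ref > 1e-6)
        if distinct < 2:
            raise DoubleSpikeError(
                "spike composition must differ from the reference in at least "
                f"two of three ratios (differs in {distinct})"
            )

    def abundances(self, ratios: np.ndarray | None = None) -> np.ndarray:
        """Fractional abundances (110, 111, 113, 114) implied by a ratio triple.

        Abundances are on the four-isotope basis used throughout this module.
        """
        r = np.asarray(self.reference_ratios if ratios is None else ratios, dtype=float)
        full = np.concatenate(([1.0], r))
        return full / full.sum()

    def atomic_mass(self, ratios: np.ndarray | None = None) -> float:
        """Mean atomic mass (u) of a composition given by a ratio triple."""
        return float(np.dot(self.abundances(ratios), self.isotope_masses))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "IsotopeSystem":
        return cls(
            isotope_masses=tuple(d["isotope_masses"]),
            reference_ratios=tuple(d["reference_ratios"]),
            spike_ratios=tuple(d["spike_ratios"]),
            spike_conc_ng_per_g=float(d.get("spike_conc_ng_per_g", 100.0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IsotopeSystem":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "IsotopeSystem":
        """The packaged placeholder Cd system (see ``data/cd_system.json``)."""
        text = resources.files("cdisoflux").joinpath("data/cd_system.json").read_text()
        return cls.from_dict(json.loads(text))


@dataclass
class SpikeMixture:
    """Solved state of one spiked measurement."""

    measured_ratios: tuple[float, float, float]
    p: float
    alpha: float
    beta: float
    converged: bool
    iterations: int
    residual: float = 0.0

    @property
    def delta114_permil(self) -> float:
        return delta_from_alpha(self.alpha)

    @property
    def physical(self) -> bool:
        """True when the solved spike fraction lies in [0, 1] (small tolerance)."""
        return -1e-9 <= self.p <= 1 + 1e-9


_DELTA_MASS_RATIO = 113.9033589 / 109.9030066  # m114/m110, used for delta<->alpha


def delta_from_alpha(alpha: float, mass_ratio: float = _DELTA_MASS_RATIO) -> float:
    """delta114 (permil) implied by an exponential-law exponent."""
    return (mass_ratio**alpha - 1.0) * 1000.0


def alpha_from_delta(delta_permil: float, mass_ratio: float = _DELTA_MASS_RATIO) -> float:
    """Exponential-law exponent reproducing a given delta114 (permil)."""
    return float(np.log1p(delta_permil / 1000.0) / np.log(mass_ratio))


def forward_mix(
    p: float, alpha: float, beta: float, system: IsotopeSystem
) -> np.ndarray:
    """Model the measured ratio triple of a spiked, mass-biased mixture.

    The natural end-member is the reference composition fractionated by
    ``alpha``; it is blended with the (unfractionated) spike in 110Cd molar
    proportion ``p`` and the blend is fractionated instrumentally by ``beta``.
    """
    if not 0.0 <= p <= 1.0:
        raise DoubleSpikeError(f"spike fraction p={p} outside [0, 1]")
    q = system.mass_ratios
    natural = np.asarray(system.reference_ratios) * q**alpha
    mixture = (1.0 - p) * natural + p * np.asarray(system.spike_ratios)
    return mixture * q**beta


def _residual_and_jacobian(
    x: np.ndarray, measured: np.ndarray, system: IsotopeSystem
) -> tuple[np.ndarray, np.ndarray]:
    p, alpha, beta = x
    q = system.mass_ratios
    lnq = np.log(q)
    natural = np.asarray(system.reference_ratios) * q**alpha
    spike = np.asarray(system.spike_ratios)
    mixture = (1.0 - p) * natural + p * spike
    qb = q**beta
    f = mixture * qb - measured
    jac = np.empty((3, 3))
    jac[:, 0] = (spike - natural) * qb
    jac[:, 1] = (1.0 - p) * natural * lnq * qb
    jac[:, 2] = mixture * lnq * qb
    return f, jac


def invert_double_spike(
    measured: np.ndarray | tuple[float, float, float],
    system: IsotopeSystem,
    initial_guess: tuple[float, float, float] = (0.5, 0.0, 0.0),
    tol: float = 1e-12,
    max_iter: int = 100,
) -> SpikeMixture:
    """Solve the three mixing equations for (p, alpha, beta).

    Damped Newton iteration: full steps are halved until the residual norm
    decreases. Convergence is declared when the residual norm falls below
    ``tol`` relative to the measured-ratio norm.

    Raises
    ------
    ConvergenceError
        If the residual has not converged after ``max_iter`` accepted steps.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != (3,) or not np.all(measured > 0):
        raise DoubleSpikeError("measured must be three positive ratios")
    system.check_invertible()
    x = np.asarray(initial_guess, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DoubleSpikeError("initial guess must be finite")
    scale = float(np.linalg.norm(measured))

    f, jac = _residual_and_jacobian(x, measured, system)
    norm = np.linalg.norm(f)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if norm <= tol * scale:
            break
        step = np.linalg.solve(jac, -f)
        lam = 1.0
        for _ in range(40):  # backtracking line search
            trial = x + lam * step
            f_trial, jac_trial = _residual_and_jacobian(trial, measured, system)
            norm_trial = np.linalg.norm(f_trial)
            if norm_trial < norm:
                break
            lam *= 0.5
        else:
            raise ConvergenceError(
                "line search failed to reduce the residual", f, iterations
            )
        x, f, jac, norm = trial, f_trial, jac_trial, norm_trial
    converged = norm <= tol * scale
    if not converged:
        raise ConvergenceError(
            f"no convergence after {max_iter} iterations (|residual| = {norm:.3e})",
            f,
            iterations,
        )
    p, alpha, beta = (float(v) for v in x)
    mix = SpikeMixture(
        measured_ratios=tuple(measured),
        p=p,
        alpha=alpha,
        beta=beta,
        converged=True,
        iterations=iterations,
        residual=float(norm / scale),
    )
    if not mix.physical:
        warnings.warn(
            f"solved spike fraction p={p:.4f} is unphysical (outside [0, 1])",
            stacklevel=2,
        )
    return mix


def isotope_dilution_conc(
    mix: SpikeMixture,
    spike_mass_g: float,
    sample_dry_mass_g: float,
    system: IsotopeSystem,
) -> float:
    """Natural Cd concentration (mg/kg dry weight) by isotope dilution.

    The solved ``p`` gives the 110Cd molar split between spike and sample;
    the known spike amount then fixes the natural Cd amount::

        n110_natural = n110_spike * (1 - p) / p

    which converts to a natural Cd mass through the abundance and mean atomic
    mass of each composition.
    """
    if spike_mass_g <= 0 or sample_dry_mass_g <= 0:
        raise DoubleSpikeError("spike and sample masses must be positive")
    if not mix.converged:
        raise DoubleSpikeError("mixture has not converged; cannot quantify")
    if mix.p <= 0:
        raise DoubleSpikeError("no spike detected (p = 0); isotope dilution undefined")
    if mix.p >= 1:
        warnings.warn("p = 1: no natural Cd detected, returning 0", stacklevel=2)
        return 0.0

    spike_ng = system.spike_conc_ng_per_g * spike_mass_g
    x110_spike = system.abundances(np.asarray(system.spike_ratios))[0]
    n110_spike = spike_ng / system.atomic_mass(np.asarray(system.spike_ratios)) * x110_spike

    n110_natural = n110_spike * (1.0 - mix.p) / mix.p
    natural_ratios = np.asarray(system.reference_ratios) * system.mass_ratios**mix.alpha
    x110_nat = system.abundances(natural_ratios)[0]
    natural_ng = n110_natural / x110_nat * system.atomic_mass(natural_ratios)
    # ng per g of dry sample = ug/kg; divide by 1000 for mg/kg
    return natural_ng / sample_dry_mass_g / 1000.0


@dataclass(frozen=True)
class SpikePlan:
    """Recommended spike addition for one sample."""

    feasible: bool
    spike_cd_ng: float = field(default=float("nan"))
    spike_solution_g: float = field(default=float("nan"))
    window_ng: tuple[float, float] = (float("nan"), float("nan"))
    reason: str = ""


def plan_spike(
    estimated_natural_cd_ng: float,
    target_ratio_range: tuple[float, float] = (1.0, 2.0),
    target_total_ng: tuple[float, float] = (200.0, 300.0),
    system: IsotopeSystem | None = None,
) -> SpikePlan:
    """Choose a spike Cd amount for a sample of estimated natural Cd content.

    The spike:natural Cd mass ratio must land in ``target_ratio_range`` and
    the total (spike + natural) Cd in ``target_total_ng``. When both
    constraints can be met the midpoint of the feasible window is
    recommended; otherwise an explicit infeasibility result is returned
    (never a silently clamped value).
    """
    if estimated_natural_cd_ng <= 0:
        raise DoubleSpikeError("estimated natural Cd must be positive")
    lo_ratio, hi_ratio = target_ratio_range
    lo_total, hi_total = target_total_ng
    if not (lo_ratio < hi_ratio and lo_total < hi_total):
        raise DoubleSpikeError("target windows must be ordered (low < high)")

    n = estimated_natural_cd_ng
    lo = max(lo_ratio * n, lo_total - n)
    hi = min(hi_ratio * n, hi_total - n)
    if lo > hi or hi <= 0:
        return SpikePlan(
            feasible=False,
            reason=(
                f"no spike amount satisfies ratio in [{lo_ratio}, {hi_ratio}] and "
                f"total in [{lo_total}, {hi_total}] ng for {n:.4g} ng natural Cd"
            ),
        )
    lo = max(lo, 0.0)
    rec = 0.5 * (lo + hi)
    conc = system.spike_conc_ng_per_g if system is not None else float("nan")
    return SpikePlan(
        feasible=True,
        spike_cd_ng=rec,
        spike_solution_g=rec / conc,
        window_ng=(lo, hi),
    )
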