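"""Sigmoid modelling of root-hair length profiles.

Root-hair length as a function of distance d from the root tip is modelled
with the symmetric sigmoid

    f(d) = L_noise + (L_max - L_noise) / (1 + exp((d50 - d) / delta))

where L_max and L_noise are the upper and lower asymptotes (L_noise being
the small residual signal measured over the hairless zone), d50 the
inflection-point distance and delta the slope factor. The tangent at the
inflection point meets the asymptotes at d50 - 2*delta and d50 + 2*delta:
these delimit the root-hair growth region (width 4*delta), and the segment
from the tip to d50 - 2*delta estimates the combined cell division and
elongation zones. When the root growth rate is known, the hair growth rate
follows as (L_max - L_noise) / (4 * delta) * rate_root.

Fitting is a two-step least-squares procedure: a first fit over a
user-chosen range yields (d50_1, delta_1); the definitive fit is then
restricted to d50_1 +/- 5 * delta_1 (clipped to the data extent), which
trims the flat plateau and tip regions that would otherwise dominate the
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

__all__ = [
    "sigmoid",
    "sigmoid_slope",
    "SigmoidParams",
    "DerivedParams",
    "ConvergenceError",
    "RootHairSigmoidModel",
    "SigmoidFitResults",
    "TwoStepFitResults",
    "fit_sigmoid",
    "two_step_fit",
    "derive_parameters",
]


def sigmoid(d, L_noise, L_max, d50, delta):
    """The symmetric sigmoid f(d) (overflow-safe via the logistic expit)."""
    d = np.asarray(d, dtype=float)
    return L_noise + (L_max - L_noise) * expit((d - d50) / delta)


def sigmoid_slope(d, L_noise, L_max, d50, delta):
    """Analytic derivative df/dd; equals (L_max - L_noise)/(4 delta) at d50."""
    s = expit((np.asarray(d, dtype=float) - d50) / delta)
    return (L_max - L_noise) * s * (1.0 - s) / delta


class ConvergenceError(RuntimeError):
    """Raised when the least-squares fit does not converge.

    Carries the initial parameter values in ``initial_values``.
    """

    def __init__(self, message: str, initial_values: dict):
        super().__init__(message)
        self.initial_values = initial_values


@dataclass
class SigmoidParams:
    """Fitted sigmoid parameters with goodness of fit."""

    L_noise: float
    L_max: float
    d50: float
    delta: float
    r2: float
    fit_range_um: tuple
    n_points: int

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.fit_range_um[0] >= self.fit_range_um[1]:
            raise ValueError("fit range start must precede end")

    def predict(self, d):
        return sigmoid(d, self.L_noise, self.L_max, self.d50, self.delta)


@dataclass
class DerivedParams:
    """Biological quantities derived from the fitted sigmoid.

    initiation_um / arrest_um: positions where the inflection-point tangent
    meets the lower / upper asymptote (d50 -/+ 2 delta), used as the start
    and end of root-hair growth. growth_region_um is their separation
    (4 delta); div_elong_zone_um is the tip-to-initiation distance, an
    estimate of the cumulated division and elongation zones.
    rh_growth_rate_um_h is present only when a root growth rate was given.
    """

    initiation_um: float
    arrest_um: float
    growth_region_um: float
    div_elong_zone_um: float
    rh_growth_rate_um_h: float | None = None


def derive_parameters(
    p: SigmoidParams, root_growth_rate_um_h: float | None = None
) -> DerivedParams:
    """Compute the derived quantities from fitted sigmoid parameters.

    The hair growth rate is (L_max - L_noise) / (4 delta) times the root
    growth rate: hairs traverse the growth region (length 4 delta) at the
    root's elongation speed while growing from L_noise to L_max.
    """
    initiation = p.d50 - 2.0 * p.delta
    arrest = p.d50 + 2.0 * p.delta
    rate = None
    if root_growth_rate_um_h is not None:
        rate = (p.L_max - p.L_noise) / (4.0 * p.delta) * root_growth_rate_um_h
    return DerivedParams(
        initiation_um=initiation,
        arrest_um=arrest,
        growth_region_um=4.0 * p.delta,
        div_elong_zone_um=initiation,
        rh_growth_rate_um_h=rate,
    )


def _initial_values(d: np.ndarray, L: np.ndarray, range_um) -> np.ndarray:
    """Starting values for the optimiser.

    L_noise0 / L_max0 are the observed extremes; d50_0 is the first distance
    whose length reaches half of L_max0; delta0 is the first distance whose
    length reaches 5% of L_max0 (a tenth of the half-maximum level), falling
    back to a tenth of the range width when no point qualifies or the value
    would be non-positive.
    """
    L_noise0 = float(L.min())
    L_max0 = float(L.max())
    half = L_max0 / 2.0
    idx = np.nonzero(L >= half)[0]
    d50_0 = float(d[idx[0]]) if len(idx) else float(np.median(d))
    idx2 = np.nonzero(L >= 0.1 * half)[0]
    delta0 = float(d[idx2[0]]) if len(idx2) else 0.0
    if delta0 <= 0:
        delta0 = (range_um[1] - range_um[0]) / 10.0
    return np.array([L_noise0, L_max0, d50_0, delta0])


class RootHairSigmoidModel:
    """Symmetric-sigmoid model of a root-hair length profile.

    Parameters
    ----------
    d : array-like
        Distances from the root tip, µm.
    L : array-like
        Root-hair length estimates, µm.
    fit_range_um : (float, float), optional
        Restrict the fit to this distance range (defaults to the data
        extent).

    Use :meth:`from_profile` to build the model from an
    :class:`~roothairsizer.profile.RHProfile`, dropping annotated points.
    """

    MIN_POINTS = 8

    def __init__(self, d, L, fit_range_um: tuple | None = None):
        d = np.asarray(d, dtype=float)
        L = np.asarray(L, dtype=float)
        if d.shape != L.shape or d.ndim != 1:
            raise ValueError("d and L must be 1-D arrays of equal length")
        if fit_range_um is None:
            fit_range_um = (float(d.min()), float(d.max()))
        lo, hi = fit_range_um
        if hi <= lo:
            raise ValueError("fit range start must precede end")
        keep = (d >= lo) & (d <= hi)
        order = np.argsort(d[keep], kind="stable")
        self.d = d[keep][order]
        self.L = L[keep][order]
        self.fit_range_um = (float(lo), float(hi))
        if len(self.d) < self.MIN_POINTS:
            raise ValueError(
                f"need >= {self.MIN_POINTS} points in range, have {len(self.d)}"
            )
        if len(np.unique(self.d)) < 4:
            raise ValueError("distances must span >= 4 distinct values")

    @classmethod
    def from_profile(
        cls,
        profile,
        fit_range_um: tuple | None = None,
        exclude_flags: Iterable[str] = (),
        sides: Sequence[str] = ("left", "right"),
    ) -> "RootHairSigmoidModel":
        """Build the model from an RHProfile.

        Points carrying a set flag for any label in ``exclude_flags`` are
        dropped (annotated artefact regions), as are points from sides not
        listed in ``sides``.
        """
        excl = set(exclude_flags)
        pts = [
            p
            for p in profile.points
            if p.side in sides and not any(p.flags.get(lab, 0) for lab in excl)
        ]
        model = cls(
            [p.d_um for p in pts], [p.L_um for p in pts], fit_range_um=fit_range_um
        )
        model.n_excluded = len(profile.points) - len(pts)
        return model

    def fit(self, max_nfev: int = 5000) -> "SigmoidFitResults":
        """Unweighted least-squares fit of the sigmoid.

        Raises :class:`ConvergenceError` (carrying the initial values) when
        the optimiser fails, and ``ValueError`` on degenerate data (all
        lengths equal).
        """
        d, L = self.d, self.L
        ss_tot = float(np.sum((L - L.mean()) ** 2))
        if ss_tot == 0.0:
            raise ValueError("degenerate data: all lengths are equal")
        x0 = _initial_values(d, L, self.fit_range_um)
        lower = np.array([0.0, 0.0, -np.inf, 1e-9])
        upper = np.full(4, np.inf)
        x0 = np.clip(x0, lower + 1e-12, None)

        def resid(x):
            return sigmoid(d, *x) - L

        sol = least_squares(
            resid,
            x0,
            bounds=(lower, upper),
            method="trf",
            ftol=1e-8,
            xtol=1e-10,
            max_nfev=max_nfev,
        )
        init = dict(zip(("L_noise", "L_max", "d50", "delta"), x0))
        if not sol.success:
            raise ConvergenceError(f"sigmoid fit did not converge: {sol.message}", init)
        ss_res = float(np.sum(sol.fun**2))
        r2 = 1.0 - ss_res / ss_tot
        params = SigmoidParams(
            L_noise=float(sol.x[0]),
            L_max=float(sol.x[1]),
            d50=float(sol.x[2]),
            delta=float(sol.x[3]),
            r2=r2,
            fit_range_um=self.fit_range_um,
            n_points=len(d),
        )
        return SigmoidFitResults(self, params, sol)

    def fit_two_step(self, max_nfev: int = 5000) -> "TwoStepFitResults":
        """Two-step fit: a first fit over the model's range, then the
        definitive fit over d50_1 +/- 5 delta_1 (clipped to the data extent).
        """
        try:
            first = self.fit(max_nfev=max_nfev)
        except ConvergenceError as exc:
            raise ConvergenceError(f"first fit failed: {exc}", exc.initial_values) from exc
        except ValueError as exc:
            raise ValueError(f"first fit failed: {exc}") from exc
        p1 = first.params
        requested = (p1.d50 - 5.0 * p1.delta, p1.d50 + 5.0 * p1.delta)
        clipped = (
            max(requested[0], float(self.d.min())),
            min(requested[1], float(self.d.max())),
        )
        try:
            second_model = RootHairSigmoidModel(self.d, self.L, fit_range_um=clipped)
            final = second_model.fit(max_nfev=max_nfev)
        except ConvergenceError as exc:
            raise ConvergenceError(f"second fit failed: {exc}", exc.initial_values) from exc
        except ValueError as exc:
            raise ValueError(f"second fit failed: {exc}") from exc
        return TwoStepFitResults(
            first=first,
            final=final,
            requested_range_um=requested,
            clipped_range_um=clipped,
        )


class SigmoidFitResults:
    """Results of a sigmoid fit: estimates, standard errors, diagnostics."""

    _NAMES = ("L_noise", "L_max", "d50", "delta")

    def __init__(self, model: RootHairSigmoidModel, params: SigmoidParams, sol):
        self.model = model
        self.params = params
        self._sol = sol
        self.nobs = params.n_points
        self.bse = self._standard_errors(sol)

    def _standard_errors(self, sol) -> np.ndarray:
        # Gauss-Newton covariance: (J'J)^-1 * s^2, pseudo-inverted for safety
        dof = max(1, self.nobs - 4)
        s2 = float(np.sum(sol.fun**2)) / dof
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * s2
            return np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            return np.full(4, np.nan)

    @property
    def r2(self) -> float:
        return self.params.r2

    def values(self) -> np.ndarray:
        p = self.params
        return np.array([p.L_noise, p.L_max, p.d50, p.delta])

    def predict(self, d):
        return self.params.predict(d)

    def derived(self, root_growth_rate_um_h: float | None = None) -> DerivedParams:
        return derive_parameters(self.params, root_growth_rate_um_h)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Root-hair sigmoid fit",
            "=" * 46,
            f"{'n points':<16}{self.nobs:>10}",
            f"{'fit range (um)':<16}{p.fit_range_um[0]:>10.1f} .. {p.fit_range_um[1]:.1f}",
            f"{'r2':<16}{p.r2:>10.4f}",
            "-" * 46,
            f"{'param':<10}{'estimate':>12}{'std err':>12}",
        ]
        for name, val, se in zip(self._NAMES, self.values(), self.bse):
            lines.append(f"{name:<10}{val:>12.4g}{se:>12.3g}")
        der = self.derived()
        lines += [
            "-" * 46,
            f"{'initiation (um)':<22}{der.initiation_um:>12.1f}",
            f"{'arrest (um)':<22}{der.arrest_um:>12.1f}",
            f"{'growth region (um)':<22}{der.growth_region_um:>12.1f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "L_noise_um": p.L_noise,
            "L_max_um": p.L_max,
            "d50_um": p.d50,
            "delta_um": p.delta,
            "r2": p.r2,
            "fit_range_um": list(p.fit_range_um),
            "n_points": p.n_points,
            "bse": dict(zip(self._NAMES, self.bse.tolist())),
        }


@dataclass
class TwoStepFitResults:
    """First (range-finding) and final (definitive) sigmoid fits.

    ``requested_range_um`` is the second fit's range d50_1 +/- 5 delta_1 as
    requested; ``clipped_range_um`` is that range intersected with the data
    extent, which is what the final fit actually used.
    """

    first: SigmoidFitResults
    final: SigmoidFitResults
    requested_range_um: tuple
    clipped_range_um: tuple

    @property
    def params(self) -> SigmoidParams:
        return self.final.params

    def derived(self, root_growth_rate_um_h: float | None = None) -> DerivedParams:
        return self.final.derived(root_growth_rate_um_h)

    def summary(self) -> str:
        head = (
            f"Two-step fit: second range requested "
            f"[{self.requested_range_um[0]:.1f}, {self.requested_range_um[1]:.1f}] um, "
            f"used [{self.clipped_range_um[0]:.1f}, {self.clipped_range_um[1]:.1f}] um\n"
        )
        return head + self.final.summary()

    def plot(self, ax=None, root_growth_rate_um_h=None):
        """Data with both fits and the d50 +/- 2 delta growth-zone markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        m = self.first.model
        ax.plot(m.d, m.L, ".", color="0.6", ms=3, label="profile")
        lo, hi = self.clipped_range_um
        ax.axvspan(lo, hi, color="0.9", zorder=0)
        dd = np.linspace(m.d.min(), m.d.max(), 400)
        ax.plot(dd, self.first.predict(dd), "k-", lw=1, label="fit 1")
        ax.plot(dd, self.final.predict(dd), "r-", lw=1.5, label="fit 2")
        der = self.final.derived()
        for x in (der.initiation_um, der.arrest_um):
            ax.axvline(x, ls="--", color="b", lw=0.8)
        ax.set_xlabel("distance from root tip (um)")
        ax.set_ylabel("RH length (um)")
        ax.legend(frameon=False)
        return ax


# ---------------------------------------------------------------------------
# functional wrappers over the model objects


def fit_sigmoid(
    profile, range_um: tuple, exclude_flags: Iterable[str] = ()
) -> SigmoidParams:
    """Single least-squares sigmoid fit of a profile over a range."""
    model = RootHairSigmoidModel.from_profile(
        profile, fit_range_um=range_um, exclude_flags=exclude_flags
    )
    return model.fit().params


def two_step_fit(
    profile, first_range_um: tuple, exclude_flags: Iterable[str] = ()
) -> TwoStepFitResults:
    """Two-step sigmoid fit of a profile; the final fit is the result."""
    model = RootHairSigmoidModel.from_profile(
        profile, fit_range_um=first_range_um, exclude_flags=exclude_flags
    )
    return model.fit_two_step()
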