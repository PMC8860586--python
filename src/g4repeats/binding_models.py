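"""Equilibrium binding models: anisotropy titrations and Job plots.

Anisotropy titration (1:1 model).  With total labelled DNA ``D_tot``
and total protein tetramer ``V_tot``, the bound fraction ``b`` of DNA
is the exact root of the binding quadratic, and the observed
anisotropy is

    A_obs = A0 + dA * (D + V + KD - sqrt((D + V + KD)^2 - 4 D V)) / (2 D)

with D = D_tot, V = V_tot.  ``fit_titration`` recovers (KD, A0, dA) by
multi-start nonlinear least squares.

Job plot (continuous variation).  At fixed total concentration C of
DNA strands plus protein monomers, a DNA fraction x gives D0 = x*C
strands and T0 = (1-x)*C/4 tetramers; the one-step equilibrium
D + s*T <-> D*T_s (overall dissociation constant KD^s, i.e. KD per
step) is solved for the complex concentration.  The signal maximum
sits at x = 1/(1+4s) in the strong-binding limit, so one bound
tetramer peaks at 0.2 and two at 1/9 ~ 0.1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares


# --------------------------------------------------------------------------
# 1:1 anisotropy model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnisotropyModel:
    """1:1 binding parameters; concentrations in nM, anisotropy unitless."""

    kd: float  # dissociation constant (nM)
    a0: float  # anisotropy of free DNA
    da: float  # total anisotropy change on saturation
    d_tot: float  # total labelled DNA (nM)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_D must be > 0")
        if self.d_tot <= 0:
            raise ValueError("D_tot must be > 0")


def bound_fraction(kd: float, d_tot: float, v_tot) -> np.ndarray | float:
    """Exact 1:1 bound fraction of DNA from the binding quadratic."""
    v = np.asarray(v_tot, dtype=float)
    if (v < 0).any():
        raise ValueError("V_tot must be >= 0")
    s = d_tot + v + kd
    disc = s * s - 4.0 * d_tot * v
    b = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * d_tot)
    b = np.clip(b, 0.0, 1.0)
    return b if b.shape else float(b)


def anisotropy_model(model: AnisotropyModel, v_tot) -> np.ndarray | float:
    """Observed anisotropy A0 + dA*b at total tetramer concentration ``v_tot``."""
    return model.a0 + model.da * bound_fraction(model.kd, model.d_tot, v_tot)


def invert_bound_fraction(kd: float, d_tot: float, b: float) -> float:
    """Tetramer concentration producing bound fraction ``b`` (closed form).

    From the mass-action relation V = b*D_tot + b*KD/(1-b); the oracle
    inverse of ``bound_fraction``.
    """
    if not 0 <= b < 1:
        raise ValueError("b must be in [0, 1)")
    return b * d_tot + b * kd / (1.0 - b)


@dataclass
class TitrationFit:
    """Result of a 1:1 titration fit."""

    model: AnisotropyModel
    se: dict[str, float]
    residual_norm: float
    converged: bool
    identifiable: bool
    n_points: int
    starts_tried: int
    residuals: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kd_nM": self.model.kd,
            "a0": self.model.a0,
            "da": self.model.da,
            "d_tot_nM": self.model.d_tot,
            "se": self.se,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "n_points": self.n_points,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


class FitError(RuntimeError):
    """Non-convergent fit; carries the best attempt found."""

    def __init__(self, message: str, best: TitrationFit | None = None):
        super().__init__(message)
        self.best = best


def fit_titration(
    v_tot: Sequence[float],
    a_obs: Sequence[float],
    d_tot: float,
) -> TitrationFit:
    """Least-squares fit of (KD, A0, dA) to an anisotropy titration.

    ``v_tot`` are total tetramer concentrations (nM), ``a_obs`` the
    observed anisotropies.  KD is initialized at 0.1x/1x/10x the median
    positive concentration (multi-start) and A0/dA from the data
    extremes; asymptotic standard errors come from the Jacobian at the
    optimum.  A flat titration (no anisotropy change) is reported as
    unidentifiable rather than fitted to a meaningless KD.
    """
    v = np.asarray(v_tot, dtype=float)
    a = np.asarray(a_obs, dtype=float)
    if v.shape != a.shape or v.ndim != 1:
        raise ValueError("v_tot and a_obs must be 1-D arrays of equal length")
    if len(v) < 5:
        raise ValueError("need at least 5 titration points")
    if d_tot <= 0:
        raise ValueError("D_tot must be > 0")

    def resid(theta):
        kd, a0, da = theta
        return a0 + da * bound_fraction(kd, d_tot, v) - a

    mid = float(np.median(v[v > 0])) if (v > 0).any() else 1.0
    a0_init = float(a[np.argmin(v)])
    da_init = float(a[np.argmax(v)] - a0_init) or 1e-3
    best = None
    starts = [0.1 * mid, mid, 10.0 * mid]
    for kd0 in starts:
        try:
            sol = least_squares(
                resid,
                x0=[kd0, a0_init, da_init],
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        partial = None
        if best is not None:
            kd, a0, da = best.x
            partial = TitrationFit(
                AnisotropyModel(max(kd, 1e-12), a0, da, d_tot),
                {}, float(np.linalg.norm(best.fun)), False, False,
                len(v), len(starts), best.fun,
            )
        raise FitError("titration fit did not converge", best=partial)

    kd, a0, da = (float(t) for t in best.x)
    dof = max(len(v) - 3, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se_vec = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        se = {"kd": float(se_vec[0]), "a0": float(se_vec[1]), "da": float(se_vec[2])}
        singular = False
    except np.linalg.LinAlgError:
        se = {"kd": float("inf"), "a0": float("inf"), "da": float("inf")}
        singular = True

    a_span = float(a.max() - a.min())
    identifiable = bool(
        not singular
        and abs(da) > max(1e-9, 1e-3 * max(a_span, 1e-12))
        and np.isfinite(se["kd"])
        and se["kd"] < 100.0 * max(kd, 1e-12)
    )
    return TitrationFit(
        model=AnisotropyModel(kd, a0, da, d_tot),
        se=se,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=True,
        identifiable=identifiable,
        n_points=len(v),
        starts_tried=len(starts),
        residuals=best.fun,
    )


# --------------------------------------------------------------------------
# Job plot (continuous variation)
# --------------------------------------------------------------------------


@dataclass
class JobSeries:
    """Continuous-variation series.

    ``fractions`` are DNA-strand molar fractions of the fixed total
    ``total_uM`` (DNA strands + protein monomers); ``signal`` is the
    equilibrium complex concentration (uM); ``s`` is the number of
    tetramers bound per DNA.
    """

    fractions: np.ndarray
    signal: np.ndarray
    total_uM: float
    s: int
    kd_nM: float | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fractions.shape != self.signal.shape:
            raise ValueError("fractions and signal must have equal length")
        if (np.diff(self.fractions) <= 0).any():
            raise ValueError("fractions must be strictly increasing")
        if (self.signal < -1e-12).any():
            raise ValueError("signal must be >= 0")


def solve_complex_uM(d0: float, t0: float, s: int, kd_step_uM: float) -> float:
    """Complex concentration for D + s*T <-> complex at one grid point.

    One-step overall equilibrium with dissociation constant
    ``kd_step_uM**s``: solves (D0-C)*(T0-s*C)^s = KD^s * C by a
    bracketing root search on [0, min(D0, T0/s)] (relative tolerance
    1e-12).
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if d0 < 0 or t0 < 0:
        raise ValueError("concentrations must be >= 0")
    c_max = min(d0, t0 / s)
    if c_max <= 0:
        return 0.0
    k_ov = kd_step_uM ** s

    def f(c):
        return (d0 - c) * (t0 - s * c) ** s - k_ov * c

    # f(0) > 0, f(c_max) < 0: a sign change is guaranteed
    return float(brentq(f, 0.0, c_max, rtol=1e-12, xtol=1e-30, maxiter=300))


def equilibrium_residual(d0: float, t0: float, s: int, kd_step_uM: float, c: float) -> float:
    """Relative mass-action residual of a solved point (conservation audit)."""
    k_ov = kd_step_uM ** s
    lhs = (d0 - c) * (t0 - s * c) ** s
    rhs = k_ov * c
    scale = max(abs(lhs), abs(rhs), d0 * t0 ** s * 1e-30)
    return abs(lhs - rhs) / scale if scale > 0 else 0.0


def simulate_job_series(
    s: int,
    kd_nM: float = 25.0,
    total_uM: float = 10.0,
    fractions: Sequence[float] | None = None,
) -> JobSeries:
    """Simulate the continuous-variation experiment.

    For each DNA fraction x of the fixed total (DNA strands + protein
    monomers, default 10 uM): D0 = x*total, monomers = (1-x)*total,
    tetramers T0 = monomers/4; the one-step equilibrium D + s*T <->
    complex is solved for the complex concentration.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.02, 0.99, 0.02), 10)
    x = np.asarray(fractions, dtype=float)
    if ((x <= 0) | (x >= 1)).any():
        raise ValueError("fractions must lie strictly inside (0, 1)")
    kd_uM = kd_nM * 1e-3
    signal = np.empty_like(x)
    for i, xi in enumerate(x):
        d0 = xi * total_uM
        t0 = (1.0 - xi) * total_uM / 4.0
        signal[i] = solve_complex_uM(d0, t0, s, kd_uM)
    return JobSeries(x, signal, total_uM, s, kd_nM)


@dataclass(frozen=True)
class JobPeak:
    fraction: float  # interpolated peak DNA molar fraction
    grid_fraction: float  # argmax on the measured grid
    s_inferred: int  # tetramers bound per DNA: round((1/x - 1)/4)
    signal_max: float


def job_peak(series: JobSeries) -> JobPeak:
    """Locate the complex-signal maximum and infer the stoichiometry.

    The grid argmax is refined by the vertex of the parabola through
    the top point and its neighbours (skipped at grid edges); the
    number of tetramers per DNA follows from the peak fraction x* as
    round((1/x* - 1)/4).
    """
    x, y = series.fractions, series.signal
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    span = float(y.max() - y.min())
    if span <= 0 or (y.max() > 0 and span < 1e-9 * y.max()):
        raise ValueError("flat series: no peak")
    i = int(np.argmax(y))
    xi = float(x[i])
    if 0 < i < len(x) - 1:
        x3, y3 = x[i - 1 : i + 2], y[i - 1 : i + 2]
        denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
        a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
        b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0]) + x3[0] ** 2 * (y3[1] - y3[2])) / denom
        if a < 0:
            xv = -b / (2 * a)
            if x3[0] <= xv <= x3[2]:
                xi = float(xv)
    s_inf = int(round((1.0 / xi - 1.0) / 4.0))
    return JobPeak(xi, float(x[i]), s_inf, float(y.max()))


# --------------------------------------------------------------------------
# circular dichroism
# --------------------------------------------------------------------------


def molar_ellipticity(theta_mdeg, residue_conc_M: float, path_cm: float = 1.0):
    """Convert observed ellipticity (mdeg) to molar ellipticity.

    [theta] = theta_mdeg / (10 * path_cm * residue_conc_M), in
    deg cm^2 dmol^-1, using the DNA *residue* concentration.
    """
    if residue_conc_M <= 0:
        raise ValueError("residue concentration must be > 0")
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    return np.asarray(theta_mdeg, dtype=float) / (10.0 * path_cm * residue_conc_M)
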