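"""Usual-intake distribution construction (1-d and 2-d paths).

A person's usual intake is their long-run mean daily intake; across people it
varies only through the between-individual component.  On the transformed
scale a person's usual value is mu + b_i with b_i ~ N(0, s_b2); the
distribution on the original scale is the bias-corrected back-transformation
of that normal, evaluated on a deterministic percentile grid.

Two routes supply (s_b2, s_w2):

* **2-d path** — both components estimated from repeat-day data
  (:func:`intakevar.mixed_model.decompose`);
* **1-d path** — only the total variance is estimable from single-day data;
  an externally supplied WIV:total ratio beta splits it as
  s_w2 = beta * s_total2, s_b2 = (1 - beta) * s_total2.

As beta grows the modeled usual-intake distribution shrinks toward its
center; at beta = 1 it collapses to a point, which is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import VarianceComponents, _build_design
from .ratios import VarianceRatio
from .transform import TransformSpec, boxcox_apply, boxcox_inverse_taylor, \
    _inverse_domain_ok

__all__ = [
    "UsualIntakeDistribution",
    "total_variance_1d",
    "partition_external",
    "model_distribution",
    "model_distribution_2d",
    "BETA_UPPER_GUARD",
]

#: Assumed WIV:total at or above this is refused: the modeled distribution
#: degenerates toward a point mass and loses validity.
BETA_UPPER_GUARD = 0.995


@dataclass
class UsualIntakeDistribution:
    """Discrete usual-intake distribution on the original nutrient scale."""

    grid: np.ndarray
    masses: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.grid.shape != self.masses.shape:
            raise ValueError("grid and masses must align")
        if np.any(self.masses < 0):
            raise ValueError("masses must be >= 0")
        if abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")
        if np.any(np.diff(self.grid) < 0):
            raise ValueError("grid must be nondecreasing")

    @property
    def mean(self) -> float:
        return float(np.sum(self.grid * self.masses))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.sum(self.masses * (self.grid - m) ** 2))

    @property
    def is_point_mass(self) -> bool:
        return bool(np.ptp(self.grid) == 0)

    def quantile(self, p):
        cum = np.cumsum(self.masses)
        idx = np.searchsorted(cum, np.asarray(p, dtype=float), side="left")
        idx = np.clip(idx, 0, self.grid.size - 1)
        out = self.grid[idx]
        return out if out.ndim else float(out)

    def cdf(self, x) -> float:
        """P(usual intake < x)."""
        return float(self.masses[self.grid < x].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "usual_intake": self.grid,
            "mass": self.masses,
            "cum_prob": np.cumsum(self.masses),
        })


def total_variance_1d(
    data: pd.DataFrame,
    transform: TransformSpec,
    subject_col: str = "subject_id",
    intake_col: str = "intake",
    sequence_col: str | None = None,
    weekend_col: str | None = "weekend",
    extra_fixed_effects: tuple = (),
    weight_col: str | None = None,
) -> dict:
    """Total (residual) variance of transformed single-day intakes.

    Fits (weighted) least squares of the transformed intake on the
    configured fixed effects and returns ``{"mu": prediction at reference
    levels, "s_total2": residual variance, "fixed_effects": {...}, "n": n}``.
    With single-day data the between- and within-individual components are
    confounded; this total is what an external WIV:total ratio partitions.

    Raises
    ------
    ValueError
        If any subject appears more than once (repeats belong to the 2-d
        path - mixing them here would double count days as people).
    """
    counts = data.groupby(subject_col).size()
    if (counts > 1).any():
        raise ValueError(
            "repeats present: dataset has subjects with multiple days; "
            "use the 2-d path (decompose + model_distribution_2d)")
    y = boxcox_apply(data[intake_col].to_numpy(dtype=float), transform)
    # single-day data: sequence is constant, so only weekend/extras enter
    X, names = _build_design(
        data.assign(_seq=1), "_seq", weekend_col, extra_fixed_effects)
    w = (np.ones(len(data)) if weight_col is None
         else data[weight_col].to_numpy(dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    sw = np.sqrt(w)
    beta_hat, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta_hat
    dof = max(len(y) - X.shape[1], 1)
    s_total2 = float(np.sum(w * resid**2) / (w.sum() * dof / len(y)))
    fe = dict(zip(names, beta_hat))
    mu = float(fe.pop("Intercept"))
    return {"mu": mu, "s_total2": s_total2, "fixed_effects": fe, "n": len(y)}


def partition_external(s_total2: float, beta_external) -> dict:
    """Split a total variance with an external WIV:total ratio.

    ``s_b2 = (1 - beta) * s_total2``; ``s_w2 = beta * s_total2``; the two
    reconstruct ``s_total2`` exactly.

    Raises
    ------
    ValueError
        If beta is outside [0, 1) - beta = 1 would remove all variance and
        return a single point estimate (degenerate).
    """
    if isinstance(beta_external, VarianceRatio):
        if beta_external.kind != "wiv_to_total":
            raise ValueError(
                "external ratio must be on the WIV:total scale "
                "(convert first)")
        beta = beta_external.value
    else:
        beta = float(beta_external)
    if s_total2 < 0:
        raise ValueError("s_total2 must be >= 0")
    if beta == 1:
        raise ValueError(
            "degenerate: beta = 1 removes all between-individual variance "
            "and returns a point-mass distribution")
    if not 0 <= beta < 1:
        raise ValueError(f"beta must lie in [0, 1), got {beta}")
    return {"s_w2": beta * s_total2, "s_b2": (1.0 - beta) * s_total2}


def model_distribution(
    mu: float,
    s_b2: float,
    s_w2: float,
    transform: TransformSpec,
    grid_size: int = 400,
    weekend_coef: float | None = None,
    beta_used: float | None = None,
    path: str = "one_day",
) -> UsualIntakeDistribution:
    """Usual-intake distribution from transformed-scale parameters.

    The grid is the Taylor-corrected back-transformation of
    ``mu + sqrt(s_b2) * z_p`` at percentile midpoints p = (k - 0.5)/G with
    equal masses 1/G.  When ``weekend_coef`` is given, the per-person usual
    transformed value is the day-type mixture
    ``5/7 * weekday + 2/7 * weekend``, i.e. ``mu + 2/7 * weekend_coef``.
    Grid points whose back-transformation leaves the domain are clamped to
    the boundary and counted in ``meta["n_clamped"]``.
    """
    if s_b2 < 0:
        raise ValueError("s_b2 must be >= 0")
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    mu_eff = mu + (2.0 / 7.0) * weekend_coef if weekend_coef else mu
    if s_b2 == 0:
        value = boxcox_inverse_taylor(mu_eff, s_w2, transform, clamp=True)
        grid = np.array([max(value, 0.0)])
        masses = np.array([1.0])
        n_clamped = 0
    else:
        p = (np.arange(1, grid_size + 1) - 0.5) / grid_size
        z = stats.norm.ppf(p)
        ty = mu_eff + np.sqrt(s_b2) * z
        ok = _inverse_domain_ok(ty, transform.lam)
        n_clamped = int(np.sum(~ok))
        grid = np.asarray(
            boxcox_inverse_taylor(ty, s_w2, transform, clamp=True),
            dtype=float)
        if np.any(~np.isfinite(grid)):  # lam < 0 upper-boundary clamp
            cap = grid[np.isfinite(grid)].max(initial=0.0)
            grid = np.where(np.isfinite(grid), grid, cap)
        grid = np.maximum(grid, 0.0)  # intakes are nonnegative
        grid = np.maximum.accumulate(grid)  # guard monotonicity at clamps
        masses = np.full(grid_size, 1.0 / grid_size)
    if n_clamped:
        warnings.warn(
            f"{n_clamped} grid points clamped to the back-transformation "
            "domain boundary", stacklevel=2)
    meta = {
        "lambda": transform.lam, "shift": transform.shift,
        "s_w2_used": s_w2, "s_b2_used": s_b2,
        "beta_used": beta_used if beta_used is not None
        else (s_w2 / (s_w2 + s_b2) if s_w2 + s_b2 > 0 else None),
        "mu": mu, "path": path, "grid_size": grid_size,
        "n_clamped": n_clamped,
    }
    return UsualIntakeDistribution(grid=grid, masses=masses, meta=meta)


def model_distribution_2d(
    components: VarianceComponents,
    transform: TransformSpec | None = None,
    grid_size: int = 400,
) -> UsualIntakeDistribution:
    """2-d path: distribution from estimated components.

    Identical construction to :func:`model_distribution` with the REML
    (s_b2, s_w2); ``meta["path"] = "two_day"``.  A boundary-flagged s_b2 = 0
    collapses to a point mass (with a warning).
    """
    spec = transform if transform is not None else components.transform
    if components.s_b2 == 0:
        warnings.warn(
            "between-individual variance at boundary 0: usual-intake "
            "distribution is a point mass", stacklevel=2)
    wk = components.fixed_effects.get("weekend")
    return model_distribution(
        mu=components.mu, s_b2=components.s_b2, s_w2=components.s_w2,
        transform=spec, grid_size=grid_size, weekend_coef=wk,
        beta_used=components.beta, path="two_day",
    )
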