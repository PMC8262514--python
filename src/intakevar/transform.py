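"""Box-Cox transformation with lambda chosen by residual normality.

Daily nutrient intakes are right-skewed; variance decomposition assumes
normal residuals on some transformed scale.  The transformation family is

    g(x) = ((x + shift)**lam - 1) / lam     (lam != 0)
    g(x) = log(x + shift)                   (lam == 0)

with ``shift >= 0`` accommodating occasional zero intakes.  ``lam`` is
selected on a grid by maximizing the Shapiro-Wilk statistic of the
residuals of the variance-decomposition model refitted at each candidate —
the scale on which the residuals look most normal wins.  By default the
marginal residuals (person effect + day deviation) are scored; the
within-subject conditional set is available but identifies the power only
weakly when day-to-day spread is small.

Back-transformation of a *usual* (person-level mean) value must account for
the day-level noise that the transformation curvature turns into bias; the
second-order Taylor correction

    BT(y) = g_inv(y) + 0.5 * s_w2 * g_inv''(y)

is the standard device (the same one the NCI macros apply).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TransformSpec",
    "boxcox_apply",
    "boxcox_inverse",
    "boxcox_inverse_taylor",
    "fit_lambda",
    "default_shift",
]


@dataclass(frozen=True)
class TransformSpec:
    """A fitted (or fixed) Box-Cox transformation.

    Attributes
    ----------
    lam : float
        Box-Cox power.
    shift : float
        Nonnegative constant added to intakes before transformation.
    normality_score : float or None
        Shapiro-Wilk W of the model residuals at the chosen ``lam``
        (None when the spec was fixed by hand).
    search_trace : tuple of (lam, score) pairs
        Grid-search trace, for run logs.
    """

    lam: float
    shift: float = 0.0
    normality_score: float | None = None
    residual_set: str = "marginal"
    search_trace: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be >= 0")

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "shift": self.shift,
            "normality_score": self.normality_score,
            "residual_set": self.residual_set,
        }


def boxcox_apply(x, spec: TransformSpec):
    """Apply ``g`` to intake values. Raises on ``x + shift <= 0``."""
    x = np.asarray(x, dtype=float)
    z = x + spec.shift
    if np.any(z <= 0):
        raise ValueError(
            "domain error: intake + shift must be > 0 for the Box-Cox "
            "transformation"
        )
    lam = spec.lam
    if lam == 0:
        out = np.log(z)
    else:
        out = (np.power(z, lam) - 1.0) / lam
    return out if out.ndim else float(out)


def _inverse_domain_ok(y, lam):
    if lam == 0:
        return np.ones(np.shape(y), dtype=bool)
    return lam * np.asarray(y, dtype=float) + 1.0 > 0


def boxcox_inverse(y, spec: TransformSpec, clamp: bool = False):
    """Exact inverse ``g_inv(y) = (lam*y + 1)**(1/lam) - shift``.

    Out-of-range ``y`` (``lam*y + 1 <= 0`` for ``lam != 0``) raises a domain
    error unless ``clamp=True``, which maps such points to the domain
    boundary (value ``-shift``, i.e. zero intake when ``shift = 0``).
    """
    y = np.asarray(y, dtype=float)
    lam = spec.lam
    if lam == 0:
        out = np.exp(y) - spec.shift
    else:
        arg = lam * y + 1.0
        bad = arg <= 0
        if np.any(bad):
            if not clamp:
                raise ValueError(
                    "domain error: lam*y + 1 <= 0 has no back-transform "
                    "(pass clamp=True to map to the boundary)"
                )
            arg = np.where(bad, 0.0, arg)
        with np.errstate(divide="ignore"):
            # boundary for lam > 0 is intake 0; for lam < 0 it is +inf
            out = np.power(arg, 1.0 / lam) - spec.shift
    return out if out.ndim else float(out)


def _ginv_second_derivative(y, lam):
    """d2/dy2 of the inverse transform (shift does not enter)."""
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return np.exp(y)
    arg = lam * y + 1.0
    return (1.0 - lam) * np.power(arg, 1.0 / lam - 2.0)


def boxcox_inverse_taylor(y, s_w2: float, spec: TransformSpec,
                          clamp: bool = False):
    """Bias-corrected back-transformation of a usual (person-mean) value.

    ``BT(y) = g_inv(y) + 0.5 * s_w2 * g_inv''(y)``.  With ``s_w2 = 0`` this
    is the exact inverse; for ``lam = 1`` the inverse is linear and the
    correction vanishes identically.  For convex inverses (``lam < 1``) the
    correction is nonnegative.
    """
    if s_w2 < 0:
        raise ValueError("s_w2 must be >= 0")
    base = boxcox_inverse(y, spec, clamp=clamp)
    if s_w2 == 0:
        return base
    y_arr = np.asarray(y, dtype=float)
    ok = _inverse_domain_ok(y_arr, spec.lam)
    corr = np.where(ok, _ginv_second_derivative(np.where(ok, y_arr, 0.0),
                                                spec.lam), 0.0)
    out = np.asarray(base) + 0.5 * s_w2 * corr
    return out if out.ndim else float(out)


def default_shift(intakes) -> float:
    """Half the smallest positive observed intake if zeros occur, else 0."""
    x = np.asarray(intakes, dtype=float)
    if np.all(x > 0):
        return 0.0
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("degenerate data: no positive intakes")
    return float(pos.min() / 2.0)


def _marginal_residuals(y, X):
    """Residuals after removing fixed effects only (subject effect kept)."""
    y = np.asarray(y, dtype=float)
    if X is not None and X.shape[1] > 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta
    return y - y.mean()


def _conditional_residuals(y, subject, X):
    """Within-subject residuals after removing fixed effects by OLS.

    For a model with a subject random intercept, the conditional (level-1)
    residuals are the deviations of each day from its subject's predicted
    mean; on balanced data subject-demeaning the OLS fixed-effect residuals
    reproduces that set exactly (BLUP shrinkage moves only the subject
    means, which demeaning removes).
    """
    y = np.asarray(y, dtype=float)
    if X is not None and X.shape[1] > 0:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:
        resid = y - y.mean()
    _, inv = np.unique(subject, return_inverse=True)
    counts = np.bincount(inv)
    if np.all(counts == 1):
        return resid  # single-day data: marginal residuals
    means = np.bincount(inv, weights=resid) / counts
    return resid - means[inv]


def _normality_score(resid) -> float:
    resid = np.asarray(resid, dtype=float)
    if resid.size > 5000:  # Shapiro-Wilk p-values degrade; W is still fine
        rng = np.random.default_rng(0)
        resid = rng.choice(resid, size=5000, replace=False)
    if np.ptp(resid) == 0:
        return -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(resid).statistic)


def fit_lambda(
    data,
    intake_col: str = "intake",
    subject_col: str = "subject_id",
    fixed_effect_cols: tuple = ("sequence", "weekend"),
    lambda_grid=None,
    shift: float | None = None,
    refine: bool = True,
    engine: str = "fast",
    residual_set: str = "marginal",
):
    """Select the Box-Cox power by residual normality on a grid.

    At each candidate ``lam`` the intake column is transformed and the
    variance-decomposition model (fixed effects + subject random intercept)
    is refitted; the ``lam`` whose conditional residuals score highest on
    Shapiro-Wilk wins.  The default grid is -2..2 in steps of 0.05 with one
    refinement pass at 0.01 resolution around the best candidate.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format recalls (one row per subject-day).
    engine : {"fast", "reml"}
        "fast" computes residuals by least squares on the fixed effects
        (plus subject demeaning for the conditional set; exact for balanced
        designs); "reml" refits the full mixed model at every candidate
        (slow, for audit).
    residual_set : {"marginal", "conditional"}
        Which residuals feed the normality score.  Marginal residuals
        (subject effect + day deviation) are the default: they carry the
        full between+within spread, so the power is well identified.  The
        conditional (within-subject) set checks only day-to-day normality
        and is weakly identifying when the within-day spread is small.

    Returns
    -------
    TransformSpec
    """
    y_raw = np.asarray(data[intake_col], dtype=float)
    if y_raw.size < 30:
        raise ValueError("need at least 30 observations to select lambda")
    if shift is None:
        shift = default_shift(y_raw)
    if np.any(y_raw + shift <= 0):
        raise ValueError("intake + shift must be > 0")
    if np.ptp(y_raw) == 0:
        raise ValueError("degenerate data: all intakes identical")
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 10)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    subject = np.asarray(data[subject_col])
    X = _design_matrix(data, fixed_effect_cols)

    if residual_set not in ("marginal", "conditional"):
        raise ValueError(f"unknown residual_set {residual_set!r}")

    def score(lam: float) -> float:
        spec = TransformSpec(lam=lam, shift=shift)
        ty = boxcox_apply(y_raw, spec)
        if residual_set == "marginal":
            resid = _marginal_residuals(ty, X)
        elif engine == "reml":
            resid = _reml_conditional_residuals(ty, subject, X)
        else:
            resid = _conditional_residuals(ty, subject, X)
        return _normality_score(resid)

    trace = [(float(l), score(float(l))) for l in lambda_grid]
    best_lam, best_score = max(trace, key=lambda t: t[1])
    if refine and len(lambda_grid) > 1:
        step = float(np.min(np.diff(np.sort(lambda_grid))))
        fine = np.round(np.arange(best_lam - step, best_lam + step + 1e-9,
                                  0.01), 10)
        fine_trace = [(float(l), score(float(l))) for l in fine
                      if not any(abs(l - t[0]) < 1e-9 for t in trace)]
        trace.extend(fine_trace)
        best_lam, best_score = max(trace, key=lambda t: t[1])
    return TransformSpec(
        lam=best_lam, shift=shift, normality_score=best_score,
        residual_set=residual_set, search_trace=tuple(trace),
    )


def _design_matrix(data, fixed_effect_cols):
    """Intercept + treatment-coded categorical columns that exist and vary."""
    import pandas as pd

    n = len(data)
    cols = [np.ones(n)]
    for name in fixed_effect_cols:
        if name not in data.columns:
            continue
        col = data[name]
        if col.isna().all():
            continue
        dummies = pd.get_dummies(col, drop_first=True, dtype=float)
        for c in dummies.columns:
            v = dummies[c].to_numpy()
            if np.ptp(v) > 0:
                cols.append(v)
    return np.column_stack(cols)


def _reml_conditional_residuals(ty, subject, X):
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(ty, X, groups=subject)
        fit = model.fit(reml=True)
    fitted_re = np.zeros_like(ty)
    re = fit.random_effects
    for i, g in enumerate(subject):
        fitted_re[i] = float(np.asarray(re[g])[0])
    return ty - X @ fit.fe_params - fitted_re
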