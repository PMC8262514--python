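"""Variance decomposition of transformed intakes via a linear mixed model.

The model on the transformed scale is

    g(intake_ij) = mu + seq_j + weekend*w_ij + b_i + e_ij,
    b_i ~ N(0, s_b2),   e_ij ~ N(0, s_w2),

with recall sequence as a categorical fixed effect, an optional weekend
indicator, a subject random intercept, and independent day residuals.  The
within-individual variance (WIV) is the residual variance s_w2; the
between-individual variance (BIV) is the random-intercept variance s_b2.
The default estimator is REML (statsmodels MixedLM, the lme4-equivalent
path); ``method="anova"`` gives the classical one-way method-of-moments
estimator, which is unbounded below and can report a negative s_b2 — useful
both as an independent cross-check and to surface the beta > 1 artifacts
that a boundary-constrained REML hides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratios import components_to_ratios
from .transform import TransformSpec, boxcox_apply

__all__ = [
    "VarianceComponents",
    "CannotDecomposeError",
    "decompose",
    "decompose_by_group",
    "anova_components",
]

#: Below this many subjects the decomposition warns (the conventional
#: guidance asks for repeat observations on at least 30-40 individuals).
DEFAULT_MIN_SUBJECTS = 30


class CannotDecomposeError(ValueError):
    """Dataset has no repeat days: within/between split is unidentifiable."""


@dataclass
class VarianceComponents:
    """REML (or ANOVA) variance components on the transformed scale."""

    s_w2: float
    s_b2: float
    mu: float
    fixed_effects: dict
    transform: TransformSpec
    n_subjects: int
    n_with_repeats: int
    method: str = "reml"
    flags: list = field(default_factory=list)
    converged: bool = True

    @property
    def beta(self) -> float:
        """WIV:total on the transformed scale."""
        return components_to_ratios(self.s_w2, self.s_b2)["beta"]

    @property
    def s_total2(self) -> float:
        return self.s_w2 + self.s_b2

    def to_dict(self) -> dict:
        return {
            "s_w2": self.s_w2, "s_b2": self.s_b2, "mu": self.mu,
            "beta": self.beta, "method": self.method,
            "n_subjects": self.n_subjects,
            "n_with_repeats": self.n_with_repeats,
            "fixed_effects": dict(self.fixed_effects),
            "flags": list(self.flags), "converged": self.converged,
            "transform": self.transform.to_dict(),
        }


def _validate(data, subject_col, sequence_col, intake_col):
    if sequence_col is not None and data.duplicated(
            [subject_col, sequence_col]).any():
        raise ValueError(
            f"duplicate ({subject_col}, {sequence_col}) pairs in dataset")
    if (data[intake_col] < 0).any():
        raise ValueError("intakes must be >= 0")


def _repeat_counts(data, subject_col):
    counts = data.groupby(subject_col).size()
    return int(len(counts)), int((counts >= 2).sum())


def _build_design(data, sequence_col, weekend_col, extra_cols):
    """Treatment-coded design matrix and coefficient names (no intercept col
    returned separately; intercept is first)."""
    n = len(data)
    cols = {"Intercept": np.ones(n)}
    if sequence_col is not None and sequence_col in data.columns:
        seq = data[sequence_col]
        for lev in sorted(seq.unique())[1:]:
            cols[f"sequence[{lev}]"] = (seq == lev).to_numpy(dtype=float)
    if weekend_col is not None and weekend_col in data.columns:
        wk = data[weekend_col]
        if wk.notna().any() and wk.fillna(0).nunique() > 1:
            cols["weekend"] = wk.fillna(0).to_numpy(dtype=float)
    for name in extra_cols or ():
        col = data[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
            cols[name] = col.to_numpy(dtype=float)
        else:
            for lev in sorted(col.unique())[1:]:
                cols[f"{name}[{lev}]"] = (col == lev).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def anova_components(y, subject, X=None):
    """One-way ANOVA method-of-moments components (the classical oracle).

    After removing fixed effects (OLS on ``X`` if given), the balanced-design
    mean squares give s_w2 = MSW and s_b2 = (MSB - MSW) / k0 where k0 is the
    (harmonic-adjusted) per-subject day count.  s_b2 may be negative.
    """
    y = np.asarray(y, dtype=float)
    if X is not None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta + y.mean()  # keep location for mu elsewhere
    else:
        resid = y
    _, inv = np.unique(subject, return_inverse=True)
    counts = np.bincount(inv)
    g = counts.size
    n = y.size
    means = np.bincount(inv, weights=resid) / counts
    grand = resid.mean()
    ssw = float(np.sum((resid - means[inv]) ** 2))
    ssb = float(np.sum(counts * (means - grand) ** 2))
    if n - g == 0:
        raise CannotDecomposeError(
            "cannot decompose - every subject has a single day; "
            "use the external-ratio (1-d) path")
    msw = ssw / (n - g)
    msb = ssb / (g - 1)
    k0 = (n - np.sum(counts**2) / n) / (g - 1)
    return {"s_w2": msw, "s_b2": (msb - msw) / k0, "msw": msw, "msb": msb}


def _profile_reml(y, subject, X, psi_hint=None):
    """Polish the random-intercept REML optimum by 1-D profiling.

    For a single random intercept the covariance is block diagonal,
    V_i = s_w2 (I + psi J) with psi = s_b2/s_w2, so both the GLS fixed
    effects and the residual variance profile out in closed form and the
    REML criterion reduces to a scalar function of psi, which is maximized
    to high precision.  Returns (s_w2, s_b2, fe_params).
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    _, inv = np.unique(subject, return_inverse=True)
    counts = np.bincount(inv)
    n, p = y.size, X.shape[1]

    def crit_and_est(psi):
        shrink = psi / (1.0 + counts * psi)  # per group
        # X' W^-1 X and X' W^-1 y via group totals
        Xg = np.zeros((counts.size, p))
        for j in range(p):
            Xg[:, j] = np.bincount(inv, weights=X[:, j])
        yg = np.bincount(inv, weights=y)
        XtWX = X.T @ X - (Xg * shrink[:, None]).T @ Xg
        XtWy = X.T @ y - (Xg * shrink[:, None]).T @ yg
        beta = np.linalg.solve(XtWX, XtWy)
        resid = y - X @ beta
        rg = np.bincount(inv, weights=resid)
        rss = float(resid @ resid - np.sum(shrink * rg**2))
        s_w2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtWX)
        neg2l = ((n - p) * np.log(s_w2)
                 + float(np.sum(np.log1p(counts * psi))) + logdet)
        return neg2l, s_w2, beta

    hi = max(10.0, 20.0 * psi_hint) if psi_hint else 50.0
    res = minimize_scalar(lambda psi: crit_and_est(psi)[0],
                          bounds=(0.0, hi), method="bounded",
                          options={"xatol": 1e-12})
    psi = float(res.x)
    _, s_w2, beta = crit_and_est(psi)
    # check the boundary explicitly: bounded search cannot land on 0 exactly
    if psi < 1e-8 and crit_and_est(0.0)[0] <= crit_and_est(psi)[0]:
        psi = 0.0
        _, s_w2, beta = crit_and_est(0.0)
    return s_w2, psi * s_w2, beta


def decompose(
    data: pd.DataFrame,
    transform: TransformSpec,
    subject_col: str = "subject_id",
    sequence_col: str | None = "sequence",
    weekend_col: str | None = "weekend",
    intake_col: str = "intake",
    extra_fixed_effects: tuple = (),
    method: str = "reml",
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
) -> VarianceComponents:
    """Estimate (s_w2, s_b2, mu, fixed effects) on the transformed scale.

    Parameters
    ----------
    data : long-format recalls, one row per subject-day.
    transform : fitted or fixed :class:`TransformSpec`.
    method : {"reml", "anova"}
        REML via statsmodels MixedLM (default; s_b2 constrained >= 0, a zero
        estimate is flagged ``"boundary"``), or the unconstrained
        method-of-moments estimator (s_b2 may be negative, flagged).

    Raises
    ------
    CannotDecomposeError
        If no subject has a repeat day.
    """
    _validate(data, subject_col, sequence_col, intake_col)
    n_subjects, n_with_repeats = _repeat_counts(data, subject_col)
    if n_with_repeats == 0:
        raise CannotDecomposeError(
            "cannot decompose - every subject has a single day; "
            "use the external-ratio (1-d) path")
    if n_subjects < min_subjects:
        warnings.warn(
            f"only {n_subjects} subjects (< {min_subjects}); variance "
            "components will be imprecise", stacklevel=2)

    y = boxcox_apply(data[intake_col].to_numpy(dtype=float), transform)
    subject = data[subject_col].to_numpy()
    X, names = _build_design(data, sequence_col, weekend_col,
                             extra_fixed_effects)
    flags: list[str] = []

    if method == "anova":
        comps = anova_components(y, subject, X if X.shape[1] > 1 else None)
        beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
        s_w2, s_b2 = comps["s_w2"], comps["s_b2"]
        if s_b2 < 0:
            flags.append("negative_between_variance")
        fe = dict(zip(names, beta_hat))
        mu = fe.pop("Intercept")
        converged = True
    elif method == "reml":
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=subject)
            fit = model.fit(reml=True)
        converged = bool(fit.converged)
        if not converged:
            flags.append("no_convergence")
        psi_hint = float(np.asarray(fit.cov_re)[0, 0]) / max(
            float(fit.scale), 1e-300)
        # polish: locate the 1-D profile-REML optimum to machine precision
        s_w2, s_b2, beta_hat = _profile_reml(y, subject, X,
                                             psi_hint=psi_hint)
        if s_b2 <= 0.0:
            s_b2 = 0.0
            flags.append("boundary")
        fe = dict(zip(names, np.asarray(beta_hat, dtype=float)))
        mu = fe.pop("Intercept")
    else:
        raise ValueError(f"unknown method {method!r}")

    return VarianceComponents(
        s_w2=float(s_w2), s_b2=float(s_b2), mu=float(mu), fixed_effects=fe,
        transform=transform, n_subjects=n_subjects,
        n_with_repeats=n_with_repeats, method=method, flags=flags,
        converged=converged,
    )


def decompose_by_group(
    data: pd.DataFrame,
    group_col: str,
    fit_transform: bool = True,
    transform: TransformSpec | None = None,
    **kwargs,
) -> dict:
    """Independent decomposition per subset (age band, season, setting...).

    Each group gets its own Box-Cox fit (unless a fixed ``transform`` is
    supplied).  Groups that cannot be decomposed are reported under their
    label as ``{"status": "cannot decompose", "reason": ...}`` rather than
    dropped.

    Returns
    -------
    dict mapping group label -> VarianceComponents or status dict.
    """
    from .transform import fit_lambda

    if group_col not in data.columns:
        raise ValueError(f"group column {group_col!r} not in dataset")
    out: dict = {}
    for label, sub in data.groupby(group_col, sort=True):
        if len(sub) == 0:
            out[label] = {"status": "skipped", "reason": "empty group"}
            continue
        try:
            spec = transform
            if spec is None or fit_transform:
                spec = fit_lambda(
                    sub,
                    intake_col=kwargs.get("intake_col", "intake"),
                    subject_col=kwargs.get("subject_col", "subject_id"),
                ) if transform is None else transform
            out[label] = decompose(sub, spec, **kwargs)
        except (CannotDecomposeError, ValueError) as err:
            out[label] = {"status": "cannot decompose", "reason": str(err)}
    return out
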