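"""Variance-ratio parameterizations, conversions, and plausibility screening.

Day-to-day (within-individual, WIV) and person-to-person (between-individual,
BIV) variability of nutrient intake is summarized by three interconvertible
ratios:

* ``cv_ratio``  — R_CV = CV_w / CV_b, the ratio of within- to
  between-individual coefficients of variation;
* ``wiv_to_biv`` — alpha = s_w^2 / s_b^2, the ratio of the variance
  components themselves;
* ``wiv_to_total`` — beta = s_w^2 / (s_b^2 + s_w^2), the fraction of total
  (residual) variance attributable to within-individual variation.

Conversions follow alpha = R_CV**2, beta = alpha / (1 + alpha) and
alpha = beta / (1 - beta).  CVs cannot be recovered from variances without
the component means, so converting *to* ``cv_ratio`` is refused.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "VarianceRatio",
    "RatioDatabaseEntry",
    "RatioConversionError",
    "InfiniteAlphaError",
    "convert_ratio",
    "components_to_ratios",
    "flag_implausible",
    "read_ratio_database",
    "write_ratio_database",
    "DEFAULT_ALPHA_CUTOFF",
]

RATIO_KINDS = ("cv_ratio", "wiv_to_biv", "wiv_to_total")

#: Screening cutoff for implausibly high ratios: WIV:BIV > 10,
#: equivalently WIV:total > 10/11 ~= 0.91.
DEFAULT_ALPHA_CUTOFF = 10.0


class RatioConversionError(ValueError):
    """A requested ratio conversion is not defined."""


class InfiniteAlphaError(RatioConversionError):
    """beta = 1 implies zero between-individual variance: alpha is infinite."""


@dataclass(frozen=True)
class VarianceRatio:
    """One variance ratio in one parameterization.

    Parameters
    ----------
    kind : {"cv_ratio", "wiv_to_biv", "wiv_to_total"}
        Parameterization of ``value``.
    value : float
        Nonnegative; for ``wiv_to_total`` additionally <= 1 unless the
        underlying between-individual variance estimate was negative (such
        values are kept, not truncated, and flagged by
        :func:`flag_implausible`).
    source : str
        Free-text provenance tag.
    """

    kind: str
    value: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in RATIO_KINDS:
            raise ValueError(f"unknown ratio kind {self.kind!r}")
        if not math.isfinite(self.value) and not math.isinf(self.value):
            raise ValueError("ratio value must be a real number")
        if self.value < 0:
            raise ValueError(f"ratio value must be >= 0, got {self.value}")


def convert_ratio(r: VarianceRatio, target_kind: str) -> VarianceRatio:
    """Convert a :class:`VarianceRatio` to another parameterization.

    Uses alpha = R_CV**2, beta = alpha/(1+alpha), alpha = beta/(1-beta).
    Converting to the same kind returns an equal ratio.  Conversion to
    ``cv_ratio`` from either variance ratio is refused: a CV ratio depends on
    the component means, which variances alone do not determine.

    Raises
    ------
    RatioConversionError
        If ``target_kind`` is ``cv_ratio`` and ``r`` is not already one.
    InfiniteAlphaError
        If beta = 1 is converted to alpha (zero between-individual variance).
    """
    if target_kind not in RATIO_KINDS:
        raise ValueError(f"unknown ratio kind {target_kind!r}")
    if r.kind == target_kind:
        return replace(r)
    if target_kind == "cv_ratio":
        raise RatioConversionError(
            "not invertible: cv_ratio cannot be recovered from variance "
            "ratios without the component means"
        )

    # route everything through alpha
    if r.kind == "cv_ratio":
        alpha = r.value**2
    elif r.kind == "wiv_to_biv":
        alpha = r.value
    else:  # wiv_to_total
        beta = r.value
        if beta == 1.0:
            if target_kind == "wiv_to_biv":
                raise InfiniteAlphaError(
                    "infinite alpha: beta = 1 means zero between-individual "
                    "variance"
                )
            alpha = math.inf
        else:
            alpha = beta / (1.0 - beta)

    if target_kind == "wiv_to_biv":
        return VarianceRatio("wiv_to_biv", alpha, r.source)
    # target beta
    beta = 1.0 if math.isinf(alpha) else alpha / (1.0 + alpha)
    return VarianceRatio("wiv_to_total", beta, r.source)


def components_to_ratios(s_w2: float, s_b2: float) -> dict:
    """Variance components -> ``{"alpha": ..., "beta": ..., "flags": [...]}``.

    ``s_b2`` may be negative (method-of-moments estimation can produce it);
    the resulting beta then exceeds 1 and is flagged ``implausible`` rather
    than truncated, so artifacts like a reported ratio of 1.04 remain visible.

    Raises
    ------
    ValueError
        If ``s_w2 < 0`` or both components are zero ("no variance").
    """
    if s_w2 < 0:
        raise ValueError(f"within-individual variance must be >= 0, got {s_w2}")
    total = s_w2 + s_b2
    if s_w2 == 0 and s_b2 == 0:
        raise ValueError("no variance: s_w2 = s_b2 = 0")

    flags: list[str] = []
    if s_b2 == 0:
        alpha = math.inf
        flags.append("infinite_alpha")
    else:
        alpha = s_w2 / s_b2
    if total == 0:
        beta = math.inf
        flags.append("zero_total_variance")
    else:
        beta = s_w2 / total
    if s_b2 < 0:
        flags.append("negative_between_variance")
    if beta > 1 or beta < 0 or alpha < 0:
        flags.append("implausible")
    return {"alpha": alpha, "beta": beta, "flags": flags}


def flag_implausible(
    r: VarianceRatio, alpha_cutoff: float = DEFAULT_ALPHA_CUTOFF
) -> tuple[bool, str]:
    """Screen a ratio against the WIV:BIV > 10 (WIV:total > 0.91) cutoff.

    Returns ``(True, reason)`` when the ratio exceeds the cutoff, lies
    outside its valid range (beta > 1), or is negative; ``(False, "")``
    otherwise.  The cutoff is configurable via ``alpha_cutoff`` (on the
    alpha = WIV:BIV scale; the beta-scale equivalent is
    ``alpha_cutoff / (1 + alpha_cutoff)``).
    """
    v = r.value
    if v < 0:
        return True, "negative ratio value"
    beta_cutoff = alpha_cutoff / (1.0 + alpha_cutoff)
    if r.kind == "wiv_to_total":
        if v > 1:
            return True, (
                f"out-of-range: WIV:total = {v:g} > 1 (implausible negative "
                "between-individual variance)"
            )
        if v > beta_cutoff:
            return True, (
                f"WIV:total = {v:g} exceeds cutoff {beta_cutoff:.2f} "
                f"(WIV:BIV > {alpha_cutoff:g})"
            )
        return False, ""
    # cv_ratio squares to alpha
    alpha = v**2 if r.kind == "cv_ratio" else v
    if alpha > alpha_cutoff:
        return True, f"WIV:BIV = {alpha:g} exceeds cutoff {alpha_cutoff:g}"
    return False, ""


@dataclass
class RatioDatabaseEntry:
    """One row of the compiled variance-ratio database."""

    country: str
    setting: str
    population_group: str
    nutrient: str
    method: str
    n_subjects: int | None
    n_days: int | None
    ratios: list[VarianceRatio] = field(default_factory=list)
    interval_note: str = ""
    statistical_method_note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nutrient:
            raise ValueError("nutrient must be non-empty")
        if not self.population_group:
            raise ValueError("population_group must be non-empty")


_MANDATORY = ("nutrient", "population_group")
_RATIO_COLS = {
    "cv_ratio": "cv_ratio",
    "wiv_to_biv": "wiv_to_biv",
    "alpha": "wiv_to_biv",
    "wiv_to_total": "wiv_to_total",
    "beta": "wiv_to_total",
    "ratio_value": None,  # paired with ratio_kind
}
_KNOWN = {
    "country", "setting", "region_setting", "population_group", "nutrient",
    "method", "dietary_method", "n_subjects", "n_days", "interval_note",
    "statistical_method_note", "ratio_kind", "source",
} | set(_RATIO_COLS)


def _opt_int(s: str | None) -> int | None:
    if s is None or s == "":
        return None
    return int(float(s))


def read_ratio_database(path) -> list[RatioDatabaseEntry]:
    """Read a CSV ratio database (header row mandatory; UTF-8).

    Ratios may be given either as a ``ratio_kind``/``ratio_value`` pair or as
    dedicated ``wiv_to_biv``/``alpha`` and/or ``wiv_to_total``/``beta``
    columns.  When a row carries both an alpha and a beta that disagree by
    more than 1e-6 after conversion, a warning is emitted and both are kept.
    Unknown columns are preserved in ``entry.extra``.  An empty file yields
    an empty list.
    """
    entries: list[RatioDatabaseEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return entries
        cols = [c.strip() for c in reader.fieldnames]
        for col in _MANDATORY:
            if col not in cols:
                raise ValueError(f"missing mandatory column: {col!r}")
        has_pair = "ratio_kind" in cols and "ratio_value" in cols
        ratio_cols = [c for c in cols if c in _RATIO_COLS and _RATIO_COLS[c]]
        if not has_pair and not ratio_cols:
            raise ValueError(
                "missing mandatory column: need ratio_kind/ratio_value or one "
                "of wiv_to_biv/alpha/wiv_to_total/beta"
            )
        for i, row in enumerate(reader, start=2):
            row = {k.strip(): (v or "").strip() for k, v in row.items() if k}
            source = row.get("source", "")
            ratios: list[VarianceRatio] = []
            if has_pair and row.get("ratio_value"):
                ratios.append(
                    VarianceRatio(row["ratio_kind"], float(row["ratio_value"]),
                                  source)
                )
            for col in ratio_cols:
                if row.get(col):
                    ratios.append(
                        VarianceRatio(_RATIO_COLS[col], float(row[col]), source)
                    )
            _warn_if_inconsistent(ratios, line=i)
            entries.append(
                RatioDatabaseEntry(
                    country=row.get("country", ""),
                    setting=row.get("setting", row.get("region_setting", "")),
                    population_group=row["population_group"],
                    nutrient=row["nutrient"],
                    method=row.get("method", row.get("dietary_method", "")),
                    n_subjects=_opt_int(row.get("n_subjects")),
                    n_days=_opt_int(row.get("n_days")),
                    ratios=ratios,
                    interval_note=row.get("interval_note", ""),
                    statistical_method_note=row.get(
                        "statistical_method_note", ""),
                    extra={k: v for k, v in row.items() if k not in _KNOWN},
                )
            )
    return entries


def _warn_if_inconsistent(ratios: list[VarianceRatio], line: int) -> None:
    alphas = [r.value for r in ratios if r.kind == "wiv_to_biv"]
    betas = [r.value for r in ratios if r.kind == "wiv_to_total"]
    for a in alphas:
        for b in betas:
            if b < 1 and abs(a / (1 + a) - b) > 1e-6:
                warnings.warn(
                    f"line {line}: alpha={a:g} and beta={b:g} disagree by "
                    f"more than 1e-6 after conversion",
                    stacklevel=3,
                )


def write_ratio_database(entries: list[RatioDatabaseEntry], path) -> None:
    """Write entries as CSV; one row per (entry, ratio) pair.

    ``read_ratio_database(write_ratio_database(entries))`` is the identity on
    parsed fields (entries carrying several ratios come back as several
    single-ratio entries sharing the descriptive fields).
    """
    extra_cols = sorted({k for e in entries for k in e.extra})
    cols = ["country", "setting", "population_group", "nutrient", "method",
            "n_subjects", "n_days", "ratio_kind", "ratio_value", "source",
            "interval_note", "statistical_method_note", *extra_cols]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for e in entries:
            base = {
                "country": e.country, "setting": e.setting,
                "population_group": e.population_group,
                "nutrient": e.nutrient, "method": e.method,
                "n_subjects": "" if e.n_subjects is None else e.n_subjects,
                "n_days": "" if e.n_days is None else e.n_days,
                "interval_note": e.interval_note,
                "statistical_method_note": e.statistical_method_note,
                **e.extra,
            }
            for r in e.ratios or [None]:
                row = dict(base)
                if r is not None:
                    row.update(ratio_kind=r.kind, ratio_value=repr(r.value),
                               source=r.source)
                writer.writerow(row)
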