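"""Synthetic dietary-recall data with known variance structure.

Generates long-format subject-day recall datasets from the same generative
model the decomposition assumes: on the transformed scale, subject i on
day j has

    t_ij = mu + b_i + weekend_effect * w_ij + sequence_effect_j + e_ij,
    b_i ~ N(0, s_b2),  e_ij ~ N(0, s_w2),

with the reported intake the exact Box-Cox inverse of t_ij at the
generative power ``lambda_true``.  The weekend indicator is Bernoulli(2/7)
(two weekend days out of seven) unless a scheduled calendar mode is
requested.  An optional stratified-cluster design with weights emulates a
national survey structure.  Every dataset carries a truth sidecar so tests
recover the generating parameters without re-deriving them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ratios import components_to_ratios
from .transform import TransformSpec, boxcox_inverse, _inverse_domain_ok

__all__ = ["SyntheticConfig", "generate", "generate_subsample_design",
           "write_dataset", "read_truth"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a two-recall micronutrient survey
    on ~500 women with a moderately skewed intake (log-scale truth)."""

    n_subjects: int = 500
    n_days: int = 2
    mu: float = 0.0
    s_b2: float = 0.25
    s_w2: float = 0.50
    lambda_true: float = 0.0
    shift_true: float = 0.0
    weekend_effect: float = 0.0
    sequence_effects: tuple = ()  # additive shift for day 2, 3, ... (day 1 = 0)
    day_autocorrelation: float = 0.0  # AR(1) across a subject's days
    weekend_mode: str = "random"  # or "scheduled": day j weekend iff j even
    design: dict | None = None  # {n_strata, clusters_per_stratum,
    #                              weight_model: equal|variable,
    #                              cluster_effect_sd}
    group_labels: tuple | None = None  # optional per-subject group assignment
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("need n_subjects >= 1 and n_days >= 1")
        if self.s_b2 < 0 or self.s_w2 < 0:
            raise ValueError("variance components must be >= 0")
        if not 0 <= abs(self.day_autocorrelation) < 1:
            raise ValueError("day_autocorrelation must lie in (-1, 1)")

    @property
    def beta_true(self) -> float:
        return components_to_ratios(self.s_w2, self.s_b2)["beta"]

    def truth(self) -> dict:
        t = asdict(self)
        t["beta_true"] = self.beta_true
        t["alpha_true"] = components_to_ratios(self.s_w2, self.s_b2)["alpha"]
        return t


def _day_residuals(rng, n_subjects, n_days, s_w2, rho):
    e = rng.normal(0.0, np.sqrt(s_w2), size=(n_subjects, n_days))
    if rho == 0 or n_days == 1:
        return e
    out = np.empty_like(e)
    out[:, 0] = e[:, 0]
    for j in range(1, n_days):
        out[:, j] = rho * out[:, j - 1] + np.sqrt(1 - rho**2) * e[:, j]
    return out


def generate(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a recall dataset and its truth record.

    Returns ``(data, truth)`` where ``data`` has columns ``subject_id,
    sequence, weekend, intake`` (plus ``weight, stratum, cluster`` under a
    survey design and ``group`` when group labels are configured).  Draws
    whose transformed value falls outside the inverse-transform domain are
    resampled (count recorded in the truth record); more than 1% resampled
    raises, advising a parameter change.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_subjects, config.n_days
    spec = TransformSpec(lam=config.lambda_true, shift=config.shift_true)

    seq_fx = np.zeros(d)
    for j, v in enumerate(config.sequence_effects[: d - 1], start=1):
        seq_fx[j] = v

    b = rng.normal(0.0, np.sqrt(config.s_b2), size=n)
    e = _day_residuals(rng, n, d, config.s_w2, config.day_autocorrelation)
    if config.weekend_mode == "scheduled":
        weekend = np.tile((np.arange(1, d + 1) % 2 == 0).astype(int), (n, 1))
    else:
        weekend = rng.binomial(1, 2.0 / 7.0, size=(n, d))

    t = (config.mu + b[:, None] + e
         + config.weekend_effect * weekend + seq_fx[None, :])

    # resample draws the generative inverse transform cannot map back
    n_resampled = 0
    bad = ~_inverse_domain_ok(t, config.lambda_true)
    while np.any(bad):
        n_resampled += int(bad.sum())
        if n_resampled > 0.01 * n * d:
            raise ValueError(
                "more than 1% of draws fell outside the inverse-transform "
                "domain; choose mu/variances compatible with lambda_true")
        e_new = rng.normal(0.0, np.sqrt(config.s_w2), size=int(bad.sum()))
        t[bad] = (config.mu + np.broadcast_to(b[:, None], t.shape)[bad]
                  + e_new + config.weekend_effect * weekend[bad]
                  + np.broadcast_to(seq_fx[None, :], t.shape)[bad])
        bad = ~_inverse_domain_ok(t, config.lambda_true)

    intake = np.asarray(boxcox_inverse(t, spec), dtype=float)
    intake = np.maximum(intake, 0.0)

    data = pd.DataFrame({
        "subject_id": np.repeat([f"S{i:05d}" for i in range(n)], d),
        "sequence": np.tile(np.arange(1, d + 1), n),
        "weekend": weekend.ravel(),
        "intake": intake.ravel(),
    })

    if config.design:
        data = _attach_design(data, config, rng, b)
    if config.group_labels:
        labels = np.asarray(config.group_labels)
        per_subject = labels[rng.integers(0, labels.size, size=n)]
        data["group"] = np.repeat(per_subject, d)

    truth = config.truth()
    truth["n_resampled"] = n_resampled
    truth["n_rows"] = len(data)
    return data, truth


def _attach_design(data, config, rng, b):
    """Assign subjects to strata/clusters; optionally add cluster effects
    (on the transformed scale this would re-enter the intake, so cluster
    effects are injected as a multiplicative intake tilt) and weights."""
    dz = dict(config.design)
    n_strata = int(dz.get("n_strata", 8))
    cps = int(dz.get("clusters_per_stratum", 2))
    weight_model = dz.get("weight_model", "equal")
    cl_sd = float(dz.get("cluster_effect_sd", 0.0))
    n = config.n_subjects

    stratum_of = np.sort(np.arange(n) % n_strata)
    order = rng.permutation(n)
    stratum = np.empty(n, dtype=int)
    stratum[order] = stratum_of
    # balanced take per cluster (fixed cluster sample sizes, as in a
    # cluster survey); randomness only in which subject lands where
    cluster = np.empty(n, dtype=int)
    for s in range(n_strata):
        idx = rng.permutation(np.flatnonzero(stratum == s))
        cluster[idx] = np.arange(idx.size) % cps

    if weight_model == "variable":
        # deterministic in (stratum, cluster) so the design, not the draw,
        # fixes the weights — replication SEs are design-conditional
        s_idx, c_idx = np.meshgrid(np.arange(n_strata), np.arange(cps),
                                   indexing="ij")
        w_cluster = 0.6 + 0.35 * (s_idx % 4) + 0.45 * c_idx
        weight = w_cluster[stratum, cluster]
    else:
        weight = np.ones(n)

    d = config.n_days
    data = data.copy()
    data["stratum"] = np.repeat(stratum, d)
    data["cluster"] = np.repeat(
        [f"{s}-{c}" for s, c in zip(stratum, cluster)], d)
    data["weight"] = np.repeat(weight, d)

    if cl_sd > 0:
        u = rng.normal(0.0, cl_sd, size=(n_strata, cps))
        tilt = u[stratum, cluster]
        data["intake"] = data["intake"].to_numpy() * np.exp(
            np.repeat(tilt, d))
    return data


def generate_subsample_design(
    config: SyntheticConfig, fraction_with_repeat: float
) -> tuple[pd.DataFrame, dict]:
    """All subjects observed on day 1; a seeded random fraction gets day 2.

    Emulates surveys collecting the repeat recall on a subsample only.
    Raises when the fraction would leave fewer than 2 subjects with repeats.
    """
    if not 0 < fraction_with_repeat <= 1:
        raise ValueError("fraction_with_repeat must lie in (0, 1]")
    cfg = SyntheticConfig(**{**asdict(config), "n_days": max(config.n_days, 2)})
    data, truth = generate(cfg)
    if fraction_with_repeat == 1:
        truth["fraction_with_repeat"] = 1.0
        return data, truth
    n = cfg.n_subjects
    n_repeat = int(round(fraction_with_repeat * n))
    if n_repeat < 2:
        raise ValueError(
            "fraction_with_repeat leaves fewer than 2 subjects with a "
            "second observation")
    rng = np.random.default_rng(cfg.seed + 1)
    subjects = data["subject_id"].unique()
    keep_repeat = set(rng.choice(subjects, size=n_repeat, replace=False))
    mask = (data["sequence"] == 1) | data["subject_id"].isin(keep_repeat)
    out = data.loc[mask].reset_index(drop=True)
    truth = dict(truth)
    truth["fraction_with_repeat"] = fraction_with_repeat
    truth["n_with_repeats"] = n_repeat
    truth["n_rows"] = len(out)
    return out, truth


def write_dataset(data: pd.DataFrame, truth: dict, path, truth_path=None):
    """Write the long-format CSV plus a JSON truth sidecar."""
    data.to_csv(path, index=False)
    if truth_path is None:
        truth_path = str(path) + ".truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, default=lambda o: list(o)
                  if isinstance(o, tuple) else o)
    return truth_path


def read_truth(truth_path) -> dict:
    with open(truth_path, encoding="utf-8") as fh:
        return json.load(fh)
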