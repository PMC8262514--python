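"""EAR cut-point prevalence, WIV:total sensitivity grids, and BRR errors.

The EAR cut-point method estimates the prevalence of inadequate intake as
the fraction of the usual-intake distribution falling below the Estimated
Average Requirement.  The estimate is trustworthy only when the true
prevalence is neither very low (< 8-10%) nor very high (> 90-92%); estimates
near those bounds carry flags.

Because the 1-d path borrows its WIV:total ratio externally, prevalence
should be reported across a grid of assumed ratios (default 0.05 to 0.95 in
steps of 0.05, plus 0.99) — the sensitivity curve.  Design-based standard
errors use balanced repeated replication (BRR) with a Fay coefficient:
replicate r keeps the selected half-sample at weight (2 - fay) and the
complement at fay, and

    SE = sqrt( 1 / (R * (1 - fay)^2) * sum_r (theta_r - theta)^2 ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard as _sylvester_hadamard

from .transform import TransformSpec
from .usual_intake import (
    BETA_UPPER_GUARD,
    UsualIntakeDistribution,
    model_distribution,
    partition_external,
    total_variance_1d,
)

__all__ = [
    "PrevalenceEstimate",
    "SensitivityCurve",
    "ear_cutpoint",
    "sensitivity_grid",
    "brr_se",
    "brr_replicate_weights",
    "hadamard_matrix",
    "default_beta_grid",
    "EAR_REGISTRY",
]

#: Default EAR registry (per-day cutoffs for women of reproductive age):
#: dietary folate 320 ug/d (IOM), vitamin A 500 ug RAE/d (IOM), zinc 6 mg/d
#: (IZiNCG, mixed/refined vegetarian diet). Overridable per run.
EAR_REGISTRY = {
    "folate": {"ear": 320.0, "units": "ug/d DFE", "provenance": "IOM"},
    "vitamin_a": {"ear": 500.0, "units": "ug RAE/d", "provenance": "IOM"},
    "zinc": {"ear": 6.0, "units": "mg/d", "provenance": "IZiNCG"},
}

# cut-point validity bounds: hard warnings at the outer ends of the quoted
# ranges (8%, 92%), soft notices at the inner ends (10%, 90%)
HARD_LOW, SOFT_LOW = 0.08, 0.10
HARD_HIGH, SOFT_HIGH = 0.92, 0.90


def default_beta_grid() -> np.ndarray:
    """The assumed-ratio grid 0.05, 0.10, ..., 0.95 plus 0.99."""
    return np.append(np.round(np.arange(0.05, 0.951, 0.05), 10), 0.99)


@dataclass
class PrevalenceEstimate:
    """Prevalence of inadequate intake below an EAR, with validity flags."""

    prevalence: float
    ear: float
    se: float | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.prevalence < SOFT_LOW:
            self.flags.add("near_zero_bound")
        if self.prevalence > SOFT_HIGH:
            self.flags.add("near_one_bound")
        if self.prevalence < HARD_LOW or self.prevalence > HARD_HIGH:
            self.flags.add("outside_cutpoint_validity")


@dataclass
class SensitivityCurve:
    """Prevalence as a function of the assumed WIV:total ratio."""

    beta_grid: np.ndarray
    prevalences: list
    reference: PrevalenceEstimate | None = None
    reference_beta: float | None = None

    def __post_init__(self) -> None:
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        if np.any(np.diff(self.beta_grid) <= 0):
            raise ValueError("beta grid must be strictly increasing")
        if self.beta_grid[0] < 0 or self.beta_grid[-1] > BETA_UPPER_GUARD:
            raise ValueError(
                f"beta grid must lie in [0, {BETA_UPPER_GUARD}]")
        if len(self.prevalences) != self.beta_grid.size:
            raise ValueError("one prevalence per grid value required")

    @property
    def prevalence_range(self) -> tuple:
        """(min, max) prevalence across the tested grid — the honest way to
        report a highly uncertain external ratio."""
        vals = [p.prevalence for p in self.prevalences]
        return (min(vals), max(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta_grid,
            "prevalence": [p.prevalence for p in self.prevalences],
            "se": [p.se for p in self.prevalences],
            "flags": [";".join(sorted(p.flags)) for p in self.prevalences],
        })


def ear_cutpoint(dist: UsualIntakeDistribution, ear: float) -> PrevalenceEstimate:
    """Prevalence of inadequacy: mass of the usual-intake grid below the EAR."""
    if ear <= 0:
        raise ValueError("ear must be > 0")
    prev = dist.cdf(ear)
    est = PrevalenceEstimate(prevalence=prev, ear=ear)
    if dist.is_point_mass:
        est.flags.add("degenerate_distribution")
    return est


def sensitivity_grid(
    data: pd.DataFrame,
    ear: float,
    beta_grid=None,
    transform: TransformSpec | None = None,
    reference_components=None,
    grid_size: int = 400,
    weight_col: str | None = None,
    **tv_kwargs,
) -> SensitivityCurve:
    """Run the full 1-d pipeline once per assumed WIV:total value.

    For each beta in the grid: partition the single-day total variance,
    model the usual-intake distribution, apply the EAR cut-point.  When
    ``reference_components`` (from repeat-day data) is given, its 2-d
    prevalence is attached as the reference point the curve should cross
    near the true ratio.

    ``transform=None`` fits the Box-Cox power on the single-day data.
    """
    from .transform import fit_lambda
    from .usual_intake import model_distribution_2d

    if beta_grid is None:
        beta_grid = default_beta_grid()
    beta_grid = np.asarray(beta_grid, dtype=float)
    bad = beta_grid[beta_grid >= BETA_UPPER_GUARD]
    if bad.size:
        raise ValueError(
            f"beta values {bad.tolist()} rejected: at WIV:total >= "
            f"{BETA_UPPER_GUARD} the modeled distribution degenerates "
            "toward a point mass")
    if transform is None:
        transform = fit_lambda(data, **{k: v for k, v in tv_kwargs.items()
                                        if k in ("intake_col", "subject_col")})
    tv = total_variance_1d(data, transform, weight_col=weight_col, **tv_kwargs)
    prevalences = []
    for beta in beta_grid:
        parts = partition_external(tv["s_total2"], float(beta))
        dist = model_distribution(
            mu=tv["mu"], s_b2=parts["s_b2"], s_w2=parts["s_w2"],
            transform=transform, grid_size=grid_size,
            weekend_coef=tv["fixed_effects"].get("weekend"),
            beta_used=float(beta), path="one_day")
        prevalences.append(ear_cutpoint(dist, ear))
    reference = None
    reference_beta = None
    if reference_components is not None:
        ref_dist = model_distribution_2d(reference_components,
                                         grid_size=grid_size)
        reference = ear_cutpoint(ref_dist, ear)
        reference_beta = reference_components.beta
    return SensitivityCurve(beta_grid=beta_grid, prevalences=prevalences,
                            reference=reference, reference_beta=reference_beta)


# ---------------------------------------------------------------------------
# Balanced repeated replication


def _paley_hadamard(q: int) -> np.ndarray:
    """Paley type-I Hadamard matrix of order q + 1 (q prime, q % 4 == 3)."""
    residues = set((i * i) % q for i in range(1, q))

    def chi(a):
        a %= q
        if a == 0:
            return 0
        return 1 if a in residues else -1

    # H = I + S with S skew (possible because chi(-1) = -1 for q % 4 == 3)
    Q = np.array([[chi(j - i) for j in range(q)] for i in range(q)])
    H = np.empty((q + 1, q + 1), dtype=int)
    H[0, 0] = 1
    H[0, 1:] = 1
    H[1:, 0] = -1
    H[1:, 1:] = Q + np.eye(q, dtype=int)
    # normalize first column to +1
    H[H[:, 0] == -1] *= -1
    return H


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    for p in range(2, int(n**0.5) + 1):
        if n % p == 0:
            return False
    return True


def hadamard_matrix(order: int) -> np.ndarray:
    """Hadamard matrix of the given order via Sylvester and Paley I
    constructions (plus Sylvester doubling of a Paley core).

    Raises if no construction covers the order (callers round up instead).
    """
    if order == 1:
        return np.array([[1]])
    if order == 2:
        return np.array([[1, 1], [1, -1]])
    if order % 4 != 0:
        raise ValueError(f"no Hadamard matrix of order {order}")
    # pure Sylvester
    if order & (order - 1) == 0:
        return _sylvester_hadamard(order)
    # Paley I or doubling of a smaller constructible order
    if _is_prime(order - 1) and (order - 1) % 4 == 3:
        return _paley_hadamard(order - 1)
    if order % 2 == 0:
        try:
            H = hadamard_matrix(order // 2)
            return np.block([[H, H], [H, -H]])
        except ValueError:
            pass
    raise ValueError(f"no Hadamard construction available for order {order}")


def _usable_order(minimum: int) -> int:
    order = max(4, ((minimum + 3) // 4) * 4)
    while True:
        try:
            hadamard_matrix(order)
            return order
        except ValueError:
            order += 4


def brr_replicate_weights(
    data: pd.DataFrame,
    n_replicates: int = 48,
    fay: float = 0.7,
    stratum_col: str = "stratum",
    cluster_col: str = "cluster",
    weight_col: str = "weight",
    seed: int | None = None,
) -> np.ndarray:
    """Replicate weight matrix (R x n) for a 2-clusters-per-stratum design.

    Half-sample membership follows the columns of a Hadamard matrix whose
    order is ``n_replicates`` rounded up to the nearest constructible order
    >= the number of strata (a change is logged via warning).  ``seed``
    randomizes which cluster in each stratum is labelled first.
    """
    if not 0 <= fay < 1:
        raise ValueError("fay must lie in [0, 1): fay = 1 zeroes the "
                         "denominator of the BRR variance formula")
    for col in (stratum_col, cluster_col):
        if col not in data.columns:
            raise ValueError(
                f"no design column {col!r}: BRR needs stratum/cluster "
                "identifiers - use a simple analytic SE instead")
    strata = data[stratum_col].to_numpy()
    clusters = data[cluster_col].to_numpy()
    stratum_labels = np.unique(strata)
    H_order = _usable_order(max(n_replicates, stratum_labels.size))
    if H_order != n_replicates:
        warnings.warn(
            f"replicate count adjusted from {n_replicates} to {H_order} "
            "(nearest constructible Hadamard order)", stacklevel=2)
    H = hadamard_matrix(H_order)

    rng = np.random.default_rng(seed)
    half = np.zeros(len(data), dtype=int)  # 0/1 cluster label within stratum
    for h, lab in enumerate(stratum_labels):
        mask = strata == lab
        labs = np.unique(clusters[mask])
        if labs.size < 2:
            raise ValueError(
                f"stratum {lab!r} has a single cluster: BRR requires >= 2 "
                "clusters per stratum")
        if labs.size > 2:
            raise ValueError(
                f"stratum {lab!r} has {labs.size} clusters; BRR with "
                "half-samples requires exactly 2 per stratum")
        first = labs[rng.integers(0, 2)] if seed is not None else labs[0]
        half[mask] = (clusters[mask] != first).astype(int)

    base = (np.ones(len(data)) if weight_col not in data.columns
            else data[weight_col].to_numpy(dtype=float))
    col_of = {lab: h % H.shape[1] for h, lab in enumerate(stratum_labels)}
    hcols = np.array([col_of[s] for s in strata])
    W = np.empty((H_order, len(data)))
    for r in range(H_order):
        sign = H[r, hcols]  # +1 selects the first half-sample
        selected = (sign == 1) == (half == 0)
        W[r] = base * np.where(selected, 2.0 - fay, fay)
    return W


def brr_se(
    data: pd.DataFrame,
    statistic_fn,
    n_replicates: int = 48,
    fay: float = 0.7,
    stratum_col: str = "stratum",
    cluster_col: str = "cluster",
    weight_col: str = "weight",
    seed: int | None = None,
) -> float:
    """BRR standard error of ``statistic_fn(data, weights) -> float``.

    ``statistic_fn`` receives the dataset and a weight vector and must
    return the weighted statistic; it is called once with the full-sample
    weights and once per replicate with Fay-perturbed weights.
    """
    W = brr_replicate_weights(
        data, n_replicates=n_replicates, fay=fay, stratum_col=stratum_col,
        cluster_col=cluster_col, weight_col=weight_col, seed=seed)
    base = (np.ones(len(data)) if weight_col not in data.columns
            else data[weight_col].to_numpy(dtype=float))
    theta = statistic_fn(data, base)
    reps = np.array([statistic_fn(data, w) for w in W])
    R = W.shape[0]
    var = np.sum((reps - theta) ** 2) / (R * (1.0 - fay) ** 2)
    return float(np.sqrt(var))
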