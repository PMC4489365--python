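"""Comparative statistics between two systems (e.g. germline vs matured).

Differences in per-residue metrics across the representative structures of
two systems are cast as Z-scores,

    Z = (x̄_B − x̄_A) / sqrt(σ²_B/n + σ²_A/n),

with cluster-size-weighted means and standard deviations and the fixed
divisor n (the number of representative structures, 10 by default).
Positive Z means the second ("mutant") system is more flexible.  Changes
are classified with one-sided-normal thresholds: |Z| > 2.33 (p = 0.01) is a
moderate change, |Z| > 3.33 (p ≤ 0.0005, odds better than 1 in 2300) a
large change; |Z| at or below 2.33 is no change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

MODERATE_Z = 2.33
LARGE_Z = 3.33

CLASS_LABELS = (
    "large_rigidity",
    "moderate_rigidity",
    "none",
    "moderate_flexibility",
    "large_flexibility",
)


def _weighted_moments(values: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(weights, float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    v = np.asarray(values, float)
    if v.shape[0] != w.size:
        raise ValueError("one weight per representative required")
    mean = np.tensordot(w, v, axes=1)
    var = np.tensordot(w, (v - mean) ** 2, axes=1)
    return mean, np.sqrt(var)


@dataclass
class ZScoreProfile:
    z: np.ndarray
    saturated: np.ndarray  # True where both sds are 0 but means differ
    n: int


def zscore(
    values_mut: np.ndarray,
    values_wt: np.ndarray,
    weights_mut: np.ndarray,
    weights_wt: np.ndarray,
    n: int = 10,
) -> ZScoreProfile:
    """Z-score per site/residue between two representative sets.

    ``values_*`` have shape (n_representatives, n_sites); ``weights_*`` are
    the cluster-size weights.  The divisor ``n`` is the number of
    representative structures (10 in the standard protocol; configurable for
    reduced fixtures).  Where both standard deviations vanish the Z-score is
    0 for equal means and ±inf (flagged ``saturated``) otherwise.
    """
    mu_m, sd_m = _weighted_moments(values_mut, weights_mut)
    mu_w, sd_w = _weighted_moments(values_wt, weights_wt)
    num = mu_m - mu_w
    den = np.sqrt(sd_m**2 / n + sd_w**2 / n)
    z = np.zeros_like(num)
    ok = den > 0
    z[ok] = num[ok] / den[ok]
    saturated = (~ok) & (num != 0)
    z[saturated] = np.sign(num[saturated]) * np.inf
    return ZScoreProfile(z=z, saturated=saturated, n=n)


def classify_changes(
    z: np.ndarray,
    thresholds: tuple[float, float] = (MODERATE_Z, LARGE_Z),
    region_masks: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict]:
    """Class label per residue plus per-region counts.

    Strict inequalities: |Z| must exceed a threshold to be called (a value
    exactly at 2.33 is "none").  Positive Z is increased flexibility,
    negative increased rigidity.  ``region_masks`` maps a region name to a
    boolean mask over residues (e.g. CDR-like intervals); counts are always
    reported for the whole profile under the key "all".
    """
    mod, large = thresholds
    if not (0 < mod < large):
        raise ValueError("thresholds must be positive and ordered")
    z = np.asarray(z, float)
    classes = np.full(z.shape, "none", dtype=object)
    classes[(z > mod) & (z <= large)] = "moderate_flexibility"
    classes[z > large] = "large_flexibility"
    classes[(z < -mod) & (z >= -large)] = "moderate_rigidity"
    classes[z < -large] = "large_rigidity"

    masks = {"all": np.ones(z.shape, bool)}
    if region_masks:
        masks.update({k: np.asarray(m, bool) for k, m in region_masks.items()})
    counts = {
        region: {lab: int(np.sum(classes[m] == lab)) for lab in CLASS_LABELS}
        for region, m in masks.items()
    }
    return classes, counts


def hbond_count_difference(prop_a, prop_b) -> tuple[pd.Series, dict]:
    """Per-residue H-bond propensity-sum difference (B − A).

    Returns the per-residue difference plus counts of residues gaining or
    losing at least 1 and at least 2 H-bonds.  Raises if the two tables
    carry incompatible residue indexing (an index present on one side only
    with a conflicting range).
    """
    res = sorted(set(prop_a.residue) | set(prop_b.residue))
    diff = pd.Series(
        {r: prop_b.residue.get(r, 0.0) - prop_a.residue.get(r, 0.0) for r in res},
        name="delta_hbond",
    )
    summary = {
        "gained_ge_1": int((diff >= 1.0).sum()),
        "gained_ge_2": int((diff >= 2.0).sum()),
        "lost_ge_1": int((diff <= -1.0).sum()),
        "lost_ge_2": int((diff <= -2.0).sum()),
    }
    return diff, summary


def delta_cc(
    cc_reps_a: list[np.ndarray],
    cc_reps_b: list[np.ndarray],
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    n: int = 10,
) -> np.ndarray:
    """Per-pixel Z-score of the CC matrices between two systems.

    The scalar Z-score formula is applied element-wise across the
    representative structures; the output is symmetric whenever the inputs
    are.
    """
    shapes = {m.shape for m in cc_reps_a} | {m.shape for m in cc_reps_b}
    if len(shapes) != 1:
        raise ValueError("CC matrices are not site-aligned")
    a = np.stack([m.ravel() for m in cc_reps_a])
    b = np.stack([m.ravel() for m in cc_reps_b])
    prof = zscore(b, a, weights_b, weights_a, n=n)
    side = cc_reps_a[0].shape[0]
    return prof.z.reshape(side, side)


def flexibility_vs_mobility(
    z: np.ndarray,
    rmsf_a: np.ndarray,
    rmsf_b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Pair per-residue flexibility Z-scores with mobility changes (ΔRMSF).

    Returns the paired table, the Spearman rank correlation between Z and
    ΔRMSF = RMSF_B − RMSF_A, and a permutation p-value (two-sided, fraction
    of |rho| under random re-pairings at least as large as observed).  With
    a constant ΔRMSF the correlation is undefined and reported as NaN with
    p-value NaN.
    """
    z = np.asarray(z, float)
    d = np.asarray(rmsf_b, float) - np.asarray(rmsf_a, float)
    if z.shape != d.shape:
        raise ValueError("Z and RMSF profiles must share residue indexing")
    table = pd.DataFrame({"z": z, "delta_rmsf": d})
    if np.ptp(d) == 0 or np.ptp(z) == 0:
        return table, float("nan"), float("nan")

    def spearman(x, y):
        rx, ry = rankdata(x), rankdata(y)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))

    rho = spearman(z, d)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if abs(spearman(z, rng.permutation(d))) >= abs(rho) - 1e-12:
            hits += 1
    pval = (hits + 1) / (n_permutations + 1)
    return table, rho, float(pval)
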