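"""Flexibility index and cooperativity correlation as native-basin averages.

The flexibility index of rotatable bond i is the ensemble average of
f_i = h_i − l_i: h_i = A/H is the density of independent (disordered)
degrees of freedom in the flexible region containing bond i, l_i = B/L the
density of redundant constraints in its over-constrained region; an
isostatically locked bond scores 0.  Positive values mean flexibility,
negative rigidity.

The cooperativity correlation (CC) matrix tracks mechanical couplings over
the backbone phi/psi torsions: +h for pairs sharing a flexible region, −l
for pairs locked in the same rigid region, 0 when mechanically uncoupled.
Both metrics are averaged over the native-basin macrostates with Boltzmann
weights at T = T_m, so they characterise equilibrium fluctuations of the
folded state; a second, cluster-size-weighted average across the
representative structures is provided by :func:`structure_weighted_average`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigidity import RigidityReport
from .thermo import GridSamples, NativeBasin


@dataclass
class FlexibilityProfile:
    """Per-site and per-residue flexibility index at one temperature."""

    site_values: np.ndarray
    site_residues: np.ndarray
    site_kinds: list[str]
    residue_index: np.ndarray
    residue_values: np.ndarray
    temperature: float
    n_macrostates: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"residue_index": self.residue_index, "fi": self.residue_values}
        )

    def to_site_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "site": np.arange(self.site_values.shape[0]),
            "residue_index": self.site_residues,
            "kind": self.site_kinds,
            "fi": self.site_values,
        })


@dataclass
class CCMatrix:
    """Cooperativity correlation over backbone torsion sites (phi/psi order)."""

    matrix: np.ndarray
    site_indices: np.ndarray   # into the torsion-site inventory
    site_residues: np.ndarray
    temperature: float


def flexibility_index_single(report: RigidityReport) -> np.ndarray:
    """f = h − l per torsion site for a single constraint topology."""
    return report.site_f.copy()


def _basin_average(grid: GridSamples, basin: NativeBasin, attr: str) -> np.ndarray:
    acc = None
    for (i, j), w in zip(basin.nodes, basin.weights):
        node = (int(grid.hb_axis[i]), int(grid.nat_axis[j]))
        value = getattr(grid.samples[node], attr)
        if value is None:
            raise ValueError(
                "mechanical statistics were not collected during sampling "
                "(sample_grid(collect_mech=True) required)"
            )
        acc = w * value if acc is None else acc + w * value
    if acc is None:
        raise ValueError("empty native basin")
    return acc


def flexibility_index(grid: GridSamples, basin: NativeBasin) -> FlexibilityProfile:
    """Boltzmann-weighted flexibility index over the native basin.

    Per-residue values are the unweighted mean of that residue's backbone
    (phi/psi) sites.
    """
    site_fi = _basin_average(grid, basin, "mean_f")
    inv = grid.inventory
    residues = inv.site_residue
    kinds = [s.backbone_kind for s in inv.sites]
    backbone = inv.backbone_sites
    res_ids = np.unique(residues[backbone]) if backbone.size else np.unique(residues)
    res_vals = np.array(
        [
            site_fi[[s for s in backbone if residues[s] == r]].mean()
            for r in res_ids
        ]
    ) if backbone.size else np.zeros(0)
    return FlexibilityProfile(
        site_values=site_fi,
        site_residues=residues,
        site_kinds=kinds,
        residue_index=res_ids,
        residue_values=res_vals,
        temperature=basin.temperature,
        n_macrostates=len(basin.nodes),
    )


def cooperativity_correlation(grid: GridSamples, basin: NativeBasin) -> CCMatrix:
    """Boltzmann-weighted CC matrix over the native basin (symmetric)."""
    cc = _basin_average(grid, basin, "cc_mean")
    inv = grid.inventory
    bb = inv.backbone_sites
    return CCMatrix(
        matrix=cc,
        site_indices=bb.copy(),
        site_residues=inv.site_residue[bb],
        temperature=basin.temperature,
    )


def structure_weighted_average(
    profiles: list[np.ndarray], weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-size-weighted mean and standard deviation across representatives.

    ``profiles`` are site-aligned arrays (any common shape); ``weights``
    must be positive and sum to 1.  The weighted standard deviation uses
    the weights directly (population form), matching how uncertainties are
    propagated into the Z-score comparison.
    """
    w = np.asarray(weights, float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must be non-negative and sum to 1")
    if len(profiles) != w.size:
        raise ValueError("one weight per profile required")
    shapes = {p.shape for p in profiles}
    if len(shapes) != 1:
        raise ValueError("profiles are not site-aligned (differing shapes)")
    stack = np.stack(profiles)
    mean = np.tensordot(w, stack, axes=1)
    var = np.tensordot(w, (stack - mean) ** 2, axes=1)
    return mean, np.sqrt(var)
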