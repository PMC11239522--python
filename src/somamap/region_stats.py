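"""Group-wise comparison of per-region cell densities.

Per structure level: two-sided unpaired t-tests (Welch by default) on
per-region densities, log2 fold changes of group means, and
Benjamini-Hochberg FDR control at q = 0.1 applied within the set of
regions tested at that level ("level-aware" correction).  Fiber tracts are
excluded from all statistical comparisons.

A note on the significance threshold: the convention in whole-brain c-Fos
screens is BH correction at a false-discovery rate of 0.1 (sometimes
loosely described as an FWER); what is implemented here is FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas_map import aggregate_to_level
from .ontology import Ontology

DEFAULT_ALPHA = 0.1


@dataclass
class GroupDesign:
    """Assignment of samples to experimental groups."""

    samples: list[tuple[str, str]]  # (sample_id, group label)

    def __post_init__(self):
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.groups = sorted({g for _, g in self.samples})
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")

    def members(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"group {group!r} not in design")
        return [s for s, g in self.samples if g == group]

    @classmethod
    def from_csv(cls, path) -> "GroupDesign":
        df = pd.read_csv(path)
        return cls(list(zip(df["sample_id"].astype(str), df["group"].astype(str))))


# ------------------------------------------------------------ density matrix

def density_matrix(tables: dict[str, pd.DataFrame], ontology: Ontology,
                   level: int, normalization: str = "per_mm3") -> pd.DataFrame:
    """Samples x regions density matrix at one structure level.

    ``tables`` maps sample_id -> region count table (leaf level).  Fiber
    tracts are dropped from the matrix; with ``per_mm3_per_total`` each
    sample's densities are additionally divided by its total detected cell
    count (which still includes fiber-tract and unassigned cells).
    """
    if normalization not in ("per_mm3", "per_mm3_per_total"):
        raise ValueError("normalization must be per_mm3 or per_mm3_per_total")
    rows = {}
    region_order = None
    for sid, tab in tables.items():
        agg = aggregate_to_level(tab, ontology, level)
        total = float(tab["n_cells"].sum())
        agg = agg[agg["region_id"] != 0]
        agg = agg[[not ontology[r].is_fiber_tract for r in agg["region_id"]]]
        dens = agg.set_index("region_id")["density_cells_per_mm3"]
        if normalization == "per_mm3_per_total":
            dens = dens / total if total > 0 else dens * 0.0
        rows[sid] = dens
        if region_order is None:
            region_order = list(dens.index)
        elif list(dens.index) != region_order:
            raise ValueError("tables disagree on the region set; "
                             "were they built against the same ontology?")
    return pd.DataFrame(rows).T[region_order]


# ------------------------------------------------------------- comparisons

def _log2_fold_change(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """log2(mean_a / mean_b); a zero mean is replaced by a pseudo-density of
    half the smallest nonzero mean so empty regions stay finite while
    nonzero ratios are untouched."""
    nz = np.concatenate([mean_a[mean_a > 0], mean_b[mean_b > 0]])
    eps = 0.5 * nz.min() if nz.size else 1.0
    return np.log2(np.maximum(mean_a, eps) / np.maximum(mean_b, eps))


def compare_groups(matrix: pd.DataFrame, design: GroupDesign,
                   group_a: str, group_b: str, alpha: float = DEFAULT_ALPHA,
                   level: int | None = None,
                   welch: bool = True) -> pd.DataFrame:
    """Per-region two-sided unpaired t-tests (a vs b) with BH correction.

    Rows follow the matrix's region columns.  ``log2_fold_change`` is
    positive where group_a is denser.  Significance means adjusted p <
    ``alpha``.  With ``welch=False`` the pooled-variance Student's test is
    used instead of Welch's.
    """
    ids_a = [s for s in design.members(group_a) if s in matrix.index]
    ids_b = [s for s in design.members(group_b) if s in matrix.index]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    A = matrix.loc[ids_a].to_numpy(float)
    B = matrix.loc[ids_b].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0, equal_var=not welch)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    # zero-variance regions: identical data yields t=0, p=1; a clean
    # mean difference with zero variance is maximally significant
    degen = ~np.isfinite(t)
    same = degen & (mean_a == mean_b)
    diff = degen & ~same
    with np.errstate(invalid="ignore"):
        t = np.where(same, 0.0, t)
        p = np.where(same, 1.0, p)
        t = np.where(diff, np.inf * np.sign(mean_a - mean_b), t)
        p = np.where(diff, 0.0, p)
    rej, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    out = pd.DataFrame({
        "region_id": matrix.columns,
        "level": level if level is not None else -1,
        f"mean_density_{group_a}": mean_a,
        f"mean_density_{group_b}": mean_b,
        "log2_fold_change": _log2_fold_change(mean_a, mean_b),
        "t_statistic": t,
        "p_value": p,
        "p_adjusted": p_adj,
        "significant": rej,
    })
    return out.reset_index(drop=True)


def level_sweep(tables: dict[str, pd.DataFrame], ontology: Ontology,
                design: GroupDesign, group_a: str, group_b: str,
                levels=None, alpha: float = DEFAULT_ALPHA,
                normalization: str = "per_mm3",
                global_correction: bool = False) -> pd.DataFrame:
    """One comparison per structure level, long format.

    BH correction is applied within each level independently (the level-
    aware scheme); ``global_correction=True`` instead corrects across the
    pooled tests of all levels.
    """
    if levels is None:
        levels = range(1, ontology.max_level + 1)
    parts = []
    for lev in levels:
        m = density_matrix(tables, ontology, lev, normalization)
        parts.append(compare_groups(m, design, group_a, group_b,
                                    alpha=alpha, level=lev))
    out = pd.concat(parts, ignore_index=True)
    if global_correction:
        rej, p_adj, _, _ = multipletests(out["p_value"].to_numpy(),
                                         alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["significant"] = rej
    return out
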