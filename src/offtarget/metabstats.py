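"""Differential-abundance statistics for treated-vs-control metabolomics.

Metabolite intensities from untargeted LC-MS are positive, heavy-tailed and
measured on a handful of biological replicates, so effect sizes are reported
as log2 fold changes of replicate means and significance by a one-sided
Mann-Whitney rank test.  For the tiny sample sizes typical of such panels
(n = 3 vs 3) the test's p-value is computed exactly by enumerating rank
arrangements; larger samples use the tie-corrected normal approximation.

The same rank test serves the single-cell length comparisons elsewhere in the
package, where length distributions are far from normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "AbundanceTable",
    "log_fold_change",
    "mann_whitney_one_sided",
    "differential_table",
    "heatmap_matrix",
    "significance_stars",
]

EXACT_LIMIT = 12  # enumerate rank arrangements up to this pooled size


@dataclass
class AbundanceTable:
    """Sample x metabolite intensity matrix with sample and metabolite metadata.

    sample_meta must carry 'condition', 'time_point' and 'replicate' columns
    indexed like the intensity rows; metabolite_meta carries at least
    'annotation_score' indexed by metabolite id.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame
    metabolite_meta: pd.DataFrame

    def __post_init__(self):
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        missing = {"condition", "time_point", "replicate"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta lacks columns {sorted(missing)}")
        if not self.intensities.index.equals(self.sample_meta.index):
            raise ValueError("intensities and sample_meta indices differ")
        if self.intensities.columns.duplicated().any():
            raise ValueError("metabolite identifiers must be unique")

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def subset(self, condition: str, time_point=None) -> pd.DataFrame:
        mask = self.sample_meta["condition"] == condition
        if time_point is not None:
            mask &= self.sample_meta["time_point"] == time_point
        return self.intensities.loc[mask.to_numpy()]

    # -- TSV round trip --------------------------------------------------
    def to_tsv(self, prefix) -> None:
        self.intensities.to_csv(f"{prefix}_intensities.tsv", sep="\t")
        self.sample_meta.to_csv(f"{prefix}_samples.tsv", sep="\t")
        self.metabolite_meta.to_csv(f"{prefix}_metabolites.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, prefix) -> "AbundanceTable":
        return cls(
            pd.read_csv(f"{prefix}_intensities.tsv", sep="\t", index_col=0),
            pd.read_csv(f"{prefix}_samples.tsv", sep="\t", index_col=0),
            pd.read_csv(f"{prefix}_metabolites.tsv", sep="\t", index_col=0),
        )


def log_fold_change(treated, control, pseudocount: float = 0.0, base: float = 2.0) -> float:
    """log_base of (mean(treated)+pc) / (mean(control)+pc).

    Replicates are aggregated by arithmetic mean of raw intensities.  With
    pseudocount 0 a zero denominator (or numerator) raises; a pseudocount of
    half the smallest positive intensity is a reasonable default for sparse
    panels.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("need at least one replicate on each side")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num = treated.mean() + pseudocount
    den = control.mean() + pseudocount
    if num <= 0 or den <= 0:
        raise ZeroDivisionError(
            "undefined log ratio: zero mean intensity with zero pseudocount"
        )
    return float(np.log(num / den) / np.log(base))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x over y, with 0.5 credit for ties."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[: x.size].sum()
    return float(rx - x.size * (x.size + 1) / 2.0)


def mann_whitney_one_sided(x, y, alternative: str = "greater"):
    """One-sided Mann-Whitney rank test of x against y.

    alternative='greater' tests whether x tends to exceed y.  When the pooled
    sample size is at most 12 the p-value is exact: every C(n+m, n)
    assignment of the pooled observations to the two groups is enumerated
    (which handles ties exactly); otherwise the tie-corrected normal
    approximation with continuity correction is used.  Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if alternative == "less":
        u_less, p = mann_whitney_one_sided(y, x, "greater")
        return x.size * y.size - u_less, p

    u_obs = _u_statistic(x, y)
    n, m = x.size, y.size
    if n + m <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        total = 0
        hits = 0
        idx = range(n + m)
        for comb in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if u >= u_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nm = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (nm * (nm - 1))
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0  # all observations identical
    z = (u_obs - mu - 0.5) / math.sqrt(sigma2)
    return u_obs, float(norm.sf(z))


def significance_stars(p: float) -> str:
    """Star convention: * p<=0.05, ** p<=0.001, *** p<=0.0001."""
    if p <= 1e-4:
        return "***"
    if p <= 1e-3:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def differential_table(
    table: AbundanceTable,
    contrast: tuple[str, str],
    time_points=None,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-metabolite, per-time-point differential abundance.

    contrast = (treated_condition, control_condition).  The one-sided test
    direction follows the observed median difference per metabolite (and is
    recorded in the 'direction' column: accumulation for positive log fold
    change, depletion for negative).
    """
    treated_cond, control_cond = contrast
    if time_points is None:
        time_points = sorted(table.sample_meta["time_point"].unique())
    rows = []
    for t in time_points:
        tr = table.subset(treated_cond, t)
        ct = table.subset(control_cond, t)
        if tr.empty or ct.empty:
            raise ValueError(
                f"condition pair {contrast} incomplete at time point {t!r}"
            )
        for met in table.intensities.columns:
            xv, yv = tr[met].to_numpy(), ct[met].to_numpy()
            lfc = log_fold_change(xv, yv, pseudocount)
            direction = "accumulation" if lfc >= 0 else "depletion"
            alt = "greater" if np.median(xv) >= np.median(yv) else "less"
            u, p = mann_whitney_one_sided(xv, yv, alt)
            rows.append({
                "metabolite": met,
                "time_point": t,
                "log_fold_change": lfc,
                "U": u,
                "p_value": p,
                "direction": direction,
                "stars": significance_stars(p),
            })
    return pd.DataFrame(rows)


def heatmap_matrix(diff: pd.DataFrame) -> pd.DataFrame:
    """Metabolite x time-point matrix of log fold changes (heat-map layout)."""
    return diff.pivot(index="metabolite", columns="time_point",
                      values="log_fold_change")
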