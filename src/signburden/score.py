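"""Unweighted genetic risk score (GRS) and group comparisons.

The GRS of an individual is the plain sum of risk-allele dosages over the
variant panel — no effect-size weights.  With complete hard calls over M
variants it is an integer in [0, 2M].  Missing calls are handled by either
summing what is observed ("raw") or rescaling to the full panel size
("rescale", the default: grs * M_total / m_used keeps individuals with
different marker availability on a comparable scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import DosageMatrix, SamplePanel


def compute_grs(matrix: DosageMatrix, missing_policy: str = "rescale") -> pd.DataFrame:
    """Per-sample GRS; columns ``sample``, ``grs``, ``m_used``.

    ``missing_policy``: "rescale" multiplies each sum by M_total/m_used so
    scores stay on the full-panel scale; "raw" reports the bare sum.  Samples
    with no non-missing variant at all are excluded with a warning.
    """
    if matrix.n_variants == 0:
        raise ValueError("dosage matrix has no variants")
    if missing_policy not in ("rescale", "raw"):
        raise ValueError(f"unknown missing policy: {missing_policy!r}")
    d = matrix.dosage
    m_used = np.sum(~np.isnan(d), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grs = np.nansum(d, axis=1)
    if missing_policy == "rescale":
        with np.errstate(divide="ignore", invalid="ignore"):
            grs = grs * (matrix.n_variants / m_used)
    table = pd.DataFrame({"sample": matrix.samples, "grs": grs, "m_used": m_used})
    dropped = table[table["m_used"] == 0]
    if len(dropped):
        warnings.warn(
            f"excluding {len(dropped)} sample(s) with no scored variants: "
            f"{', '.join(dropped['sample'].head().tolist())}",
            stacklevel=2,
        )
        table = table[table["m_used"] > 0].reset_index(drop=True)
    return table


def summarize(
    scores: pd.DataFrame, panel: SamplePanel, level: str = "super_population"
) -> pd.DataFrame:
    """Group summaries (n, mean, min, q25, median, q75, max), sorted by median
    descending so the highest-burden group leads the table."""
    labels = panel.group_of(level)
    df = scores.copy()
    df["group"] = df["sample"].map(labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "sample"].head().tolist()
        raise ValueError(f"scored sample(s) absent from panel: {', '.join(missing)}")
    # linear interpolation between order statistics, stated for reproducibility
    agg = df.groupby("group")["grs"].agg(
        n="size",
        mean="mean",
        min="min",
        q25=lambda s: s.quantile(0.25, interpolation="linear"),
        median="median",
        q75=lambda s: s.quantile(0.75, interpolation="linear"),
        max="max",
    )
    return agg.sort_values("median", ascending=False).reset_index()


def cdf_coordinates(
    scores: pd.DataFrame, panel: SamplePanel, level: str = "super_population"
) -> pd.DataFrame:
    """Empirical CDF coordinates per group (for cumulative-distribution plots)."""
    labels = panel.group_of(level)
    df = scores.copy()
    df["group"] = df["sample"].map(labels)
    out = []
    for grp, sub in df.groupby("group"):
        x = np.sort(sub["grs"].to_numpy())
        out.append(pd.DataFrame({"group": grp, "grs": x, "cdf": np.arange(1, len(x) + 1) / len(x)}))
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class MeanComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    diff: float  # mean_a - mean_b
    t: float
    df: float
    p: float


def compare_means(
    scores: pd.DataFrame,
    panel: SamplePanel,
    group_a: str,
    group_b: str,
    level: str = "super_population",
) -> MeanComparison:
    """Welch (unequal-variance) two-sided t-test of mean GRS between groups."""
    labels = panel.group_of(level)
    df = scores.copy()
    df["group"] = df["sample"].map(labels)
    a = df.loc[df["group"] == group_a, "grs"].to_numpy()
    b = df.loc[df["group"] == group_b, "grs"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 scored samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: identical constants compare as equal
        equal = a.mean() == b.mean()
        return MeanComparison(group_a, group_b, len(a), len(b), float(a.mean()),
                              float(b.mean()), float(a.mean() - b.mean()),
                              0.0 if equal else np.inf, float(len(a) + len(b) - 2),
                              1.0 if equal else 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch–Satterthwaite degrees of freedom
    sa, sb = va / len(a), vb / len(b)
    dof = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return MeanComparison(
        group_a, group_b, len(a), len(b),
        float(a.mean()), float(b.mean()), float(a.mean() - b.mean()),
        float(t), float(dof), float(p),
    )
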