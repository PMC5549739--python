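"""Per-population risk-allele frequencies and the binomial QTL sign test.

Under neutral drift each risk allele is equally likely to end up more common
in either of two populations, so the number of variants at higher frequency
in a focal population is Binomial(n, ½).  The sign test computes the exact
binomial tail of the observed count; no phenotypic effect sizes enter.  The
test consumes frequency tables, so published per-population frequencies can
be fed directly without genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genotypes import DosageMatrix, SamplePanel

log = logging.getLogger(__name__)

LARGE_DIFF_THRESHOLD = 0.2

FREQ_COLUMNS = ["variant_id", "group", "f", "n_chrom"]


def allele_freq(
    matrix: DosageMatrix,
    panel: SamplePanel,
    group: str,
    level: str = "super_population",
    exclude_pops: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Risk-allele frequency per variant within one group.

    f = (sum of non-missing dosages) / (2 * non-missing sample count);
    n_chrom = 2 * that count.  Variants missing in every group sample are
    dropped (logged), since no frequency is defined for them.
    """
    labels = panel.group_of(level)
    pops = panel.group_of("population")
    keep = [
        i
        for i, s in enumerate(matrix.samples)
        if labels.get(s) == group and pops.get(s) not in exclude_pops
    ]
    if not keep:
        raise ValueError(f"no samples in group {group!r}")
    d = matrix.dosage[keep, :]
    n_obs = np.sum(~np.isnan(d), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        total = np.nansum(d, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_obs > 0, total / (2 * n_obs), np.nan)
    table = pd.DataFrame(
        {"variant_id": matrix.variants, "group": group, "f": f, "n_chrom": 2 * n_obs}
    )
    undefined = table[table["n_chrom"] == 0]
    for vid in undefined["variant_id"]:
        log.info("variant %s has no observed genotype in group %s; dropped", vid, group)
    return table[table["n_chrom"] > 0].reset_index(drop=True)


@dataclass(frozen=True)
class SignTestResult:
    focal: str
    reference: str
    n_total: int
    n_ties: int
    n_informative: int
    n_higher: int
    p0: float
    alternative: str
    p: float

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "reference": self.reference,
            "n_total": self.n_total,
            "n_ties": self.n_ties,
            "n_informative": self.n_informative,
            "n_higher": self.n_higher,
            "p0": self.p0,
            "alternative": self.alternative,
            "p": self.p,
        }


def sign_test_counts(
    n_higher: int, n_informative: int, alternative: str = "greater", p0: float = 0.5
) -> float:
    """Exact binomial p for ``n_higher`` successes out of ``n_informative``.

    One-sided ("greater"): P(X >= k).  Two-sided: twice the smaller tail
    (P(X >= k) vs P(X <= k)), capped at 1.
    """
    if not 0 <= n_higher <= n_informative:
        raise ValueError("need 0 <= n_higher <= n_informative")
    if n_informative == 0:
        warnings.warn("sign test with no informative variants; p = 1", stacklevel=2)
        return 1.0
    upper = float(binom.sf(n_higher - 1, n_informative, p0))  # P(X >= k)
    if alternative == "greater":
        return min(upper, 1.0)
    if alternative == "two-sided":
        lower = float(binom.cdf(n_higher, n_informative, p0))  # P(X <= k)
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative: {alternative!r}")


def _aligned(freq_focal: pd.DataFrame, freq_ref: pd.DataFrame) -> pd.DataFrame:
    fa = freq_focal[["variant_id", "f"]].rename(columns={"f": "f_focal"})
    fb = freq_ref[["variant_id", "f"]].rename(columns={"f": "f_ref"})
    merged = fa.merge(fb, on="variant_id", how="inner")
    if len(merged) != len(fa) or len(merged) != len(fb):
        raise ValueError("frequency tables must cover the same variant set")
    return merged


def sign_test(
    freq_focal: pd.DataFrame,
    freq_ref: pd.DataFrame,
    alternative: str = "greater",
) -> SignTestResult:
    """Binomial sign test for systematically higher risk-allele frequency.

    Exact ties (f_focal == f_ref) are excluded, following classical sign-test
    practice: a tied variant carries no directional information.
    """
    m = _aligned(freq_focal, freq_ref)
    n_total = len(m)
    ties = int((m["f_focal"] == m["f_ref"]).sum())
    n_informative = n_total - ties
    n_higher = int((m["f_focal"] > m["f_ref"]).sum())
    p = sign_test_counts(n_higher, n_informative, alternative)
    focal = str(freq_focal["group"].iloc[0]) if "group" in freq_focal and len(freq_focal) else "focal"
    ref = str(freq_ref["group"].iloc[0]) if "group" in freq_ref and len(freq_ref) else "reference"
    return SignTestResult(focal, ref, n_total, ties, n_informative, n_higher, 0.5, alternative, p)


@dataclass(frozen=True)
class DiffSummary:
    n_total: int
    min_abs_diff: float
    max_abs_diff: float
    threshold: float
    n_large: int
    prop_large: float

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "min_abs_diff": self.min_abs_diff,
            "max_abs_diff": self.max_abs_diff,
            "threshold": self.threshold,
            "n_large": self.n_large,
            "prop_large": self.prop_large,
        }


def diff_summary(
    freq_focal: pd.DataFrame,
    freq_ref: pd.DataFrame,
    threshold: float = LARGE_DIFF_THRESHOLD,
) -> DiffSummary:
    """Extremes and large-difference count of per-variant |Δf|.

    "Large" uses a strict > on the configurable threshold (default 0.2).
    """
    m = _aligned(freq_focal, freq_ref)
    adiff = (m["f_focal"] - m["f_ref"]).abs()
    n_large = int((adiff > threshold).sum())
    return DiffSummary(
        n_total=len(m),
        min_abs_diff=float(adiff.min()) if len(m) else 0.0,
        max_abs_diff=float(adiff.max()) if len(m) else 0.0,
        threshold=threshold,
        n_large=n_large,
        prop_large=n_large / len(m) if len(m) else 0.0,
    )


def subset_sign_test(
    freq_focal: pd.DataFrame,
    freq_ref: pd.DataFrame,
    threshold: float = LARGE_DIFF_THRESHOLD,
    alternative: str = "greater",
) -> tuple[SignTestResult, list[str]]:
    """Sign test restricted to variants with |Δf| > ``threshold``.

    Returns the result plus the subset's variant ids.  An empty subset yields
    p = 1 with a warning.
    """
    m = _aligned(freq_focal, freq_ref)
    big = m[(m["f_focal"] - m["f_ref"]).abs() > threshold]
    ids = big["variant_id"].tolist()
    if not ids:
        warnings.warn(f"no variants with |diff| > {threshold}; p = 1", stacklevel=2)
    sub_focal = freq_focal[freq_focal["variant_id"].isin(ids)]
    sub_ref = freq_ref[freq_ref["variant_id"].isin(ids)]
    if not ids:
        focal = str(freq_focal["group"].iloc[0]) if "group" in freq_focal and len(freq_focal) else "focal"
        ref = str(freq_ref["group"].iloc[0]) if "group" in freq_ref and len(freq_ref) else "reference"
        return SignTestResult(focal, ref, 0, 0, 0, 0, 0.5, alternative, 1.0), ids
    return sign_test(sub_focal, sub_ref, alternative), ids


def read_freq_table(path) -> pd.DataFrame:
    """Read a frequency TSV (variant_id, group, f, n_chrom) — the import
    format for published per-population frequency tables."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "group": str})
    missing = set(FREQ_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing column(s): {sorted(missing)}")
    if "n_chrom" not in df.columns:
        df["n_chrom"] = np.nan
    return df[FREQ_COLUMNS]


def write_freq_table(table: pd.DataFrame, path) -> None:
    table[FREQ_COLUMNS].to_csv(path, sep="\t", index=False)
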