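"""Greedy LD pruning on genotype-dosage correlation.

r² here is the squared Pearson correlation of unphased dosage vectors
(composite/genotypic LD) over pairwise-complete samples — phase-free, which is
all that dosage data permits.  Pruning visits variants in a deterministic
order (genomic by default, or most-significant-first) and keeps a variant only
if its r² against every already-kept variant on the same chromosome is below
the threshold.  Cross-chromosome pairs are never pruned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import RiskVariant
from .genotypes import DosageMatrix

#: Sentinel for an r² that is undefined because one vector is monomorphic.
MONOMORPHIC = "monomorphic"

DEFAULT_R2_THRESHOLD = 0.2


def pairwise_r2(g1: np.ndarray, g2: np.ndarray):
    """Squared Pearson correlation over pairwise-complete observations.

    Returns the sentinel :data:`MONOMORPHIC` when fewer than two complete
    pairs exist or either vector has zero variance among them (such a pair is
    treated as unlinked by the pruner).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have the same length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if ok.sum() < 2:
        return MONOMORPHIC
    a, b = g1[ok], g2[ok]
    va = a - a.mean()
    vb = b - b.mean()
    denom = np.sqrt((va**2).sum() * (vb**2).sum())
    if denom == 0.0:
        return MONOMORPHIC
    r = float((va * vb).sum() / denom)
    return min(r * r, 1.0)


@dataclass
class PruneResult:
    kept: list[str]
    removed: list[tuple[str, str, float]]  # (variant, culprit, r2)
    threshold: float

    def removed_ids(self) -> list[str]:
        return [v for v, _, _ in self.removed]

    def to_frame(self) -> pd.DataFrame:
        rows = [(v, "kept", "", np.nan) for v in self.kept]
        rows += [(v, "removed", c, r2) for v, c, r2 in self.removed]
        return pd.DataFrame(rows, columns=["variant_id", "status", "culprit", "r2"])


def greedy_prune(
    matrix: DosageMatrix,
    threshold: float = DEFAULT_R2_THRESHOLD,
    catalog: Optional[Sequence[RiskVariant]] = None,
    rank_by_p: bool = False,
) -> PruneResult:
    """Greedy keep-first pruning of ``matrix``'s variants at ``threshold``.

    Default visit order is genomic (chromosome, position, variant_id); with
    ``rank_by_p`` (requires ``catalog``) the most significant association is
    visited — hence kept — first.  Deterministic for fixed input and order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("r2 threshold must be in (0, 1]")

    ids = list(matrix.variants)
    info = {v: (matrix.chrom[i], matrix.pos[i], i) for i, v in enumerate(ids)}

    if rank_by_p:
        if catalog is None:
            raise ValueError("rank_by_p requires the catalog for p-values")
        pvals = {v.variant_id: v.assoc_p for v in catalog}
        order = sorted(ids, key=lambda v: (pvals.get(v, 1.0), v))
    else:
        def _chrom_key(c: str):
            return (0, int(c)) if c.isdigit() else (1, c)
        order = sorted(ids, key=lambda v: (_chrom_key(info[v][0]), info[v][1], v))

    kept: list[str] = []
    removed: list[tuple[str, str, float]] = []
    for vid in order:
        chrom, _, col = info[vid]
        culprit = None
        for kid in kept:
            kchrom, _, kcol = info[kid]
            if kchrom != chrom:
                continue
            r2 = pairwise_r2(matrix.dosage[:, col], matrix.dosage[:, kcol])
            if r2 != MONOMORPHIC and r2 >= threshold:
                culprit = (kid, r2)
                break
        if culprit is None:
            kept.append(vid)
        else:
            removed.append((vid, culprit[0], culprit[1]))

    # Defensive post-condition: no kept same-chromosome pair at/above threshold.
    _assert_pruned(matrix, kept, threshold)
    return PruneResult(kept=kept, removed=removed, threshold=threshold)


def _assert_pruned(matrix: DosageMatrix, kept: Sequence[str], threshold: float) -> None:
    idx = {v: i for i, v in enumerate(matrix.variants)}
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if matrix.chrom[idx[a]] != matrix.chrom[idx[b]]:
                continue
            r2 = pairwise_r2(matrix.dosage[:, idx[a]], matrix.dosage[:, idx[b]])
            if r2 != MONOMORPHIC and r2 >= threshold:
                raise AssertionError(f"pruning violated: r2({a},{b})={r2:.3f} >= {threshold}")
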