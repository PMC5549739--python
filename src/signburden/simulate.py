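"""Two-population drift/selection simulator for risk-variant datasets.

Population allele frequencies diverge from a shared ancestral frequency p
under the Balding–Nichols model: each population's frequency is drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance F·p(1−p) with
F the fixation index F_ST.  A directional "selection" regime adds a fixed
logit-scale shift δ to the focal population's risk-allele frequency; δ = 0 is
the neutral null.  Genotypes are Binomial(2, f) per individual (Hardy–
Weinberg), optionally with LD blocks of near-copies to exercise pruning.

``emit_dataset`` writes a catalog TSV, a VCF 4.2 (GT, optional DS), a
two-group panel file and a truth table; a fixed seed yields byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])

FOCAL_POP, FOCAL_GROUP = "SIMA", "GRPA"
REF_POP, REF_GROUP = "SIMB", "GRPB"


@dataclass
class SimConfig:
    """Study conditions for one simulated two-population dataset.

    Defaults mirror the real-data analysis the simulator stands in for:
    147 quasi-independent risk variants, a few hundred individuals per
    population group, and continental-scale divergence (F_ST = 0.15, about
    the African–European value); ancestral frequencies uniform on
    [0.05, 0.95] keep variants comfortably polymorphic.
    """

    n_variants: int = 147
    n_per_pop: int = 300
    fst: float = 0.15
    ancestral_dist: tuple = ("uniform", 0.05, 0.95)  # or ("beta", a, b)
    delta: float = 0.0
    ld_blocks: Optional[Sequence[tuple[int, float]]] = None  # (size, fidelity)
    write_ds: bool = False
    clamp: tuple[float, float] = (0.01, 0.99)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.n_variants < 1 or self.n_per_pop < 1:
            raise ValueError("n_variants and n_per_pop must be positive")
        if self.ld_blocks:
            if sum(s for s, _ in self.ld_blocks) > self.n_variants:
                raise ValueError("ld_blocks exceed n_variants")
            for size, fid in self.ld_blocks:
                if size < 2 or not 0.0 <= fid <= 1.0:
                    raise ValueError("each LD block needs size >= 2 and fidelity in [0,1]")


@dataclass
class SimOutput:
    truth: pd.DataFrame
    catalog_path: Path
    vcf_path: Path
    panel_path: Path
    truth_path: Path

    def to_json(self) -> str:
        return json.dumps(
            {
                "catalog": str(self.catalog_path),
                "vcf": str(self.vcf_path),
                "panel": str(self.panel_path),
                "truth": str(self.truth_path),
            },
            indent=2,
        )


def shift_frequency(f, delta: float, clamp: tuple[float, float] = (0.01, 0.99)):
    """Shift a frequency on the logit scale: f' = expit(logit(f) + delta)."""
    f = np.asarray(f, dtype=float)
    logit = np.log(f / (1.0 - f))
    shifted = 1.0 / (1.0 + np.exp(-(logit + delta)))
    out = np.clip(shifted, clamp[0], clamp[1])
    return float(out) if out.ndim == 0 else out


def _draw_ancestral(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *params = config.ancestral_dist
    if kind == "uniform":
        lo, hi = params
        p = rng.uniform(lo, hi, size=config.n_variants)
    elif kind == "beta":
        a, b = params
        p = rng.beta(a, b, size=config.n_variants)
    else:
        raise ValueError(f"unknown ancestral_dist kind: {kind!r}")
    return np.clip(p, config.clamp[0], config.clamp[1])


def balding_nichols(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """One population frequency per ancestral p under the Beta drift model."""
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def draw_frequencies(config: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Truth table: ancestral p and both population frequencies per variant.

    The focal population's risk-allele frequency receives the logit shift
    delta (neutral when 0).  All frequencies are clamped to ``config.clamp``
    to avoid monomorphic variants that downstream steps would discard.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = _draw_ancestral(config, rng)
    lo, hi = config.clamp
    f_focal = np.clip(balding_nichols(p, config.fst, rng), lo, hi)
    f_ref = np.clip(balding_nichols(p, config.fst, rng), lo, hi)
    shifted = config.delta != 0.0
    if shifted:
        f_focal = shift_frequency(f_focal, config.delta, config.clamp)
    ids = [f"rs{900000 + i}" for i in range(config.n_variants)]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": 100_000 * (np.arange(config.n_variants) + 1),
            "ancestral_p": p,
            "f_focal": f_focal,
            "f_ref": f_ref,
            "shifted": shifted,
        }
    )


def _draw_genotypes(
    truth: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """(2*n_per_pop, L) matrix of risk-allele counts; focal samples first."""
    n = config.n_per_pop
    L = len(truth)
    g = np.empty((2 * n, L), dtype=np.int64)
    g[:n, :] = rng.binomial(2, truth["f_focal"].to_numpy()[None, :], size=(n, L))
    g[n:, :] = rng.binomial(2, truth["f_ref"].to_numpy()[None, :], size=(n, L))
    if config.ld_blocks:
        # Blocks occupy consecutive variants from the start; the first member
        # seeds the block, the rest are copies in which each genotype is
        # redrawn from Binomial(2, f) with probability 1 - fidelity, so the
        # marginal frequency stays exactly the truth-table value.
        start = 0
        for size, fidelity in config.ld_blocks:
            seed_col = g[:, start]
            for j in range(start + 1, start + size):
                truth.loc[j, ["ancestral_p", "f_focal", "f_ref"]] = truth.loc[
                    start, ["ancestral_p", "f_focal", "f_ref"]
                ].to_numpy()
                col = seed_col.copy()
                redraw = rng.random(2 * n) < (1.0 - fidelity)
                f = np.concatenate(
                    [
                        np.full(n, truth.at[start, "f_focal"]),
                        np.full(n, truth.at[start, "f_ref"]),
                    ]
                )
                col[redraw] = rng.binomial(2, f[redraw])
                g[:, j] = col
            start += size
    return g


def emit_dataset(config: SimConfig, outdir) -> SimOutput:
    """Draw a full dataset and write catalog/VCF/panel/truth files.

    Risk allele = the simulated ALT allele; every catalog p-value is
    genome-wide significant so the dataset passes the catalog filters
    untouched.  Same seed -> byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    truth = draw_frequencies(config, rng)
    g = _draw_genotypes(truth, config, rng)
    L = len(truth)
    n = config.n_per_pop

    # random REF != ALT per variant
    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    ref = BASES[ref_idx]
    alt = BASES[alt_idx]

    samples = [f"SA{i:04d}" for i in range(n)] + [f"SB{i:04d}" for i in range(n)]

    catalog_path = outdir / "catalog.tsv"
    with open(catalog_path, "w", newline="") as fh:
        fh.write("variant_id\tchrom\tpos\trisk\tother\ttrait\tp\n")
        for i in range(L):
            fh.write(
                f"{truth.at[i, 'variant_id']}\t{truth.at[i, 'chrom']}\t{truth.at[i, 'pos']}"
                f"\t{alt[i]}\t{ref[i]}\tSimulatedTrait\t1e-09\n"
            )

    ds = None
    if config.write_ds:
        noise = rng.normal(0.0, 0.05, size=g.shape)
        ds = np.clip(g + noise, 0.0, 2.0)

    vcf_path = outdir / "genotypes.vcf"
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=signburden-simulate\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if config.write_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        fmt = "GT:DS" if config.write_ds else "GT"
        for i in range(L):
            if config.write_ds:
                cells = [f"{gt_str[int(g[s, i])]}:{ds[s, i]:.3f}" for s in range(2 * n)]
            else:
                cells = [gt_str[int(g[s, i])] for s in range(2 * n)]
            fh.write(
                f"{truth.at[i, 'chrom']}\t{truth.at[i, 'pos']}\t{truth.at[i, 'variant_id']}"
                f"\t{ref[i]}\t{alt[i]}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )

    panel_path = outdir / "panel.txt"
    with open(panel_path, "w", newline="") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for s in samples[:n]:
            fh.write(f"{s}\t{FOCAL_POP}\t{FOCAL_GROUP}\n")
        for s in samples[n:]:
            fh.write(f"{s}\t{REF_POP}\t{REF_GROUP}\n")

    truth_path = outdir / "truth.tsv"
    truth_out = truth.copy()
    for c in ("ancestral_p", "f_focal", "f_ref"):
        truth_out[c] = truth_out[c].map(lambda x: f"{x:.10g}")
    truth_out.to_csv(truth_path, sep="\t", index=False)

    return SimOutput(truth, catalog_path, vcf_path, panel_path, truth_path)


def sample_group_frequencies(
    truth: pd.DataFrame, n_per_pop: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Estimated risk-allele frequencies from binomial allele-count sampling.

    Equivalent to drawing 2*n_per_pop Hardy–Weinberg chromosomes per
    population and counting risk alleles — the fast path used by the
    calibration studies, where per-individual genotypes are never needed.
    """
    n_chrom = 2 * n_per_pop
    fa = rng.binomial(n_chrom, truth["f_focal"].to_numpy()) / n_chrom
    fb = rng.binomial(n_chrom, truth["f_ref"].to_numpy()) / n_chrom
    return fa, fb
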