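"""End-to-end orchestration: catalog -> prune -> score -> sign test.

``run`` executes the whole analysis from a single :class:`RunConfig`, writes
every stage artifact (normalized catalog, match report, prune log, scores,
summaries, frequency tables) plus ``report.json`` and ``report.txt`` under
the output directory, and returns the :class:`Report`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from . import catalog as catalog_mod, genotypes, ldprune, score as score_mod, seltest
from ._version import __version__

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    catalog: str
    vcf: str
    panel: str
    outdir: str
    focal_group: str = "AFR"
    reference_group: str = "EUR"
    exclude_pops: list[str] = field(default_factory=list)
    hla_chrom: str = "6"
    hla_start: int = 25_000_000
    hla_end: int = 35_000_000
    r2_threshold: float = 0.2
    gw_p_threshold: float = 5e-8
    large_diff_threshold: float = 0.2
    missing_policy: str = "rescale"
    alternative: str = "greater"
    prune: bool = True
    level: str = "super_population"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.focal_group == self.reference_group:
            raise ValueError("focal and reference group must differ")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if not 0 < self.gw_p_threshold <= 1:
            raise ValueError("gw_p_threshold must be in (0, 1]")
        if not 0 <= self.large_diff_threshold < 1:
            raise ValueError("large_diff_threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class Report:
    config: dict
    version: str
    timestamp: str
    stage_counts: dict
    group_summary: list[dict]
    mean_comparisons: list[dict]
    sign_tests: list[dict]
    diff_summary: dict
    subset_variants: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: RunConfig) -> Report:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the failing stage
                raise StageError(name, exc) from exc
        return deco

    @stage("catalog.load")
    def _loaded():
        variants, rejected = catalog_mod.load_catalog(config.catalog)
        counts["catalog_rows"] = len(variants) + len(rejected)
        counts["catalog_parsed"] = len(variants)
        return variants

    @stage("catalog.filter_genome_wide")
    def _significant():
        kept = catalog_mod.filter_genome_wide(_loaded, config.gw_p_threshold)
        counts["genome_wide"] = len(kept)
        return kept

    @stage("catalog.exclude_region")
    def _no_hla():
        region = catalog_mod.GenomicRegion(config.hla_chrom, config.hla_start, config.hla_end)
        kept, removed = catalog_mod.exclude_region(_significant, region)
        counts["after_region_exclusion"] = len(kept)
        log.info("region exclusion removed %d variant(s)", len(removed))
        return kept

    @stage("catalog.dedupe")
    def _unique():
        unique, conflicts = catalog_mod.dedupe(_no_hla)
        counts["after_dedupe"] = len(unique)
        if conflicts:
            log.warning("risk-allele conflicts at: %s", [c[0] for c in conflicts])
        catalog_mod.write_catalog(unique, outdir / "catalog_normalized.tsv")
        return unique

    @stage("genotypes.read_panel")
    def _panel():
        return genotypes.read_panel(config.panel)

    @stage("genotypes.read_vcf")
    def _matrix_report():
        matrix, match = genotypes.read_vcf(config.vcf, _unique, _panel)
        counts["matched_in_vcf"] = matrix.n_variants
        genotypes.write_match_report(match, outdir / "match_report.tsv")
        return matrix

    matrix = _matrix_report

    if config.prune:
        @stage("ldprune.greedy_prune")
        def _pruned():
            result = ldprune.greedy_prune(matrix, config.r2_threshold, catalog=_unique)
            result.to_frame().to_csv(outdir / "prune.tsv", sep="\t", index=False)
            return matrix.select_variants(result.kept)
        matrix = _pruned
    counts["after_pruning"] = matrix.n_variants

    @stage("score.compute_grs")
    def _scores():
        table = score_mod.compute_grs(matrix, config.missing_policy)
        counts["scored_samples"] = len(table)
        return table

    @stage("score.summarize")
    def _summary():
        summary = score_mod.summarize(_scores, _panel, config.level)
        labeled = _scores.copy()
        labeled["group"] = labeled["sample"].map(_panel.group_of(config.level))
        labeled.to_csv(outdir / "scores.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
        score_mod.cdf_coordinates(_scores, _panel, config.level).to_csv(
            outdir / "grs_cdf.tsv", sep="\t", index=False
        )
        return summary

    @stage("score.compare_means")
    def _comparisons():
        comps = [
            score_mod.compare_means(
                _scores, _panel, config.focal_group, config.reference_group, config.level
            )
        ]
        if config.exclude_pops:
            # continental-only sensitivity: drop admixed populations from focal
            pops = _panel.group_of("population")
            keep = [
                s
                for s in _scores["sample"]
                if pops.get(s) not in config.exclude_pops
            ]
            sub = _scores[_scores["sample"].isin(keep)]
            comps.append(
                score_mod.compare_means(
                    sub, _panel, config.focal_group, config.reference_group, config.level
                )
            )
        return comps

    @stage("seltest.allele_freq")
    def _freqs():
        fa = seltest.allele_freq(matrix, _panel, config.focal_group, config.level)
        fb = seltest.allele_freq(matrix, _panel, config.reference_group, config.level)
        common = sorted(set(fa["variant_id"]) & set(fb["variant_id"]),
                        key=list(matrix.variants).index)
        fa = fa[fa["variant_id"].isin(common)].reset_index(drop=True)
        fb = fb[fb["variant_id"].isin(common)].reset_index(drop=True)
        seltest.write_freq_table(fa, outdir / f"freq_{config.focal_group}.tsv")
        seltest.write_freq_table(fb, outdir / f"freq_{config.reference_group}.tsv")
        return fa, fb

    fa, fb = _freqs

    @stage("seltest.sign_test")
    def _sign():
        return seltest.sign_test(fa, fb, config.alternative)

    @stage("seltest.diff_summary")
    def _diffs():
        return seltest.diff_summary(fa, fb, config.large_diff_threshold)

    @stage("seltest.subset_sign_test")
    def _subset():
        return seltest.subset_sign_test(
            fa, fb, config.large_diff_threshold, config.alternative
        )

    subset_result, subset_ids = _subset
    counts["sign_test_variants"] = _sign.n_total

    report = Report(
        config=asdict(config),
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        stage_counts=counts,
        group_summary=_summary.to_dict(orient="records"),
        mean_comparisons=[asdict(c) for c in _comparisons],
        sign_tests=[_sign.to_dict(), subset_result.to_dict()],
        diff_summary=_diffs.to_dict(),
        subset_variants=subset_ids,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    (outdir / "report.txt").write_text(report_render(report))
    return report


def report_render(report: Report) -> str:
    """Human-readable report: stage funnel, group summary table sorted by
    median, mean comparisons, and the sign-test paragraph."""
    if not report.group_summary:
        raise ValueError("report has no group summaries to render")
    lines = [
        "signburden report",
        "=================",
        f"version {report.version}  generated {report.timestamp}",
        "",
        "Stage funnel",
        "------------",
    ]
    for k, v in report.stage_counts.items():
        lines.append(f"  {k:<24} {v}")
    lines += ["", "GRS by group (sorted by median)", "-------------------------------",
              f"  {'group':<10}{'n':>6}{'mean':>10}{'min':>8}{'q25':>8}{'median':>8}{'q75':>8}{'max':>8}"]
    for row in report.group_summary:
        lines.append(
            f"  {row['group']:<10}{row['n']:>6}{row['mean']:>10.2f}{row['min']:>8.1f}"
            f"{row['q25']:>8.1f}{row['median']:>8.1f}{row['q75']:>8.1f}{row['max']:>8.1f}"
        )
    lines += ["", "Mean comparisons (Welch t)", "--------------------------"]
    for c in report.mean_comparisons:
        lines.append(
            f"  {c['group_a']} (n={c['n_a']}, mean={c['mean_a']:.2f}) vs "
            f"{c['group_b']} (n={c['n_b']}, mean={c['mean_b']:.2f}): "
            f"diff={c['diff']:.2f}, t={c['t']:.2f}, df={c['df']:.1f}, p={c['p']:.3g}"
        )
    full, subset = report.sign_tests
    d = report.diff_summary
    lines += [
        "",
        "Sign test",
        "---------",
        f"  {full['n_higher']} of {full['n_informative']} informative variants "
        f"({full['n_ties']} ties excluded of {full['n_total']}) have higher "
        f"risk-allele frequency in {full['focal']} than {full['reference']}; "
        f"exact binomial ({full['alternative']}) p = {full['p']:.4g}.",
        f"  |diff| range {d['min_abs_diff']:.3f}-{d['max_abs_diff']:.3f}; "
        f"{d['n_large']} of {d['n_total']} variants exceed {d['threshold']:.2f} "
        f"({100 * d['prop_large']:.0f}%).",
        f"  Large-difference subset: {subset['n_higher']} of {subset['n_informative']} "
        f"higher in {full['focal']}; p = {subset['p']:.4g}.",
        "",
    ]
    return "\n".join(lines)
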