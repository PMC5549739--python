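"""VCF genotype/dosage extraction and risk-allele harmonization.

A catalog risk allele is reported relative to an arbitrary strand and allele
ordering; the VCF fixes REF/ALT on the '+' strand.  ``resolve_orientation``
reconciles the two (exact match first, then reverse-complement), and
``read_vcf`` turns matched records into a samples x variants matrix of
risk-allele dosages in [0, 2] (NaN = missing call).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import RiskVariant

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class OrientationMode(str, Enum):
    RISK_IS_ALT = "risk_is_alt"
    RISK_IS_REF = "risk_is_ref"
    FLIP_RISK_IS_ALT = "flip_risk_is_alt"
    FLIP_RISK_IS_REF = "flip_risk_is_ref"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class AlleleOrientation:
    mode: OrientationMode
    ambiguous_palindrome: bool = False

    @property
    def resolved(self) -> bool:
        return self.mode is not OrientationMode.UNRESOLVED

    def risk_dosage(self, alt_dosage):
        """Transform an ALT dosage into a risk-allele dosage."""
        if self.mode in (OrientationMode.RISK_IS_ALT, OrientationMode.FLIP_RISK_IS_ALT):
            return alt_dosage
        if self.mode in (OrientationMode.RISK_IS_REF, OrientationMode.FLIP_RISK_IS_REF):
            return 2.0 - alt_dosage
        raise ValueError("cannot compute dosage for an unresolved orientation")


def resolve_orientation(
    risk: str, other: Optional[str], ref: str, alt: str
) -> AlleleOrientation:
    """Match a (risk, other) allele pair onto a VCF (ref, alt) pair.

    Exact match wins; otherwise the reverse-complement (strand-flipped) match.
    Palindromic pairs (A/T or C/G) that match without flipping are accepted as
    plus-strand but flagged ``ambiguous_palindrome`` — for such pairs the flip
    is indistinguishable from an allele swap.  When ``other`` is unknown
    (None) matching proceeds on the risk allele alone.  No match at all yields
    ``UNRESOLVED`` (a value, never an exception).
    """
    palindromic = other is not None and _COMPLEMENT[risk] == other

    def _match(r: str, o: Optional[str]) -> Optional[str]:
        # returns "alt"/"ref" if (r, o) fits (alt, ref) resp. (ref, alt)
        if r == alt and (o is None or o == ref):
            return "alt"
        if r == ref and (o is None or o == alt):
            return "ref"
        return None

    side = _match(risk, other)
    if side is not None:
        mode = OrientationMode.RISK_IS_ALT if side == "alt" else OrientationMode.RISK_IS_REF
        return AlleleOrientation(mode, ambiguous_palindrome=palindromic)

    flipped = _match(_COMPLEMENT[risk], None if other is None else _COMPLEMENT[other])
    if flipped is not None:
        mode = (
            OrientationMode.FLIP_RISK_IS_ALT
            if flipped == "alt"
            else OrientationMode.FLIP_RISK_IS_REF
        )
        return AlleleOrientation(mode, ambiguous_palindrome=palindromic)

    return AlleleOrientation(OrientationMode.UNRESOLVED, ambiguous_palindrome=palindromic)


@dataclass
class SamplePanel:
    """Sample -> population / super-population assignments (1000G panel style)."""

    table: pd.DataFrame  # columns: sample, pop, super_pop

    def __post_init__(self):
        required = {"sample", "pop", "super_pop"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"panel table must have columns {sorted(required)}")
        dup = self.table["sample"][self.table["sample"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample id(s) in panel: {', '.join(dup.head().tolist())}")
        if (self.table[["pop", "super_pop"]].isna() | (self.table[["pop", "super_pop"]] == "")).any().any():
            raise ValueError("every sample needs a non-empty pop and super_pop")
        # each population must map to exactly one super-population
        amb = self.table.groupby("pop")["super_pop"].nunique()
        if (amb > 1).any():
            raise ValueError(f"population(s) mapped to >1 super-population: {amb[amb > 1].index.tolist()}")

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def group_of(self, level: str = "super_pop") -> pd.Series:
        """sample-indexed Series of group labels at the requested level."""
        if level not in ("pop", "super_pop", "population", "super_population"):
            raise ValueError(f"unknown panel level: {level}")
        col = "pop" if level in ("pop", "population") else "super_pop"
        return self.table.set_index("sample")[col]

    def __len__(self) -> int:
        return len(self.table)


def read_panel(path) -> SamplePanel:
    """Read a whitespace-delimited panel file with header sample/pop/super_pop."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"sample_id": "sample", "population": "pop", "super_population": "super_pop"}
    df = df.rename(columns=rename)
    extra = set(df.columns) - {"sample", "pop", "super_pop", "gender", "sex"}
    if extra:
        warnings.warn(f"ignoring unknown panel column(s): {sorted(extra)}", stacklevel=2)
    return SamplePanel(df[["sample", "pop", "super_pop"]].copy())


@dataclass
class DosageMatrix:
    """Samples x variants risk-allele dosages in [0, 2]; NaN marks missing."""

    samples: list[str]
    variants: list[str]
    dosage: np.ndarray  # float (n_samples, n_variants)
    source: list[str]  # per-variant "GT" or "DS"
    chrom: list[str] = field(default_factory=list)
    pos: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape does not match sample/variant lists")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] (or be NaN)")
        if not self.chrom:
            self.chrom = ["?"] * len(self.variants)
        if not self.pos:
            self.pos = [0] * len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variants.index(variant_id)]

    def select_variants(self, variant_ids: Sequence[str]) -> "DosageMatrix":
        idx = [self.variants.index(v) for v in variant_ids]
        return DosageMatrix(
            samples=list(self.samples),
            variants=list(variant_ids),
            dosage=self.dosage[:, idx],
            source=[self.source[i] for i in idx],
            chrom=[self.chrom[i] for i in idx],
            pos=[self.pos[i] for i in idx],
        )


@dataclass(frozen=True)
class VariantMatch:
    variant_id: str
    status: str  # matched | missing | skipped
    detail: str = ""


def read_vcf(
    path,
    catalog: Sequence[RiskVariant],
    panel: Optional[SamplePanel] = None,
    prefer_ds: bool = True,
) -> tuple[DosageMatrix, list[VariantMatch]]:
    """Extract risk-allele dosages for catalog variants from a VCF.

    Records are matched by rsID first, then by chrom:pos.  Multi-allelic
    records and unresolved allele orientations are skipped with a logged
    reason.  DS (imputed dosage) takes precedence over GT when present and
    ``prefer_ds`` is true.  Variant columns come back in catalog order.

    Returns the matrix plus a per-catalog-variant match report.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    vcf_samples = list(vcf.samples)
    if panel is not None:
        overlap = set(vcf_samples) & set(panel.samples)
        if not overlap:
            raise ValueError("VCF sample set is disjoint from the panel")

    by_id = {v.variant_id: v for v in catalog}
    by_pos = {(v.chromosome, v.position): v for v in catalog}

    columns: dict[str, np.ndarray] = {}
    sources: dict[str, str] = {}
    coords: dict[str, tuple[str, int]] = {}
    report: dict[str, VariantMatch] = {}

    for rec in vcf:
        chrom = rec.CHROM.lstrip("chr")
        target = by_id.get(rec.ID) if rec.ID else None
        if target is None:
            target = by_pos.get((chrom, rec.POS))
        if target is None:
            continue
        vid = target.variant_id
        if vid in columns:
            continue  # first matching record wins
        if len(rec.ALT) != 1:
            report[vid] = VariantMatch(vid, "skipped", f"multi-allelic ({len(rec.ALT)} ALTs)")
            log.info("skipping %s: multi-allelic", vid)
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            report[vid] = VariantMatch(vid, "skipped", f"not a SNP ({ref}/{alt})")
            continue
        orient = resolve_orientation(target.risk_allele, target.other_allele, ref, alt)
        if not orient.resolved:
            report[vid] = VariantMatch(
                vid, "skipped",
                f"unresolved orientation (risk={target.risk_allele}/{target.other_allele or '?'}"
                f" vs {ref}/{alt})",
            )
            log.info("skipping %s: unresolved allele orientation", vid)
            continue

        try:
            ds = rec.format("DS") if prefer_ds else None
        except KeyError:  # DS absent from the FORMAT header
            ds = None
        if ds is not None:
            alt_dosage = np.asarray(ds, dtype=float).reshape(-1)
            alt_dosage = np.where((alt_dosage < 0) | (alt_dosage > 2), np.nan, alt_dosage)
            src = "DS"
        else:
            gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2 ALT copies, 3 unknown
            alt_dosage = np.where(gt == 3, np.nan, gt)
            src = "GT"
        columns[vid] = orient.risk_dosage(alt_dosage)
        sources[vid] = src
        coords[vid] = (chrom, rec.POS)
        detail = "palindromic, accepted as plus-strand" if orient.ambiguous_palindrome else orient.mode.value
        report[vid] = VariantMatch(vid, "matched", detail)

    matched_ids = [v.variant_id for v in catalog if v.variant_id in columns]
    full_report = [
        report.get(v.variant_id, VariantMatch(v.variant_id, "missing", "not found in VCF"))
        for v in catalog
    ]
    matrix = DosageMatrix(
        samples=vcf_samples,
        variants=matched_ids,
        dosage=(
            np.column_stack([columns[v] for v in matched_ids])
            if matched_ids
            else np.empty((len(vcf_samples), 0))
        ),
        source=[sources[v] for v in matched_ids],
        chrom=[coords[v][0] for v in matched_ids],
        pos=[coords[v][1] for v in matched_ids],
    )
    return matrix, full_report


def subset_samples(
    matrix: DosageMatrix,
    panel: SamplePanel,
    groups: Iterable[str],
    exclude: Iterable[str] = (),
) -> DosageMatrix:
    """Restrict to samples whose super-population is in ``groups`` and whose
    population is not in ``exclude`` (e.g. AFR minus the admixed ACB/ASW)."""
    groups = set(groups)
    exclude = set(exclude)
    known = set(panel.table["super_pop"])
    unknown = groups - known
    if unknown:
        raise ValueError(f"unknown super-population code(s): {sorted(unknown)}")
    tab = panel.table.set_index("sample")
    keep = [
        i
        for i, s in enumerate(matrix.samples)
        if s in tab.index
        and tab.at[s, "super_pop"] in groups
        and tab.at[s, "pop"] not in exclude
    ]
    if not keep:
        raise ValueError(f"no samples left after restricting to {sorted(groups)} minus {sorted(exclude)}")
    return DosageMatrix(
        samples=[matrix.samples[i] for i in keep],
        variants=list(matrix.variants),
        dosage=matrix.dosage[keep, :],
        source=list(matrix.source),
        chrom=list(matrix.chrom),
        pos=list(matrix.pos),
    )


def write_match_report(report: Sequence[VariantMatch], path) -> None:
    pd.DataFrame([(m.variant_id, m.status, m.detail) for m in report],
                 columns=["variant_id", "status", "detail"]).to_csv(path, sep="\t", index=False)
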