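"""Risk-variant catalog parsing, filtering, and deduplication.

The catalog defines which SNPs enter the genetic risk score.  Two tab-delimited
dialects are accepted: the GWAS-Catalog export (columns ``SNPS``, ``CHR_ID``,
``CHR_POS``, ``STRONGEST SNP-RISK ALLELE``, ``DISEASE/TRAIT``, ``P-VALUE``,
with the risk allele embedded as ``rsID-X``) and a simpler native layout
(``variant_id``, ``chrom``, ``pos``, ``risk``, ``other``, ``trait``, ``p``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

VALID_BASES = frozenset("ACGT")
VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])

#: Default genome-wide significance threshold for catalog associations.
GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class RiskVariant:
    """One catalog SNP with a declared risk-increasing allele."""

    variant_id: str
    chromosome: str
    position: int
    risk_allele: str
    other_allele: Optional[str]  # None when the source does not report it
    trait: str
    assoc_p: float
    x_linked: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.risk_allele not in VALID_BASES:
            raise ValueError(f"{self.variant_id}: invalid risk allele {self.risk_allele!r}")
        if self.other_allele is not None:
            if self.other_allele not in VALID_BASES:
                raise ValueError(f"{self.variant_id}: invalid other allele {self.other_allele!r}")
            if self.other_allele == self.risk_allele:
                raise ValueError(f"{self.variant_id}: risk and other allele identical")


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open 1-based region [start, end) on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"region start {self.start} must be < end {self.end}")

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position < self.end


#: Extended MHC window on GRCh37: gene-dense, long-range LD, conventionally
#: excluded from independent-SNP scores.  Configurable wherever it is used.
HLA_REGION = GenomicRegion("6", 25_000_000, 35_000_000)


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str
    raw: str


class CatalogError(Exception):
    """Configuration/parse problem with a catalog file."""


# Column-name aliases, checked case-insensitively after stripping.
_COLUMN_ALIASES = {
    "variant_id": ("variant_id", "snps", "snp", "rsid"),
    "chromosome": ("chrom", "chr", "chr_id", "chromosome"),
    "position": ("pos", "chr_pos", "position", "bp"),
    "risk": ("risk", "risk_allele", "strongest snp-risk allele"),
    "other": ("other", "other_allele", "ref_allele"),
    "trait": ("trait", "disease/trait", "disease_trait", "disease"),
    "p": ("p", "p-value", "pvalue", "p_value", "assoc_p"),
}

_REQUIRED = ("variant_id", "chromosome", "position", "risk", "trait", "p")


def _map_columns(header: list[str]) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[canonical] = lowered.index(alias)
                break
    missing = [c for c in _REQUIRED if c not in mapping]
    if missing:
        raise CatalogError(f"catalog header missing mandatory column(s): {', '.join(missing)}")
    return mapping


def _parse_risk_field(raw: str, variant_id: str) -> str:
    """Extract a risk allele from either a bare base or an 'rsID-X' field."""
    raw = raw.strip()
    if "-" in raw:
        raw = raw.rsplit("-", 1)[1]
    raw = raw.upper()
    if raw == "?":
        raise ValueError("unknown risk allele")
    if raw not in VALID_BASES:
        raise ValueError(f"unparseable risk allele {raw!r}")
    return raw


def load_catalog(path) -> tuple[list[RiskVariant], list[RejectedRow]]:
    """Parse a tab-delimited risk-variant catalog.

    Returns ``(variants, rejected)``: one :class:`RiskVariant` per parseable
    row, plus a list of rejected rows with reasons (unknown/unparseable risk
    alleles, bad coordinates, malformed p-values).

    Raises
    ------
    CatalogError
        If a mandatory column is absent or the file has no data rows.
    """
    variants: list[RiskVariant] = []
    rejected: list[RejectedRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CatalogError(f"empty catalog file: {path}") from None
        cols = _map_columns(header)
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            n_rows += 1
            raw = "\t".join(row)
            try:
                other = None
                if "other" in cols and cols["other"] < len(row):
                    o = row[cols["other"]].strip().upper()
                    other = o if o in VALID_BASES else None
                chrom = row[cols["chromosome"]].strip().lstrip("chr").upper() or "?"
                variants.append(
                    RiskVariant(
                        variant_id=row[cols["variant_id"]].strip(),
                        chromosome=chrom,
                        position=int(row[cols["position"]].strip()),
                        risk_allele=_parse_risk_field(row[cols["risk"]], row[cols["variant_id"]]),
                        other_allele=other,
                        trait=row[cols["trait"]].strip(),
                        assoc_p=float(row[cols["p"]].strip()),
                        x_linked=chrom == "X",
                    )
                )
            except (ValueError, IndexError) as exc:
                rejected.append(RejectedRow(lineno, str(exc), raw))
    if n_rows == 0:
        raise CatalogError(f"catalog file has a header but no data rows: {path}")
    return variants, rejected


def filter_genome_wide(
    variants: Iterable[RiskVariant], threshold: float = GENOME_WIDE_P
) -> list[RiskVariant]:
    """Keep variants whose association p-value is <= ``threshold``."""
    if not threshold > 0:
        raise ValueError("p-value threshold must be positive")
    return [v for v in variants if v.assoc_p <= threshold]


def exclude_region(
    variants: Iterable[RiskVariant], region: GenomicRegion = HLA_REGION
) -> tuple[list[RiskVariant], list[RiskVariant]]:
    """Partition variants into (kept, removed) by half-open region overlap."""
    kept, removed = [], []
    for v in variants:
        (removed if region.contains(v.chromosome, v.position) else kept).append(v)
    return kept, removed


def dedupe(
    variants: Iterable[RiskVariant],
) -> tuple[list[RiskVariant], list[tuple[str, str, str]]]:
    """Collapse repeated rsIDs (a SNP can be reported for several traits).

    First occurrence in input order wins.  Returns ``(unique, conflicts)``
    where each conflict is ``(variant_id, kept_risk_allele, other_risk_allele)``
    for rsIDs that appear with *different* risk alleles — these are reported,
    never silently merged (the conflicting later record is dropped).
    """
    seen: dict[str, RiskVariant] = {}
    conflicts: list[tuple[str, str, str]] = []
    for v in variants:
        prev = seen.get(v.variant_id)
        if prev is None:
            seen[v.variant_id] = v
        elif v.risk_allele != prev.risk_allele:
            conflicts.append((v.variant_id, prev.risk_allele, v.risk_allele))
    return list(seen.values()), conflicts


def write_catalog(variants: Iterable[RiskVariant], path) -> None:
    """Write the normalized catalog TSV (the native dialect)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "chrom", "pos", "risk", "other", "trait", "p"])
        for v in variants:
            w.writerow(
                [v.variant_id, v.chromosome, v.position, v.risk_allele,
                 v.other_allele or "?", v.trait, f"{v.assoc_p:.6g}"]
            )
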