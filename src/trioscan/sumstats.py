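"""Reading, validation and threshold filtering of GWAS summary-statistic tables.

Input dialect: tab-separated, UTF-8, header row with columns
``rsid, chrom, pos, effect_allele, pvalue, trait, study_id``.
Each file carries associations of a single trait layer (microbe or
metabolite), passed explicitly as ``trait_type``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConsistencyError, RecordValidationError, SumstatsFormatError

__all__ = [
    "TraitType",
    "AssociationRecord",
    "ThresholdConfig",
    "REQUIRED_COLUMNS",
    "load_sumstats",
    "write_sumstats",
    "filter_significant",
    "dedupe_records",
    "chrom_sort_key",
]

REQUIRED_COLUMNS = ("rsid", "chrom", "pos", "effect_allele", "pvalue", "trait", "study_id")

_VALID_ALLELES = frozenset("ACGT")
_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])


class TraitType(str, enum.Enum):
    """Which omics layer an association belongs to."""

    MICROBE = "microbe"
    METABOLITE = "metabolite"


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix and uppercase; '23' is mapped to 'X'."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "23":
        c = "X"
    return c


def chrom_sort_key(chrom: str) -> tuple[int, int]:
    """Deterministic ordering key: autosomes numerically, then X."""
    c = normalize_chrom(chrom)
    if c == "X":
        return (1, 23)
    return (0, int(c))


@dataclass(frozen=True, slots=True)
class AssociationRecord:
    """One SNP-trait association row from either GWAS layer.

    Coordinates are 1-based on GRCh37. Invariants are enforced at
    construction time and raise :class:`RecordValidationError`.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    pvalue: float
    trait: str
    trait_type: TraitType
    study_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "effect_allele", str(self.effect_allele).strip().upper())
        object.__setattr__(self, "trait_type", TraitType(self.trait_type))
        if not str(self.rsid).strip():
            raise RecordValidationError("empty rsid")
        if self.chrom not in _VALID_CHROMS:
            raise RecordValidationError(f"invalid chromosome {self.chrom!r}")
        if not isinstance(self.pos, int) or self.pos < 1:
            raise RecordValidationError(f"position must be a positive integer, got {self.pos!r}")
        if self.effect_allele not in _VALID_ALLELES:
            raise RecordValidationError(f"effect allele must be one of A/C/G/T, got {self.effect_allele!r}")
        if not (0.0 < float(self.pvalue) <= 1.0):
            raise RecordValidationError(f"p-value must lie in (0, 1], got {self.pvalue!r}")
        if not str(self.trait).strip():
            raise RecordValidationError("empty trait name")


@dataclass(frozen=True, slots=True)
class ThresholdConfig:
    """Strict suggestive-significance p-value thresholds per trait layer."""

    alpha_microbe: float = 1e-6
    alpha_metabolite: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("alpha_microbe", "alpha_metabolite"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {a!r}")

    def alpha_for(self, trait_type: TraitType) -> float:
        return self.alpha_microbe if TraitType(trait_type) is TraitType.MICROBE else self.alpha_metabolite


def load_sumstats(path: str | Path, trait_type: TraitType | str) -> list[AssociationRecord]:
    """Read a summary-statistics TSV into validated :class:`AssociationRecord` rows.

    Row order of the file is preserved. Malformed rows abort the load with a
    :class:`RecordValidationError` naming the offending 1-based data row.
    """
    path = Path(path)
    trait_type = TraitType(trait_type)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas-specific parse failures
        raise SumstatsFormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[AssociationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            pos = int(str(row.pos).strip())
        except ValueError:
            raise RecordValidationError(f"unparsable position {row.pos!r}", row=i) from None
        try:
            pvalue = float(str(row.pvalue).strip())
        except ValueError:
            raise RecordValidationError(f"unparsable p-value {row.pvalue!r}", row=i) from None
        try:
            records.append(
                AssociationRecord(
                    rsid=str(row.rsid).strip(),
                    chrom=str(row.chrom),
                    pos=pos,
                    effect_allele=str(row.effect_allele),
                    pvalue=pvalue,
                    trait=str(row.trait).strip(),
                    trait_type=trait_type,
                    study_id=str(row.study_id).strip(),
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(str(exc), row=i) from None
    return records


def write_sumstats(records: Iterable[AssociationRecord], path: str | Path) -> None:
    """Serialize records back to the canonical TSV dialect."""
    rows = [
        {
            "rsid": r.rsid,
            "chrom": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "pvalue": repr(float(r.pvalue)),
            "trait": r.trait,
            "study_id": r.study_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, sep="\t", index=False)


def filter_significant(
    records: Sequence[AssociationRecord], cfg: ThresholdConfig | None = None
) -> list[AssociationRecord]:
    """Keep records with p-value strictly below the layer's threshold.

    Strict inequality: a p-value equal to the threshold is excluded.
    Order is preserved; the input is not modified.
    """
    cfg = cfg or ThresholdConfig()
    return [r for r in records if r.pvalue < cfg.alpha_for(r.trait_type)]


def dedupe_records(records: Sequence[AssociationRecord]) -> list[AssociationRecord]:
    """Collapse duplicate (rsid, trait) keys to the record with smallest p-value.

    Output order is deterministic: sorted by (chrom, pos, rsid, trait).
    Raises :class:`ConsistencyError` if one rsid maps to conflicting
    (chrom, pos) coordinates anywhere in the input.
    """
    seen_pos: dict[str, tuple[str, int]] = {}
    conflicted: list[str] = []
    for r in records:
        key = (r.chrom, r.pos)
        prev = seen_pos.setdefault(r.rsid, key)
        if prev != key and r.rsid not in conflicted:
            conflicted.append(r.rsid)
    if conflicted:
        raise ConsistencyError(
            "conflicting coordinates for rsid(s): " + ", ".join(sorted(conflicted))
        )

    best: dict[tuple[str, str], AssociationRecord] = {}
    for r in records:
        key = (r.rsid, r.trait)
        cur = best.get(key)
        if cur is None or r.pvalue < cur.pvalue:
            best[key] = r
    return sorted(best.values(), key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.rsid, r.trait))
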