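"""Exception hierarchy for trioscan."""


class TrioscanError(Exception):
    """Base class for all trioscan errors."""


class SumstatsFormatError(TrioscanError):
    """The summary-statistics file is structurally invalid (e.g. missing column)."""


class RecordValidationError(TrioscanError):
    """A single row failed validation; carries the 1-based row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class ConsistencyError(TrioscanError):
    """Mutually contradictory records (e.g. one rsid at two positions)."""


class PhasingError(TrioscanError):
    """Unphased genotype encountered while loading a panel in strict phased mode."""


class EmptyPanelError(TrioscanError):
    """No usable variants after filtering a reference panel."""


class MonomorphicVariantError(TrioscanError):
    """LD is undefined because one variant has zero allele variance in the panel."""


class PanelLookupError(TrioscanError):
    """A requested rsid is not present in the haplotype panel."""


class GenerationError(TrioscanError):
    """A synthetic-data target (e.g. realized r-squared regime) is unreachable."""


class PipelineStageError(TrioscanError):
    """A pipeline stage aborted; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
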