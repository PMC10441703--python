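"""Exception hierarchy and the not-available sentinel used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass


class MrAtlasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrAtlasError):
    """Invalid configuration: missing columns, bad thresholds, unreadable paths."""


class AlleleMismatchError(MrAtlasError):
    """Target allele matches neither orientation of a summary-statistic row."""

    def __init__(self, snp_id: str, alleles: tuple[str, str], target: str):
        self.snp_id = snp_id
        self.alleles = alleles
        self.target = target
        super().__init__(
            f"{snp_id}: target allele {target!r} matches neither orientation "
            f"of allele pair {alleles}"
        )


class EmptyInstrumentSetError(MrAtlasError):
    """No instruments survived selection/harmonization for a pair."""


class PanelLookupError(MrAtlasError):
    """SNP absent from the LD reference panel."""


class UndefinedRatioError(MrAtlasError):
    """Wald ratio requested with a zero SNP-exposure effect."""


class CollinearityError(MrAtlasError):
    """Degenerate regression design (e.g. all SNP-exposure effects equal)."""


class DegenerateSetError(MrAtlasError):
    """Every instrument was flagged as an outlier; no corrected estimate exists."""


@dataclass(frozen=True)
class Unavailable:
    """Marker for a result a method cannot produce on a given instrument set.

    Mirrors the reporting convention for methods that require a minimum
    number of instruments (e.g. the weighted median needs at least three):
    the pipeline records "NA" with a reason instead of raising.
    """

    method: str
    reason: str
    n_snp: int = 0

    def __bool__(self) -> bool:  # pragma: no cover - convenience only
        return False


def is_unavailable(obj) -> bool:
    return isinstance(obj, Unavailable)
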