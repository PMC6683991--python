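"""Core domain types shared across the package.

A *clonotype* is a group of receptor sequences treated as one T- or B-cell
clone.  Following common practice for bulk repertoire data, clonotypes are
keyed by the CDR3 amino-acid sequence (optionally together with the V gene
call).  Records enter the package from AIRR Rearrangement TSVs or
vdjtools-style clonotype tables and are validated into :class:`ClonotypeRecord`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AMINO_ACIDS",
    "CDR3_ALPHABET",
    "Tissue",
    "ClonotypeRecord",
    "SampleMeta",
    "RepertoireError",
    "FormatError",
    "InputError",
    "DegenerateInputError",
    "ConfigurationError",
]

#: The 20 proteinogenic amino-acid letters.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Letters allowed in a CDR3 amino-acid string.  ``*`` marks a stop codon and
#: ``_`` a frameshift; both are only meaningful for non-productive rearrangements.
CDR3_ALPHABET = frozenset(AMINO_ACIDS + "*_")


class RepertoireError(Exception):
    """Base class for errors raised by this package."""


class FormatError(RepertoireError):
    """A file does not conform to the expected tabular dialect."""


class InputError(RepertoireError):
    """Inconsistent or invalid in-memory inputs."""


class DegenerateInputError(RepertoireError):
    """An operation received an input it is mathematically undefined on."""


class ConfigurationError(RepertoireError):
    """Incompatible analysis settings (e.g. mixed clonotype key modes)."""


class Tissue(str, enum.Enum):
    """Anatomical source of a sorted sample."""

    blood = "blood"
    LN = "LN"
    tonsil = "tonsil"
    other = "other"


@dataclass(frozen=True)
class ClonotypeRecord:
    """One observed receptor sequence in one sample.

    Parameters
    ----------
    sample_id
        Opaque sample identifier; must match a metadata row when metadata
        are in play.
    cdr3_aa
        Upper-case CDR3 amino-acid sequence.  ``*`` / ``_`` (stop /
        frameshift markers) are rejected for records flagged productive.
    cdr3_nt
        Optional CDR3 nucleotide sequence.
    v_call, j_call
        Gene-segment calls; may be empty strings when the caller could not
        assign a segment.
    read_count
        Non-negative read (or UMI-consensus) support for this sequence.
    isotype
        Heavy-chain isotype for BCR data (``IGHG1`` .. ``IGHG4``, ``IGHM`` ...).
    productive
        Whether the rearrangement is in-frame and stop-free.
    complete_v
        Whether the V region is covered over FR1-FR4.
    v_mutations
        Somatic mutation count over FR1-FR3 (CDR3 excluded), from upstream
        germline alignment; this package never computes alignments.
    """

    sample_id: str
    cdr3_aa: str
    read_count: int
    v_call: str = ""
    j_call: str = ""
    cdr3_nt: Optional[str] = None
    isotype: Optional[str] = None
    productive: Optional[bool] = None
    complete_v: Optional[bool] = None
    v_mutations: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise InputError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - CDR3_ALPHABET
        if bad:
            raise InputError(
                f"cdr3_aa {self.cdr3_aa!r} contains invalid letters {sorted(bad)}"
            )
        if ("*" in self.cdr3_aa or "_" in self.cdr3_aa) and self.productive:
            raise InputError(
                f"stop/frameshift markers in {self.cdr3_aa!r} are incompatible "
                "with productive=True"
            )
        if self.read_count < 0:
            raise InputError(f"read_count must be >= 0, got {self.read_count}")
        if self.v_mutations is not None and self.v_mutations < 0:
            raise InputError("v_mutations must be >= 0")


@dataclass(frozen=True)
class SampleMeta:
    """Study-design annotation for one sequenced sample."""

    sample_id: str
    individual_id: str
    timepoint_days: int
    tissue: Tissue
    population: str
    group: str

    def __post_init__(self) -> None:
        if not isinstance(self.tissue, Tissue):
            object.__setattr__(self, "tissue", Tissue(self.tissue))


@dataclass
class WarningReport:
    """Accumulates non-fatal issues raised while reading a table.

    Readers never silently drop rows: every skipped row is enumerated here
    with its 1-based row number and a reason.
    """

    messages: list = field(default_factory=list)
    skipped_rows: list = field(default_factory=list)  # (row_number, reason)

    def warn(self, message: str) -> None:
        self.messages.append(message)

    def skip(self, row_number: int, reason: str) -> None:
        self.skipped_rows.append((row_number, reason))

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_rows)
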