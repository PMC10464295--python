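"""Core domain types shared across the pipeline.

Coordinate conventions, used everywhere without exception:

* residue numbers are 1-based, in full-protein coordinates (HGVS style);
  each alignment row carries the residue number of its first aligned
  residue as ``offset``;
* alignment columns are 1-based;
* reference positions are reported in the residue numbering of the
  reference structure (author numbering), never in UniProt coordinates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ConfigError, FormatError

#: canonical 20-residue alphabet
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: disease-class labels used throughout counting and statistics
CANCER = "cancer"
NONCANCER = "non-cancer"
BENIGN = "benign"
IGNORE = "ignore"


class MappingStatus(str, enum.Enum):
    """Outcome of projecting one variant onto the reference structure."""

    MAPPED = "mapped"
    REFERENCE_GAP = "excluded_reference_gap"
    OUT_OF_DOMAIN = "excluded_out_of_domain"
    REF_MISMATCH = "excluded_ref_mismatch"
    UNMATCHED_GENE = "unmatched_gene"


@dataclass(frozen=True, slots=True)
class Substitution:
    """A single amino-acid substitution, e.g. V600E."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AA_ALPHABET:
            raise ConfigError(f"ref_aa: {self.ref_aa!r} is not a standard residue")
        if self.alt_aa not in AA_ALPHABET:
            raise ConfigError(f"alt_aa: {self.alt_aa!r} is not a standard residue")
        if self.ref_aa == self.alt_aa:
            raise ConfigError("ref_aa equals alt_aa: not a substitution")
        if self.position < 1:
            raise ConfigError(f"position: must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One variant table row.

    ``protein_change`` is the raw input text (any accepted dialect);
    ``substitution`` is its normalized parse. ``conditions`` is the
    semicolon-split condition list from the source table.
    """

    gene: str
    protein_change: str
    substitution: Substitution
    clinical_significance: str
    conditions: tuple[str, ...] = ()
    allele_frequency: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.allele_frequency is not None and not (0.0 <= self.allele_frequency <= 1.0):
            raise ConfigError(
                f"allele_frequency: must be in [0, 1], got {self.allele_frequency}"
            )


@dataclass(frozen=True, slots=True)
class MsaRow:
    """One aligned sequence: a kinase domain of one gene."""

    gene: str
    protein_id: str
    offset: int
    sequence: str

    def __post_init__(self) -> None:
        if self.offset < 1:
            raise FormatError(f"offset for {self.gene} must be >= 1, got {self.offset}")
        bad = set(self.sequence) - set(AA_ALPHABET + GAP)
        if bad:
            raise FormatError(
                f"row {self.gene}|{self.protein_id}: unknown characters {sorted(bad)!r}"
            )

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count(GAP)


@dataclass(frozen=True)
class AlignedKinaseSet:
    """The structure-based MSA: equal-length gapped rows over a common
    column space, one of which is the reference."""

    rows: tuple[MsaRow, ...]
    reference_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        n = len(self.rows[0].sequence)
        for row in self.rows:
            if len(row.sequence) != n:
                raise FormatError(
                    f"ragged alignment: row {row.gene}|{row.protein_id} has length "
                    f"{len(row.sequence)}, expected {n}"
                )
        keys = [(r.gene, r.protein_id) for r in self.rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise FormatError(f"duplicate gene/protein_id pairs: {dupes}")
        if not (0 <= self.reference_index < len(self.rows)):
            raise FormatError(f"reference_index {self.reference_index} out of range")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0].sequence)

    @property
    def reference_row(self) -> MsaRow:
        return self.rows[self.reference_index]

    def rows_for_gene(self, gene: str) -> list[MsaRow]:
        return [r for r in self.rows if r.gene == gene]


@dataclass(frozen=True, slots=True)
class StructureResidue:
    residue_number: int
    residue_name: str  # 3-letter code
    x: float
    y: float
    z: float
    b_factor: float = 0.0


@dataclass(frozen=True)
class ReferenceStructure:
    """CA-only reference structure; residue order defines the mapping
    from reference-row ungapped index to author residue number."""

    residues: tuple[StructureResidue, ...]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError("structure has no residues")
        nums = [r.residue_number for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise FormatError("residue numbers must be strictly increasing")
        for r in self.residues:
            if r.b_factor > 999.99 or r.b_factor < -99.99:
                raise FormatError(
                    f"b_factor {r.b_factor} at residue {r.residue_number} does not fit "
                    "the fixed-width PDB field"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.residue_number for r in self.residues]


@dataclass(frozen=True, slots=True)
class MappedVariant:
    """A VariantRecord joined to an alignment column and a reference
    residue number, or an exclusion status explaining why not."""

    variant: VariantRecord
    status: MappingStatus
    alignment_column: int | None = None
    reference_residue_number: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        is_mapped = self.status is MappingStatus.MAPPED
        has_coords = self.alignment_column is not None and self.reference_residue_number is not None
        if is_mapped != has_coords:
            raise ConfigError("status 'mapped' iff both coordinates are present")


@dataclass(frozen=True, slots=True)
class ClassifiedVariant:
    """A mapped variant with its disease-class assignment.

    ``condition_classes`` keeps the per-condition classification so the
    gene/disease breakdown can be restricted to conditions of one class.
    """

    mapped: MappedVariant
    classes: frozenset[str]
    condition_classes: tuple[tuple[str, str], ...] = ()

    @property
    def position(self) -> int:
        assert self.mapped.reference_residue_number is not None
        return self.mapped.reference_residue_number

    @property
    def record_id(self) -> str:
        return self.mapped.variant.record_id

    @property
    def gene(self) -> str:
        return self.mapped.variant.gene


@dataclass(frozen=True, slots=True)
class ExclusionRecord:
    """One dropped/excluded input row, with a machine-readable reason."""

    record_id: str
    gene: str
    protein_change: str
    reason: str
    detail: str = ""
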