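"""Variant-to-structure coordinate mapping.

Projects per-protein residue numbers through the MSA onto the residue
numbering of the reference structure. Variants that land in columns where
the reference row is gapped are excluded (with an explicit status), as are
variants outside a row's aligned domain and, optionally, variants whose
stated reference amino acid disagrees with the alignment cell.
"""

from __future__ import annotations

import re

from Bio.Data.IUPACData import protein_letters_3to1

from .errors import ConsistencyError, MappingError, ProteinChangeError
from .model import (
    GAP,
    AA_ALPHABET,
    AlignedKinaseSet,
    ExclusionRecord,
    MappedVariant,
    MappingStatus,
    MsaRow,
    ReferenceStructure,
    Substitution,
    VariantRecord,
)

_SUB3 = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]{3})$")
_SUB1 = re.compile(r"^([A-Za-z])(\d+)([A-Za-z*])$")

# tokens that mark HGVS protein changes other than simple substitutions
_REJECT_TOKENS = (
    ("fs", "frameshift"),
    ("ext", "extension"),
    ("delins", "indel"),
    ("del", "indel"),
    ("ins", "indel"),
    ("dup", "indel"),
)


def parse_protein_change(text: str) -> Substitution:
    """Parse a protein-change string into a normalized :class:`Substitution`.

    Accepts three dialects, case-insensitively: ``p.Val600Glu``,
    ``p.V600E`` and ``V600E``. Anything that is not a single
    missense substitution (frameshift, nonsense, indel, duplication,
    extension, synonymous) raises :class:`ProteinChangeError` with a
    machine-readable reason code.
    """
    if text is None or not str(text).strip():
        raise ProteinChangeError(text, "unparsable")
    body = str(text).strip()
    if body.lower().startswith("p."):
        body = body[2:]
    body = body.strip("()")
    low = body.lower()
    for token, reason in _REJECT_TOKENS:
        if token in low:
            raise ProteinChangeError(text, reason)
    if body.endswith("="):
        raise ProteinChangeError(text, "synonymous")

    m = _SUB3.match(body)
    if m:
        ref3, pos, alt3 = m.group(1).title(), int(m.group(2)), m.group(3).title()
        if alt3 == "Ter":
            raise ProteinChangeError(text, "nonsense")
        try:
            ref1 = protein_letters_3to1[ref3]
            alt1 = protein_letters_3to1[alt3]
        except KeyError:
            raise ProteinChangeError(text, "unparsable") from None
    else:
        m = _SUB1.match(body)
        if not m:
            raise ProteinChangeError(text, "unparsable")
        ref1, pos, alt1 = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if alt1 in ("*", "X"):
            raise ProteinChangeError(text, "nonsense")
    if ref1 not in AA_ALPHABET or alt1 not in AA_ALPHABET:
        raise ProteinChangeError(text, "unparsable")
    if ref1 == alt1:
        raise ProteinChangeError(text, "synonymous")
    return Substitution(ref1, pos, alt1)


def residue_to_column(row: MsaRow, residue_number: int) -> int | None:
    """1-based alignment column holding ``residue_number`` of ``row``.

    The k-th non-gap character of a row is residue number
    ``offset + k - 1``. Returns ``None`` when the residue number falls
    before the row's offset or past its last aligned residue.
    """
    k = residue_number - row.offset + 1
    if k < 1:
        return None
    seen = 0
    for col, ch in enumerate(row.sequence, start=1):
        if ch != GAP:
            seen += 1
            if seen == k:
                return col
    return None


def check_reference_consistency(msa: AlignedKinaseSet, structure: ReferenceStructure) -> None:
    """Raise unless the ungapped reference row and the structure agree in length."""
    n_ref = msa.reference_row.ungapped_length
    if n_ref != len(structure):
        raise ConsistencyError(
            f"ungapped reference row has {n_ref} residues but the structure has "
            f"{len(structure)}"
        )


def column_to_reference_residue(
    msa: AlignedKinaseSet, structure: ReferenceStructure, column: int
) -> int | None:
    """Author residue number of the reference structure at an alignment
    column, or ``None`` when the reference row is gapped there."""
    if not (1 <= column <= msa.n_columns):
        raise MappingError(f"column {column} outside [1, {msa.n_columns}]")
    check_reference_consistency(msa, structure)
    ref_seq = msa.reference_row.sequence
    if ref_seq[column - 1] == GAP:
        return None
    k = column - ref_seq[:column].count(GAP)  # ordinal among non-gap chars
    return structure.residues[k - 1].residue_number


def map_variants(
    variants: list[VariantRecord],
    msa: AlignedKinaseSet,
    structure: ReferenceStructure,
    verify_ref_aa: bool = True,
) -> tuple[list[MappedVariant], list[ExclusionRecord]]:
    """Project every variant onto the reference structure.

    Returns one :class:`MappedVariant` per input (conservation:
    ``len(output) == len(input)``) plus an exclusion log carrying every
    non-mapped record. Genes with several alignment rows (multi-domain
    kinases) are resolved by keeping the single row for which the residue
    is in-domain; in-domain in two or more rows is an error.
    """
    check_reference_consistency(msa, structure)
    by_gene: dict[str, list[MsaRow]] = {}
    for row in msa.rows:
        by_gene.setdefault(row.gene, []).append(row)

    # reference-row cumulative non-gap counts, reused across variants
    ref_seq = msa.reference_row.sequence
    results: list[MappedVariant] = []
    exclusions: list[ExclusionRecord] = []

    def exclude(v: VariantRecord, status: MappingStatus, detail: str = "") -> None:
        results.append(MappedVariant(v, status, detail=detail))
        exclusions.append(
            ExclusionRecord(v.record_id, v.gene, v.protein_change, status.value, detail)
        )

    for v in variants:
        rows = by_gene.get(v.gene)
        if not rows:
            exclude(v, MappingStatus.UNMATCHED_GENE, "gene not present in the alignment")
            continue
        hits = []
        for row in rows:
            col = residue_to_column(row, v.substitution.position)
            if col is not None:
                hits.append((row, col))
        if not hits:
            exclude(v, MappingStatus.OUT_OF_DOMAIN, "residue outside the aligned domain")
            continue
        if len(hits) > 1:
            raise MappingError(
                f"gene {v.gene}: residue {v.substitution.position} is in-domain in "
                f"{len(hits)} alignment rows; cannot resolve"
            )
        row, col = hits[0]
        cell = row.sequence[col - 1]
        if verify_ref_aa and cell != v.substitution.ref_aa:
            exclude(
                v,
                MappingStatus.REF_MISMATCH,
                f"alignment has {cell} at column {col}, variant states "
                f"{v.substitution.ref_aa}",
            )
            continue
        if ref_seq[col - 1] == GAP:
            exclude(v, MappingStatus.REFERENCE_GAP, f"reference gapped at column {col}")
            continue
        k = col - ref_seq[:col].count(GAP)
        results.append(
            MappedVariant(
                v,
                MappingStatus.MAPPED,
                alignment_column=col,
                reference_residue_number=structure.residues[k - 1].residue_number,
            )
        )
    return results, exclusions
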