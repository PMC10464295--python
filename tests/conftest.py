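"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from kinspot.model import (
    GAP,
    AA_ALPHABET,
    AlignedKinaseSet,
    MsaRow,
    ReferenceStructure,
    StructureResidue,
    Substitution,
    VariantRecord,
)
from kinspot.synthetic import generate_reference_structure


def make_msa(seqs, offsets=None, genes=None, reference_index=0) -> AlignedKinaseSet:
    """Build a small alignment from gapped strings."""
    offsets = offsets or [1] * len(seqs)
    genes = genes or [f"G{i}" for i in range(len(seqs))]
    rows = tuple(
        MsaRow(gene=g, protein_id=f"P{i}", offset=o, sequence=s.upper())
        for i, (g, o, s) in enumerate(zip(genes, offsets, seqs))
    )
    return AlignedKinaseSet(rows, reference_index=reference_index)


def make_variant(
    gene="G1",
    change="V600E",
    significance="Pathogenic",
    conditions=("Melanoma",),
    allele_frequency=None,
    record_id="r1",
) -> VariantRecord:
    from kinspot.mapping import parse_protein_change

    return VariantRecord(
        gene=gene,
        protein_change=change,
        substitution=parse_protein_change(change),
        clinical_significance=significance,
        conditions=tuple(conditions),
        allele_frequency=allele_frequency,
        record_id=record_id,
    )


def random_msa(rng, max_rows=20, max_cols=50) -> AlignedKinaseSet:
    """Random gapped alignment; reference row 0 is never fully gapped."""
    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols = int(rng.integers(10, max_cols + 1))
    alphabet = np.array(list(AA_ALPHABET))
    seqs = []
    for i in range(n_rows):
        chars = alphabet[rng.integers(0, 20, size=n_cols)].copy()
        gap_mask = rng.random(n_cols) < 0.3
        if i == 0 and gap_mask.all():
            gap_mask[int(rng.integers(0, n_cols))] = False
        chars[gap_mask] = GAP
        seqs.append("".join(chars))
    offsets = [int(o) for o in rng.integers(1, 500, size=n_rows)]
    # rows that are all gaps are legal alignment rows; keep them
    return make_msa(seqs, offsets=offsets)


def brute_force_row_map(row: MsaRow) -> dict[int, int]:
    """Independent oracle: residue number -> 1-based column, by scanning."""
    mapping = {}
    k = 0
    for col, ch in enumerate(row.sequence, start=1):
        if ch != GAP:
            mapping[row.offset + k] = col
            k += 1
    return mapping


def brute_force_reference_map(msa: AlignedKinaseSet, structure: ReferenceStructure) -> dict[int, int]:
    """Independent oracle: column -> structure residue number (non-gap only)."""
    out = {}
    k = 0
    for col, ch in enumerate(msa.reference_row.sequence, start=1):
        if ch != GAP:
            out[col] = structure.residues[k].residue_number
            k += 1
    return out


def textbook_chi2(table) -> float:
    """Independent oracle: Pearson chi-square as sum((O-E)^2 / E) from
    row/column margins, no correction."""
    table = [list(map(float, row)) for row in table]
    row_sums = [sum(r) for r in table]
    col_sums = [sum(c) for c in zip(*table)]
    total = sum(row_sums)
    chi2 = 0.0
    for i, r in enumerate(row_sums):
        for j, c in enumerate(col_sums):
            expected = r * c / total
            if expected > 0:
                chi2 += (table[i][j] - expected) ** 2 / expected
    return chi2


def brute_force_hotspots(position_counts: dict[int, int], quantile: float) -> list[int]:
    """Independent oracle: rank-and-tie top-quantile selection by full sort."""
    items = sorted(
        ((p, c) for p, c in position_counts.items() if c > 0),
        key=lambda pc: (-pc[1], pc[0]),
    )
    if not items:
        return []
    k = math.ceil(quantile * len(items))
    cutoff = items[k - 1][1]
    return [p for p, c in items if c >= cutoff]


@pytest.fixture
def tiny_msa() -> AlignedKinaseSet:
    # reference: 8 residues, gapped at columns 3 and 7 of 10
    return make_msa(
        [
            "AC-DEFG-HI",
            "ACWDE-GQHI",
            "-CYDEFGRH-",
        ],
        offsets=[100, 1, 30],
        genes=["REF", "BRAF", "EGFR"],
    )


@pytest.fixture
def tiny_structure(tiny_msa) -> ReferenceStructure:
    return generate_reference_structure(tiny_msa)
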