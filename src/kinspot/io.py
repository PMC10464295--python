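"""Readers and writers for every external format the pipeline touches.

Formats: aligned FASTA (headers ``>GENE|PROTEIN_ID|offset=N``), variant
and benign TSV tables, CA-only PDB v3.3 structures, annotated PDBs with
per-residue counts in the B-factor column, exclusion-log TSVs and
breakdown JSON.
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser

from .errors import FormatError, ProteinChangeError
from .mapping import parse_protein_change
from .model import (
    AlignedKinaseSet,
    ExclusionRecord,
    MsaRow,
    ReferenceStructure,
    StructureResidue,
    VariantRecord,
)

VARIANT_COLUMNS = ("gene", "protein_change", "clinical_significance", "conditions")
OPTIONAL_COLUMNS = ("allele_frequency", "record_id")


# ---------------------------------------------------------------------------
# aligned FASTA


def _parse_header(header: str) -> tuple[str, str, int]:
    parts = header.split("|")
    gene = parts[0]
    protein_id = parts[1] if len(parts) > 1 and parts[1] else gene
    offset = 1
    for part in parts[2:]:
        if part.startswith("offset="):
            try:
                offset = int(part[len("offset="):])
            except ValueError:
                raise FormatError(f"bad offset in header {header!r}") from None
    return gene, protein_id, offset


def read_msa(path, reference_id: str | None = None) -> AlignedKinaseSet:
    """Read an aligned multi-FASTA into an :class:`AlignedKinaseSet`.

    The reference row is the one whose gene, protein id or ``GENE|ID``
    matches ``reference_id``; by default the first row. Lowercase
    residues are accepted and upcased; a ragged alignment or unknown
    characters raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    rows = []
    for rec in records:
        gene, protein_id, offset = _parse_header(rec.id)
        rows.append(MsaRow(gene, protein_id, offset, str(rec.seq).upper()))
    reference_index = 0
    if reference_id is not None:
        matches = [
            i
            for i, r in enumerate(rows)
            if reference_id in (r.gene, r.protein_id, f"{r.gene}|{r.protein_id}")
        ]
        if len(matches) != 1:
            raise FormatError(
                f"reference id {reference_id!r} matches {len(matches)} rows"
            )
        reference_index = matches[0]
    return AlignedKinaseSet(tuple(rows), reference_index)


def write_msa(msa: AlignedKinaseSet, path) -> None:
    with open(path, "w") as fh:
        for row in msa.rows:
            fh.write(f">{row.gene}|{row.protein_id}|offset={row.offset}\n")
            fh.write(row.sequence + "\n")


# ---------------------------------------------------------------------------
# variant tables


def read_variant_table(path) -> tuple[list[VariantRecord], list[ExclusionRecord]]:
    """Read a variant TSV into records, dropping-and-logging rows whose
    protein change is not a single amino-acid substitution.

    Required columns: gene, protein_change, clinical_significance,
    conditions (semicolon-separated). Optional: allele_frequency,
    record_id (synthesized from the row ordinal when absent).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table {path}: missing required columns {missing}")
    records: list[VariantRecord] = []
    exclusions: list[ExclusionRecord] = []
    for ordinal, row in enumerate(df.itertuples(index=False), start=1):
        record_id = getattr(row, "record_id", "") or f"row{ordinal:06d}"
        gene = row.gene.strip()
        change = row.protein_change.strip()
        af_text = getattr(row, "allele_frequency", "")
        allele_frequency = None
        if af_text not in ("", None) and not (
            isinstance(af_text, float) and math.isnan(af_text)
        ):
            try:
                allele_frequency = float(af_text)
            except ValueError:
                raise FormatError(
                    f"variant table {path}: bad allele_frequency {af_text!r} "
                    f"in record {record_id}"
                ) from None
        conditions = tuple(
            c.strip() for c in row.conditions.split(";") if c.strip()
        )
        try:
            substitution = parse_protein_change(change)
        except ProteinChangeError as err:
            exclusions.append(
                ExclusionRecord(
                    record_id, gene, change,
                    "not_single_aa_substitution", err.reason,
                )
            )
            continue
        records.append(
            VariantRecord(
                gene=gene,
                protein_change=change,
                substitution=substitution,
                clinical_significance=row.clinical_significance.strip(),
                conditions=conditions,
                allele_frequency=allele_frequency,
                record_id=record_id,
            )
        )
    ids = [r.record_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"variant table {path}: duplicate record_id values")
    return records, exclusions


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    rows = [
        {
            "gene": r.gene,
            "protein_change": r.protein_change,
            "clinical_significance": r.clinical_significance,
            "conditions": ";".join(r.conditions),
            "allele_frequency": "" if r.allele_frequency is None else repr(r.allele_frequency),
            "record_id": r.record_id,
        }
        for r in records
    ]
    cols = list(VARIANT_COLUMNS) + list(OPTIONAL_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_exclusion_log(exclusions: Iterable[ExclusionRecord], path) -> None:
    rows = [
        {
            "record_id": e.record_id,
            "gene": e.gene,
            "protein_change": e.protein_change,
            "reason": e.reason,
            "detail": e.detail,
        }
        for e in exclusions
    ]
    pd.DataFrame(
        rows, columns=["record_id", "gene", "protein_change", "reason", "detail"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PDB structures

_PDB_DIALECT = "single model, CA only, no altlocs, no insertion codes"


def read_structure(path, chain_id: str = "A") -> ReferenceStructure:
    """Read a CA-only reference structure from PDB text.

    First model, configured chain only. Insertion codes, altlocs and
    duplicate residue numbers violate the declared dialect and raise
    :class:`FormatError`.
    """
    # pre-scan: Bio.PDB silently merges duplicate residues, so duplicate
    # CA records must be caught on the raw text
    seen_ca: set[tuple[str, str]] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("ATOM") and line[12:16].strip() == "CA":
                key = (line[21], line[22:27].strip())
                if key in seen_ca:
                    raise FormatError(
                        f"{path}: duplicate residue number {key[1]} in chain {key[0]}"
                    )
                seen_ca.add(key)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    models = list(structure.get_models())
    if not models:
        raise FormatError(f"{path}: no models")
    model = models[0]
    chains = {c.id: c for c in model.get_chains()}
    if chain_id not in chains:
        raise FormatError(
            f"{path}: chain {chain_id!r} not present (has {sorted(chains)})"
        )
    residues = []
    seen_numbers = set()
    for res in chains[chain_id].get_residues():
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue
        if icode.strip():
            raise FormatError(
                f"{path}: insertion code {icode!r} at residue {resseq} "
                f"(dialect: {_PDB_DIALECT})"
            )
        if "CA" not in res:
            continue
        ca = res["CA"]
        if ca.is_disordered() or (ca.get_altloc() or " ").strip():
            raise FormatError(
                f"{path}: altloc on CA of residue {resseq} (dialect: {_PDB_DIALECT})"
            )
        if resseq in seen_numbers:
            raise FormatError(f"{path}: duplicate residue number {resseq}")
        seen_numbers.add(resseq)
        x, y, z = ca.coord
        residues.append(
            StructureResidue(
                residue_number=int(resseq),
                residue_name=res.get_resname().strip(),
                x=float(x),
                y=float(y),
                z=float(z),
                b_factor=float(ca.get_bfactor()),
            )
        )
    if not residues:
        raise FormatError(f"{path}: no CA atoms in chain {chain_id}")
    return ReferenceStructure(tuple(residues), chain_id=chain_id)


def _atom_line(serial: int, res: StructureResidue, chain_id: str, b: float) -> str:
    # PDB v3.3 fixed columns: serial 7-11, name 13-16, resName 18-20,
    # chain 22, resSeq 23-26, x/y/z 31-54, occupancy 55-60, B 61-66,
    # element 77-78.
    return (
        f"ATOM  {serial:>5}  CA  {res.residue_name:>3} {chain_id}"
        f"{res.residue_number:>4}    "
        f"{res.x:8.3f}{res.y:8.3f}{res.z:8.3f}{1.00:6.2f}{b:6.2f}"
        f"          {'C':>2}\n"
    )


def write_structure(structure: ReferenceStructure, path, b_factors: dict[int, float] | None = None) -> None:
    """Write the structure as fixed-column CA-only ATOM records.

    ``b_factors`` overrides the stored per-residue B-factors (missing
    residues fall back to the stored value).
    """
    b_factors = b_factors or {}
    with open(path, "w") as fh:
        for serial, res in enumerate(structure.residues, start=1):
            b = b_factors.get(res.residue_number, res.b_factor)
            if b > 999.99 or b < -99.99:
                raise FormatError(
                    f"B-factor {b} at residue {res.residue_number} overflows the field"
                )
            fh.write(_atom_line(serial, res, structure.chain_id, b))
        fh.write("TER\nEND\n")


def write_annotated_pdb(
    structure: ReferenceStructure, per_residue_counts: dict[int, int], path
) -> None:
    """Encode per-residue mutation counts in the B-factor column.

    Residues without a count get 0.00. Counts above 999 overflow the
    fixed-width field and are a hard error (never clipped); so are counts
    at residue numbers absent from the structure.
    """
    known = set(structure.residue_numbers)
    b_factors: dict[int, float] = {n: 0.0 for n in known}
    for residue_number, count in per_residue_counts.items():
        if residue_number not in known:
            raise FormatError(
                f"count given for residue {residue_number}, not in the structure"
            )
        if not (0 <= int(count) <= 999):
            raise FormatError(
                f"count {count} at residue {residue_number} outside the writable "
                "range [0, 999]"
            )
        b_factors[residue_number] = float(int(count))
    write_structure(structure, path, b_factors=b_factors)


def read_annotated_counts(path, chain_id: str = "A") -> dict[int, int]:
    """Recover integer per-residue counts from an annotated PDB."""
    structure = read_structure(path, chain_id=chain_id)
    return {r.residue_number: int(round(r.b_factor)) for r in structure.residues}


# ---------------------------------------------------------------------------
# JSON trees


def write_json(obj, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
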