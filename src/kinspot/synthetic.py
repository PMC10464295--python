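"""Synthetic input generator with planted ground truth.

Emulates the four pipeline inputs — a structure-based kinase-domain MSA,
a CA-only reference structure, a ClinVar-style pathogenic variant table
and a gnomAD-style benign table — with a known generative model so every
downstream stage can be checked against planted truth:

* the MSA is random over the 20-residue alphabet: row 0 is the reference
  (never gapped at its own columns); a few extra "insert" columns, where
  the reference is gapped, exercise reference-gap exclusion; every other
  row is gapped independently at each reference column with probability
  ``gap_fraction`` and carries a random residue-number offset;
* background mutations arise per row as a Poisson process with mean
  ``background_rate`` per ungapped residue per disease class, placed
  uniformly over the row's residues (the uniform background is a modeling
  choice, not an inference about real kinases);
* each planted hotspot adds Poisson(``mean_mutations``) mutations of its
  class at one reference position, spread uniformly over the rows that
  are ungapped in that column;
* benign records get population allele frequencies straddling the 1%
  filter threshold.

A truth sidecar table records each variant's true reference position and
class; it is written next to the inputs but never read by any analysis
stage.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .errors import ConfigError
from .model import (
    AA_ALPHABET,
    BENIGN,
    CANCER,
    GAP,
    NONCANCER,
    AlignedKinaseSet,
    MsaRow,
    ReferenceStructure,
    StructureResidue,
    Substitution,
    VariantRecord,
)
from . import io as kio

DEFAULT_CANCER_POOL = (
    "Melanoma",
    "Lung adenocarcinoma",
    "Acute myeloid leukemia",
    "Neoplasm of the large intestine",
    "Gastrointestinal stromal tumor",
    "Squamous cell carcinoma of the head and neck",
    "Hereditary cancer-predisposing syndrome",
    "Multiple myeloma",
)
DEFAULT_NONCANCER_POOL = (
    "Noonan syndrome",
    "Cardiofaciocutaneous syndrome",
    "Developmental and epileptic encephalopathy",
    "Okur-Chung neurodevelopmental syndrome",
    "Pulmonary hypertension",
    "X-linked agammaglobulinemia",
    "Leber congenital amaurosis",
    "Intellectual developmental disorder",
)

_PATHOGENIC_LABELS = ("Pathogenic", "Likely pathogenic")


@dataclass(frozen=True)
class PlantedHotspot:
    """One planted signal: ``position`` is a 1-based index into the
    ungapped reference sequence; ``mean_mutations`` is the Poisson mean
    of the total mutation count planted there."""

    position: int
    disease_class: str
    mean_mutations: float


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 100
    ref_length: int = 250
    gap_fraction: float = 0.15
    planted_hotspots: tuple[PlantedHotspot, ...] = ()
    #: mean background mutations per protein per ungapped residue per class
    background_rate: float = 0.02
    cancer_condition_pool: tuple[str, ...] = DEFAULT_CANCER_POOL
    noncancer_condition_pool: tuple[str, ...] = DEFAULT_NONCANCER_POOL
    seed: int = 0
    n_benign: int = 30
    #: columns where the reference is gapped; default ref_length // 25
    n_reference_gap_columns: int | None = None
    insert_occupancy: float = 0.5
    #: fraction of pathogenic records that also draw a condition from the
    #: other pool (one mutation can be related to several diseases)
    mixed_condition_fraction: float = 0.05
    #: force one benign allele frequency to sit exactly on the 1% threshold
    benign_af_at_threshold: bool = True

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins: must be >= 1, got {self.n_proteins}")
        if self.ref_length < 1:
            raise ConfigError(f"ref_length: must be >= 1, got {self.ref_length}")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ConfigError(f"gap_fraction: must be in [0, 1), got {self.gap_fraction}")
        if self.background_rate < 0:
            raise ConfigError(f"background_rate: must be >= 0, got {self.background_rate}")
        if self.n_benign < 0:
            raise ConfigError(f"n_benign: must be >= 0, got {self.n_benign}")
        if not self.cancer_condition_pool:
            raise ConfigError("cancer_condition_pool: must be non-empty")
        if not self.noncancer_condition_pool:
            raise ConfigError("noncancer_condition_pool: must be non-empty")
        if not (0.0 <= self.insert_occupancy <= 1.0):
            raise ConfigError(
                f"insert_occupancy: must be in [0, 1], got {self.insert_occupancy}"
            )
        if not (0.0 <= self.mixed_condition_fraction <= 1.0):
            raise ConfigError(
                "mixed_condition_fraction: must be in [0, 1], got "
                f"{self.mixed_condition_fraction}"
            )
        if self.n_reference_gap_columns is not None and self.n_reference_gap_columns < 0:
            raise ConfigError(
                "n_reference_gap_columns: must be >= 0, got "
                f"{self.n_reference_gap_columns}"
            )
        for h in self.planted_hotspots:
            if not (1 <= h.position <= self.ref_length):
                raise ConfigError(
                    f"planted_hotspots: position {h.position} outside "
                    f"[1, {self.ref_length}]"
                )
            if h.disease_class not in (CANCER, NONCANCER, BENIGN):
                raise ConfigError(
                    f"planted_hotspots: unknown class {h.disease_class!r}"
                )
            if h.mean_mutations <= 0:
                raise ConfigError(
                    f"planted_hotspots: mean_mutations must be > 0, got "
                    f"{h.mean_mutations}"
                )

    @property
    def resolved_reference_gap_columns(self) -> int:
        if self.n_reference_gap_columns is not None:
            return self.n_reference_gap_columns
        return self.ref_length // 25


# ---------------------------------------------------------------------------
# MSA and structure


def generate_msa(config: SimulationConfig) -> AlignedKinaseSet:
    """Deterministic random MSA; row 0 is the reference, ungapped over its
    own ``ref_length`` columns, with extra reference-gap columns inserted."""
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AA_ALPHABET))
    n_insert = config.resolved_reference_gap_columns
    total_cols = config.ref_length + n_insert
    insert_cols = set()
    if n_insert:
        insert_cols = set(rng.choice(total_cols, size=n_insert, replace=False).tolist())
    is_ref_col = np.array([c not in insert_cols for c in range(total_cols)])

    offsets = rng.integers(1, 501, size=config.n_proteins)
    letters = rng.integers(0, len(alphabet), size=(config.n_proteins, total_cols))
    gap_draw = rng.random(size=(config.n_proteins, total_cols))

    rows = []
    for i in range(config.n_proteins):
        chars = alphabet[letters[i]].copy()
        if i == 0:
            chars[~is_ref_col] = GAP  # reference: residues only at its own columns
        else:
            gap_at_insert = (~is_ref_col) & (gap_draw[i] >= config.insert_occupancy)
            gap_at_core = is_ref_col & (gap_draw[i] < config.gap_fraction)
            chars[gap_at_insert | gap_at_core] = GAP
        rows.append(
            MsaRow(
                gene=f"KIN{i:03d}",
                protein_id=f"SYNP{i:04d}",
                offset=int(offsets[i]),
                sequence="".join(chars),
            )
        )
    return AlignedKinaseSet(tuple(rows), reference_index=0)


def generate_reference_structure(msa: AlignedKinaseSet) -> ReferenceStructure:
    """Ideal-helix CA trace for the ungapped reference row: one residue
    per reference residue, numbered offset..offset+L-1, B-factors 0.00."""
    ref = msa.reference_row
    seq = ref.sequence.replace(GAP, "")
    if not seq:
        raise ConfigError("reference row has no residues")
    residues = []
    for i, aa in enumerate(seq):
        theta = math.radians(100.0 * i)  # ~3.6 residues/turn
        residues.append(
            StructureResidue(
                residue_number=ref.offset + i,
                residue_name=seq3(aa).upper(),
                x=2.3 * math.cos(theta),
                y=2.3 * math.sin(theta),
                z=1.5 * i,
                b_factor=0.0,
            )
        )
    return ReferenceStructure(tuple(residues), chain_id="A")


# ---------------------------------------------------------------------------
# variants


def _row_geometry(msa: AlignedKinaseSet):
    """Per row: array of ungapped column indices (0-based) and chars."""
    cols, chars = [], []
    for row in msa.rows:
        arr = np.frombuffer(row.sequence.encode(), dtype=np.uint8)
        idx = np.nonzero(arr != ord(GAP))[0]
        cols.append(idx)
        chars.append([row.sequence[c] for c in idx])
    return cols, chars


def _reference_position_of_column(msa: AlignedKinaseSet, col0: int) -> int | None:
    """Structure residue number at 0-based column, None if reference gapped."""
    ref = msa.reference_row
    if ref.sequence[col0] == GAP:
        return None
    k = col0 + 1 - ref.sequence[: col0 + 1].count(GAP)
    return ref.offset + k - 1


def _dialect(rng, sub: Substitution) -> str:
    style = rng.integers(0, 3)
    if style == 0:
        return f"p.{seq3(sub.ref_aa)}{sub.position}{seq3(sub.alt_aa)}"
    if style == 1:
        return f"p.{sub.ref_aa}{sub.position}{sub.alt_aa}"
    return str(sub)


def _make_variant(
    rng,
    msa: AlignedKinaseSet,
    row_index: int,
    ungapped_index: int,
    disease_class: str,
    config: SimulationConfig,
    record_id: str,
    origin: str,
    row_cols,
    row_chars,
) -> tuple[VariantRecord, dict]:
    row = msa.rows[row_index]
    col0 = int(row_cols[row_index][ungapped_index])
    ref_aa = row_chars[row_index][ungapped_index]
    residue_number = row.offset + ungapped_index
    alt_candidates = [a for a in AA_ALPHABET if a != ref_aa]
    alt_aa = alt_candidates[int(rng.integers(0, len(alt_candidates)))]
    sub = Substitution(ref_aa, residue_number, alt_aa)

    classes = {disease_class}
    pools = {CANCER: config.cancer_condition_pool, NONCANCER: config.noncancer_condition_pool}
    pool = pools[disease_class]
    n_cond = 1 + int(rng.random() < 0.3)
    picks = rng.choice(len(pool), size=min(n_cond, len(pool)), replace=False)
    conditions = [pool[int(p)] for p in picks]
    if rng.random() < config.mixed_condition_fraction:
        other = NONCANCER if disease_class == CANCER else CANCER
        other_pool = pools[other]
        conditions.append(other_pool[int(rng.integers(0, len(other_pool)))])
        classes.add(other)

    record = VariantRecord(
        gene=row.gene,
        protein_change=_dialect(rng, sub),
        substitution=sub,
        clinical_significance=_PATHOGENIC_LABELS[int(rng.integers(0, 2))],
        conditions=tuple(conditions),
        record_id=record_id,
    )
    ref_pos = _reference_position_of_column(msa, col0)
    truth = {
        "record_id": record_id,
        "gene": row.gene,
        "protein_change": record.protein_change,
        "residue_number": residue_number,
        "reference_position": "" if ref_pos is None else ref_pos,
        "classes": ";".join(sorted(classes)),
        "origin": origin,
    }
    return record, truth


def generate_variants(
    msa: AlignedKinaseSet, config: SimulationConfig
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Pathogenic variant table plus its ground-truth sidecar.

    Background mutations: per row and class, Poisson(background_rate x
    ungapped length), uniform over the row's residues. Planted cancer /
    non-cancer hotspots: Poisson(mean) mutations at the planted reference
    position, uniform over rows ungapped there.
    """
    rng = np.random.default_rng([config.seed, 1])
    row_cols, row_chars = _row_geometry(msa)
    records: list[VariantRecord] = []
    truths: list[dict] = []
    serial = 0

    def emit(row_index, ungapped_index, disease_class, origin):
        nonlocal serial
        serial += 1
        rec, truth = _make_variant(
            rng, msa, row_index, ungapped_index, disease_class, config,
            f"VAR{serial:06d}", origin, row_cols, row_chars,
        )
        records.append(rec)
        truths.append(truth)

    for row_index in range(len(msa.rows)):
        n_res = len(row_cols[row_index])
        if n_res == 0:
            continue
        for disease_class in (CANCER, NONCANCER):
            n_bg = rng.poisson(config.background_rate * n_res)
            for _ in range(int(n_bg)):
                emit(row_index, int(rng.integers(0, n_res)), disease_class, "background")

    ref_cols = row_cols[msa.reference_index]
    for hotspot in config.planted_hotspots:
        if hotspot.disease_class == BENIGN:
            continue  # benign planting lives in generate_benign_variants
        col0 = int(ref_cols[hotspot.position - 1])
        eligible = [
            ri for ri in range(len(msa.rows))
            if msa.rows[ri].sequence[col0] != GAP
        ]
        non_reference = [ri for ri in eligible if ri != msa.reference_index]
        if not non_reference and len(msa.rows) > 1:
            warnings.warn(
                f"planted position {hotspot.position} is gapped in every "
                "non-reference row; planting on the reference row only",
                stacklevel=2,
            )
        total = int(rng.poisson(hotspot.mean_mutations))
        for _ in range(total):
            ri = eligible[int(rng.integers(0, len(eligible)))]
            ungapped_index = int(np.searchsorted(row_cols[ri], col0))
            emit(ri, ungapped_index, hotspot.disease_class, "hotspot")

    truth = pd.DataFrame(
        truths,
        columns=[
            "record_id", "gene", "protein_change", "residue_number",
            "reference_position", "classes", "origin",
        ],
    )
    return records, truth


def generate_benign_variants(
    msa: AlignedKinaseSet, config: SimulationConfig
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Benign (gnomAD-style) records with allele frequencies in (0, 0.5].

    When at least two records are generated, one frequency is forced
    below 1% and one to at least 1% (exactly 0.01 when
    ``benign_af_at_threshold`` is set) so the downstream filter boundary
    is always exercised. Planted benign hotspots draw frequencies at or
    above the threshold.
    """
    rng = np.random.default_rng([config.seed, 2])
    row_cols, row_chars = _row_geometry(msa)
    n_rows = len(msa.rows)
    records: list[VariantRecord] = []
    truths: list[dict] = []
    serial = 0

    def emit(row_index, ungapped_index, allele_frequency, origin):
        nonlocal serial
        serial += 1
        record_id = f"BEN{serial:04d}"
        row = msa.rows[row_index]
        col0 = int(row_cols[row_index][ungapped_index])
        ref_aa = row_chars[row_index][ungapped_index]
        residue_number = row.offset + ungapped_index
        alt_candidates = [a for a in AA_ALPHABET if a != ref_aa]
        alt_aa = alt_candidates[int(rng.integers(0, len(alt_candidates)))]
        sub = Substitution(ref_aa, residue_number, alt_aa)
        records.append(
            VariantRecord(
                gene=row.gene,
                protein_change=_dialect(rng, sub),
                substitution=sub,
                clinical_significance="Benign",
                conditions=("not provided",),
                allele_frequency=float(allele_frequency),
                record_id=record_id,
            )
        )
        ref_pos = _reference_position_of_column(msa, col0)
        truths.append(
            {
                "record_id": record_id,
                "gene": row.gene,
                "protein_change": records[-1].protein_change,
                "residue_number": residue_number,
                "reference_position": "" if ref_pos is None else ref_pos,
                "classes": BENIGN,
                "origin": origin,
            }
        )

    def random_af() -> float:
        return float(np.exp(rng.uniform(np.log(1e-4), np.log(0.5))))

    for i in range(config.n_benign):
        ri = int(rng.integers(0, n_rows))
        if len(row_cols[ri]) == 0:
            continue
        if i == 0 and config.n_benign >= 2:
            af = float(10 ** rng.uniform(-4, -2.1))  # strictly below 1%
        elif i == 1 and config.n_benign >= 2:
            af = 0.01 if config.benign_af_at_threshold else float(10 ** rng.uniform(-1.9, -0.4))
        else:
            af = random_af()
        emit(ri, int(rng.integers(0, len(row_cols[ri]))), af, "background")

    ref_cols = row_cols[msa.reference_index]
    for hotspot in config.planted_hotspots:
        if hotspot.disease_class != BENIGN:
            continue
        col0 = int(ref_cols[hotspot.position - 1])
        eligible = [
            ri for ri in range(n_rows) if msa.rows[ri].sequence[col0] != GAP
        ]
        total = int(rng.poisson(hotspot.mean_mutations))
        for _ in range(total):
            ri = eligible[int(rng.integers(0, len(eligible)))]
            ungapped_index = int(np.searchsorted(row_cols[ri], col0))
            emit(ri, ungapped_index, float(rng.uniform(0.01, 0.5)), "hotspot")

    truth = pd.DataFrame(
        truths,
        columns=[
            "record_id", "gene", "protein_change", "residue_number",
            "reference_position", "classes", "origin",
        ],
    )
    return records, truth


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate and write all four inputs plus the truth sidecar.

    Returns a name -> path map: msa, structure, variants, benign, truth.
    The truth table is for validation only and is never read by the
    analysis stages.
    """
    os.makedirs(outdir, exist_ok=True)
    msa = generate_msa(config)
    structure = generate_reference_structure(msa)
    variants, truth_path = generate_variants(msa, config)
    benign, truth_benign = generate_benign_variants(msa, config)
    paths = {
        "msa": os.path.join(outdir, "msa.fasta"),
        "structure": os.path.join(outdir, "reference.pdb"),
        "variants": os.path.join(outdir, "variants.tsv"),
        "benign": os.path.join(outdir, "benign.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    kio.write_msa(msa, paths["msa"])
    kio.write_structure(structure, paths["structure"])
    kio.write_variant_table(variants, paths["variants"])
    kio.write_variant_table(benign, paths["benign"])
    pd.concat([truth_path, truth_benign], ignore_index=True).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
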