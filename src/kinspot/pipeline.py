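"""End-to-end orchestration: read -> filter -> map -> classify -> count
-> hotspots -> statistics -> benign branch -> outputs.

The analysis path contains no randomness: identical inputs and
configuration yield byte-identical outputs. All randomness lives in
:mod:`kinspot.synthetic`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import io as kio
from .classify import (
    DiseaseClassLexicon,
    assign_classes,
    audit_conditions,
    condition_classes,
    filter_benign,
    filter_pathogenic,
    load_lexicon,
)
from .errors import ConfigError
from .hotspots import (
    HotspotReport,
    PositionCounts,
    count_by_position,
    position_breakdown,
    rank_genes,
    select_hotspots,
)
from .mapping import check_reference_consistency, map_variants
from .model import (
    BENIGN,
    CANCER,
    NONCANCER,
    AlignedKinaseSet,
    ClassifiedVariant,
    ExclusionRecord,
    MappingStatus,
    ReferenceStructure,
    VariantRecord,
)
from .stats import classify_positions

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Paths and parameters for one full analysis run."""

    msa: str
    structure: str
    variants: str
    outdir: str
    benign: str | None = None
    lexicon_overrides: str | None = None
    reference_id: str | None = None
    chain_id: str = "A"
    quantile: float = 0.05
    alpha: float = 0.05
    af_threshold: float = 0.01
    yates: bool = True
    verify_ref_aa: bool = True
    collapse_aa: bool = False
    include_likely_benign: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 1):
            raise ConfigError(f"quantile: must be in (0, 1), got {self.quantile}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha: must be in (0, 1), got {self.alpha}")
        if not (0 <= self.af_threshold <= 1):
            raise ConfigError(
                f"af_threshold: must be in [0, 1], got {self.af_threshold}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisResult:
    """Everything one run produces, in memory."""

    counts: PositionCounts
    stats: pd.DataFrame
    hotspots: dict[str, list[int]]
    breakdowns: dict[str, list[HotspotReport]]
    gene_ranks: dict[str, pd.DataFrame]
    classified: list[ClassifiedVariant]
    classified_benign: list[ClassifiedVariant]
    exclusions: list[ExclusionRecord]
    audit: pd.DataFrame
    benign_summary: dict
    total_per_position: dict[int, int]


def summarize_benign(counts: PositionCounts) -> dict:
    """Total benign mutations, positions touched and the per-position
    maximum (the headline of the benign branch)."""
    per_position = {
        pos: counts.get(pos, BENIGN)
        for pos in counts.positions
        if counts.get(pos, BENIGN) > 0
    }
    return {
        "total": sum(per_position.values()),
        "n_positions": len(per_position),
        "max_per_position": max(per_position.values()) if per_position else 0,
    }


def _classify_mapped(mapped, lexicon, exclusions) -> list[ClassifiedVariant]:
    classified = []
    for mv in mapped:
        if mv.status is not MappingStatus.MAPPED:
            continue
        classes = assign_classes(mv.variant, lexicon)
        if not classes:
            exclusions.append(
                ExclusionRecord(
                    mv.variant.record_id, mv.variant.gene, mv.variant.protein_change,
                    "no_informative_condition", ";".join(mv.variant.conditions),
                )
            )
            continue
        classified.append(
            ClassifiedVariant(mv, classes, condition_classes(mv.variant, lexicon))
        )
    return classified


def analyze(
    msa: AlignedKinaseSet,
    structure: ReferenceStructure,
    pathogenic: list[VariantRecord],
    benign: list[VariantRecord] = (),
    lexicon: DiseaseClassLexicon | None = None,
    quantile: float = 0.05,
    alpha: float = 0.05,
    af_threshold: float = 0.01,
    yates: bool = True,
    verify_ref_aa: bool = True,
    collapse_aa: bool = False,
    include_likely_benign: bool = False,
    parse_exclusions: list[ExclusionRecord] | None = None,
) -> AnalysisResult:
    """Run the complete in-memory analysis on parsed inputs."""
    lexicon = lexicon or DiseaseClassLexicon()
    check_reference_consistency(msa, structure)
    exclusions: list[ExclusionRecord] = list(parse_exclusions or [])

    kept, sig_excluded = filter_pathogenic(list(pathogenic))
    exclusions.extend(sig_excluded)
    mapped, map_excluded = map_variants(kept, msa, structure, verify_ref_aa=verify_ref_aa)
    exclusions.extend(map_excluded)
    classified = _classify_mapped(mapped, lexicon, exclusions)

    benign_kept, benign_excluded = filter_benign(
        list(benign), af_threshold=af_threshold,
        include_likely_benign=include_likely_benign,
    )
    exclusions.extend(benign_excluded)
    mapped_benign, benign_map_excluded = map_variants(
        benign_kept, msa, structure, verify_ref_aa=verify_ref_aa
    )
    exclusions.extend(benign_map_excluded)
    classified_benign = [
        ClassifiedVariant(mv, frozenset({BENIGN}))
        for mv in mapped_benign
        if mv.status is MappingStatus.MAPPED
    ]

    counts = count_by_position(classified + classified_benign, collapse_aa=collapse_aa)
    stats = classify_positions(counts, alpha=alpha, yates=yates)

    hotspot_sets: dict[str, list[int]] = {}
    breakdowns: dict[str, list[HotspotReport]] = {}
    ranks: dict[str, pd.DataFrame] = {}
    for cls in (CANCER, NONCANCER):
        if counts.total(cls) > 0:
            positions = select_hotspots(counts, cls, quantile=quantile)
        else:
            positions = []
        hotspot_sets[cls] = positions
        breakdowns[cls] = [
            position_breakdown(classified, pos, cls, rank=rank, collapse_aa=collapse_aa)
            for rank, pos in enumerate(positions, start=1)
        ]
        ranks[cls] = rank_genes(classified, cls, collapse_aa=collapse_aa)

    # record-level pathogenic totals per position (each record once,
    # regardless of how many classes it belongs to)
    total_per_position: dict[int, int] = {}
    seen: set[tuple] = set()
    for cv in classified:
        key = (cv.record_id, cv.position)
        if key in seen:
            continue
        seen.add(key)
        total_per_position[cv.position] = total_per_position.get(cv.position, 0) + 1

    return AnalysisResult(
        counts=counts,
        stats=stats,
        hotspots=hotspot_sets,
        breakdowns=breakdowns,
        gene_ranks=ranks,
        classified=classified,
        classified_benign=classified_benign,
        exclusions=exclusions,
        audit=audit_conditions(list(pathogenic) + list(benign), lexicon),
        benign_summary=summarize_benign(counts),
        total_per_position=total_per_position,
    )


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_full_analysis(config: RunConfig) -> AnalysisResult:
    """File-to-file run: read all inputs, analyze, write every output
    table, the four annotated PDBs and a run manifest into ``outdir``.

    Consistency failures abort before any output is written.
    """
    t0 = time.time()
    for name in ("msa", "structure", "variants"):
        path = getattr(config, name)
        if not os.path.exists(path):
            raise ConfigError(f"{name}: no such file: {path}")
    if config.benign is not None and not os.path.exists(config.benign):
        raise ConfigError(f"benign: no such file: {config.benign}")

    msa = kio.read_msa(config.msa, reference_id=config.reference_id)
    structure = kio.read_structure(config.structure, chain_id=config.chain_id)
    check_reference_consistency(msa, structure)
    pathogenic, parse_excl = kio.read_variant_table(config.variants)
    benign: list[VariantRecord] = []
    if config.benign is not None:
        benign, benign_parse_excl = kio.read_variant_table(config.benign)
        parse_excl = parse_excl + benign_parse_excl
    lexicon = load_lexicon(config.lexicon_overrides)

    result = analyze(
        msa, structure, pathogenic, benign,
        lexicon=lexicon,
        quantile=config.quantile,
        alpha=config.alpha,
        af_threshold=config.af_threshold,
        yates=config.yates,
        verify_ref_aa=config.verify_ref_aa,
        collapse_aa=config.collapse_aa,
        include_likely_benign=config.include_likely_benign,
        parse_exclusions=parse_excl,
    )

    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    result.counts.to_frame().to_csv(
        os.path.join(outdir, "counts.tsv"), sep="\t", index=False
    )
    result.stats.to_csv(os.path.join(outdir, "stats.tsv"), sep="\t", index=False)
    for cls, suffix in ((CANCER, "cancer"), (NONCANCER, "noncancer")):
        rows = [
            {
                "class": cls,
                "rank": rank,
                "position": pos,
                "count": result.counts.get(pos, cls),
            }
            for rank, pos in enumerate(result.hotspots[cls], start=1)
        ]
        pd.DataFrame(rows, columns=["class", "rank", "position", "count"]).to_csv(
            os.path.join(outdir, f"hotspots_{suffix}.tsv"), sep="\t", index=False
        )
        kio.write_json(
            [b.to_dict() for b in result.breakdowns[cls]],
            os.path.join(outdir, f"breakdown_{suffix}.json"),
        )
        result.gene_ranks[cls].to_csv(
            os.path.join(outdir, f"gene_ranks_{suffix}.tsv"), sep="\t", index=False
        )

    cancer_counts = {p: result.counts.get(p, CANCER) for p in result.counts.positions}
    noncancer_counts = {p: result.counts.get(p, NONCANCER) for p in result.counts.positions}
    benign_counts = {p: result.counts.get(p, BENIGN) for p in result.counts.positions}
    kio.write_annotated_pdb(structure, cancer_counts, os.path.join(outdir, "annotated_cancer.pdb"))
    kio.write_annotated_pdb(structure, noncancer_counts, os.path.join(outdir, "annotated_noncancer.pdb"))
    kio.write_annotated_pdb(structure, benign_counts, os.path.join(outdir, "annotated_benign.pdb"))
    kio.write_annotated_pdb(structure, result.total_per_position, os.path.join(outdir, "annotated_total.pdb"))

    kio.write_exclusion_log(result.exclusions, os.path.join(outdir, "exclusions.tsv"))
    result.audit.to_csv(os.path.join(outdir, "condition_audit.tsv"), sep="\t", index=False)

    reason_counts: dict[str, int] = {}
    for e in result.exclusions:
        reason_counts[e.reason] = reason_counts.get(e.reason, 0) + 1
    manifest = {
        "tool": "kinspot",
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": {
            "msa": _sha256(config.msa),
            "structure": _sha256(config.structure),
            "variants": _sha256(config.variants),
            "benign": _sha256(config.benign) if config.benign else None,
        },
        "exclusion_reason_counts": reason_counts,
        "benign_summary": result.benign_summary,
        "runtime_seconds": round(time.time() - t0, 3),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
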