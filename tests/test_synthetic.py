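"""The synthetic input generator: determinism, planted-signal statistics
and ground-truth consistency."""

import numpy as np
import pytest

from kinspot.errors import ConfigError
from kinspot.model import BENIGN, CANCER, GAP, NONCANCER
from kinspot.synthetic import (
    PlantedHotspot,
    SimulationConfig,
    generate_benign_variants,
    generate_msa,
    generate_reference_structure,
    generate_variants,
    write_bundle,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"n_proteins": 0}, "n_proteins"),
            ({"ref_length": 0}, "ref_length"),
            ({"gap_fraction": 1.0}, "gap_fraction"),
            ({"background_rate": -0.1}, "background_rate"),
            ({"cancer_condition_pool": ()}, "cancer_condition_pool"),
            ({"planted_hotspots": (PlantedHotspot(0, CANCER, 5.0),)}, "planted_hotspots"),
            ({"ref_length": 10,
              "planted_hotspots": (PlantedHotspot(11, CANCER, 5.0),)}, "planted_hotspots"),
            ({"planted_hotspots": (PlantedHotspot(5, "weird", 5.0),)}, "planted_hotspots"),
            ({"planted_hotspots": (PlantedHotspot(5, CANCER, 0.0),)}, "planted_hotspots"),
        ],
    )
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            SimulationConfig(**kwargs)


class TestGenerateMsa:
    def test_single_row_degenerate_case(self):
        msa = generate_msa(SimulationConfig(n_proteins=1, ref_length=5, gap_fraction=0.0))
        assert len(msa.rows) == 1
        assert msa.n_columns >= 5
        assert msa.reference_row.ungapped_length == 5

    def test_reference_row_ungapped_at_its_own_columns(self):
        msa = generate_msa(SimulationConfig(n_proteins=5, ref_length=50, seed=2))
        assert msa.reference_row.ungapped_length == 50

    def test_same_seed_byte_identical(self, tmp_path):
        config = SimulationConfig(n_proteins=10, ref_length=60, seed=0)
        a = tmp_path / "a"
        b = tmp_path / "b"
        paths_a = write_bundle(config, a)
        paths_b = write_bundle(config, b)
        for name in paths_a:
            bytes_a = open(paths_a[name], "rb").read()
            bytes_b = open(paths_b[name], "rb").read()
            assert bytes_a == bytes_b, name

    def test_different_seed_differs(self):
        m1 = generate_msa(SimulationConfig(n_proteins=5, ref_length=40, seed=0))
        m2 = generate_msa(SimulationConfig(n_proteins=5, ref_length=40, seed=1))
        assert m1.rows != m2.rows

    def test_gap_fraction_matches_target(self):
        # gap fraction measured over non-reference rows at reference columns
        config = SimulationConfig(
            n_proteins=100, ref_length=100, gap_fraction=0.3, seed=9,
            n_reference_gap_columns=0,
        )
        msa = generate_msa(config)
        chars = np.array([list(r.sequence) for r in msa.rows[1:]])
        observed = (chars == GAP).mean()
        assert observed == pytest.approx(0.3, abs=0.03)


class TestGenerateReferenceStructure:
    def test_numbering_follows_offset(self):
        msa = generate_msa(SimulationConfig(n_proteins=2, ref_length=5, seed=1))
        offset = msa.reference_row.offset
        structure = generate_reference_structure(msa)
        assert structure.residue_numbers == list(range(offset, offset + 5))

    def test_b_factors_initialized_to_zero(self):
        msa = generate_msa(SimulationConfig(n_proteins=2, ref_length=5, seed=1))
        structure = generate_reference_structure(msa)
        assert all(r.b_factor == 0.0 for r in structure.residues)

    def test_written_structure_reparses_identically(self, tmp_path):
        from kinspot import io as kio

        msa = generate_msa(SimulationConfig(n_proteins=2, ref_length=30, seed=6))
        structure = generate_reference_structure(msa)
        p = tmp_path / "ref.pdb"
        kio.write_structure(structure, p)
        assert kio.read_structure(p).residue_numbers == structure.residue_numbers


class TestGenerateVariants:
    def test_no_background_all_variants_at_planted_position(self):
        config = SimulationConfig(
            n_proteins=10, ref_length=40, background_rate=0.0, seed=5,
            planted_hotspots=(PlantedHotspot(20, CANCER, 12.0),),
        )
        msa = generate_msa(config)
        variants, truth = generate_variants(msa, config)
        assert len(variants) > 0
        expected = msa.reference_row.offset + 19
        assert set(truth["reference_position"]) == {expected}

    def test_planted_mean_over_replicates(self):
        # Poisson(20) at one position: mean over 100 replicates within 20 +/- 1.5
        base = SimulationConfig(
            n_proteins=20, ref_length=50, background_rate=0.0, seed=0,
            planted_hotspots=(PlantedHotspot(25, CANCER, 20.0),),
        )
        msa = generate_msa(base)
        counts = []
        for rep in range(100):
            config = SimulationConfig(
                n_proteins=20, ref_length=50, background_rate=0.0, seed=rep,
                planted_hotspots=(PlantedHotspot(25, CANCER, 20.0),),
            )
            variants, _ = generate_variants(msa, config)
            counts.append(len(variants))
        assert np.mean(counts) == pytest.approx(20.0, abs=1.5)

    def test_truth_sidecar_covers_every_variant_exactly_once(self):
        config = SimulationConfig(
            n_proteins=20, ref_length=60, seed=3,
            planted_hotspots=(PlantedHotspot(30, CANCER, 10.0),),
        )
        msa = generate_msa(config)
        variants, truth = generate_variants(msa, config)
        assert sorted(truth["record_id"]) == sorted(v.record_id for v in variants)
        assert truth["record_id"].is_unique

    def test_significances_and_conditions_match_class(self):
        config = SimulationConfig(
            n_proteins=15, ref_length=50, seed=8, mixed_condition_fraction=0.0
        )
        msa = generate_msa(config)
        variants, truth = generate_variants(msa, config)
        classes = dict(zip(truth["record_id"], truth["classes"]))
        for v in variants:
            assert v.clinical_significance in ("Pathogenic", "Likely pathogenic")
            pool = (
                config.cancer_condition_pool
                if classes[v.record_id] == CANCER
                else config.noncancer_condition_pool
            )
            assert all(c in pool for c in v.conditions)


class TestGenerateBenign:
    def config(self, **kwargs):
        return SimulationConfig(n_proteins=10, ref_length=40, seed=2, **kwargs)

    def test_deterministic(self):
        config = self.config()
        msa = generate_msa(config)
        a, _ = generate_benign_variants(msa, config)
        b, _ = generate_benign_variants(msa, config)
        assert a == b

    def test_frequencies_straddle_threshold_with_exact_boundary(self):
        config = self.config(n_benign=10)
        msa = generate_msa(config)
        records, _ = generate_benign_variants(msa, config)
        afs = [r.allele_frequency for r in records]
        assert any(af < 0.01 for af in afs)
        assert any(af >= 0.01 for af in afs)
        assert 0.01 in afs  # exact boundary value survives the >= filter
        assert all(0 < af <= 0.5 for af in afs)
        assert all(r.clinical_significance == "Benign" for r in records)

    def test_zero_requested_records(self):
        config = self.config(n_benign=0)
        msa = generate_msa(config)
        records, truth = generate_benign_variants(msa, config)
        assert records == [] and len(truth) == 0

    def test_planted_benign_hotspot_survives_af_filter(self):
        from kinspot.classify import filter_benign

        config = self.config(
            n_benign=0,
            planted_hotspots=(PlantedHotspot(10, BENIGN, 8.0),),
        )
        msa = generate_msa(config)
        records, truth = generate_benign_variants(msa, config)
        kept, _ = filter_benign(records)
        assert len(kept) == len(records) > 0
        assert set(truth["origin"]) == {"hotspot"}
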