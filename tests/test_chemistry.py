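"""Forward chemistry: fragment sampling, conversion, read emission."""

import gzip

import numpy as np
import pytest

from conftest import run_pipeline, single_molecule_pair
from sixbct.chemistry import (
    ChemistryParams,
    SimulationConfig,
    convert_strand,
    sample_fragments,
    simulate_run,
    write_fastq_pair,
)
from sixbct.dna import STATE_5HMC, STATE_5MC, STATE_C, STATE_NONE
from sixbct.errors import InvalidParameterError
from sixbct.readproc import ME1U, ME2U, has_both_scars
from sixbct.reference import FeatureAnnotation, make_genome, make_spikeins


IDEAL = ChemistryParams.ideal(read_length=80)


class TestConvertStrand:
    """Hand-traced worked examples of the five chemistry steps."""

    def trace(self, state):
        rng = np.random.default_rng(0)
        states = np.array([STATE_NONE, state, STATE_NONE, STATE_NONE])
        return convert_strand("ACGT", states, IDEAL, rng)

    def test_unmodified_c_deaminated_on_both_strands(self):
        # original C -> T; aligned copy TGCA loses its C -> TGTA
        assert self.trace(STATE_C) == ("ATGT", "TGTA")

    def test_5mc_protected_and_copied(self):
        # Ox protects the original 5mC; MT methylates + protects the copy CpG
        assert self.trace(STATE_5MC) == ("ACGT", "TGCA")

    def test_5hmc_protected_copy_not_methylated(self):
        # glucosylation protects original 5hmC but blocks MT on the copy:
        # the (protected, deaminated-copy) signature decoded as 5hmC
        assert self.trace(STATE_5HMC) == ("ACGT", "TGTA")

    def test_atg_positions_never_altered_without_error(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=200).tolist())
        states = np.array([STATE_5MC if b == "C" and i % 2 else
                           (STATE_C if b == "C" else STATE_NONE)
                           for i, b in enumerate(seq)], dtype=np.int8)
        orig, _ = convert_strand(seq, states, IDEAL, rng)
        for i, b in enumerate(seq):
            if b in "ATG":
                assert orig[i] == b

    def test_failed_deamination_leaves_c_unconverted(self):
        params = ChemistryParams.ideal(read_length=80, p_deaminate=0.0)
        rng = np.random.default_rng(0)
        states = np.array([STATE_NONE, STATE_C, STATE_NONE, STATE_NONE])
        orig, copy = convert_strand("ACGT", states, params, rng)
        assert orig == "ACGT" and copy == "TGCA"


class TestSampleFragments:
    def test_enrichment_matches_closed_form_mixture(self):
        genome = make_genome(1, [40000])
        # intervals covering 5% of the genome at 20x enrichment
        ann = FeatureAnnotation([("chr1", 10000, 12000, "H3K4me1")],
                                {"H3K4me1": 20.0})
        mols = sample_fragments(genome, ann, "H3K4me1", 20000, IDEAL, seed=2)
        inside = sum(1 for m in mols if 10000 <= m.start < 12000)
        expected = 20 * 0.05 / (20 * 0.05 + 0.95)   # ~0.513
        se = np.sqrt(expected * (1 - expected) / 20000)
        assert abs(inside / 20000 - expected) <= 3 * se

    def test_igg_is_uniform(self):
        genome = make_genome(1, [40000])
        ann = FeatureAnnotation([("chr1", 10000, 12000, "H3K4me1")],
                                {"H3K4me1": 20.0})
        mols = sample_fragments(genome, ann, "IgG", 20000, IDEAL, seed=3)
        inside = sum(1 for m in mols if 10000 <= m.start < 12000)
        se = np.sqrt(0.05 * 0.95 / 20000)
        assert abs(inside / 20000 - 0.05) <= 4 * se

    def test_no_partials_when_probability_zero(self):
        genome = make_genome(1, [5000])
        mols = sample_fragments(genome, None, "WG", 500, IDEAL, seed=1)
        assert all(m.kind == "double-hairpin" for m in mols)

    def test_all_partial_when_probability_one(self):
        genome = make_genome(1, [5000])
        params = ChemistryParams.ideal(read_length=80, p_partial_fragment=1.0)
        mols = sample_fragments(genome, None, "WG", 200, params, seed=1)
        assert all(m.kind == "partial" for m in mols)

    def test_rejects_nonpositive_count(self):
        genome = make_genome(1, [5000])
        with pytest.raises(InvalidParameterError):
            sample_fragments(genome, None, "WG", 0, IDEAL, seed=1)


class TestEmitReadpair:
    def test_me2u_scars_as_printed(self):
        pair, _, _ = single_molecule_pair(
            "ACGT", [STATE_NONE, STATE_C, STATE_NONE, STATE_NONE],
            pad5="ATTAATTAAT", pad3="TTAATTAATT")
        assert pair.mate1.startswith("AAGAGATAG")
        assert pair.mate2.startswith("AAAAAACAA")
        assert len(pair.mate1) == len(pair.mate2) == 80

    def test_me1u_prefix_structure(self):
        pair, _, _ = single_molecule_pair(
            "ACGT", [STATE_NONE, STATE_C, STATE_NONE, STATE_NONE],
            pad5="ATTAATTAAT", pad3="TTAATTAATT", dialect=ME1U)
        assert pair.mate1[8:27] == "AGATGTGTATAAGAGATAG"
        assert pair.mate2[8:27] == "AAATATATATAAAAAACAA"

    def test_partial_molecules_lack_a_scar(self):
        genome = make_genome(2, [5000])
        params = ChemistryParams.ideal(read_length=80, p_partial_fragment=1.0)
        from conftest import landscape_from_states
        land = landscape_from_states(genome, {})
        cfg = SimulationConfig(genome=genome, landscape=land, params=params,
                               target_mark="WG", n_fragments=300, seed=4)
        # all partial, all escaping digestion
        cfg.params = ChemistryParams.ideal(
            read_length=80, p_partial_fragment=1.0, p_exo_escape=1.0)
        res = simulate_run(cfg)
        assert len(res.pairs) == 300
        assert all(not has_both_scars(p, ME2U) for p in res.pairs)


class TestSimulateRun:
    def test_fastq_bytes_identical_across_runs(self, tmp_path):
        genome = make_genome(3, [5000])
        from conftest import landscape_from_states
        land = landscape_from_states(genome, {})
        cfg = SimulationConfig(genome=genome, landscape=land, params=IDEAL,
                               target_mark="WG", n_fragments=1000, seed=9)
        blobs = []
        for run in range(2):
            res = simulate_run(cfg)
            r1 = tmp_path / f"run{run}_R1.fastq.gz"
            r2 = tmp_path / f"run{run}_R2.fastq.gz"
            write_fastq_pair(res.pairs, r1, r2)
            blobs.append((r1.read_bytes(), r2.read_bytes()))
        assert blobs[0] == blobs[1]
        # and the payload really is FASTQ
        lines = gzip.decompress(blobs[0][0]).decode().splitlines()
        assert lines[0].startswith("@") and len(lines) == 4000

    def test_spikein_fraction_binomial(self):
        genome = make_genome(3, [20000])
        from conftest import landscape_from_states
        land = landscape_from_states(genome, {})
        cfg = SimulationConfig(
            genome=genome, landscape=land, params=IDEAL, target_mark="WG",
            n_fragments=20000, seed=10, spikeins=make_spikeins(1),
            spikein_fraction=0.01)
        res = simulate_run(cfg)
        se = np.sqrt(20000 * 0.01 * 0.99)
        assert abs(res.n_spikein - 200) <= 3 * se

    def test_ideal_run_all_pairs_scarred(self, small_genome, ideal_params):
        from conftest import landscape_from_states
        land = landscape_from_states(small_genome, {})
        cfg = SimulationConfig(genome=small_genome, landscape=land,
                               params=ideal_params, target_mark="WG",
                               n_fragments=500, seed=2)
        res = simulate_run(cfg)
        assert all(has_both_scars(p, ME2U) for p in res.pairs)


class TestRoundTripProperties:
    def test_lower_deamination_raises_modc_miscalls(self, small_genome):
        """Unconverted unmodified C reads as protected, i.e. modified."""
        from conftest import landscape_from_states
        land = landscape_from_states(small_genome, {})

        def miscall_rate(p_deam, seed):
            params = ChemistryParams.ideal(
                read_length=100, insert_length_mean=55, insert_length_sd=10,
                p_deaminate=p_deam)
            out = run_pipeline(small_genome, land, params, 800, seed)
            df = out["table"].df
            mod = (df["n_M"] + df["n_H"] + df["n_X"]).sum()
            total = df.sum().sum()
            return mod / total

        assert miscall_rate(0.9, 5) > miscall_rate(1.0, 5)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(p_deaminate=1.5),
        dict(seq_error=-0.1),
        dict(read_length=10),
        dict(gap_duplication=-1),
        dict(insert_length_mean=0),
    ])
    def test_bad_params_raise(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ChemistryParams(**kwargs)
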