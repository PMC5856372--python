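"""The generative library-prep model: stage behaviour and global laws."""

import filecmp

import numpy as np
import pytest

from wgbsbias.biassim import (
    Fragment,
    GenomeIndex,
    Methylome,
    PcrModel,
    ProtocolModel,
    STATE_5MC,
    STATE_UNMOD,
    SimConfig,
    apply_methylome,
    bisulfite_convert,
    degradation_beta_for_ratio,
    emit_reads,
    fragment_genome,
    fragment_with_c_content,
    pcr_amplify,
    random_genome,
    simulate,
    stage_rng,
    tandem_reference,
)
from wgbsbias.methylation_quant import extract_per_cytosine, global_methylation
from wgbsbias.refio import ReferenceGenome


class TestSyntheticGenomes:
    def test_random_genome_gc_and_cpg_depletion(self):
        genome = random_genome(100_000, gc=0.42, cpg_obs_exp=0.2, seed=1)
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.42, abs=0.03)
        c = seq.count("C") / len(seq)
        g = seq.count("G") / len(seq)
        cpg = seq.count("CG") / (len(seq) - 1)
        assert cpg / (c * g) == pytest.approx(0.2, abs=0.05)

    def test_fragment_with_exact_c_content(self):
        for c_frac in (0.15, 0.30):
            genome = fragment_with_c_content(200, c_frac, seed=1)
            seq = genome["fragment"]
            assert seq.count("C") / len(seq) == c_frac

    def test_tandem_reference(self):
        genome = tandem_reference("TTAGGG", 5)
        assert genome["tandem"] == "TTAGGG" * 5


class TestGenomeIndex:
    def test_context_classes_top_strand(self):
        # CGA -> z at 0; CAG -> x at 3; CAA -> h at 6; trailing C -> u
        index = GenomeIndex(ReferenceGenome({"c": "CGACAGCAAC"}))
        pos, ctx = index.cytosines_in("c", 0, 10, "+")
        assert list(zip(pos, ctx)) == [(0, "z"), (3, "x"), (6, "h"), (9, "u")]

    def test_context_classes_bottom_strand(self):
        # bottom-strand C at top G; context read right-to-left complemented
        index = GenomeIndex(ReferenceGenome({"c": "ACGT"}))
        pos, ctx = index.cytosines_in("c", 0, 4, "-")
        assert list(zip(pos, ctx)) == [(2, "z")]

    def test_resistant_motif_marks_both_strands(self):
        index = GenomeIndex(
            ReferenceGenome({"c": "AACCAGGTT"}), resistant_motifs=[("CCWGG", 9.0)]
        )
        # top: CCAGG at 2..6, its two Cs at 2,3
        assert index.multiplier("c", "+", 2) == 9.0
        assert index.multiplier("c", "+", 3) == 9.0
        # bottom: Gs of the top CCWGG carry the complementary CCTGG's Cs
        assert index.multiplier("c", "-", 5) == 9.0
        assert index.multiplier("c", "-", 6) == 9.0
        assert index.multiplier("c", "+", 0) == 1.0


class TestFragmentGenome:
    def test_expected_count_for_target_depth(self):
        genome = random_genome(10_000, seed=3)
        frags = fragment_genome(genome, mean_length=150, depth=10, seed=1)
        assert len(frags) == round(10_000 * 10 / 150)

    def test_same_seed_identical_stream(self):
        genome = random_genome(5_000, seed=3)
        a = fragment_genome(genome, depth=5, seed=9)
        b = fragment_genome(genome, depth=5, seed=9)
        assert [(f.start, f.end, f.strand) for f in a] == [
            (f.start, f.end, f.strand) for f in b
        ]

    def test_length_and_start_distributions(self):
        genome = random_genome(50_000, seed=3)
        frags = fragment_genome(
            genome, mean_length=150, length_sd=30, depth=30, seed=1
        )
        lengths = np.array([len(f) for f in frags])
        starts = np.array([f.start for f in frags])
        assert lengths.mean() == pytest.approx(150, abs=2)
        assert lengths.std() == pytest.approx(30, abs=3)
        assert abs((starts / 50_000).mean() - 0.5) < 0.02  # uniform starts
        strands = np.mean([f.strand == "+" for f in frags])
        assert strands == pytest.approx(0.5, abs=0.02)

    def test_fragments_within_bounds(self):
        genome = ReferenceGenome({"tiny": "ACGT" * 30})
        frags = fragment_genome(genome, mean_length=100, depth=5, seed=1)
        for f in frags:
            assert 0 <= f.start < f.end <= 120


def _uniform_fragments(genome, n, chrom=None, length=None):
    name = chrom or next(iter(genome))
    L = length or len(genome[name])
    return [
        Fragment(index=k, chrom=name, start=0, end=L, strand="+")
        for k in range(n)
    ]


class TestApplyMethylome:
    @pytest.mark.parametrize("p,expected", [(1.0, STATE_5MC), (0.0, STATE_UNMOD)])
    def test_deterministic_extremes(self, p, expected):
        genome = random_genome(2_000, gc=0.5, cpg_obs_exp=1.0, seed=4)
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 5)
        apply_methylome(frags, index, Methylome(p_mCG=p), rng=stage_rng(1, 1))
        for f in frags:
            for ctx, state in zip(f.c_contexts, f.states):
                if ctx == "z":
                    assert state == expected

    def test_half_probability_binomial(self):
        genome = random_genome(5_000, gc=0.5, cpg_obs_exp=1.0, seed=4)
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 30)
        apply_methylome(frags, index, Methylome(p_mCG=0.5), rng=stage_rng(1, 1))
        states = [
            s
            for f in frags
            for ctx, s in zip(f.c_contexts, f.states)
            if ctx == "z"
        ]
        frac = np.mean([s == STATE_5MC for s in states])
        assert frac == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / len(states)))


class TestBisulfiteConvert:
    def test_survival_closed_form(self):
        # beta chosen so a molecule with 10 unmodified Cs survives at 1/2
        seq = "CA" * 10 + "TT" * 70
        genome = ReferenceGenome({"c": seq})
        index = GenomeIndex(genome)
        beta = 1 - 0.5 ** (1 / 10)
        frags = _uniform_fragments(genome, 10_000)
        apply_methylome(frags, index, Methylome(p_mCG=0, p_mCH=0), rng=stage_rng(1, 1))
        assert all(f.n_unmodified == 10 for f in frags)
        survivors = bisulfite_convert(
            frags, index, ProtocolModel(beta_unmod=beta), rng=stage_rng(1, 2)
        )
        assert len(survivors) / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_null_protocol_everything_survives_fully_converted(self):
        genome = random_genome(2_000, seed=4)
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 20)
        apply_methylome(frags, index, Methylome(p_mCG=0), rng=stage_rng(1, 1))
        survivors = bisulfite_convert(
            frags, index, ProtocolModel(), rng=stage_rng(1, 2)
        )
        assert len(survivors) == 20
        assert all(all(f.converted) for f in survivors)

    def test_modification_protection(self):
        # fully methylated molecules must survive at least as often as
        # unmodified ones whenever beta_mod <= beta_unmod
        genome = fragment_with_c_content(150, 0.30, seed=2)
        index = GenomeIndex(genome)
        protocol = ProtocolModel(beta_unmod=0.03, beta_mod=0.005)
        rates = {}
        for p, label in ((0.0, "unmod"), (1.0, "meth")):
            frags = _uniform_fragments(genome, 5_000)
            meth = Methylome(p_mCG=p, p_mCH=p)
            apply_methylome(frags, index, meth, rng=stage_rng(3, 1))
            rates[label] = len(
                bisulfite_convert(frags, index, protocol, rng=stage_rng(3, 2))
            )
        assert rates["meth"] > rates["unmod"]

    def test_recovery_ratio_calibration(self):
        # the two-pool demonstration: beta calibrated for a 2x ratio
        # between 15% C and 30% C unmethylated fragments
        beta = degradation_beta_for_ratio(2.0, delta_c=0.15, length=150)
        survived = {}
        for c_frac, name in ((0.15, "cpoor"), (0.30, "crich")):
            genome = fragment_with_c_content(150, c_frac, seed=5, name=name)
            index = GenomeIndex(genome)
            frags = _uniform_fragments(genome, 4_000)
            apply_methylome(
                frags, index, Methylome(p_mCG=0, p_mCH=0), rng=stage_rng(4, 1)
            )
            survived[name] = len(
                bisulfite_convert(
                    frags, index, ProtocolModel(beta_unmod=beta),
                    rng=stage_rng(4, 2),
                )
            )
        assert survived["cpoor"] / survived["crich"] == pytest.approx(2.0, abs=0.15)

    def test_beta_mod_above_beta_unmod_rejected(self):
        with pytest.raises(ValueError):
            ProtocolModel(beta_unmod=0.01, beta_mod=0.02)


class TestPcrAmplify:
    def _converted_fragments(self, genome, n):
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, n)
        apply_methylome(frags, index, Methylome(p_mCG=0), rng=stage_rng(1, 1))
        return bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(1, 2))

    def test_zero_cycles_identity(self):
        genome = random_genome(1_000, seed=6)
        frags = self._converted_fragments(genome, 10)
        out = pcr_amplify(frags, PcrModel(cycles=0), rng=stage_rng(1, 3))
        assert all(f.copies == 1 for f in out)

    def test_perfect_efficiency_doubles_per_cycle(self):
        genome = random_genome(1_000, seed=6)
        frags = self._converted_fragments(genome, 5)
        out = pcr_amplify(
            frags,
            PcrModel(cycles=3, efficiency_base=1.0, efficiency_slope=0.0),
            rng=stage_rng(1, 3),
        )
        assert all(f.copies == 8 for f in out)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_positive_slope_enriches_g_rich_molecules(self, seed):
        genome = random_genome(40_000, seed=7)
        index = GenomeIndex(genome)
        # random fragments so the pool has real G-fraction spread
        frags = fragment_genome(genome, depth=2, seed=seed)
        apply_methylome(frags, index, Methylome(p_mCG=0), rng=stage_rng(seed, 1))
        frags = bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(seed, 2))
        before = np.mean([f.g_frac for f in frags])
        out = pcr_amplify(
            frags,
            PcrModel(cycles=8, efficiency_base=0.6, efficiency_slope=2.0),
            rng=stage_rng(seed, 3),
        )
        after = np.average([f.g_frac for f in out], weights=[f.copies for f in out])
        assert after > before


class TestEmitReads:
    def test_fully_methylated_cpg_gives_uppercase_z(self):
        genome = ReferenceGenome({"c": "TTACGTTT"})
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 1)
        apply_methylome(frags, index, Methylome(p_mCG=1.0), rng=stage_rng(1, 1))
        survivors = bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(1, 2))
        alns, raws = emit_reads(survivors, genome, read_length=8, rng=stage_rng(1, 4))
        assert alns[0].call_string == "...Z...."
        assert raws[0].sequence == "TTACGTTT"  # 5mC resists conversion

    def test_unmodified_fragment_fully_converted(self):
        genome = ReferenceGenome({"c": "TTACGTTT"})
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 1)
        apply_methylome(frags, index, Methylome(p_mCG=0.0), rng=stage_rng(1, 1))
        survivors = bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(1, 2))
        alns, raws = emit_reads(survivors, genome, read_length=8, rng=stage_rng(1, 4))
        assert alns[0].call_string == "...z...."
        assert raws[0].sequence == "TTATGTTT"

    def test_bottom_strand_read_sequence_and_orientation(self):
        genome = ReferenceGenome({"c": "TTACGTTT"})
        index = GenomeIndex(genome)
        frags = [Fragment(index=0, chrom="c", start=0, end=8, strand="-")]
        apply_methylome(frags, index, Methylome(p_mCG=0.0), rng=stage_rng(1, 1))
        survivors = bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(1, 2))
        alns, raws = emit_reads(survivors, genome, read_length=8, rng=stage_rng(1, 4))
        assert alns[0].bs_strand == "OB"
        # bottom strand of TTACGTTT is AAACGTAA read 5'->3'; its C converts
        assert raws[0].sequence == "AAATGTAA"
        assert alns[0].call_string == "....z..."

    def test_post_bs_reads_are_complementary(self):
        genome = ReferenceGenome({"c": "TTACGTTT"})
        index = GenomeIndex(genome)
        frags = _uniform_fragments(genome, 1)
        apply_methylome(frags, index, Methylome(p_mCG=0.0), rng=stage_rng(1, 1))
        survivors = bisulfite_convert(frags, index, ProtocolModel(), rng=stage_rng(1, 2))
        alns, raws = emit_reads(
            survivors, genome, read_length=8,
            protocol_direction="post_bs", rng=stage_rng(1, 4),
        )
        assert alns[0].bs_strand == "CTOT"
        assert raws[0].sequence == "AAACATAA"  # revcomp of TTATGTTT

    def test_extraction_reproduces_truth_at_deterministic_rates(self):
        # p_mCG = 1 and no conversion noise: every extracted CpG is 100%
        bundle = simulate(
            SimConfig(
                seed=13,
                genome_length=5_000,
                depth=20,
                methylome=Methylome(p_mCG=1.0),
                protocol=ProtocolModel(),
            )
        )
        table = extract_per_cytosine(bundle.alignments, contexts={"CG"})
        assert len(table) > 0
        assert all(r.percent == 100.0 for r in table.records.values())

    def test_conservation_reads_reconcile_with_fragments(self, null_bundle):
        emitted = sum(f.emitted for f in null_bundle.truth.fragments)
        assert emitted == len(null_bundle.alignments)
        ids = {a.read_id for a in null_bundle.alignments}
        assert len(ids) == len(null_bundle.alignments)

    def test_pcr_copies_beyond_first_are_flagged_duplicate(self):
        bundle = simulate(
            SimConfig(
                seed=14,
                genome_length=5_000,
                depth=10,
                methylome=Methylome(p_mCG=0.5),
                protocol=ProtocolModel(),
                pcr=PcrModel(cycles=4, efficiency_base=0.9),
                target_reads=1_000,
            )
        )
        dup = sum(a.is_duplicate for a in bundle.alignments)
        assert 0 < dup < len(bundle.alignments)


class TestSimulateGlobalLaws:
    def test_overestimation_law(self):
        # degradation spares methylated molecules, inflating measured mCG
        bundle = simulate(
            SimConfig(
                seed=15,
                genome_length=30_000,
                depth=40,
                methylome=Methylome(p_mCG=0.7),
                protocol=ProtocolModel(beta_unmod=0.1),
            )
        )
        table = extract_per_cytosine(bundle.alignments, contexts={"CG"})
        measured = global_methylation(table)
        truth = bundle.truth.true_global_meth("z")
        assert measured > truth + 0.5

    def test_no_degradation_no_overestimation(self, null_bundle):
        table = extract_per_cytosine(null_bundle.alignments, contexts={"CG"})
        measured = global_methylation(table)
        truth = null_bundle.truth.true_global_meth("z")
        n = sum(r.total_count for r in table.records.values())
        se = 100 * np.sqrt(0.7 * 0.3 / n)
        assert abs(measured - truth) < 4 * se

    def test_amplification_free_estimates_better(self):
        # at matched read depth PCR copies shrink the effective sample of
        # distinct molecules, so the amplified protocol's global mCG
        # estimate scatters more and errs more, over replicate libraries
        from wgbsbias.biassim import get_preset

        deviations = {}
        for preset in ("pbat_like", "heat_like"):
            protocol, pcr, direction = get_preset(preset)
            devs = []
            for seed in range(41, 51):
                bundle = simulate(
                    SimConfig(
                        seed=seed,
                        genome_length=20_000,
                        depth=25,
                        methylome=Methylome(p_mCG=0.7),
                        protocol=protocol,
                        pcr=pcr,
                        protocol_direction=direction,
                    )
                )
                table = extract_per_cytosine(
                    bundle.alignments, contexts={"CG"}, include_duplicates=True
                )
                devs.append(
                    global_methylation(table)
                    - bundle.truth.true_global_meth("z")
                )
            deviations[preset] = np.asarray(devs)
        assert np.abs(deviations["pbat_like"]).mean() < np.abs(
            deviations["heat_like"]
        ).mean()
        assert deviations["pbat_like"].std() < deviations["heat_like"].std()

    def test_determinism_byte_identical_outputs(self, tmp_path):
        config = SimConfig(
            seed=77,
            genome_length=4_000,
            depth=10,
            methylome=Methylome(p_mCG=0.6),
            protocol=ProtocolModel(beta_unmod=0.01, epsilon_CH=0.01),
            pcr=PcrModel(cycles=3, efficiency_base=0.8),
        )
        simulate(config, out_dir=tmp_path / "a")
        simulate(config, out_dir=tmp_path / "b")
        for name in (
            "genome.fa", "reads.sam", "reads.fastq",
            "truth_positions.tsv", "truth_fragments.tsv",
        ):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_spike_reference_is_unmethylated(self):
        bundle = simulate(
            SimConfig(
                seed=16,
                genome_length=5_000,
                depth=10,
                methylome=Methylome(p_mCG=0.9),
                protocol=ProtocolModel(),
                spike_name="lambda",
            )
        )
        spike_calls = [
            ch
            for a in bundle.alignments
            if a.interval.chrom == "lambda"
            for ch in a.call_string
            if ch != "."
        ]
        assert spike_calls and all(ch.islower() for ch in spike_calls)

    def test_heat_converts_better_than_alkaline(self):
        # the two denaturation chemistries are calibrated to a ~4x gap in
        # conversion-failure rate; recover it from unmethylated libraries
        from wgbsbias.biassim import get_preset
        from wgbsbias.conversion_qc import spike_in_conversion

        efficiency = {}
        for preset in ("heat_like", "alkaline_like"):
            protocol, pcr, direction = get_preset(preset)
            bundle = simulate(
                SimConfig(
                    seed=31,
                    genome_length=40_000,
                    genome_gc=0.5,
                    genome_cpg_obs_exp=1.0,
                    depth=150,
                    methylome=Methylome(p_mCG=0.0),
                    protocol=protocol,
                    pcr=pcr,
                    protocol_direction=direction,
                )
            )
            efficiency[preset] = spike_in_conversion(bundle.alignments).efficiency
        assert efficiency["heat_like"] > efficiency["alkaline_like"]
        ratio = (1 - efficiency["alkaline_like"]) / (1 - efficiency["heat_like"])
        assert 2.5 < ratio < 6.5

    def test_presets_all_resolve(self):
        from wgbsbias.biassim import PRESET_NAMES, get_preset

        for name in PRESET_NAMES:
            protocol, pcr, direction = get_preset(name)
            assert direction in ("pre_bs", "post_bs")
        protocol, pcr, _ = get_preset("pbat_like")
        assert pcr.cycles == 0
        with pytest.raises(KeyError):
            get_preset("nope")
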