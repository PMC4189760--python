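import numpy as np
import pytest

from besurvey import besio, composition, repeatacct, ssrmine, synteny
from besurvey._dna import revcomp
from besurvey.simulate import (
    CapacityError,
    ConfigError,
    Rearrangement,
    RepeatFamily,
    SurveySpec,
    derive_reference,
    generate_genome,
    run_simulation,
    simulate_library,
    write_sam,
)
from besurvey.simulate.truth import CloneTruth, ReadTruth, TruthTable

BARE = dict(ssr_density=0.0, repeat_families=())


def _small_spec(**kw):
    defaults = dict(
        genome_length=50_000,
        n_clones=20,
        insert_mean=2.0,
        insert_sd=0.5,
        insert_min=1.0,
        insert_max=4.0,
        read_length_mean=300,
        read_length_sd=80,
        read_min=100,
        read_max=600,
        seed=1,
    )
    defaults.update(kw)
    return SurveySpec(**defaults)


class TestSpecValidation:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SurveySpec(ssr_class_mix=(0.5, 0.5, 0.1, 0, 0, 0))

    def test_insert_ordering(self):
        with pytest.raises(ConfigError):
            _small_spec(insert_min=5.0)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        spec = _small_spec(seed=9)
        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(spec.to_dict()))
        assert SurveySpec.from_yaml(path) == spec


class TestGenerateGenome:
    def test_nothing_planted(self):
        spec = SurveySpec(genome_length=10_000, gc_fraction=0.5, seed=2, **BARE)
        genome, truth = generate_genome(spec)
        assert len(genome) == 10_000
        assert truth.ssrs == [] and truth.repeats == []
        assert ssrmine.scan_sequence(genome) == []

    def test_single_planted_mono_roundtrip(self):
        spec = SurveySpec(
            genome_length=10_000, seed=3, explicit_ssrs=(("A", 12),), **BARE
        )
        genome, truth = generate_genome(spec)
        assert len(truth.ssrs) == 1
        t = truth.ssrs[0]
        assert (t.end - t.start, t.unit) == (12, "A")
        loci = ssrmine.scan_sequence(genome)
        assert [(l.start, l.end, l.unit) for l in loci] == [(t.start, t.end, "A")]

    def test_determinism(self):
        spec = _small_spec(seed=7)
        g1, t1 = generate_genome(spec)
        g2, t2 = generate_genome(spec)
        assert g1 == g2
        assert t1.ssrs == t2.ssrs and t1.repeats == t2.repeats

    def test_capacity_error(self):
        spec = SurveySpec(
            genome_length=10_000,
            repeat_families=(RepeatFamily("big", "ClassI/LTR/Copia", 5_000, 10),),
            ssr_density=0.0,
            seed=1,
        )
        with pytest.raises(CapacityError):
            generate_genome(spec)

    def test_planted_ssr_set_recovered_exactly(self):
        spec = SurveySpec(genome_length=200_000, ssr_density=15, seed=5,
                          repeat_families=())
        genome, truth = generate_genome(spec)
        detected = {(l.start, l.end, l.unit) for l in ssrmine.scan_sequence(genome)}
        planted = {(s.start, s.end, s.unit) for s in truth.ssrs}
        assert detected == planted
        assert len(planted) == round(15 * 200_000 / 100_000)

    def test_class_mix_apportionment(self):
        spec = SurveySpec(genome_length=500_000, ssr_density=20, seed=6,
                          repeat_families=())
        _, truth = generate_genome(spec)
        counts = {}
        for s in truth.ssrs:
            counts[s.unit_len] = counts.get(s.unit_len, 0) + 1
        total = sum(counts.values())
        for i, prop in enumerate(spec.ssr_class_mix):
            assert counts.get(i + 1, 0) == pytest.approx(prop * total, abs=1)

    def test_planted_repeats_are_exact_copies(self):
        fam = RepeatFamily("copia", "ClassI/LTR/Copia", 400, 5)
        spec = SurveySpec(genome_length=100_000, repeat_families=(fam,),
                          ssr_density=0.0, seed=8)
        genome, truth = generate_genome(spec)
        assert len(truth.repeats) == 5
        copies = {genome[r.start : r.end] for r in truth.repeats}
        assert len(copies) == 1  # mutation rate 0 -> byte-identical copies

    def test_mutated_copies_diverge(self):
        fam = RepeatFamily("copia", "ClassI/LTR/Copia", 400, 5)
        spec = SurveySpec(genome_length=100_000, repeat_families=(fam,),
                          ssr_density=0.0, repeat_mutation_rate=0.05, seed=8)
        genome, truth = generate_genome(spec)
        assert any(r.n_mutations > 0 for r in truth.repeats)

    @pytest.mark.parametrize("gc", [0.3, 0.42, 0.6])
    def test_gc_recovery(self, gc):
        spec = SurveySpec(genome_length=200_000, gc_fraction=gc, seed=4, **BARE)
        genome, _ = generate_genome(spec)
        # binomial SD of the GC fraction estimate at n=200k is ~0.11 pp
        assert composition.gc_content(genome).gc_percent == pytest.approx(
            100 * gc, abs=0.5
        )

    def test_distributional_recovery_over_seeds(self):
        gcs, densities, fractions = [], [], []
        for seed in range(10):
            spec = SurveySpec(genome_length=500_000, seed=seed,
                              insert_mean=2.0, insert_sd=0.5, insert_min=1.0,
                              insert_max=4.0)
            genome, truth = generate_genome(spec)
            gcs.append(composition.gc_content(genome).gc_percent)
            densities.append(100_000 * len(truth.ssrs) / len(genome))
            fractions.append(100 * truth.repeat_nt() / len(genome))
        gc_se = np.std(gcs) / np.sqrt(len(gcs))
        assert abs(np.mean(gcs) - 42.0) <= 3 * gc_se
        # planted counts are apportioned deterministically, so density and
        # repeat fraction deviate from spec only through integer rounding
        assert np.mean(densities) == pytest.approx(10.8, abs=0.35)
        target_fraction = 100 * (0.0787 + 0.1018 + 0.0034 + 0.0005)
        assert np.mean(fractions) == pytest.approx(target_fraction, abs=1.0)


class TestSimulateLibrary:
    def test_read_counts_fully_paired(self):
        spec = _small_spec(n_clones=100)
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        assert beset.total_reads == 200
        ends = [r.end for r in beset.records]
        assert ends.count("F") == 100 and ends.count("R") == 100

    def test_degenerate_insert_distribution(self):
        spec = _small_spec(insert_sd=0.0, insert_mean=2.0)
        genome, truth = generate_genome(spec)
        _, truth = simulate_library(genome, spec, truth)
        assert {c.insert_len for c in truth.clones} == {2_000}

    def test_reads_are_genome_substrings(self):
        spec = _small_spec(n_clones=50, seed=11)
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        clones = {c.clone_id: c for c in truth.clones}
        for rec in beset.records:
            c = clones[rec.clone_id]
            if rec.end == "F":
                assert genome[c.start : c.start + rec.length] == rec.sequence
            else:
                seg = genome[c.start + c.insert_len - rec.length : c.start + c.insert_len]
                assert revcomp(seg) == rec.sequence

    def test_unpaired_fraction(self):
        spec = _small_spec(n_clones=200, unpaired_fraction=0.3, seed=13)
        genome, truth = generate_genome(spec)
        beset, _ = simulate_library(genome, spec, truth)
        pairing = beset.pairing
        single = sum(1 for ends in pairing.values() if len(ends) == 1)
        assert 30 <= single <= 90  # binomial(200, 0.3) well within 99.9%

    def test_organellar_requires_sequences(self):
        spec = _small_spec(organellar_rate=0.1)
        genome, truth = generate_genome(spec)
        with pytest.raises(ConfigError):
            simulate_library(genome, spec, truth)

    def test_genome_must_exceed_insert_max(self):
        spec = _small_spec()
        with pytest.raises(ConfigError):
            simulate_library("ACGT" * 100, spec)

    def test_organellar_count_within_binomial_ci(self):
        # 99% central interval of Binomial(82,944, 4.34e-4) is [22, 52]
        # (scipy.stats.binom.interval, frozen)
        spec = SurveySpec(
            genome_length=50_000, n_clones=82_944,
            insert_mean=2.0, insert_sd=0.5, insert_min=1.0, insert_max=4.0,
            read_length_mean=120, read_length_sd=10, read_min=100, read_max=200,
            organellar_rate=0.000434, seed=42, **BARE,
        )
        genome, truth = generate_genome(spec)
        org = [("chloroplast_genome", genome[:20_000])]
        _, truth = simulate_library(genome, spec, truth, organellar=org)
        n_org = sum(1 for c in truth.clones if c.provenance != "nuclear")
        assert 22 <= n_org <= 52

    def test_planted_duplicates_give_expected_redundancy(self):
        spec = _small_spec(n_clones=500, duplicate_rate=0.054, seed=17)
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        assert beset.total_reads == 1_000
        assert sum(1 for c in truth.clones if c.duplicate_of) == 27
        assert besio.redundancy(beset) == pytest.approx(0.054)

    def test_short_reads_discarded(self):
        spec = _small_spec(
            insert_mean=0.12, insert_sd=0.05, insert_min=0.05, insert_max=0.3,
            n_clones=200, seed=19,
        )
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        assert truth.n_discarded_reads > 0
        assert all(r.length >= spec.read_min for r in beset.records)


def _manual_truth(genome_len, clone_start=50_000, insert=100_000, read_len=500):
    truth = TruthTable(genome_length=genome_len)
    truth.clones.append(CloneTruth("bac00000", clone_start, insert, "nuclear"))
    truth.reads.append(ReadTruth("bac00000F", "bac00000", "F", read_len, "nuclear"))
    truth.reads.append(ReadTruth("bac00000R", "bac00000", "R", read_len, "nuclear"))
    return truth


def _plain_genome(n, seed=23):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestDeriveReference:
    def test_identity_reference_all_collinear(self):
        spec = _small_spec(n_clones=60, insert_mean=60, insert_sd=20,
                           insert_min=20, insert_max=120,
                           genome_length=400_000, seed=29)
        genome, truth = generate_genome(spec)
        _, truth = simulate_library(genome, spec, truth)
        _, truth = derive_reference(genome, spec, truth)
        paired = [p for p in truth.pairs if p.category not in ("SE", "unmapped")]
        assert paired and all(p.category == "PE_collinear" for p in paired)

    def test_inversion_spanning_one_end_is_rearranged(self):
        genome = _plain_genome(400_000)
        spec = SurveySpec(
            genome_length=400_000, seed=1,
            rearrangements=(Rearrangement("inversion", 49_000, 3_000),), **BARE,
        )
        _, truth = derive_reference(genome, spec, _manual_truth(400_000))
        assert truth.pairs[0].category == "PE_rearranged"

    def test_huge_insertion_between_ends_is_gapped(self):
        genome = _plain_genome(400_000)
        spec = SurveySpec(
            genome_length=400_000, seed=1,
            rearrangements=(Rearrangement("insertion", 100_000, 6_000_000),), **BARE,
        )
        _, truth = derive_reference(genome, spec, _manual_truth(400_000))
        assert truth.pairs[0].category == "PE_gapped"
        assert truth.pairs[0].span_bp == pytest.approx(6_100_000, abs=1)

    def test_deletion_of_one_end_is_se(self):
        genome = _plain_genome(400_000)
        spec = SurveySpec(
            genome_length=400_000, seed=1,
            rearrangements=(Rearrangement("deletion", 49_000, 3_000),), **BARE,
        )
        _, truth = derive_reference(genome, spec, _manual_truth(400_000))
        assert truth.pairs[0].category == "SE"

    def test_translocation_across_break_non_colocalized(self):
        genome = _plain_genome(400_000)
        spec = SurveySpec(
            genome_length=400_000, seed=1,
            rearrangements=(Rearrangement("translocation", 49_000, 3_000, dest=350_000),),
            reference_breaks=(200_000,), **BARE,
        )
        _, truth = derive_reference(genome, spec, _manual_truth(400_000))
        assert truth.pairs[0].category == "PE_non_colocalized"

    def test_overlapping_edits_rejected(self):
        genome = _plain_genome(50_000)
        spec = SurveySpec(
            genome_length=50_000, seed=1,
            rearrangements=(
                Rearrangement("inversion", 10_000, 5_000),
                Rearrangement("deletion", 12_000, 5_000),
            ), **BARE,
        )
        with pytest.raises(ConfigError, match="overlap"):
            derive_reference(genome, spec, _manual_truth(50_000, 20_000, 10_000))

    def test_classifier_matches_truth_on_sam(self, tmp_path):
        spec = _small_spec(
            genome_length=600_000, n_clones=150, seed=31,
            insert_mean=60, insert_sd=25, insert_min=20, insert_max=120,
            unpaired_fraction=0.1,
            rearrangements=(
                Rearrangement("inversion", 100_000, 40_000),
                Rearrangement("deletion", 200_000, 10_000),
                Rearrangement("insertion", 300_000, 400_000),
                Rearrangement("translocation", 420_000, 30_000, dest=550_000),
            ),
            reference_breaks=(250_000,),
        )
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        refmap, truth = derive_reference(genome, spec, truth)
        sam = tmp_path / "aln.sam"
        write_sam(sam, refmap, beset, truth)
        classes = {
            c.clone_id: c.category
            for c in synteny.classify_all(synteny.load_alignments(sam))
        }
        expected = {p.clone_id: p.category for p in truth.pairs}
        assert classes == expected
        assert len(set(expected.values())) >= 3  # the edits actually exercise rules

    def test_sam_sequences_match_reference(self, tmp_path):
        spec = _small_spec(genome_length=300_000, n_clones=30, seed=37,
                           insert_mean=60, insert_sd=20, insert_min=20,
                           insert_max=120,
                           rearrangements=(Rearrangement("inversion", 50_000, 100_000),))
        genome, truth = generate_genome(spec)
        beset, truth = simulate_library(genome, spec, truth)
        refmap, truth = derive_reference(genome, spec, truth)
        sam = tmp_path / "aln.sam"
        write_sam(sam, refmap, beset, truth)
        chroms = dict(refmap.chromosome_sequences())
        import pysam

        with pysam.AlignmentFile(str(sam), "r") as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                ref = chroms[rec.reference_name]
                assert (
                    ref[rec.reference_start : rec.reference_end]
                    == rec.query_sequence
                )


class TestRunSimulation:
    def test_files_written_and_deterministic(self, tmp_path):
        spec = _small_spec(n_clones=30, seed=41)
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run_simulation(spec, out1)
        run_simulation(spec, out2)
        names = [
            "genome.fasta", "reads.fasta", "reference.fasta", "alignments.sam",
            "repeat_library.fasta", "truth_ssrs.tsv", "truth_repeats.tsv",
            "truth_clones.tsv", "truth_reads.tsv", "truth_pairs.tsv",
        ]
        for name in names:
            b1 = (out1 / name).read_bytes()
            assert b1 == (out2 / name).read_bytes()
            assert b1  # non-empty

    def test_organellar_hits_emitted(self, tmp_path):
        spec = _small_spec(n_clones=100, organellar_rate=0.2, seed=43)
        org = [("mitochondrial_genome", _plain_genome(30_000))]
        beset, truth = run_simulation(spec, tmp_path / "sim", organellar=org)
        hits = tmp_path / "sim" / "organellar_hits.tsv"
        assert hits.exists()
        labels = besio.screen_organellar(beset, hits)
        expected = {
            r.name: (r.provenance if r.provenance != "organellar" else "nuclear")
            for r in truth.reads
        }
        assert labels == expected
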