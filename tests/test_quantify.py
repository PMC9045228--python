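"""Junction signatures, footprint counting, abundances, enrichment, CFU ratios."""

import gzip

import pytest
from hypothesis import given, settings, strategies as st
from Bio.Seq import Seq

from shufflon import (
    AbundanceTable,
    CountTable,
    GeneratorConfig,
    build_locus,
    conjugation_frequency,
    count_footprints,
    enrichment,
    find_sfx_sites,
    generate_locus,
    make_signatures,
    relative_abundance,
    simulate_reads,
)
from shufflon.quantify import UndefinedAbundanceError, signatures_to_fasta
from shufflon.locus import DEFAULT_CONSENSUS


def _revcomp(s):
    return str(Seq(s).reverse_complement())


def _write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")


class TestMakeSignatures:
    def test_default_tp114_like(self, locus):
        sigs = make_signatures(locus)
        assert len(sigs) == 8
        assert all(s.k == 39 for s in sigs)
        kmers = [s.kmer for s in sigs]
        assert len(set(kmers + [_revcomp(m) for m in kmers])) == 16

    def test_signatures_split_at_core_boundary(self, locus):
        sigs = make_signatures(locus)
        const_end = locus.sites[0].core_end
        const_side = locus.sequence[const_end - 19 : const_end]
        assert all(s.kmer.startswith(const_side) for s in sigs)
        assert all(s.kmer[12:19] == locus.core_seq for s in sigs)

    def test_single_cassette_two_signatures(self):
        locus1, _ = generate_locus(GeneratorConfig(seed=5, n_cassettes=1))
        sigs = make_signatures(locus1)
        assert len(sigs) == 2
        assert sigs[0].kmer[:19] == sigs[1].kmer[:19]
        assert sigs[0].kmer[19:] != sigs[1].kmer[19:]

    def test_collision_extends_k(self):
        """Cassettes sharing a 22-bp start force symmetric growth to k=45."""
        import numpy as np

        rng = np.random.default_rng(11)
        bases = "ACGT"
        rand = lambda n: "".join(rng.choice(list(bases), size=n))
        tmpl = DEFAULT_CONSENSUS.right_arm_template
        site = lambda left, trip: left + DEFAULT_CONSENSUS.core + tmpl[:6] + trip + tmpl[9:]
        shared = rand(10)
        interior1 = shared + "A" + rand(50)
        interior2 = shared + "C" + rand(50)
        seq = (
            rand(40)
            + site(rand(12), "GTG")
            + interior1
            + site(rand(12), "GTG")  # same triplet: identical right arms
            + interior2
            + site(rand(12), "ATC")
            + rand(40)
        )
        built = build_locus(seq, find_sfx_sites(seq))
        sigs = make_signatures(built)
        assert all(s.k == 45 for s in sigs)
        kmers = [s.kmer for s in sigs]
        assert len(set(kmers)) == len(kmers)

    def test_bad_split_rejected(self, locus):
        with pytest.raises(ValueError):
            make_signatures(locus, k=39, c=0)
        with pytest.raises(ValueError):
            make_signatures(locus, k=39, c=39)


class TestCountFootprints:
    def test_reverse_complement_read_counts(self, locus, tmp_path):
        sigs = make_signatures(locus)
        target = sigs[0]
        read = "ACGTAC" + _revcomp(target.kmer) + "GGCATC"
        path = tmp_path / "reads.fastq"
        _write_fastq(path, [read])
        table = count_footprints(path, sigs)
        assert table.counts[target.label] == 1
        assert table.total_positive == 1
        assert table.n_reads_scanned == 1

    def test_empty_fastq(self, locus, tmp_path):
        path = tmp_path / "empty.fastq"
        path.write_text("")
        table = count_footprints(path, make_signatures(locus))
        assert table.total_positive == 0
        with pytest.raises(UndefinedAbundanceError):
            relative_abundance(table)

    def test_error_free_reads_match_truth_exactly(self, locus, tmp_path):
        """With no errors, per-variant counts equal the junction-covering reads."""
        config = GeneratorConfig(seed=1, depth=5000, error_rate=0.0)
        freqs = {"A": 0.5, "B'": 0.3, "C": 0.2}
        fastq = tmp_path / "reads.fastq"
        truth_df = simulate_reads(locus, freqs, config, fastq, seed=7)
        sigs = make_signatures(locus)
        table = count_footprints(fastq, sigs)
        jstart = locus.sites[0].core_end - 19
        jend = jstart + 39
        covering = truth_df[
            (truth_df["start"] <= jstart)
            & (truth_df["start"] + config.read_length >= jend)
        ]
        expected = covering.groupby("variant").size().to_dict()
        observed = {k: v for k, v in table.counts.items() if v}
        assert observed == expected
        assert table.ambiguous == 0

    def test_strand_symmetry(self, locus, tmp_path):
        config = GeneratorConfig(seed=2, depth=2000, error_rate=0.0)
        fastq = tmp_path / "fwd.fastq"
        simulate_reads(locus, {"A": 0.6, "D": 0.4}, config, fastq, seed=3)
        reads = [
            line.strip()
            for i, line in enumerate(fastq.read_text().splitlines())
            if i % 4 == 1
        ]
        rc_path = tmp_path / "rc.fastq"
        _write_fastq(rc_path, [_revcomp(r) for r in reads])
        sigs = make_signatures(locus)
        assert count_footprints(fastq, sigs).counts == count_footprints(rc_path, sigs).counts

    def test_per_occurrence_mode(self, locus, tmp_path):
        sigs = make_signatures(locus)
        target = sigs[2]
        read = target.kmer + "ACGT" + _revcomp(target.kmer)
        path = tmp_path / "double.fastq"
        _write_fastq(path, [read])
        per_read = count_footprints(path, sigs, count_mode="per_read")
        per_occ = count_footprints(path, sigs, count_mode="per_occurrence")
        assert per_read.counts[target.label] == 1
        assert per_occ.counts[target.label] == 2

    def test_ambiguous_reads_excluded(self, locus, tmp_path):
        sigs = make_signatures(locus)
        chimera = sigs[0].kmer + "ACGT" + sigs[1].kmer
        path = tmp_path / "chimera.fastq"
        _write_fastq(path, [chimera])
        table = count_footprints(path, sigs)
        assert table.ambiguous == 1
        assert table.total_positive == 0

    def test_malformed_fastq(self, locus, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\nNOPLUS\nIIII\n")
        with pytest.raises(ValueError, match="malformed"):
            count_footprints(path, make_signatures(locus))

    def test_gzip_and_pooling(self, locus, tmp_path):
        sigs = make_signatures(locus)
        a = tmp_path / "a.fastq"
        _write_fastq(a, [sigs[0].kmer])
        b = tmp_path / "b.fastq.gz"
        with gzip.open(b, "wt") as fh:
            fh.write(f"@r0\n{sigs[1].kmer}\n+\n{'I' * sigs[1].k}\n")
        table = count_footprints([a, b], sigs)
        assert table.counts[sigs[0].label] == 1
        assert table.counts[sigs[1].label] == 1


class TestAbundance:
    def test_direct_formula(self):
        table = CountTable(counts={"A": 30, "B": 10, "C": 0}, n_reads_scanned=100)
        ab = relative_abundance(table)
        assert ab.freq == {"A": 0.75, "B": 0.25, "C": 0.0}

    def test_locked_population_pattern(self):
        table = CountTable(counts={"D": 17, "A": 0}, n_reads_scanned=17)
        assert relative_abundance(table).freq["D"] == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.dictionaries(st.sampled_from("ABCD"), st.integers(0, 1000), min_size=2),
        st.integers(2, 10),
    )
    def test_scale_invariance(self, counts, factor):
        if sum(counts.values()) == 0:
            counts["A"] = 1
        t1 = CountTable(counts=counts, n_reads_scanned=sum(counts.values()))
        scaled = {k: v * factor for k, v in counts.items()}
        t2 = CountTable(counts=scaled, n_reads_scanned=sum(scaled.values()))
        assert relative_abundance(t1).freq == pytest.approx(relative_abundance(t2).freq)

    def test_sums_to_one(self):
        table = CountTable(counts={"A": 3, "B": 7, "C": 11}, n_reads_scanned=30)
        assert sum(relative_abundance(table).freq.values()) == pytest.approx(1.0, abs=1e-12)


class TestEnrichment:
    def test_identical_tables_zero(self):
        ab = AbundanceTable(freq={"A": 0.25, "B": 0.75}, total_positive=100)
        res = enrichment(ab, ab, pseudocount=0.01)
        assert all(v == 0 for v in res.log2fc.values())

    def test_concentrated_variant_maximal(self):
        donor = AbundanceTable(freq={v: 0.125 for v in "ABCDEFGH"}, total_positive=800)
        trans = AbundanceTable(
            freq={v: (1.0 if v == "C" else 0.0) for v in "ABCDEFGH"}, total_positive=800
        )
        res = enrichment(donor, trans)
        assert max(res.log2fc, key=res.log2fc.get) == "C"

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
        st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    )
    def test_antisymmetry(self, w1, w2):
        d = AbundanceTable(freq={k: v / sum(w1) for k, v in zip("ABC", w1)}, total_positive=100)
        t = AbundanceTable(freq={k: v / sum(w2) for k, v in zip("ABC", w2)}, total_positive=100)
        fwd = enrichment(d, t, pseudocount=0.01).log2fc
        rev = enrichment(t, d, pseudocount=0.01).log2fc
        for v in "ABC":
            assert fwd[v] == pytest.approx(-rev[v])

    def test_nonpositive_pseudocount_rejected(self):
        ab = AbundanceTable(freq={"A": 1.0}, total_positive=10)
        with pytest.raises(ValueError):
            enrichment(ab, ab, pseudocount=0.0)


class TestConjugationFrequency:
    def test_simple_ratio(self):
        res = conjugation_frequency(10, 1e6)
        assert res.value == pytest.approx(1e-5)
        assert not res.censored

    def test_zero_transconjugants_censored_at_lod(self):
        res = conjugation_frequency(0, 1e6, lod=1e-8)
        assert res.value == 1e-8
        assert res.censored

    def test_below_lod_censored(self):
        res = conjugation_frequency(1, 1e9, lod=1e-8)
        assert res.value == 1e-8
        assert res.censored

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(1, 1e6), st.floats(1e3, 1e9), st.floats(1.5, 1e4))
    def test_scale_invariance(self, t, r, scale):
        a = conjugation_frequency(t, r)
        b = conjugation_frequency(t * scale, r * scale)
        assert a.value == pytest.approx(b.value)
        assert a.censored == b.censored

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            conjugation_frequency(-1, 100)


def test_signature_fasta_roundtrip(locus, tmp_path):
    from shufflon.cli import _read_signature_fasta

    sigs = make_signatures(locus)
    path = tmp_path / "sigs.fasta"
    signatures_to_fasta(sigs, path)
    back = _read_signature_fasta(path)
    assert [(s.label, s.kmer, s.c) for s in back] == [(s.label, s.kmer, s.c) for s in sigs]
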