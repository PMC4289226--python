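"""Assembly: seed extension, reference consensus, deduplication,
clustering, chimera screening, annotation and naming."""

import dataclasses

import numpy as np
import pytest

from venomforge import assembly, seqsim
from venomforge.assembly import (
    ReferenceProtein,
    Transcript,
    annotate_and_name,
    cluster_toxins,
    deduplicate,
    detect_chimeras,
    extend_seed,
    pairwise_divergence,
    reference_consensus,
)
from venomforge.codons import reverse_complement


def _random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _tile_reads(seq, read_len=151, step=10, q=35):
    starts = list(range(0, len(seq) - read_len + 1, step))
    if starts[-1] != len(seq) - read_len:
        starts.append(len(seq) - read_len)  # cover the 3' end
    return [
        type("R", (), {"sequence": seq[s : s + read_len], "quality": [q] * read_len})()
        for s in starts
    ]


class TestExtendSeed:
    def test_no_overlapping_reads_returns_seed(self, rng):
        seed = _random_seq(rng, 200)
        reads = [_random_seq(rng, 151) for _ in range(10)]
        assert extend_seed(seed, reads) == seed

    def test_planted_transcript_recovered_exactly(self, rng):
        transcript = _random_seq(rng, 600)
        reads = _tile_reads(transcript)
        centre = len(reads) // 2
        seed = reads[centre].sequence
        contig = extend_seed(seed, reads)
        assert contig == transcript
        assert seed in contig

    def test_99_nt_exact_overlap_not_used(self, rng):
        seed = _random_seq(rng, 200)
        # a read overlapping the 3' end by exactly 99 nt
        read = seed[-99:] + _random_seq(rng, 52)
        assert extend_seed(seed, [read], min_overlap=100) == seed
        # ...and with 100 nt it is
        read100 = seed[-100:] + _random_seq(rng, 51)
        assert extend_seed(seed, [read100], min_overlap=100).endswith(read100)

    def test_low_quality_reads_excluded(self, rng):
        seed = _random_seq(rng, 200)
        ext = seed[-120:] + _random_seq(rng, 31)
        bad = type("R", (), {"sequence": ext, "quality": [29] + [35] * 150})()
        good = type("R", (), {"sequence": ext, "quality": [35] * 151})()
        assert extend_seed(seed, [bad]) == seed
        assert extend_seed(seed, [good]) != seed

    def test_short_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            extend_seed(_random_seq(rng, 50), [], min_overlap=100)


class TestReferenceConsensus:
    def _reference(self, rng, utr5=60, cds_codons=60, utr3=60):
        cds = "ATG" + "".join(
            seqsim.SENSE_CODONS[i] for i in rng.integers(0, 61, cds_codons - 2)
        ) + "TAA"
        seq = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
        return Transcript(
            id="ref1", sequence=seq, cds_span=(utr5, utr5 + 3 * cds_codons)
        )

    def test_uniform_coverage_reproduces_reference(self, rng):
        ref = self._reference(rng)
        reads = _tile_reads(ref.sequence, read_len=120, step=10)
        # pad the terminal ramps so depth >= 5 over the full length
        reads += [reads[0]] * 5 + [reads[-1]] * 5
        out = reference_consensus(reads, [ref], min_coverage=5)
        assert len(out) == 1
        assert out[0].sequence == ref.sequence
        assert out[0].cds == ref.cds

    def test_low_coverage_utr_flanks_trimmed(self, rng):
        ref = self._reference(rng)
        reads = _tile_reads(ref.sequence, read_len=120, step=10)
        out = reference_consensus(reads, [ref], min_coverage=5)
        assert len(out) == 1
        # CDS intact, shallow UTR ends removed
        assert out[0].cds == ref.cds
        assert out[0].sequence in ref.sequence
        assert len(out[0].sequence) < len(ref.sequence)

    def test_low_cds_coverage_drops_reference(self, rng):
        ref = self._reference(rng)
        lo, hi = ref.cds_span
        # reads covering only the first half of the CDS
        reads = _tile_reads(ref.sequence[: (lo + hi) // 2], read_len=100, step=5)
        out = reference_consensus(reads, [ref], min_coverage=5)
        assert out == []

    def test_homozygous_substitution_enters_consensus(self, rng):
        ref = self._reference(rng)
        lo, _ = ref.cds_span
        pos = lo + 30
        variant = (
            ref.sequence[:pos]
            + ("A" if ref.sequence[pos] != "A" else "C")
            + ref.sequence[pos + 1 :]
        )
        reads = _tile_reads(variant, read_len=120, step=6)
        out = reference_consensus(reads, [ref], min_coverage=5)
        assert len(out) == 1
        lo_ref, hi_ref = ref.cds_span
        assert out[0].cds == variant[lo_ref:hi_ref]
        assert out[0].cds != ref.cds

    def test_reference_without_cds_span_rejected(self, rng):
        ref = Transcript(id="x", sequence=_random_seq(rng, 100), cds_span=None)
        with pytest.raises(ValueError):
            reference_consensus([], [ref])


class TestDeduplicate:
    def _t(self, tid, seq, span=None):
        return Transcript(id=tid, sequence=seq, cds_span=span or (0, len(seq)))

    def test_identical_transcripts_collapse(self, rng):
        seq = _random_seq(rng, 300)
        out = deduplicate([self._t("a", seq), self._t("b", seq)])
        assert len(out) == 1

    def test_contained_cds_collapses_into_longer(self, rng):
        long_seq = _random_seq(rng, 600)
        short = self._t("short", long_seq[100:400])
        longer = self._t("long", long_seq)
        out = deduplicate([short, longer])
        assert [t.id for t in out] == ["long"]

    def test_disjoint_sequences_both_kept(self, rng):
        out = deduplicate(
            [self._t("a", _random_seq(rng, 300)), self._t("b", _random_seq(rng, 300))]
        )
        assert len(out) == 2


class TestClusterToxins:
    def _toxin(self, tid, cds, abundance=0.0):
        return Transcript(
            id=tid,
            sequence=cds,
            cds_span=(0, len(cds)),
            class_label="3FTx",
            abundance=abundance,
        )

    def test_identical_sequences_form_one_cluster(self, rng):
        cds = _random_seq(rng, 300)
        clusters = cluster_toxins([self._toxin(f"t{i}", cds) for i in range(4)])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_single_linkage_chains_through_intermediate(self, rng):
        base = list(_random_seq(rng, 300))
        a = "".join(base)
        b_l = list(base)
        b_l[10] = "A" if base[10] != "A" else "C"
        b_l[20] = "A" if base[20] != "A" else "C"
        b = "".join(b_l)
        c_l = list(b_l)
        c_l[40] = "A" if b_l[40] != "A" else "C"
        c_l[50] = "A" if b_l[50] != "A" else "C"
        c = "".join(c_l)
        # A-B and B-C at 2/300 (0.67%); A-C at 4/300 (1.33%)
        assert pairwise_divergence(a, c) > 0.01
        clusters = cluster_toxins(
            [self._toxin("A", a), self._toxin("B", b), self._toxin("C", c)]
        )
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_empty_input_gives_empty_output(self):
        assert cluster_toxins([]) == []

    def test_partition_and_naming_by_abundance(self, rng):
        c1 = _random_seq(rng, 300)
        c2 = _random_seq(rng, 300)
        ts = [
            self._toxin("x", c1, abundance=1.0),
            self._toxin("y", c1, abundance=3.0),
            self._toxin("z", c2, abundance=10.0),
        ]
        clusters = cluster_toxins(ts)
        assert [c.name for c in clusters] == ["3FTx-1", "3FTx-2"]
        assert clusters[0].members == ["3FTx-1"]  # singleton: no letter
        assert clusters[1].members == ["3FTx-2a", "3FTx-2b"]
        assert clusters[1].member_sources["3FTx-2a"] == "y"  # most abundant
        named = {m for c in clusters for m in c.members}
        assert len(named) == 3  # every toxin in exactly one cluster

    def test_planted_clusters_recovered_from_truth(self, small_truth, small_config):
        sp = small_config.species[0]
        toxins = [
            Transcript(
                id=t.id,
                sequence=t.cds,
                cds_span=(0, len(t.cds)),
                class_label=t.class_label,
                abundance=t.expression_weight,
            )
            for t in small_truth.transcripts[sp]
            if t.is_toxin
        ]
        clusters = cluster_toxins(toxins)
        true_partition = {}
        for t in small_truth.transcripts[sp]:
            if t.is_toxin:
                true_partition.setdefault(t.cluster_id, set()).add(t.id)
        found_partition = [
            set(c.member_sources.values()) for c in clusters
        ]
        matched = sum(
            1 for members in true_partition.values() if members in found_partition
        )
        assert matched >= 0.95 * len(true_partition)


class TestDetectChimeras:
    def test_genuine_transcript_not_flagged(self, rng):
        seq = _random_seq(rng, 500)
        other = _random_seq(rng, 500)
        db = [
            Transcript(id="self", sequence=seq, cds_span=(0, len(seq))),
            Transcript(id="o1", sequence=other, cds_span=(0, len(other))),
            Transcript(id="o2", sequence=_random_seq(rng, 500), cds_span=(0, 500)),
        ]
        reads = _tile_reads(seq, read_len=151, step=15)
        verdicts = detect_chimeras([db[0]], reads, db)
        assert not verdicts[0].is_chimera

    def test_constructed_fusion_flagged_with_parents(self, rng):
        x = _random_seq(rng, 600)
        y = _random_seq(rng, 600)
        fusion = x[:300] + y[300:]
        db = [
            Transcript(id="X", sequence=x, cds_span=(0, 600)),
            Transcript(id="Y", sequence=y, cds_span=(0, 600)),
            Transcript(id="F", sequence=fusion, cds_span=(0, 600)),
        ]
        reads = _tile_reads(x, step=20) + _tile_reads(y, step=20)
        verdicts = detect_chimeras(
            [db[2]], reads, db
        )
        v = verdicts[0]
        assert v.is_chimera
        assert {p for p, _ in v.parents} == {"X", "Y"}
        assert abs(v.breakpoint - 300) <= 60

    def test_low_but_even_coverage_not_flagged(self, rng):
        seq = _random_seq(rng, 500)
        db = [
            Transcript(id="self", sequence=seq, cds_span=(0, 500)),
            Transcript(id="o1", sequence=_random_seq(rng, 500), cds_span=(0, 500)),
            Transcript(id="o2", sequence=_random_seq(rng, 500), cds_span=(0, 500)),
        ]
        reads = _tile_reads(seq, read_len=151, step=75)  # ~2x depth
        v = detect_chimeras([db[0]], reads, db)[0]
        assert not v.is_chimera
        assert v.evenness > 0.5


class TestAnnotateAndName:
    def test_reference_identity_assigns_class_and_cluster_names(self, small_truth, small_config):
        sp = small_config.species[0]
        transcripts = [
            Transcript(
                id=f"contig{i}",
                sequence=t.cds,
                cds_span=(0, len(t.cds)),
                abundance=t.expression_weight,
            )
            for i, t in enumerate(small_truth.transcripts[sp])
        ]
        refs = [
            ReferenceProtein(
                id=t.id,
                sequence=t.mature_protein(),
                description=f"{t.class_label} venom toxin",
                class_label=t.class_label,
            )
            for t in small_truth.transcripts[sp]
            if t.is_toxin
        ]
        annotated, clusters = annotate_and_name(transcripts, refs)
        true_by_cds = {
            t.cds: t for t in small_truth.transcripts[sp]
        }
        n_toxins_true = sum(t.is_toxin for t in small_truth.transcripts[sp])
        n_toxins_found = sum(t.class_label != "nontoxin" for t in annotated)
        assert n_toxins_found == n_toxins_true
        for t in annotated:
            truth_t = true_by_cds[t.cds]
            assert t.class_label == truth_t.class_label
        # multi-member clusters get letter suffixes
        multi = [c for c in clusters if len(c.members) > 1]
        assert multi
        for c in multi:
            assert c.members[0].endswith("a")
            assert c.members[1].endswith("b")

    def test_random_sequence_is_nontoxin(self, rng):
        cds = "ATG" + "".join(
            seqsim.SENSE_CODONS[i] for i in rng.integers(0, 61, 80)
        ) + "TAA"
        refs = [
            ReferenceProtein("r", "MKTLLLTLVVVTIVCLDLGYT" * 4, "3FTx venom toxin", "3FTx")
        ]
        t = Transcript(id="q", sequence=cds, cds_span=(0, len(cds)))
        annotated, _ = annotate_and_name([t], refs, score_threshold=120.0)
        assert annotated[0].class_label == "nontoxin"
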