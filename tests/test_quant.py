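"""Read mapping to CDS databases and expression-table construction."""

import dataclasses

import numpy as np
import pytest

from venomforge import quant, seqsim, tables
from venomforge.quant import (
    CdsEntry,
    MappingResult,
    abundance_table,
    class_summary,
    map_reads_to_cds,
)


def _entry(name, seq, cluster=None, class_label="3FTx", member="a"):
    return CdsEntry(
        name=name,
        sequence=seq,
        cluster=cluster or name,
        class_label=class_label,
        member=member,
    )


def _reads_from(seq, n, length=130, rng=None):
    rng = rng or np.random.default_rng(0)
    starts = rng.integers(0, max(1, len(seq) - length + 1), n)
    return [seq[s : s + length] for s in starts]


class TestMapReads:
    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            map_reads_to_cds(["ACGT"], [])

    def test_all_reads_map_to_single_cds(self, rng):
        cds = "".join("ACGT"[b] for b in rng.integers(0, 4, 600))
        other = "".join("ACGT"[b] for b in rng.integers(0, 4, 600))
        db = [_entry("t1", cds), _entry("t2", other)]
        result = map_reads_to_cds(_reads_from(cds, 50, rng=rng), db)
        assert result.n_mapped == 50
        assert result.cluster_counts == {"t1": 50}

    def test_identity_boundary_at_95_percent(self, rng):
        cds = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        db = [_entry("t1", cds)]
        read = list(cds[100:251])  # 151 nt
        for i in range(0, 9):  # 9 mismatches -> 94.0% identity
            pos = i * 15
            read[pos] = "A" if read[pos] != "A" else "C"
        bad_read = "".join(read)
        result = map_reads_to_cds([bad_read], db, min_identity=0.95)
        assert result.n_mapped == 0
        read7 = list(cds[100:251])
        for i in range(0, 7):  # 7 mismatches -> 95.4% identity
            pos = i * 15
            read7[pos] = "A" if read7[pos] != "A" else "C"
        result = map_reads_to_cds(["".join(read7)], db, min_identity=0.95)
        assert result.n_mapped == 1

    def test_mapped_fractions_track_known_weights(self):
        # three transcripts at weights 0.5/0.3/0.2; error-free reads
        rng = np.random.default_rng(11)
        cfg = seqsim.SimulationConfig(
            seed=11,
            error_rate=0.0,
            chimera_rate=0.0,
            unspliced_rate=0.0,
            n_read_pairs=0,
        )
        ts = []
        for i, w in enumerate((0.5, 0.3, 0.2)):
            body = "".join(
                seqsim.SENSE_CODONS[j] for j in rng.integers(0, 61, 180)
            )
            ts.append(
                seqsim.TranscriptTruth(
                    id=f"T{i}",
                    cds="ATG" + body + "TAA",
                    utr5="",
                    utr3="",
                    class_label="3FTx",
                    cluster_id=f"T{i}",
                    expression_weight=w,
                )
            )
        truth = seqsim.SyntheticTruth(
            cfg, {"speciesA": ts, "speciesB": []}, [], {}
        )
        cfg = dataclasses.replace(cfg, n_read_pairs=20000)
        reads = seqsim.simulate_reads(truth, cfg, species="speciesA")
        db = [_entry(t.id, t.cds) for t in ts]
        merged = [p.read1 for p in reads]  # error-free read 1 == insert head
        result = map_reads_to_cds(merged, db, seed=5)
        n = result.n_mapped
        for t, w in zip(ts, (0.5, 0.3, 0.2)):
            got = result.cluster_counts[t.id]
            sd = np.sqrt(len(reads) * w * (1 - w))
            assert abs(got - n * w) < 3 * sd + (len(reads) - n)


class TestAbundanceTable:
    def _result(self, counts, depths, classes):
        meta = {
            cl: {
                "cluster_size": 1,
                "cds_length": len(depths[cl]),
                "class_label": classes[cl],
                "representative": cl,
            }
            for cl in counts
        }
        return MappingResult(
            cluster_counts=counts,
            depths={k: np.array(v, dtype=float) for k, v in depths.items()},
            cluster_meta=meta,
            n_mapped=sum(counts.values()),
            n_reads=sum(counts.values()),
            seed=0,
        )

    def test_single_toxin_cluster_row_is_100_100(self):
        res = self._result({"T": 10}, {"T": [1] * 30}, {"T": "3FTx"})
        rows = abundance_table(res)
        assert rows[0].pct_toxin_reads == pytest.approx(100.0)
        assert rows[0].pct_total_reads == pytest.approx(100.0)

    def test_median_coverage_is_positional_median(self):
        res = self._result({"T": 5}, {"T": [1, 2, 3, 4, 100]}, {"T": "3FTx"})
        rows = abundance_table(res)
        scale = 10_000_000 / 5
        assert rows[0].median_coverage == pytest.approx(3 * scale)

    def test_toxin_total_ratio_constant_across_rows(self):
        res = self._result(
            {"A": 50, "B": 30, "N": 120},
            {"A": [5] * 10, "B": [3] * 10, "N": [2] * 10},
            {"A": "3FTx", "B": "SVMPIII", "N": "nontoxin"},
        )
        rows = abundance_table(res)
        ratios = {
            round(r.pct_total_reads / r.pct_toxin_reads, 9) for r in rows
        }
        assert len(ratios) == 1
        assert sum(r.pct_toxin_reads for r in rows) == pytest.approx(100.0, abs=0.05)
        assert rows[0].rank == 1 and rows[0].pct_toxin_reads >= rows[1].pct_toxin_reads

    def test_zero_mapped_reads_warns_and_empties(self):
        res = self._result({}, {}, {})
        with pytest.warns(UserWarning):
            assert abundance_table(res) == []


class TestClassSummary:
    def test_single_class_takes_full_share(self):
        res = TestAbundanceTable()._result(
            {"A": 10, "B": 10}, {"A": [1] * 9, "B": [1] * 9}, {"A": "3FTx", "B": "3FTx"}
        )
        per_class, toxin_total = class_summary(
            abundance_table(res), class_of_cluster={"A": "3FTx", "B": "3FTx"}
        )
        assert per_class["3FTx"]["pct_toxin_reads"] == pytest.approx(100.0)
        assert per_class["3FTx"]["n_clusters"] == 2

    def test_unknown_class_grouped_as_other_with_warning(self):
        rows = tables.load_toxin_expression("boiga")[:2]
        with pytest.warns(UserWarning):
            per_class, _ = class_summary(rows, class_of_cluster={})
        assert per_class["other"]["n_clusters"] == 2

    def test_published_tables_internally_consistent(self):
        # each printed table's % columns keep one toxin/total ratio
        for species in ("boiga", "hypsiglena"):
            rows = tables.load_toxin_expression(species)
            ratios = [
                r.pct_total_reads / r.pct_toxin_reads
                for r in rows
                if r.pct_toxin_reads >= 0.1  # printed rounding dominates below
            ]
            assert max(ratios) - min(ratios) < 0.02
            assert sum(r.pct_toxin_reads for r in rows) == pytest.approx(
                100.0, abs=0.05
            )


class TestEndToEndQuantification:
    def test_cluster_counts_match_read_provenance(self, small_truth, small_config):
        """Mapped counts per cluster agree with the ground-truth record of
        which reads actually overlap each coding sequence."""
        cfg = dataclasses.replace(
            small_config,
            error_rate=0.0,
            adapter="",
            chimera_rate=0.0,
            unspliced_rate=0.0,
            n_read_pairs=4000,
        )
        sp = cfg.species[0]
        reads = seqsim.simulate_reads(small_truth, cfg)
        by_id = small_truth.by_id(sp)
        db = [
            _entry(
                t.id,
                t.cds,
                cluster=t.cluster_id or t.id,
                class_label=t.class_label,
            )
            for t in small_truth.transcripts[sp]
        ]
        merged = [p.read1 for p in reads]
        result = map_reads_to_cds(merged, db, seed=3)
        expected: dict[str, int] = {}
        for p in reads:
            t = by_id[p.source_id]
            cds_lo = len(t.utr5)
            cds_hi = cds_lo + len(t.cds)
            read_end = p.insert_start + min(len(p.read1), p.insert_length)
            overlap = min(read_end, cds_hi) - max(p.insert_start, cds_lo)
            if overlap >= quant.MIN_END_OVERLAP:
                key = t.cluster_id or t.id
                expected[key] = expected.get(key, 0) + 1
        total_expected = sum(expected.values())
        assert result.n_mapped == pytest.approx(total_expected, rel=0.02)
        for cl, n_exp in expected.items():
            got = result.cluster_counts.get(cl, 0)
            assert got == pytest.approx(n_exp, rel=0.05, abs=5)

    def test_toxin_share_of_cds_reads_tracks_truth(self, small_truth, small_config):
        """The toxin percentage of CDS-mapped reads matches the share
        predicted from expression weights restricted to CDS-overlapping
        inserts."""
        cfg = dataclasses.replace(
            small_config,
            error_rate=0.0,
            adapter="",
            chimera_rate=0.0,
            unspliced_rate=0.0,
            n_read_pairs=4000,
        )
        sp = cfg.species[0]
        reads = seqsim.simulate_reads(small_truth, cfg)
        by_id = small_truth.by_id(sp)
        db = [
            _entry(
                t.id,
                t.cds,
                cluster=t.cluster_id or t.id,
                class_label=t.class_label,
            )
            for t in small_truth.transcripts[sp]
        ]
        result = map_reads_to_cds([p.read1 for p in reads], db, seed=3)
        table = abundance_table(result)
        _, toxin_total = class_summary(
            table,
            class_of_cluster={
                (t.cluster_id or t.id) + ("a" if r_size(small_truth, sp, t) > 1 else ""): t.class_label
                for t in small_truth.transcripts[sp]
            },
        )
        n_tox = n_all = 0
        for p in reads:
            t = by_id[p.source_id]
            cds_lo = len(t.utr5)
            read_end = p.insert_start + min(len(p.read1), p.insert_length)
            overlap = min(read_end, cds_lo + len(t.cds)) - max(
                p.insert_start, cds_lo
            )
            if overlap >= quant.MIN_END_OVERLAP:
                n_all += 1
                n_tox += t.is_toxin
        expected_pct = 100.0 * n_tox / n_all
        assert toxin_total == pytest.approx(expected_pct, abs=2.0)


def r_size(truth, sp, t):
    return sum(
        1 for u in truth.transcripts[sp] if u.cluster_id == t.cluster_id
    ) if t.cluster_id else 1
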