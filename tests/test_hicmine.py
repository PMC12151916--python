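"""Tandem repeat counting, read classification, contact extraction and
recurrence aggregation."""

import dataclasses
import warnings

import numpy as np
import pytest

from telomir import hicmine, synth
from telomir.hicmine import (
    PairRecord,
    aggregate_recurrent,
    classify_read,
    count_tandem_units,
    expand_anchor,
    extract_telomeric_contacts,
    revcomp,
)

UNIT = "TTAGGG"


def brute_force_max_run(seq: str, unit: str) -> tuple[int, str]:
    """Longest tandem unit run over both orientations, by direct scanning."""
    best, ori = 0, "forward"
    for pattern, label in ((unit, "forward"), (revcomp(unit), "reverse")):
        k = len(pattern)
        for i in range(len(seq)):
            run = 0
            j = i
            while seq[j : j + k] == pattern:
                run += 1
                j += k
            if run > best:
                best, ori = run, label
    return best, ori


def random_read(rng, length=75):
    bases = "ACGT"
    return "".join(bases[i] for i in rng.integers(0, 4, length))


class TestCountTandemUnits:
    def test_pure_forward_array(self):
        call = count_tandem_units(UNIT * 7)
        assert call.max_tandem_units == 7
        assert call.unit_orientation == "forward"

    def test_reverse_array_in_random_flanks(self):
        rng = np.random.default_rng(0)
        seq = random_read(rng, 20) + "CCCTAA" * 10 + random_read(rng, 20)
        call = count_tandem_units(seq)
        assert call.max_tandem_units == 10
        assert call.unit_orientation == "reverse"

    def test_oracle_equivalence_on_random_reads(self):
        rng = np.random.default_rng(42)
        for i in range(500):
            seq = random_read(rng)
            if i % 3 == 0:  # plant a run so nonzero cases are exercised
                n = int(rng.integers(1, 10))
                pos = int(rng.integers(0, 75 - 6 * min(n, 12) + 1)) if 6 * n <= 75 else 0
                unit = UNIT if rng.random() < 0.5 else revcomp(UNIT)
                seq = (seq[:pos] + unit * n + seq[pos + 6 * n :])[:75]
            expected, _ = brute_force_max_run(seq, UNIT)
            call = count_tandem_units(seq)
            assert call.max_tandem_units == expected, seq
            assert call.total_units >= call.max_tandem_units
            assert call.total_units <= len(seq) // 6

    def test_mismatch_tolerance_counts_degenerate_units(self):
        seq = "TTAGGG" + "TTAGGA" + "TTAGGG" * 5
        assert count_tandem_units(seq).max_tandem_units == 5
        assert count_tandem_units(seq, max_mismatch_per_unit=1).max_tandem_units == 7

    def test_empty_and_invalid_sequences(self):
        assert count_tandem_units("").max_tandem_units == 0
        with pytest.raises(ValueError):
            count_tandem_units("TTAGGG-TTAGGG")
        assert count_tandem_units("TTANGG" * 3).max_tandem_units == 0


class TestClassify:
    @pytest.mark.parametrize(
        "units,expected",
        [(0, "non_telomeric"), (6, "non_telomeric"), (7, "telomeric"), (12, "telomeric")],
    )
    def test_seven_unit_threshold(self, units, expected):
        call = hicmine.RepeatCall("r", units, "forward", units)
        assert classify_read(call) == expected

    def test_min_units_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_read(hicmine.RepeatCall("r", 3, "forward", 3), min_units=0)


class TestExpandAnchor:
    def test_symmetric_pad(self):
        assert expand_anchor(("chr1", 1000, 1150)) == ("chr1", 900, 1250)

    def test_clipping_at_chromosome_start_and_end(self):
        assert expand_anchor(("chr1", 50, 150), 100, {"chr1": 10_000}) == ("chr1", 0, 250)
        assert expand_anchor(("chr1", 9_900, 9_990), 100, {"chr1": 10_000}) == (
            "chr1",
            9_800,
            10_000,
        )

    def test_zero_pad_is_identity(self):
        assert expand_anchor(("chr1", 10, 20), 0) == ("chr1", 10, 20)


def _pair(rid, seq1, seq2, chrom1="chr1", pos1=100, chrom2="chr1", pos2=50_000,
          mapq1=60, mapq2=60):
    return PairRecord(rid, chrom1, pos1, chrom2, pos2, "+", "-", seq1, seq2, mapq1, mapq2)


class TestExtraction:
    TELO = [("chr1", 0, 3000), ("chr1", 97_000, 100_000)]
    ITS = [("chr1", 60_000, 60_060, 10), ("chr1", 70_000, 70_030, 5)]

    def test_planted_contacts_recovered_exactly(self, genome, default_config, tmp_path):
        cfg = dataclasses.replace(default_config, contacts_per_run=0, n_hic_runs=1,
                                  planted_recurrence=1)
        truth = synth.generate_hic_runs(genome, cfg, str(tmp_path))
        records = hicmine.read_pairs(
            str(tmp_path / "run_00.pairs"), str(tmp_path / "run_00.seqs.tsv")
        )
        contacts, tally = extract_telomeric_contacts(
            records, "run_00", genome.telomere_intervals, genome.its_intervals
        )
        planted_here = truth[truth["runs"].str.contains("run_00")]
        assert len(contacts) == len(planted_here) == tally["kept"]
        for _, site in planted_here.iterrows():
            assert any(
                c.anchor_chrom == site["chrom"]
                and c.anchor_start < site["end"]
                and site["start"] < c.anchor_end
                for c in contacts
            )

    def test_non_telomeric_pair_yields_nothing(self):
        rng = np.random.default_rng(1)
        rec = _pair("r1", random_read(rng, 80), random_read(rng, 80))
        contacts, tally = extract_telomeric_contacts([rec], "run", self.TELO)
        assert contacts == [] and tally["no_telomeric_mate"] == 1

    def test_telo_telo_pair_dropped_and_tallied(self):
        rec = _pair("r1", UNIT * 12, "CCCTAA" * 12)
        contacts, tally = extract_telomeric_contacts([rec], "run", self.TELO)
        assert contacts == [] and tally["telo_telo"] == 1

    def test_anchor_inside_big_its_discarded(self):
        rng = np.random.default_rng(2)
        rec = _pair("r1", UNIT * 12, random_read(rng, 80), pos2=60_010)
        contacts, tally = extract_telomeric_contacts(
            [rec], "run", self.TELO, self.ITS
        )
        assert contacts == [] and tally["anchor_in_its"] == 1
        # the same anchor passes when the ITS discard rule is off
        contacts2, _ = extract_telomeric_contacts(
            [rec], "run", self.TELO, self.ITS, discard_its_anchors=False
        )
        assert len(contacts2) == 1

    def test_small_its_does_not_block_anchor(self):
        rng = np.random.default_rng(3)
        rec = _pair("r1", UNIT * 12, random_read(rng, 80), pos2=70_005)
        contacts, _ = extract_telomeric_contacts([rec], "run", self.TELO, self.ITS)
        assert len(contacts) == 1

    def test_low_mapq_anchor_dropped(self):
        rng = np.random.default_rng(4)
        rec = _pair("r1", UNIT * 12, random_read(rng, 80), mapq2=5)
        contacts, tally = extract_telomeric_contacts([rec], "run", self.TELO)
        assert contacts == [] and tally["low_mapq"] == 1


class TestAggregation:
    def _contact(self, run, chrom="chr1", start=10_000, end=10_080):
        call = hicmine.RepeatCall("r", 10, "forward", 10)
        return hicmine.ContactRecord(run, call, chrom, start, end, 60)

    SIZES = {"chr1": 100_000}

    def test_nearby_anchors_merge_and_pool_runs(self):
        contacts = [
            self._contact("run_00", start=10_000, end=10_080),
            self._contact("run_01", start=10_050, end=10_130),
        ]
        out = aggregate_recurrent(contacts, self.SIZES, pad_bp=100, min_runs=2)
        assert len(out) == 1
        assert out[0].supporting_runs == {"run_00", "run_01"}
        assert (out[0].start, out[0].end) == (9_900, 10_230)

    def test_min_runs_monotonicity(self):
        contacts = [
            self._contact("run_00"),
            self._contact("run_01"),
            self._contact("run_02", start=50_000, end=50_080),
        ]
        n1 = len(aggregate_recurrent(contacts, self.SIZES, min_runs=1))
        n2 = len(aggregate_recurrent(contacts, self.SIZES, min_runs=2))
        n3 = len(aggregate_recurrent(contacts, self.SIZES, min_runs=3))
        assert n1 >= n2 >= n3
        assert (n1, n2) == (2, 1)

    def test_min_runs_above_available_warns_and_empties(self):
        with pytest.warns(UserWarning, match="min_runs"):
            out = aggregate_recurrent(
                [self._contact("run_00")], self.SIZES, min_runs=5
            )
        assert out == []

    def test_nearest_end_annotation(self):
        out = aggregate_recurrent(
            [self._contact("run_00"), self._contact("run_01")],
            self.SIZES,
            min_runs=2,
        )
        assert out[0].nearest_end == "chr1_p"
        # merged padded window is [9900, 10180): midpoint 10040
        assert out[0].distance_to_nearest_end_bp == 10_040


class TestSamInput:
    def test_sam_pairs_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        anchor_seq = random_read(rng, 60)
        sam = tmp_path / "mini.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:100000\n"
            f"p1\t73\tchr1\t101\t0\t60M\t=\t50001\t0\t{UNIT * 10}\t*\n"
            f"p1\t133\tchr1\t50001\t60\t60M\t=\t101\t0\t{anchor_seq}\t*\n"
        )
        records = list(hicmine.read_pairs_from_sam(str(sam)))
        assert len(records) == 1
        rec = records[0]
        assert rec.pos1 == 100 and rec.pos2 == 50_000
        contacts, _ = extract_telomeric_contacts(
            [rec], "sam_run", [("chr1", 0, 3000)]
        )
        assert len(contacts) == 1
        assert contacts[0].anchor_start == 50_000


class TestNoiseDegradation:
    def test_precision_degrades_monotonically_with_telomeric_noise(self, tmp_path):
        """Recurrence filtering is perfect without one-off telomeric noise
        and loses precision monotonically as that noise rate rises."""
        import tempfile
        from telomir.io import overlaps

        cfg0 = synth.SimulationConfig(
            seed=31, n_hic_runs=8, planted_recurrence=8, contacts_per_run=200
        )
        genome = synth.generate_genome(cfg0)
        precisions = []
        for frac in (0.0, 0.2, 0.6):
            cfg = dataclasses.replace(cfg0, noise_telomeric_fraction=frac)
            out = tmp_path / f"noise_{frac}"
            truth = synth.generate_hic_runs(genome, cfg, str(out))
            contacts = []
            for r in range(cfg.n_hic_runs):
                rid = f"run_{r:02d}"
                records = hicmine.read_pairs(
                    str(out / f"{rid}.pairs"), str(out / f"{rid}.seqs.tsv")
                )
                cs, _ = extract_telomeric_contacts(
                    records, rid, genome.telomere_intervals, genome.its_intervals
                )
                contacts.extend(cs)
            inter = aggregate_recurrent(contacts, genome.chrom_sizes, min_runs=2)
            expected = [
                (t["chrom"], int(t["start"]), int(t["end"]))
                for _, t in truth.iterrows()
            ]
            correct = sum(
                any(
                    m.chrom == c and overlaps(m.start, m.end, s, e)
                    for c, s, e in expected
                )
                for m in inter
            )
            precisions.append(correct / len(inter))
        assert precisions[0] == 1.0
        assert precisions[0] >= precisions[1] >= precisions[2]
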