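"""Cut calling: strand inversion, profiles, polar export, hotspots."""

import numpy as np
import pytest

from nickscope import (
    BOTTOM,
    TOP,
    CutEvent,
    CutProfile,
    NickEvent,
    NickModel,
    aggregate_profile,
    align_reads,
    build_index,
    call_cut,
    call_cuts,
    export_polar,
    hotspots,
    make_plasmid,
    read_profile_tsv,
    sample_nicks,
    simulate_gloeseq_reads,
    write_profile_tsv,
)
from nickscope.circular import ReadAlignment
from nickscope.cutcalling import STRAND_INVERSION


def _aln(strand, start, status="unique", placements=None):
    placements = placements or ((strand, start),)
    return ReadAlignment("r", strand, start, 0, status, tuple(placements))


class TestCallCut:
    def test_plus_read_reports_bottom_cut(self):
        assert call_cut(_aln("plus", 100)) == CutEvent(100, BOTTOM)

    def test_minus_read_reports_top_cut(self):
        assert call_cut(_aln("minus", 7)) == CutEvent(7, TOP)

    def test_inversion_is_involution(self):
        back = {"top": "minus", "bottom": "plus"}
        for aln_strand, cut_strand in STRAND_INVERSION.items():
            assert back[cut_strand] == aln_strand
            assert STRAND_INVERSION[back[cut_strand]] == cut_strand

    def test_unmapped_read_yields_no_cut(self):
        with pytest.raises(ValueError, match="unmapped"):
            call_cut(ReadAlignment("r", None, None, None, "unmapped"))

    def test_ambiguous_dropped_by_default(self):
        amb = _aln("plus", 1, "ambiguous", [("plus", 1), ("plus", 5)])
        cuts, weights = call_cuts([amb, _aln("minus", 3)])
        assert cuts == [CutEvent(3, TOP)]
        assert weights == [1.0]

    def test_fractional_mode_conserves_weight(self):
        amb = _aln("plus", 1, "ambiguous", [("plus", 1), ("minus", 5), ("plus", 8)])
        cuts, weights = call_cuts([amb, _aln("plus", 2)], ambiguous="fractional")
        assert len(cuts) == 4
        assert abs(sum(weights) - 2.0) < 1e-9


class TestAggregateProfile:
    def test_counting_example(self):
        prof = aggregate_profile(
            [CutEvent(3, TOP), CutEvent(3, TOP), CutEvent(9, BOTTOM)], L=10
        )
        assert prof.counts_top[3] == 2
        assert prof.counts_bottom[9] == 1
        assert prof.total == 3

    def test_empty_input_zero_profile(self):
        prof = aggregate_profile([], L=10)
        assert prof.total == 0

    def test_order_independence(self):
        rng = np.random.default_rng(1)
        cuts = [
            CutEvent(int(p), [TOP, BOTTOM][s])
            for p, s in zip(rng.integers(0, 50, 200), rng.integers(0, 2, 200))
        ]
        a = aggregate_profile(cuts, 50)
        perm = [cuts[i] for i in rng.permutation(200)]
        b = aggregate_profile(perm, 50)
        assert np.array_equal(a.counts_top, b.counts_top)
        assert np.array_equal(a.counts_bottom, b.counts_bottom)

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            aggregate_profile([CutEvent(10, TOP)], L=10)


class TestExportPolar:
    def test_angles(self):
        prof = aggregate_profile([CutEvent(0, TOP), CutEvent(5, BOTTOM)], L=10)
        table = export_polar(prof).set_index("position")
        assert table.loc[0, "theta"] == 0.0
        assert table.loc[5, "theta"] == pytest.approx(np.pi)

    def test_raw_radii_are_counts(self):
        prof = aggregate_profile([CutEvent(2, TOP)] * 4, L=10)
        table = export_polar(prof)
        assert table["radius"].tolist() == [4.0]

    def test_normalized_radii_sum_to_one(self):
        cuts = [CutEvent(2, TOP)] * 3 + [CutEvent(7, BOTTOM)] * 7
        table = export_polar(aggregate_profile(cuts, 10), normalized=True)
        assert table["radius"].sum() == pytest.approx(1.0)


class TestHotspots:
    def test_uniform_profile_has_none(self):
        prof = CutProfile(10, np.full(10, 5.0), np.full(10, 5.0))
        assert len(hotspots(prof, k=1.0)) == 0

    def test_single_spike_found(self):
        top = np.zeros(100)
        top[42] = 100.0
        found = hotspots(CutProfile(100, top, np.zeros(100)), k=3.0)
        assert found[["position", "strand"]].values.tolist() == [[42, TOP]]

    def test_all_zero_profile_empty(self):
        assert len(hotspots(CutProfile(10, np.zeros(10), np.zeros(10)))) == 0

    def test_monotone_in_k(self):
        """Lowering k never removes a hotspot; checked against a brute
        filter on random profiles."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            prof = CutProfile(
                40, rng.poisson(2.0, 40).astype(float), rng.poisson(2.0, 40).astype(float)
            )
            pooled = np.concatenate([prof.counts_top, prof.counts_bottom])
            prev: set | None = None
            for k in (4.0, 3.0, 2.0, 1.0, 0.5):
                found = hotspots(prof, k=k)
                got = {(p, s) for p, s in zip(found["position"], found["strand"])}
                brute = {
                    (p % 40, TOP if p < 40 else BOTTOM)
                    for p in np.flatnonzero(pooled > pooled.mean() + k * pooled.std())
                }
                assert got == brute
                if prev is not None:
                    assert prev <= got
                prev = got


class TestEndToEnd:
    def test_round_trip_exact_recovery(self, plasmid, plasmid_index):
        """simulate >= 1000 nicks -> map -> call -> aggregate recovers the
        ground-truth (position, strand) multiset exactly."""
        model = NickModel(
            np.random.default_rng(5).gamma(0.5, size=(2, plasmid.length)),
            total_events=1200,
            seed=6,
        )
        nicks = sample_nicks(model, plasmid)
        reads = simulate_gloeseq_reads(plasmid, nicks, 120, 0.0, 7)
        alns = align_reads(reads, plasmid_index, 0)
        cuts, weights = call_cuts(alns)
        assert len(cuts) == sum(a.status == "unique" for a in alns) == 1200
        prof = aggregate_profile(cuts, plasmid.length, weights)
        truth = aggregate_profile(
            [CutEvent(p, s) for p, s in nicks], plasmid.length
        )
        assert np.array_equal(prof.counts_top, truth.counts_top)
        assert np.array_equal(prof.counts_bottom, truth.counts_bottom)

    def test_round_trip_with_sequencing_errors(self, plasmid, plasmid_index):
        """With 1% substitution errors, >= 99% of reads still call the
        true cut.

        A 120-nt read at 1% error carries ~1.2 substitutions on average
        and exceeds 3 in ~3% of reads, so this check maps with a
        permissive mismatch budget (6); the scan still recovers the true
        placement because random 120-mers never come close elsewhere."""
        model = NickModel(
            np.random.default_rng(8).gamma(0.5, size=(2, plasmid.length)),
            total_events=600,
            seed=9,
        )
        nicks = sample_nicks(model, plasmid)
        reads = simulate_gloeseq_reads(plasmid, nicks, 120, 0.01, 10)
        alns = align_reads(reads, plasmid_index, 6)
        correct = sum(
            a.status == "unique" and CutEvent(n.position, n.strand) == call_cut(a)
            for n, a in zip(nicks, alns)
        )
        assert correct / len(nicks) >= 0.99

    @pytest.mark.parametrize("strand", [TOP, BOTTOM])
    def test_strand_bookkeeping(self, plasmid, plasmid_index, strand):
        """Nicks confined to one strand leave the other strand's profile
        identically zero."""
        rng = np.random.default_rng(11)
        nicks = [NickEvent(int(p), strand) for p in rng.integers(0, plasmid.length, 100)]
        reads = simulate_gloeseq_reads(plasmid, nicks, 120, 0.0, 12)
        cuts, weights = call_cuts(align_reads(reads, plasmid_index, 0))
        prof = aggregate_profile(cuts, plasmid.length, weights)
        other = prof.counts_bottom if strand == TOP else prof.counts_top
        same = prof.counts_top if strand == TOP else prof.counts_bottom
        assert other.sum() == 0
        assert same.sum() == len(nicks)


def test_profile_tsv_round_trip(tmp_path):
    cuts = [CutEvent(3, TOP), CutEvent(3, TOP), CutEvent(9, BOTTOM)]
    prof = aggregate_profile(cuts, 12)
    path = tmp_path / "profile.tsv"
    write_profile_tsv(prof, "plasmid", path)
    back = read_profile_tsv(path, 12)
    assert np.array_equal(back.counts_top, prof.counts_top)
    assert np.array_equal(back.counts_bottom, prof.counts_bottom)
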