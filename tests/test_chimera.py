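import numpy as np
import pytest

from mitoveritas.chimera import (
    analyze_chimera,
    chimera_stats,
    project_onto,
    segment_breakpoints,
    windowed_assignment,
)
from mitoveritas.io_metadata import MitogenomeRecord
from mitoveritas.simulate import PanelConfig, implant_chimera


@pytest.fixture(scope="module")
def flat_panel(panel):
    return panel.genome_panel()


def own_and_donor(panel):
    return panel.species[0], panel.species[3]


class TestWindowedAssignment:
    def test_clean_query_assigns_own_species_everywhere(self, panel, flat_panel):
        sp = panel.species[0]
        rng = np.random.default_rng(1)
        rec = MitogenomeRecord("Q1", panel.new_individual(sp, rng), sp)
        for a in windowed_assignment(rec, flat_panel):
            assert a.assessable and a.best_species == sp

    def test_implanted_fragment_windows_match_direct_oracle(self, panel, flat_panel):
        """Window assignment equals the per-window argmin of mean p-distance
        computed directly on the construction."""
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(2)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, _ = implant_chimera(base, donor, [(6000, 10000)],
                                 donor_species=donor_sp)
        rec = MitogenomeRecord("Q2", seq, own)
        assignments = windowed_assignment(rec, flat_panel)

        # oracle: colinear panel, so distances computed by direct slicing
        q = np.frombuffer(seq.encode(), np.uint8)
        by_species: dict[str, list[np.ndarray]] = {}
        for sp, g in flat_panel:
            by_species.setdefault(sp, []).append(
                np.frombuffer(g.encode(), np.uint8))
        for a in assignments:
            s, e = a.window_start, a.window_end
            dists = {
                sp: float(np.mean([(q[s:e] != g[s:e]).mean() for g in gs]))
                for sp, gs in by_species.items()
            }
            oracle = min(dists, key=lambda k: (dists[k], k != rec.species_on_record, k))
            assert a.best_species == oracle
            if 6000 <= s and e <= 10000:
                assert a.best_species == donor_sp
            if e <= 6000 or s >= 10000:
                assert a.best_species == own

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            windowed_assignment("ACGT" * 1000, [])


class TestSegmentBreakpoints:
    def test_single_species_gives_one_segment(self, panel, flat_panel):
        sp = panel.species[1]
        rng = np.random.default_rng(3)
        rec = MitogenomeRecord("Q3", panel.new_individual(sp, rng), sp)
        report = analyze_chimera(rec, flat_panel)
        assert len(report.segments) == 1
        assert report.segments[0].assigned_species == sp
        assert report.heterospecific_proportion == 0.0
        assert report.donor_species == set()

    def test_breakpoints_recovered_within_75bp(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(4)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, _ = implant_chimera(base, donor, [(5000, 9000)],
                                 donor_species=donor_sp)
        rec = MitogenomeRecord("Q4", seq, own)
        report = analyze_chimera(rec, flat_panel)
        het = [s for s in report.segments if s.is_heterospecific]
        assert len(het) == 1
        assert abs(het[0].start - 5000) <= 75
        assert abs(het[0].end - 9000) <= 75

    def test_two_separated_fragments_counted(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(5)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, _ = implant_chimera(base, donor, [(2000, 3500), (9000, 10500)],
                                 donor_species=donor_sp)
        rec = MitogenomeRecord("Q5", seq, own)
        report = analyze_chimera(rec, flat_panel)
        assert report.n_heterospecific_fragments == 2
        assert report.donor_species == {donor_sp}

    @pytest.mark.parametrize("seed", range(4))
    def test_segments_tile_assessed_region(self, panel, flat_panel, seed):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(100 + seed)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        start = int(rng.integers(0, 10_000))
        seq, _ = implant_chimera(base, donor, [(start, start + 3000)],
                                 donor_species=donor_sp)
        rec = MitogenomeRecord("Q6", seq, own)
        report = analyze_chimera(rec, flat_panel)
        segs = report.segments
        assert sum(s.length for s in segs) == report.assessed_length
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
            assert a.assigned_species != b.assigned_species

    def test_proportion_monotone_in_implant_size(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(6)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        props = []
        for size in (500, 1000, 2000, 4000, 8000):
            seq, _ = implant_chimera(base, donor, [(4000, 4000 + size)],
                                     donor_species=donor_sp)
            rec = MitogenomeRecord("Q7", seq, own)
            props.append(analyze_chimera(rec, flat_panel).heterospecific_proportion)
        assert props == sorted(props)

    def test_70bp_fragment_found_with_small_windows(self, panel, flat_panel):
        """The smallest observed fragments (70 bp) need window <= 70 and
        step <= 35 — the documented sensitivity trade-off."""
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(7)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, _ = implant_chimera(base, donor, [(5000, 5070)],
                                 donor_species=donor_sp)
        rec = MitogenomeRecord("Q8", seq, own)
        fine = analyze_chimera(rec, flat_panel, window=70, step=35)
        assert any(s.is_heterospecific and s.assigned_species == donor_sp
                   for s in fine.segments)

    def test_all_unassessable_yields_empty(self):
        assignments = windowed_assignment("N" * 2000, [("Aviana alpha", "A" * 2000)])
        assert segment_breakpoints(assignments) == []


class TestChimeraStats:
    def test_proportion_arithmetic(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(8)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, truth = implant_chimera(base, donor, [(6000, 10000)],
                                     donor_species=donor_sp)
        assert truth.params["proportion_pct"] == 25.0
        rec = MitogenomeRecord("Q9", seq, own)
        report = analyze_chimera(rec, flat_panel)
        assert report.heterospecific_proportion == pytest.approx(25.0, abs=1.0)

    def test_divergence_from_authentic_matches_construction(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(9)
        base = panel.new_individual(own, rng)
        donor = panel.new_individual(donor_sp, rng)
        seq, _ = implant_chimera(base, donor, [(6000, 10000)],
                                 donor_species=donor_sp)
        # oracle: direct p-distance donor vs authentic on the implanted span
        d_arr = np.frombuffer(donor.encode(), np.uint8)[6000:10000]
        b_arr = np.frombuffer(base.encode(), np.uint8)[6000:10000]
        true_div = float((d_arr != b_arr).mean())
        rec = MitogenomeRecord("Q10", seq, own)
        report = analyze_chimera(rec, flat_panel)
        het = [s for s in report.segments if s.is_heterospecific]
        assert het[0].divergence_from_authentic == pytest.approx(true_div, abs=0.02)

    def test_misidentified_source_flag(self, panel, flat_panel):
        own, donor_sp = own_and_donor(panel)
        rng = np.random.default_rng(10)
        donor = panel.new_individual(donor_sp, rng)
        rec = MitogenomeRecord("Q11", donor, own)  # fully foreign sequence
        report = analyze_chimera(rec, flat_panel)
        assert report.possible_misidentified_source

    def test_one_based_conversion(self):
        from mitoveritas.chimera import ChimeraSegment

        seg = ChimeraSegment(start=0, end=100, assigned_species="x")
        assert seg.as_one_based() == (1, 100)


def test_projection_handles_indels():
    base = "ACGTACGTACGTACGTACGT" * 10
    with_del = base[:100] + base[103:]
    proj = project_onto(with_del, base)
    # projection has query length and mostly matches the query
    q = np.frombuffer(with_del.encode(), np.uint8)
    assert proj.size == q.size
    assert (proj == q).mean() > 0.95
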