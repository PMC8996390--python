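"""pegRNA/ngRNA/PE4 design: candidate ranking, PBS/RTT construction, round-trip."""

import numpy as np
import pytest

from primewindow._seq import revcomp
from primewindow.editor_model import builtin_profile
from primewindow.errors import (
    DesignError,
    EditOutsideWindowError,
    EditUpstreamOfNickError,
    RttTooShortError,
)
from primewindow.pegrna_design import (
    EditSpec,
    apply_edit,
    assemble_pe4_construct,
    candidate_sites_for_edit,
    design_pegrna,
    pick_ngrna,
    relative_edit_position,
    sweep_designs,
)
from primewindow.site_scanner import scan_contig
from primewindow.synthetic_data import make_genome, plant_sites

from oracles import oracle_splice


def _planted_site(profile, seed=0, length=300, strand="+"):
    genome, _ = make_genome(1, [length], 0.5, seed=seed)
    genome, truth = plant_sites(genome, profile, 1, seed=seed, strands=(strand,))
    seq = genome["contig_1"]
    t = truth[0]
    site = next(
        s
        for s in scan_contig(seq, "contig_1", profile)
        if s.pam_start == t["pam_start"] and s.strand == t["strand"]
    )
    return seq, site


class TestCandidates:
    def test_tt_at_fn_nick_ranked_first(self, fn):
        seq, site = _planted_site(fn, seed=1)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        search = candidate_sites_for_edit(seq, edit, fn)
        assert len(search) >= 1
        top_site, rel = search.sites[0]
        assert rel == 0  # at the nick
        assert top_site.nick_gap == site.nick_gap
        assert site.nick_gap == site.pam_start - 6  # 6 bp upstream of the PAM

    def test_gap_outside_narrow_window_has_no_candidate(self, sp):
        """A gap 6 nt upstream of an NGG PAM is outside the (-1,+3) window."""
        seq = "T" * 30 + "AGG" + "T" * 30
        edit = EditSpec("c", "insertion", "TT", gap=30 - 6)
        search = candidate_sites_for_edit(seq, edit, sp)
        covered_gaps = {s.nick_gap for s, _ in search.sites}
        assert 24 not in covered_gaps
        # and on a locus with only that PAM, the search reports the nearest PAM
        lone = "T" * 25 + "AGG" + "T" * 25
        miss = candidate_sites_for_edit(
            lone, EditSpec("c", "insertion", "TT", gap=25 - 6), sp
        )
        if not miss.sites:
            assert miss.no_candidate_reason["nearest_pam_start"] == 25

    def test_substitution_in_overlap_hits_both_editors(self, sp, fn):
        """Position +3 of the Fn nick is -1 of the Sp nick: both windows hold it."""
        seq = "T" * 30 + "AGG" + "T" * 30
        edit = EditSpec("c", "substitution", "C", pos=26)
        expected_rel = {"FnPE": 3, "SpPE": -1}
        for profile in (sp, fn):
            search = candidate_sites_for_edit(seq, edit, profile)
            rels = {rel for s, rel in search.sites if s.pam_start == 30}
            assert expected_rel[profile.name] in rels

    def test_ranked_nick_proximal_first(self, fn):
        seq, site = _planted_site(fn, seed=2)
        edit = EditSpec("contig_1", "substitution",
                        "A" if seq[site.nick_gap] != "A" else "C",
                        pos=site.nick_gap)
        search = candidate_sites_for_edit(seq, edit, fn)
        rels = [abs(rel) for _, rel in search.sites]
        assert rels == sorted(rels)


class TestDesign:
    def test_fn_tt_insertion_roundtrip(self, fn):
        seq, site = _planted_site(fn, seed=3)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        d = design_pegrna(site, edit, seq, l_pbs=13, l_rtt=14)
        assert len(d.pbs) == 13 and len(d.rtt) == 14
        # RTT contains AA (template-strand complement of TT) mirroring the gap
        assert "AA" in d.rtt
        recon = oracle_splice(seq, d.rtt, site.nick_gap, net_insertion=2)
        assert recon == apply_edit(seq, edit)

    def test_pbs_is_revcomp_of_protospacer_suffix_at_nick(self, fn, sp):
        for profile, seed in ((fn, 4), (sp, 5)):
            seq, site = _planted_site(profile, seed=seed)
            edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
            d = design_pegrna(site, edit, seq, l_pbs=10)
            spacer_wt = site.protospacer_seq(seq)
            # revcomp(pbs) must be a substring of the protospacer ending at the nick
            nick_index_in_spacer = profile.protospacer_len - profile.nick_offset
            assert revcomp(d.pbs) == spacer_wt[nick_index_in_spacer - 10 : nick_index_in_spacer]

    def test_minus_strand_roundtrip(self, fn):
        seq, site = _planted_site(fn, seed=6, strand="-")
        edit = EditSpec("contig_1", "insertion", "CT", gap=site.nick_gap)
        d = design_pegrna(site, edit, seq, l_pbs=12, l_rtt=15)
        # splice on the minus strand: mirror the contig, then compare
        L = len(seq)
        local = revcomp(seq)
        recon_local = oracle_splice(local, d.rtt, L - site.nick_gap, net_insertion=2)
        assert revcomp(recon_local) == apply_edit(seq, edit)

    def test_insertion_offsets_match_construction_rules(self, fn, sp):
        """TT lands 6 nt upstream of the PAM for FnPE designs, 3 nt for SpPE."""
        for profile, offset in ((fn, 6), (sp, 3)):
            seq, site = _planted_site(profile, seed=7)
            edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
            d = design_pegrna(site, edit, seq)
            edited = apply_edit(seq, edit)
            assert site.nick_gap == site.pam_start - offset
            assert edited[site.nick_gap : site.nick_gap + 2] == "TT"

    def test_rtt_too_short(self, fn):
        seq, site = _planted_site(fn, seed=8)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        with pytest.raises(RttTooShortError) as err:
            design_pegrna(site, edit, seq, l_rtt=2)
        assert err.value.min_feasible == 3
        with pytest.raises(DesignError):
            design_pegrna(site, edit, seq, l_rtt=0)

    def test_edit_outside_window_rejected(self, fn):
        seq, site = _planted_site(fn, seed=9)
        far = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap + 50)
        with pytest.raises(EditOutsideWindowError):
            design_pegrna(site, far, seq)

    def test_edit_upstream_of_nick_rejected(self, fn):
        """In-window positions 5' of the nick cannot be encoded by the RTT."""
        seq, site = _planted_site(fn, seed=10)
        upstream_pos = min(site.editable_positions) if site.strand == "+" else max(
            site.editable_positions
        )
        edit = EditSpec(
            "contig_1", "substitution",
            "A" if seq[upstream_pos] != "A" else "C", pos=upstream_pos,
        )
        assert relative_edit_position(site, edit) < 0
        with pytest.raises(EditUpstreamOfNickError):
            design_pegrna(site, edit, seq)

    def test_substitution_changes_exactly_one_base(self, fn):
        seq, site = _planted_site(fn, seed=11)
        pos = site.nick_gap if site.strand == "+" else site.nick_gap - 1
        edit = EditSpec(
            "contig_1", "substitution", "A" if seq[pos] != "A" else "C", pos=pos
        )
        edited = apply_edit(seq, edit)
        diffs = [i for i, (a, b) in enumerate(zip(seq, edited)) if a != b]
        assert diffs == [pos]
        d = design_pegrna(site, edit, seq)
        assert d.relative_edit_position in range(1, fn.window[1] + 1)

    def test_u6_spacer_g_prepend(self, fn):
        seq, site = _planted_site(fn, seed=12)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        d = design_pegrna(site, edit, seq)
        assert d.spacer_u6.startswith("G")
        if d.spacer.startswith("G"):
            assert d.spacer_u6 == d.spacer
        else:
            assert d.spacer_u6 == "G" + d.spacer


class TestSweep:
    def test_grid_shape_and_roundtrip(self, fn):
        seq, site = _planted_site(fn, seed=13)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        table = sweep_designs(site, edit, seq, pbs_range=(8, 15), rtt_range=(10, 20))
        assert len(table) == 8 * 11
        ok = table[table.ok]
        # l_pbs 15 exceeds the 14 nt between the FnPE nick and the PAM-distal
        # protospacer end, so exactly that column is flagged, never dropped
        assert len(ok) == 7 * 11
        assert set(table[~table.ok].l_pbs) == {15}
        edited = apply_edit(seq, edit)
        for row in ok.itertuples():
            recon = oracle_splice(seq, row.rtt, site.nick_gap, net_insertion=2)
            assert recon == edited

    def test_invalid_combos_flagged_not_dropped(self, fn):
        seq, site = _planted_site(fn, seed=14)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        table = sweep_designs(site, edit, seq, pbs_range=(8, 9), rtt_range=(1, 3))
        assert len(table) == 2 * 3
        assert (~table.ok).sum() >= 2  # rtt 1..2 cannot cover TT + homology
        assert set(table[~table.ok].reason) == {"RttTooShortError"}

    def test_gc_percent_column(self, fn):
        from primewindow._seq import gc_percent

        assert gc_percent("GCGC") == 100.0
        assert gc_percent("ATAT") == 0.0
        seq, site = _planted_site(fn, seed=15)
        edit = EditSpec("contig_1", "insertion", "TT", gap=site.nick_gap)
        table = sweep_designs(site, edit, seq, pbs_range=(10, 10), rtt_range=(12, 12))
        row = table.iloc[0]
        assert row.pbs_gc_pct == pytest.approx(gc_percent(row.pbs), abs=0.01)


class TestNgRNAAndPe4:
    def _locus_with_opposite_pam(self, fn):
        """FnPE '+' site plus one '-' site whose nick is ~50 bp away."""
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        # plant '+' PAM at 60 (nick gap 54) and '-' CCN so its nick lands ~50 bp later
        seq = seq[:60] + "TGG" + seq[63:]
        # minus-strand site: CCN at p, nick gap = p+3+6; want ~104 -> p = 95
        seq = seq[:95] + "CCT" + seq[98:]
        return seq

    def test_pick_within_range(self, fn):
        seq = self._locus_with_opposite_pam(fn)
        site = next(
            s for s in scan_contig(seq, "c", fn) if s.strand == "+" and s.pam_start == 60
        )
        picks = pick_ngrna(seq, site, fn, distance_range=(40, 100))
        assert picks, "expected at least one ngRNA candidate"
        assert all(p.strand == "-" for p in picks)
        assert all(40 <= abs(p.nick_distance) <= 100 for p in picks)
        dists = [abs(p.nick_distance) for p in picks]
        assert dists == sorted(dists)

    def test_tight_range_empty(self, fn):
        seq = self._locus_with_opposite_pam(fn)
        site = next(
            s for s in scan_contig(seq, "c", fn) if s.strand == "+" and s.pam_start == 60
        )
        near = pick_ngrna(seq, site, fn, distance_range=(0, 10))
        assert all(abs(p.nick_distance) <= 10 for p in near)

    def test_pe4_assembly_tiles_and_splits(self, fn):
        seq = self._locus_with_opposite_pam(fn)
        site = next(
            s for s in scan_contig(seq, "c", fn) if s.strand == "+" and s.pam_start == 60
        )
        edit = EditSpec("c", "insertion", "AA", gap=site.nick_gap)
        d = design_pegrna(site, edit, seq)
        (ng, *_rest) = pick_ngrna(seq, site, fn, distance_range=(20, 120))
        construct = assemble_pe4_construct(d, ng, scaffold="GTTTTAGA", csy4_site="GTTCACTGCC")
        segs = construct.segments()
        # concatenation identity and tiling without overlap
        assert construct.sequence == "".join(
            segs[name] for name, _, _ in construct.annotations
        )
        ends = [e for _, _, e in construct.annotations]
        starts = [s for _, s, _ in construct.annotations]
        assert starts[1:] == ends[:-1] and starts[0] == 0
        assert ends[-1] == len(construct.sequence)
        # in-silico Csy4 cleavage regenerates the two guide units
        left, right = construct.sequence.split("GTTCACTGCC")
        assert left == d.spacer + "GTTTTAGA" + d.rtt + d.pbs
        assert right == ng.protospacer + "GTTTTAGA"

    def test_rna_output(self, fn):
        seq = self._locus_with_opposite_pam(fn)
        site = next(s for s in scan_contig(seq, "c", fn) if s.strand == "+")
        edit = EditSpec("c", "insertion", "AA", gap=site.nick_gap)
        d = design_pegrna(site, edit, seq)
        picks = pick_ngrna(seq, site, fn, distance_range=(20, 120))
        construct = assemble_pe4_construct(d, picks[0], rna=True)
        assert "T" not in construct.sequence and "U" in construct.sequence


class TestRoundTripProperty:
    def test_random_loci_and_edits(self, fn, sp):
        """Splicing the designed RTT onto the nicked strand reconstructs the
        intended edited allele for random loci, edits and PBS/RTT lengths."""
        rng = np.random.default_rng(777)
        n_ok = 0
        trials = 120
        for trial in range(trials):
            profile = (fn, sp)[trial % 2]
            strand = "+-"[trial // 2 % 2]
            seq, site = _planted_site(
                profile, seed=int(rng.integers(1 << 30)), strand=strand
            )
            hi = profile.window[1]
            if rng.random() < 0.5:
                rel = int(rng.integers(0, hi))  # insertion gap at/3' of nick
                gap = site.nick_gap + (rel if strand == "+" else -rel)
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 4)))
                edit = EditSpec("contig_1", "insertion", ins, gap=gap)
                net = len(ins)
            else:
                rel = int(rng.integers(1, hi + 1))  # substitution at +1..+hi
                pos = site.nick_gap + (rel - 1 if strand == "+" else -rel)
                alt = "ACGT"[(("ACGT".index(seq[pos])) + 1 + rng.integers(3)) % 4]
                if alt == seq[pos]:
                    alt = "ACGT"[("ACGT".index(alt) + 1) % 4]
                edit = EditSpec("contig_1", "substitution", alt, pos=pos)
                net = 0
            l_pbs = int(rng.integers(8, 15))
            min_rtt = rel + net + 1 if edit.edit_type == "insertion" else rel + 1
            avail = (
                len(seq) - site.nick_gap + net if strand == "+" else site.nick_gap + net
            )
            l_rtt = int(rng.integers(min_rtt, min(34, avail + 1)))
            d = design_pegrna(site, edit, seq, l_pbs=l_pbs, l_rtt=l_rtt)
            if strand == "+":
                recon = oracle_splice(seq, d.rtt, site.nick_gap, net)
                expected = apply_edit(seq, edit)
            else:
                local = revcomp(seq)
                recon = revcomp(
                    oracle_splice(local, d.rtt, len(seq) - site.nick_gap, net)
                )
                expected = apply_edit(seq, edit)
            assert recon == expected, f"trial {trial} failed"
            n_ok += 1
        assert n_ok == trials
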