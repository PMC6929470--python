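"""ORF extraction, orthogroup filters, and alignment trimming."""

import numpy as np
import pytest

from omegak.orthogroups import (
    Member,
    RawOrthogroup,
    ReferenceGeneMap,
    collapsed_orthologue_filter,
    filter_pipeline,
    longest_orf,
    match_to_reference,
    merge_and_dedup,
    reverse_complement,
    size_taxon_filter,
    trim_sequences,
)
from omegak.simulate import random_cds, simulate_filter_study


def brute_force_orfs(seq, min_len):
    """Exhaustive 6-frame scan, written independently of _scan_frame."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            i = 0
            while i < len(codons):
                if codons[i] == "ATG":
                    j = i
                    while j < len(codons) and codons[j] not in stops:
                        j += 1
                    end = j + 1 if j < len(codons) else j
                    orf = "".join(codons[i:end])
                    if len(orf) >= min_len:
                        out.append((strand, frame, orf))
                    # next ORF in this frame starts after this stop
                    i = end
                else:
                    i += 1
    return out


class TestLongestORF:
    def test_below_threshold_is_none(self):
        rng = np.random.default_rng(0)
        cds = random_cds(rng, 50)  # 150 nt
        assert longest_orf(cds, min_len=200) is None

    def test_exact_single_orf(self):
        rng = np.random.default_rng(1)
        cds = random_cds(rng, 100)  # 300 nt
        orf = longest_orf(cds, min_len=200)
        assert orf is not None and orf.sequence == cds
        assert (orf.start, orf.end, orf.strand) == (0, 300, "+")

    def test_longest_of_two(self):
        rng = np.random.default_rng(2)
        short = random_cds(rng, 70)  # 210 nt
        long = random_cds(rng, 150)  # 450 nt
        transcript = short + "CC" + long
        orf = longest_orf(transcript, min_len=200, both_strands=False)
        assert orf.sequence == long

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        got = longest_orf(transcript, min_len=60)
        want = brute_force_orfs(transcript, 60)
        if not want:
            assert got is None
        else:
            best_len = max(len(o) for _, _, o in want)
            assert got is not None and len(got.sequence) == best_len
            assert any(o == got.sequence for _, _, o in want)

    def test_reverse_strand_recovery(self):
        rng = np.random.default_rng(3)
        cds = random_cds(rng, 120)
        rc = reverse_complement(cds)
        orf = longest_orf(rc, min_len=200, both_strands=True)
        assert orf is not None and orf.sequence == cds and orf.strand == "-"
        assert longest_orf(rc, min_len=200, both_strands=False) is None or len(
            longest_orf(rc, min_len=200, both_strands=False).sequence
        ) < len(cds)

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            longest_orf("ATGXXXTAA")

    def test_orf_table_uses_one_based_coordinates(self):
        from omegak.orthogroups import orf_table

        rng = np.random.default_rng(4)
        cds = random_cds(rng, 80)
        orf = longest_orf("CC" + cds, min_len=200, both_strands=False,
                          transcript_id="t1")
        tab = orf_table([orf])
        assert tab.loc[0, "start_1based"] == 3  # 0-based start 2
        assert tab.loc[0, "end_1based"] == 2 + len(cds)
        assert tab.loc[0, "length_nt"] == len(cds)


def _group(gid, members):
    return RawOrthogroup(gid, [Member(sp, g, s) for sp, g, s in members])


class TestGroupFilters:
    def test_match_to_reference_rules(self):
        ref = ReferenceGeneMap(cds={"r1": "ATG"}, orthologues={"g1": {"r1"}, "g2": {"r1"}})
        groups = [
            _group("both", [("s1", "g1", "A"), ("s2", "g2", "A"), ("s3", "gX", "A")]),
            _group("none", [("s1", "gY", "A")]),
        ]
        kept, audit = match_to_reference(groups, ref)
        assert [g.id for g in kept] == ["both"]
        assert len(kept[0].members) == 2
        assert match_to_reference([], ref) == ([], [])

    @pytest.mark.parametrize(
        "focal,ref_n,keep",
        [(2, 3, False), (3, 3, True), (5, 3, False), (4, 1, True), (5, 1, False)],
    )
    def test_collapsed_filter_boundaries(self, focal, ref_n, keep):
        g = _group("g", [("s1", f"g{i}", "A") for i in range(focal)])
        got, _ = collapsed_orthologue_filter(g, ref_n)
        assert got is keep

    def test_merge_identical_signatures(self):
        ref = ReferenceGeneMap(
            cds={}, orthologues={"a": {"r1", "r2"}, "b": {"r1", "r2"}, "c": {"r3"}}
        )
        groups = [
            _group("g1", [("s1", "a", "A")]),
            _group("g2", [("s2", "b", "C")]),
            _group("g3", [("s1", "c", "G")]),
        ]
        kept, _ = merge_and_dedup(groups, ref)
        assert len(kept) == 2
        merged = next(g for g in kept if len(g.members) == 2)
        assert {m.gene_id for m in merged.members} == {"a", "b"}

    def test_exact_duplicates_collapse(self):
        ref = ReferenceGeneMap(cds={}, orthologues={"a": {"r1"}})
        g1 = _group("g1", [("s1", "a", "AAA")])
        g2 = _group("g2", [("s1", "a", "AAA")])
        kept, audit = merge_and_dedup([g1, g2], ref)
        assert len(kept) == 1 and len(kept[0].members) == 1
        assert any(not a["kept"] for a in audit)

    def test_size_taxon_boundaries(self):
        groups = []
        for n in (6, 7, 80, 81):
            groups.append(
                _group(f"n{n}", [(f"s{i % 10}", f"g{n}_{i}", "A") for i in range(n)])
            )
        kept, _ = size_taxon_filter(groups, min_seqs=7, max_seqs=80, min_taxa=7)
        assert {g.id for g in kept} == {"n7", "n80"}
        six_taxa = _group("t6", [(f"s{i % 6}", f"t{i}", "A") for i in range(20)])
        kept, audit = size_taxon_filter([six_taxa])
        assert kept == [] and "taxa" in audit[0]["reason"]
        assert size_taxon_filter([]) == ([], [])


class TestTrim:
    def test_gapless_unchanged(self):
        recs = [("a", "ATGAAA"), ("b", "ATGAAC")]
        assert trim_sequences(recs) == recs

    def test_unanimity_filter_at_full_resoverlap(self):
        # at resoverlap 1.0 a column is good for a sequence only when
        # every other sequence matches its gap state, so the good-column
        # set is shared: the step acts as an alignment-level filter.
        unanimous = [("a", "AAAA--"), ("b", "CCAA--"), ("c", "GGAA--")]
        # all sequences kept; -noallgaps then strips columns 5-6
        assert trim_sequences(unanimous, 1.0, 0.38) == [
            ("a", "AAAA"), ("b", "CCAA"), ("c", "GGAA")
        ]
        # one idiosyncratic sequence pushes the unanimous fraction of
        # every sequence to 3/10 < 0.38: the whole alignment is emptied
        discordant = [
            ("a", "AAAAAAAAAA"),
            ("b", "AAAAAAAAAA"),
            ("c", "AAAAAAAAAA"),
            ("d", "CCC-------"),
        ]
        assert trim_sequences(discordant, 1.0, 0.38) == []

    def test_gappy_sequence_removed(self):
        # hand-computed at resoverlap 2/3: for a/b/c every column has
        # >= 2 of 3 others matching (good fraction 1.0); for d columns
        # 3..9 have 0 of 3 matching -> good fraction 3/10 < 0.38
        recs = [
            ("a", "AAAAAAAAAA"),
            ("b", "AAAAAAAAAA"),
            ("c", "AAAAAAAAAA"),
            ("d", "CCC-------"),
        ]
        out = trim_sequences(recs, resoverlap=2 / 3, seqoverlap=0.38)
        names = [n for n, _ in out]
        assert "d" not in names and set(names) == {"a", "b", "c"}

    def test_allgap_columns_removed_after_drop(self):
        recs = [
            ("a", "AAA---"),
            ("b", "AAA---"),
            ("c", "AAA---"),
            ("d", "GGGGGG"),
        ]
        # d: 3 of 6 positions good (0.5 < 0.6) -> dropped; a/b/c keep
        # all positions (2 of 3 others always match); columns 4-6 are
        # then all-gap and vanish
        out = trim_sequences(recs, resoverlap=2 / 3, seqoverlap=0.6)
        assert [n for n, _ in out] == ["a", "b", "c"]
        assert all(len(s) == 3 for _, s in out)

    def test_never_grows(self):
        rng = np.random.default_rng(0)
        cols = 30
        recs = []
        for i in range(5):
            seq = "".join(
                "-" if rng.random() < 0.3 else "ACGT"[rng.integers(4)]
                for _ in range(cols)
            )
            recs.append((f"s{i}", seq))
        out = trim_sequences(recs, resoverlap=0.5, seqoverlap=0.3)
        assert len(out) <= len(recs)
        assert all(len(s) <= cols for _, s in out)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            trim_sequences([("a", "AAA")])


class TestPipeline:
    def test_planted_violations_dropped_exactly(self):
        fs = simulate_filter_study(seed=11)
        kept, audit = filter_pipeline(fs.raw_groups, fs.reference_map)
        dropped = {
            r["group_id"]: r["stage"]
            for _, r in audit.iterrows()
            if not r["kept"]
        }
        assert dropped == fs.expected_dropped

    def test_idempotent(self):
        fs = simulate_filter_study(seed=12)
        kept, _ = filter_pipeline(fs.raw_groups, fs.reference_map)
        kept2, audit2 = filter_pipeline(kept, fs.reference_map)
        assert [g.id for g in kept2] == [g.id for g in kept]
        assert all(a["kept"] for _, a in audit2.iterrows())
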