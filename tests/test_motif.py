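"""IUPAC scanner against a regex oracle; positional statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiptargets.io import GeneModel, GenomicInterval
from chiptargets.motif import (
    IupacMotif,
    MotifSite,
    center_distance_density,
    normalized_gene_coordinate,
    normalized_position_profile,
    reverse_complement,
    scan,
    sites_per_peak,
)
from util import cons, regex_scan

RNG = np.random.default_rng(1234)


def random_seq(n, rng=RNG):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestIupacMotif:
    def test_valid_patterns(self):
        assert len(IupacMotif("GTACTRC")) == 7
        assert IupacMotif("tcttctst").pattern == "TCTTCTST"

    def test_invalid_code_named_in_error(self):
        with pytest.raises(ValueError, match="'X'"):
            IupacMotif("GTAXC")

    def test_length_limit(self):
        with pytest.raises(ValueError):
            IupacMotif("A" * 21)

    def test_reverse_complement(self):
        assert reverse_complement("GTACTRC") == "GYAGTAC"
        assert reverse_complement("TCTTCTST") == "ASAGAAGA"


class TestScan:
    def test_degenerate_position_matches_both_bases(self):
        (site,) = [s for s in scan("AAGTACTACAA", "GTACTRC") if s.strand == "+"]
        assert (site.interval.start, site.matched_text) == (2, "GTACTAC")
        (site,) = [s for s in scan("AAGTACTGCAA", "GTACTRC") if s.strand == "+"]
        assert site.matched_text == "GTACTGC"

    def test_strand_symmetry_of_reverse_complement(self):
        seq = "AAGTACTACAA"
        rc = reverse_complement(seq)
        fwd = scan(seq, "GTACTRC")
        rev = scan(rc, "GTACTRC")
        assert len(fwd) == len(rev)
        assert {s.strand for s in fwd} ^ {s.strand for s in rev} in (set(), {"+", "-"})

    def test_n_in_sequence_never_matches(self):
        assert scan("AAGTACTNCAA", "GTACTRC") == []
        # but an N motif position accepts an N in the sequence
        assert len([s for s in scan("ANA", "ANA", both_strands=False)]) == 1

    def test_overlapping_matches_all_reported(self):
        sites = [s for s in scan("GTACGTAC", "GTAC") if s.strand == "+"]
        assert [s.interval.start for s in sites] == [0, 4]
        # tandem arrangement where plus matches overlap
        plus = [s for s in scan("ATGTACATGTACAT", "TGTACA") if s.strand == "+"]
        assert [s.interval.start for s in plus] == [1, 7]

    def test_invalid_sequence_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            scan("ACGU", "GTAC")

    def test_offset_shifts_coordinates(self):
        (site,) = [s for s in scan("AAGTACTACAA", "GTACTRC", offset=100) if s.strand == "+"]
        assert (site.interval.start, site.interval.end) == (102, 109)

    @pytest.mark.parametrize("pattern", ["GTACTRC", "TCTTCTST"])
    def test_equals_regex_oracle_on_random_sequences(self, pattern):
        motif = IupacMotif(pattern)
        rng = np.random.default_rng(99)
        for _ in range(100):
            seq = random_seq(500, rng)
            got = sorted((s.interval.start, s.strand) for s in scan(seq, motif))
            assert got == regex_scan(seq, motif.pattern, motif.revcomp.pattern)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=200))
    def test_revcomp_invariance_property(self, seq):
        motif = IupacMotif("GTACTRC")
        fwd = {(s.interval.start, s.strand) for s in scan(seq, motif)}
        n = len(seq)
        m = len(motif)
        mirrored = {
            (n - start - m, "+" if strand == "-" else "-")
            for start, strand in fwd
        }
        rev = {(s.interval.start, s.strand) for s in scan(reverse_complement(seq), motif)}
        assert rev == mirrored


class TestSitesPerPeak:
    def test_two_planted_copies(self):
        seq = random_seq(200) + "GTACTAC" + random_seq(50) + "GTACTGC" + random_seq(200)
        seq = seq.replace("GTACT", "GCCCT", 0)  # no-op; keep planted copies only
        genome = {"chr1": seq}
        peaks = [cons(150, len(seq) - 150, name="p")]
        sites, per_peak, hist = sites_per_peak(peaks, genome, "GTACTRC")
        planted = [s for s in sites if s.matched_text in ("GTACTAC", "GTACTGC")]
        assert per_peak["p"] >= 2 and len(planted) >= 2

    def test_impossible_motif_counts_zero(self):
        genome = {"chr1": "GC" * 300}
        peaks = [cons(100, 500, name="p")]
        sites, per_peak, hist = sites_per_peak(peaks, genome, "GTACTRC")
        assert sites == [] and per_peak["p"] == 0 and hist == {0: 1}

    def test_core_vs_full_motif_counts(self):
        # a promoter-like stretch carrying 8 GTAC cores of which 2 extend
        # to the full degenerate motif (synthetic arrangement)
        rng = np.random.default_rng(55)
        spacer = lambda: "".join("CCTT"[i] for i in rng.integers(0, 4, 20))
        cores = ["GTACCAA"] * 6 + ["GTACTAC", "GTACTGC"]
        seq = "CCTTCC" * 20
        for c in cores:
            seq += c + spacer()
        seq += "CCTTCC" * 20
        genome = {"chr1": seq}
        peaks = [cons(10, len(seq) - 10, name="p")]
        _, per_core, _ = sites_per_peak(peaks, genome, "GTAC", both_strands=False)
        _, per_full, _ = sites_per_peak(peaks, genome, "GTACTRC", both_strands=False)
        assert per_core["p"] == 8
        assert per_full["p"] == 2

    def test_peak_beyond_chromosome_end_errors(self):
        with pytest.raises(ValueError, match="past the end"):
            sites_per_peak([cons(0, 500, name="p")], {"chr1": "ACGT" * 50}, "GTAC")


def site_at(offset, peak_id="p"):
    return MotifSite(
        interval=GenomicInterval("chr1", 1000, 1007),
        strand="+",
        matched_text="GTACTAC",
        peak_id=peak_id,
        offset_from_peak_center=offset,
    )


class TestCenterDistanceDensity:
    def test_all_sites_at_center(self):
        edges, dens = center_distance_density([site_at(0.0)] * 5)
        k = np.searchsorted(edges, 0.0) - 1
        assert dens[k] == 1.0 and dens.sum() == pytest.approx(1.0)

    def test_symmetric_sites_two_bins(self):
        edges, dens = center_distance_density([site_at(-100.0), site_at(100.0)])
        assert dens.sum() == pytest.approx(1.0)
        nz = dens[dens > 0]
        assert len(nz) == 2 and np.allclose(nz, 0.5)
        # symmetry of the binning itself
        assert np.allclose(dens, dens[::-1])

    def test_empty_sites_empty_density(self):
        edges, dens = center_distance_density([])
        assert edges.size == 0 and dens.size == 0

    def test_bins_are_centered_on_zero(self):
        edges, _ = center_distance_density([site_at(10.0)], bin_bp=75)
        assert np.any(np.isclose(edges, -37.5)) and np.any(np.isclose(edges, 37.5))

    def test_absolute_mode_folds_sign(self):
        edges, dens = center_distance_density(
            [site_at(-100.0), site_at(100.0)], absolute=True
        )
        assert edges[0] == 0.0
        assert (dens > 0).sum() == 1


class TestNormalizedProfile:
    @pytest.mark.parametrize(
        "offset,gene_len,expected",
        [
            (1000, 4000, 500.0),    # fraction 0.25 of the normalized 2-kb body
            (-110, 4000, -110.0),   # upstream coordinates unscaled
            (4050, 4000, 2050.0),   # 50 bp past the TTS
            (0, 1, 0.0),            # degenerate 1-bp gene
        ],
    )
    def test_coordinate_mapping(self, offset, gene_len, expected):
        assert normalized_gene_coordinate(offset, gene_len) == expected

    def test_fractional_mapping_is_exact(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            L = int(rng.integers(1, 10_000))
            d = int(rng.integers(0, L))
            assert normalized_gene_coordinate(d, L) == (d / L) * 2000

    def test_gene_length_must_be_positive(self):
        with pytest.raises(ValueError):
            normalized_gene_coordinate(10, 0)

    def _gene(self, start, length, strand="+", gene_id="G1"):
        return GeneModel(gene_id, GenomicInterval("chr1", start, start + length, strand))

    def test_bins_and_skips(self):
        gene = self._gene(10_000, 4000)
        genes = {"G1": gene}
        def msite(pos):
            return MotifSite(GenomicInterval("chr1", pos - 3, pos + 4), "+", "GTACTAC")
        linked = [
            (msite(11_000), "G1"),   # 1000 bp in -> 500 -> bin [400, 600)
            (msite(9_890), "G1"),    # TSS-110 -> bin [-200, 0)
            (msite(14_050), "G1"),   # TTS+50 -> 2050
            (msite(11_000), "NOPE"), # unknown gene -> skipped
        ]
        edges, counts, skipped = normalized_position_profile(linked, genes, bin_bp=200)
        assert skipped == 1 and counts.sum() == 3
        def bin_count(lo):
            return counts[int(np.where(edges[:-1] == lo)[0][0])]
        assert bin_count(400) == 1 and bin_count(-200) == 1 and bin_count(2000) == 1

    def test_planted_upstream_sites_modal_bin(self):
        # motifs at TSS-150 ± 25 across 100 genes: modal 200-bp bin is [-200, 0)
        rng = np.random.default_rng(101)
        genes, linked = {}, []
        pos = 10_000
        for i in range(100):
            gid = f"G{i}"
            strand = "+" if rng.random() < 0.5 else "-"
            g = self._gene(pos, int(rng.integers(1000, 4000)), strand, gid)
            genes[gid] = g
            off = -150 + rng.uniform(-25, 25)
            genomic = g.tss + off if strand == "+" else g.tss - off
            m = MotifSite(
                GenomicInterval("chr1", int(genomic) - 3, int(genomic) + 4),
                "+", "GTACTAC",
            )
            linked.append((m, gid))
            pos += 12_000
        edges, counts, _ = normalized_position_profile(linked, genes)
        modal_lo = edges[int(np.argmax(counts))]
        assert modal_lo == -200.0
        # all in-gene coordinates stay inside [0, body_norm)
        assert counts.sum() == 100
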