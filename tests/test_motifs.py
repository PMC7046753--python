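from __future__ import annotations

import numpy as np
import pytest

import oracles
from cobindkit import (
    ParseError,
    PositionWeightModel,
    ValidationError,
    global_enrichment,
    interpret_pair,
    local_enrichment,
    motif_centered_rescan,
    positional_bias,
    pwm_from_consensus,
    read_jaspar,
    scan_sequences,
    write_jaspar,
)
from cobindkit.motifs import RegionHit, enrichment_report, scan_regions
from cobindkit.simulate import random_sequences


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@pytest.fixture
def pwm_library(rng):
    """Random continuous-count PWMs of assorted lengths."""
    lib = []
    for i, L in enumerate((6, 8, 10, 12)):
        counts = rng.random((4, L)) * 10 + 0.1
        lib.append(PositionWeightModel(f"M{i}", counts))
    return lib


class TestJasparIO:
    def test_round_trip_counts_exact(self, tmp_path, pwm_library):
        path = tmp_path / "lib.jaspar"
        write_jaspar(pwm_library, path)
        back = read_jaspar(path)
        assert [p.name for p in back] == [p.name for p in pwm_library]
        for a, b in zip(pwm_library, back):
            assert np.allclose(a.counts, b.counts)

    def test_parses_jaspar_2016_format(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 CCAAT\nA [ 10 0 0 5 ]\nC [ 0 10 0 5 ]\n"
            "G [ 0 0 10 5 ]\nT [ 0 0 0 5 ]\n"
        )
        (pwm,) = read_jaspar(path)
        assert pwm.name == "MA0001.1 CCAAT"
        assert pwm.length == 4
        assert pwm.counts[0, 0] == 10

    def test_missing_base_row_rejected(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(">M\nA [ 1 2 3 4 ]\nC [ 1 2 3 4 ]\nG [ 1 2 3 4 ]\n")
        with pytest.raises(ParseError):
            read_jaspar(path)

    def test_unequal_rows_rejected(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">M\nA [ 1 2 3 4 ]\nC [ 1 2 3 ]\nG [ 1 2 3 4 ]\nT [ 1 2 3 4 ]\n"
        )
        with pytest.raises(ParseError, match="unequal"):
            read_jaspar(path)

    def test_frequency_columns_normalized(self, pwm_library):
        for pwm in pwm_library:
            assert np.allclose(pwm.frequencies.sum(axis=0), 1.0, atol=1e-9)


class TestScanning:
    def test_consensus_scores_one(self, pwm_library, rng):
        for pwm in pwm_library:
            seq = "".join(rng.choice(list("ACGT"), 150))
            planted = seq[:60] + pwm.consensus + seq[60 + pwm.length :]
            (hit,) = scan_sequences([planted], pwm)
            assert hit.best_score == pytest.approx(1.0)
            assert hit.offset == 60 and hit.strand == "+"

    def test_anti_consensus_scores_zero(self, pwm_library):
        """The per-position argmin string sits at the bottom of the scale."""
        for pwm in pwm_library:
            (hit,) = scan_sequences([pwm.anti_consensus], pwm, strands="+")
            assert hit.best_score == pytest.approx(0.0)

    def test_matches_exhaustive_oracle(self, pwm_library, rng):
        seqs = random_sequences(rng, 50, 150)
        for pwm in pwm_library:
            hits = scan_sequences(seqs, pwm)
            for seq, hit in zip(seqs, hits):
                raw, offset, strand = oracles.best_instance(seq, pwm.frequencies.tolist())
                assert hit.best_score == pytest.approx(pwm.normalize(np.array(raw)), abs=1e-9)
                assert (hit.offset, hit.strand) == (offset, strand)

    def test_reverse_complement_symmetry(self, pwm_library, rng):
        """Reverse-complementing a region mirrors the hit and swaps strand.

        The consensus is planted once so the best instance is unique and the
        mirrored offset is well-defined (random sequence can tie on repeated
        k-mers).
        """
        W = 100
        for pwm in pwm_library:
            seqs = []
            planted_at = []
            cons, rc = pwm.consensus, revcomp(pwm.consensus)
            while len(seqs) < 20:
                (s,) = random_sequences(rng, 1, W)
                o = int(rng.integers(0, W - pwm.length + 1))
                s = s[:o] + cons + s[o + pwm.length :]
                # a chance second consensus occurrence would make the best
                # instance ambiguous; only unique plants are informative
                if s.count(cons) + s.count(rc) == 1:
                    seqs.append(s)
                    planted_at.append(o)
            fwd = scan_sequences(seqs, pwm)
            rev = scan_sequences([revcomp(s) for s in seqs], pwm)
            for o, f, r in zip(planted_at, fwd, rev):
                assert f.best_score == pytest.approx(1.0)
                assert r.best_score == pytest.approx(1.0)
                assert (f.offset, f.strand) == (o, "+")
                assert (r.offset, r.strand) == (W - pwm.length - o, "-")

    def test_ambiguous_bases_score_column_mean(self, pwm_library):
        pwm = pwm_library[0]
        (hit,) = scan_sequences(["N" * 50], pwm)
        expected = pwm.normalize(np.array(pwm.frequencies.mean(axis=0).sum()))
        assert hit.best_score == pytest.approx(float(expected), abs=1e-9)

    def test_sequence_shorter_than_motif_rejected(self, pwm_library):
        with pytest.raises(ValidationError):
            scan_sequences(["ACGT"], pwm_library[-1])


class TestGlobalEnrichment:
    def _hits(self, scores):
        return [RegionHit(i, s, 0, "+", 5.0) for i, s in enumerate(scores)]

    def test_no_shift_not_significant(self, rng):
        scores = rng.random(300)
        p = global_enrichment(self._hits(scores), self._hits(scores.copy()))
        assert 0.3 < p < 0.7

    def test_planted_motif_highly_significant(self, rng, pwm_library):
        pwm = pwm_library[1]
        bg = random_sequences(rng, 500, 150)
        inp = random_sequences(rng, 500, 150)
        for i in range(400):  # plant in 80%
            inp[i] = inp[i][:70] + pwm.consensus + inp[i][70 + pwm.length :]
        p = global_enrichment(scan_sequences(inp, pwm), scan_sequences(bg, pwm))
        assert p < 1e-10

    def test_downward_shift_gives_large_p(self, rng):
        x = rng.random(300) * 0.5
        y = rng.random(300) * 0.5 + 0.4
        p = global_enrichment(self._hits(x), self._hits(y))
        assert p > 0.5

    def test_small_background_rejected(self, rng):
        h = self._hits(rng.random(50))
        with pytest.raises(ValidationError):
            global_enrichment(h, h)


class TestLocalEnrichment:
    def _genome(self, rng, n_regions, spacing=1000, length=None):
        length = length or (n_regions + 2) * spacing
        genome = {"chr1": "".join(rng.choice(list("ACGT"), length))}
        centers = [(i + 1) * spacing for i in range(n_regions)]
        return genome, [("chr1", c) for c in centers]

    def test_motif_at_summits_significant(self, rng, pwm_library):
        pwm = pwm_library[0]
        genome, regions = self._genome(rng, 100)
        arr = np.array(list(genome["chr1"]))
        for _, c in regions:
            arr[c - pwm.length // 2 : c - pwm.length // 2 + pwm.length] = list(pwm.consensus)
        genome = {"chr1": "".join(arr)}
        assert local_enrichment(regions, genome, pwm) < 1e-6

    def test_tiled_repeat_no_contrast(self, rng, pwm_library):
        pwm = pwm_library[0]
        unit = "ACGTGGTCA"
        genome = {"chr1": unit * 6000}
        regions = [("chr1", 1000 + i * 900) for i in range(50)]
        p = local_enrichment(regions, genome, pwm)
        assert 0.05 < p < 0.95

    def test_motif_only_in_flanks_large_p(self, rng, pwm_library):
        pwm = pwm_library[0]
        genome, regions = self._genome(rng, 100)
        arr = np.array(list(genome["chr1"]))
        for _, c in regions:
            for fc in (c - 150, c + 150):
                arr[fc - pwm.length // 2 : fc - pwm.length // 2 + pwm.length] = list(
                    pwm.consensus
                )
        genome = {"chr1": "".join(arr)}
        assert local_enrichment(regions, genome, pwm) > 0.5


class TestPositionalBias:
    def test_central_concentration_significant(self):
        hits = [RegionHit(i, 1.0, 70, "+", 75.0) for i in range(100)]
        assert positional_bias(hits, n_offsets=141) < 1e-10

    def test_uniform_positions_calibrated(self, rng):
        """Null p-values are approximately U(0,1) (KS distance < 0.1)."""
        n_off = 141
        ps = []
        for _ in range(500):
            offsets = rng.integers(0, n_off, size=100)
            hits = [RegionHit(i, 1.0, int(o), "+", o + 5.0) for i, o in enumerate(offsets)]
            ps.append(positional_bias(hits, n_offsets=n_off))
        ps = np.sort(ps)
        grid = (np.arange(len(ps)) + 1) / len(ps)
        assert np.abs(ps - grid).max() < 0.1

    def test_half_support_significant(self, rng):
        offsets = rng.integers(0, 70, size=200)
        hits = [RegionHit(i, 1.0, int(o), "+", o + 5.0) for i, o in enumerate(offsets)]
        assert positional_bias(hits, n_offsets=141) < 1e-6

    def test_few_regions_reduce_bins(self):
        hits = [RegionHit(i, 1.0, i, "+", i + 5.0) for i in range(10)]
        with pytest.warns(UserWarning, match="bins"):
            p = positional_bias(hits, n_offsets=141, bins=15)
        assert 0 < p <= 1


def _spacing_genome(rng, n_regions, anchor, partner, distance, strand="+",
                    fraction=1.0, spacing=1000):
    """Random genome with anchor+partner consensi planted at region centers."""
    length = (n_regions + 2) * spacing
    arr = np.array(list("ACGT"))[rng.integers(0, 4, length)]
    regions = []
    n_plant = int(round(fraction * n_regions))
    for i in range(n_regions):
        c = (i + 1) * spacing
        regions.append(("chr1", c))
        if i < n_plant:
            a = anchor.consensus
            p = partner.consensus if strand == "+" else revcomp(partner.consensus)
            arr[c - len(a) // 2 : c - len(a) // 2 + len(a)] = list(a)
            pc = c + distance
            arr[pc - len(p) // 2 : pc - len(p) // 2 + len(p)] = list(p)
    return {"chr1": "".join(arr)}, regions


class TestMotifCenteredRescan:
    anchor = pwm_from_consensus("ANCHOR", "TTGACGTCAA")
    partner = pwm_from_consensus("PARTNER", "CCAATCAG")

    def test_planted_downstream_partner_recovered(self, rng):
        genome, regions = _spacing_genome(rng, 200, self.anchor, self.partner, 17)
        arr = motif_centered_rescan(regions, genome, self.anchor, [self.partner])
        res = arr["PARTNER"]
        assert res.modal_distances == [17]
        assert res.positional_bias_p < 0.01
        frac_plus = (res.strands == "+").mean()
        assert frac_plus > 0.95

    def test_partner_absent_no_dominant_spacing(self, rng):
        """An unplanted motif never concentrates at a single distance.

        (Its chi-square p can still be small because every region carries the
        same planted anchor content, so the robust null property is the lack
        of a dominant histogram mode, not a uniform p.)
        """
        genome, regions = _spacing_genome(rng, 200, self.anchor, self.partner, 17)
        other = pwm_from_consensus("OTHER", "GGGTACCCAGT")
        res = motif_centered_rescan(regions, genome, self.anchor, [other])["OTHER"]
        mode_frac = res.histogram["count"].max() / res.n_regions
        assert mode_frac < 0.2

    def test_minus_strand_partner_reported(self, rng):
        genome, regions = _spacing_genome(
            rng, 200, self.anchor, self.partner, -23, strand="-"
        )
        res = motif_centered_rescan(regions, genome, self.anchor, [self.partner])["PARTNER"]
        assert res.modal_distances == [-23]
        assert (res.strands == "-").mean() > 0.95

    def test_low_quality_regions_discarded(self, rng):
        genome, regions = _spacing_genome(
            rng, 100, self.anchor, self.partner, 17, fraction=0.5
        )
        res = motif_centered_rescan(regions, genome, self.anchor, [self.partner])["PARTNER"]
        assert res.n_discarded >= 40  # ~half lack a good anchor instance
        assert res.n_regions + res.n_discarded == 100
        assert int(res.histogram["count"].sum()) == res.n_regions

    def test_no_passing_region_rejected(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 20_000))}
        regions = [("chr1", 1000 + 500 * i) for i in range(10)]
        anchor = pwm_from_consensus("A", "TTGACGTCAAGGTCCA", weight=1000)
        with pytest.raises(ValidationError, match="anchor"):
            motif_centered_rescan(regions, genome, anchor, [self.partner],
                                  quality_threshold=0.99)


class TestEnrichmentReport:
    def _setup(self, rng, plant_a=True, plant_b=True):
        a = pwm_from_consensus("MOTIF_A", "TTGACGTCAA")
        b = pwm_from_consensus("MOTIF_B", "CCAATCAG")
        decoy = pwm_from_consensus("DECOY", "GTAGGCATT")
        n = 300
        genome_len = (n + 2) * 1000
        arr = np.array(list("ACGT"))[rng.integers(0, 4, genome_len)]
        regions = []
        for i in range(n):
            c = (i + 1) * 1000
            regions.append(("chr1", c))
            if plant_a and i % 5 != 0:
                arr[c - 30 : c - 30 + len(a.consensus)] = list(a.consensus)
            if plant_b and i % 5 != 1:
                arr[c + 10 : c + 10 + len(b.consensus)] = list(b.consensus)
        genome = {"chr1": "".join(arr)}
        bg_arr = np.array(list("ACGT"))[rng.integers(0, 4, genome_len)]
        bg_genome = {"chr1": "".join(bg_arr)}
        background = [("chr1", (i + 1) * 1000) for i in range(n)]
        reports = enrichment_report(
            regions, genome, [a, b, decoy], background, background_genome=bg_genome
        )
        return reports

    def test_both_planted_rank_first_and_label(self, rng):
        reports = self._setup(rng)
        assert {reports[0].motif, reports[1].motif} == {"MOTIF_A", "MOTIF_B"}
        assert interpret_pair(reports, "MOTIF_A", "MOTIF_B") == "both bound"

    def test_tethered_case_label(self, rng):
        reports = self._setup(rng, plant_b=False)
        assert interpret_pair(reports, "MOTIF_A", "MOTIF_B") == "MOTIF_B: tethered (no motif)"

    def test_neither_planted_label(self, rng):
        reports = self._setup(rng, plant_a=False, plant_b=False)
        assert (
            interpret_pair(reports, "MOTIF_A", "MOTIF_B")
            == "no direct evidence; possible third factor"
        )

    def test_empty_library_rejected(self, rng):
        with pytest.raises(ValidationError):
            enrichment_report([("chr1", 500)], {"chr1": "A" * 1000}, [], [])


def test_out_of_bounds_window_skipped_with_warning():
    genome = {"chr1": "ACGT" * 100}
    pwm = pwm_from_consensus("M", "ACGTAC")
    with pytest.warns(UserWarning, match="out of bounds"):
        hits = scan_regions([("chr1", 10), ("chr1", 200)], genome, pwm, window=150)
    assert [h.region for h in hits] == [1]
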