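import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hortus import recruitment as rc
from hortus import synthetic_community as sc
from hortus.io_formats import SequenceRecord


def make_contigs(rng, lengths):
    return [
        SequenceRecord(id=f"ctg{i}", seq="".join(rng.choice(list("ACGT"), n)))
        for i, n in enumerate(lengths)
    ]


class TestPseudogenome:
    def test_ascending_offsets(self):
        rng = np.random.default_rng(0)
        pg = rc.build_pseudogenome(make_contigs(rng, [100, 50]), "g", "ascending")
        assert pg.contig_lengths == [50, 100]
        assert pg.offsets == [0, 50]
        assert pg.total_length == 150

    def test_coordinate_round_trip(self):
        rng = np.random.default_rng(1)
        pg = rc.build_pseudogenome(make_contigs(rng, [100, 50]), "g", "ascending")
        contig, local = pg.global_to_local(120)
        assert (contig, local) == ("ctg0", 70)  # the 100 bp contig sits at 50
        assert pg.local_to_global(contig, local) == 120
        for pos in range(pg.total_length):
            c, l = pg.global_to_local(pos)
            assert pg.local_to_global(c, l) == pos

    def test_descending_reverses_offsets(self):
        rng = np.random.default_rng(2)
        contigs = make_contigs(rng, [100, 50])
        asc = rc.build_pseudogenome(contigs, "g", "ascending")
        desc = rc.build_pseudogenome(contigs, "g", "descending")
        assert desc.contig_ids == asc.contig_ids[::-1]
        assert desc.seq != asc.seq and sorted(desc.seq) == sorted(asc.seq)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rc.build_pseudogenome([], "g")


class TestBandAssignment:
    def test_boundary_belongs_to_upper_band(self):
        assert rc.assign_band(95.0, rc.DEFAULT_BANDS) == "95-100"
        assert rc.assign_band(94.999, rc.DEFAULT_BANDS) == "90-95"

    def test_topmost_closed_at_100(self):
        assert rc.assign_band(100.0, rc.DEFAULT_BANDS) == "95-100"

    def test_below_range_bucket(self):
        assert rc.assign_band(60.0, rc.DEFAULT_BANDS) == rc.BELOW_RANGE


@pytest.fixture(scope="module")
def two_genome_db():
    pseudos = []
    for seed, name in ((30, "Klebsiella_like"), (31, "Pantoea_like")):
        rng = np.random.default_rng(seed)
        contigs = [
            SequenceRecord(id=f"{name}_ctg{i}",
                           seq="".join(rng.choice(list("ACGT"), n)))
            for i, n in enumerate([8_000, 12_000, 20_000])
        ]
        pseudos.append(rc.build_pseudogenome(contigs, name, "ascending"))
    return pseudos


class TestRecruitReads:
    def test_error_free_read_recruited_at_true_position(self, two_genome_db):
        pg = two_genome_db[0]
        read = SequenceRecord(id="r", seq=pg.seq[1000:1250])
        res = rc.recruit_reads([read], two_genome_db)
        row = res.table.iloc[0]
        assert row["genome_id"] == pg.genome_id
        assert row["position"] == 1000
        assert row["identity"] == 100.0

    def test_read_goes_to_closer_genome(self, two_genome_db):
        a, b = two_genome_db
        ref = SequenceRecord(id="frag", seq=b.seq[5000:5250])
        far = sc.mutate_strain(ref, 0.10, seed=1)
        read = SequenceRecord(id="r", seq=far.seq)
        # the same fragment, only slightly diverged, also exists in no other
        # genome, so the read must recruit to its true source b
        res = rc.recruit_reads([read], two_genome_db)
        assert res.table.iloc[0]["genome_id"] == b.genome_id

    def test_unrelated_read_absent(self, two_genome_db):
        rng = np.random.default_rng(4)
        read = SequenceRecord(id="r", seq="".join(rng.choice(list("ACGT"), 250)))
        res = rc.recruit_reads([read], two_genome_db)
        assert len(res.table) == 0

    def test_junction_spanning_read_flagged(self, two_genome_db):
        pg = two_genome_db[0]
        j = pg.offsets[1]
        read = SequenceRecord(id="r", seq=pg.seq[j - 100:j + 150])
        res = rc.recruit_reads([read], two_genome_db)
        assert bool(res.table.iloc[0]["junction"])

    def test_reverse_complement_read_recruited(self, two_genome_db):
        pg = two_genome_db[1]
        read = SequenceRecord(id="r", seq=pg.seq[2000:2250]).reverse_complement()
        res = rc.recruit_reads([read], two_genome_db)
        row = res.table.iloc[0]
        assert row["genome_id"] == pg.genome_id and row["identity"] == 100.0


class TestBandSummary:
    @staticmethod
    def result_from(identities, genome="g"):
        table = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(len(identities))],
            "genome_id": genome, "position": 0,
            "identity": identities,
            "band": [rc.assign_band(x, rc.DEFAULT_BANDS) for x in identities],
            "junction": False,
        })
        return rc.RecruitmentResult(table=table)

    def test_fraction_above_strict_cutoff(self):
        summary = rc.band_summary(self.result_from([99.0, 99.0, 97.0]))
        assert summary["fraction_gt_98"].item() == pytest.approx(2 / 3)

    def test_exactly_98_is_not_above(self):
        summary = rc.band_summary(self.result_from([98.0, 99.0]))
        assert summary["reads_gt_98"].item() == 1

    def test_conservation_across_bands(self):
        rng = np.random.default_rng(5)
        ids = rng.uniform(60, 100, size=200)
        summary = rc.band_summary(self.result_from(list(ids)))
        bands = [c for c in summary.columns
                 if "-" in str(c) or c == rc.BELOW_RANGE]
        assert summary[bands].sum(axis=1).item() == summary["total"].item() == 200

    def test_divergence_dichotomy_matches_binomial_tail(self, two_genome_db):
        """Strains at divergence 0.001 vs 0.03 give >98% fractions near 1
        and near 0, each within the 99% interval of the binomial oracle."""
        k_pg, p_pg = two_genome_db
        n = 150
        fracs = {}
        for pg, delta, seed in ((k_pg, 0.001, 6), (p_pg, 0.03, 7)):
            ref = SequenceRecord(id=pg.genome_id, seq=pg.seq)
            strain = sc.mutate_strain(ref, delta, seed=seed)
            spec = sc.CommunitySpec(seed=seed, n_reads=n, read_error_rate=0.0)
            reads, _ = sc.simulate_reads([strain], [1.0], spec)
            res = rc.recruit_reads(reads, [pg])
            t = res.table[res.table["genome_id"] == pg.genome_id]
            frac = (t["identity"] > 98.0).mean()
            p0 = stats.binom.cdf(4, 250, delta)  # >98% of 250 bp = <=4 mismatches
            half = 2.576 * np.sqrt(p0 * (1 - p0) / n) + 1.0 / n
            assert abs(frac - p0) <= half
            fracs[delta] = frac
        assert fracs[0.001] > 0.9 and fracs[0.03] < 0.3


class TestIdentitySummary:
    def test_two_point_mean_and_sd(self):
        t = TestBandSummary.result_from([98.0, 100.0])
        s = rc.identity_summary(t, min_reads=1)
        assert s["mean_identity"].item() == pytest.approx(99.0)
        assert s["sd_identity"].item() == pytest.approx(np.sqrt(2))

    def test_min_reads_is_strict(self):
        t = TestBandSummary.result_from([99.0] * 100)
        assert len(rc.identity_summary(t, min_reads=100)) == 0
        assert len(rc.identity_summary(t, min_reads=99)) == 1

    def test_mean_identity_tracks_divergence(self, two_genome_db):
        pg = two_genome_db[0]
        ref = SequenceRecord(id="ref", seq=pg.seq)
        strain = sc.mutate_strain(ref, 0.02, seed=8)
        spec = sc.CommunitySpec(seed=8, n_reads=150, read_error_rate=0.0)
        reads, _ = sc.simulate_reads([strain], [1.0], spec)
        res = rc.recruit_reads(reads, [pg])
        s = rc.identity_summary(res, min_reads=100)
        assert s["mean_identity"].item() == pytest.approx(98.0, abs=0.3)


class TestGcTrack:
    def test_homogeneous_genome_deviations_near_zero(self):
        rng = np.random.default_rng(9)
        pg = rc.build_pseudogenome(make_contigs(rng, [40_000]), "g")
        track = rc.gc_track(pg, window=10_000, step=1_000)
        assert track["gc_deviation"].abs().max() < 2.0  # binomial noise scale

    def test_planted_gc_island_detected(self):
        rng = np.random.default_rng(10)
        seq = list("".join(rng.choice(list("ACGT"), 60_000)))
        seq[25_000:35_000] = list("".join(rng.choice(["G", "C"], 10_000)))
        pg = rc.build_pseudogenome([SequenceRecord(id="c", seq="".join(seq))], "g")
        track = rc.gc_track(pg, window=5_000, step=1_000)
        inside = track[(track["start"] >= 25_000) & (track["end"] <= 35_000)]
        outside = track[track["end"] <= 20_000]
        # the pure-GC island pulls the genome mean up ~8 points, so the
        # island sits far above the mean and the background below it
        assert inside["gc_deviation"].min() > 20.0
        assert outside["gc_deviation"].max() < 0.0

    def test_windows_tile_to_genome_end(self):
        rng = np.random.default_rng(11)
        pg = rc.build_pseudogenome(make_contigs(rng, [12_345]), "g")
        track = rc.gc_track(pg, window=5_000, step=1_000)
        assert track["end"].iloc[-1] == pg.total_length
        assert (track["start"].diff().dropna() == 1_000).all()

    def test_window_larger_than_genome_rejected(self):
        rng = np.random.default_rng(12)
        pg = rc.build_pseudogenome(make_contigs(rng, [1_000]), "g")
        with pytest.raises(ValueError):
            rc.gc_track(pg, window=5_000, step=1_000)
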