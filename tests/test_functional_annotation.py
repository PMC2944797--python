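import numpy as np
import pytest

from hortus import functional_annotation as fa
from hortus import synthetic_community as sc
from hortus.datasets import leafcutter_garden_cazy_annotations
from hortus.io_formats import SequenceRecord


class TestCallOrfs:
    def test_minimal_orf(self):
        (orf,) = fa.call_orfs(SequenceRecord(id="c", seq="ATGAAATAA"), min_orf_codons=2)
        prot, start, end, strand = orf
        assert prot.seq == "MK"
        assert (start, end, strand) == (0, 9, "+")

    def test_no_start_codon_yields_nothing(self):
        assert fa.call_orfs(SequenceRecord(id="c", seq="AAATTTCCCGGG"), 1) == []

    def test_minus_strand_orf_coordinates(self):
        from Bio.Seq import Seq

        fwd = "ATGAAACCCTAA"
        contig = SequenceRecord(id="c", seq=str(Seq(fwd).reverse_complement()))
        (orf,) = fa.call_orfs(contig, min_orf_codons=2)
        prot, start, end, strand = orf
        assert prot.seq == "MKP"
        assert strand == "-"
        assert contig.seq[start:end] == str(Seq(fwd).reverse_complement())

    def test_min_length_filter(self):
        seq = "ATG" + "AAA" * 10 + "TAA"
        assert fa.call_orfs(SequenceRecord(id="c", seq=seq), min_orf_codons=60) == []
        assert len(fa.call_orfs(SequenceRecord(id="c", seq=seq), min_orf_codons=5)) >= 1


class TestDualEvidenceCazy:
    def proteins_from(self, family_db, fams, rng):
        """Novel proteins carrying each family's motif between fresh flanks."""
        out = []
        for i, fam in enumerate(fams):
            aas = sorted("ACDEFGHIKLMNPQRSTVWY")
            flank1 = "".join(rng.choice(aas, 25))
            flank2 = "".join(rng.choice(aas, 25))
            out.append(SequenceRecord(
                id=f"p_{fam}_{i}", seq=flank1 + family_db.motifs[fam] + flank2,
                alphabet="protein",
            ))
        return out

    def test_motif_bearing_protein_gets_its_family(self, family_db):
        rng = np.random.default_rng(0)
        prots = self.proteins_from(family_db, family_db.families, rng)
        anns = {a.protein_id: a for a in fa.annotate_cazy(prots, family_db)}
        for prot, fam in zip(prots, family_db.families):
            assert anns[prot.id].families == [fam]
            me, de = anns[prot.id].evidence[fam]
            assert me <= 1e-5 and de <= 1e-5

    def test_member_hit_without_domain_hit_rejected(self, family_db):
        # a member's flank region hits the member but carries no motif,
        # so the domain channel stays silent and the protein is dropped
        fam = family_db.families[0]
        member = family_db.members[fam][0]
        flank_only = SequenceRecord(
            id="flank", seq=member.seq[:30], alphabet="protein"
        )
        mem_e, dom_e = fa.gather_evidence([flank_only], family_db)["flank"]
        assert mem_e.get(fam, 1.0) <= 1e-5
        assert family_db.family_to_domain[fam] not in dom_e
        assert fa.annotate_cazy([flank_only], family_db) == []

    def test_bifunctional_protein_gets_both_families(self, family_db):
        f1, f2 = family_db.families[:2]
        rng = np.random.default_rng(1)
        aas = sorted("ACDEFGHIKLMNPQRSTVWY")
        prot = SequenceRecord(
            id="bifunctional",
            seq="".join(rng.choice(aas, 15)) + family_db.motifs[f1]
            + "".join(rng.choice(aas, 15)) + family_db.motifs[f2],
            alphabet="protein",
        )
        (ann,) = fa.annotate_cazy([prot], family_db)
        assert ann.families == sorted([f1, f2])

    def test_dual_evidence_subset_of_single_evidence(self, family_db, planted_contigs):
        contigs, _ = planted_contigs
        peptides = []
        rng = np.random.default_rng(2)
        prots = self.proteins_from(family_db, family_db.families, rng)
        evidence = fa.gather_evidence(prots, family_db)
        dual = fa.annotate_cazy(prots, family_db)
        for ann in dual:
            mem_e, dom_e = evidence[ann.protein_id]
            for fam in ann.families:
                assert fam in mem_e  # member-evidence-only set
                assert family_db.family_to_domain[fam] in dom_e  # domain-only set


class TestTranslatedAnnotation:
    def test_planted_genes_recovered_at_contig_level(self, family_db, planted_contigs):
        contigs, truths = planted_contigs
        anns = {a.protein_id: a for a in fa.annotate_cazy_translated(contigs, family_db)}
        for contig, truth in zip(contigs, truths):
            expected = sorted(truth["family"])
            assert anns[contig.id].families == expected

    def test_reverse_complement_invariance(self, family_db, planted_contigs):
        contigs, _ = planted_contigs
        contig = contigs[0]
        rc = contig.reverse_complement()
        a = fa.annotate_cazy_translated([contig], family_db)
        b = fa.annotate_cazy_translated([rc], family_db)
        assert [x.families for x in a] == [x.families for x in b]

    def test_random_contigs_yield_no_annotation(self, family_db):
        rng = np.random.default_rng(3)
        contigs = [
            SequenceRecord(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), 1000)))
            for i in range(20)
        ]
        assert fa.annotate_cazy_translated(contigs, family_db) == []


class TestSummarizeFamilies:
    def test_published_counts_reproduce_grand_totals(self):
        summary = fa.summarize_families(leafcutter_garden_cazy_annotations())
        assert summary.n_modules == 69
        assert summary.n_families == 28

    def test_singleton(self):
        ann = fa.CazymeAnnotation("p", ["GH8"], {"GH8": (1e-30, 1e-12)}, "gamma")
        summary = fa.summarize_families([ann])
        assert summary.n_modules == 1 and summary.n_families == 1

    def test_breakdown_sums_to_module_count(self):
        summary = fa.summarize_families(leafcutter_garden_cazy_annotations())
        groups = [c for c in summary.table.columns if c not in ("family", "modules")]
        assert (summary.table[groups].sum(axis=1) == summary.table["modules"]).all()

    def test_totals_invariant_to_input_order(self):
        anns = leafcutter_garden_cazy_annotations()
        a = fa.summarize_families(anns)
        b = fa.summarize_families(anns[::-1])
        assert a.n_modules == b.n_modules and a.n_families == b.n_families
        assert a.table.equals(b.table)


@pytest.fixture(scope="module")
def cog_db():
    rng = np.random.default_rng(4)
    aas = sorted("ACDEFGHIKLMNPQRSTVWY")
    members = {
        f"COG{i:04d}": [SequenceRecord(
            id=f"COG{i:04d}__m1", seq="".join(rng.choice(aas, 80)),
            alphabet="protein",
        )]
        for i in range(5)
    }
    cats = dict(zip(members, "GEKLC"))
    return fa.CogDb(members=members, categories=cats)


class TestCog:
    def test_label_propagation(self, cog_db):
        member = cog_db.members["COG0002"][0]
        query = SequenceRecord(id="q", seq=member.seq, alphabet="protein")
        anns, table = fa.annotate_cog([query], cog_db)
        assert anns[0].cog_id == "COG0002" and anns[0].category == "K"

    def test_category_proportions_sum_to_one(self, cog_db):
        queries = [
            SequenceRecord(id=f"q{i}", seq=m[0].seq, alphabet="protein")
            for i, m in enumerate(cog_db.members.values())
        ]
        _, table = fa.annotate_cog(queries, cog_db)
        assert table["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_annotation_rate_on_half_planted_fixture(self, cog_db):
        rng = np.random.default_rng(5)
        aas = sorted("ACDEFGHIKLMNPQRSTVWY")
        planted = [
            SequenceRecord(id=f"hit{i}",
                           seq=cog_db.members[f"COG{i % 5:04d}"][0].seq,
                           alphabet="protein")
            for i in range(50)
        ]
        noise = [
            SequenceRecord(id=f"noise{i}", seq="".join(rng.choice(aas, 80)),
                           alphabet="protein")
            for i in range(50)
        ]
        anns, _ = fa.annotate_cog(planted + noise, cog_db)
        assert len(anns) / 100 == pytest.approx(0.50, abs=0.02)

    def test_missing_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            fa.CogDb(
                members={"COG1": [SequenceRecord(id="m", seq="MKL" * 10,
                                                 alphabet="protein")]},
                categories={},
            )
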