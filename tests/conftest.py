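import numpy as np
import pytest

from hortus import synthetic_community as sc
from hortus.io_formats import SequenceRecord


@pytest.fixture(scope="session")
def community_spec():
    return sc.CommunitySpec(seed=7)


@pytest.fixture(scope="session")
def reference_collection(community_spec):
    return sc.generate_reference_collection(community_spec)


@pytest.fixture(scope="session")
def family_db():
    specs = [
        sc.FamilySpec("GH8-like", n_members=2, motif_length=40),
        sc.FamilySpec("GH18-like", n_members=2, motif_length=40),
        sc.FamilySpec("CE4-like", n_members=2, motif_length=40),
    ]
    return sc.generate_family_db(specs, seed=11)


@pytest.fixture(scope="session")
def planted_contigs(family_db):
    """Contigs each carrying one known family gene (strands randomized)."""
    from hortus.functional_annotation import FamilyDb

    rng = np.random.default_rng(13)
    contigs, truths = [], []
    for i, fam in enumerate(family_db.families):
        base = "".join(rng.choice(list("ACGT"), size=3000))
        dom = family_db.family_to_domain[fam]
        sub = FamilyDb(
            members={fam: family_db.members[fam]},
            domains={dom: family_db.domains[dom]},
            family_to_domain={fam: dom},
            motifs={fam: family_db.motifs[fam]},
        )
        contig, truth = sc.plant_family_genes(
            SequenceRecord(id=f"contig_{i}", seq=base), sub,
            copies_per_family=1, seed=100 + i, strands="both",
        )
        contigs.append(contig)
        truths.append(truth)
    return contigs, truths
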