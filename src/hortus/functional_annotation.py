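"""ORF calling, dual-evidence CAZy annotation, and COG assignment.

A protein is designated a carbohydrate-active enzyme for family F only
when it has BOTH a significant hit to F's member proteins AND a
significant hit to F's correlated protein domain (the family->domain
correlation list) — two independent evidence channels at the same
e-value cutoff. A protein may carry several families ("modules": one
module = one (protein, family) assignment); hits to multiple members of
the same family count once.

COG assignment is single-evidence best-hit, with the standard
one-letter functional categories tabulated as proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .io_formats import SequenceRecord, read_fasta, write_fasta
from . import homology_search as hs

__all__ = [
    "FamilyDb",
    "CazymeAnnotation",
    "CogAnnotation",
    "CogDb",
    "call_orfs",
    "annotate_cazy",
    "annotate_cazy_translated",
    "gather_evidence",
    "summarize_families",
    "annotate_cog",
]

COG_CATEGORIES = set("JAKLBDYVTMNZWUOCGEFHIPQRSX")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FamilyDb:
    """Family member proteins, correlated domains, and the family->domain map."""

    members: dict[str, list[SequenceRecord]]
    domains: dict[str, list[SequenceRecord]]
    family_to_domain: dict[str, str]
    motifs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("family database is empty")
        for fam, mem in self.members.items():
            if not mem:
                raise ValueError(f"family {fam} has no members")
            dom = self.family_to_domain.get(fam)
            if dom is None:
                raise ValueError(f"family {fam} has no correlated domain")
            if dom not in self.domains:
                raise ValueError(f"domain {dom} (family {fam}) unresolvable")

    @property
    def families(self) -> list[str]:
        return sorted(self.members)

    def member_family(self, member_id: str) -> str:
        for fam, mem in self.members.items():
            if any(m.id == member_id for m in mem):
                return fam
        raise KeyError(member_id)

    def save(self, out_dir: str | Path) -> None:
        """On-disk layout: members.fasta + domains.fasta + family_domain_map.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta([m for mem in self.members.values() for m in mem],
                    out / "members.fasta")
        write_fasta([d for doms in self.domains.values() for d in doms],
                    out / "domains.fasta")
        pd.DataFrame(
            [{"family_id": f, "domain_id": d} for f, d in sorted(self.family_to_domain.items())]
        ).to_csv(out / "family_domain_map.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "FamilyDb":
        """Member ids must be ``<family>__<token>``; domain ids may carry ``__`` suffixes."""
        d = Path(in_dir)
        fam2dom = {
            str(r.family_id): str(r.domain_id)
            for r in pd.read_csv(d / "family_domain_map.tsv", sep="\t").itertuples()
        }
        members: dict[str, list[SequenceRecord]] = {}
        for rec in read_fasta(d / "members.fasta", alphabet="protein"):
            fam = rec.id.split("__")[0]
            members.setdefault(fam, []).append(rec)
        domains: dict[str, list[SequenceRecord]] = {}
        for rec in read_fasta(d / "domains.fasta", alphabet="protein"):
            domains.setdefault(rec.id.split("__")[0], []).append(rec)
        return cls(members=members, domains=domains, family_to_domain=fam2dom)


@dataclass
class CazymeAnnotation:
    """One protein's family assignments with their dual evidence."""

    protein_id: str
    families: list[str]
    evidence: dict[str, tuple[float, float]]  # family -> (member e, domain e)
    source_group: str = "Unknown"

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError(f"{self.protein_id}: annotation without families")
        if len(set(self.families)) != len(self.families):
            raise ValueError(f"{self.protein_id}: duplicate family assignment")


@dataclass
class CogAnnotation:
    protein_id: str
    cog_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in COG_CATEGORIES:
            raise ValueError(
                f"{self.cog_id}: category {self.category!r} not a standard COG category"
            )


@dataclass
class CogDb:
    members: dict[str, list[SequenceRecord]]  # cog id -> member proteins
    categories: dict[str, str]  # cog id -> one-letter category

    def __post_init__(self) -> None:
        for cog in self.members:
            cat = self.categories.get(cog)
            if cat is None:
                raise ValueError(f"COG {cog} has no functional category")
            if cat not in COG_CATEGORIES:
                raise ValueError(f"COG {cog}: category {cat!r} not standard")


# ---------------------------------------------------------------------------
# ORF calling


def call_orfs(
    contig: SequenceRecord, min_orf_codons: int = 60
) -> list[tuple[SequenceRecord, int, int, str]]:
    """All maximal start->stop ORFs on the six frames, naive caller.

    Returns (protein record, start, end, strand) with 0-based half-open
    coordinates on the forward strand; the stop codon is inside
    [start, end). ``min_orf_codons`` counts coding codons including the
    start codon but not the stop. Contigs without ORFs yield an empty
    list.
    """
    if contig.alphabet != "nucleotide":
        raise ValueError("ORF calling requires nucleotide input")
    L = len(contig.seq)
    found: list[tuple[int, int, str]] = []
    rc = str(Seq(contig.seq).reverse_complement())
    for strand, s in (("+", contig.seq), ("-", rc)):
        for f in range(3):
            start_codon: int | None = None
            for p in range(f, L - 2, 3):
                codon = s[p:p + 3]
                if codon in _STOPS:
                    if start_codon is not None and (p - start_codon) // 3 >= min_orf_codons:
                        a, b = start_codon, p + 3
                        if strand == "-":
                            a, b = L - b, L - start_codon
                        found.append((a, b, strand))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = p
    out = []
    found.sort()
    for n, (a, b, strand) in enumerate(found, start=1):
        sub = contig.seq[a:b]
        if strand == "-":
            sub = str(Seq(sub).reverse_complement())
        prot = str(Seq(sub[:-3]).translate())
        out.append((
            SequenceRecord(
                id=f"{contig.id}|orf{n}", seq=prot, alphabet="protein",
                description=f"{contig.id}:{a}-{b}({strand})",
            ),
            a, b, strand,
        ))
    return out


# ---------------------------------------------------------------------------
# dual-evidence CAZy annotation


def _family_indexes(db: FamilyDb, k: int = 4):
    member_records = [m for mem in db.members.values() for m in mem]
    domain_records = [d for doms in db.domains.values() for d in doms]
    midx = hs.build_index(member_records, k=k)
    didx = hs.build_index(domain_records, k=k)
    member_fam = {m.id: fam for fam, mem in db.members.items() for m in mem}
    domain_of = {d.id: dom for dom, doms in db.domains.items() for d in doms}
    return midx, didx, member_fam, domain_of


def gather_evidence(
    proteins: Sequence[SequenceRecord], db: FamilyDb, evalue_max: float = 1e-5
) -> dict[str, tuple[dict[str, float], dict[str, float]]]:
    """Per protein: best member e-value per family, best domain e-value per domain."""
    if not db.members:
        raise ValueError("empty family database")
    midx, didx, member_fam, domain_of = _family_indexes(db)
    out: dict[str, tuple[dict[str, float], dict[str, float]]] = {}
    for prot in proteins:
        mem_e: dict[str, float] = {}
        for hit in hs.search_all(prot, midx, evalue_max):
            fam = member_fam[hit.subject_id]
            mem_e[fam] = min(mem_e.get(fam, float("inf")), hit.e_value)
        dom_e: dict[str, float] = {}
        for hit in hs.search_all(prot, didx, evalue_max):
            dom = domain_of[hit.subject_id]
            dom_e[dom] = min(dom_e.get(dom, float("inf")), hit.e_value)
        out[prot.id] = (mem_e, dom_e)
    return out


def annotate_cazy(
    proteins: Sequence[SequenceRecord],
    db: FamilyDb,
    evalue_max: float = 1e-5,
    source_groups: Mapping[str, str] | None = None,
) -> list[CazymeAnnotation]:
    """Dual-evidence family assignment.

    Family F is assigned iff the protein hits one of F's members AND F's
    correlated domain, both at e <= evalue_max. Member evidence for F
    combined with domain evidence only for some other, uncorrelated
    family confers nothing.
    """
    evidence = gather_evidence(proteins, db, evalue_max)
    out = []
    for prot in proteins:
        mem_e, dom_e = evidence[prot.id]
        assigned: dict[str, tuple[float, float]] = {}
        for fam, me in sorted(mem_e.items()):
            de = dom_e.get(db.family_to_domain[fam])
            if me <= evalue_max and de is not None and de <= evalue_max:
                assigned[fam] = (me, de)
        if assigned:
            out.append(CazymeAnnotation(
                protein_id=prot.id, families=sorted(assigned),
                evidence=assigned,
                source_group=(source_groups or {}).get(prot.id, "Unknown"),
            ))
    return out


def annotate_cazy_translated(
    contigs: Sequence[SequenceRecord],
    db: FamilyDb,
    evalue_max: float = 1e-5,
    min_peptide: int = 20,
    source_groups: Mapping[str, str] | None = None,
) -> list[CazymeAnnotation]:
    """Dual-evidence annotation of nucleotide input via six-frame translation.

    Evidence is gathered over every stop-free peptide (>= ``min_peptide``
    residues) of all six reading frames and attributed to the contig id,
    so the result is identical for a contig and its reverse complement.
    """
    if not contigs:
        raise ValueError("no contigs to annotate")
    out = []
    for contig in contigs:
        peptides: list[SequenceRecord] = []
        for frame in hs.six_frame_translate(contig):
            for i, pep in enumerate(frame.seq.split("*")):
                if len(pep) >= min_peptide:
                    peptides.append(SequenceRecord(
                        id=f"{frame.id}|pep{i}", seq=pep, alphabet="protein",
                    ))
        if not peptides:
            continue
        evidence = gather_evidence(peptides, db, evalue_max)
        mem_e: dict[str, float] = {}
        dom_e: dict[str, float] = {}
        for me, de in evidence.values():
            for fam, e in me.items():
                mem_e[fam] = min(mem_e.get(fam, float("inf")), e)
            for dom, e in de.items():
                dom_e[dom] = min(dom_e.get(dom, float("inf")), e)
        assigned = {
            fam: (me, dom_e[db.family_to_domain[fam]])
            for fam, me in sorted(mem_e.items())
            if me <= evalue_max
            and dom_e.get(db.family_to_domain[fam], float("inf")) <= evalue_max
        }
        if assigned:
            out.append(CazymeAnnotation(
                protein_id=contig.id, families=sorted(assigned),
                evidence=assigned,
                source_group=(source_groups or {}).get(contig.id, "Unknown"),
            ))
    return out


@dataclass
class FamilySummary:
    table: pd.DataFrame  # family, modules, per-source-group breakdown
    n_modules: int
    n_families: int


def summarize_families(annotations: Sequence[CazymeAnnotation]) -> FamilySummary:
    """Per-family module counts with source-group breakdown and grand totals.

    A module is one (protein, family) pair, so a bifunctional protein
    contributes one module to each of its families. Totals are invariant
    to input order.
    """
    rows = []
    for ann in annotations:
        for fam in ann.families:
            rows.append({"family": fam, "source_group": ann.source_group})
    if not rows:
        return FamilySummary(
            table=pd.DataFrame(columns=["family", "modules"]),
            n_modules=0, n_families=0,
        )
    df = pd.DataFrame(rows)
    breakdown = (
        df.groupby(["family", "source_group"]).size().unstack(fill_value=0)
    )
    table = breakdown.sum(axis=1).rename("modules").to_frame()
    table = table.join(breakdown).sort_index().reset_index()
    return FamilySummary(
        table=table,
        n_modules=len(df),
        n_families=df["family"].nunique(),
    )


def annotate_cog(
    proteins: Sequence[SequenceRecord],
    cog_db: CogDb,
    evalue_max: float = 1e-5,
) -> tuple[list[CogAnnotation], pd.DataFrame]:
    """Best-COG-per-protein assignment plus the category proportion table.

    Proportions are taken over annotated proteins only and sum to 1.
    """
    records = [m for mem in cog_db.members.values() for m in mem]
    idx = hs.build_index(records, k=4)
    member_cog = {m.id: cog for cog, mem in cog_db.members.items() for m in mem}
    out: list[CogAnnotation] = []
    for prot in proteins:
        hit = hs.top_hit(prot, idx, evalue_max)
        if hit is None:
            continue
        cog = member_cog[hit.subject_id]
        out.append(CogAnnotation(
            protein_id=prot.id, cog_id=cog, category=cog_db.categories[cog],
        ))
    if out:
        counts = pd.Series([a.category for a in out]).value_counts().sort_index()
        props = (counts / counts.sum()).rename("proportion").rename_axis("category")
        table = props.reset_index()
    else:
        table = pd.DataFrame(columns=["category", "proportion"])
    return out, table
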