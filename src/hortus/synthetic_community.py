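"""Synthetic multi-genus communities with known truth labels.

Generates reference genomes at controlled GC, symbiont-like strains
diverged from them at a per-site substitution rate, protein-family
databases whose members share a conserved motif, genomes seeded with
known family genes, and fixed-length reads with i.i.d. substitution
errors. Every simulated read and planted gene is recorded in a truth
table so recovery can be scored exactly.

The mutation and read-error models are substitution-only: the identity
of an error-free read drawn from a strain at divergence d is then
distributed as 100 * (1 - Binomial(L, d) / L), which the recruitment
statistics are checked against.

Randomness: each operation derives its own numpy Generator from
``seed + <fixed per-operation offset>``, so operations are reproducible
independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .functional_annotation import FamilyDb
from .io_formats import SequenceRecord

__all__ = [
    "GenusSpec",
    "CommunitySpec",
    "FamilySpec",
    "generate_reference_collection",
    "mutate_strain",
    "generate_family_db",
    "plant_family_genes",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed per-operation RNG offsets
_OFF_GENOMES = 11
_OFF_STRAIN = 23
_OFF_FAMILIES = 37
_OFF_PLANT = 41
_OFF_READS = 53

# codons per amino acid, standard code, stops excluded
_CODONS: dict[str, list[str]] = {}
for _c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3)):
    _aa = str(Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)
_AA20 = sorted(_CODONS)


@dataclass(frozen=True)
class GenusSpec:
    name: str
    superkingdom: str = "Bacterial"
    abundance: float = 1.0
    genome_length: int = 50_000
    gc: float = 0.5


@dataclass
class CommunitySpec:
    """Generative truth for a synthetic community.

    Defaults emulate the community structure the pipeline targets: a
    bacterial community dominated by two enterobacterial genera
    (Pantoea- and Klebsiella-like, jointly ~45% of sequences) over a
    tail of minor genera, ~55% GC genomes, and 250 bp reads (a typical
    pyrosequencing read length) with a 1% per-base substitution error.
    """

    genera: list[GenusSpec] = field(default_factory=lambda: [
        GenusSpec("Pantoea", "Bacterial", 0.30, 60_000, 0.55),
        GenusSpec("Klebsiella", "Bacterial", 0.15, 60_000, 0.57),
        GenusSpec("Bradyrhizobium", "Bacterial", 0.15, 50_000, 0.63),
        GenusSpec("Streptomyces", "Bacterial", 0.15, 50_000, 0.70),
        GenusSpec("Burkholderia", "Bacterial", 0.15, 50_000, 0.66),
        GenusSpec("Solibacter", "Bacterial", 0.10, 40_000, 0.61),
    ])
    strain_divergence: float | Mapping[str, float] = 0.02
    read_length_bp: int = 250
    read_error_rate: float = 0.01
    n_reads: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genera:
            raise ValueError("community needs at least one genus")
        total = sum(g.abundance for g in self.genera)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        divs = (
            self.strain_divergence.values()
            if isinstance(self.strain_divergence, Mapping)
            else [self.strain_divergence]
        )
        for d in divs:
            if not 0.0 <= d <= 0.25:
                raise ValueError(f"strain divergence {d} outside [0, 0.25]")
        if not 0.0 <= self.read_error_rate <= 0.25:
            raise ValueError("read error rate outside [0, 0.25]")
        for g in self.genera:
            if g.genome_length <= 0:
                raise ValueError(f"genome length for {g.name} must be > 0")
            if not 0.0 <= g.gc <= 1.0:
                raise ValueError(f"GC fraction for {g.name} outside [0, 1]")
        if self.read_length_bp <= 0 or self.n_reads < 0:
            raise ValueError("read length must be > 0 and read count >= 0")


@dataclass(frozen=True)
class FamilySpec:
    """A CAZy-like protein family with a conserved motif and a correlated domain."""

    family_id: str
    n_members: int = 3
    motif_length: int = 40
    domain_id: str = ""

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("family needs >= 1 member")
        if self.motif_length < 10:
            raise ValueError("motif must be >= 10 residues")
        if not self.domain_id:
            object.__setattr__(self, "domain_id", f"Dom_{self.family_id}")


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def generate_reference_collection(
    spec: CommunitySpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """One reference genome per genus plus its taxonomy table.

    Genome bases are i.i.d. at the genus GC fraction. Deterministic for
    a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed + _OFF_GENOMES)
    records, rows = [], []
    for g in spec.genera:
        gid = f"{g.name}_ref"
        records.append(SequenceRecord(
            id=gid, seq=_random_genome(rng, g.genome_length, g.gc),
            description=f"synthetic reference genome, genus {g.name}",
        ))
        rows.append({"genome_id": gid, "genus": g.name, "superkingdom": g.superkingdom})
    return records, pd.DataFrame(rows)


def mutate_strain(
    genome: SequenceRecord, divergence: float, seed: int
) -> SequenceRecord:
    """Substitute each site independently with probability ``divergence``.

    Substituted sites take one of the three alternative bases uniformly,
    so every substituted site differs from the reference; length is
    preserved. Protein input is rejected.
    """
    if genome.alphabet != "nucleotide":
        raise ValueError("can only mutate nucleotide genomes")
    if not 0.0 <= divergence <= 0.25:
        raise ValueError(f"divergence {divergence} outside [0, 0.25]")
    rng = np.random.default_rng(seed + _OFF_STRAIN)
    arr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < divergence
    n = int(mask.sum())
    if n:
        base_idx = np.searchsorted(_BASES, arr[mask])
        shift = rng.integers(1, 4, size=n)
        arr[mask] = _BASES[(base_idx + shift) % 4]
    return SequenceRecord(
        id=f"{genome.id}_strain", seq=arr.tobytes().decode("ascii"),
        description=f"strain of {genome.id} at divergence {divergence}",
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length))


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def generate_family_db(
    specs: Sequence[FamilySpec], seed: int, flank_length: int = 30
) -> FamilyDb:
    """Build a family database whose members share a conserved motif.

    Each family gets a random motif of the requested length; members are
    the motif between random flanks, and the correlated domain's model
    sequence is the motif itself (an independent second evidence channel
    keyed by the family->domain correlation list).
    """
    rng = np.random.default_rng(seed + _OFF_FAMILIES)
    members: dict[str, list[SequenceRecord]] = {}
    domains: dict[str, list[SequenceRecord]] = {}
    fam2dom: dict[str, str] = {}
    motifs: dict[str, str] = {}
    for fs in specs:
        motif = _random_protein(rng, fs.motif_length)
        motifs[fs.family_id] = motif
        members[fs.family_id] = [
            SequenceRecord(
                id=f"{fs.family_id}__m{i + 1}",
                seq=_random_protein(rng, flank_length) + motif
                + _random_protein(rng, flank_length),
                alphabet="protein",
                description=f"synthetic member of family {fs.family_id}",
            )
            for i in range(fs.n_members)
        ]
        domains[fs.domain_id] = [SequenceRecord(
            id=fs.domain_id, seq=motif, alphabet="protein",
            description=f"synthetic domain model correlated with {fs.family_id}",
        )]
        fam2dom[fs.family_id] = fs.domain_id
    return FamilyDb(members=members, domains=domains, family_to_domain=fam2dom,
                    motifs=motifs)


def plant_family_genes(
    genome: SequenceRecord,
    db: FamilyDb,
    copies_per_family: int = 1,
    seed: int = 0,
    flank_codons: int = 16,
    strands: str = "both",
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Overwrite random non-overlapping genome segments with family genes.

    Each planted insert is an in-frame stop, a start codon, codons for
    (random flank + family motif + random flank), and a stop codon, so a
    naive ORF caller recovers exactly the planted coordinates. The truth
    table records gene id, family, 0-based half-open coordinates of the
    ORF (start codon through stop codon) on the forward strand, and
    strand.
    """
    if genome.alphabet != "nucleotide":
        raise ValueError("genes can only be planted into nucleotide genomes")
    rng = np.random.default_rng(seed + _OFF_PLANT)
    fams = db.families
    inserts: list[tuple[str, str, str]] = []  # (gene_id, family, insert seq fwd-orf)
    for fam in fams:
        for c in range(copies_per_family):
            protein = (
                "M" + _random_protein(rng, flank_codons)
                + db.motifs[fam] + _random_protein(rng, flank_codons)
            )
            orf = _reverse_translate(rng, protein) + "TAA"
            inserts.append((f"{fam}_gene{c + 1}", fam, orf))
    total = sum(len(ins) + 3 for _, _, ins in inserts)
    L = len(genome.seq)
    if total > L:
        raise ValueError(
            f"genome {genome.id} ({L} bp) too short for {len(inserts)} inserts "
            f"({total} bp)"
        )
    # choose non-overlapping slots by rejection
    taken: list[tuple[int, int]] = []
    rows = []
    seq = list(genome.seq)
    for gene_id, fam, orf in inserts:
        ins_len = len(orf) + 3  # leading in-frame stop
        for _ in range(10_000):
            pos = int(rng.integers(0, L - ins_len + 1))
            if all(pos + ins_len <= s or pos >= e for s, e in taken):
                break
        else:
            raise ValueError("could not place all gene inserts without overlap")
        taken.append((pos, pos + ins_len))
        strand = "+" if strands == "forward" else ("+", "-")[rng.integers(2)]
        if strand == "+":
            insert = "TAA" + orf
            start, end = pos + 3, pos + 3 + len(orf)
        else:
            insert = str(Seq("TAA" + orf).reverse_complement())
            start, end = pos, pos + len(orf)
        seq[pos:pos + ins_len] = insert
        rows.append({
            "gene_id": gene_id, "family": fam, "genome_id": genome.id,
            "start": start, "end": end, "strand": strand,
        })
    truth = pd.DataFrame(rows)
    return (
        SequenceRecord(
            id=genome.id, seq="".join(seq),
            description=genome.description + f" + {len(inserts)} planted family genes",
        ),
        truth,
    )


def simulate_reads(
    genomes: Sequence[SequenceRecord],
    abundances: Sequence[float],
    spec: CommunitySpec,
    references: Mapping[str, str] | None = None,
    taxonomy: Mapping[str, str] | None = None,
    strands: str = "forward",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw fixed-length reads with i.i.d. substitution errors.

    Each read's source genome is drawn with probability equal to its
    abundance, the start is uniform, and each base is substituted
    independently at ``spec.read_error_rate``. ``references`` optionally
    maps a genome id to the undiverged reference sequence so the truth
    table can record each read's true identity to the reference (strain
    divergence plus read error); otherwise identity is measured against
    the source genome itself.
    """
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    if len(genomes) != len(abundances):
        raise ValueError("one abundance per genome required")
    L = spec.read_length_bp
    for g in genomes:
        if L > len(g.seq):
            raise ValueError(f"read length {L} exceeds genome {g.id} ({len(g.seq)} bp)")
    rng = np.random.default_rng(spec.seed + _OFF_READS)
    choice = rng.choice(len(genomes), size=spec.n_reads, p=np.asarray(abundances))
    reads: list[SequenceRecord] = []
    rows = []
    width = max(6, len(str(max(spec.n_reads, 1))))
    for i, gi in enumerate(choice):
        g = genomes[gi]
        start = int(rng.integers(0, len(g.seq) - L + 1))
        frag = g.seq[start:start + L]
        strand = "+" if strands == "forward" else ("+", "-")[rng.integers(2)]
        arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
        mask = rng.random(L) < spec.read_error_rate
        n_err = int(mask.sum())
        if n_err:
            base_idx = np.searchsorted(_BASES, arr[mask])
            shift = rng.integers(1, 4, size=n_err)
            arr[mask] = _BASES[(base_idx + shift) % 4]
        seq = arr.tobytes().decode("ascii")
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        ref = references.get(g.id) if references else None
        template = ref[start:start + L] if ref is not None else frag
        read_fwd = arr.tobytes().decode("ascii")
        mismatches = sum(a != b for a, b in zip(read_fwd, template))
        rid = f"read_{i:0{width}d}"
        reads.append(SequenceRecord(id=rid, seq=seq, description=f"from {g.id}"))
        rows.append({
            "read_id": rid, "genome_id": g.id,
            "genus": taxonomy.get(g.id, g.id) if taxonomy else g.id,
            "start": start, "end": start + L, "strand": strand,
            "n_errors": n_err,
            "identity_to_reference": 100.0 * (L - mismatches) / L,
        })
    return reads, pd.DataFrame(rows)
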