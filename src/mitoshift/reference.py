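"""Circular mtDNA reference model: gene annotation, variant consequences, contexts.

The human mitochondrial genome is a 16,569-bp circle (rCRS numbering,
1-based).  This module provides the reference services every other part of
the package relies on: circular trinucleotide contexts, region/consequence
classification of single-nucleotide substitutions under the vertebrate
mitochondrial genetic code, the D-loop sub-region lookup, and per-strand
trinucleotide background frequencies used to normalise mutational spectra.

Conventions
-----------
* Coordinates are 1-based inclusive throughout, matching m.414-style
  nomenclature.
* The loaded FASTA strand is treated as the light (L) strand; the heavy (H)
  strand is its reverse complement.  Genes annotated with strand ``H`` are
  read directly off the FASTA sequence; strand ``L`` genes (MT-ND6 and eight
  tRNAs) are read off the reverse complement.
* The D-loop wraps the origin (16024–576).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

MT_LENGTH = 16_569

#: Low-complexity intervals excluded from variant calling (1-based, closed).
LOW_COMPLEXITY = ((66, 71), (300, 316), (513, 525), (3106, 3107),
                  (12418, 12425), (16182, 16194))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Vertebrate mitochondrial genetic code (NCBI translation table 2).
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RegionClass(str, Enum):
    """Mutually exclusive functional class of a substitution."""

    DLOOP = "dloop"
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    RRNA = "rRNA"
    TRNA = "tRNA"
    NONCODING_OTHER = "noncoding_other"


@dataclass(frozen=True)
class GeneAnnotation:
    name: str
    start: int  # 1-based inclusive; start > end means the feature wraps the origin
    end: int
    strand: str  # 'H' = sense equals the FASTA strand, 'L' = reverse complement
    kind: str  # protein | tRNA | rRNA | dloop

    def __post_init__(self):
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError(f"{self.name}: interval outside [1, {MT_LENGTH}]")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    @property
    def length(self) -> int:
        if self.wraps:
            return MT_LENGTH - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    @property
    def incomplete_stop(self) -> bool:
        """Protein genes ending mid-codon (stop completed by polyadenylation)."""
        return self.kind == "protein" and self.length % 3 != 0


@dataclass
class MitoReference:
    """The circular reference sequence plus its feature annotation."""

    sequence: str
    genes: list[GeneAnnotation]
    low_complexity: tuple = LOW_COMPLEXITY
    dloop_subregions: list[GeneAnnotation] = field(default_factory=list)
    pathogenic_sites: set = field(default_factory=set)  # {(position, alt)}
    pathogenic_table: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.sequence) != MT_LENGTH:
            raise ValueError(
                f"mtDNA reference must be {MT_LENGTH} bp, got {len(self.sequence)}"
            )
        self.sequence = self.sequence.upper()
        if not any(g.kind == "dloop" for g in self.genes):
            raise ValueError("annotation must include a D-loop feature")
        seen: dict[tuple, GeneAnnotation] = {}
        for g in self.genes:
            key = (g.start, g.end, g.kind)
            if key in seen:
                raise ValueError(f"duplicate feature {g.name} / {seen[key].name}")
            seen[key] = g
        # genomic order resolves overlapping-gene precedence (ATP8 before ATP6)
        self.genes = sorted(self.genes, key=lambda g: (g.start % (MT_LENGTH + 1), g.end))
        self._features_cache: dict[int, tuple] = {}

    # -- basic sequence access -------------------------------------------------

    def base(self, position: int) -> str:
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside [1, {MT_LENGTH}]")
        return self.sequence[position - 1]

    def trinucleotide_context(self, position: int) -> str:
        """Bases at (position-1, position, position+1) with circular wrap."""
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside [1, {MT_LENGTH}]")
        i = position - 1
        return (self.sequence[i - 1]
                + self.sequence[i]
                + self.sequence[(i + 1) % MT_LENGTH])

    # -- feature lookup --------------------------------------------------------

    def features_at(self, position: int) -> tuple:
        """All annotated features containing ``position``, in genomic order."""
        cached = self._features_cache.get(position)
        if cached is None:
            cached = tuple(g for g in self.genes if g.contains(position))
            self._features_cache[position] = cached
        return cached

    def feature_kind(self, position: int) -> str:
        """Kind of the first feature covering the position ('noncoding' if none)."""
        feats = self.features_at(position)
        return feats[0].kind if feats else "noncoding"

    def in_low_complexity(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.low_complexity)

    def dloop_subregion(self, position: int) -> str | None:
        """Label of the smallest configured D-loop sub-interval covering the site."""
        hits = [r for r in self.dloop_subregions if r.contains(position)]
        if not hits:
            return None
        return min(hits, key=lambda r: r.length).name

    # -- consequence classification -------------------------------------------

    def _codon(self, gene: GeneAnnotation, position: int) -> tuple[str, int]:
        """Sense-strand codon containing ``position`` and the offset within it.

        Incomplete terminal codons are completed with adenines, emulating
        polyadenylation of the transcript.
        """
        if gene.strand == "H":
            offset = (position - gene.start) % MT_LENGTH if gene.wraps else position - gene.start
            codon_start = gene.start + 3 * (offset // 3)
            bases = [self.sequence[(codon_start - 1 + k) % MT_LENGTH] for k in range(3)]
            # beyond the gene end -> polyA completion
            for k in range(3):
                p = (codon_start + k - 1) % MT_LENGTH + 1
                if not gene.contains(p):
                    bases[k] = "A"
            return "".join(bases), offset % 3
        # L-strand gene: sense runs end -> start on the complement
        offset = gene.end - position
        codon_end = gene.end - 3 * (offset // 3)
        bases = []
        for k in range(3):
            p = codon_end - k
            if p < gene.start:
                bases.append("A")
            else:
                bases.append(self.sequence[p - 1].translate(_COMPLEMENT))
        return "".join(bases), offset % 3

    @staticmethod
    def _translate(codon: str) -> str:
        if codon in _MITO_TABLE.stop_codons:
            return "*"
        return _MITO_TABLE.forward_table.get(codon, "X")

    def classify_variant_region(self, position: int, ref_allele: str,
                                alt_allele: str) -> RegionClass:
        """Functional class of a single-base substitution.

        Protein-coding positions are translated under the vertebrate
        mitochondrial code in the gene's reading frame and strand; other
        annotated features return their kind.  Where protein genes overlap
        (ATP8/ATP6, ND4L/ND4) the first gene in genomic order decides the
        reported class; :meth:`classify_variant_detailed` also exposes the
        alternative consequence.
        """
        return self.classify_variant_detailed(position, ref_allele, alt_allele)[0]

    def classify_variant_detailed(self, position, ref_allele, alt_allele):
        """Returns (RegionClass, list of per-protein-gene consequences)."""
        ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
        if self.base(position) != ref_allele:
            raise ValueError(
                f"ref allele {ref_allele} does not match reference base "
                f"{self.base(position)} at position {position}"
            )
        feats = self.features_at(position)
        if not feats:
            return RegionClass.NONCODING_OTHER, []
        protein_calls = []
        for gene in feats:
            if gene.kind != "protein":
                continue
            codon, off = self._codon(gene, position)
            if gene.strand == "H":
                alt_codon = codon[:off] + alt_allele + codon[off + 1:]
            else:
                alt_codon = (codon[:off]
                             + alt_allele.translate(_COMPLEMENT)
                             + codon[off + 1:])
            same = self._translate(codon) == self._translate(alt_codon)
            protein_calls.append(
                (gene.name, RegionClass.SYNONYMOUS if same else RegionClass.NONSYNONYMOUS)
            )
        first = feats[0]
        if first.kind == "protein":
            return protein_calls[0][1], protein_calls
        mapping = {"dloop": RegionClass.DLOOP, "rRNA": RegionClass.RRNA,
                   "tRNA": RegionClass.TRNA}
        return mapping.get(first.kind, RegionClass.NONCODING_OTHER), protein_calls

    # -- context backgrounds ---------------------------------------------------

    def context_frequencies(self, strand: str = "L") -> dict[str, int]:
        """Counts of each trinucleotide over all circular positions of a strand.

        The H-strand count of a context equals the L-strand count of its
        reverse complement; both sum to the genome length.
        """
        if strand not in ("L", "H"):
            raise ValueError("strand must be 'L' or 'H'")
        counts: dict[str, int] = {}
        for pos in range(1, MT_LENGTH + 1):
            tri = self.trinucleotide_context(pos)
            if strand == "H":
                tri = revcomp(tri)
            counts[tri] = counts.get(tri, 0) + 1
        return counts

    def region_lengths(self) -> dict[str, int]:
        """Base-pair span of each feature kind (overlaps counted once, by precedence)."""
        lengths: dict[str, int] = {}
        for pos in range(1, MT_LENGTH + 1):
            kind = self.feature_kind(pos)
            lengths[kind] = lengths.get(kind, 0) + 1
        return lengths


# -- loading -------------------------------------------------------------------


def _read_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "start", "end", "strand", "kind"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [GeneAnnotation(r["name"], int(r["start"]), int(r["end"]),
                           str(r["strand"]), str(r["kind"]))
            for _, r in df.iterrows()]


def _read_subregions(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [GeneAnnotation(r["name"], int(r["start"]), int(r["end"]), "H", "dloop_sub")
            for _, r in df.iterrows()]


def _read_pathogenic(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if missing := {"position", "alt"} - set(df.columns):
        raise ValueError(f"pathogenic table missing columns: {sorted(missing)}")
    return df


def load_reference(fasta_path, annotation_path, *, subregion_path=None,
                   pathogenic_path=None) -> MitoReference:
    """Load a mitochondrial reference from a single-record FASTA + annotation TSV."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq).upper()
    genes = _read_annotation(annotation_path)
    subs = _read_subregions(subregion_path) if subregion_path else []
    ref = MitoReference(seq, genes, dloop_subregions=subs)
    if pathogenic_path:
        table = _read_pathogenic(pathogenic_path)
        ref.pathogenic_table = table
        ref.pathogenic_sites = {(int(p), str(a)) for p, a in
                                zip(table["position"], table["alt"])}
    return ref


def _data_path(name: str) -> Path:
    return Path(resources.files("mitoshift").joinpath("data", name))


@lru_cache(maxsize=1)
def default_reference() -> MitoReference:
    """Bundled reference: synthetic rCRS-like sequence + standard annotation.

    The base sequence is a deterministic synthetic stand-in matched to human
    mtDNA composition (see :mod:`mitoshift.synthref`); the gene/region
    coordinates are the standard rCRS annotation.  Substitute a real rCRS
    FASTA via :func:`load_reference` for analyses of real data.
    """
    from .synthref import synthetic_rcrs_sequence

    genes = _read_annotation(_data_path("annotation.tsv"))
    subs = _read_subregions(_data_path("dloop_subregions.tsv"))
    patho = _read_pathogenic(_data_path("pathogenic_sites.tsv"))
    ref = MitoReference(synthetic_rcrs_sequence(), genes, dloop_subregions=subs)
    ref.pathogenic_table = patho
    ref.pathogenic_sites = {(int(p), str(a)) for p, a in
                            zip(patho["position"], patho["alt"])}
    return ref


def write_fasta(ref: MitoReference, path, name: str = "chrM") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, MT_LENGTH, 70):
            fh.write(ref.sequence[i:i + 70] + "\n")
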