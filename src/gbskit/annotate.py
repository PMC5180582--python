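"""SNP genomic-context and coding-effect classification against GFF3 gene models.

Location classes follow an overlap precedence of CDS exon > UTR > intron >
intergenic; UTR side (5' vs 3') respects transcript strand.  Coding effects
are obtained by rebuilding the transcript's coding sequence from its CDS
segments, substituting the allele, and translating the affected codon with
the standard genetic code.  With multiple overlapping transcripts the most
severe class is reported (stop_gained > frameshift > start_lost >
stop_lost > missense > synonymous).

GFF3 coordinates (1-based inclusive) are converted to the package's 0-based
half-open convention at the boundary; parsing is delegated to gffutils with
an in-memory database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq

LOCATION_CLASSES = ("exon", "intron", "5UTR", "3UTR", "intergenic")
_SEVERITY = {
    "stop_gained": 0,
    "frameshift": 1,
    "start_lost": 2,
    "stop_lost": 3,
    "missense": 4,
    "synonymous": 5,
    "non_coding": 6,
    "NA": 7,
}


@dataclass(frozen=True)
class SnpContext:
    chrom: str
    pos: int  # 0-based
    location_class: str
    effect_class: str


def load_gene_models(gff3_path: str) -> gffutils.FeatureDB:
    """Parse a GFF3 file into an in-memory gffutils database."""
    return gffutils.create_db(
        gff3_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def _features_at(db: gffutils.FeatureDB, chrom: str, pos: int, featuretype=None):
    # gffutils regions are 1-based inclusive
    return list(db.region(region=(chrom, pos + 1, pos + 1), featuretype=featuretype))


def classify_location(
    db: gffutils.FeatureDB, chrom: str, pos: int, chrom_length: int | None = None
) -> str:
    """Location class of a 0-based position under the overlap precedence."""
    if pos < 0 or (chrom_length is not None and pos >= chrom_length):
        raise ValueError(f"position {pos} outside {chrom} of length {chrom_length}")
    feats = _features_at(db, chrom, pos)
    types = {f.featuretype for f in feats}
    if "CDS" in types:
        return "exon"
    if "five_prime_UTR" in types:
        return "5UTR"
    if "three_prime_UTR" in types:
        return "3UTR"
    if "exon" in types:
        # exon outside annotated CDS/UTR features: infer UTR side from the
        # transcript's CDS extent and strand
        for feat in feats:
            if feat.featuretype != "exon":
                continue
            for parent in db.parents(feat, featuretype="mRNA"):
                cds = list(db.children(parent, featuretype="CDS"))
                if not cds:
                    continue
                cds_start = min(c.start for c in cds)
                cds_end = max(c.end for c in cds)
                g = pos + 1
                if g < cds_start:
                    return "5UTR" if parent.strand != "-" else "3UTR"
                if g > cds_end:
                    return "3UTR" if parent.strand != "-" else "5UTR"
    if "gene" in types or "mRNA" in types:
        return "intron"
    return "intergenic"


def _coding_sequence(db, transcript, genome: dict[str, str]) -> tuple[str, list[tuple[int, int]]]:
    """Spliced CDS (coding strand) and ordered genomic segments (0-based half-open)."""
    cds = sorted(db.children(transcript, featuretype="CDS"), key=lambda f: f.start)
    segments = [(f.start - 1, f.end) for f in cds]  # to 0-based half-open
    seq = "".join(genome[transcript.seqid][s:e].upper() for s, e in segments)
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        segments = segments[::-1]
    return seq, segments


def _cds_offset(segments: list[tuple[int, int]], strand: str, pos: int) -> int | None:
    """Offset of genomic ``pos`` within the spliced coding sequence, else None."""
    off = 0
    for s, e in segments:
        if s <= pos < e:
            return off + (pos - s if strand != "-" else e - 1 - pos)
        off += e - s
    return None


def classify_effect(
    db: gffutils.FeatureDB,
    genome: dict[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> str:
    """Coding-effect class of a variant at a 0-based position.

    Substitutions are translated codon-wise; length-changing alleles are
    ``frameshift`` when the length difference is not a multiple of three
    (in-frame indels are reported ``NA``).  Positions outside any CDS are
    ``non_coding``.
    """
    ref, alt = ref.upper(), alt.upper()
    transcripts = set()
    for feat in _features_at(db, chrom, pos, featuretype="CDS"):
        for parent in db.parents(feat, featuretype="mRNA"):
            transcripts.add(parent.id)
    if not transcripts:
        return "non_coding"

    if len(ref) != len(alt):
        return "frameshift" if abs(len(ref) - len(alt)) % 3 else "NA"

    best = "NA"
    for tid in transcripts:
        transcript = db[tid]
        cds_seq, segments = _coding_sequence(db, transcript, genome)
        if len(cds_seq) % 3 != 0:
            warnings.warn(f"CDS length of {tid} not a multiple of 3; effect NA")
            continue
        off = _cds_offset(segments, transcript.strand, pos)
        if off is None:
            continue
        genome_base = genome[chrom][pos].upper()
        if genome_base != ref:
            raise ValueError(
                f"reference allele {ref} does not match genome base {genome_base} "
                f"at {chrom}:{pos}"
            )
        alt_base = alt if transcript.strand != "-" else str(Seq(alt).complement())
        codon_idx = off // 3
        codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
        alt_codon = list(codon)
        alt_codon[off % 3] = alt_base
        alt_codon = "".join(alt_codon)
        ref_aa = str(Seq(codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if ref_aa == alt_aa:
            effect = "synonymous"
        elif alt_aa == "*":
            effect = "stop_gained"
        elif ref_aa == "*":
            effect = "stop_lost"
        elif codon_idx == 0 and ref_aa == "M":
            effect = "start_lost"
        else:
            effect = "missense"
        if _SEVERITY[effect] < _SEVERITY[best]:
            best = effect
    return best


def genes_near(
    db: gffutils.FeatureDB,
    loci: list[tuple[str, int]],
    window: int = 50_000,
) -> list[list[str]]:
    """Genes whose span intersects +/- ``window`` bp of each locus (0-based).

    Returns one deduplicated, start-ordered gene-ID list per locus; a gene
    exactly ``window`` bp away is included, one base further is not.
    """
    genes = sorted(db.features_of_type("gene"), key=lambda g: (g.seqid, g.start))
    out = []
    for chrom, pos in loci:
        g1 = pos + 1  # 1-based position
        hits = []
        for gene in genes:
            if gene.seqid != chrom:
                continue
            if gene.start <= g1 + window and gene.end >= g1 - window:
                if gene.id not in hits:
                    hits.append(gene.id)
        out.append(hits)
    return out


def classify_contexts(
    db: gffutils.FeatureDB,
    genome: dict[str, str],
    variants,
) -> list[SnpContext]:
    """Location + effect classes for (chrom, pos, ref, alt) variant tuples."""
    contexts = []
    for chrom, pos, ref, alt in variants:
        loc = classify_location(db, chrom, pos, len(genome.get(chrom, "")) or None)
        effect = (
            classify_effect(db, genome, chrom, pos, ref, alt)
            if loc == "exon"
            else "non_coding"
        )
        contexts.append(SnpContext(chrom, pos, loc, effect))
    return contexts
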