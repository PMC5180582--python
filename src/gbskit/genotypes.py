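"""Samples-by-loci genotype matrix with per-call depth and per-locus quality.

Calls are coded as small integers: 0 = AA (homozygous reference), 1 = AB,
2 = BB, -1 = NN (missing).  The container round-trips through VCF 4.2 with
``GT:DP`` sample fields and per-site ``QUAL`` via pysam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

AA, AB, BB, NN = 0, 1, 2, -1
CALL_LABELS = {AA: "AA", AB: "AB", BB: "BB", NN: "NN"}


@dataclass
class GenotypeMatrix:
    """Genotype calls for ``n_samples`` x ``n_loci`` biallelic SNPs.

    Attributes
    ----------
    samples : list of sample identifiers.
    loci : DataFrame with columns chrom, pos (0-based), ref, alt.
    calls : int8 array, shape (n_samples, n_loci), coded AA/AB/BB/NN.
    depth : optional int32 array of per-call read depths, same shape.
    qual : optional float array of per-locus site qualities, length n_loci.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth shape mismatch")
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
            if self.qual.shape != (len(self.loci),):
                raise ValueError("qual length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a non-missing call, per locus."""
        return (self.calls != NN).mean(axis=0)

    def dosage(self) -> np.ndarray:
        """Float additive coding (0/1/2) with NaN for missing calls."""
        g = self.calls.astype(float)
        g[self.calls == NN] = np.nan
        return g

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            qual=None if self.qual is None else self.qual[index],
        )

    # ------------------------------------------------------------------ VCF IO

    def to_vcf(self, path: str, contig_lengths: dict[str, int] | None = None) -> None:
        """Write the matrix as VCF 4.2 with GT:DP genotype fields."""
        header = pysam.VariantHeader()
        chroms = list(dict.fromkeys(self.loci["chrom"]))
        if contig_lengths is None:
            contig_lengths = {
                c: int(self.loci.loc[self.loci["chrom"] == c, "pos"].max()) + 1000
                for c in chroms
            }
        for chrom in chroms:
            header.contigs.add(chrom, length=contig_lengths[chrom])
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("DP", 1, "Integer", "Read depth")
        for s in self.samples:
            header.add_sample(s)

        gt_map = {AA: (0, 0), AB: (0, 1), BB: (1, 1), NN: (None, None)}
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for j, locus in enumerate(self.loci.itertuples()):
                rec = vcf.new_record(
                    contig=locus.chrom,
                    start=int(locus.pos),
                    alleles=(locus.ref, locus.alt),
                )
                if self.qual is not None:
                    rec.qual = float(self.qual[j])
                for i, s in enumerate(self.samples):
                    rec.samples[s]["GT"] = gt_map[int(self.calls[i, j])]
                    if self.depth is not None:
                        rec.samples[s]["DP"] = int(self.depth[i, j])
                vcf.write(rec)

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypeMatrix":
        """Read biallelic SNP records from a VCF into a GenotypeMatrix."""
        rows, calls_cols, depth_cols, quals = [], [], [], []
        has_depth = True
        with pysam.VariantFile(path) as vcf:
            samples = list(vcf.header.samples)
            for rec in vcf:
                if len(rec.alleles) != 2:
                    continue
                rows.append((rec.contig, rec.start, rec.alleles[0], rec.alleles[1]))
                quals.append(rec.qual if rec.qual is not None else np.nan)
                col = np.empty(len(samples), dtype=np.int8)
                dcol = np.zeros(len(samples), dtype=np.int32)
                for i, s in enumerate(samples):
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        col[i] = NN
                    else:
                        col[i] = sum(gt)
                    dp = rec.samples[s].get("DP")
                    if dp is None:
                        has_depth = False
                    else:
                        dcol[i] = dp
                calls_cols.append(col)
                depth_cols.append(dcol)
        loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        calls = (
            np.array(calls_cols).T if calls_cols else np.empty((len(samples), 0), np.int8)
        )
        depth = np.array(depth_cols).T if (depth_cols and has_depth) else None
        qual = np.array(quals, dtype=float)
        return cls(samples=samples, loci=loci, calls=calls, depth=depth, qual=qual)
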