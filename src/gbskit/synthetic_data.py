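"""Synthetic study generator: genome, population, observations, phenotype, reads.

Emulates the data structure of a two-enzyme (EcoRI/NlaIII) GBS experiment on
a farmed fish population so every downstream module is testable end to end
without external data:

* a multi-kilobase genome with enzyme recognition sites planted at a known
  density and a truth map of every cut coordinate;
* a biallelic SNP population (~1 SNP per kb, Hardy-Weinberg genotypes,
  uniform minor-allele frequencies);
* a depth/missingness/error observation model producing a VCF-shaped call
  set (Poisson depth, zero-depth dropout, heterozygote miscalls, extra
  missingness, site QUAL with a calibrated fraction below the quality
  threshold);
* a quantitative trait on the muscle omega-3 (EPA+DHA, mg/g) scale with a
  sparse causal architecture: tens of large-effect loci contributing a target
  share of the total additive variance on top of a polygenic background,
  plus a balanced binary sex covariate;
* paired reads whose mates begin with the enzyme-site remnants (AATTC /
  CATG), with controlled fractions violating each read-QC rule and a truth
  label per pair.

Every generator is deterministic given the seed and emits truth sidecars.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .digest import Fragment
from .enzymes import ECORI, NLAIII, Enzyme
from .genotypes import AA, AB, BB, NN, GenotypeMatrix

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are desk-scale: a 2 Mb genome and 500 samples preserve the
    study's ratios (1 SNP per kb, ~39-causal-locus architecture, trait mean
    21.5 and SD 4.1 mg/g) while keeping generation to seconds.
    """

    genome_len: int = 2_000_000
    n_chroms: int = 2
    site_density: float = 1.0  # expected enzyme sites per kb
    n_samples: int = 500
    snp_rate: float = 0.001
    maf_low: float = 0.05
    maf_high: float = 0.5
    depth_mean: float = 10.0
    het_miscall_rate: float = 0.05
    missing_rate: float = 0.02
    qual_low_frac: float = 0.05  # fraction of sites with QUAL < 100
    n_causal: int = 39
    target_var_fraction: float = 0.63
    heritability: float = 0.5
    pheno_mean: float = 21.5
    pheno_sd: float = 4.1
    sex_effect: float = 0.5
    read_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("site_density", "snp_rate", "het_miscall_rate",
                     "missing_rate", "qual_low_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 <= maf_low <= maf_high <= 0.5")
        if not 0 < self.target_var_fraction <= 1:
            raise ValueError("target_var_fraction must be in (0, 1]")
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1)")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


# --------------------------------------------------------------------- genome


def _scrub_sites(seq: np.ndarray, enzymes: list[Enzyme], rng) -> np.ndarray:
    """Mutate one base inside every spontaneous site occurrence until none remain."""
    for _ in range(50):
        text = "".join(seq)
        hits = []
        for enz in enzymes:
            hits.extend(m.start() for m in re.finditer(f"(?=({enz.site}))", text))
        if not hits:
            return seq
        for start in hits:
            mid = start + 2
            old = seq[mid]
            choices = [b for b in "ACGT" if b != old]
            seq[mid] = choices[rng.integers(len(choices))]
    raise RuntimeError("failed to scrub spontaneous enzyme sites")


def simulate_genome(
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate chromosomes with EcoRI/NlaIII sites planted at ``site_density``.

    Returns ``(sequences, truth)`` where ``truth`` lists every planted site
    (chrom, site 0-based start, cut coordinate, enzyme).  The random
    background is scrubbed of spontaneous recognition sites, so the truth
    cut map is exactly the digestion cut set.
    """
    enzymes = [ECORI, NLAIII]
    max_site = max(len(e.site) for e in enzymes)
    chrom_len = config.genome_len // config.n_chroms
    if config.site_density > 0 and chrom_len < max_site + 2:
        raise ValueError("genome_len too small to hold one enzyme site")
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    truth_rows = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        seq = _BASES[rng.integers(4, size=chrom_len)].copy()
        seq = _scrub_sites(seq, enzymes, rng)
        n_sites = rng.poisson(config.site_density * chrom_len / 1000.0)
        # keep planted sites apart so footprints never overlap
        spacing = max_site + 2
        max_slots = max((chrom_len - max_site) // spacing - 1, 0)
        n_sites = min(n_sites, max_slots)
        if n_sites > 0:
            slots = rng.choice(max_slots, size=n_sites, replace=False)
            starts = np.sort(slots * spacing + 1)
            planted = []
            for start in starts:
                enz = enzymes[rng.integers(len(enzymes))]
                seq[start : start + len(enz.site)] = list(enz.site)
                planted.append((start, start + len(enz.site)))
                truth_rows.append((chrom, int(start), int(start + enz.cut_offset), enz.name))
            # planting can create new spurious matches straddling a footprint
            seq = _scrub_planted_neighbourhood(seq, enzymes, planted, rng)
        sequences[chrom] = "".join(seq)
    truth = pd.DataFrame(truth_rows, columns=["chrom", "site_start", "cut_pos", "enzyme"])
    return sequences, truth


def _scrub_planted_neighbourhood(seq, enzymes, planted, rng):
    """Remove site matches not identical to a planted footprint."""
    footprints = {(s, e) for s, e in planted}
    starts_by_len: dict[int, set[int]] = {}
    for s, e in footprints:
        starts_by_len.setdefault(e - s, set()).add(s)
    covered = np.zeros(len(seq), dtype=bool)
    for s, e in footprints:
        covered[s:e] = True
    for _ in range(50):
        text = "".join(seq)
        bad = []
        for enz in enzymes:
            for m in re.finditer(f"(?=({enz.site}))", text):
                s = m.start()
                if s not in starts_by_len.get(len(enz.site), set()):
                    bad.append((s, s + len(enz.site)))
        if not bad:
            return seq
        for s, e in bad:
            free = [i for i in range(s, e) if not covered[i]]
            if not free:  # fully inside planted footprints; cannot happen with spacing
                continue
            i = free[len(free) // 2]
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]
    raise RuntimeError("failed to scrub spurious sites around planted footprints")


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------- population


def simulate_population(
    sequences: dict[str, str], config: SimConfig
) -> GenotypeMatrix:
    """True genotypes: biallelic loci at ``snp_rate``, HWE draws per locus.

    Locus count is Poisson-like (per-bp Bernoulli placement); allele
    frequency of the alternate allele per locus ~ Uniform(maf_low, maf_high);
    genotypes drawn from Hardy-Weinberg proportions independently per sample.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    freqs = []
    for chrom, seq in sequences.items():
        n = len(seq)
        n_loci = rng.binomial(n, config.snp_rate)
        pos = np.sort(rng.choice(n, size=n_loci, replace=False))
        for p in pos:
            ref = seq[p].upper()
            if ref == "N":
                ref = "A"
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append((chrom, int(p), ref, str(alt)))
        freqs.append(rng.uniform(config.maf_low, config.maf_high, size=n_loci))
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    q = np.concatenate(freqs) if freqs else np.empty(0)
    n_s, n_l = config.n_samples, len(loci)
    u = rng.random((n_s, n_l))
    hom_alt = q**2
    het = 2 * q * (1 - q)
    calls = np.full((n_s, n_l), AA, dtype=np.int8)
    calls[u < hom_alt + het] = AB
    calls[u < hom_alt] = BB
    return GenotypeMatrix(
        samples=[f"S{i + 1:04d}" for i in range(n_s)], loci=loci, calls=calls
    )


# --------------------------------------------------------------- observations


def simulate_observations(
    truth: GenotypeMatrix, config: SimConfig
) -> GenotypeMatrix:
    """Observed calls from the truth matrix under the depth/error model.

    Per call: depth ~ Poisson(depth_mean); depth 0 forces a missing call;
    a true heterozygote is miscalled to one of the homozygotes with
    ``het_miscall_rate`` (the dominant discordance mode in assay
    validation); an additional ``missing_rate`` of calls is masked.  Site
    QUAL is lognormal, correlated with mean site depth and calibrated so
    that ``qual_low_frac`` of sites falls below 100 in expectation.
    """
    rng = np.random.default_rng(config.seed + 2)
    calls = truth.calls.copy()
    depth = rng.poisson(config.depth_mean, size=calls.shape).astype(np.int32)

    het = calls == AB
    miscall = het & (rng.random(calls.shape) < config.het_miscall_rate)
    calls[miscall] = np.where(rng.random(calls.shape)[miscall] < 0.5, AA, BB)

    calls[depth == 0] = NN
    calls[rng.random(calls.shape) < config.missing_rate] = NN

    n_loci = truth.n_loci
    sigma = 0.5
    if config.qual_low_frac <= 0:
        mu = np.log(100.0) + 8 * sigma
    elif config.qual_low_frac >= 1:
        mu = np.log(100.0) - 8 * sigma
    else:
        from scipy.stats import norm

        mu = np.log(100.0) - sigma * norm.ppf(config.qual_low_frac)
    if n_loci:
        mean_depth = depth.mean(axis=0)
        sd = mean_depth.std()
        z_depth = (mean_depth - mean_depth.mean()) / sd if sd > 0 else np.zeros(n_loci)
        rho = 0.5
        z = rho * z_depth + np.sqrt(1 - rho**2) * rng.standard_normal(n_loci)
        qual = np.exp(mu + sigma * z)
    else:
        qual = np.empty(0)
    return GenotypeMatrix(
        samples=list(truth.samples),
        loci=truth.loci.copy(),
        calls=calls,
        depth=depth,
        qual=qual,
    )


# ------------------------------------------------------------------ phenotype


def simulate_phenotype(
    truth: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantitative trait with a sparse causal architecture plus polygenic background.

    ``n_causal`` loci carry large effects scaled so they contribute
    ``target_var_fraction`` of the total additive variance; every other
    locus carries a small background effect making up the remainder.  Total
    genetic variance is ``heritability`` of the squared trait SD; the
    environmental term and a balanced sex covariate fill the rest, so the
    marginal trait distribution has mean ``pheno_mean`` and SD ``pheno_sd``.

    Returns ``(phenotypes, effects)``: a per-sample table (sample, trait,
    sex) and a truth table of per-locus effects with a causal flag.
    """
    rng = np.random.default_rng(config.seed + 3)
    n_s, n_l = truth.n_samples, truth.n_loci
    if config.n_causal > n_l:
        raise ValueError("n_causal exceeds number of loci")
    g = truth.calls.astype(float)

    causal = np.sort(rng.choice(n_l, size=config.n_causal, replace=False))
    is_causal = np.zeros(n_l, dtype=bool)
    is_causal[causal] = True

    beta = rng.standard_normal(n_l)
    var_g_total = config.heritability * config.pheno_sd**2

    def _component(mask: np.ndarray, target_var: float) -> tuple[np.ndarray, np.ndarray]:
        b = np.where(mask, beta, 0.0)
        comp = g @ b
        v = comp.var()
        if v == 0 or target_var == 0:
            return np.zeros(n_s), np.zeros(n_l)
        scale = np.sqrt(target_var / v)
        return comp * scale, b * scale

    gc, beta_c = _component(is_causal, config.target_var_fraction * var_g_total)
    gb, beta_b = _component(~is_causal, (1 - config.target_var_fraction) * var_g_total)
    genetic = gc + gb
    beta_final = beta_c + beta_b

    sex = rng.integers(0, 2, size=n_s)
    var_sex = config.sex_effect**2 * 0.25
    var_e = config.pheno_sd**2 - var_g_total - var_sex
    if var_e <= 0:
        raise ValueError("heritability + sex effect exceed total trait variance")
    e = rng.normal(0, np.sqrt(var_e), size=n_s)
    y = (
        config.pheno_mean
        + (genetic - genetic.mean())
        + config.sex_effect * (sex - 0.5)
        + e
    )
    phenotypes = pd.DataFrame({"sample": truth.samples, "trait": y, "sex": sex})
    effects = truth.loci[["chrom", "pos"]].copy()
    effects["beta"] = beta_final
    effects["is_causal"] = is_causal
    return phenotypes, effects


# ---------------------------------------------------------------------- reads


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_reads(
    fragments: list[Fragment],
    sequences: dict[str, str],
    config: SimConfig,
    n_pairs: int = 1000,
    bad_prefix_frac: float = 0.0,
    high_n_frac: float = 0.0,
    low_qual_frac: float = 0.0,
    short_frac: float = 0.0,
) -> tuple[list[tuple[str, str, str, str, str]], pd.DataFrame]:
    """Paired reads from mixed-end fragments, with labelled QC violations.

    Mate 1 reads the fragment from its EcoRI end (sequence begins with the
    ``AATTC`` remnant); mate 2 reads the reverse complement from the NlaIII
    end (begins with ``CATG``).  Disjoint fractions of pairs are corrupted to
    violate exactly one QC rule each: a wrong start base, >5% N content, mean
    quality below 20, or a mate shorter than the 50 bp minimum.  Returns
    ``(pairs, truth)`` where each pair is (id, seq1, qual1, seq2, qual2) with
    Phred+33 quality strings, and truth labels the injected violation.
    """
    if bad_prefix_frac + high_n_frac + low_qual_frac + short_frac > 1:
        raise ValueError("violation fractions sum to more than 1")
    rng = np.random.default_rng(config.seed + 4)
    # Only (EcoRI -> NlaIII)-oriented fragments carry both site remnants
    # inside their own interval: EcoRI cuts at the start of its site, so the
    # AATTC remnant lies downstream of the cut, while NlaIII cuts at the end
    # of CATG, leaving the remnant upstream.
    usable = [
        f
        for f in fragments
        if f.length >= config.read_len
        and f.left_end == ECORI.name
        and f.right_end == NLAIII.name
    ]
    if not usable:
        raise ValueError("no EcoRI->NlaIII fragments long enough for reads")
    L = config.read_len
    q_good = chr(38 + 33) * L  # Q38
    pairs = []
    labels = []
    u = rng.random(n_pairs)
    edges = np.cumsum([bad_prefix_frac, high_n_frac, low_qual_frac, short_frac])
    for k in range(n_pairs):
        frag = usable[rng.integers(len(usable))]
        fseq = sequences[frag.seq_id][frag.start : frag.end].upper()
        seq1 = fseq[:L]
        seq2 = _revcomp(fseq)[:L]
        qual1 = qual2 = q_good
        if u[k] < edges[0]:
            viol = "bad_prefix"
            seq1 = ("T" if seq1[0] != "T" else "G") + seq1[1:]
        elif u[k] < edges[1]:
            viol = "high_n"
            n_n = int(np.ceil(0.05 * L)) + 3  # comfortably above the 5% bound
            # spare the first 5 bases so the site-prefix rule is not tripped
            idx = rng.choice(np.arange(5, L), size=n_n, replace=False)
            s = list(seq1)
            for i in idx:
                s[i] = "N"
            seq1 = "".join(s)
        elif u[k] < edges[2]:
            viol = "low_qual"
            qual1 = chr(10 + 33) * L  # mean Q10 < 20
        elif u[k] < edges[3]:
            viol = "short"
            seq1, qual1 = seq1[:40], q_good[:40]  # below the 50 bp minimum
        else:
            viol = "none"
        pairs.append((f"read{k:06d}", seq1, qual1, seq2, qual2))
        labels.append((f"read{k:06d}", viol))
    truth = pd.DataFrame(labels, columns=["pair_id", "violation"])
    return pairs, truth


def write_fastq_pairs(pairs, path1: str, path2: str) -> None:
    """Write simulated pairs as two Phred+33 FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pid, s1, q1, s2, q2 in pairs:
            f1.write(f"@{pid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{pid}/2\n{s2}\n+\n{q2}\n")
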