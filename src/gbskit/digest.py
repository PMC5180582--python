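"""In silico single/double restriction digestion and size selection.

The digestion engine underpinning two-enzyme GBS library design: cut-site
discovery with IUPAC degeneracy, fragment construction with per-end enzyme
labels, inclusive size-window selection, and the fragment-length histogram
convention used to compare enzyme combinations (fixed-width bins with all
fragments beyond an overflow length pooled into the final bar).

Coordinates are 0-based half-open throughout; fragments are exported as BED6.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .enzymes import Enzyme

TERMINUS = "terminus"


@dataclass(frozen=True)
class Fragment:
    """A digestion product: half-open genomic interval plus end identities.

    ``left_end`` / ``right_end`` name the enzyme that produced each boundary,
    or ``"terminus"`` at sequence ends.
    """

    seq_id: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length selection window in bp (default 200-300)."""

    min_len: int = 200
    max_len: int = 300

    def __post_init__(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError(f"invalid window [{self.min_len}, {self.max_len}]")

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


def find_cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates of ``enzyme`` in ``sequence``.

    Every (possibly overlapping) IUPAC match of the recognition site at
    index ``i`` yields a cut at ``i + cut_offset``.  Positions are strictly
    increasing.  ``N`` in the sequence matches only ``N`` pattern positions.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    regex = enzyme.site_regex()
    return [m.start() + enzyme.cut_offset for m in regex.finditer(seq)]


def double_digest(
    sequence: str, enz_a: Enzyme, enz_b: Enzyme, seq_id: str = "seq"
) -> list[Fragment]:
    """Digest ``sequence`` with two enzymes and label fragment ends.

    Cut sets are merged and sorted; consecutive cuts plus the sequence
    termini bound the fragments, which tile the sequence without gaps.  When
    both enzymes cut at the same coordinate a single cut is kept and the
    first enzyme takes labelling priority.  Cuts falling exactly on a
    terminus produce no zero-length fragment.
    """
    n = len(sequence)
    labels: dict[int, str] = {}
    for pos in find_cut_positions(sequence, enz_b):
        labels[pos] = enz_b.name
    for pos in find_cut_positions(sequence, enz_a):
        labels[pos] = enz_a.name  # enzyme A overrides on coincident cuts
    cuts = sorted(p for p in labels if 0 < p < n)

    bounds = [0, *cuts, n]
    fragments = []
    for left, right in zip(bounds[:-1], bounds[1:]):
        fragments.append(
            Fragment(
                seq_id=seq_id,
                start=left,
                end=right,
                left_end=labels.get(left, TERMINUS) if left != 0 else TERMINUS,
                right_end=labels.get(right, TERMINUS) if right != n else TERMINUS,
            )
        )
    return fragments


def size_select(
    fragments: Iterable[Fragment],
    window: SizeWindow,
    end_filter: str = "any",
) -> list[Fragment]:
    """Retain fragments inside the inclusive length window.

    ``end_filter`` additionally constrains fragment ends: ``"any"`` keeps
    everything in-window, ``"both_sites"`` requires both ends to be enzyme
    cuts (no terminus), ``"mixed_ends"`` requires one cut from each enzyme
    of the pair (the classic rare/common two-enzyme library).
    """
    if end_filter not in ("any", "both_sites", "mixed_ends"):
        raise ValueError(f"unknown end_filter {end_filter!r}")
    kept = []
    for frag in fragments:
        if frag.length not in window:
            continue
        if end_filter == "both_sites":
            if TERMINUS in (frag.left_end, frag.right_end):
                continue
        elif end_filter == "mixed_ends":
            if TERMINUS in (frag.left_end, frag.right_end):
                continue
            if frag.left_end == frag.right_end:
                continue
        kept.append(frag)
    return kept


def length_histogram(
    fragments: Iterable[Fragment],
    bin_edges: Sequence[int] | None = None,
    overflow_at: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Fragment-length histogram with an overflow bar.

    Returns ``(counts, edges)`` where ``counts`` has one entry per regular
    bin plus a final overflow bin pooling every fragment longer than
    ``overflow_at``.  Defaults emulate the enzyme-comparison convention:
    100 bp bins up to 1 kb, everything longer accumulated in the last bar.
    Total count equals the number of fragments.
    """
    if bin_edges is None:
        bin_edges = np.arange(0, overflow_at + 1, 100)
    edges = np.asarray(bin_edges)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    if overflow_at < edges[-1]:
        raise ValueError("overflow_at must be >= last bin edge")
    lengths = np.array([f.length for f in fragments], dtype=int)
    counts = np.zeros(len(edges) - 1 + 1, dtype=int)
    if lengths.size:
        overflow = lengths > overflow_at
        counts[-1] = int(overflow.sum())
        counts[:-1], _ = np.histogram(lengths[~overflow], bins=edges)
    return counts, edges


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def digest_fasta(
    fasta_path: str, enz_a: Enzyme, enz_b: Enzyme
) -> list[Fragment]:
    """Double-digest every record of a (optionally gzipped) FASTA file."""
    fragments: list[Fragment] = []
    with _open_text(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            fragments.extend(double_digest(str(record.seq), enz_a, enz_b, record.id))
    return fragments


def fragments_to_bed(fragments: Iterable[Fragment], path: str) -> None:
    """Write fragments as BED6: name = leftEnd_rightEnd, score = length."""
    with open(path, "w") as out:
        for f in fragments:
            name = f"{f.left_end}_{f.right_end}"
            out.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{name}\t{f.length}\t.\n")


def n_fraction(sequence: str, fragment: Fragment) -> float:
    """Fraction of ``N`` bases within a fragment's interval of ``sequence``."""
    sub = sequence[fragment.start : fragment.end].upper()
    return sub.count("N") / len(sub)
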