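"""Paired-end read cleaning for two-enzyme GBS libraries.

Rules, applied in fixed order to each read pair:

1. site check — each mate must begin with one of the enzyme-site remnants
   (``AATTC`` for EcoRI, ``CATG`` for NlaIII by default);
2. ambiguity — a mate with more than 5% ``N`` bases drops the pair;
3. quality — (a) a mate whose mean Phred quality is below 20 drops the
   pair; (b) trailing 5 bp windows with mean quality below 20 are trimmed
   from the 3' end (a final partial window is trimmed on the same rule);
   (c) a mate shorter than 50 bp after trimming drops the pair.

Failures drop the whole pair; cleaning is idempotent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

DEFAULT_PREFIXES = ("AATTC", "CATG")


@dataclass
class ReadPair:
    """One paired-end read: sequences plus per-base Phred scores."""

    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self) -> None:
        self.qual1 = np.asarray(self.qual1, dtype=int)
        self.qual2 = np.asarray(self.qual2, dtype=int)
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.id}")


def check_site_prefix(
    pair: ReadPair, allowed_prefixes: tuple[str, ...] = DEFAULT_PREFIXES,
    both_mates: bool = True,
) -> bool:
    """True when the mate(s) begin with an allowed enzyme-site remnant."""
    prefixes = tuple(p.upper() for p in allowed_prefixes)
    ok1 = pair.seq1.upper().startswith(prefixes)
    if not both_mates:
        return ok1
    return ok1 and pair.seq2.upper().startswith(prefixes)


def filter_n_fraction(seq: str, max_frac: float = 0.05) -> tuple[bool, str]:
    """Keep unless strictly more than ``max_frac`` of bases are N.

    Returns ``(keep, reason)``; an empty read is dropped with reason "empty".
    """
    if len(seq) == 0:
        return False, "empty"
    frac = seq.upper().count("N") / len(seq)
    if frac > max_frac:
        return False, "n_fraction"
    return True, ""


def _trim_tail(qual: np.ndarray, window: int, min_window_q: float) -> int:
    """New length after removing trailing windows with mean quality below threshold."""
    pos = len(qual)
    while pos > 0:
        lo = max(0, pos - window)
        if qual[lo:pos].mean() < min_window_q:
            pos = lo
        else:
            break
    return pos


def quality_clean(
    pair: ReadPair,
    min_read_q: float = 20.0,
    window: int = 5,
    min_window_q: float = 20.0,
    min_len: int = 50,
) -> tuple[ReadPair | None, str]:
    """Apply the three-step quality rule; returns (cleaned pair or None, reason)."""
    for qual in (pair.qual1, pair.qual2):
        if len(qual) == 0 or qual.mean() < min_read_q:
            return None, "mean_quality"
    len1 = _trim_tail(pair.qual1, window, min_window_q)
    len2 = _trim_tail(pair.qual2, window, min_window_q)
    if len1 < min_len or len2 < min_len:
        return None, "short"
    return (
        ReadPair(
            pair.id,
            pair.seq1[:len1],
            pair.qual1[:len1],
            pair.seq2[:len2],
            pair.qual2[:len2],
        ),
        "",
    )


def clean_pair(
    pair: ReadPair,
    allowed_prefixes: tuple[str, ...] = DEFAULT_PREFIXES,
    max_n_frac: float = 0.05,
    min_read_q: float = 20.0,
    window: int = 5,
    min_window_q: float = 20.0,
    min_len: int = 50,
    prefix_both_mates: bool = True,
) -> tuple[ReadPair | None, str]:
    """Full QC for one pair; returns (cleaned pair or None, drop reason)."""
    if not check_site_prefix(pair, allowed_prefixes, prefix_both_mates):
        return None, "site_prefix"
    for seq in (pair.seq1, pair.seq2):
        keep, reason = filter_n_fraction(seq, max_n_frac)
        if not keep:
            return None, reason
    return quality_clean(pair, min_read_q, window, min_window_q, min_len)


def clean_pairs(pairs, **kwargs) -> tuple[list[ReadPair], "pd.DataFrame"]:
    """QC a collection of pairs; returns kept pairs and a drop-reason table."""
    import pandas as pd

    kept, log = [], []
    for pair in pairs:
        cleaned, reason = clean_pair(pair, **kwargs)
        if cleaned is None:
            log.append((pair.id, reason))
        else:
            kept.append(cleaned)
    return kept, pd.DataFrame(log, columns=["pair_id", "reason"])


# ------------------------------------------------------------------ FASTQ IO


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(path1: str, path2: str) -> list[ReadPair]:
    """Load paired Phred+33 FASTQ files into ReadPair objects."""
    from Bio import SeqIO

    pairs = []
    with _open_text(path1) as h1, _open_text(path2) as h2:
        for r1, r2 in zip(
            SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq"), strict=True
        ):
            pairs.append(
                ReadPair(
                    r1.id.removesuffix("/1"),
                    str(r1.seq),
                    np.array(r1.letter_annotations["phred_quality"]),
                    str(r2.seq),
                    np.array(r2.letter_annotations["phred_quality"]),
                )
            )
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.qual1)
            q2 = "".join(chr(q + 33) for q in p.qual2)
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{q2}\n")
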