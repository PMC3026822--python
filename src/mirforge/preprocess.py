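"""Raw FASTQ -> counted unique tags.

Stages: mean-quality / ambiguous-base filtering, 3' adapter trimming,
5' adapter-contaminant removal, 18-30 nt length filtering, and
collapsing of identical sequences into ranked unique tags
(``F<rank>_x<count>``, rank 1-based by descending count with
lexicographic tie-break).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MIN_MEAN_Q = 20.0
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
ADAPTER_MIN_OVERLAP = 6
# mismatch budget: one mismatch allowed per 10 aligned bases
ADAPTER_MM_PER_10 = 1


@dataclass
class UniqueTag:
    tag_id: str
    sequence: str
    count: int


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    high_quality_reads: int = 0
    retained_fraction: float = 0.0
    unique_tags: int = 0
    length_histogram: dict = field(default_factory=dict)


def retained_fraction(raw_reads: int, clean_reads: int) -> float:
    """Percent of raw reads surviving filtering, rounded to 2 decimals."""
    if raw_reads <= 0:
        return 0.0
    return round(100.0 * clean_reads / raw_reads, 2)


def read_fastq(path):
    """Yield (title, sequence, quality); parse errors name the record."""
    idx = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {idx}: {exc}") from exc
            idx += 1
            yield rec


def _mean_quality(qual: str) -> float:
    return sum(qual.encode("ascii")) / len(qual) - 33.0


def quality_filter(reads, min_mean_q: float = DEFAULT_MIN_MEAN_Q):
    """Drop reads with mean Phred below threshold or any ambiguous base."""
    kept, dropped = [], 0
    for title, seq, qual in reads:
        if "N" in seq.upper() or not seq or _mean_quality(qual) < min_mean_q:
            dropped += 1
        else:
            kept.append((title, seq.upper(), qual))
    return kept, dropped


def _prefix_match(seq: str, adapter: str, start: int, min_overlap: int) -> bool:
    k = min(len(adapter), len(seq) - start)
    if k < min_overlap:
        return False
    seg = seq[start:start + k]
    ref = adapter[:k]
    if seg == ref:
        return True
    allowed = (k // 10) * ADAPTER_MM_PER_10
    if allowed == 0:
        return False
    mm = sum(a != b for a, b in zip(seg, ref))
    return mm <= allowed


def find_adapter_3p(seq: str, adapter: str,
                    min_overlap: int = ADAPTER_MIN_OVERLAP) -> int:
    """Leftmost start of the 3' adapter in ``seq`` (-1 if absent)."""
    # fast path: exact occurrence of the adapter seed
    seed = adapter[:min_overlap]
    p = seq.find(seed)
    while p != -1:
        if _prefix_match(seq, adapter, p, min_overlap):
            return p
        p = seq.find(seed, p + 1)
    # tolerant scan (picks up seeds carrying sequencing errors)
    for p in range(len(seq) - min_overlap + 1):
        if _prefix_match(seq, adapter, p, min_overlap):
            return p
    return -1


def trim_adapters(reads, adapter_3p: str, adapter_5p: str,
                  min_overlap: int = ADAPTER_MIN_OVERLAP):
    """Trim the 3' adapter; discard 5' adapter contaminants entirely.

    Returns (trimmed reads, n_5p_contaminants_discarded).  A read with
    no 3' adapter hit is kept untrimmed (the length filter deals with
    it downstream).
    """
    if not adapter_3p or not adapter_5p:
        raise ValueError("adapter sequences must be non-empty")
    out, n5 = [], 0
    for title, seq, qual in reads:
        if _prefix_match(seq, adapter_5p, 0, min_overlap):
            n5 += 1
            continue
        p = find_adapter_3p(seq, adapter_3p, min_overlap)
        if p >= 0:
            out.append((title, seq[:p], qual[:p]))
        else:
            out.append((title, seq, qual))
    return out, n5


def length_filter(reads, lo: int = DEFAULT_MIN_LEN, hi: int = DEFAULT_MAX_LEN):
    if lo > hi:
        raise ValueError("lo must be <= hi")
    return [r for r in reads if lo <= len(r[1]) <= hi]


def collapse(reads):
    """Collapse identical sequences into ranked UniqueTags.

    Ranking is by descending count, ties broken lexicographically by
    sequence so that tag identifiers are deterministic.
    """
    counts = Counter(seq for _t, seq, _q in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    tags = [UniqueTag(f"F{r + 1}_x{c}", s, c)
            for r, (s, c) in enumerate(ordered)]
    hist = Counter()
    for s, c in counts.items():
        hist[len(s)] += c
    return tags, dict(sorted(hist.items()))


def run_preprocess(reads, adapter_3p: str, adapter_5p: str,
                   min_mean_q: float = DEFAULT_MIN_MEAN_Q,
                   lo: int = DEFAULT_MIN_LEN, hi: int = DEFAULT_MAX_LEN):
    """Full preprocessing cascade; returns (tags, PreprocessStats)."""
    reads = list(reads)
    raw = len(reads)
    hq, _ = quality_filter(reads, min_mean_q)
    trimmed, _ = trim_adapters(hq, adapter_3p, adapter_5p)
    sized = length_filter(trimmed, lo, hi)
    tags, hist = collapse(sized)
    stats = PreprocessStats(
        raw_reads=raw,
        high_quality_reads=len(sized),
        retained_fraction=retained_fraction(raw, len(sized)),
        unique_tags=len(tags),
        length_histogram=hist)
    return tags, stats


def tags_to_fasta(tags, path, rna: bool = False) -> None:
    with open(path, "w") as fh:
        for t in tags:
            seq = t.sequence.replace("T", "U") if rna else t.sequence
            fh.write(f">{t.tag_id}\n{seq}\n")
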