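"""Sequential annotation cascade over unique tags.

Each tag receives exactly one class by fixed priority: ncRNA subclasses
(rRNA, tRNA, snRNA, snoRNA) -> known miRNA -> mRNA -> piRNA -> unknown.
First hit wins, so adding entries to a lower-priority catalog can never
change an assignment made by a higher-priority one.  Matching is exact
substring / full-length with a small mismatch budget, except for the
piRNA class, which accepts only perfect matches of 26-30 nt leftovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode
from . import homology

NC_RNA_CLASSES = ["rRNA", "tRNA", "snRNA", "snoRNA"]
ALL_CLASSES = NC_RNA_CLASSES + ["known_miRNA", "mRNA", "piRNA", "unknown"]
DEFAULT_MAX_MM = 2  # ncRNA / mRNA mismatch allowance (piRNA is 0)
PIRNA_MIN_LEN = 26
PIRNA_MAX_LEN = 30


@dataclass
class AnnotationRecord:
    tag_id: str
    assigned_class: str
    matched_reference_id: str = ""
    match_kind: str = "none"   # perfect | variant | none


class _ClassIndex:
    """Substring / k-mismatch index over one catalog class.

    References are concatenated with sentinel separators; exact lookups
    use C-level substring search and the mismatch scan compares every
    window of the concatenation with numpy (windows crossing a
    separator accrue sentinel mismatches and can never win).
    """

    def __init__(self, entries):
        self.ids = []
        self.starts = []
        parts = []
        pos = 0
        for ref_id, seq in entries:
            self.ids.append(ref_id)
            self.starts.append(pos)
            parts.append(seq.upper())
            pos += len(seq) + 3
        self.concat = ("#" * 3).join(parts)
        self.enc = encode(self.concat, strict=False) if self.concat \
            else np.zeros(0, dtype=np.uint8)
        self.starts = np.array(self.starts, dtype=np.int64)

    def _ref_at(self, pos: int) -> str:
        k = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return self.ids[max(k, 0)]

    def search(self, seq: str, max_mm: int = 0):
        """Return (ref_id, n_mismatches) for the best hit, or None."""
        p = self.concat.find(seq.upper())
        if p >= 0:
            return self._ref_at(p), 0
        if max_mm <= 0:
            return None
        L = len(seq)
        if L == 0 or L > len(self.enc):
            return None
        win = np.lib.stride_tricks.sliding_window_view(self.enc, L)
        mm = (win != encode(seq)).sum(axis=1)
        best = int(mm.argmin())
        if mm[best] <= max_mm:
            return self._ref_at(best), int(mm[best])
        return None


def classify_cascade(tags, catalogs, max_mm: int = DEFAULT_MAX_MM,
                     mirna_max_mm: int = 2) -> list[AnnotationRecord]:
    """Assign one class per tag through the fixed-priority cascade.

    ``catalogs`` maps class name -> list of (ref_id, sequence) for the
    ncRNA subclasses, mRNA and piRNA, and 'known_miRNA' -> a mature
    catalog accepted by :func:`mirforge.homology.match_known`.
    """
    missing = [c for c in NC_RNA_CLASSES + ["known_miRNA", "mRNA", "piRNA"]
               if c not in catalogs]
    if missing:
        raise ValueError(f"missing catalog classes: {missing}")
    records: dict[str, AnnotationRecord] = {}
    remaining = list(tags)
    for cls in NC_RNA_CLASSES:
        index = _ClassIndex(catalogs[cls])
        nxt = []
        for t in remaining:
            hit = index.search(t.sequence, max_mm)
            if hit:
                records[t.tag_id] = AnnotationRecord(
                    t.tag_id, cls, hit[0],
                    "perfect" if hit[1] == 0 else "variant")
            else:
                nxt.append(t)
        remaining = nxt
    # known miRNA: full-length comparison with the homology rules
    hits = homology.match_known(remaining, catalogs["known_miRNA"],
                                max_mm=mirna_max_mm)
    best_by_tag: dict[str, homology.HomologyHit] = {}
    for h in hits:
        cur = best_by_tag.get(h.tag_id)
        if cur is None or (h.n_mismatches, abs(h.length_delta)) < \
                (cur.n_mismatches, abs(cur.length_delta)):
            best_by_tag[h.tag_id] = h
    nxt = []
    for t in remaining:
        h = best_by_tag.get(t.tag_id)
        if h:
            kind = "perfect" if h.n_mismatches == 0 and h.length_delta == 0 \
                else "variant"
            records[t.tag_id] = AnnotationRecord(
                t.tag_id, "known_miRNA", h.known_mature_id, kind)
        else:
            nxt.append(t)
    remaining = nxt
    index = _ClassIndex(catalogs["mRNA"])
    nxt = []
    for t in remaining:
        hit = index.search(t.sequence, max_mm)
        if hit:
            records[t.tag_id] = AnnotationRecord(
                t.tag_id, "mRNA", hit[0],
                "perfect" if hit[1] == 0 else "variant")
        else:
            nxt.append(t)
    remaining = nxt
    # piRNA: 26-30 nt leftovers, perfect matches only
    index = _ClassIndex(catalogs["piRNA"])
    for t in remaining:
        hit = None
        if PIRNA_MIN_LEN <= len(t.sequence) <= PIRNA_MAX_LEN:
            hit = index.search(t.sequence, 0)
        if hit:
            records[t.tag_id] = AnnotationRecord(
                t.tag_id, "piRNA", hit[0], "perfect")
        else:
            records[t.tag_id] = AnnotationRecord(t.tag_id, "unknown")
    return [records[t.tag_id] for t in tags]


def composition_summary(records, tags) -> pd.DataFrame:
    """Per-class read/tag counts and percentages (2-decimal rounding)."""
    count_by_id = {t.tag_id: t.count for t in tags}
    rows = {c: {"read_count": 0, "tag_count": 0} for c in ALL_CLASSES}
    for r in records:
        rows[r.assigned_class]["read_count"] += count_by_id[r.tag_id]
        rows[r.assigned_class]["tag_count"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "class"
    total_reads = df["read_count"].sum()
    total_tags = df["tag_count"].sum()
    df["read_fraction"] = (100.0 * df["read_count"]
                           / max(total_reads, 1)).round(2)
    df["tag_fraction"] = (100.0 * df["tag_count"]
                          / max(total_tags, 1)).round(2)
    return df[["read_count", "read_fraction", "tag_count", "tag_fraction"]]
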