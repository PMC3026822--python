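"""isomiR cataloguing: terminal variants, substitutions, 3' additions.

Each tag is aligned without gaps against every catalog precursor at
5'-start offsets within +-4 nt of the reference mature; trailing bases
that the precursor cannot explain become a non-templated 3' addition
(NTA).  Offset sign convention: negative = the tag extends beyond the
reference end, positive = it is trimmed relative to the reference.
A variant species is a distinct tag sequence assigned to a miRNA; the
canonical isomiR has zero offsets, no substitutions and an empty NTA.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode

MAX_OFFSET = 4   # terminal variability cap, nt
MAX_MM = 2       # internal substitutions allowed in the templated body
MAX_NTA = 3


@dataclass
class PrecursorEntry:
    """Catalog entry: precursor with the reference mature interval on it."""

    name: str
    precursor: str
    mature_start: int
    mature_end: int

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature_start:self.mature_end]


@dataclass
class IsomiR:
    mirna_name: str
    tag_id: str
    sequence: str
    count: int
    offset5: int
    offset3: int
    substitutions: list = field(default_factory=list)
    nta: str = ""
    templated: bool = True
    ambiguous: bool = False

    @property
    def canonical(self) -> bool:
        return (self.offset5 == 0 and self.offset3 == 0
                and not self.substitutions and not self.nta)


def _entry_alignment_costs(tags_enc, L, entry_enc_padded, entry,
                           max_offset, max_mm, max_nta):
    """Per-tag best (cost, p, nta_len) against one entry; vectorised.

    Cost packs (body mismatches, total terminal offset, NTA length)
    lexicographically.  Returns arrays; cost is huge where no valid
    placement exists.
    """
    M = tags_enc.shape[0]
    Lp = len(entry.precursor)
    INF = 1 << 30
    best = np.full(M, INF, dtype=np.int64)
    best_p = np.zeros(M, dtype=np.int64)
    best_nta = np.zeros(M, dtype=np.int64)
    for p in range(max(0, entry.mature_start - max_offset),
                   entry.mature_start + max_offset + 1):
        if p + L > Lp + max_nta + 1:
            continue
        window = entry_enc_padded[p:p + L]
        B = tags_enc != window                       # (M, L) mismatches
        rev = B[:, ::-1]
        trailing = np.argmin(rev, axis=1)            # run of 3' mismatches
        all_mm = B.all(axis=1)
        trailing[all_mm] = L
        nta_len = np.minimum(trailing, max_nta)
        total_mm = B.sum(axis=1)
        # mismatches left in the body once the NTA suffix is stripped
        body_mm = total_mm - nta_len
        templated_end = p + L - nta_len
        o5 = p - entry.mature_start
        o3 = entry.mature_end - templated_end
        valid = ((body_mm <= max_mm) & (np.abs(o3) <= max_offset)
                 & (templated_end <= Lp))
        cost = body_mm * 1000 + (abs(o5) + np.abs(o3)) * 10 + nta_len
        cost = np.where(valid, cost, INF)
        upd = cost < best
        best[upd] = cost[upd]
        best_p[upd] = p
        best_nta[upd] = nta_len[upd]
    return best, best_p, best_nta


def assign_and_classify(tags, catalog, max_offset: int = MAX_OFFSET,
                        max_mm: int = MAX_MM,
                        max_nta: int = MAX_NTA) -> list[IsomiR]:
    """Assign tags to catalog miRNAs and classify their variation.

    A tag aligning equally well to several precursors is assigned to
    each of them with ``ambiguous=True``.  Tags with no valid placement
    are silently unassigned.
    """
    entries = [e if isinstance(e, PrecursorEntry) else PrecursorEntry(*e)
               for e in catalog]
    if not entries or not tags:
        return []
    by_len = defaultdict(list)
    for t in tags:
        by_len[len(t.sequence)].append(t)
    padded = {e.name: np.concatenate([
        encode(e.precursor), np.full(max_nta + 8, 255, dtype=np.uint8)])
        for e in entries}
    results = []
    for L, ts in sorted(by_len.items()):
        T = np.array([encode(t.sequence) for t in ts])
        costs = np.empty((len(ts), len(entries)), dtype=np.int64)
        ps = np.empty_like(costs)
        ntas = np.empty_like(costs)
        for j, e in enumerate(entries):
            c, p, nl = _entry_alignment_costs(
                T, L, padded[e.name], e, max_offset, max_mm, max_nta)
            costs[:, j], ps[:, j], ntas[:, j] = c, p, nl
        gmin = costs.min(axis=1)
        for i, t in enumerate(ts):
            if gmin[i] >= (1 << 30):
                continue
            winners = np.nonzero(costs[i] == gmin[i])[0]
            ambiguous = len(winners) > 1
            for j in winners:
                e = entries[j]
                p, nl = int(ps[i, j]), int(ntas[i, j])
                body = t.sequence[:L - nl]
                subs = [(k, e.precursor[p + k], body[k])
                        for k in range(len(body))
                        if e.precursor[p + k] != body[k]]
                results.append(IsomiR(
                    mirna_name=e.name, tag_id=t.tag_id,
                    sequence=t.sequence, count=t.count,
                    offset5=p - e.mature_start,
                    offset3=e.mature_end - (p + L - nl),
                    substitutions=subs, nta=t.sequence[L - nl:],
                    templated=(nl == 0), ambiguous=ambiguous))
    return results


def reconstruct(entry: PrecursorEntry, iso: IsomiR) -> str:
    """Rebuild the tag sequence from its classification (exact)."""
    a = entry.mature_start + iso.offset5
    b = entry.mature_end - iso.offset3
    body = list(entry.precursor[a:b])
    for pos, _ref, obs in iso.substitutions:
        body[pos] = obs
    return "".join(body) + iso.nta


@dataclass
class IsomirSummary:
    mirna_name: str
    n_isomirs: int
    total_reads: int
    most_abundant_seq: str
    matches_reference: bool


def summarize(isomirs, catalog):
    """Per-miRNA isomiR diversity and global statistics.

    Returns (summaries, global_stats).  global_stats reports the total
    variant-species count both summed per miRNA and as globally unique
    sequences, the diversity histogram, and how many miRNAs have a
    modal sequence that differs from the reference mature.
    """
    entries = {e.name: (e if isinstance(e, PrecursorEntry)
                        else PrecursorEntry(*e)) for e in
               (catalog if not isinstance(catalog, dict) else
                catalog.values())}
    by_mirna = defaultdict(list)
    for iso in isomirs:
        by_mirna[iso.mirna_name].append(iso)
    summaries = []
    n_modal_mismatch = 0
    for name in sorted(by_mirna):
        isos = by_mirna[name]
        seq_counts = defaultdict(int)
        for iso in isos:
            seq_counts[iso.sequence] += iso.count
        modal = max(seq_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]
        ref = entries[name].mature_seq if name in entries else ""
        match = modal == ref
        if not match:
            n_modal_mismatch += 1
        summaries.append(IsomirSummary(
            mirna_name=name, n_isomirs=len(seq_counts),
            total_reads=sum(seq_counts.values()),
            most_abundant_seq=modal, matches_reference=match))
    hist = defaultdict(int)
    for s in summaries:
        hist[s.n_isomirs] += 1
    stats = {
        "n_mirnas": len(summaries),
        "n_isomirs_summed": sum(s.n_isomirs for s in summaries),
        "n_isomirs_unique_global": len({iso.sequence for iso in isomirs}),
        "n_modal_mismatch": n_modal_mismatch,
        "diversity_histogram": dict(sorted(hist.items())),
    }
    return summaries, stats


def isomirs_to_frame(isomirs) -> pd.DataFrame:
    rows = [{
        "miRNA": i.mirna_name, "tag_id": i.tag_id, "sequence": i.sequence,
        "count": i.count, "offset5": i.offset5, "offset3": i.offset3,
        "substitutions": ";".join(f"{p}{r}>{o}" for p, r, o in
                                  i.substitutions),
        "nta": i.nta, "templated": i.templated, "ambiguous": i.ambiguous,
    } for i in isomirs]
    return pd.DataFrame(rows, columns=[
        "miRNA", "tag_id", "sequence", "count", "offset5", "offset3",
        "substitutions", "nta", "templated", "ambiguous"])
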