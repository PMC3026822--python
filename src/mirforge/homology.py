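"""Homology identification (method 2) and cross-method merging.

Unique tags are compared full-length against a known-mature catalog
with explicit mismatch/overhang counting: terminal overhangs of up to
2 nt enter the signed length delta rather than the mismatch count, and
up to 2 internal mismatches define the "variant" class (0 mismatches is
the "perfect" class).  Cross-species synonyms of the same miRNA name
collapse into one miRNA species; finally the three identification
methods' catalogs merge into a single record set with Venn-style
provenance counts.
"""

from __future__ import annotations

import itertools
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from ._seq import encode, to_dna

MAX_OVERHANG = 2


@dataclass
class CatalogEntry:
    entry_id: str     # e.g. "ptr-let-7b"
    species: str      # "ptr"
    name: str         # "let-7b"
    sequence: str


@dataclass
class HomologyHit:
    tag_id: str
    known_mature_id: str
    species_of_origin: str
    n_mismatches: int
    length_delta: int


@dataclass
class MirnaRecord:
    """One catalog entry with provenance over the identification methods."""

    name: str
    mature_seq: str
    star_seq: str = ""
    precursor: str = ""
    methods: set = field(default_factory=set)
    dominant_arm: str = "mature"


_SPECIES_RE = re.compile(r"^[a-z]{3,4}-")


def base_name(name: str) -> str:
    """Strip a miRBase species prefix: 'ptr-let-7b' -> 'let-7b'."""
    return _SPECIES_RE.sub("", name)


def parse_mature_fasta(path) -> list[CatalogEntry]:
    """Read a catalog with headers '>{species}-{name} {accession}'."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        m = _SPECIES_RE.match(ident)
        sp = m.group(0)[:-1] if m else ""
        entries.append(CatalogEntry(ident, sp, base_name(ident),
                                    to_dna(str(rec.seq))))
    return entries


def _as_entries(catalog) -> list[CatalogEntry]:
    out = []
    for e in catalog:
        if isinstance(e, CatalogEntry):
            out.append(e)
        else:  # (entry_id, species, name, seq) tuples from the simulator
            out.append(CatalogEntry(*e))
    return out


def match_known(tags, catalog, max_mm: int = 2,
                max_overhang: int = MAX_OVERHANG) -> list[HomologyHit]:
    """Best full-length alignment of each tag against each catalog entry.

    For every (tag, entry) pair the ungapped offset minimising
    (mismatches, |length_delta|) is kept, subject to terminal overhangs
    <= ``max_overhang`` at each end and mismatches <= ``max_mm``.
    """
    entries = _as_entries(catalog)
    if not entries or not tags:
        return []
    by_len: dict[int, list] = defaultdict(list)
    for t in tags:
        by_len[len(t.sequence)].append(t)
    enc_tags = {
        L: (np.array([encode(t.sequence) for t in ts]), ts)
        for L, ts in by_len.items()
    }
    hits = []
    for e in entries:
        m_enc = encode(e.sequence)
        Lm = len(e.sequence)
        for L, (T, ts) in enc_tags.items():
            best = np.full(len(ts), 1 << 30, dtype=np.int64)
            best_mm = np.zeros(len(ts), dtype=np.int64)
            found = np.zeros(len(ts), dtype=bool)
            for o in range(-max_overhang, max_overhang + 1):
                # tag position i aligns mature position i + o
                left_over = abs(o)
                right_over = abs(o + L - Lm)
                if left_over > max_overhang or right_over > max_overhang:
                    continue
                a = max(0, -o)
                b = min(L, Lm - o)
                if b - a <= 0:
                    continue
                mm = (T[:, a:b] != m_enc[a + o:b + o]).sum(axis=1)
                cost = mm * 10 + abs(L - Lm)
                upd = (mm <= max_mm) & (cost < best)
                best[upd] = cost[upd]
                best_mm[upd] = mm[upd]
                found |= upd
            for k in np.nonzero(found)[0]:
                hits.append(HomologyHit(
                    tag_id=ts[k].tag_id, known_mature_id=e.entry_id,
                    species_of_origin=e.species,
                    n_mismatches=int(best_mm[k]), length_delta=L - Lm))
    return hits


def _tag_count(tag_id: str) -> int:
    # tag ids encode the count exactly: suffix "_x" + count
    return int(tag_id.rsplit("_x", 1)[1])


def collapse_species(hits, tags) -> list[MirnaRecord]:
    """Group hits by base miRNA name into one species per name.

    Hits to e.g. ptr-let-7b and xtr-let-7b form the single group
    "let-7b"; the group representative is the highest-count tag.
    Idempotent: re-collapsing the output changes nothing.
    """
    seq_by_id = {t.tag_id: t.sequence for t in tags}
    groups: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        groups[base_name(h.known_mature_id)].append(h)
    records = []
    for name in sorted(groups):
        hs = groups[name]
        rep = max(hs, key=lambda h: (_tag_count(h.tag_id), h.tag_id))
        records.append(MirnaRecord(
            name=name, mature_seq=seq_by_id[rep.tag_id],
            methods={"method2"}))
    return records


VENN_CELLS = ["m1", "m2", "m3", "m1m2", "m1m3", "m2m3", "m1m2m3"]


def _record_key(rec: MirnaRecord):
    # conserved records merge by name; novel ones by mature sequence
    if rec.name.startswith(("ssc-miR-new", "ssc-miR-large")):
        return ("seq", rec.mature_seq)
    return ("name", base_name(rec.name))


def merge_methods(m1, m2, m3):
    """Union of the three methods' catalogs with provenance.

    Returns (merged records, venn dict over the 7 exclusive cells,
    conflicts).  A name bound to two mature sequences differing by more
    than 2 nt is a conflict: both are kept with numeric suffixes.
    """
    merged: dict = {}
    conflicts = []
    for rec in itertools.chain(m1, m2, m3):
        key = _record_key(rec)
        if key not in merged:
            merged[key] = MirnaRecord(
                name=base_name(rec.name) if key[0] == "name" else rec.name,
                mature_seq=rec.mature_seq, star_seq=rec.star_seq,
                precursor=rec.precursor, methods=set(rec.methods),
                dominant_arm=rec.dominant_arm)
            continue
        cur = merged[key]
        if key[0] == "name" and _seq_conflict(cur.mature_seq, rec.mature_seq):
            conflicts.append((cur.name, cur.mature_seq, rec.mature_seq))
            alt_key = ("name", f"{base_name(rec.name)}.{len(conflicts) + 1}")
            rec2 = MirnaRecord(
                name=alt_key[1], mature_seq=rec.mature_seq,
                star_seq=rec.star_seq, precursor=rec.precursor,
                methods=set(rec.methods), dominant_arm=rec.dominant_arm)
            merged.setdefault(alt_key, rec2).methods |= rec.methods
            continue
        cur.methods |= rec.methods
        if not cur.precursor and rec.precursor:
            cur.precursor = rec.precursor
            cur.star_seq = rec.star_seq
    records = list(merged.values())
    venn = {c: 0 for c in VENN_CELLS}
    for rec in records:
        cell = "".join(m.replace("method", "m") for m in
                       sorted(rec.methods))
        venn[cell] += 1
    return records, venn, conflicts


def _seq_conflict(a: str, b: str, tol: int = 2) -> bool:
    if abs(len(a) - len(b)) > tol:
        return True
    n = min(len(a), len(b))
    mm = sum(x != y for x, y in zip(a[:n], b[:n])) + abs(len(a) - len(b))
    return mm > tol
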