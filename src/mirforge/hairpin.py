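"""Hairpin-based miRNA discovery (read-anchored and genome-homolog scans).

Tags are mapped exactly to the genome, candidate precursor windows are
excised around read-dense loci, folded, and filtered on stem-loop
structure: folding free energy below -17 kcal/mol, the mature strand
confined to one arm without touching the terminal loop, a minimum
paired fraction of mature bases, and a dinucleotide-shuffle p-value.
Surviving candidates are scored on their read signature - concentration
of reads on the mature arm, presence of star reads with the 2-nt 3'
overhang Dicer leaves, sharp 5'-end homogeneity - with loop reads
penalised.  The same folding/filter machinery serves the genome-wide
scan seeded by known mature sequences (identity > 95%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from . import folding
from .homology import MirnaRecord, match_known, base_name

DG_MAX = -17.0           # kcal/mol; retained candidates fold below this
MIN_PAIRED_FRACTION = 0.6
MAX_SHUFFLE_P = 0.05
DEFAULT_FLANK = 70
MAX_LOCI = 5             # multi-mapping cap
CLUSTER_GAP = 30
SCORE_MIN = 2.0
N_SHUFFLES = 99

# signature score weights: mature concentration, star evidence,
# 5'-homogeneity, loop penalty, abundance
W_MATURE, W_STAR, W_HOMOG, W_LOOP, W_ABUND = 3.0, 2.0, 2.0, 4.0, 0.2


@dataclass
class Placement:
    tag_id: str
    sequence: str
    count: int
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class HairpinCandidate:
    contig: str
    start: int
    end: int
    strand: str
    precursor_seq: str
    structure: str
    delta_g: float
    mature_interval: tuple          # window coordinates, 0-based half-open
    star_interval: tuple = (0, 0)
    loop_interval: tuple = (0, 0)
    signature: dict = field(default_factory=dict)
    shuffle_p: float | None = None
    score: float | None = None


def map_tags(tags, genome: dict, max_loci: int = MAX_LOCI):
    """Exact-match placements of tags on both genome strands.

    Returns (placements, multimapped_tag_ids); tags hitting more than
    ``max_loci`` loci are flagged and excluded from the placement list.
    """
    placements = []
    multimapped = set()
    for t in tags:
        hits = []
        for contig, seq in genome.items():
            for query, strand in ((t.sequence, "+"),
                                  (revcomp(t.sequence), "-")):
                p = seq.find(query)
                while p != -1:
                    hits.append(Placement(t.tag_id, t.sequence, t.count,
                                          contig, p, p + len(query), strand))
                    p = seq.find(query, p + 1)
        if len(hits) > max_loci:
            multimapped.add(t.tag_id)
        else:
            placements.extend(hits)
    return placements, multimapped


def excise_precursors(placements, genome: dict, flank: int = DEFAULT_FLANK):
    """Two candidate windows per placement (tag on 5' arm, tag on 3' arm).

    Each window is (contig, start, end, strand, window_seq,
    mature_interval) with the window sequence oriented 5'->3' on the
    placement strand and coordinates clipped to the contig.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for pl in placements:
        contig_seq = genome[pl.contig]
        n = len(contig_seq)
        for ws, we in ((pl.start, min(pl.end + flank, n)),
                       (max(pl.start - flank, 0), pl.end)):
            seq = contig_seq[ws:we]
            if pl.strand == "-":
                seq = revcomp(seq)
                m_off = we - pl.end
            else:
                m_off = pl.start - ws
            out.append((pl.contig, ws, we, pl.strand, seq,
                        (m_off, m_off + (pl.end - pl.start))))
    return out


def fold(seq: str):
    """Dot-bracket structure and dG of ``seq`` (built-in backend)."""
    return folding.fold(seq)


def _terminal_loop(pt: np.ndarray, i: int, j: int):
    """Terminal loop of the main helix containing pair (i, j).

    Walks inward following, at each level, the widest immediate child
    helix (side decorations such as small bulge hairpins are skipped),
    until a pair encloses no further pairs; returns the positions
    strictly inside it.
    """
    while True:
        children = []
        k = i + 1
        while k < j:
            if i < pt[k] < j and k < pt[k]:
                children.append((k, int(pt[k])))
                k = int(pt[k]) + 1
            else:
                k += 1
        if not children:
            return (i + 1, j)
        i, j = max(children, key=lambda c: c[1] - c[0])


LOOP_SLACK = 4  # nt of terminal fraying a mature may extend into the loop


def _arm_and_loop(structure: str, mature: tuple, slack: int = LOOP_SLACK):
    """Which arm the mature sits on, and the terminal loop interval.

    Returns (arm, loop_interval, pair_table) with arm in {'5p','3p'}.
    Raises ValueError with a reason when the mature straddles the loop
    (pairs in both directions, reaches into the opposite arm, or
    overlaps the terminal loop by more than ``slack`` frayed bases) or
    is entirely unpaired.
    """
    pt = folding.pair_table(structure)
    a, b = mature
    # A few pairs internal to the mature are structural noise (the
    # Dicer duplex pairs mature<->star); many of them mean the mature
    # spans the loop and pairs with itself, i.e. it straddles.
    intra = [k for k in range(a, b) if pt[k] >= 0 and a <= pt[k] < b]
    if len(intra) > 2 * slack:
        raise ValueError("loop overlap")
    paired = [k for k in range(a, b) if pt[k] >= 0
              and not (a <= pt[k] < b)]
    if not paired:
        raise ValueError("unpaired")
    opens = [k for k in paired if structure[k] == "("]
    closes = [k for k in paired if structure[k] == ")"]
    if opens and closes:
        raise ValueError("loop overlap")
    if opens:
        arm = "5p"
        im = max(opens)
        loop = _terminal_loop(pt, im, int(pt[im]))
    else:
        arm = "3p"
        im = min(closes)
        loop = _terminal_loop(pt, int(pt[im]), im)
    overlap = min(b, loop[1]) - max(a, loop[0])
    if overlap > slack:
        raise ValueError("loop overlap")
    # reaching past the loop into the opposite arm is always fatal
    if (arm == "5p" and b > loop[1]) or (arm == "3p" and a < loop[0] - 1):
        raise ValueError("loop overlap")
    return arm, loop, pt


def infer_star(structure: str, mature: tuple):
    """Star interval implied by the mature pairing plus 2-nt 3' overhang."""
    arm, _loop, pt = _arm_and_loop(structure, mature)
    a, b = mature
    partners = [int(pt[k]) for k in range(a, b)
                if pt[k] >= 0 and not (a <= pt[k] < b)]
    lo, hi = min(partners), max(partners) + 1
    if arm == "5p":
        return (lo + 2, hi + 2), arm
    return (max(lo - 2, 0), hi - 2), arm


TRIM_MARGIN = 5


def trim_to_hairpin(candidate: HairpinCandidate,
                    margin: int = TRIM_MARGIN) -> HairpinCandidate:
    """Trim an excised window down to the stem-loop around the mature.

    The window carries genomic flank beyond the actual precursor; the
    candidate is cut to the span of the mature's helix (paired mature
    bases plus their partners) with a small margin, refolded, and its
    coordinates remapped.  Significance testing on the trimmed
    precursor compares the hairpin against shuffles of itself rather
    than of unrelated flank.
    """
    pt = folding.pair_table(candidate.structure)
    a, b = candidate.mature_interval
    anchors = [k for k in range(a, b) if pt[k] >= 0]
    if not anchors:
        return candidate
    span = anchors + [int(pt[k]) for k in anchors]
    lo = max(0, min(span) - margin)
    hi = min(len(candidate.precursor_seq), max(span) + 1 + margin)
    lo = min(lo, a)
    hi = max(hi, b)
    seq = candidate.precursor_seq[lo:hi]
    structure, dg = folding.fold(seq)
    if candidate.strand == "-":
        g_start = candidate.end - hi
        g_end = candidate.end - lo
    else:
        g_start = candidate.start + lo
        g_end = candidate.start + hi
    return HairpinCandidate(
        candidate.contig, g_start, g_end, candidate.strand, seq, structure,
        dg, (a - lo, b - lo))


def structure_filter(candidate: HairpinCandidate,
                     dg_max: float = DG_MAX,
                     min_paired: float = MIN_PAIRED_FRACTION,
                     max_shuffle_p: float = MAX_SHUFFLE_P,
                     check_significance: bool = True):
    """Stem-loop acceptance test; returns (passed, reasons)."""
    reasons = []
    if not (candidate.delta_g < dg_max):
        reasons.append("energy")
    a, b = candidate.mature_interval
    try:
        _arm, loop, pt = _arm_and_loop(candidate.structure,
                                       candidate.mature_interval)
        n_paired = sum(1 for k in range(a, b) if pt[k] >= 0)
        if n_paired / (b - a) < min_paired:
            reasons.append("pairing")
    except ValueError as exc:
        reasons.append(str(exc))
    if check_significance:
        if candidate.shuffle_p is None:
            raise ValueError("shuffle_p not computed for candidate")
        if candidate.shuffle_p > max_shuffle_p:
            reasons.append("significance")
    return (not reasons), reasons


def filter_candidate_set(candidates, dg_max: float = DG_MAX,
                         n_shuffles: int = N_SHUFFLES, seed: int = 0):
    """Fold and structure-filter bare (seq, mature_interval, ...) tuples.

    Convenience for candidate sets that exist outside a genome context
    (benchmarks, designed sequences).  Returns the retained
    HairpinCandidate list.
    """
    retained = []
    for k, item in enumerate(candidates):
        seq, mature = item[0], item[1]
        structure, dg = folding.fold(seq)
        cand = HairpinCandidate("candidate", 0, len(seq), "+", seq,
                                structure, dg, tuple(mature))
        ok, _ = structure_filter(cand, dg_max, check_significance=False)
        if not ok:
            continue
        cand.shuffle_p = folding.shuffle_significance(seq, n_shuffles,
                                                      seed=seed + k)
        ok, _ = structure_filter(cand, dg_max)
        if ok:
            retained.append(cand)
    return retained


def _assign_region(read_ivl, mature, star, loop):
    mid = (read_ivl[0] + read_ivl[1]) / 2
    for name, (a, b) in (("mature", mature), ("star", star), ("loop", loop)):
        if a - 2 <= mid < b + 2:
            return name
    return "other"


def signature_score(candidate: HairpinCandidate, placements,
                    window=None):
    """Read-signature score and dominant arm for a filtered candidate.

    ``placements`` are the cluster's placements; ``window`` is the
    (contig, start, end, strand) the candidate was excised from (taken
    from the candidate itself when omitted).  Raises on zero mapped
    reads.
    """
    contig, ws, we, strand = window or (candidate.contig, candidate.start,
                                        candidate.end, candidate.strand)
    L = len(candidate.precursor_seq)
    reads = []
    for pl in placements:
        if pl.contig != contig or pl.strand != strand:
            continue
        if pl.end <= ws or pl.start >= we:
            continue
        if strand == "+":
            ivl = (pl.start - ws, pl.end - ws)
        else:
            ivl = (we - pl.end, we - pl.start)
        reads.append((ivl, pl.count))
    total = sum(c for _ivl, c in reads)
    if total == 0:
        raise ValueError("zero mapped reads on candidate")
    star_ivl, arm = infer_star(candidate.structure, candidate.mature_interval)
    _a, loop, _pt = _arm_and_loop(candidate.structure,
                                  candidate.mature_interval)
    counts = defaultdict(int)
    five_prime = defaultdict(int)
    star_consistent = False
    for ivl, c in reads:
        region = _assign_region(ivl, candidate.mature_interval,
                                star_ivl, loop)
        counts[region] += c
        if region == "mature":
            five_prime[ivl[0]] += c
        if region == "star" and abs(ivl[0] - star_ivl[0]) <= 2:
            star_consistent = True
    f_mature = counts["mature"] / total
    f_loop = counts["loop"] / total
    homog = max(five_prime.values()) / max(counts["mature"], 1) \
        if five_prime else 0.0
    score = (W_MATURE * f_mature + W_STAR * star_consistent
             + W_HOMOG * homog - W_LOOP * f_loop
             + W_ABUND * np.log2(total))
    mid = (candidate.mature_interval[0] + candidate.mature_interval[1]) / 2
    mature_is_5p = arm == "5p"
    half = L / 2
    reads_5p = sum(c for ivl, c in reads if (ivl[0] + ivl[1]) / 2 < half)
    reads_3p = total - reads_5p
    mature_side = reads_5p if (mid < half) else reads_3p
    dominant_arm = "mature" if mature_side >= total - mature_side else "star"
    candidate.signature = {
        "mature": counts["mature"], "star": counts["star"],
        "loop": counts["loop"], "other": counts["other"], "total": total,
    }
    candidate.score = float(score)
    return float(score), dominant_arm


def _cluster(placements):
    """Group placements into read loci (per contig, gap <= CLUSTER_GAP)."""
    by_ctg = defaultdict(list)
    for pl in placements:
        by_ctg[pl.contig].append(pl)
    clusters = []
    for _ctg, pls in sorted(by_ctg.items()):
        pls.sort(key=lambda p: (p.start, p.end, p.strand, p.tag_id))
        cur = [pls[0]]
        hi = pls[0].end
        for pl in pls[1:]:
            if pl.start <= hi + CLUSTER_GAP:
                cur.append(pl)
                hi = max(hi, pl.end)
            else:
                clusters.append(cur)
                cur = [pl]
                hi = pl.end
        clusters.append(cur)
    return clusters


def discover(tags, genome: dict, known_catalog=None,
             flank: int = DEFAULT_FLANK, dg_max: float = DG_MAX,
             min_paired: float = MIN_PAIRED_FRACTION,
             max_shuffle_p: float = MAX_SHUFFLE_P,
             score_min: float = SCORE_MIN, n_shuffles: int = N_SHUFFLES,
             seed: int = 0, max_loci: int = MAX_LOCI):
    """Read-anchored discovery: one best candidate per read cluster.

    Returns (records, candidates).  Records carry conserved homolog
    names when the mature matches the known catalog within 2
    mismatches, otherwise novel names: 'ssc-miR-new<k>' for 18-26 nt
    matures and 'ssc-miR-large<k>' for 27-30 nt.
    """
    placements, _multi = map_tags(tags, genome, max_loci)
    results = []
    for cluster in _cluster(placements):
        rep = max(cluster, key=lambda p: (p.count, p.tag_id))
        windows = excise_precursors([rep], genome, flank)
        best = None
        for contig, ws, we, strand, seq, m_ivl in windows:
            structure, dg = folding.fold(seq)
            cand = HairpinCandidate(contig, ws, we, strand, seq, structure,
                                    dg, m_ivl)
            ok, _reasons = structure_filter(
                cand, dg_max, min_paired, check_significance=False)
            if not ok:
                continue
            cand = trim_to_hairpin(cand)
            ok, _reasons = structure_filter(
                cand, dg_max, min_paired, check_significance=False)
            if not ok:
                continue
            cand.shuffle_p = folding.shuffle_significance(
                cand.precursor_seq, n_shuffles, seed=seed + ws)
            ok, _reasons = structure_filter(cand, dg_max, min_paired,
                                            max_shuffle_p)
            if not ok:
                continue
            try:
                score, dom = signature_score(cand, cluster)
            except ValueError:
                continue
            if score < score_min:
                continue
            if best is None or score > best[0].score:
                best = (cand, dom, rep)
        if best:
            results.append(best)
    # deduplicate candidates whose genomic intervals overlap
    results.sort(key=lambda r: -r[0].score)
    kept = []
    for cand, dom, rep in results:
        if any(k[0].contig == cand.contig
               and max(k[0].start, cand.start) < min(k[0].end, cand.end)
               for k in kept):
            continue
        kept.append((cand, dom, rep))
    records = []
    counters = {"new": 0, "large": 0}
    for cand, dom, rep in sorted(kept, key=lambda r: (r[0].contig,
                                                      r[0].start)):
        star_ivl, _arm = infer_star(cand.structure, cand.mature_interval)
        a, b = [max(0, star_ivl[0]), min(len(cand.precursor_seq),
                                         star_ivl[1])]
        star_seq = cand.precursor_seq[a:b]
        name = None
        if known_catalog:
            hits = match_known([rep], known_catalog, max_mm=2)
            if hits:
                hit = min(hits, key=lambda h: (h.n_mismatches,
                                               abs(h.length_delta)))
                name = base_name(hit.known_mature_id)
        if name is None:
            kind = "new" if len(rep.sequence) <= 26 else "large"
            counters[kind] += 1
            name = f"ssc-miR-{kind}{counters[kind]}"
        records.append(MirnaRecord(
            name=name, mature_seq=rep.sequence, star_seq=star_seq,
            precursor=cand.precursor_seq, methods={"method1"},
            dominant_arm=dom))
    return records, [r[0] for r in kept]


def genome_homolog_scan(known_matures, genome: dict,
                        flank: int = DEFAULT_FLANK,
                        min_identity: float = 0.95,
                        dg_max: float = DG_MAX,
                        max_shuffle_p: float = MAX_SHUFFLE_P,
                        n_shuffles: int = N_SHUFFLES, seed: int = 0):
    """Genome-wide scan seeded by known matures (method 3).

    Ungapped full-length hits with identity strictly above
    ``min_identity`` are excised with flanking context, folded and kept
    when the structure filter passes.
    """
    from .homology import _as_entries
    entries = _as_entries(known_matures)
    records = []
    seen_loci = []
    for ctg, seq in sorted(genome.items()):
        enc_fwd = encode(seq)
        for e in entries:
            L = len(e.sequence)
            if L > len(seq):
                continue
            max_mm = int(np.ceil((1.0 - min_identity) * L)) - 1 \
                if (1.0 - min_identity) * L == int((1.0 - min_identity) * L) \
                else int((1.0 - min_identity) * L)
            m_enc = encode(e.sequence)
            win = np.lib.stride_tricks.sliding_window_view(enc_fwd, L)
            for strand, query in (("+", m_enc),
                                  ("-", encode(revcomp(e.sequence)))):
                mm = (win != query).sum(axis=1)
                for p in np.nonzero(mm <= max_mm)[0]:
                    p = int(p)
                    locus = (ctg, p, p + L)
                    if any(c == ctg and max(s, p) < min(en, p + L)
                           for c, s, en in seen_loci):
                        continue
                    pl = Placement(f"{e.entry_id}@{p}", e.sequence, 1,
                                   ctg, p, p + L, strand)
                    for contig, ws, we, st, wseq, m_ivl in \
                            excise_precursors([pl], genome, flank):
                        structure, dg = folding.fold(wseq)
                        cand = HairpinCandidate(contig, ws, we, st, wseq,
                                                structure, dg, m_ivl)
                        ok, _ = structure_filter(cand, dg_max,
                                                 check_significance=False)
                        if not ok:
                            continue
                        cand = trim_to_hairpin(cand)
                        ok, _ = structure_filter(cand, dg_max,
                                                 check_significance=False)
                        if not ok:
                            continue
                        cand.shuffle_p = folding.shuffle_significance(
                            cand.precursor_seq, n_shuffles, seed=seed + ws)
                        ok, _ = structure_filter(cand, dg_max,
                                                 max_shuffle_p=max_shuffle_p)
                        if not ok:
                            continue
                        seen_loci.append(locus)
                        records.append(MirnaRecord(
                            name=base_name(e.entry_id),
                            mature_seq=seq[p:p + L] if strand == "+"
                            else revcomp(seq[p:p + L]),
                            precursor=wseq, methods={"method3"}))
                        break
    # one record per miRNA name (first passing locus wins)
    uniq = {}
    for r in records:
        uniq.setdefault(r.name, r)
    return list(uniq.values())
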