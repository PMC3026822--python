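"""Mapping, excision, structure filtering, scoring, homolog scan."""

import numpy as np
import pytest

from mirforge import folding, hairpin, simlib, preprocess
from mirforge.hairpin import (HairpinCandidate, Placement, excise_precursors,
                              genome_homolog_scan, map_tags, signature_score,
                              structure_filter)
from mirforge.preprocess import UniqueTag
from mirforge._seq import revcomp

COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _stem_hairpin(arm_len=22, seed=1):
    rng = np.random.default_rng(seed)
    arm = "".join(rng.choice(list("ACGT"), size=arm_len))
    return arm + "GCAATCGATTCA" + revcomp(arm), arm


def test_map_tags_both_strands_and_multimap_cap():
    prec, arm = _stem_hairpin()
    genome = {"c1": "TTTTTTTTTT" + prec + "TTTTTTTTTT"}
    tags = [UniqueTag("F1_x5", arm, 5)]
    placements, multi = map_tags(tags, genome)
    # forward hit at the arm, reverse hit at the (complementary) far arm
    strands = sorted(p.strand for p in placements)
    assert strands == ["+", "-"]
    assert not multi
    rep = ["AAAAAAAAAAAAAAAAAAAA"]
    g2 = {"c1": "TTTT".join(["AAAAAAAAAAAAAAAAAAAAAA"] * 8)}
    _pls, multi2 = map_tags([UniqueTag("F1_x1", rep[0], 1)], g2)
    assert multi2 == {"F1_x1"}


def test_excision_windows_clip_and_bound():
    pl = Placement("F1_x1", "A" * 22, 1, "c1", 0, 22, "+")
    genome = {"c1": "A" * 200}
    wins = excise_precursors([pl], genome, flank=70)
    for _c, ws, we, _s, seq, m_ivl in wins:
        assert ws >= 0 and we <= 200
        assert we - ws <= 22 + 70
        assert 0 <= m_ivl[0] < m_ivl[1] <= len(seq)
    with pytest.raises(ValueError):
        excise_precursors([pl], genome, flank=0)


def test_excised_window_contains_planted_precursor():
    cfg = simlib.SimConfig(n_hairpins=3, genome_length=6000, rng_seed=6)
    truth = simlib.simulate_genome(cfg)
    genome = {truth.genome_id: truth.genome_seq}
    for hp in truth.hairpins:
        pl = Placement("F1_x1", hp.mature_seq, 1, truth.genome_id,
                       hp.mature_start, hp.mature_end, "+")
        wins = excise_precursors([pl], genome, flank=70)
        assert any(hp.precursor_seq in seq for _c, _ws, _we, _s, seq, _m
                   in wins)


def _candidate(seq, mature, shuffle_p=0.01):
    structure, dg = folding.fold(seq)
    return HairpinCandidate("c1", 0, len(seq), "+", seq, structure, dg,
                            mature, shuffle_p=shuffle_p)


def test_structure_filter_pass_and_energy_reason():
    prec, arm = _stem_hairpin()
    cand = _candidate(prec, (0, len(arm)))
    ok, reasons = structure_filter(cand)
    assert ok and cand.delta_g < -17
    weak = _candidate("AAAAATTTTTAAAAATTTTTAAAA", (0, 20))
    ok, reasons = structure_filter(weak)
    assert not ok and "energy" in reasons


def test_structure_filter_loop_overlap_reason():
    prec, arm = _stem_hairpin()
    # a "mature" centred on the terminal loop straddles both arms
    centre = len(prec) // 2
    cand = _candidate(prec, (centre - 10, centre + 10))
    ok, reasons = structure_filter(cand, check_significance=False)
    assert not ok and "loop overlap" in reasons


def test_structure_filter_significance_reason():
    prec, arm = _stem_hairpin()
    cand = _candidate(prec, (0, len(arm)), shuffle_p=0.2)
    ok, reasons = structure_filter(cand)
    assert not ok and reasons == ["significance"]


def test_signature_score_prefers_concentrated_mature_reads():
    prec, arm = _stem_hairpin()
    n = len(arm)
    star_start = len(prec) - n

    def placements(mature_reads, star_reads, loop_reads):
        pls = [Placement("F1_x%d" % mature_reads, arm, mature_reads,
                         "c1", 0, n, "+")]
        if star_reads:
            pls.append(Placement("F2_x%d" % star_reads, "x", star_reads,
                                 "c1", star_start, len(prec), "+"))
        if loop_reads:
            pls.append(Placement("F3_x%d" % loop_reads, "x", loop_reads,
                                 "c1", n + 2, n + 12, "+"))
        return pls

    cand = _candidate(prec, (0, n))
    hi, dom_hi = signature_score(cand, placements(90, 5, 5))
    cand2 = _candidate(prec, (0, n))
    lo, dom_lo = signature_score(cand2, placements(50, 5, 45))
    assert hi > lo
    assert dom_hi == "mature"


def test_star_dominated_locus_reports_star_arm():
    # the star-named arm may dominate expression (8483 vs 4 reads)
    prec, arm = _stem_hairpin()
    n = len(arm)
    pls = [Placement("F1_x4", arm, 4, "c1", 0, n, "+"),
           Placement("F2_x8483", "x", 8483, "c1", len(prec) - n,
                     len(prec), "+")]
    cand = _candidate(prec, (0, n))
    _score, dom = signature_score(cand, pls)
    assert dom == "star"


def test_signature_score_zero_reads_is_error():
    prec, arm = _stem_hairpin()
    cand = _candidate(prec, (0, len(arm)))
    with pytest.raises(ValueError, match="zero mapped reads"):
        signature_score(cand, [])


def test_all_loop_reads_score_below_threshold():
    prec, arm = _stem_hairpin()
    n = len(arm)
    pls = [Placement("F1_x50", "x", 50, "c1", n + 2, n + 11, "+")]
    cand = _candidate(prec, (0, n))
    score, _dom = signature_score(cand, pls)
    assert score < hairpin.SCORE_MIN


@pytest.mark.parametrize("n_mm,expected", [(0, True), (1, True), (2, False)])
def test_homolog_scan_identity_threshold(n_mm, expected):
    """identity > 95% over a 22-mer admits at most one mismatch."""
    prec, arm = _stem_hairpin(22, seed=9)
    rng = np.random.default_rng(0)
    flank = "".join(rng.choice(list("ACGT"), size=300))
    genome = {"c1": flank[:150] + prec + flank[150:]}
    mature = list(arm)
    for k in range(n_mm):
        pos = 3 + 2 * k
        mature[pos] = COMP[mature[pos]]
    catalog = [("hsa-miR-7", "hsa", "miR-7", "".join(mature))]
    records = genome_homolog_scan(catalog, genome, seed=4)
    assert bool(records) is expected
    if records:
        assert records[0].methods == {"method3"}
        assert records[0].name == "miR-7"


def test_discovery_recovers_planted_hairpins_error_free(small_library):
    cfg, truth, _reads, tags, _stats = small_library
    genome = {truth.genome_id: truth.genome_seq}
    known = simlib.make_known_catalog(truth, cfg.rng_seed)
    records, cands = hairpin.discover(tags, genome, known, seed=cfg.rng_seed)
    assert all(c.delta_g < -17.0 for c in cands)
    loci = [(c.start, c.end) for c in cands]
    hit = sum(1 for hp in truth.hairpins
              if any(max(s, hp.mature_start) < min(e, hp.mature_end)
                     for s, e in loci))
    assert hit >= 0.9 * len(truth.hairpins)
    # conserved names come from the known catalog
    assert all(r.name.startswith("miR-s") for r in records)
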