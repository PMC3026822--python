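"""Known-mature matching, species collapsing, three-method merge."""

import numpy as np
import pytest

from mirforge.homology import (CatalogEntry, MirnaRecord, base_name,
                               collapse_species, match_known, merge_methods,
                               parse_mature_fasta)
from mirforge.preprocess import UniqueTag

MIR = "TGGAATGTAAAGAAGTATGTAT"   # 22 nt


def _tag(seq, count=1, rank=1):
    return UniqueTag(f"F{rank}_x{count}", seq, count)


def _catalog():
    return [CatalogEntry("ptr-let-7b", "ptr", "let-7b", MIR),
            CatalogEntry("xtr-let-7b", "xtr", "let-7b",
                         MIR[:5] + "CC" + MIR[7:]),
            CatalogEntry("hsa-miR-206", "hsa", "miR-206",
                         "CCCCCGGGGGAAAAATTTTTCC")]


def test_perfect_variant_and_rejected_matches():
    tags = [_tag(MIR, 10, 1),                        # perfect
            _tag(MIR[:3] + "CC" + MIR[5:], 5, 2),    # 2 internal subs
            _tag(MIR[:3] + "CCA" + MIR[6:], 1, 3)]   # 3 subs: no hit
    hits = match_known(tags, _catalog()[:1])
    by_tag = {h.tag_id: h for h in hits}
    assert by_tag["F1_x10"].n_mismatches == 0
    assert by_tag["F1_x10"].length_delta == 0
    assert by_tag["F2_x5"].n_mismatches == 2
    assert "F3_x1" not in by_tag


def test_terminal_overhangs_count_in_length_delta_not_mismatches():
    tags = [_tag(MIR + "TT", 3, 1), _tag(MIR[2:], 2, 2)]
    hits = match_known(tags, _catalog()[:1])
    by_tag = {h.tag_id: h for h in hits}
    assert by_tag["F1_x3"].n_mismatches == 0
    assert by_tag["F1_x3"].length_delta == 2
    assert by_tag["F2_x2"].n_mismatches == 0
    assert by_tag["F2_x2"].length_delta == -2


def test_collapse_cross_species_synonyms_to_one_species():
    tags = [_tag(MIR, 88532, 1),
            _tag(MIR[:5] + "CC" + MIR[7:], 4, 2),
            _tag("CCCCCGGGGGAAAAATTTTTCC", 7, 3)]
    hits = match_known(tags, _catalog())
    records = collapse_species(hits, tags)
    names = sorted(r.name for r in records)
    assert names == ["let-7b", "miR-206"]
    let7b = next(r for r in records if r.name == "let-7b")
    assert let7b.mature_seq == MIR   # highest-count tag represents the group


def test_collapse_representative_is_max_count():
    seqs = [MIR, MIR[:4] + "C" + MIR[5:], MIR[1:], MIR + "A", MIR[:21]]
    counts = [10, 5, 3, 2, 1]
    tags = [_tag(s, c, i + 1) for i, (s, c) in enumerate(zip(seqs, counts))]
    hits = match_known(tags, _catalog()[:1])
    records = collapse_species(hits, tags)
    assert len(records) == 1 and records[0].mature_seq == MIR


def test_collapse_is_idempotent():
    tags = [_tag(MIR, 9, 1)]
    hits = match_known(tags, _catalog())
    once = collapse_species(hits, tags)
    again = collapse_species(hits, tags)
    assert [(r.name, r.mature_seq) for r in once] == \
        [(r.name, r.mature_seq) for r in again]


def _rec(name, seq, method):
    return MirnaRecord(name=name, mature_seq=seq, methods={method})


def test_merge_methods_union_and_venn_cells():
    m1 = [_rec("miR-1", MIR, "method1"), _rec("miR-9", "A" * 22, "method1")]
    m2 = [_rec("miR-1", MIR, "method2")]
    m3 = [_rec("miR-1", MIR, "method3"), _rec("miR-7", "C" * 22, "method3")]
    merged, venn, conflicts = merge_methods(m1, m2, m3)
    rec = next(r for r in merged if r.name == "miR-1")
    assert rec.methods == {"method1", "method2", "method3"}
    assert venn == {"m1": 1, "m2": 0, "m3": 1, "m1m2": 0, "m1m3": 0,
                    "m2m3": 0, "m1m2m3": 1}
    assert sum(venn.values()) == len(merged)
    assert not conflicts


def test_merge_with_empty_method3_zeroes_its_cells():
    m1 = [_rec("miR-1", MIR, "method1")]
    merged, venn, _ = merge_methods(m1, [], [])
    assert venn["m3"] == venn["m1m3"] == venn["m2m3"] == venn["m1m2m3"] == 0
    assert venn["m1"] == 1


def test_merge_constructed_overlaps_row_sums():
    """Catalog sizes 188/416/137 with a constructed overlap structure:
    each method's Venn cells sum back to its input size."""
    rng = np.random.default_rng(0)

    def seq(i):
        rng2 = np.random.default_rng(i)
        return "".join(rng2.choice(list("ACGT"), size=22))

    core = [f"miR-c{i}" for i in range(135)]          # in all three
    m1_names = core + [f"miR-a{i}" for i in range(53)]           # 188
    m2_names = core + [f"miR-b{i}" for i in range(281)]          # 416
    m3_names = core + [f"miR-d{i}" for i in range(2)]            # 137
    all_names = sorted(set(m1_names + m2_names + m3_names))
    seqs = {n: seq(k) for k, n in enumerate(all_names)}
    m1 = [_rec(n, seqs[n], "method1") for n in m1_names]
    m2 = [_rec(n, seqs[n], "method2") for n in m2_names]
    m3 = [_rec(n, seqs[n], "method3") for n in m3_names]
    merged, venn, conflicts = merge_methods(m1, m2, m3)
    assert not conflicts
    assert venn["m1"] + venn["m1m2"] + venn["m1m3"] + venn["m1m2m3"] == 188
    assert venn["m2"] + venn["m1m2"] + venn["m2m3"] + venn["m1m2m3"] == 416
    assert venn["m3"] + venn["m1m3"] + venn["m2m3"] + venn["m1m2m3"] == 137
    assert venn["m1m2m3"] == 135
    assert sum(venn.values()) == len(merged)


def test_merge_conflicting_sequences_kept_with_suffixes():
    a = _rec("miR-5", "A" * 22, "method1")
    b = _rec("miR-5", "C" * 22, "method2")
    merged, _venn, conflicts = merge_methods([a], [b], [])
    assert len(conflicts) == 1
    assert len(merged) == 2
    assert {r.mature_seq for r in merged} == {"A" * 22, "C" * 22}


def test_base_name_and_fasta_roundtrip(tmp_path):
    p = tmp_path / "cat.fa"
    p.write_text(">ptr-let-7b MIMAT0000\nUGGAAUGUAAAGAAGUAUGUAU\n")
    entries = parse_mature_fasta(p)
    assert entries[0].species == "ptr"
    assert entries[0].name == "let-7b"
    assert entries[0].sequence == MIR
    assert base_name("ssc-miR-140") == "miR-140"
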