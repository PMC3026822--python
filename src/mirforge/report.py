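"""Pipeline orchestration and summary artifacts.

Runs simulate -> preprocess -> annotate -> discover -> homology/merge ->
isomiR -> families in order, writes every table to a run directory, and
keeps a manifest of per-stage record counts so the accounting (length
distribution, class composition, method overlap) is auditable.  Given
the same configuration and seed the run is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from . import simlib, preprocess, annotate, hairpin, homology, isomir, \
    families as families_mod
from .isomir import PrecursorEntry


@dataclass
class PipelineConfig:
    sim: simlib.SimConfig = field(default_factory=simlib.SimConfig)
    min_mean_q: float = preprocess.DEFAULT_MIN_MEAN_Q
    min_len: int = preprocess.DEFAULT_MIN_LEN
    max_len: int = preprocess.DEFAULT_MAX_LEN
    flank: int = hairpin.DEFAULT_FLANK
    dg_max: float = hairpin.DG_MAX
    score_min: float = hairpin.SCORE_MIN
    n_shuffles: int = hairpin.N_SHUFFLES
    max_mm_homology: int = 2


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages[stage] = {"in": int(n_in), "out": int(n_out)}


def length_distribution(tags, lo: int = 18, hi: int = 30) -> pd.DataFrame:
    """Read counts and percentages per insert length."""
    counts = {L: 0 for L in range(lo, hi + 1)}
    for t in tags:
        counts[len(t.sequence)] = counts.get(len(t.sequence), 0) + t.count
    total = sum(counts.values())
    df = pd.DataFrame({
        "length": list(counts), "read_count": list(counts.values())})
    df["percent"] = (100.0 * df["read_count"] / max(total, 1)).round(2)
    return df


def run_pipeline(config: PipelineConfig, outdir=None):
    """Execute the full pipeline on a simulated library.

    Returns (manifest, outputs dict).  When ``outdir`` is given, every
    table is written there (TSV/FASTA/JSON).
    """
    manifest = RunManifest(config=_config_dict(config), version=__version__)
    outputs = {}

    truth = simlib.simulate_genome(config.sim)
    reads = simlib.simulate_reads(truth, config.sim)
    manifest.record("simulate", 0, len(reads))

    tags, stats = preprocess.run_preprocess(
        reads, config.sim.adapter_3p, config.sim.adapter_5p,
        config.min_mean_q, config.min_len, config.max_len)
    manifest.record("preprocess", stats.raw_reads, stats.high_quality_reads)
    outputs["preprocess_stats"] = stats
    outputs["tags"] = tags

    known_catalog = simlib.make_known_catalog(truth, config.sim.rng_seed)
    catalogs = dict(truth.contaminant_catalogs)
    catalogs = {cls: [(f"{cls}{k + 1}", s) for k, s in enumerate(seqs)]
                for cls, seqs in catalogs.items()}
    catalogs["known_miRNA"] = known_catalog
    records = annotate.classify_cascade(tags, catalogs)
    composition = annotate.composition_summary(records, tags)
    manifest.record("annotate", len(tags), len(records))
    outputs["annotation"] = records
    outputs["composition"] = composition

    genome = {truth.genome_id: truth.genome_seq}
    m1_records, candidates = hairpin.discover(
        tags, genome, known_catalog, flank=config.flank,
        dg_max=config.dg_max, score_min=config.score_min,
        n_shuffles=config.n_shuffles, seed=config.sim.rng_seed)
    manifest.record("discover", len(tags), len(m1_records))
    outputs["method1"] = m1_records
    outputs["candidates"] = candidates

    mirna_tags = [t for t, r in zip(tags, records)
                  if r.assigned_class in ("known_miRNA", "unknown")]
    hits = homology.match_known(mirna_tags, known_catalog,
                                max_mm=config.max_mm_homology)
    m2_records = homology.collapse_species(hits, mirna_tags)
    manifest.record("homology", len(mirna_tags), len(m2_records))
    outputs["method2"] = m2_records

    m3_records = hairpin.genome_homolog_scan(
        known_catalog, genome, flank=config.flank, dg_max=config.dg_max,
        n_shuffles=config.n_shuffles, seed=config.sim.rng_seed)
    manifest.record("homolog_scan", len(known_catalog), len(m3_records))
    outputs["method3"] = m3_records

    merged, venn, conflicts = homology.merge_methods(
        m1_records, m2_records, m3_records)
    manifest.record("merge", len(m1_records) + len(m2_records)
                    + len(m3_records), len(merged))
    outputs["catalog"] = merged
    outputs["venn"] = venn
    outputs["conflicts"] = conflicts

    iso_catalog = []
    for rec, cand in zip(m1_records, candidates):
        a, b = cand.mature_interval
        iso_catalog.append(PrecursorEntry(rec.name, cand.precursor_seq,
                                          a, b))
    iso_tags = [t for t, r in zip(tags, records)
                if r.assigned_class in ("known_miRNA", "unknown")]
    isomirs = isomir.assign_and_classify(iso_tags, iso_catalog)
    summaries, iso_stats = isomir.summarize(isomirs, iso_catalog)
    manifest.record("isomir", len(iso_tags), len(isomirs))
    outputs["isomirs"] = isomirs
    outputs["isomir_summaries"] = summaries
    outputs["isomir_stats"] = iso_stats

    fams = families_mod.group_families(
        [(r.name, r.mature_seq) for r in merged if len(r.mature_seq) >= 8])
    manifest.record("families", len(merged), len(fams))
    outputs["families"] = fams

    outputs["length_distribution"] = length_distribution(tags)
    outputs["truth"] = truth

    if outdir is not None:
        _write_outputs(outdir, manifest, outputs, truth)
    return manifest, outputs


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["sim"]["isomir_profile"] = {
        f"{k[0]},{k[1]}": v for k, v in d["sim"]["isomir_profile"].items()}
    return d


def _write_outputs(outdir, manifest, outputs, truth) -> None:
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    simlib.write_genome_fasta(truth, out / "genome.fa")
    simlib.write_truth_tsv(truth, out / "truth.tsv")
    preprocess.tags_to_fasta(outputs["tags"], out / "tags.fa")
    pd.DataFrame([{
        "tag_id": r.tag_id, "class": r.assigned_class,
        "reference": r.matched_reference_id, "kind": r.match_kind,
    } for r in outputs["annotation"]]).to_csv(
        out / "annotation.tsv", sep="\t", index=False)
    outputs["composition"].to_csv(out / "composition.tsv", sep="\t")
    outputs["length_distribution"].to_csv(
        out / "length_distribution.tsv", sep="\t", index=False)
    with open(out / "precursors.fa", "w") as fh:
        for cand in outputs["candidates"]:
            fh.write(f">{cand.contig}:{cand.start}-{cand.end}({cand.strand})"
                     f" dG={cand.delta_g:.2f}\n{cand.precursor_seq}\n"
                     f"{cand.structure}\n")
    pd.DataFrame([{
        "name": r.name, "mature_seq": r.mature_seq, "star_seq": r.star_seq,
        "methods": ",".join(sorted(r.methods)),
        "dominant_arm": r.dominant_arm,
    } for r in outputs["catalog"]]).to_csv(
        out / "catalog.tsv", sep="\t", index=False)
    pd.DataFrame([outputs["venn"]]).to_csv(out / "venn.tsv", sep="\t",
                                           index=False)
    isomir.isomirs_to_frame(outputs["isomirs"]).to_csv(
        out / "isomirs.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "miRNA": s.mirna_name, "n_isomirs": s.n_isomirs,
        "total_reads": s.total_reads,
        "most_abundant_seq": s.most_abundant_seq,
        "matches_reference": s.matches_reference,
    } for s in outputs["isomir_summaries"]]).to_csv(
        out / "isomir_summary.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "seed": f.seed, "size": len(f.members),
        "members": ",".join(f.members),
    } for f in outputs["families"]]).to_csv(
        out / "families.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": manifest.config, "version": manifest.version,
                   "stages": manifest.stages}, fh, indent=2, sort_keys=True)
        fh.write("\n")
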