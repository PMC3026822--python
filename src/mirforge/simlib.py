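"""Synthetic data generator for the discovery pipeline.

Emulates the statistical structure of a pooled-tissue small-RNA Solexa
library: a mock genome with planted miRNA hairpins, mock reference
catalogs (ncRNA classes, mRNA fragments, 26-30 nt piRNA-like entries,
and a miRBase-style known-mature set), sequencing reads carrying isomiR
terminal offsets / untemplated 3' additions / base-call errors plus
ligated adapters, and microarray signal matrices with negative-control
probes.  Everything is driven by a single integer seed and is
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seq import revcomp, BASES
from . import folding

# Default isomiR terminal-offset profile: mass concentrated on the
# reference ends, +-1 at either end at 0.08 each, +-2 at 0.02 each.
DEFAULT_ISOMIR_PROFILE = {
    (0, 0): 0.60,
    (-1, 0): 0.08, (1, 0): 0.08, (0, -1): 0.08, (0, 1): 0.08,
    (-2, 0): 0.02, (2, 0): 0.02, (0, -2): 0.02, (0, 2): 0.02,
}

# Classic Illumina small-RNA adapters.
ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

CONTAMINANT_CLASS_WEIGHTS = {
    "rRNA": 0.30, "tRNA": 0.20, "snRNA": 0.05, "snoRNA": 0.05,
    "mRNA": 0.25, "piRNA": 0.15,
}

MATURE_LENGTHS = np.array([20, 21, 22, 23, 24])
MATURE_LENGTH_P = np.array([0.10, 0.25, 0.40, 0.20, 0.05])


@dataclass
class SimConfig:
    """Parameters of the simulated library."""

    n_hairpins: int = 20
    genome_length: int = 50_000
    read_depth: int = 20_000
    isomir_profile: dict = field(
        default_factory=lambda: dict(DEFAULT_ISOMIR_PROFILE))
    nta_rate: float = 0.05
    substitution_error_rate: float = 0.01
    contaminant_fraction: float = 0.25
    adapter_3p: str = ADAPTER_3P
    adapter_5p: str = ADAPTER_5P
    rng_seed: int = 0
    # secondary knobs (not part of the headline contract)
    read_length: int = 36
    adapter5_contam_rate: float = 0.01
    star_fraction: float = 0.08
    equal_weights: bool = False

    def validate(self) -> None:
        probs = [self.nta_rate, self.substitution_error_rate,
                 self.contaminant_fraction, self.adapter5_contam_rate,
                 self.star_fraction]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.read_depth < 0 or self.n_hairpins < 0:
            raise ValueError("depth and counts must be non-negative")
        if abs(sum(self.isomir_profile.values()) - 1.0) > 1e-9:
            raise ValueError("isomir_profile must sum to 1")
        if not self.adapter_3p or not self.adapter_5p:
            raise ValueError("adapter sequences must be non-empty")


@dataclass
class PlantedHairpin:
    hairpin_id: str
    contig: str
    start: int
    end: int
    strand: str
    mature_start: int
    mature_end: int
    star_start: int
    star_end: int
    mature_seq: str
    precursor_seq: str


@dataclass
class SimTruth:
    """Ground truth of one simulated genome."""

    genome_id: str
    genome_seq: str
    hairpins: list
    contaminant_catalogs: dict
    expression_weights: dict


def _random_seq(rng: np.random.Generator, length: int,
                p: np.ndarray | None = None) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=p))


def _make_precursor(rng: np.random.Generator) -> tuple[str, str, int, int]:
    """Random mature arm + loop + near-complementary star arm.

    The star arm carries two point changes so the hairpin is stable but
    the two arms are not exact reverse complements (avoids phantom
    opposite-strand self-mappings).  Retries until the fold clears the
    -17 kcal/mol stability filter (near-certain on the first draw).
    """
    for _ in range(20):
        m_len = int(rng.choice(MATURE_LENGTHS, p=MATURE_LENGTH_P))
        mature = _random_seq(rng, m_len)
        loop = _random_seq(rng, int(rng.integers(10, 15)))
        star = list(revcomp(mature))
        for pos in rng.choice(np.arange(2, m_len - 2), size=2, replace=False):
            star[pos] = rng.choice([b for b in BASES if b != star[pos]])
        star = "".join(star)
        prec = mature + loop + star
        _, dg = folding.fold(prec)
        if dg < -17.0:
            return prec, mature, m_len, len(loop)
    raise RuntimeError("failed to design a stable hairpin")


def _contaminant_catalogs(rng: np.random.Generator) -> dict:
    cats = {
        "rRNA": [_random_seq(rng, 300)],
        "tRNA": [_random_seq(rng, 76) for _ in range(3)],
        "snRNA": [_random_seq(rng, 150) for _ in range(2)],
        "snoRNA": [_random_seq(rng, 120) for _ in range(2)],
        "mRNA": [_random_seq(rng, 400) for _ in range(5)],
        "piRNA": [_random_seq(rng, int(rng.integers(26, 31)))
                  for _ in range(40)],
    }
    return cats


def simulate_genome(config: SimConfig) -> SimTruth:
    """Build the mock genome and its truth table.

    Hairpins are planted at evenly spaced, non-overlapping loci on the
    plus strand of a single contig; each planted precursor passes the
    dG < -17 kcal/mol stability filter when folded by the built-in
    backend.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_hairpins
    if n > 0 and config.genome_length < 200 * n:
        raise ValueError(
            f"genome_length {config.genome_length} too small to place "
            f"{n} hairpins (need >= {200 * n})")
    genome = list(_random_seq(rng, config.genome_length))
    hairpins = []
    weights = {}
    if n > 0:
        spacing = config.genome_length // n
        for i in range(n):
            prec, mature, m_len, l_len = _make_precursor(rng)
            lo = spacing * i + 40
            hi = spacing * (i + 1) - len(prec) - 40
            start = int(rng.integers(lo, max(lo + 1, hi)))
            end = start + len(prec)
            genome[start:end] = list(prec)
            hid = f"hp{i + 1}"
            hairpins.append(PlantedHairpin(
                hairpin_id=hid, contig="sim1", start=start, end=end,
                strand="+",
                mature_start=start, mature_end=start + m_len,
                star_start=start + m_len + l_len, star_end=end,
                mature_seq=mature, precursor_seq=prec))
            if config.equal_weights:
                weights[hid] = 1.0
            else:
                weights[hid] = float(rng.lognormal(0.0, 1.2))
    return SimTruth(
        genome_id="sim1", genome_seq="".join(genome), hairpins=hairpins,
        contaminant_catalogs=_contaminant_catalogs(rng),
        expression_weights=weights)


def make_known_catalog(truth: SimTruth, seed: int = 0,
                       n_variant_species: int = 1) -> list:
    """Mock miRBase-style mature catalog covering the planted hairpins.

    Each planted mature gets one exact entry and optionally extra
    cross-species synonyms carrying 1-2 substitutions, mimicking the
    minor inter-species differences of real mature catalogs.  Entries
    are (entry_id, species, base_name, sequence).
    """
    rng = np.random.default_rng(seed + 101)
    species_pool = ["hsa", "mmu", "rno", "bta", "ptr"]
    catalog = []
    for i, hp in enumerate(truth.hairpins):
        name = f"miR-s{i + 1}"
        sp = species_pool[i % len(species_pool)]
        catalog.append((f"{sp}-{name}", sp, name, hp.mature_seq))
        for v in range(n_variant_species):
            sp2 = species_pool[(i + v + 1) % len(species_pool)]
            seq = list(hp.mature_seq)
            for pos in rng.choice(len(seq), size=int(rng.integers(1, 3)),
                                  replace=False):
                seq[pos] = rng.choice([b for b in BASES if b != seq[pos]])
            catalog.append((f"{sp2}-{name}", sp2, name, "".join(seq)))
    return catalog


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in BASES if b != arr[i]])
    return "".join(arr)


def simulate_reads(truth: SimTruth, config: SimConfig) -> list:
    """Sample ``read_depth`` reads as (title, sequence, quality) tuples.

    A read is, in decreasing priority: an adapter-dimer artifact (5'
    adapter contaminant), a contaminant-class fragment, or a mature
    miRNA variant drawn from the isomiR offset profile with optional
    untemplated 3' addition, per-base substitution errors on the insert,
    and the 3' adapter ligated and truncated at the read length.
    Qualities are constant Phred 40.
    """
    config.validate()
    if config.read_depth == 0:
        return []
    if not truth.hairpins and config.contaminant_fraction == 0:
        raise ValueError(
            "cannot generate reads: empty truth and contaminant_fraction 0")
    rng = np.random.default_rng(config.rng_seed + 7919)
    offsets = list(config.isomir_profile.keys())
    off_p = np.array([config.isomir_profile[o] for o in offsets])
    off_p = off_p / off_p.sum()
    classes = list(CONTAMINANT_CLASS_WEIGHTS)
    class_p = np.array([CONTAMINANT_CLASS_WEIGHTS[c] for c in classes])
    class_p = class_p / class_p.sum()
    hp_ids = [hp.hairpin_id for hp in truth.hairpins]
    hp_by_id = {hp.hairpin_id: hp for hp in truth.hairpins}
    if hp_ids:
        w = np.array([truth.expression_weights[h] for h in hp_ids])
        w = w / w.sum()
    genome = truth.genome_seq
    reads = []
    for i in range(config.read_depth):
        title = f"read{i + 1}"
        if rng.random() < config.adapter5_contam_rate:
            seq = (config.adapter_5p + config.adapter_3p
                   )[:config.read_length]
            reads.append((title, seq, "I" * len(seq)))
            continue
        is_contam = (rng.random() < config.contaminant_fraction
                     or not hp_ids)
        if is_contam:
            cls = classes[rng.choice(len(classes), p=class_p)]
            entries = truth.contaminant_catalogs[cls]
            entry = entries[rng.integers(len(entries))]
            if cls == "piRNA":
                insert = entry
            else:
                ln = int(rng.integers(18, 31))
                ln = min(ln, len(entry))
                pos = int(rng.integers(0, len(entry) - ln + 1))
                insert = entry[pos:pos + ln]
        else:
            hp = hp_by_id[hp_ids[rng.choice(len(hp_ids), p=w)]]
            if truth.hairpins and rng.random() < config.star_fraction:
                lo, hi = hp.star_start, hp.star_end
            else:
                lo, hi = hp.mature_start, hp.mature_end
            o5, o3 = offsets[rng.choice(len(offsets), p=off_p)]
            a = max(0, lo + o5)
            b = min(len(genome), hi - o3)
            insert = genome[a:b]
            if rng.random() < config.nta_rate:
                n_add = 1 if rng.random() < 0.8 else 2
                for k in range(n_add):
                    nxt = genome[b + k] if b + k < len(genome) else "A"
                    choices = [c for c in "AT" if c != nxt] or ["A"]
                    insert += choices[rng.integers(len(choices))]
        insert = _apply_errors(insert, config.substitution_error_rate, rng)
        seq = (insert + config.adapter_3p)[:config.read_length]
        reads.append((title, seq, "I" * len(seq)))
    return reads


def write_genome_fasta(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{truth.genome_id}\n")
        seq = truth.genome_seq
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_truth_tsv(truth: SimTruth, path) -> None:
    rows = [asdict(hp) for hp in truth.hairpins]
    cols = ["hairpin_id", "contig", "start", "end", "strand",
            "mature_start", "mature_end", "star_start", "star_end",
            "mature_seq"]
    pd.DataFrame(rows, columns=cols + ["precursor_seq"])[cols].to_csv(
        path, sep="\t", index=False)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_catalog_fasta(catalog, path) -> None:
    """miRBase-style headers: >{species}-{name} {accession}."""
    with open(path, "w") as fh:
        for k, (entry_id, _sp, _name, seq) in enumerate(catalog):
            fh.write(f">{entry_id} MIMATSIM{k:05d}\n{seq}\n")


def make_precursor_candidates(n: int = 50, seed: int = 0) -> list:
    """Synthetic precursor candidates spanning strong and weak folds.

    Half are designed stem-loops (random or GC-biased arms folded back
    with a short loop), half are AU-rich near-hairpins and unstructured
    sequences that should fail the stability filter.  Returns
    (sequence, mature_interval, kind) with kind in {'strong', 'weak'}.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if i % 2 == 0:
            arm_len = int(rng.integers(20, 28))
            p = [0.2, 0.3, 0.3, 0.2] if i % 4 == 0 else None
            arm = "".join(rng.choice(list(BASES), size=arm_len, p=p))
            loop = _random_seq(rng, int(rng.integers(8, 13)))
            seq = arm + loop + revcomp(arm)
            out.append((seq, (0, arm_len), "strong"))
        else:
            L = int(rng.integers(55, 90))
            seq = "".join(rng.choice(list("AT"), size=L,
                                     p=[0.5, 0.5])) if i % 4 == 1 else \
                _random_seq(rng, L)
            out.append((seq, (0, 22), "weak"))
    return out


def make_array_dataset(n_probes: int = 500, n_true: int = 25,
                       effect: float = 2.0, sigma: float = 0.5,
                       n_per_group: int = 3, n_neg: int = 20,
                       seed: int = 0):
    """Two-group microarray matrix with planted log2 effects.

    Probe baselines are drawn on the log2 scale, the first ``n_true``
    miRNA probes get a +``effect`` log2 shift in group A, and signals
    are exponentiated back with additive normal background matching the
    negative-control distribution.  Returns (signal DataFrame,
    probe_class Series, groups Series, true_probe_ids).
    """
    rng = np.random.default_rng(seed)
    arrays = [f"A{i + 1}" for i in range(n_per_group)] + \
             [f"B{i + 1}" for i in range(n_per_group)]
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=arrays)
    probes = [f"probe{i + 1}" for i in range(n_probes)] + \
             [f"neg{i + 1}" for i in range(n_neg)]
    probe_class = pd.Series(
        ["miRNA"] * n_probes + ["negative_control"] * n_neg, index=probes)
    base = rng.uniform(8.0, 12.0, size=n_probes)
    log2sig = np.empty((n_probes, len(arrays)))
    for j, arr in enumerate(arrays):
        mu = base + (effect if groups[arr] == "A" else 0.0) * \
            (np.arange(n_probes) < n_true)
        log2sig[:, j] = rng.normal(mu, sigma)
    bg = rng.normal(100.0, 10.0, size=(n_probes + n_neg, len(arrays)))
    signal = np.vstack([2.0 ** log2sig, np.zeros((n_neg, len(arrays)))]) + bg
    signal = np.clip(signal, 1.0, None)
    df = pd.DataFrame(signal, index=probes, columns=arrays)
    true_ids = [f"probe{i + 1}" for i in range(n_true)]
    return df, probe_class, groups, true_ids
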