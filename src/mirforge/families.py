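"""Seed-based miRNA family partitioning.

The seed is mature positions 2-8 (1-based, inclusive): the 7-nt region
that dominates target recognition and defines family membership.  An
``end=9`` option gives 8-mer (positions 2-9) semantics.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass


@dataclass
class SeedFamily:
    seed: str
    members: list


def extract_seed(mature_seq: str, end: int = 8) -> str:
    """Seed substring at 1-based positions 2..end (default 2-8, 7 nt)."""
    if len(mature_seq) < end:
        raise ValueError(
            f"mature sequence shorter than {end} nt: {mature_seq!r}")
    return mature_seq[1:end]


def group_families(catalog, end: int = 8) -> list[SeedFamily]:
    """Partition matures into families of identical seed.

    ``catalog`` is an iterable of (name, mature_seq) pairs or objects
    with .name/.mature_seq.  Output order and member order are sorted,
    so grouping is invariant to input order.
    """
    groups = defaultdict(list)
    for item in catalog:
        if hasattr(item, "mature_seq"):
            name, seq = item.name, item.mature_seq
        else:
            name, seq = item
        groups[extract_seed(seq, end)].append(name)
    return [SeedFamily(seed, sorted(members))
            for seed, members in sorted(groups.items())]
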