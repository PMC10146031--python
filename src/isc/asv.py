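"""Dereplication, abundance-skew denoising, and ASV table construction.

The denoiser implements the published UNOISE abundance-skew rule: a unique
sequence of size ``s`` at edit distance ``d`` from an established centroid
of size ``c`` is treated as a sequencing/PCR error of that centroid iff
``s / c <= beta(d) = 1 / 2**(alpha * d + 1)``.  Reads are typically pooled
across the samples of a dataset before denoising and then mapped back per
sample, which is what :func:`build_table` does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd

from isc.formats import SeqRecord

#: join candidates farther than this are never absorbed (beta(10) < 1e-6)
MAX_JOIN_DISTANCE = 10


@dataclass
class UniqueSeq:
    sequence: str
    size: int
    exemplar_id: str


@dataclass
class Asv:
    sequence: str
    size: int
    exemplar_id: str
    members: list[str] = field(default_factory=list)


@dataclass
class AbundanceTable:
    """ASV x sample integer count matrix with optional per-sample labels
    (e.g. 'pre'/'post' correction, or the dataset group)."""

    counts: pd.DataFrame
    labels: dict[str, str] = field(default_factory=dict)


def beta(d: int, alpha: float = 2.0) -> float:
    """UNOISE skew threshold for edit distance ``d``."""
    return 1.0 / 2 ** (alpha * d + 1)


def dereplicate(records: list[SeqRecord]) -> list[UniqueSeq]:
    """Collapse identical sequences, keeping the first read id seen as the
    exemplar.  Sorted by size descending, ties broken lexicographically by
    sequence."""
    sizes: dict[str, int] = {}
    exemplar: dict[str, str] = {}
    for rec in records:
        if rec.sequence not in sizes:
            sizes[rec.sequence] = 0
            exemplar[rec.sequence] = rec.id
        sizes[rec.sequence] += 1
    uniques = [UniqueSeq(s, n, exemplar[s]) for s, n in sizes.items()]
    uniques.sort(key=lambda u: (-u.size, u.sequence))
    return uniques


def denoise(uniques: list[UniqueSeq], alpha: float = 2.0,
            minsize: int = 8) -> list[Asv]:
    """Greedy abundance-skew denoising pass.

    Uniques are visited in descending abundance.  Each one joins the
    nearest eligible centroid (skew test against the centroid's current
    accumulated size; ties on distance go to the larger centroid) or, if
    none is eligible and its size reaches ``minsize``, founds a new
    centroid; otherwise it contributes to no centroid.
    """
    centroids: list[Asv] = []
    for u in uniques:
        best = None  # (distance, -size, index)
        for idx, c in enumerate(centroids):
            res = edlib.align(u.sequence, c.sequence, task="distance",
                              k=MAX_JOIN_DISTANCE)
            d = res["editDistance"]
            if d <= 0:
                continue
            if u.size / c.size <= beta(d, alpha):
                key = (d, -c.size, idx)
                if best is None or key < best:
                    best = key
        if best is not None:
            c = centroids[best[2]]
            c.size += u.size
            c.members.append(u.exemplar_id)
        elif u.size >= minsize:
            centroids.append(
                Asv(u.sequence, u.size, u.exemplar_id, [u.exemplar_id])
            )
    return centroids


def map_reads(records: list[SeqRecord], asvs: list[Asv],
              min_identity: float = 0.97) -> pd.Series:
    """Count reads per ASV for one sample.

    Each read is assigned to the highest-identity ASV provided the identity
    (1 - edits / longer length) reaches ``min_identity``; ties go to the
    first ASV in abundance order.  Unassignable reads are not counted.
    """
    if not asvs:
        raise ValueError("no ASVs to map against")
    counts = [0] * len(asvs)
    exact = {}
    for idx, asv in enumerate(asvs):
        exact.setdefault(asv.sequence, idx)
    for rec in records:
        hit = exact.get(rec.sequence)
        if hit is not None:
            counts[hit] += 1
            continue
        best_idx = -1
        best_ident = 0.0
        for idx, asv in enumerate(asvs):
            longer = max(len(rec.sequence), len(asv.sequence))
            k = int((1.0 - min_identity) * longer) + 1
            res = edlib.align(rec.sequence, asv.sequence, task="distance",
                              k=k)
            d = res["editDistance"]
            if d < 0:
                continue
            ident = 1.0 - d / longer
            if ident >= min_identity and ident > best_ident:
                best_ident = ident
                best_idx = idx
        if best_idx >= 0:
            counts[best_idx] += 1
    return pd.Series(counts, index=[f"ASV_{i+1}" for i in range(len(asvs))])


def build_table(samples: dict[str, list[SeqRecord]], alpha: float = 2.0,
                minsize: int = 8, min_identity: float = 0.97,
                labels: dict[str, str] | None = None) -> AbundanceTable:
    """Pool all samples, denoise once, then map each sample back.

    Returns an :class:`AbundanceTable` whose rows are ``ASV_i`` ids in
    abundance order of the pooled denoising pass.
    """
    pooled: list[SeqRecord] = []
    for reads in samples.values():
        pooled.extend(reads)
    asvs = denoise(dereplicate(pooled), alpha=alpha, minsize=minsize)
    if not asvs:
        raise ValueError("denoising produced no ASVs (inputs too sparse?)")
    cols = {
        sid: map_reads(reads, asvs, min_identity=min_identity)
        for sid, reads in samples.items()
    }
    df = pd.DataFrame(cols).astype(int)
    return AbundanceTable(df, dict(labels or {}))
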