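"""Primer catalog model: amplicon windows, Same/Near/Short/Long categories,
and per-sample read depth filtering/resampling.

An amplicon window is the 1-based inclusive coordinate interval on the
reference gene delimited by a primer pair's start and end positions.  The
catalog of eleven published 18S v4 primer pairs ships with the package
(``isc/data/primer_catalog.tsv``); the most widely used window (group
``Same2``, 564-980) serves as the baseline against which every other window
is categorized.
"""

from __future__ import annotations

import importlib.resources
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from isc.formats import SeqRecord

IUPAC = set("ACGTRYSWKMBDHVN")

#: Baseline window: the most-used primer pair (group Same2).
BASELINE_START = 564
BASELINE_END = 980

CATEGORIES = ("Same", "Near", "Short", "Long")


@dataclass(frozen=True)
class PrimerSet:
    """One catalog row: a primer pair and the window it amplifies."""

    group_id: str
    forward: str
    start: int
    reverse: str
    end: int
    sample_size: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end and not (self.start == self.end):
            raise ValueError(
                f"{self.group_id}: start {self.start} > end {self.end}"
            )
        for primer in (self.forward, self.reverse):
            if not primer or set(primer) - IUPAC:
                raise ValueError(
                    f"{self.group_id}: primer {primer!r} is not an IUPAC "
                    "nucleotide string"
                )
        if self.sample_size < 0:
            raise ValueError(f"{self.group_id}: negative sample size")


def amplicon_length(p: PrimerSet) -> int:
    """Window length in bp (1-based inclusive: end - start + 1)."""
    return p.end - p.start + 1


def baseline_primer_set() -> PrimerSet:
    return PrimerSet("Same2", "CCAGCASCYGCGGTAAT", BASELINE_START,
                     "ACTTTCGTTCTTGATYRA", BASELINE_END, 23)


def classify(p: PrimerSet, baseline: PrimerSet | None = None,
             threshold_bp: int = 50) -> str:
    """Categorize a primer window against the baseline window.

    ``Same`` means the identical window.  Otherwise the amplicon-length
    difference decides: within ``threshold_bp`` is ``Near``, more than
    ``threshold_bp`` shorter is ``Short``, more than ``threshold_bp`` longer
    is ``Long``.  The boundary case (exactly ``threshold_bp``) goes to
    ``Near`` so the four labels partition all windows.
    """
    if baseline is None:
        baseline = baseline_primer_set()
    if p.start == baseline.start and p.end == baseline.end:
        return "Same"
    delta = amplicon_length(p) - amplicon_length(baseline)
    if abs(delta) <= threshold_bp:
        return "Near"
    return "Short" if delta < 0 else "Long"


def load_catalog(path=None) -> list[PrimerSet]:
    """Load a primer catalog TSV; defaults to the packaged eleven-row
    catalog of published 18S v4 metabarcoding primer pairs."""
    if path is None:
        path = importlib.resources.files("isc.data") / "primer_catalog.tsv"
    df = pd.read_csv(path, sep="\t")
    return [
        PrimerSet(str(r.group_id), str(r.forward), int(r.start),
                  str(r.reverse), int(r.end), int(r.sample_size))
        for r in df.itertuples(index=False)
    ]


def summarize_catalog(catalog: list[PrimerSet],
                      baseline: PrimerSet | None = None,
                      threshold_bp: int = 50) -> dict[str, tuple[int, int]]:
    """Per-category (n_datasets, n_samples) summary of a catalog."""
    out = {c: [0, 0] for c in CATEGORIES}
    for p in catalog:
        cat = classify(p, baseline, threshold_bp)
        out[cat][0] += 1
        out[cat][1] += p.sample_size
    return {c: (n, s) for c, (n, s) in out.items()}


def filter_and_resample(
    samples: dict[str, list[SeqRecord]],
    min_reads: int = 5000,
    cap: int = 10000,
    seed: int = 0,
) -> dict[str, list[SeqRecord]]:
    """Harmonize per-sample sequencing depth.

    Samples with fewer than ``min_reads`` reads are removed; samples with
    more than ``cap`` reads are downsampled uniformly without replacement to
    exactly ``cap`` (preserving input order); samples in between pass
    through unchanged.  Deterministic given ``seed``; each kept sample draws
    from an independent substream keyed by its id so the result does not
    depend on dict ordering.
    """
    out: dict[str, list[SeqRecord]] = {}
    for sid in samples:
        reads = samples[sid]
        if len(reads) < min_reads:
            continue
        if len(reads) > cap:
            rng = np.random.default_rng(
                [seed, zlib.crc32(sid.encode()) % (2**31)]
            )
            keep = rng.choice(len(reads), size=cap, replace=False)
            keep.sort()
            out[sid] = [reads[i] for i in keep]
        else:
            out[sid] = list(reads)
    return out
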