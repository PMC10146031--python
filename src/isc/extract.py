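"""The information scale correction step: excise the located sub-region
from each read, in model orientation, and summarize what the correction did
to read counts and lengths per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from isc.formats import HitTable, SeqRecord
from isc.phmm import ProfileHMM, RegionHit, reverse_complement, search


@dataclass
class IscReport:
    """Per-sample correction statistics: read counts and length summaries
    before/after, and detection sensitivity."""

    frame: pd.DataFrame

    COLUMNS = (
        "sample_id", "reads_before", "reads_after", "sensitivity",
        "len_min_before", "len_median_before", "len_max_before",
        "len_min_after", "len_median_after", "len_max_after",
    )


def excise(record: SeqRecord, hit) -> SeqRecord:
    """Cut the hit window out of the read, returned in model orientation.

    ``hit`` may be a :class:`RegionHit` or a hit-table row.  Coordinates
    are 1-based inclusive on the forward read strand; minus-strand hits are
    reverse-complemented so every output is oriented like the model.
    """
    if not isinstance(hit, RegionHit):
        hit = RegionHit(*hit)
    if hit.read_id != record.id:
        raise ValueError(
            f"hit for {hit.read_id!r} applied to record {record.id!r}"
        )
    if not (1 <= hit.read_start <= hit.read_end <= len(record)):
        raise ValueError(
            f"hit window {hit.read_start}..{hit.read_end} outside read "
            f"{record.id!r} of length {len(record)}"
        )
    window = record.sequence[hit.read_start - 1 : hit.read_end]
    if hit.strand == "-":
        window = reverse_complement(window)
    qual = None
    if record.quality is not None:
        qual = record.quality[hit.read_start - 1 : hit.read_end]
        if hit.strand == "-":
            qual = qual[::-1]
    return SeqRecord(record.id, window, qual)


def run_isc(
    samples: dict[str, list[SeqRecord]],
    model: ProfileHMM,
    min_bits: float = 20.0,
    min_coverage: float = 0.5,
) -> tuple[dict[str, list[SeqRecord]], IscReport]:
    """Apply the correction to every sample.

    Reads without a hit, or whose hit covers less than ``min_coverage`` of
    the model's match states, are dropped; surviving reads are replaced by
    their excised sub-region.  Returns the corrected samples and a
    per-sample report.
    """
    corrected: dict[str, list[SeqRecord]] = {}
    rows = []
    for sid, reads in samples.items():
        hits = search(model, reads, min_bits=min_bits)
        by_id = {row[0]: row for row in hits.rows}
        out = []
        for rec in reads:
            row = by_id.get(rec.id)
            if row is None:
                continue
            coverage = (row[4] - row[3] + 1) / model.K
            if coverage < min_coverage:
                continue
            out.append(excise(rec, row))
        corrected[sid] = out
        rows.append(_report_row(sid, reads, out, len(by_id)))
    report = IscReport(pd.DataFrame(rows, columns=list(IscReport.COLUMNS)))
    return corrected, report


def _report_row(sid, before, after, n_hits):
    lb = np.array([len(r) for r in before]) if before else np.array([0])
    la = np.array([len(r) for r in after]) if after else np.array([0])
    return (
        sid, len(before), len(after),
        n_hits / len(before) if before else 0.0,
        int(lb.min()), float(np.median(lb)), int(lb.max()),
        int(la.min()), float(np.median(la)), int(la.max()),
    )
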