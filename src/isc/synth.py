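"""Synthetic amplicon data with known truth.

The generator emulates the structure the correction method assumes: a
family of related full-length templates (a variable target sub-region with
more conserved flanks, like the 18S v4 region inside its gene), shared
per-sample communities, and per-dataset primer windows that slice different
amounts of sequence around that sub-region, plus per-base sequencing error.
Because every mutation and indel event is recorded, the true sub-region
alignment and per-read sub-region coordinates are known exactly.

Two family layouts are available.  The default mutates every taxon
independently from a common ancestor.  With ``n_lineages`` set, taxa come
in lineages whose members share an *identical* sub-region but differ in
their flanks — the situation where extra flanking sequence in a long
amplicon resolves taxa that the sub-region alone cannot, which is exactly
the information-scale effect the correction is meant to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from isc.formats import Msa, SeqRecord
from isc.phmm import reverse_complement

BASES = np.array(list("ACGT"))

#: Category windows as (start, end) offsets applied to the true sub-region
#: interval.  Length deltas mirror published primer catalogs: Near within
#: 50 bp of the baseline, Short about 73 bp shorter, Long about 161 bp
#: longer.
CATEGORY_WINDOWS = {
    "Same": (0, 0),
    "Near": (0, -22),
    "Short": (7, -66),
    "Long": (-80, 81),
}


@dataclass
class FamilyTruth:
    """Ground truth for a template family."""

    region_start: dict[str, int]    # 1-based inclusive, per taxon
    region_end: dict[str, int]
    lineage: dict[str, int]


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    abundances: dict[str, float]            # taxon -> sampling probability
    read_taxon: dict[str, str]              # read id -> source taxon
    read_region: dict[str, tuple[int, int]]  # region window, fwd read coords
    read_strand: dict[str, str]


@dataclass
class CategoryBundle:
    """Four dataset groups observing the same communities through
    different windows."""

    samples: dict[str, dict[str, list[SeqRecord]]]  # group -> sample -> reads
    truths: dict[str, dict[str, SampleTruth]]
    msa: Msa
    templates: list[SeqRecord]
    family: FamilyTruth
    windows: dict[str, tuple[int, int]]
    region_len: int


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), *key])


def _mutate_sites(seq: np.ndarray, rate: float, mask, rng) -> np.ndarray:
    """Substitute masked positions with probability ``rate``, always to a
    different base."""
    out = seq.copy()
    hit = np.flatnonzero((rng.random(seq.size) < rate) & mask)
    for i in hit:
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _evolve_region(region: np.ndarray, divergence: float, indel_rate: float,
                   rng):
    """One taxon's sub-region as aligned events against the ancestor.

    Returns (kept, inserts): ``kept[j]`` is the character at ancestral
    column j or '-' if deleted; ``inserts[j]`` is sequence inserted after
    column j.
    """
    n = region.size
    kept = _mutate_sites(region, divergence, np.ones(n, bool), rng)
    kept = kept.astype(object)
    inserts: dict[int, str] = {}
    j = 0
    while j < n:
        if rng.random() < indel_rate:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                for d in range(j, min(j + length, n)):
                    kept[d] = "-"
                j += length
                continue
            inserts[j] = "".join(rng.choice(BASES, size=length))
        j += 1
    return kept, inserts


def make_family(n_taxa: int, region_len: int = 380, flank_len: int = 200,
                divergence: float = 0.10, indel_rate: float = 0.01,
                seed: int = 0, n_lineages: int | None = None,
                flank_margin: int = 0):
    """Generate a template family and the true sub-region alignment.

    Each taxon's template is left flank + sub-region + right flank.  The
    sub-region diverges at ``divergence`` per site with indels at
    ``indel_rate``; flanks diverge at ``divergence / 5`` with no indels, so
    the sub-region coordinates inside every template are exact.
    ``flank_margin`` keeps that many flank positions next to the sub-region
    invariant in all taxa.  With ``n_lineages``, lineage members share the
    ancestor's evolved sub-region exactly and differ only in their flanks.

    Returns ``(msa, templates, truth)`` where ``msa`` is the true
    sub-region alignment suitable for model training.
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    rng = _rng(seed, 0)
    region = rng.choice(BASES, size=region_len)
    left = rng.choice(BASES, size=flank_len)
    right = rng.choice(BASES, size=flank_len)
    flank_div = divergence / 5.0
    left_mask = np.arange(flank_len) < flank_len - flank_margin
    right_mask = np.arange(flank_len) >= flank_margin

    n_lin = n_lineages if n_lineages is not None else n_taxa
    lineages = []
    for li in range(n_lin):
        lrng = _rng(seed, 1, li)
        kept, inserts = _evolve_region(region, divergence, indel_rate, lrng)
        lineages.append((
            kept, inserts,
            _mutate_sites(left, flank_div, left_mask, lrng),
            _mutate_sites(right, flank_div, right_mask, lrng),
        ))

    names = [f"taxon{t+1:03d}" for t in range(n_taxa)]
    rows_kept, rows_ins = [], []
    templates = []
    truth = FamilyTruth({}, {}, {})
    for t, name in enumerate(names):
        li = t % n_lin
        kept, inserts, lleft, lright = lineages[li]
        if n_lineages is None:
            tleft, tright = lleft, lright
        else:
            trng = _rng(seed, 2, t)
            tleft = _mutate_sites(lleft, flank_div, left_mask, trng)
            tright = _mutate_sites(lright, flank_div, right_mask, trng)
        region_seq = "".join(
            inserts.get(-1, "")
            + "".join(
                ("" if kept[j] == "-" else kept[j]) + inserts.get(j, "")
                for j in range(region_len)
            )
        )
        template = "".join(tleft) + region_seq + "".join(tright)
        templates.append(SeqRecord(name, template))
        truth.region_start[name] = flank_len + 1
        truth.region_end[name] = flank_len + len(region_seq)
        truth.lineage[name] = li
        rows_kept.append(kept)
        rows_ins.append(inserts)

    msa = _assemble_msa(names, rows_kept, rows_ins, region_len)
    return msa, templates, truth


def _assemble_msa(names, rows_kept, rows_ins, region_len) -> Msa:
    widths = [max((len(ins.get(j, "")) for ins in rows_ins), default=0)
              for j in range(region_len)]
    rows = []
    for name, kept, inserts in zip(names, rows_kept, rows_ins):
        parts = []
        for j in range(region_len):
            parts.append(kept[j])
            ins = inserts.get(j, "")
            parts.append(ins + "-" * (widths[j] - len(ins)))
        rows.append((name, "".join(parts)))
    return Msa(rows)


def simulate_sample(
    templates: list[SeqRecord],
    truth: FamilyTruth,
    window: tuple[int, int],
    depth: int = 10000,
    error_rate: float = 0.005,
    lognormal_sigma: float = 1.5,
    seed: int = 0,
    sample_id: str = "s1",
    abundances: np.ndarray | None = None,
    strand_fraction: float = 0.5,
) -> tuple[list[SeqRecord], SampleTruth]:
    """Draw one sample's reads through a primer window.

    ``window`` is a (start, end) offset pair applied to each taxon's true
    sub-region interval.  Taxon abundances are log-normal (drawn once for
    the sample, or supplied via ``abundances`` to share a community across
    datasets), read counts are multinomial at ``depth``, errors are
    per-base substitutions, and ``strand_fraction`` of the reads are
    reverse-complemented.
    """
    rng = _rng(seed, 3)
    ds, de = window
    names = [t.id for t in templates]
    if abundances is None:
        weights = rng.lognormal(0.0, lognormal_sigma, size=len(names))
    else:
        weights = np.asarray(abundances, float)
        if weights.size != len(names):
            raise ValueError("abundance vector length != number of taxa")
    probs = weights / weights.sum()
    counts = rng.multinomial(depth, probs)

    windows = {}
    for t in templates:
        ws = truth.region_start[t.id] + ds
        we = truth.region_end[t.id] + de
        if ws < 1 or we > len(t.sequence) or ws > we:
            raise ValueError(
                f"window {window} outside template {t.id} "
                f"(length {len(t.sequence)})"
            )
        windows[t.id] = (ws, we)

    reads: list[SeqRecord] = []
    st = SampleTruth(dict(zip(names, probs)), {}, {}, {})
    idx = 0
    for t, n_reads in zip(templates, counts):
        ws, we = windows[t.id]
        base = t.sequence[ws - 1 : we]
        L = len(base)
        rs, re = truth.region_start[t.id], truth.region_end[t.id]
        o1, o2 = max(ws, rs) - ws + 1, min(we, re) - ws + 1
        for _ in range(n_reads):
            idx += 1
            rid = f"{sample_id}_r{idx}"
            arr = np.array(list(base))
            arr = _mutate_sites(arr, error_rate, np.ones(L, bool), rng)
            seq = "".join(arr)
            if rng.random() < strand_fraction:
                seq = reverse_complement(seq)
                strand = "-"
                region_coords = (L - o2 + 1, L - o1 + 1)
            else:
                strand = "+"
                region_coords = (o1, o2)
            reads.append(SeqRecord(rid, seq))
            st.read_taxon[rid] = t.id
            st.read_region[rid] = region_coords
            st.read_strand[rid] = strand
    return reads, st


def make_category_bundle(
    n_samples_per_group: int = 20,
    seed: int = 0,
    depth: int = 10000,
    n_taxa: int = 48,
    n_lineages: int = 16,
    region_len: int = 380,
    flank_len: int = 200,
    divergence: float = 0.10,
    indel_rate: float = 0.01,
    error_rate: float = 0.005,
    lognormal_sigma: float = 1.5,
    windows: dict[str, tuple[int, int]] | None = None,
) -> CategoryBundle:
    """The four-category benchmark: Same / Near / Short / Long datasets
    observing the same communities.

    Sample ``i`` of every group draws its reads from the same community
    realization (one log-normal abundance vector per ``i``), so before
    correction the groups' tables differ only through their windows.  A
    24 bp flank margin next to the sub-region stays invariant so that
    near-baseline windows add no taxonomic information.
    """
    windows = dict(windows or CATEGORY_WINDOWS)
    msa, templates, family = make_family(
        n_taxa, region_len=region_len, flank_len=flank_len,
        divergence=divergence, indel_rate=indel_rate, seed=seed,
        n_lineages=n_lineages, flank_margin=24,
    )
    shared = [
        _rng(seed, 4, i).lognormal(0.0, lognormal_sigma, size=n_taxa)
        for i in range(n_samples_per_group)
    ]
    samples: dict[str, dict[str, list[SeqRecord]]] = {}
    truths: dict[str, dict[str, SampleTruth]] = {}
    for gi, (group, window) in enumerate(windows.items()):
        samples[group] = {}
        truths[group] = {}
        for i in range(n_samples_per_group):
            sid = f"{group}_{i+1:02d}"
            reads, st = simulate_sample(
                templates, family, window, depth=depth,
                error_rate=error_rate, seed=(seed * 1000 + gi * 101 + i) % (2**31),
                sample_id=sid, abundances=shared[i],
            )
            samples[group][sid] = reads
            truths[group][sid] = st
    return CategoryBundle(samples, truths, msa, templates, family, windows,
                          region_len)
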