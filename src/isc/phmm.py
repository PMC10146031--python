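"""Nucleotide profile HMM: model construction from an alignment of the
target sub-region, and glocal Viterbi search to locate that sub-region in
reads.

The architecture is the classic match/insert/delete profile over {A,C,G,T}.
Alignment columns whose non-gap occupancy reaches ``match_fraction`` become
match states; emissions and transitions are maximum-likelihood estimates
with an additive (Laplace) pseudocount.  Search is *glocal*: global with
respect to the model but local with respect to the read, i.e. any amount of
flanking read sequence on either side of the aligned region is free
(unscored), and the alignment may enter and leave the model at internal
match states, paying a small skip penalty, so that reads covering only part
of the modelled region still align.  Scores are log2-odds (bits) against a
uniform background; ambiguous bases score zero bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from isc.formats import HitTable, Msa, SeqRecord

ALPHABET = "ACGT"
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: Probability mass diverted from the flush begin->M1 (and MK->end)
#: transition to internal entry (exit) points, shared evenly.
SKIP_MASS = 0.01


class ModelBuildError(ValueError):
    """No usable match columns in the training alignment."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ProfileHMM:
    """Profile HMM parameters (probabilities, not scores).

    ``transitions`` holds one (3,) row per source state.  For node ``k < K``
    the destinations are (M_{k+1}, I_k, D_{k+1}); for the last node the
    first slot is the transition to the end state and the third slot is
    zero.  ``begin`` is the distribution over (M_1, I_0, D_1); glocal
    search replaces begin/end with the internal entry/exit distribution
    derived from ``SKIP_MASS``.
    """

    K: int
    match_emission: np.ndarray      # (K, 4)
    insert_emission: np.ndarray     # (K+1, 4), rows I_0..I_K
    tr_m: np.ndarray                # (K, 3)
    tr_i: np.ndarray                # (K+1, 3)
    tr_d: np.ndarray                # (K, 3)
    begin: np.ndarray               # (3,)
    background: np.ndarray          # (4,)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ModelBuildError("model needs at least one match state")
        for name in ("match_emission", "insert_emission", "tr_m", "tr_i",
                     "tr_d"):
            arr = getattr(self, name)
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if not np.isclose(self.begin.sum(), 1.0, atol=1e-9):
            raise ValueError("begin distribution must sum to 1")

    # -- derived score tables -------------------------------------------

    def entry_bits(self) -> np.ndarray:
        """log2 entry probability per match state (glocal internal entry)."""
        q = np.empty(self.K)
        if self.K == 1:
            q[0] = 1.0
        else:
            q[:] = SKIP_MASS / (self.K - 1)
            q[0] = 1.0 - SKIP_MASS
        return np.log2(q)

    def exit_bits(self) -> np.ndarray:
        q = np.empty(self.K)
        if self.K == 1:
            q[0] = 1.0
        else:
            q[:] = SKIP_MASS / (self.K - 1)
            q[-1] = 1.0 - SKIP_MASS
        return np.log2(q)

    def emission_bits(self) -> tuple[np.ndarray, np.ndarray]:
        """Match and insert log2-odds tables with a fifth, zero-bit column
        for ambiguous symbols."""
        m = np.zeros((self.K, 5))
        m[:, :4] = np.log2(self.match_emission / self.background)
        i = np.zeros((self.K + 1, 5))
        i[:, :4] = np.log2(self.insert_emission / self.background)
        return m, i

    def transition_bits(self) -> tuple[np.ndarray, ...]:
        """Interior transition scores, arrays of length K-1 indexed by the
        source node."""
        n = max(self.K - 1, 1)
        with np.errstate(divide="ignore"):
            tm = np.log2(np.maximum(self.tr_m[:n], 1e-300))
            ti = np.log2(np.maximum(self.tr_i[1 : n + 1], 1e-300))
            td = np.log2(np.maximum(self.tr_d[:n], 1e-300))
        if self.K == 1:
            z = np.full(1, -np.inf)
            return (z,) * 9
        return (tm[:, 0], tm[:, 1], tm[:, 2],
                ti[:, 0], ti[:, 1], ti[:, 2],
                td[:, 0], td[:, 1], td[:, 2])


@dataclass
class RegionHit:
    """A located sub-region: 1-based inclusive coordinates on the forward
    strand of the read, and the match-state interval covered."""

    read_id: str
    read_start: int
    read_end: int
    model_start: int
    model_end: int
    strand: str
    bit_score: float

    def as_row(self) -> tuple:
        return (self.read_id, self.read_start, self.read_end,
                self.model_start, self.model_end, self.strand,
                round(self.bit_score, 3))


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_profile(msa: Msa, match_fraction: float = 0.5,
                  pseudocount: float = 1.0) -> ProfileHMM:
    """Estimate a profile HMM from an alignment of the target sub-region.

    Columns whose non-gap fraction is at least ``match_fraction`` become
    match states.  Emission probabilities are (count + pseudocount) /
    (total + 4 * pseudocount); transition probabilities are estimated from
    each row's implied match/insert/delete path with the same additive
    pseudocount.  The background is uniform.
    """
    n_rows = len(msa.rows)
    cols = np.array(
        [encode(row) for _, row in msa.rows], dtype=np.int8
    )  # gaps encode as 4
    gap = np.array([[c == "-" for c in row] for _, row in msa.rows])
    occupancy = 1.0 - gap.mean(axis=0)
    is_match = occupancy >= match_fraction
    K = int(is_match.sum())
    if K == 0:
        raise ModelBuildError(
            f"no column reaches match occupancy {match_fraction}"
        )

    match_counts = np.zeros((K, 4))
    insert_counts = np.zeros((K + 1, 4))
    # transition counts; destination order (M_next, I_here, D_next)
    cm = np.zeros((K, 3))
    ci = np.zeros((K + 1, 3))
    cd = np.zeros((K, 3))
    cb = np.zeros(3)

    n_match_upto = np.cumsum(is_match)  # match states seen through column c
    match_index = n_match_upto - 1      # column -> match state (0-based)

    for r in range(n_rows):
        prev = ("B", 0)  # state type, node (match states 1..K)
        for c in range(msa.n_columns):
            if is_match[c]:
                node = match_index[c] + 1
                if gap[r, c]:
                    cur = ("D", node)
                else:
                    cur = ("M", node)
                    sym = cols[r, c]
                    if sym < 4:
                        match_counts[node - 1, sym] += 1
            else:
                if gap[r, c]:
                    continue
                # insert belongs to the last match node passed
                node = int(n_match_upto[c])
                cur = ("I", node)
                sym = cols[r, c]
                if sym < 4:
                    insert_counts[node, sym] += 1
            _count_transition(prev, cur, cb, cm, ci, cd)
            prev = cur
        _count_transition(prev, ("E", K + 1), cb, cm, ci, cd)

    def _laplace(counts: np.ndarray) -> np.ndarray:
        return (counts + pseudocount) / (
            counts.sum(axis=-1, keepdims=True) + counts.shape[-1] * pseudocount
        )

    return ProfileHMM(
        K=K,
        match_emission=_laplace(match_counts),
        insert_emission=_laplace(insert_counts),
        tr_m=_laplace(cm),
        tr_i=_laplace(ci),
        tr_d=_laplace(cd),
        begin=_laplace(cb),
        background=np.full(4, 0.25),
    )


def _count_transition(prev, cur, cb, cm, ci, cd) -> None:
    ptype, pnode = prev
    ctype, cnode = cur
    # destination slot: 0 = next match/end, 1 = insert at same node, 2 = delete
    slot = {"M": 0, "E": 0, "I": 1, "D": 2}[ctype]
    if ptype == "B":
        cb[slot] += 1
    elif ptype == "M":
        cm[pnode - 1, slot] += 1
    elif ptype == "I":
        ci[pnode, slot] += 1
    elif ptype == "D":
        cd[pnode - 1, slot] += 1


# ---------------------------------------------------------------------------
# glocal Viterbi
# ---------------------------------------------------------------------------

@njit(cache=True)
def _viterbi_kernel(x, em, ins, entry, exit_,
                    tmm, tmi, tmd, tim, tii, tid, tdm, tdi, tdd):
    L = x.shape[0]
    K = em.shape[0]
    NEG = -1e30
    VM = np.full((L, K), NEG)
    VI = np.full((L, K), NEG)   # column K-1 unused
    VD = np.full((L, K), NEG)
    PM = np.zeros((L, K), dtype=np.int8)  # 0 entry, 1 M, 2 I, 3 D
    PI = np.zeros((L, K), dtype=np.int8)
    PD = np.zeros((L, K), dtype=np.int8)

    for i in range(L):
        xi = x[i]
        for j in range(K):
            # match
            best = entry[j]
            ptr = 0
            if i > 0 and j > 0:
                s = VM[i - 1, j - 1] + tmm[j - 1]
                if s > best:
                    best = s
                    ptr = 1
                s = VI[i - 1, j - 1] + tim[j - 1]
                if s > best:
                    best = s
                    ptr = 2
                s = VD[i - 1, j - 1] + tdm[j - 1]
                if s > best:
                    best = s
                    ptr = 3
            VM[i, j] = em[j, xi] + best
            PM[i, j] = ptr
            # insert (I_j exists for j < K-1 in 0-based node terms)
            if j < K - 1 and i > 0:
                best = VM[i - 1, j] + tmi[j]
                ptr = 1
                s = VI[i - 1, j] + tii[j]
                if s > best:
                    best = s
                    ptr = 2
                s = VD[i - 1, j] + tdi[j]
                if s > best:
                    best = s
                    ptr = 3
                VI[i, j] = ins[j + 1, xi] + best
                PI[i, j] = ptr
            # delete
            if j > 0:
                best = VM[i, j - 1] + tmd[j - 1]
                ptr = 1
                s = VI[i, j - 1] + tid[j - 1]
                if s > best:
                    best = s
                    ptr = 2
                s = VD[i, j - 1] + tdd[j - 1]
                if s > best:
                    best = s
                    ptr = 3
                VD[i, j] = best
                PD[i, j] = ptr

    # best exit from a match state
    best = NEG
    bi = 0
    bj = 0
    for i in range(L):
        for j in range(K):
            s = VM[i, j] + exit_[j]
            if s > best:
                best = s
                bi = i
                bj = j

    # traceback
    max_len = L + K + 1
    states = np.empty(max_len, dtype=np.int8)   # 0 M, 1 I, 2 D
    nodes = np.empty(max_len, dtype=np.int32)
    n = 0
    i = bi
    j = bj
    st = 0
    while True:
        states[n] = st
        nodes[n] = j
        n += 1
        if st == 0:
            ptr = PM[i, j]
            if ptr == 0:
                break
            i -= 1
            j -= 1
            st = ptr - 1
        elif st == 1:
            ptr = PI[i, j]
            i -= 1
            st = ptr - 1
        else:
            ptr = PD[i, j]
            j -= 1
            st = ptr - 1
    return best, i, bi, j, bj, states[:n][::-1].copy(), nodes[:n][::-1].copy()


_STATE_NAMES = ("M", "I", "D")


def viterbi_glocal(model: ProfileHMM, seq: str):
    """Best glocal alignment of ``seq`` to the model.

    Returns ``(path, bit_score, (read_start, read_end, model_start,
    model_end))`` with 1-based inclusive read coordinates and match-state
    indices.  ``path`` is a list of (state, node) pairs, state in
    {'M','I','D'}, node in 1..K.  A score is always produced; thresholding
    belongs to :func:`search`.
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    x = encode(seq)
    em, ins = model.emission_bits()
    score, i0, i1, j0, j1, states, nodes = _viterbi_kernel(
        x, em, ins, model.entry_bits(), model.exit_bits(),
        *model.transition_bits(),
    )
    path = [(_STATE_NAMES[s], int(n) + 1) for s, n in zip(states, nodes)]
    return path, float(score), (i0 + 1, i1 + 1, j0 + 1, j1 + 1)


def search(model: ProfileHMM, records: list[SeqRecord],
           min_bits: float = 20.0, both_strands: bool = True) -> HitTable:
    """Locate the modelled sub-region in each read.

    Both orientations are scored (unless ``both_strands`` is false) and the
    better one kept; a hit is emitted iff its bit score reaches
    ``min_bits``.  At most one hit per read.  Hit coordinates are mapped
    back to the forward strand of the read.
    """
    hits = HitTable()
    em, ins = model.emission_bits()
    entry = model.entry_bits()
    exit_ = model.exit_bits()
    trans = model.transition_bits()
    for rec in records:
        L = len(rec.sequence)
        sc_f, co_f = _score(rec.sequence, em, ins, entry, exit_, trans)
        strand = "+"
        score, coords = sc_f, co_f
        if both_strands:
            sc_r, co_r = _score(reverse_complement(rec.sequence), em, ins,
                                entry, exit_, trans)
            if sc_r > sc_f:
                strand = "-"
                score = sc_r
                rs, re, ms, me = co_r
                coords = (L - re + 1, L - rs + 1, ms, me)
        if score >= min_bits:
            rs, re, ms, me = coords
            hits.rows.append(
                RegionHit(rec.id, rs, re, ms, me, strand, score).as_row()
            )
    return hits


def _score(seq, em, ins, entry, exit_, trans):
    x = encode(seq)
    score, i0, i1, j0, j1, _, _ = _viterbi_kernel(
        x, em, ins, entry, exit_, *trans
    )
    return float(score), (i0 + 1, i1 + 1, j0 + 1, j1 + 1)


def shuffled_null_scores(model: ProfileHMM, records: list[SeqRecord],
                         seed: int = 0) -> np.ndarray:
    """Empirical null: best-hit bit scores of per-read shuffled sequences.

    Shuffling preserves each read's base composition but destroys the
    positional signal, giving a reference distribution for choosing
    ``min_bits``.
    """
    rng = np.random.default_rng(seed)
    em, ins = model.emission_bits()
    entry = model.entry_bits()
    exit_ = model.exit_bits()
    trans = model.transition_bits()
    scores = []
    for rec in records:
        shuffled = "".join(rng.permutation(list(rec.sequence)))
        s_f, _ = _score(shuffled, em, ins, entry, exit_, trans)
        s_r, _ = _score(reverse_complement(shuffled), em, ins, entry, exit_,
                        trans)
        scores.append(max(s_f, s_r))
    return np.array(scores)


def sensitivity(hits: HitTable, records: list[SeqRecord]) -> float:
    """Fraction of reads with a reported hit."""
    if not records:
        return 0.0
    return len(hits) / len(records)


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def save_model(model: ProfileHMM, path) -> None:
    """Write the model in a simple line-oriented text format."""
    with open(path, "w") as fh:
        fh.write(f"ihmm 1\nK {model.K}\nalphabet {ALPHABET}\n")
        _write_block(fh, "match_emission", model.match_emission)
        _write_block(fh, "insert_emission", model.insert_emission)
        _write_block(fh, "tr_m", model.tr_m)
        _write_block(fh, "tr_i", model.tr_i)
        _write_block(fh, "tr_d", model.tr_d)
        _write_block(fh, "begin", model.begin.reshape(1, -1))
        _write_block(fh, "background", model.background.reshape(1, -1))


def _write_block(fh, name: str, arr: np.ndarray) -> None:
    fh.write(f"{name} {arr.shape[0]}\n")
    for row in arr:
        fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def load_model(path) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or lines[0].split()[0] != "ihmm":
        raise ValueError(f"{path} is not an ihmm model file")
    pos = 1
    header: dict[str, str] = {}
    blocks: dict[str, np.ndarray] = {}
    while pos < len(lines):
        key, val = lines[pos].split(maxsplit=1)
        if key in ("K", "alphabet"):
            header[key] = val
            pos += 1
            continue
        n = int(val)
        rows = [[float(v) for v in lines[pos + 1 + r].split()]
                for r in range(n)]
        blocks[key] = np.array(rows)
        pos += 1 + n
    return ProfileHMM(
        K=int(header["K"]),
        match_emission=blocks["match_emission"],
        insert_emission=blocks["insert_emission"],
        tr_m=blocks["tr_m"],
        tr_i=blocks["tr_i"],
        tr_d=blocks["tr_d"],
        begin=blocks["begin"][0],
        background=blocks["background"][0],
    )
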