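"""Self-contained local nucleotide homology search.

A seed-and-extend search stands in for BLASTn: candidate loci are nominated
by exact 11-mer matches plus spaced weight-9 seeds (a length-15 sampling
pattern, which keeps sensitivity for short, strongly diverged homologs
where no 11 bp identical run survives), screened by an ungapped X-drop
extension, and then solved exactly by an affine-gap Smith-Waterman dynamic
program on the seed-localised subject window. The same dynamic program
doubles as the validation oracle (``smith_waterman``), so a hit's score can
never exceed the oracle score for its window.

Hit significance uses Karlin-Altschul statistics, E = K * m * n *
exp(-lambda * S), with (lambda, K) fitted to the extreme-value distribution
of optimal local scores of random sequence pairs (``calibrate_karlin``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .errors import AlignmentSizeError, CalibrationError
from .seqio import ScaffoldSet

_NEG = np.int32(-(10 ** 8))

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
_COMP = str.maketrans("ACGTN", "TGCAN")

MAX_ORACLE_LEN = 100_000

#: Spaced seed sampling pattern: match positions (1) over a 15-column span,
#: weight 9. Spaced sampling decorrelates neighbouring seed offsets, which
#: raises sensitivity over a contiguous 9-mer of the same weight.
SPACED_PATTERN = (1, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 1, 0, 1)


@dataclass(frozen=True)
class AlignmentScoring:
    """Megablast-style scoring with frozen Karlin-Altschul constants.

    ``gap_open`` and ``gap_extend`` are positive costs; a gap of length k
    costs gap_open + k * gap_extend. The default (lambda, K) were fitted
    once with ``calibrate_karlin(seed=0)`` under the default scoring.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    karlin_lambda: float = 0.72
    karlin_K: float = 0.98

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are subtracted and must be >= 0")
        if self.karlin_lambda <= 0 or self.karlin_K <= 0:
            raise ValueError("Karlin constants must be positive")

    def evalue(self, score: int, m: int, n: int) -> float:
        return float(self.karlin_K * m * n *
                     math.exp(-self.karlin_lambda * score))


@dataclass
class LocalHit:
    """One local alignment between a query and a scaffold.

    Query coordinates are 0-based half-open on the forward query; subject
    coordinates are always forward-strand scaffold coordinates, with
    ``strand`` recording the orientation of the match. The gapped rows are
    given in query orientation (the subject row is reverse-complemented for
    minus-strand hits). ``identity`` is matches over comparable columns,
    i.e. excluding gap and N columns.
    """

    query_id: str
    scaffold_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aligned_len: int
    matches: int
    identity: float
    score: int
    evalue: float
    q_gapped: str
    s_gapped: str

    @property
    def subject_span(self) -> int:
        return self.s_end - self.s_start

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Exact affine-gap local alignment (numba kernels)

@njit(cache=True)
def _dp_fill(H, E, F, q, s, match, mismatch, go, ge):
    """Fill H/E/F (pre-sized >= (m+1, n+1)) for the affine local recurrence.

    go is the cost of a length-1 gap (open + extend); ge extends by one.
    E consumes query bases (gap in subject row), F consumes subject bases.
    """
    m, n = len(q), len(s)
    for j in range(n + 1):
        H[0, j] = 0
        E[0, j] = _NEG
        F[0, j] = _NEG
    for i in range(1, m + 1):
        H[i, 0] = 0
        E[i, 0] = _NEG
        F[i, 0] = _NEG
        qc = q[i - 1]
        for j in range(1, n + 1):
            e = H[i - 1, j] - go
            if E[i - 1, j] - ge > e:
                e = E[i - 1, j] - ge
            E[i, j] = e
            f = H[i, j - 1] - go
            if F[i, j - 1] - ge > f:
                f = F[i, j - 1] - ge
            F[i, j] = f
            sub = match if (qc == s[j - 1] and qc < 4 and s[j - 1] < 4) else mismatch
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h


class _DpWorkspace:
    """Reusable H/E/F buffers; grown on demand, sliced per alignment."""

    def __init__(self):
        self.shape = (0, 0)
        self.H = self.E = self.F = None

    def matrices(self, m: int, n: int):
        if m + 1 > self.shape[0] or n + 1 > self.shape[1]:
            rows = max(m + 1, self.shape[0])
            cols = max(n + 1, self.shape[1])
            self.H = np.zeros((rows, cols), dtype=np.int32)
            self.E = np.zeros((rows, cols), dtype=np.int32)
            self.F = np.zeros((rows, cols), dtype=np.int32)
            self.shape = (rows, cols)
        return (self.H[:m + 1, :n + 1], self.E[:m + 1, :n + 1],
                self.F[:m + 1, :n + 1])


_WORKSPACE = _DpWorkspace()


def _dp_full(q, s, match, mismatch, go, ge):
    H, E, F = _WORKSPACE.matrices(len(q), len(s))
    _dp_fill(H, E, F, q, s, match, mismatch, go, ge)
    return H, E, F


@njit(cache=True)
def _dp_score(q, s, match, mismatch, go, ge):
    """Optimal local score only (linear memory)."""
    n = len(s)
    Hp = np.zeros(n + 1, dtype=np.int32)
    Ep = np.full(n + 1, _NEG, dtype=np.int32)
    best = 0
    for i in range(len(q)):
        qc = q[i]
        f = _NEG
        diag = Hp[0]
        Hp[0] = 0
        for j in range(1, n + 1):
            e = Hp[j] - go
            if Ep[j] - ge > e:
                e = Ep[j] - ge
            Ep[j] = e
            f2 = Hp[j - 1] - go  # Hp[j-1] already updated = current row
            if f - ge > f2:
                f2 = f - ge
            f = f2
            sub = match if (qc == s[j - 1] and qc < 4 and s[j - 1] < 4) else mismatch
            h = diag + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = Hp[j]
            Hp[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _ungapped_xdrop(q, s, qpos, spos, wlen, match, mismatch, xdrop):
    """Ungapped extension score around a seed at (qpos, spos), span wlen."""
    score = 0
    for k in range(wlen):
        score += match if (q[qpos + k] == s[spos + k] and q[qpos + k] < 4) else mismatch
    # right
    best = 0
    cur = 0
    i, j = qpos + wlen, spos + wlen
    while i < len(q) and j < len(s):
        cur += match if (q[i] == s[j] and q[i] < 4 and s[j] < 4) else mismatch
        if cur > best:
            best = cur
        if cur < best - xdrop:
            break
        i += 1
        j += 1
    score += best
    # left
    best = 0
    cur = 0
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        cur += match if (q[i] == s[j] and q[i] < 4 and s[j] < 4) else mismatch
        if cur > best:
            best = cur
        if cur < best - xdrop:
            break
        i -= 1
        j -= 1
    return score + best


def _traceback(H, E, F, q: np.ndarray, s: np.ndarray, sc: AlignmentScoring,
               i: int, j: int):
    """Trace one optimal alignment ending at H[i, j].

    Tie-break within a cell prefers diagonal, then query-consuming gap,
    then subject-consuming gap, which makes the trace deterministic.
    """
    go = sc.gap_open + sc.gap_extend
    q_chars, s_chars = [], []
    letters = "ACGTN"
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            match = sc.match if (q[i - 1] == s[j - 1] and q[i - 1] < 4
                                 and s[j - 1] < 4) else sc.mismatch
            if v == H[i - 1, j - 1] + match:
                q_chars.append(letters[q[i - 1]])
                s_chars.append(letters[s[j - 1]])
                i -= 1
                j -= 1
            elif v == E[i, j]:
                state = "E"
            elif v == F[i, j]:
                state = "F"
            else:  # pragma: no cover - recurrence guarantees a predecessor
                break
        elif state == "E":
            q_chars.append(letters[q[i - 1]])
            s_chars.append("-")
            opened = H[i - 1, j] - go
            i -= 1
            if E[i + 1, j] == opened:
                state = "H"
        else:  # state == "F"
            q_chars.append("-")
            s_chars.append(letters[s[j - 1]])
            opened = H[i, j - 1] - go
            j -= 1
            if F[i, j + 1] == opened:
                state = "H"
    return i, j, "".join(reversed(q_chars)), "".join(reversed(s_chars))


def _column_stats(q_gapped: str, s_gapped: str) -> tuple[int, int, int]:
    """(aligned_len, matches, comparable non-N non-gap columns)."""
    matches = 0
    comparable = 0
    for a, b in zip(q_gapped, s_gapped):
        if a == "-" or b == "-" or a == "N" or b == "N":
            continue
        comparable += 1
        if a == b:
            matches += 1
    return len(q_gapped), matches, comparable


def _align_window(q: np.ndarray, s: np.ndarray, sc: AlignmentScoring,
                  max_end_cells: int = 32):
    """Optimal local alignment of encoded query vs subject.

    Among co-optimal end cells the returned alignment minimises
    (s_start, q_start, aligned_len).
    """
    H, E, F = _dp_full(q, s, sc.match, sc.mismatch,
                       sc.gap_open + sc.gap_extend, sc.gap_extend)
    best = int(H.max())
    if best <= 0:
        return None
    ii, jj = np.nonzero(H == best)
    candidates = []
    for i, j in list(zip(ii.tolist(), jj.tolist()))[:max_end_cells]:
        qi, sj, qg, sg = _traceback(H, E, F, q, s, sc, i, j)
        candidates.append(((sj, qi, len(qg)), qi, sj, i, j, qg, sg))
    candidates.sort(key=lambda c: c[0])
    _, q0, s0, q1, s1, qg, sg = candidates[0]
    return best, q0, q1, s0, s1, qg, sg


def smith_waterman(query: str, subject: str,
                   scoring: AlignmentScoring | None = None,
                   query_id: str = "query",
                   scaffold_id: str = "subject") -> LocalHit | None:
    """Exact optimal forward-orientation local alignment (test oracle).

    Returns None when no positive-scoring alignment exists. Intended for
    validation; sequences beyond 100 kb are rejected.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    if len(query) > MAX_ORACLE_LEN or len(subject) > MAX_ORACLE_LEN:
        raise AlignmentSizeError("oracle aligner is limited to 100 kb inputs")
    sc = scoring or AlignmentScoring()
    res = _align_window(encode(query), encode(subject), sc)
    if res is None:
        return None
    score, q0, q1, s0, s1, qg, sg = res
    alen, matches, comparable = _column_stats(qg, sg)
    return LocalHit(
        query_id=query_id, scaffold_id=scaffold_id,
        q_start=q0, q_end=q1, s_start=s0, s_end=s1, strand="+",
        aligned_len=alen, matches=matches,
        identity=matches / comparable if comparable else 0.0,
        score=score, evalue=sc.evalue(score, len(query), len(subject)),
        q_gapped=qg, s_gapped=sg,
    )


# ---------------------------------------------------------------------------
# Seeding

def _kmer_codes(arr: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all contiguous w-mers plus a no-N validity mask."""
    if len(arr) < w:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    powers = (4 ** np.arange(w - 1, -1, -1)).astype(np.int64)
    valid = ~(windows >= 4).any(axis=1)
    codes = windows.astype(np.int64) @ powers
    return codes, valid


def _spaced_codes(arr: np.ndarray, pattern=SPACED_PATTERN):
    """Codes of spaced seeds (sampled columns of the pattern)."""
    span = len(pattern)
    if len(arr) < span:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    idx = np.array([i for i, p in enumerate(pattern) if p], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, span)[:, idx]
    powers = (4 ** np.arange(len(idx) - 1, -1, -1)).astype(np.int64)
    valid = ~(windows >= 4).any(axis=1)
    codes = windows.astype(np.int64) @ powers
    return codes, valid


def _seed_positions(q_arr: np.ndarray, s_arr: np.ndarray, word_size: int):
    """(s_pos, q_pos) pairs for exact word seeds and spaced seeds."""
    pairs: list[tuple[int, int]] = []
    for codes_fn, w in ((lambda a: _kmer_codes(a, word_size), word_size),
                        (_spaced_codes, len(SPACED_PATTERN))):
        q_codes, q_valid = codes_fn(q_arr)
        if len(q_codes) == 0:
            continue
        qmap: dict[int, list[int]] = {}
        for pos in np.nonzero(q_valid)[0].tolist():
            qmap.setdefault(int(q_codes[pos]), []).append(pos)
        s_codes, s_valid = codes_fn(s_arr)
        if len(s_codes) == 0:
            continue
        # membership via sorted query codes
        uniq = np.array(sorted(qmap), dtype=np.int64)
        loc = np.searchsorted(uniq, s_codes)
        loc[loc >= len(uniq)] = 0
        hit = s_valid & (uniq[loc] == s_codes) if len(uniq) else np.zeros(
            len(s_codes), dtype=bool)
        for sp in np.nonzero(hit)[0].tolist():
            for qp in qmap[int(s_codes[sp])]:
                pairs.append((sp, qp, w))
    return pairs


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _min_significant_score(sc: AlignmentScoring, m: int, n: int,
                           max_evalue: float) -> int:
    """Smallest integer score with E-value <= max_evalue."""
    return max(1, math.ceil(
        math.log(sc.karlin_K * m * n / max_evalue) / sc.karlin_lambda))


# ---------------------------------------------------------------------------
# Seed-and-extend search

def find_hits(query: str, scaffolds: ScaffoldSet,
              scoring: AlignmentScoring | None = None,
              min_len: int = 100, min_identity: float = 0.60,
              max_evalue: float = 1e-4, word_size: int = 11,
              window_margin: int = 40, min_ungapped: int = 22,
              xdrop: int = 15, max_hits_per_window: int = 10,
              abut_gap: int = 30, query_id: str = "query") -> list[LocalHit]:
    """Seed-and-extend search of ``query`` against both strands.

    Seeds (exact ``word_size``-mers plus spaced weight-9 matches) passing an
    ungapped X-drop score of ``min_ungapped`` nominate subject windows sized
    to hold a full query alignment; each window is solved exactly by the
    affine-gap dynamic program, with iterative masking so multiple
    insertions falling in one window each yield a hit (secondary alignments
    abutting an already-reported hit are treated as fragments of it and
    suppressed). Hits are filtered to aligned length >= min_len, identity >=
    min_identity (gap/N columns excluded) and E-value <= max_evalue with
    database size = total scaffold length; finally, same-scaffold/strand
    hits whose subject intervals overlap by more than half of the shorter
    are merged, keeping the higher-scoring one.
    """
    m = len(query)
    if not 100 <= m <= 2000:
        raise ValueError(f"query length {m} outside [100, 2000]")
    if len(scaffolds) == 0:
        return []
    sc = scoring or AlignmentScoring()
    n_total = scaffolds.total_length()
    s_min = _min_significant_score(sc, m, n_total, max_evalue)

    q_arr = encode(query)
    hits: list[LocalHit] = []
    for rec in scaffolds:
        L = len(rec.sequence)
        for strand in "+-":
            subject = rec.sequence if strand == "+" else revcomp(rec.sequence)
            s_arr = encode(subject)
            windows = []
            for sp, qp, w in _seed_positions(q_arr, s_arr, word_size):
                ug = _ungapped_xdrop(q_arr, s_arr, qp, sp, w,
                                     sc.match, sc.mismatch, xdrop)
                if ug < min_ungapped:
                    continue
                lo = max(0, sp - qp - window_margin)
                hi = min(L, sp + (m - qp) + window_margin)
                windows.append((lo, hi))
            for lo, hi in _merge_intervals(windows):
                win = s_arr[lo:hi].copy()
                found: list[tuple[int, int, int, int]] = []
                for _ in range(max_hits_per_window):
                    res = _align_window(q_arr, win, sc)
                    if res is None or res[0] < s_min:
                        break
                    score, q0, q1, s0, s1, qg, sg = res
                    # A secondary alignment abutting a previous one in the
                    # subject AND covering a mostly different query interval
                    # is a broken-off fragment of the same insertion, not a
                    # separate homolog: mask it without reporting.
                    fragment = False
                    for a, b, qa, qb in found:
                        if s0 < b + abut_gap and s1 > a - abut_gap:
                            q_ov = min(q1, qb) - max(q0, qa)
                            if q_ov < 0.3 * min(q1 - q0, qb - qa):
                                fragment = True
                                break
                    found.append((s0, s1, q0, q1))
                    win[s0:s1] = 4  # mask and continue
                    if fragment:
                        continue
                    alen, matches, comparable = _column_stats(qg, sg)
                    identity = matches / comparable if comparable else 0.0
                    a, b = lo + s0, lo + s1
                    if strand == "-":
                        a, b = L - (lo + s1), L - (lo + s0)
                    ev = sc.evalue(score, m, n_total)
                    if alen >= min_len and identity >= min_identity and ev <= max_evalue:
                        hits.append(LocalHit(
                            query_id=query_id, scaffold_id=rec.id,
                            q_start=q0, q_end=q1, s_start=a, s_end=b,
                            strand=strand, aligned_len=alen, matches=matches,
                            identity=identity, score=score, evalue=ev,
                            q_gapped=qg, s_gapped=sg,
                        ))
    return merge_overlapping_hits(hits)


def merge_overlapping_hits(hits: list[LocalHit],
                           max_overlap: float = 0.5) -> list[LocalHit]:
    """Collapse same-scaffold/strand hits overlapping > max_overlap of the
    shorter subject interval, keeping the higher-scoring one."""
    kept: list[LocalHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.scaffold_id, h.s_start)):
        redundant = False
        for k in kept:
            if k.scaffold_id != h.scaffold_id or k.strand != h.strand:
                continue
            ov = min(k.s_end, h.s_end) - max(k.s_start, h.s_start)
            shorter = min(k.subject_span, h.subject_span)
            if shorter > 0 and ov > max_overlap * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.scaffold_id, h.s_start, h.strand))
    return kept


# ---------------------------------------------------------------------------
# Karlin-Altschul calibration

def calibrate_karlin(scoring: AlignmentScoring | None = None, seed: int = 0,
                     n_sim: int = 80, seq_len: int = 300) -> tuple[float, float]:
    """Fit (lambda, K) from optimal local scores of random sequence pairs.

    Scores of optimal local alignments of unrelated sequences follow an
    extreme-value (Gumbel) distribution whose tail matches
    P(S >= s) ~ K m n exp(-lambda s); a Gumbel fit with location mu and
    scale beta gives lambda = 1/beta and K = exp(mu/beta) / (m n).
    """
    sc = scoring or AlignmentScoring()
    rng = np.random.default_rng(seed)
    go, ge = sc.gap_open + sc.gap_extend, sc.gap_extend
    scores = np.array([
        _dp_score(rng.integers(0, 4, seq_len).astype(np.uint8),
                  rng.integers(0, 4, seq_len).astype(np.uint8),
                  sc.match, sc.mismatch, go, ge)
        for _ in range(n_sim)
    ], dtype=float)
    if scores.std() < 1e-9:
        raise CalibrationError(
            "degenerate score distribution; fall back to the default "
            "AlignmentScoring constants")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(loc / scale) / (seq_len * seq_len)
    if not (0.05 < lam < 5.0) or not (K > 0):
        raise CalibrationError(
            f"implausible fit (lambda={lam:.3g}, K={K:.3g}); fall back to "
            "the default AlignmentScoring constants")
    return lam, K
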