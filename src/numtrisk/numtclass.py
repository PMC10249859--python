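"""NUMT calling, diagnosis and ground-truth scoring.

Raw homology hits become NUMT records with a length category (C1-C5), a
divergence, and the two diagnosability flags a barcode-QC screen can apply:
frameshift indels (any alignment gap whose length is not a multiple of
three) and premature stop codons under the invertebrate mitochondrial code
(TAA/TAG; AGA/AGG encode serine and TGA tryptophan, so neither is a stop).
A NUMT with either defect has an IPSC and can be recognised and excluded;
the dangerous remainder is the C5* class — full-barcode-length (651-661
bp), IPSC-free, > 2% diverged — which is indistinguishable from a genuine
mitochondrial haplotype and inflates species counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .homsearch import LocalHit
from .simgen import GroundTruthNumt, INVERTEBRATE_MITO_TABLE

#: Length category bounds (bp, inclusive). C5 is open-ended upward; the
#: nominal upper bound 661 is used only for exposure midpoints.
CATEGORY_BOUNDS: dict[str, tuple[int, int]] = {
    "C1": (100, 150),
    "C2": (151, 300),
    "C3": (301, 450),
    "C4": (451, 600),
    "C5": (601, 661),
}

C5_STAR_SPAN = (651, 661)
C5_STAR_MIN_DIVERGENCE = 2.0


@dataclass
class NumtRecord:
    hit: LocalHit
    length: int
    category: str | None
    divergence: float
    has_frameshift: bool
    has_premature_stop: bool
    is_c5_star: bool
    copy_group: str | None = None

    @property
    def has_ipsc(self) -> bool:
        return self.has_frameshift or self.has_premature_stop


@dataclass
class RecoveryMetrics:
    recall: float
    precision: float
    n_truth: int
    n_records: int
    n_matched: int
    divergence_mae: float
    divergence_mae_gap_free: float
    ipsc_tp: int
    ipsc_fp: int
    ipsc_fn: int
    ipsc_tn: int

    @property
    def ipsc_sensitivity(self) -> float:
        d = self.ipsc_tp + self.ipsc_fn
        return self.ipsc_tp / d if d else float("nan")

    @property
    def ipsc_specificity(self) -> float:
        d = self.ipsc_tn + self.ipsc_fp
        return self.ipsc_tn / d if d else float("nan")


# ---------------------------------------------------------------------------
# Hit-level filters and category assignment

def filter_residual_hits(hits: list[LocalHit], query_len: int = 658) -> list[LocalHit]:
    """Drop hits that are almost certainly residual mitochondrial sequence
    rather than NUMTs: full query coverage (within 1 bp) at >= 99%
    identity. Such near-perfect full-length matches are either leftover
    mitogenome fragments or integrations too recent to affect OTU counts
    at a 2% threshold."""
    kept = []
    for h in hits:
        full_cov = h.query_span >= query_len - 1
        if full_cov and h.identity >= 0.99:
            continue
        kept.append(h)
    return kept


def assign_category(length: int) -> str | None:
    """Map a NUMT length (bp) to C1..C5; None below the 100 bp floor."""
    if length < 0:
        raise ValueError(f"negative length {length}")
    if length < 100:
        return None
    for cat, (lo, hi) in CATEGORY_BOUNDS.items():
        if lo <= length <= hi:
            return cat
    return "C5"  # any length >= 601


# ---------------------------------------------------------------------------
# IPSC diagnosis

def _gap_runs(q_gapped: str, s_gapped: str):
    """Maximal gap runs as (column_start, length, row) with row 'q' or 's'."""
    runs = []
    for row_name, row in (("q", q_gapped), ("s", s_gapped)):
        i = 0
        n = len(row)
        while i < n:
            if row[i] == "-":
                j = i
                while j < n and row[j] == "-":
                    j += 1
                runs.append((i, j - i, row_name))
                i = j
            else:
                i += 1
    runs.sort()
    return runs


def collapse_gap_pairs(q_gapped: str, s_gapped: str,
                       max_sep: int = 12) -> tuple[str, str]:
    """Remove compensating equal-length gap pairs in opposite rows.

    At high divergence an optimal affine aligner sometimes explains a
    cluster of substitutions with an insertion/deletion pair that shifts
    the register locally and shifts it straight back. Such a pair is not
    evidence of indels in the homolog. When two gap runs of equal length
    sit in opposite rows within ``max_sep`` columns of each other, the
    stretch between them is re-paired ungapped (both rows lose the same
    number of gap columns, so the ungapped rows align column for column).
    """
    changed = True
    while changed:
        changed = False
        runs = _gap_runs(q_gapped, s_gapped)
        for (c1, l1, r1), (c2, l2, r2) in zip(runs, runs[1:]):
            if r1 == r2 or l1 != l2:
                continue
            if c2 - (c1 + l1) > max_sep:
                continue
            lo, hi = c1, c2 + l2
            q_mid = q_gapped[lo:hi].replace("-", "")
            s_mid = s_gapped[lo:hi].replace("-", "")
            q_gapped = q_gapped[:lo] + q_mid + q_gapped[hi:]
            s_gapped = s_gapped[:lo] + s_mid + s_gapped[hi:]
            changed = True
            break
    return q_gapped, s_gapped


def detect_frameshift(q_gapped: str, s_gapped: str, end_guard: int = 0) -> bool:
    """True iff any maximal gap run (in either row) has length % 3 != 0.

    Each gap is judged separately: two compensating gaps of lengths 2 and 1
    restore the net frame but still count, since each disrupts the local
    codon structure a translation screen reads. Gap runs falling entirely
    within ``end_guard`` columns of either alignment end are ignored (off
    by default): a local aligner occasionally accretes a short gapped tail
    of chance matches beyond the true homologous region, and those gaps are
    alignment noise, not indels of the homolog.
    """
    n = len(q_gapped)
    return any(
        length % 3 != 0
        for col, length, _r in _gap_runs(q_gapped, s_gapped)
        if not (col + length <= end_guard or col >= n - end_guard)
    )


def _stop_codons(code_table: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[code_table].stop_codons)


def detect_premature_stop(q_gapped: str, s_gapped: str, q_start: int,
                          frame_offset: int,
                          code_table: int = INVERTEBRATE_MITO_TABLE,
                          end_guard_codons: int = 0) -> bool:
    """Translate the aligned subject in the query-anchored reading frame
    and report any stop codon strictly before the final translated codon.

    ``frame_offset`` is the codon phase of query base 0. Translation starts
    at the first complete codon at or after the alignment start; after a
    frameshift gap run (length % 3 != 0) the partial codon is discarded and
    translation re-anchors at the next query codon boundary. A stop in the
    very last codon is terminal, not premature. ``end_guard_codons``
    additionally ignores that many codons at each end of the translated
    span (off by default), discounting chance-match tails the local aligner
    may append beyond the true homologous region.
    """
    stops = _stop_codons(code_table)
    fs_cols = {col + length for col, length, _r in
               _gap_runs(q_gapped, s_gapped) if length % 3 != 0}

    codons: list[str] = []
    buf: list[str] = []
    anchored = False
    qpos = q_start
    for col, (qc, sc) in enumerate(zip(q_gapped, s_gapped)):
        if col in fs_cols:  # a frameshift run just ended: re-anchor
            anchored = False
            buf = []
        if not anchored:
            if qc != "-" and (frame_offset + qpos) % 3 == 0:
                anchored = True
            elif qc != "-":
                qpos += 1
                continue
            else:
                continue
        if sc != "-":
            buf.append(sc)
            if len(buf) == 3:
                codons.append("".join(buf))
                buf = []
        if qc != "-":
            qpos += 1
    if len(codons) < 2 + 2 * end_guard_codons:
        return False
    g = end_guard_codons
    return any(c in stops for c in codons[g:len(codons) - 1 - g])


# ---------------------------------------------------------------------------
# Record assembly and scoring

def classify(hit: LocalHit, frame_offset: int,
             code_table: int = INVERTEBRATE_MITO_TABLE,
             copy_group: str | None = None) -> NumtRecord:
    """Build the full NUMT record for one surviving hit.

    Length is the subject-side span (insertion-inclusive); divergence is
    100 * (1 - identity) over non-gap, non-N columns.
    """
    length = hit.subject_span
    divergence = 100.0 * (1.0 - hit.identity)
    qg, sg = collapse_gap_pairs(hit.q_gapped, hit.s_gapped)
    has_fs = detect_frameshift(qg, sg, end_guard=8)
    has_stop = detect_premature_stop(
        qg, sg, hit.q_start, frame_offset, code_table, end_guard_codons=1)
    has_ipsc = has_fs or has_stop
    lo, hi = C5_STAR_SPAN
    is_star = (lo <= length <= hi and not has_ipsc
               and divergence > C5_STAR_MIN_DIVERGENCE)
    return NumtRecord(
        hit=hit, length=length, category=assign_category(length),
        divergence=divergence, has_frameshift=has_fs,
        has_premature_stop=has_stop, is_c5_star=is_star,
        copy_group=copy_group,
    )


def classify_hits(hits: list[LocalHit], frame_offset: int,
                  code_table: int = INVERTEBRATE_MITO_TABLE,
                  min_length: int = 100) -> list[NumtRecord]:
    """Classify all hits, keeping only those at or above the length floor."""
    records = []
    for h in hits:
        rec = classify(h, frame_offset, code_table)
        if rec.category is not None and rec.length >= min_length:
            records.append(rec)
    return records


def category_counts(records: list[NumtRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORY_BOUNDS}
    counts["C5*"] = 0
    for r in records:
        if r.category:
            counts[r.category] += 1
        if r.is_c5_star:
            counts["C5*"] += 1
    return counts


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


def evaluate_against_truth(records: list[NumtRecord],
                           truth: list[GroundTruthNumt],
                           min_overlap: float = 0.5,
                           query_len: int | None = None) -> RecoveryMetrics:
    """Score called NUMTs against planted ground truth.

    A record matches a truth entry iff they share a scaffold and their
    intervals reciprocally overlap by at least ``min_overlap`` of each.
    Matching is greedy one-to-one by decreasing overlap. When ``query_len``
    is given, the truth-side fraction is judged against
    min(planted_length, query_len): a hit from a query of that length can
    never span more of a longer insertion, so requiring half-coverage of
    the full insert would score the matching rule, not the detector. The
    IPSC confusion matrix compares planted flags (frameshift or premature
    stop) with detected flags on matched pairs; divergence error is
    reported both overall and for gap-free (indel-less) plantings, where
    the exact-count substitution model makes the planted value sharp.
    """
    pairs = []
    for ri, rec in enumerate(records):
        r_iv = (rec.hit.s_start, rec.hit.s_end)
        for ti, t in enumerate(truth):
            if rec.hit.scaffold_id != t.scaffold_id:
                continue
            ov = _overlap(r_iv, t.scaffold_interval)
            if ov <= 0:
                continue
            t_span = t.planted_length
            if query_len is not None:
                t_span = min(t_span, query_len)
            if (ov / (r_iv[1] - r_iv[0]) >= min_overlap
                    and ov / t_span >= min_overlap):
                pairs.append((ov, ri, ti))
    pairs.sort(key=lambda p: -p[0])
    used_r: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _ov, ri, ti in pairs:
        if ri in used_r or ti in used_t:
            continue
        used_r.add(ri)
        used_t.add(ti)
        matched.append((ri, ti))

    tp = fp = fn = tn = 0
    abs_err: list[float] = []
    abs_err_gf: list[float] = []
    for ri, ti in matched:
        rec, t = records[ri], truth[ti]
        planted_ipsc = t.has_frameshift or t.has_planted_stop
        if planted_ipsc and rec.has_ipsc:
            tp += 1
        elif planted_ipsc:
            fn += 1
        elif rec.has_ipsc:
            fp += 1
        else:
            tn += 1
        err = abs(rec.divergence - 100.0 * t.planted_divergence)
        abs_err.append(err)
        if not t.indels:
            abs_err_gf.append(err)

    def mean(xs):
        return sum(xs) / len(xs) if xs else float("nan")

    return RecoveryMetrics(
        recall=len(matched) / len(truth) if truth else float("nan"),
        precision=len(matched) / len(records) if records else float("nan"),
        n_truth=len(truth), n_records=len(records), n_matched=len(matched),
        divergence_mae=mean(abs_err),
        divergence_mae_gap_free=mean(abs_err_gf),
        ipsc_tp=tp, ipsc_fp=fp, ipsc_fn=fn, ipsc_tn=tn,
    )
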