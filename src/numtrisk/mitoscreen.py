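"""Removal of residual mitochondrial sequence from nuclear assemblies.

Assemblies routinely retain mitochondrial scaffolds — some labelled as such
in their FASTA headers, some overlooked. Both must go before NUMT scanning,
or the mitogenome itself is counted as a perfect "NUMT". Very long
mito-matching scaffolds (> 20 kb) are never auto-classified: they may be
mitogenomes with expanded intergenic regions or genuine long NUMTs, and the
screen stays conservative by only flagging them for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MitogenomeValidationError
from .homsearch import AlignmentScoring, find_hits
from .seqio import ScaffoldSet, has_mito_label
from .simgen import CANONICAL_GENE_ORDER, Mitogenome


def drop_labelled_scaffolds(assembly: ScaffoldSet) -> tuple[ScaffoldSet, list[str]]:
    """Remove every scaffold whose description carries a mitochondrial
    label, regardless of length. Returns (cleaned assembly, removed ids)."""
    removed = [r.id for r in assembly if has_mito_label(r.description)]
    return assembly.drop(removed), removed


@dataclass
class MitoScreenResult:
    candidates: list[str] = field(default_factory=list)
    flagged_for_review: list[str] = field(default_factory=list)
    coverage: dict[str, float] = field(default_factory=dict)


def detect_mito_scaffolds(assembly: ScaffoldSet, mitogenome: Mitogenome,
                          min_cov: float = 0.80, min_ident: float = 0.95,
                          max_len: int = 20000,
                          scoring: AlignmentScoring | None = None,
                          chunk: int = 1000) -> MitoScreenResult:
    """Identify unannotated scaffolds that are probably mitogenomes.

    The reference mitogenome is searched in ~1 kb chunks (the aligner takes
    queries up to 2 kb) and per-scaffold alignable coverage is the union of
    reference intervals hit at identity >= min_ident. A scaffold is a
    candidate iff coverage >= min_cov and its length <= max_len; longer
    high-coverage scaffolds are only flagged for review.
    """
    result = MitoScreenResult()
    if len(assembly) == 0:
        return result
    m = len(mitogenome)
    starts = list(range(0, m - chunk + 1, chunk))
    if not starts:
        starts = [0]
    # per-scaffold union of covered reference intervals
    covered: dict[str, list[tuple[int, int]]] = {}
    for cs in starts:
        ce = m if (cs + 2 * chunk > m) else cs + chunk  # absorb remainder
        query = mitogenome.sequence[cs:ce]
        for h in find_hits(query, assembly, scoring=scoring,
                           min_len=100, min_identity=min_ident,
                           query_id=f"mito_{cs}"):
            covered.setdefault(h.scaffold_id, []).append(
                (cs + h.q_start, cs + h.q_end))
        if ce == m:
            break
    for sid, intervals in covered.items():
        intervals.sort()
        total = 0
        cur_lo, cur_hi = intervals[0]
        for lo, hi in intervals[1:]:
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        total += cur_hi - cur_lo
        cov = total / m
        result.coverage[sid] = cov
        if cov >= min_cov:
            if len(assembly[sid]) <= max_len:
                result.candidates.append(sid)
            else:
                result.flagged_for_review.append(sid)
    result.candidates.sort()
    result.flagged_for_review.sort()
    return result


def screen_assembly(assembly: ScaffoldSet, mitogenome: Mitogenome | None = None,
                    **detect_kwargs) -> tuple[ScaffoldSet, dict]:
    """Full screen: drop labelled scaffolds, then detected mitogenome
    candidates. Returns the cleaned assembly and a report dict."""
    cleaned, labelled = drop_labelled_scaffolds(assembly)
    report = {"labelled_removed": labelled, "detected_removed": [],
              "flagged_for_review": []}
    if mitogenome is not None:
        det = detect_mito_scaffolds(cleaned, mitogenome, **detect_kwargs)
        cleaned = cleaned.drop(det.candidates)
        report["detected_removed"] = det.candidates
        report["flagged_for_review"] = det.flagged_for_review
    return cleaned, report


# ---------------------------------------------------------------------------
# Mitogenome annotation validation

_CANONICAL_PCGS = tuple(
    (name, strand) for name, _len, strand in CANONICAL_GENE_ORDER
    if not name.startswith("rrn")
)
_KNOWN_NAMES = frozenset(n for n, _l, _s in CANONICAL_GENE_ORDER)
# common synonyms seen in annotation files
_SYNONYMS = {
    "COI": "COX1", "COII": "COX2", "COIII": "COX3",
    "CO1": "COX1", "CO2": "COX2", "CO3": "COX3",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "COB": "CYTB", "CYTB": "CYTB", "16S": "rrnL", "12S": "rrnS",
}


def validate_mitogenome(gene_table) -> bool:
    """Check a (name, start, end, strand) table for the 13 canonical
    protein-coding genes in the canonical circular order.

    Rotation of the circle is allowed; reflection is not. The strand
    pattern must match the canonical pattern under the same rotation.
    rRNA rows are accepted and ignored; unknown names raise
    MitogenomeValidationError rather than returning False.
    """
    pcgs = []
    for name, start, end, strand in gene_table:
        canon = _SYNONYMS.get(name.upper(), name)
        if canon not in _KNOWN_NAMES:
            raise MitogenomeValidationError(f"unknown gene name {name!r}")
        if canon.startswith("rrn"):
            continue
        pcgs.append((canon, int(start), strand))
    names = [p[0] for p in pcgs]
    if sorted(names) != sorted(n for n, _ in _CANONICAL_PCGS):
        return False
    pcgs.sort(key=lambda p: p[1])
    observed = [(n, s) for n, _start, s in pcgs]
    k = len(_CANONICAL_PCGS)
    for rot in range(k):
        rotated = [_CANONICAL_PCGS[(rot + i) % k] for i in range(k)]
        if observed == rotated:
            return True
    return False
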