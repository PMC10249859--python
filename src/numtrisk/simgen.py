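"""Synthetic mitogenomes, nuclear assemblies, and planted NUMTs.

The generator emits complete ground truth for every planted insertion so the
detection, diagnosis and classification stages can be scored exactly. The
design choices that matter:

* The mitogenome carries the 13 protein-coding genes and 2 rRNAs in the
  canonical insect order (tRNAs are not modelled). Protein-coding genes are
  sampled codon-by-codon from the non-stop codons of the invertebrate
  mitochondrial code, so the annotated COI frame is stop-free by
  construction.
* Substitutions use an exact-count site model: exactly ``round(d * L)``
  distinct sites change, so the realised p-distance of a gap-free planted
  NUMT equals its nominal divergence to within 1/L.
* NUMT lengths follow a Pareto distribution with shape alpha = 1 truncated
  to [min_len, max_len], sampled by inverse CDF.
* Indel lengths are geometric(p = 0.5) truncated at 9 bp; a NUMT has a
  frameshift iff at least one of its indels has length not divisible by 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import PlacementError, SizingError
from .seqio import Scaffold, ScaffoldSet

INVERTEBRATE_MITO_TABLE = 5

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

#: Canonical insect mitochondrial gene order (protein-coding genes + rRNAs,
#: tRNAs omitted) with typical lengths. COI's length is a generator
#: parameter; the others are fixed.
CANONICAL_GENE_ORDER: tuple[tuple[str, int, str], ...] = (
    ("ND2", 1023, "+"),
    ("COX1", -1, "+"),      # length filled from coi_length
    ("COX2", 684, "+"),
    ("ATP8", 159, "+"),
    ("ATP6", 672, "+"),
    ("COX3", 786, "+"),
    ("ND3", 351, "+"),
    ("ND5", 1719, "-"),
    ("ND4", 1338, "-"),
    ("ND4L", 291, "-"),
    ("ND6", 522, "+"),
    ("CYTB", 1137, "+"),
    ("ND1", 936, "-"),
    ("rrnL", 1320, "-"),
    ("rrnS", 789, "-"),
)

PROTEIN_CODING_GENES = frozenset(
    n for n, _, _ in CANONICAL_GENE_ORDER if not n.startswith("rrn")
)

BARCODE_LENGTH = 658


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _sense_codons(table_id: int) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return sorted(table.forward_table)


def stop_codons(table_id: int = INVERTEBRATE_MITO_TABLE) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[table_id].stop_codons)


@dataclass(frozen=True)
class Mitogenome:
    """A synthetic annotated mitogenome.

    ``genes`` holds (name, start, end, strand) in genome order with 0-based
    half-open coordinates. ``frame_offset`` is the codon phase of the first
    barcode base relative to the COI reading frame (0 means the barcode
    starts on a codon boundary).
    """

    sequence: str
    genes: tuple[tuple[str, int, int, str], ...]
    coi_interval: tuple[int, int]
    barcode_interval: tuple[int, int]
    frame_offset: int
    code_table: int = INVERTEBRATE_MITO_TABLE

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def barcode(self) -> str:
        s, e = self.barcode_interval
        return self.sequence[s:e]

    @property
    def coi(self) -> str:
        s, e = self.coi_interval
        return self.sequence[s:e]

    def coding_intervals(self) -> list[tuple[str, int, int, str]]:
        """Genes in genome order (PCGs + rRNAs), as annotated."""
        return list(self.genes)


@dataclass(frozen=True)
class GroundTruthNumt:
    """Provenance record for one planted NUMT copy."""

    id: str
    scaffold_id: str
    insert_position: int
    source_interval: tuple[int, int]
    planted_length: int
    planted_divergence: float
    indels: list[tuple[int, int, bool]]  # (position, length, is_insertion)
    has_frameshift: bool
    has_planted_stop: bool
    copy_group: str
    strand: str = "+"

    @property
    def scaffold_interval(self) -> tuple[int, int]:
        return (self.insert_position, self.insert_position + self.planted_length)


@dataclass
class SimulatedDataset:
    assembly: ScaffoldSet
    mitogenome: Mitogenome
    query: str
    frame_offset: int
    truth: list[GroundTruthNumt]
    seed: int


# ---------------------------------------------------------------------------
# Mitogenome generation

def generate_mitogenome(seed: int, length: int = 15000, coi_length: int = 1536,
                        frame_offset: int = 0,
                        code_table: int = INVERTEBRATE_MITO_TABLE) -> Mitogenome:
    """Generate an annotated mitogenome with the canonical insect gene order.

    Protein-coding genes are built from uniformly sampled non-stop codons of
    ``code_table`` (reverse-complemented into the genome for minus-strand
    genes); rRNA genes and intergenic spacers are i.i.d. uniform A/C/G/T.
    The 658 bp barcode interval is placed inside COI so that its first base
    has codon phase ``frame_offset``.
    """
    if not 12000 <= length <= 20000:
        raise SizingError(f"mitogenome length {length} outside [12000, 20000]")
    if coi_length % 3 != 0 or coi_length < 900:
        raise SizingError("coi_length must be a multiple of 3 and >= 900")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")

    rng = np.random.default_rng(seed)
    sense = _sense_codons(code_table)

    gene_specs = [
        (name, coi_length if name == "COX1" else glen, strand)
        for name, glen, strand in CANONICAL_GENE_ORDER
    ]
    genes_total = sum(glen for _, glen, _ in gene_specs)
    n_gaps = len(gene_specs) + 1  # spacers between genes + control region
    spare = length - genes_total
    if spare < n_gaps:
        raise SizingError(
            f"length {length} too small to host {genes_total} bp of genes"
        )
    # Distribute spare bases across spacers; every spacer gets >= 1 bp.
    cuts = rng.multinomial(spare - n_gaps, np.full(n_gaps, 1.0 / n_gaps))
    spacers = cuts + 1

    def random_dna(n: int) -> str:
        return "".join(rng.choice(list(_BASES), size=n))

    def coding_seq(n: int) -> str:
        return "".join(rng.choice(sense, size=n // 3))

    parts: list[str] = []
    genes: list[tuple[str, int, int, str]] = []
    pos = 0
    for i, (name, glen, strand) in enumerate(gene_specs):
        spacer = random_dna(int(spacers[i]))
        parts.append(spacer)
        pos += len(spacer)
        if name.startswith("rrn"):
            gseq = random_dna(glen)
        else:
            cds = coding_seq(glen)
            gseq = cds if strand == "+" else revcomp(cds)
        parts.append(gseq)
        genes.append((name, pos, pos + glen, strand))
        pos += glen
    parts.append(random_dna(int(spacers[-1])))
    sequence = "".join(parts)
    assert len(sequence) == length

    coi = next(g for g in genes if g[0] == "COX1")
    coi_start, coi_end = coi[1], coi[2]
    barcode_start = coi_start + 24 + frame_offset
    barcode_end = barcode_start + BARCODE_LENGTH
    if barcode_end > coi_end:
        raise SizingError("COI too short to host the 658 bp barcode")

    return Mitogenome(
        sequence=sequence,
        genes=tuple(genes),
        coi_interval=(coi_start, coi_end),
        barcode_interval=(barcode_start, barcode_end),
        frame_offset=frame_offset,
        code_table=code_table,
    )


def mitogenome_gene_rows(mito: Mitogenome) -> list[tuple[str, int, int, str]]:
    """Gene rows for the BED-like table, including a ``barcode`` row whose
    score column (see seqio.write_gene_table) is unused; the barcode's
    frame offset is recoverable from its start relative to COI."""
    rows = list(mito.genes)
    rows.append(("barcode", mito.barcode_interval[0],
                 mito.barcode_interval[1], "+"))
    return rows


def load_mitogenome(fasta_path, genes_path,
                    code_table: int = INVERTEBRATE_MITO_TABLE) -> Mitogenome:
    """Rebuild an annotated mitogenome from FASTA + gene table on disk.

    The gene table must carry the 15 canonical genes plus a ``barcode``
    row; the barcode frame offset is derived from its phase within COI.
    """
    from .seqio import read_fasta, read_gene_table

    scaffolds = read_fasta(fasta_path)
    if len(scaffolds) != 1:
        raise SizingError("mitogenome FASTA must contain exactly one record")
    sequence = next(iter(scaffolds)).sequence
    rows = read_gene_table(genes_path)
    genes = tuple(r for r in rows if r[0] != "barcode")
    barcode = [r for r in rows if r[0] == "barcode"]
    if len(barcode) != 1:
        raise SizingError("gene table must contain exactly one barcode row")
    coi = [g for g in genes if g[0] == "COX1"]
    if len(coi) != 1:
        raise SizingError("gene table must contain exactly one COX1 row")
    b_start, b_end = barcode[0][1], barcode[0][2]
    coi_start, coi_end = coi[0][1], coi[0][2]
    return Mitogenome(
        sequence=sequence, genes=genes,
        coi_interval=(coi_start, coi_end),
        barcode_interval=(b_start, b_end),
        frame_offset=(b_start - coi_start) % 3,
        code_table=code_table,
    )


# ---------------------------------------------------------------------------
# Mutation and length models

def mutate_segment(seq: str, d: float, kappa: float = 2.0,
                   seed: int | np.random.Generator = 0) -> tuple[str, np.ndarray]:
    """Substitute exactly ``round(d * len(seq))`` distinct sites.

    Each chosen site becomes a different base: a transition with probability
    kappa / (kappa + 1), otherwise one of the two transversions uniformly.
    Returns the mutated sequence and the sorted substituted positions, so
    Hamming distance / length equals ``d`` up to rounding of the site count.
    """
    if not 0 <= d < 0.5:
        raise ValueError(f"divergence {d} outside [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round(d * len(seq))
    if n_sub == 0:
        return seq, np.empty(0, dtype=int)
    positions = np.sort(rng.choice(len(seq), size=n_sub, replace=False))
    out = list(seq)
    p_transition = kappa / (kappa + 1.0)
    for pos in positions:
        base = out[pos]
        if base not in _TRANSITION:  # N or ambiguity: replace with random base
            out[pos] = _BASES[rng.integers(4)]
            continue
        if rng.random() < p_transition:
            out[pos] = _TRANSITION[base]
        else:
            out[pos] = _TRANSVERSIONS[base][rng.integers(2)]
    return "".join(out), positions


def truncated_pareto_quantile(u: float, min_len: int, max_len: int) -> float:
    """Inverse CDF of Pareto(alpha=1, x_m=min_len) truncated at max_len."""
    c = 1.0 - min_len / max_len
    return min_len / (1.0 - u * c)


def truncated_pareto_cdf(x: float, min_len: int, max_len: int) -> float:
    c = 1.0 - min_len / max_len
    return (1.0 - min_len / x) / c


def sample_numt_length(seed: int | np.random.Generator, min_len: int = 100,
                       max_len: int = 1600) -> int:
    """Draw one NUMT length from the truncated Pareto(alpha=1) model."""
    if not 20 <= min_len < max_len:
        raise ValueError("require 20 <= min_len < max_len")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = truncated_pareto_quantile(rng.random(), min_len, max_len)
    return int(min(max(round(x), min_len), max_len))


# ---------------------------------------------------------------------------
# Policies

@dataclass(frozen=True)
class IndelPolicy:
    """Probability of carrying indels and how to draw them.

    ``p_indel`` is the per-NUMT probability of having at least one indel;
    the count is then 1 + Poisson(extra_rate). Lengths are geometric(0.5)
    truncated at ``max_len`` bp. ``force_frameshift`` resamples until at
    least one indel length is not a multiple of 3.
    """

    p_indel: float = 0.0
    extra_rate: float = 0.5
    max_len: int = 9
    p_insertion: float = 0.5
    force_frameshift: bool = False

    def sample(self, rng: np.random.Generator, seg_len: int):
        if rng.random() >= self.p_indel or seg_len < 30:
            return []
        n = 1 + rng.poisson(self.extra_rate)
        n = min(n, (seg_len - 20) // 10)  # keep indel sites >= 10 bp apart-ish
        if n < 1:
            return []
        while True:
            lengths = np.minimum(rng.geometric(0.5, size=n), self.max_len)
            if not self.force_frameshift or any(l % 3 for l in lengths):
                break
        positions = np.sort(rng.choice(np.arange(10, seg_len - 10), size=n,
                                       replace=False))
        return [
            (int(p), int(l), bool(rng.random() < self.p_insertion))
            for p, l in zip(positions, lengths)
        ]


@dataclass(frozen=True)
class StopPolicy:
    """Probability of forcing an in-frame premature stop codon (TAA)."""

    p_stop: float = 0.0


@dataclass(frozen=True)
class CopyPolicy:
    """Distribution of copy counts per NUMT (1 = single copy).

    ``weights[k]`` is the unnormalised probability of k+1 copies; copies are
    identical unless ``between_copy_divergence`` > 0.
    """

    weights: tuple[float, ...] = (1.0,)
    between_copy_divergence: float = 0.0

    def sample_copies(self, rng: np.random.Generator) -> int:
        w = np.asarray(self.weights, dtype=float)
        return int(rng.choice(len(w), p=w / w.sum())) + 1


def uniform_divergence_sampler(lo: float, hi: float) -> Callable[[np.random.Generator], float]:
    def sampler(rng: np.random.Generator) -> float:
        return float(rng.uniform(lo, hi))
    return sampler


# ---------------------------------------------------------------------------
# Assembly generation and planting

def generate_assembly(seed: int, n_scaffolds: int = 3,
                      scaffold_length: int = 30000, gc: float = 0.5,
                      prefix: str = "scaf") -> ScaffoldSet:
    """I.i.d. random nuclear background with configurable GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = ScaffoldSet()
    for i in range(n_scaffolds):
        seq = "".join(rng.choice(list(_BASES), size=scaffold_length, p=p))
        out.add(Scaffold(f"{prefix}_{i + 1}", "synthetic nuclear scaffold", seq))
    return out


def _coi_frame_phase(mito_pos: int, mito: Mitogenome) -> int:
    """Codon phase of a mitogenome position in the COI reading frame."""
    return (mito_pos - mito.coi_interval[0]) % 3


def _scan_premature_stop(segment: str, src_start: int, mito: Mitogenome) -> bool:
    """True if the segment carries an in-frame stop codon, judged within its
    overlap with the barcode region and excluding the first and final codon
    of that overlap (a terminal stop is not premature, and the leading codon
    mirrors the classifier's end guard against alignment-boundary noise)."""
    stops = stop_codons(mito.code_table)
    b_start, b_end = mito.barcode_interval
    src_end = src_start + len(segment)
    lo = max(src_start, b_start)
    hi = min(src_end, b_end)
    if hi - lo < 9:
        return False
    # first codon start at or after lo, in COI frame
    first = lo + (-_coi_frame_phase(lo, mito)) % 3
    codon_starts = list(range(first, hi - 2, 3))
    if len(codon_starts) < 3:
        return False
    for cs in codon_starts[1:-1]:
        codon = segment[cs - src_start:cs - src_start + 3]
        if codon in stops:
            return True
    return False


def _force_stop(segment: str, src_start: int, mito: Mitogenome,
                rng: np.random.Generator) -> str | None:
    """Overwrite one mid-span in-frame codon with TAA; None if no room.

    The codon is taken from the middle third of the segment's overlap with
    the barcode so local alignment end-trimming cannot clip it.
    """
    b_start, b_end = mito.barcode_interval
    src_end = src_start + len(segment)
    lo = max(src_start, b_start)
    hi = min(src_end, b_end)
    if hi - lo < 30:
        return None
    span = hi - lo
    mid_lo = lo + span // 3
    mid_hi = hi - span // 3
    first = mid_lo + (-_coi_frame_phase(mid_lo, mito)) % 3
    codon_starts = [cs for cs in range(first, mid_hi - 2, 3)]
    if not codon_starts:
        return None
    cs = int(rng.choice(codon_starts))
    i = cs - src_start
    return segment[:i] + "TAA" + segment[i + 3:]


def _apply_indels(segment: str, indels, rng: np.random.Generator) -> str:
    out = segment
    for pos, length, is_insertion in sorted(indels, reverse=True):
        if is_insertion:
            ins = "".join(rng.choice(list(_BASES), size=length))
            out = out[:pos] + ins + out[pos:]
        else:
            out = out[:pos] + out[pos + length:]
    return out


def _sample_source_interval(rng: np.random.Generator, mito: Mitogenome,
                            length: int, source: str) -> tuple[int, int]:
    b_start, b_end = mito.barcode_interval
    if source == "uniform":
        start = int(rng.integers(0, len(mito) - length + 1))
    elif source == "barcode":
        if length <= BARCODE_LENGTH:
            start = int(rng.integers(b_start, b_end - length + 1))
        else:
            lo = max(0, b_end - length)
            hi = min(b_start, len(mito) - length)
            if hi < lo:
                raise PlacementError("mitogenome too short for source interval")
            start = int(rng.integers(lo, hi + 1))
    else:
        raise ValueError(f"unknown source mode {source!r}")
    return start, start + length


def plant_numts(assembly: ScaffoldSet, mitogenome: Mitogenome, n_numts: int,
                divergence_sampler: Callable[[np.random.Generator], float],
                indel_policy: IndelPolicy = IndelPolicy(),
                stop_policy: StopPolicy = StopPolicy(),
                copy_policy: CopyPolicy = CopyPolicy(),
                seed: int = 0, *,
                length_sampler: Callable[[np.random.Generator], int] | None = None,
                source: str = "barcode",
                both_strands: bool = True,
                id_prefix: str = "numt") -> tuple[ScaffoldSet, list[GroundTruthNumt]]:
    """Plant ``n_numts`` NUMTs (each possibly in several copies) and return
    the edited assembly plus one ground-truth record per inserted copy.

    Each NUMT is a mitogenome interval (barcode-anchored by default),
    mutated by the exact-count substitution model, optionally edited with
    indels and/or an in-frame premature stop, optionally duplicated, and
    spliced into a uniformly chosen scaffold position and strand.
    ``has_planted_stop`` records whether the final segment carries an
    in-frame premature stop — forced or arising from substitution — since
    that is the ground truth a translation screen can be scored against.
    """
    rng = np.random.default_rng(seed)
    if n_numts == 0:
        return assembly.copy(), []
    if length_sampler is None:
        max_len = min(1600, len(mitogenome) // 4)
        length_sampler = lambda r: sample_numt_length(r, 100, max_len)

    scaffold_ids = assembly.ids
    if not scaffold_ids:
        raise PlacementError("assembly has no scaffolds")

    # plan: scaffold_id -> list of (orig_pos, plan_order, segment, record stub)
    plans: dict[str, list] = {sid: [] for sid in scaffold_ids}
    truth: list[GroundTruthNumt] = []
    used_positions: dict[str, set[int]] = {sid: set() for sid in scaffold_ids}
    order = 0

    for i in range(n_numts):
        length = int(length_sampler(rng))
        src_start, src_end = _sample_source_interval(rng, mitogenome, length, source)
        d = float(divergence_sampler(rng))
        base_seg, _ = mutate_segment(
            mitogenome.sequence[src_start:src_end], d, seed=rng)
        forced = None
        if rng.random() < stop_policy.p_stop:
            forced = _force_stop(base_seg, src_start, mitogenome, rng)
            if forced is not None:
                base_seg = forced
        indels = indel_policy.sample(rng, length)
        has_stop = _scan_premature_stop(base_seg, src_start, mitogenome)
        final_seg = _apply_indels(base_seg, indels, rng)
        has_fs = any(l % 3 != 0 for _, l, _ in indels)

        n_copies = copy_policy.sample_copies(rng)
        group = f"{id_prefix}_{i:04d}"
        for c in range(n_copies):
            seg = final_seg
            if c > 0 and copy_policy.between_copy_divergence > 0:
                seg, _ = mutate_segment(
                    final_seg, copy_policy.between_copy_divergence, seed=rng)
            strand = "-" if (both_strands and rng.random() < 0.5) else "+"
            inserted = revcomp(seg) if strand == "-" else seg
            sid = scaffold_ids[int(rng.integers(len(scaffold_ids)))]
            scaffold_len = len(assembly[sid])
            for _attempt in range(200):
                pos = int(rng.integers(0, scaffold_len + 1))
                if pos not in used_positions[sid]:
                    break
            else:
                raise PlacementError(f"no free insertion point on {sid}")
            used_positions[sid].add(pos)
            rec = GroundTruthNumt(
                id=f"{group}c{c}", scaffold_id=sid, insert_position=pos,
                source_interval=(src_start, src_end),
                planted_length=len(inserted), planted_divergence=d,
                indels=list(indels), has_frameshift=has_fs,
                has_planted_stop=has_stop, copy_group=group, strand=strand,
            )
            plans[sid].append((pos, order, inserted, rec))
            truth.append(rec)
            order += 1

    # splice insertions, then fix up final coordinates
    out = assembly.copy()
    final_truth: list[GroundTruthNumt] = []
    rec_to_final: dict[str, int] = {}
    for sid in scaffold_ids:
        plan = sorted(plans[sid], key=lambda t: (t[0], t[1]))
        if not plan:
            continue
        seq = out[sid].sequence
        pieces = []
        prev = 0
        offset = 0
        for pos, _o, inserted, rec in plan:
            pieces.append(seq[prev:pos])
            pieces.append(inserted)
            rec_to_final[rec.id] = pos + offset
            offset += len(inserted)
            prev = pos
        pieces.append(seq[prev:])
        out.replace(sid, "".join(pieces))
    for rec in truth:
        if rec.id in rec_to_final:
            final_truth.append(replace(rec, insert_position=rec_to_final[rec.id]))
        else:
            final_truth.append(rec)
    return out, final_truth


def add_residual_mito_scaffolds(assembly: ScaffoldSet, mitogenome: Mitogenome,
                                labelled: bool, length: int,
                                seed: int = 0) -> ScaffoldSet:
    """Append a residual mitogenome scaffold (partial copy or padded copy).

    If ``labelled``, the description carries the token "mitochondrion" as in
    assemblies whose mitochondrial scaffolds were flagged during assembly;
    otherwise the copy is an unlabelled, overlooked mitogenome.
    """
    if not 200 <= length <= 46000:
        raise ValueError(f"residual scaffold length {length} outside [200, 46000]")
    rng = np.random.default_rng(seed)
    m = len(mitogenome)
    if length <= m:
        start = int(rng.integers(0, m - length + 1))
        seq = mitogenome.sequence[start:start + length]
    else:
        pad = "".join(rng.choice(list(_BASES), size=length - m))
        seq = mitogenome.sequence + pad
    out = assembly.copy()
    n = sum(1 for r in assembly if r.id.startswith("mtscaf"))
    desc = ("mitochondrion, complete genome" if labelled
            else "unplaced genomic scaffold")
    out.add(Scaffold(f"mtscaf_{n + 1}", desc, seq))
    return out


# ---------------------------------------------------------------------------
# One-call dataset builder

def simulate_dataset(seed: int, *, n_numts: int = 20,
                     mito_length: int = 15000, coi_length: int = 1536,
                     frame_offset: int = 1, n_scaffolds: int = 3,
                     scaffold_length: int = 30000, gc: float = 0.5,
                     divergence: tuple[float, float] = (0.02, 0.30),
                     indel_policy: IndelPolicy = IndelPolicy(p_indel=0.3),
                     stop_policy: StopPolicy = StopPolicy(p_stop=0.3),
                     copy_policy: CopyPolicy = CopyPolicy(),
                     source: str = "barcode",
                     length_sampler=None,
                     residual_mito: str | None = None) -> SimulatedDataset:
    """Generate a full simulated species: mitogenome, assembly, planted
    NUMTs and the barcode query. ``residual_mito`` may be None, "labelled"
    or "unlabelled"."""
    rng = np.random.default_rng(seed)
    s_mito, s_asm, s_plant, s_res = rng.integers(2 ** 31, size=4)
    mito = generate_mitogenome(int(s_mito), mito_length, coi_length, frame_offset)
    assembly = generate_assembly(int(s_asm), n_scaffolds, scaffold_length, gc)
    assembly, truth = plant_numts(
        assembly, mito, n_numts,
        uniform_divergence_sampler(*divergence),
        indel_policy=indel_policy, stop_policy=stop_policy,
        copy_policy=copy_policy, seed=int(s_plant), source=source,
        length_sampler=length_sampler,
    )
    if residual_mito is not None:
        assembly = add_residual_mito_scaffolds(
            assembly, mito, labelled=(residual_mito == "labelled"),
            length=len(mito), seed=int(s_res))
    return SimulatedDataset(
        assembly=assembly, mitogenome=mito, query=mito.barcode,
        frame_offset=frame_offset, truth=truth, seed=seed,
    )
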