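"""Readers and writers for the on-disk artifacts of the pipeline.

All sequence files are plain FASTA (60-column wrap); tabular artifacts are
TSV with a fixed header row. Intervals are 0-based half-open throughout,
matching BED conventions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import FastaFormatError, TableFormatError

# IUPAC nucleotide codes; ambiguity codes other than N are normalised to N on
# read so downstream code only ever sees A/C/G/T/N.
_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIG = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

#: Case-insensitive token marking a scaffold of mitochondrial origin. Covers
#: both "mitochondrion" and "mitochondrial" in assembly headers.
MITO_LABEL_TOKEN = "mitochondri"


@dataclass(frozen=True)
class Scaffold:
    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


class ScaffoldSet:
    """Ordered collection of scaffolds with unique ids."""

    def __init__(self, records: Iterable[Scaffold] = ()):
        self._records: list[Scaffold] = []
        self._index: dict[str, int] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: Scaffold) -> None:
        if rec.id in self._index:
            raise FastaFormatError(f"duplicate scaffold id {rec.id!r}")
        self._index[rec.id] = len(self._records)
        self._records.append(rec)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self._records)

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        return self._records[self._index[scaffold_id]]

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._records]

    def total_length(self) -> int:
        return sum(len(r) for r in self._records)

    def drop(self, ids: Iterable[str]) -> "ScaffoldSet":
        dropped = set(ids)
        return ScaffoldSet(r for r in self._records if r.id not in dropped)

    def replace(self, scaffold_id: str, sequence: str) -> None:
        i = self._index[scaffold_id]
        old = self._records[i]
        self._records[i] = Scaffold(old.id, old.description, sequence)

    def copy(self) -> "ScaffoldSet":
        return ScaffoldSet(self._records)


def has_mito_label(description: str) -> bool:
    """True if a FASTA description marks the scaffold as mitochondrial."""
    return MITO_LABEL_TOKEN in description.lower()


def _validate_sequence(seq: str, rec_id: str, offset: int) -> str:
    up = seq.upper()
    for i, c in enumerate(up):
        if c not in _IUPAC:
            raise FastaFormatError(
                f"non-IUPAC character {c!r} at position {offset + i} "
                f"in record {rec_id!r}"
            )
    return up.translate(_AMBIG)


def read_fasta(path: str | Path) -> ScaffoldSet:
    """Read a (possibly empty) multi-FASTA file into a ScaffoldSet.

    The header line is split into an id (first whitespace token) and a
    description (the remainder). Lowercase bases are uppercased; IUPAC
    ambiguity codes collapse to N; anything else is rejected with the
    offending position.
    """
    records = ScaffoldSet()
    rec_id: str | None = None
    desc = ""
    chunks: list[str] = []
    seen = 0

    def flush() -> None:
        if rec_id is not None:
            records.add(Scaffold(rec_id, desc, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                rec_id = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                seen = 0
            else:
                if rec_id is None:
                    raise FastaFormatError(
                        f"sequence data before first header at line {lineno}"
                    )
                clean = _validate_sequence(line.strip(), rec_id, seen)
                seen += len(clean)
                chunks.append(clean)
    flush()
    return records


def write_fasta(records: ScaffoldSet | Iterable[Scaffold], path: str | Path,
                wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# BED6-like gene tables

GENE_TABLE_COLUMNS = ("scaffold", "start", "end", "name", "score", "strand")


def write_gene_table(genes: Sequence[tuple[str, int, int, str]], path: str | Path,
                     scaffold_id: str = "mitogenome") -> None:
    """Write (name, start, end, strand) tuples as a BED6-like TSV."""
    with open(path, "w") as fh:
        for name, start, end, strand in genes:
            fh.write(f"{scaffold_id}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def read_gene_table(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED6-like gene table into (name, start, end, strand) tuples."""
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise TableFormatError(
                    f"{path}: expected 6 tab-separated fields at line {lineno}, "
                    f"got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: non-integer coordinate at line {lineno}"
                ) from exc
            if parts[5] not in "+-":
                raise TableFormatError(f"{path}: bad strand at line {lineno}")
            genes.append((parts[3], start, end, parts[5]))
    return genes


# ---------------------------------------------------------------------------
# Hit tables

HIT_COLUMNS = (
    "query_id", "scaffold_id", "q_start", "q_end", "s_start", "s_end",
    "strand", "aligned_len", "matches", "identity", "score", "evalue",
    "q_gapped", "s_gapped",
)


def _fmt(v) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_hit_table(hits, path: str | Path) -> None:
    """Write LocalHit records as TSV (header row always present)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(_fmt(getattr(h, c)) for c in HIT_COLUMNS) + "\n")


def read_hit_table(path: str | Path):
    """Read a hit TSV back into LocalHit records."""
    from .homsearch import LocalHit  # deferred to avoid an import cycle

    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != HIT_COLUMNS:
            raise TableFormatError(f"{path}: unexpected hit-table header")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(HIT_COLUMNS):
                raise TableFormatError(
                    f"{path}: expected {len(HIT_COLUMNS)} fields at line "
                    f"{lineno}, got {len(parts)}"
                )
            try:
                hits.append(LocalHit(
                    query_id=parts[0], scaffold_id=parts[1],
                    q_start=int(parts[2]), q_end=int(parts[3]),
                    s_start=int(parts[4]), s_end=int(parts[5]),
                    strand=parts[6], aligned_len=int(parts[7]),
                    matches=int(parts[8]), identity=float(parts[9]),
                    score=int(parts[10]), evalue=float(parts[11]),
                    q_gapped=parts[12], s_gapped=parts[13],
                ))
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}: malformed value at line {lineno}: {exc}"
                ) from exc
    return hits


# ---------------------------------------------------------------------------
# Ground-truth tables

TRUTH_COLUMNS = (
    "id", "scaffold_id", "insert_position", "source_start", "source_end",
    "planted_length", "planted_divergence", "strand", "indels",
    "has_frameshift", "has_planted_stop", "copy_group",
)


def _encode_indels(indels) -> str:
    if not indels:
        return "."
    return ";".join(
        f"{pos}:{length}:{'I' if ins else 'D'}" for pos, length, ins in indels
    )


def _decode_indels(text: str):
    if text == ".":
        return []
    out = []
    for item in text.split(";"):
        pos, length, kind = item.split(":")
        out.append((int(pos), int(length), kind == "I"))
    return out


def write_truth_table(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write("\t".join([
                t.id, t.scaffold_id, str(t.insert_position),
                str(t.source_interval[0]), str(t.source_interval[1]),
                str(t.planted_length), format(t.planted_divergence, ".6g"),
                t.strand, _encode_indels(t.indels),
                str(int(t.has_frameshift)), str(int(t.has_planted_stop)),
                t.copy_group,
            ]) + "\n")


def read_truth_table(path: str | Path):
    from .simgen import GroundTruthNumt  # deferred to avoid an import cycle

    truth = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise TableFormatError(f"{path}: unexpected truth-table header")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(TRUTH_COLUMNS):
                raise TableFormatError(
                    f"{path}: bad field count at line {lineno}"
                )
            truth.append(GroundTruthNumt(
                id=parts[0], scaffold_id=parts[1],
                insert_position=int(parts[2]),
                source_interval=(int(parts[3]), int(parts[4])),
                planted_length=int(parts[5]),
                planted_divergence=float(parts[6]),
                strand=parts[7], indels=_decode_indels(parts[8]),
                has_frameshift=bool(int(parts[9])),
                has_planted_stop=bool(int(parts[10])),
                copy_group=parts[11],
            ))
    return truth


# ---------------------------------------------------------------------------
# Classified NUMT tables

NUMT_COLUMNS = HIT_COLUMNS + (
    "length", "category", "divergence", "has_frameshift",
    "has_premature_stop", "has_ipsc", "is_c5_star", "copy_group",
)


def write_numt_table(records, path: str | Path) -> None:
    """Write classified NUMT records (hit fields + classification) as TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(NUMT_COLUMNS) + "\n")
        for r in records:
            row = [_fmt(getattr(r.hit, c)) for c in HIT_COLUMNS]
            row += [
                str(r.length), r.category or ".",
                format(r.divergence, ".6g"),
                str(int(r.has_frameshift)), str(int(r.has_premature_stop)),
                str(int(r.has_ipsc)), str(int(r.is_c5_star)),
                r.copy_group or ".",
            ]
            fh.write("\t".join(row) + "\n")


def read_numt_table(path: str | Path):
    from .homsearch import LocalHit  # deferred to avoid an import cycle
    from .numtclass import NumtRecord

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != NUMT_COLUMNS:
            raise TableFormatError(f"{path}: unexpected NUMT-table header")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            p = line.split("\t")
            if len(p) != len(NUMT_COLUMNS):
                raise TableFormatError(f"{path}: bad field count at line {lineno}")
            hit = LocalHit(
                query_id=p[0], scaffold_id=p[1], q_start=int(p[2]),
                q_end=int(p[3]), s_start=int(p[4]), s_end=int(p[5]),
                strand=p[6], aligned_len=int(p[7]), matches=int(p[8]),
                identity=float(p[9]), score=int(p[10]), evalue=float(p[11]),
                q_gapped=p[12], s_gapped=p[13],
            )
            out.append(NumtRecord(
                hit=hit, length=int(p[14]),
                category=None if p[15] == "." else p[15],
                divergence=float(p[16]),
                has_frameshift=bool(int(p[17])),
                has_premature_stop=bool(int(p[18])),
                is_c5_star=bool(int(p[20])),
                copy_group=None if p[21] == "." else p[21],
            ))
    return out


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
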