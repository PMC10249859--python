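"""OTU clustering, richness-inflation arithmetic, and the exposure model.

"Exposure" of a NUMT length category to an amplicon protocol is the
category's mean length divided by the 658 bp barcode length: a protocol
can only recover a NUMT whose length reaches its amplicon, and the chance
it does scales with the category's fractional coverage of the barcode.
Category means are interval midpoints (C5 uses the nominal 601-661 bp
span). OTU clustering is single linkage at a 2% p-distance threshold, a
documented stand-in for BOLD's Refined Single Linkage algorithm, so OTU
counts on real data may differ slightly from RESL's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import UndefinedDistanceError
from .numtclass import CATEGORY_BOUNDS
from .simgen import BARCODE_LENGTH


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# Exposure model

def category_exposure(lo: int, hi: int, barcode_len: int = BARCODE_LENGTH) -> float:
    """Midpoint exposure of a length category, rounded to 2 decimals."""
    if not 0 < lo <= hi <= 1000:
        raise ValueError(f"bad category bounds ({lo}, {hi})")
    return round(((lo + hi) / 2) / barcode_len, 2)


#: Exposure fraction per category under the midpoint model.
CATEGORY_EXPOSURES: dict[str, float] = {
    cat: category_exposure(lo, hi) for cat, (lo, hi) in CATEGORY_BOUNDS.items()
}


@dataclass(frozen=True)
class ProtocolSpec:
    """An amplicon protocol: how many amplicons of what length, and which
    NUMT categories it is exposed to. The full-barcode protocol is exposed
    only to C5* NUMTs (those spanning the barcode with no IPSC), each with
    exposure 1."""

    name: str
    n_amplicons: int
    amplicon_length: tuple[int, int]
    exposed_categories: tuple[str, ...]
    exposures: dict[str, float]


def _spec(name, n_amp, length, cats) -> ProtocolSpec:
    if cats == ("C5*",):
        exp = {"C5*": 1.0}
    else:
        exp = {c: CATEGORY_EXPOSURES[c] for c in cats}
    return ProtocolSpec(name, n_amp, length, cats, exp)


PROTOCOLS: dict[str, ProtocolSpec] = {
    # single full-length barcode amplicon: only C5* NUMTs pass as barcodes
    "full": _spec("full", 1, (651, 661), ("C5*",)),
    # two mid-length amplicons for lightly degraded DNA
    "dual": _spec("dual", 2, (307, 407), ("C3", "C4", "C5")),
    # five short amplicons for heavily degraded (museum) DNA
    "five": _spec("five", 5, (100, 150), ("C1", "C2", "C3", "C4", "C5")),
    # metabarcoding: one mid-length amplicon
    "metabarcoding": _spec("metabarcoding", 1, (300, 450), ("C3", "C4", "C5")),
    # eDNA: one short amplicon
    "edna": _spec("edna", 1, (100, 150), ("C1", "C2", "C3", "C4", "C5")),
}


def protocol_exposure(category_counts: dict[str, int], protocol: ProtocolSpec,
                      n_species: int) -> tuple[float, float]:
    """Amplifiable NUMT count and per-species exposure for one protocol.

    amplifiable = sum over exposed categories of count_c * E_c;
    per_species = amplifiable / n_species * n_amplicons.
    """
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if any(v < 0 for v in category_counts.values()):
        raise ValueError("category counts must be non-negative")
    amplifiable = sum(
        category_counts.get(c, 0) * protocol.exposures[c]
        for c in protocol.exposed_categories
    )
    per_species = amplifiable / n_species * protocol.n_amplicons
    return amplifiable, per_species


def per_species_percent(amplifiable: float, n_species: int) -> int:
    """Amplifiable NUMT count as an integer percentage of the species count."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    return _round_half_up(100.0 * amplifiable / n_species)


# ---------------------------------------------------------------------------
# OTU clustering

@dataclass
class OtuPartition:
    ids: list[str]
    threshold: float
    clusters: list[list[int]]  # indices into ids, each sorted

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    def cluster_ids(self) -> list[list[str]]:
        return [[self.ids[i] for i in c] for c in self.clusters]


def pdistance_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise p-distances of sequences in one coordinate frame.

    Columns where either sequence has a gap or N are ignored for that
    pair; a pair with no comparable columns raises UndefinedDistanceError.
    """
    k = len(seqs)
    if k == 0:
        return np.zeros((0, 0))
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one aligned coordinate frame")
    arr = np.array([list(s) for s in seqs])
    valid = (arr != "-") & (arr != "N")
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            n_cmp = int(both.sum())
            if n_cmp == 0:
                raise UndefinedDistanceError(
                    f"no comparable columns between sequences {i} and {j}")
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / n_cmp
    return d


def single_linkage_otus(matrix: np.ndarray, threshold: float = 0.02,
                        ids: list[str] | None = None) -> OtuPartition:
    """Single-linkage clusters at a distance threshold.

    Clusters are the connected components of the graph with an edge
    wherever d(i, j) <= threshold, so any chain of sub-threshold links
    joins its endpoints. Output order is by smallest member index.
    """
    matrix = np.asarray(matrix, dtype=float)
    k = matrix.shape[0]
    if ids is None:
        ids = [str(i) for i in range(k)]
    if k == 0:
        return OtuPartition(ids=[], threshold=threshold, clusters=[])
    adj = csr_matrix((matrix <= threshold).astype(np.int8))
    n_comp, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: c[0])
    return OtuPartition(ids=list(ids), threshold=threshold, clusters=ordered)


# ---------------------------------------------------------------------------
# Richness-inflation and PCR arithmetic

def conversion_percentage(n_otus: int, n_seqs: int) -> int:
    """OTU count as an integer percentage of the input sequence count."""
    if n_otus > n_seqs:
        raise ValueError("n_otus cannot exceed n_seqs")
    if not 0 < n_otus:
        raise ValueError("n_otus must be positive")
    return _round_half_up(100.0 * n_otus / n_seqs)


def inflation_percent(numt_otus: int, mt_otus: int) -> int:
    """Percentage inflation of the OTU count by NUMT-derived OTUs."""
    if mt_otus <= 0:
        raise ValueError("mt_otus must be positive")
    if numt_otus < 0:
        raise ValueError("numt_otus must be non-negative")
    return _round_half_up(100.0 * ((numt_otus + mt_otus) / mt_otus - 1.0))


def pcr_copy_ratio(genome_size_ratio: float, mt_mass_fraction: float,
                   numt_copies_per_genome: int) -> float:
    """mtDNA : NUMT template ratio entering PCR.

    With a nuclear genome ``genome_size_ratio`` times larger than the
    mitogenome, a mitochondrial mass fraction ``mt_mass_fraction`` of the
    extract, and ``numt_copies_per_genome`` NUMT copies per (diploid)
    nuclear genome, mitochondrial targets outnumber NUMT targets by
    genome_size_ratio * mt_mass_fraction / numt_copies_per_genome.
    """
    if genome_size_ratio <= 0:
        raise ValueError("genome_size_ratio must be positive")
    if mt_mass_fraction < 0:
        raise ValueError("mt_mass_fraction must be >= 0")
    if numt_copies_per_genome <= 0:
        raise ValueError("numt_copies_per_genome must be positive")
    return genome_size_ratio * mt_mass_fraction / numt_copies_per_genome


def pcr_trajectory(initial_mt_advantage: float, per_cycle_factor_ratio: float,
                   cycles: int) -> float:
    """Final mt : NUMT amplicon ratio after PCR.

    ``per_cycle_factor_ratio`` is the NUMT : mt per-cycle amplification
    factor ratio (1.2 means the NUMT amplifies 20% more efficiently per
    cycle). A result below 1 means the NUMT dominates the amplicon pool.
    """
    if initial_mt_advantage <= 0 or per_cycle_factor_ratio <= 0:
        raise ValueError("ratios must be positive")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    return initial_mt_advantage * per_cycle_factor_ratio ** (-cycles)
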