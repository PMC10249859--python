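"""Reference simulation studies at reproducible, desk-scale sizes.

These functions define the package's benchmark conditions once, so the
test suite and the reporting script measure the same quantities the same
way. Sizes are chosen to finish in minutes on one core while keeping the
statistics sharp:

* recovery study — 25 species x 20 NUMTs = 500 planted insertions,
  divergence uniform on [0.02, 0.30], lengths truncated-Pareto(alpha=1) on
  [100, 1600] anchored on the barcode, 30% of NUMTs carrying indels and
  30% a premature stop;
* slope study — 100 species whose NUMT counts span 4-256 (log-uniform),
  sources uniform over the mitogenome, scored by barcode-sized window
  counts and the log2 COI-vs-mitogenome-wide regression;
* length study — 10,000 draws from the truncated Pareto length sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .homsearch import find_hits
from .mitowide import log2_regression, windowed_counts
from .numtclass import (RecoveryMetrics, classify_hits, evaluate_against_truth,
                        filter_residual_hits)
from .simgen import (BARCODE_LENGTH, IndelPolicy, StopPolicy,
                     sample_numt_length, simulate_dataset)


def _species_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2 ** 31, size=n)]


def recovery_study(seed: int = 0, n_species: int = 25,
                   numts_per_species: int = 20) -> RecoveryMetrics:
    """Plant-and-recover benchmark aggregated over all species.

    Matching uses the query-capped overlap rule (query_len = 658): a
    barcode hit can never span more than ~658 bp of a longer insertion.
    """
    tot_truth = tot_rec = tot_match = 0
    tp = fp = fn = tn = 0
    errs: list[float] = []
    errs_gf: list[float] = []
    for s in _species_seeds(seed, n_species):
        ds = simulate_dataset(seed=s, n_numts=numts_per_species)
        hits = filter_residual_hits(find_hits(ds.query, ds.assembly))
        records = classify_hits(hits, ds.frame_offset)
        m = evaluate_against_truth(records, ds.truth, query_len=BARCODE_LENGTH)
        tot_truth += m.n_truth
        tot_rec += m.n_records
        tot_match += m.n_matched
        tp += m.ipsc_tp
        fp += m.ipsc_fp
        fn += m.ipsc_fn
        tn += m.ipsc_tn
        if m.n_matched:
            errs.append(m.divergence_mae * m.n_matched)
        if not np.isnan(m.divergence_mae_gap_free):
            errs_gf.append(m.divergence_mae_gap_free)
    return RecoveryMetrics(
        recall=tot_match / tot_truth,
        precision=tot_match / tot_rec,
        n_truth=tot_truth, n_records=tot_rec, n_matched=tot_match,
        divergence_mae=sum(errs) / tot_match if tot_match else float("nan"),
        divergence_mae_gap_free=float(np.mean(errs_gf)) if errs_gf else float("nan"),
        ipsc_tp=tp, ipsc_fp=fp, ipsc_fn=fn, ipsc_tn=tn,
    )


@dataclass
class SlopeStudyResult:
    slope: float
    intercept: float
    r_squared: float
    n_species: int
    n_used: int


def slope_study(seed: int = 0, n_species: int = 100) -> SlopeStudyResult:
    """COI-count vs mitogenome-wide window-count regression on simulated
    species with uniformly sourced NUMTs.

    Per-species NUMT counts are log-uniform on [4, 256] so the regression
    has dynamic range; species where either count is zero are dropped, as
    in the log2 model.
    """
    xs: list[int] = []
    ys: list[float] = []
    for s in _species_seeds(seed, n_species):
        rng = np.random.default_rng(s)
        n_numts = int(round(2 ** rng.uniform(2, 8)))
        ds = simulate_dataset(
            seed=s, n_numts=n_numts, n_scaffolds=2, scaffold_length=6000,
            source="uniform", indel_policy=IndelPolicy(p_indel=0.3),
            stop_policy=StopPolicy(p_stop=0.3))
        wc = windowed_counts(ds.assembly, ds.mitogenome)
        xs.append(wc.coi_count)
        ys.append(wc.mean_count)
    slope, intercept, r2 = log2_regression(xs, ys)
    n_used = int(sum(1 for x, y in zip(xs, ys) if x > 0 and y > 0))
    return SlopeStudyResult(slope=slope, intercept=intercept, r_squared=r2,
                            n_species=n_species, n_used=n_used)


def length_fraction_study(seed: int = 0, n_draws: int = 10_000,
                          min_len: int = 100, max_len: int = 1600,
                          cutoff: int = 300) -> float:
    """Fraction of truncated-Pareto length draws below ``cutoff`` bp."""
    rng = np.random.default_rng(seed)
    below = sum(
        1 for _ in range(n_draws)
        if sample_numt_length(rng, min_len, max_len) < cutoff
    )
    return below / n_draws
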