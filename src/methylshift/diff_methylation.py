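"""Differential-methylation calling for the sequencing and array arms.

Sequencing arm: per gene, counts are pooled within each condition and the
pooled pair is tested against the library-size-proportional expectation
with a two-sided exact binomial test, then adjusted across genes with
Benjamini–Hochberg.  This is a deliberately simple pooled caller — it has
no replicate-aware dispersion model and is validated on synthetic data
only.

Array arm: a gene is scored as enriched when at least ``min_replicates``
of its per-replicate scores (−log10 of the per-probe-set P value) strictly
exceed the cutoff (default 2.0, i.e. P < 0.01, in at least 2 of 3
replicates).  Differential methylation between two array conditions is
then read off presence/absence of genes in the two enriched lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_features import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationCall",
    "ArrayReplicateScores",
    "ArrayPeakConfig",
    "call_diffmeth_seq",
    "call_array_peaks",
    "score_presence_absence",
    "calls_to_frame",
]


@dataclass(frozen=True)
class MethylationCall:
    """Per-gene differential-methylation verdict.

    ``direction`` is 'hyper' when the normalised methylation rate is higher
    in the first condition of the comparison, 'hypo' when lower.  ``effect``
    is the log2 ratio of normalised rates (with a 0.5 pseudocount so that a
    zero on one side stays finite).
    """

    gene_id: str
    direction: str
    p_raw: float
    p_adj: float
    effect: float

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be 'hyper' or 'hypo', got {self.direction!r}")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of (0, 1]: {self.p_raw}")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError("p_adj must be >= p_raw")
        if self.effect > 0 and self.direction != "hyper":
            raise ValueError("positive effect requires direction 'hyper'")
        if self.effect < 0 and self.direction != "hypo":
            raise ValueError("negative effect requires direction 'hypo'")


@dataclass(frozen=True)
class ArrayReplicateScores:
    """Per-gene array enrichment scores, one per biological replicate."""

    gene_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.scores) < 2:
            raise ValueError(f"gene {self.gene_id!r}: need >= 2 replicate scores")
        if not all(np.isfinite(self.scores)):
            raise ValueError(f"gene {self.gene_id!r}: non-finite score")


@dataclass(frozen=True)
class ArrayPeakConfig:
    """Replicate-concordance rule for accepting an array enrichment peak.

    Defaults encode "at least 2 of 3 replicates with score strictly > 2"
    (score = −log10 P, so the cutoff is P < 0.01).
    """

    min_replicates: int = 2
    score_cutoff: float = 2.0
    replicate_count: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.min_replicates <= self.replicate_count):
            raise ValueError("need 1 <= min_replicates <= replicate_count")


def _binom_p_two_sided(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided exact binomial p-values for paired (k, n) arrays."""
    out = np.empty(len(k), dtype=float)
    for i, (ki, ni) in enumerate(zip(k, n)):
        out[i] = stats.binomtest(int(ki), int(ni), p0).pvalue
    # extreme splits underflow to exactly 0; keep p in (0, 1]
    return np.maximum(out, np.finfo(float).tiny)


def call_diffmeth_seq(
    counts: CountMatrix,
    cond_a: Iterable[str],
    cond_b: Iterable[str],
    alpha: float = 0.05,
    return_all: bool = False,
) -> list[MethylationCall]:
    """Call per-gene differential methylation between two pooled conditions.

    Counts are summed within each condition; for each gene the split of the
    pooled total between conditions is tested against the library-size
    proportion with a two-sided exact binomial test.  P values are adjusted
    by Benjamini–Hochberg across all testable genes; calls with
    ``p_adj <= alpha`` are returned (all genes when ``return_all``).

    Genes with zero counts in both conditions yield no call and are logged.
    """
    cond_a, cond_b = list(cond_a), list(cond_b)
    if not cond_a or not cond_b:
        raise ValueError("both conditions must name at least one sample")
    for s in cond_a + cond_b:
        if s not in counts.counts.columns:
            raise ValueError(f"sample {s!r} not in count matrix")

    x_a = counts.counts[cond_a].sum(axis=1).to_numpy()
    x_b = counts.counts[cond_b].sum(axis=1).to_numpy()
    lib_a = float(counts.library_sizes[cond_a].sum())
    lib_b = float(counts.library_sizes[cond_b].sum())
    p0 = lib_a / (lib_a + lib_b)

    total = x_a + x_b
    testable = total > 0
    n_zero = int((~testable).sum())
    if n_zero:
        logger.info("call_diffmeth_seq: %d genes with zero counts in both conditions skipped", n_zero)

    genes = np.asarray(counts.gene_ids)[testable]
    ka, nt = x_a[testable], total[testable]
    p_raw = _binom_p_two_sided(ka, nt, p0)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    rate_a = (ka + 0.5) / lib_a
    rate_b = (nt - ka + 0.5) / lib_b
    effect = np.log2(rate_a / rate_b)
    # tie-break: at an exactly proportional split the call is 'hyper' with
    # p = 1, so it never survives any sensible alpha
    direction = np.where(effect >= 0, "hyper", "hypo")
    effect = np.where(effect == 0.0, 0.0, effect)

    calls = [
        MethylationCall(g, d, float(pr), float(pa), float(ef))
        for g, d, pr, pa, ef in zip(genes, direction, p_raw, p_adj, effect)
    ]
    if return_all:
        return calls
    return [c for c in calls if c.p_adj <= alpha]


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    """Tabulate calls as gene, direction, p_raw, p_adj, effect."""
    return pd.DataFrame(
        [(c.gene_id, c.direction, c.p_raw, c.p_adj, c.effect) for c in calls],
        columns=["gene_id", "direction", "p_raw", "p_adj", "effect"],
    )


def call_array_peaks(
    genes: Sequence[ArrayReplicateScores],
    cfg: ArrayPeakConfig = ArrayPeakConfig(),
) -> set[str]:
    """Genes whose score strictly exceeds the cutoff in enough replicates.

    A score exactly at the cutoff does not pass (strict '>'), so e.g.
    (2.0, 2.0, 2.0) with the default config is not enriched.
    """
    enriched: set[str] = set()
    for g in genes:
        if len(g.scores) != cfg.replicate_count:
            raise ValueError(
                f"gene {g.gene_id!r}: {len(g.scores)} replicate scores, "
                f"expected {cfg.replicate_count}"
            )
        n_pass = sum(s > cfg.score_cutoff for s in g.scores)
        if n_pass >= cfg.min_replicates:
            enriched.add(g.gene_id)
    return enriched


def score_presence_absence(
    control_enriched: set[str], treatment_enriched: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """Split genes by presence in the control vs treatment enriched lists.

    Returns ``(lost, gained, unchanged)``: genes enriched only in control
    (methylation lost under treatment), only in treatment (gained), or in
    both.  The three sets are pairwise disjoint by construction.
    """
    lost = control_enriched - treatment_enriched
    gained = treatment_enriched - control_enriched
    unchanged = control_enriched & treatment_enriched
    return lost, gained, unchanged


def read_array_scores_tsv(path) -> list[ArrayReplicateScores]:
    """Read per-gene replicate scores from a gene, rep1..repK table."""
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    rep_cols = list(df.columns[1:])
    return [
        ArrayReplicateScores(str(row[gene_col]), tuple(float(row[c]) for c in rep_cols))
        for _, row in df.iterrows()
    ]


def write_array_scores_tsv(genes: Sequence[ArrayReplicateScores], path) -> None:
    k = len(genes[0].scores) if genes else 0
    cols = ["gene_id"] + [f"rep{i + 1}" for i in range(k)]
    pd.DataFrame(
        [(g.gene_id, *g.scores) for g in genes], columns=cols
    ).to_csv(path, sep="\t", index=False)
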