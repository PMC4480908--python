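"""Synthetic methylation-enrichment experiments with recorded planted truth.

One call to :func:`simulate_experiment` produces everything the pipeline
consumes — gene models on toy chromosomes, four overlapping polycomb-
target (PCGT) component sets, sequencing counts for a knockdown arm (two
siRNAs + control) and an overexpression arm (construct + vector control),
each with input and methylation-enriched libraries, per-replicate array
scores, and qPCR Ct tables — plus the planted per-gene truth, so every
stage downstream can be scored against what was actually simulated.

The planted structure mirrors the design it emulates:

* a fraction of genes are PCGTs, built as four nested/overlapping
  component target sets ("all" ⊂ each component ⊂ "at least one");
* a set of *responsive* genes is drawn with a PCGT bias controlled by an
  odds multiplier (odds = 1 is the null); responsive genes split into a
  positive class (methylation falls under knockdown, rises under
  overexpression) and a mirrored negative class;
* enriched-library counts are negative binomial with mean proportional
  to methylation level × region length × library size, emulating the
  overdispersion of methylated-DNA capture; input libraries depend on
  length only;
* array scores are methylation signal transformed to a −log10 P scale
  with Gaussian replicate noise;
* Ct tables are generated from log2 abundances plus measurement noise.

All randomness flows from one integer seed through named substreams, one
per data layer, so the same seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .diff_methylation import ArrayReplicateScores
from .genomic_features import CountMatrix, GeneModel, write_gene_models_bed
from .qpcr import CtRecord, write_ct_table
from .diff_methylation import write_array_scores_tsv
from .enrichment import write_gmt

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_experiment",
    "simulate_truth_sets",
    "odds_for_target_rf",
]

SEQ_CONDITIONS = ("kd_siRNA1", "kd_siRNA2", "kd_control", "oe", "oe_control")
PCGT_COMPONENTS = ("Suz12_targets", "Eed_targets", "Phc1_targets", "Rnf2_targets")

# fixed substream indices per data layer; changing these changes every dataset
_STREAMS = {"genes": 1, "pcgt": 2, "truth": 3, "methylation": 4, "seq": 5, "array": 6, "qpcr": 7}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the planted experiment.

    ``enrichment_odds`` multiplies the odds that a responsive gene is a
    PCGT; 1.0 is the null.  ``effect_size`` is the planted shift of the
    log2 methylation odds in responsive genes.  ``array_noise_sd`` is the
    replicate noise on the −log10 P score scale.
    """

    n_genes: int = 20000
    pcgt_fraction: float = 0.10
    n_responsive: int = 3000
    enrichment_odds: float = 2.0
    library_size: int = 5_000_000
    dispersion: float = 10.0
    replicate_count: int = 3
    array_noise_sd: float = 0.3
    effect_size: float = 2.0
    positive_fraction: float = 0.5
    spike_fold: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pcgt_fraction < 1.0):
            raise ValueError("pcgt_fraction must be in (0, 1)")
        if not (0 <= self.n_responsive < self.n_genes):
            raise ValueError("need n_responsive < n_genes")
        if self.enrichment_odds < 0:
            raise ValueError("enrichment_odds must be >= 0")
        if self.library_size <= 0 or self.dispersion <= 0:
            raise ValueError("library_size and dispersion must be positive")
        if self.replicate_count < 2:
            raise ValueError("need >= 2 array replicates")


@dataclass
class SyntheticDataset:
    """A complete simulated experiment with its planted truth."""

    config: SimulationConfig
    gene_models: list[GeneModel]
    pcgt_sets: dict[str, set[str]]          # four components + pcgt_all + pcgt_any
    truth_positive: set[str]
    truth_negative: set[str]
    methylation: pd.DataFrame               # genes × conditions, true methylation level
    seq_counts: CountMatrix                 # samples named "<condition>:<fraction>"
    array_scores: dict[str, list[ArrayReplicateScores]]  # per condition
    ct_tables: dict[str, list[CtRecord]]

    @property
    def truth_responsive(self) -> set[str]:
        return self.truth_positive | self.truth_negative

    @property
    def universe(self) -> set[str]:
        return {m.gene_id for m in self.gene_models}

    def write(self, outdir: str | Path) -> None:
        """Write every layer in the formats the pipeline reads, plus truth."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models_bed(self.gene_models, outdir / "genes.bed")
        write_gmt(self.pcgt_sets, outdir / "pcgt_sets.gmt", description="synthetic")
        self.seq_counts.to_tsv(outdir / "seq_counts.tsv")
        for cond, scores in self.array_scores.items():
            write_array_scores_tsv(scores, outdir / f"array_scores_{cond}.tsv")
        for name, records in self.ct_tables.items():
            write_ct_table(records, outdir / f"ct_{name}.tsv")
        truth = {
            "positive": sorted(self.truth_positive),
            "negative": sorted(self.truth_negative),
            "seed": self.config.seed,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _rng(cfg_seed: int, layer: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed & 0x7FFFFFFF, _STREAMS[layer]])


def odds_for_target_rf(
    target_rf: float, n_genes: int, n_pcgt: int, n_responsive: int
) -> float:
    """Odds multiplier whose mean planted overlap hits a target RF.

    The number of PCGTs among the responsive draw follows Fisher's
    noncentral hypergeometric distribution; this solves for the odds at
    which its mean equals ``target_rf`` times the chance expectation.
    """
    expected = n_responsive * n_pcgt / n_genes
    target_mean = target_rf * expected
    if not (0 < target_mean < min(n_pcgt, n_responsive)):
        raise ValueError("target RF out of attainable range for these set sizes")

    def gap(log_odds: float) -> float:
        return (
            stats.nchypergeom_fisher.mean(n_genes, n_pcgt, n_responsive, np.exp(log_odds))
            - target_mean
        )

    return float(np.exp(brentq(gap, -12.0, 12.0, xtol=1e-10)))


def _make_gene_models(cfg: SimulationConfig) -> list[GeneModel]:
    rng = _rng(cfg.seed, "genes")
    models = []
    genes_per_chrom = 1000
    pos = 5000
    for i in range(cfg.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        if i % genes_per_chrom == 0:
            pos = 5000
        length = int(rng.integers(2000, 10000))
        gap = int(rng.integers(6000, 20000))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + length
        gene_id = f"G{i:05d}"
        if strand == "+":
            models.append(GeneModel(gene_id, chrom, "+", start, end))
        else:
            models.append(GeneModel(gene_id, chrom, "-", end, start))
        pos = end + gap
    return models


def _make_pcgt_sets(cfg: SimulationConfig, gene_ids: Sequence[str]) -> dict[str, set[str]]:
    """Four overlapping component target sets with core ⊂ component ⊂ pool."""
    rng = _rng(cfg.seed, "pcgt")
    n_any = max(4, round(cfg.pcgt_fraction * cfg.n_genes))
    pool = rng.choice(len(gene_ids), size=n_any, replace=False)
    pool_ids = [gene_ids[i] for i in pool]
    n_core = max(1, round(0.25 * n_any))
    core = set(pool_ids[:n_core])
    rest = pool_ids[n_core:]
    sets: dict[str, set[str]] = {}
    for name in PCGT_COMPONENTS:
        member = rng.random(len(rest)) < 0.6
        sets[name] = core | {g for g, m in zip(rest, member) if m}
    # every pool gene must sit in >= 1 component so the union equals the
    # drawn pool and the intersection equals the core
    uncovered = set(rest) - set().union(*sets.values())
    for g in uncovered:
        sets[PCGT_COMPONENTS[int(rng.integers(len(PCGT_COMPONENTS)))]].add(g)
    sets["pcgt_all"] = set.intersection(*(sets[n] for n in PCGT_COMPONENTS))
    sets["pcgt_any"] = set.union(*(sets[n] for n in PCGT_COMPONENTS))
    return sets


def _draw_truth(
    cfg: SimulationConfig, gene_ids: Sequence[str], pcgt_any: set[str]
) -> tuple[set[str], set[str]]:
    """Responsive draw with PCGT bias, split into positive/negative classes."""
    rng = _rng(cfg.seed, "truth")
    pcgt = [g for g in gene_ids if g in pcgt_any]
    non_pcgt = [g for g in gene_ids if g not in pcgt_any]
    if cfg.n_responsive == 0:
        return set(), set()
    k = int(
        stats.nchypergeom_fisher.rvs(
            len(gene_ids), len(pcgt), cfg.n_responsive, cfg.enrichment_odds, random_state=rng
        )
    )
    chosen = list(rng.choice(pcgt, size=k, replace=False)) + list(
        rng.choice(non_pcgt, size=cfg.n_responsive - k, replace=False)
    )
    chosen = np.array(chosen)
    rng.shuffle(chosen)
    n_pos = round(cfg.positive_fraction * cfg.n_responsive)
    return set(chosen[:n_pos]), set(chosen[n_pos:])


def _condition_methylation(
    cfg: SimulationConfig,
    gene_ids: Sequence[str],
    truth_positive: set[str],
    truth_negative: set[str],
) -> pd.DataFrame:
    """True methylation level per gene × condition.

    Baseline levels are a bimodal Beta mixture — a mostly-unmethylated
    mode, Beta(2, 8), and a clearly methylated mode, Beta(8, 2) — the
    structure of promoter methylation that enrichment assays rely on.
    In responsive genes the log2 odds of methylation shift by
    ±``effect_size``: the positive class loses methylation under
    knockdown and gains it under overexpression, the negative class
    mirrors that.
    """
    rng = _rng(cfg.seed, "methylation")
    high = rng.random(len(gene_ids)) < 0.45
    base = np.where(high, rng.beta(8.0, 2.0, size=len(gene_ids)), rng.beta(2.0, 8.0, size=len(gene_ids)))
    sign = np.zeros(len(gene_ids))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in truth_positive:
        sign[idx[g]] = 1.0
    for g in truth_negative:
        sign[idx[g]] = -1.0

    def shifted(direction: float) -> np.ndarray:
        odds = base / (1.0 - base) * 2.0 ** (direction * sign * cfg.effect_size)
        return odds / (1.0 + odds)

    meth = pd.DataFrame(index=list(gene_ids))
    meth["kd_siRNA1"] = shifted(-1.0)
    meth["kd_siRNA2"] = shifted(-1.0)
    meth["kd_control"] = base
    meth["oe"] = shifted(+1.0)
    meth["oe_control"] = base
    return meth


def _draw_counts(
    cfg: SimulationConfig,
    meth: pd.DataFrame,
    lengths: np.ndarray,
) -> CountMatrix:
    """Library counts: Poisson around a gene-level Gamma capture factor.

    Each gene gets one multiplicative capture-efficiency factor
    (Gamma with mean 1, CV² = 1/dispersion) shared across all libraries,
    then per-library counts are Poisson around library_size-normalised
    means.  Marginally the counts are negative binomial with the
    configured dispersion; because the factor is shared between the
    libraries being compared, it cancels in between-library contrasts,
    emulating stable per-fragment capture bias rather than independent
    library noise.
    """
    rng = _rng(cfg.seed, "seq")
    capture = rng.gamma(shape=cfg.dispersion, scale=1.0 / cfg.dispersion, size=len(lengths))
    columns = {}
    lib_sizes = {}
    for cond in SEQ_CONDITIONS:
        for fraction in ("input", "enriched"):
            weight = lengths.astype(float) * capture
            if fraction == "enriched":
                weight = weight * meth[cond].to_numpy()
            mu = cfg.library_size * weight / weight.sum()
            counts = rng.poisson(mu)
            name = f"{cond}:{fraction}"
            columns[name] = counts
            lib_sizes[name] = int(counts.sum())
    df = pd.DataFrame(columns, index=list(meth.index))
    return CountMatrix(counts=df, library_sizes=pd.Series(lib_sizes))


def _draw_array_scores(
    cfg: SimulationConfig, meth: pd.DataFrame
) -> dict[str, list[ArrayReplicateScores]]:
    """Scores on the −log10 P scale: signal 4 × methylation level + noise.

    A fully methylated gene sits near score 4 (clearly past the >2
    cutoff), an unmethylated one near 0; replicate noise makes genes near
    the cutoff flicker between replicates, which is what the 2-of-3
    concordance rule absorbs.
    """
    rng = _rng(cfg.seed, "array")
    out: dict[str, list[ArrayReplicateScores]] = {}
    for cond in SEQ_CONDITIONS:
        signal = 4.0 * meth[cond].to_numpy()
        noise = rng.normal(0.0, cfg.array_noise_sd, size=(len(signal), cfg.replicate_count))
        scores = np.clip(signal[:, None] + noise, 0.0, None)
        out[cond] = [
            ArrayReplicateScores(g, tuple(float(s) for s in row))
            for g, row in zip(meth.index, scores)
        ]
    return out


def _draw_ct_tables(cfg: SimulationConfig) -> dict[str, list[CtRecord]]:
    """Spike-in QC and mRNA panels as Ct tables from log2 abundances."""
    rng = _rng(cfg.seed, "qpcr")
    noise = 0.15
    tables: dict[str, list[CtRecord]] = {}

    # spike-in: methylated and unmethylated lambda amplicons; the enriched
    # fraction recovers the methylated species cfg.spike_fold times better
    spike: list[CtRecord] = []
    base_ct = 25.0
    for rep in range(3):
        sid = f"rep{rep + 1}"
        spike.append(CtRecord(sid, "lambda_meth", base_ct + rng.normal(0, noise), "spike_methylated", "input"))
        spike.append(CtRecord(sid, "lambda_unmeth", base_ct + rng.normal(0, noise), "spike_unmethylated", "input"))
        # recovery r for either species maps abundance a -> a*r, Ct -> Ct - log2 r
        r_meth, r_unmeth = 0.5 * cfg.spike_fold, 0.5
        spike.append(CtRecord(sid, "lambda_meth", base_ct - np.log2(r_meth) + rng.normal(0, noise), "spike_methylated", "enriched"))
        spike.append(CtRecord(sid, "lambda_unmeth", base_ct - np.log2(r_unmeth) + rng.normal(0, noise), "spike_unmethylated", "enriched"))
    tables["spike"] = spike

    # mRNA panel: knockdown reduces the regulator ~4-fold; reference genes flat
    mrna: list[CtRecord] = []
    for sample, sirt1_fold in (("kd", 0.25), ("control", 1.0)):
        for rep in range(3):
            mrna.append(CtRecord(sample, "SIRT1", 24.0 - np.log2(sirt1_fold) + rng.normal(0, noise)))
            mrna.append(CtRecord(sample, "GAPDH", 18.0 + rng.normal(0, noise), "reference"))
            mrna.append(CtRecord(sample, "TOP1", 21.0 + rng.normal(0, noise), "reference"))
    tables["mrna"] = mrna
    return tables


def simulate_truth_sets(cfg: SimulationConfig) -> tuple[list[str], dict[str, set[str]], set[str], set[str]]:
    """Gene ids, PCGT sets, and planted positive/negative classes only.

    Lightweight path for calibration studies that need many universes but
    no count, array or Ct layers.
    """
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    pcgt_sets = _make_pcgt_sets(cfg, gene_ids)
    pos, neg = _draw_truth(cfg, gene_ids, pcgt_sets["pcgt_any"])
    return gene_ids, pcgt_sets, pos, neg


def simulate_experiment(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic experiment from one seed."""
    n_pcgt = max(4, round(cfg.pcgt_fraction * cfg.n_genes))
    if cfg.enrichment_odds > 0 and cfg.n_responsive > 0:
        mean_overlap = stats.nchypergeom_fisher.mean(
            cfg.n_genes, n_pcgt, cfg.n_responsive, cfg.enrichment_odds
        )
        if mean_overlap > 0.98 * min(n_pcgt, cfg.n_responsive):
            raise ValueError("infeasible config: planted bias exhausts the PCGT pool")

    models = _make_gene_models(cfg)
    gene_ids = [m.gene_id for m in models]
    pcgt_sets = _make_pcgt_sets(cfg, gene_ids)
    truth_pos, truth_neg = _draw_truth(cfg, gene_ids, pcgt_sets["pcgt_any"])
    meth = _condition_methylation(cfg, gene_ids, truth_pos, truth_neg)
    lengths = np.array([m.body_end - m.body_start for m in models])
    seq_counts = _draw_counts(cfg, meth, lengths)
    array_scores = _draw_array_scores(cfg, meth)
    ct_tables = _draw_ct_tables(cfg)
    return SyntheticDataset(
        config=cfg,
        gene_models=models,
        pcgt_sets=pcgt_sets,
        truth_positive=truth_pos,
        truth_negative=truth_neg,
        methylation=meth,
        seq_counts=seq_counts,
        array_scores=array_scores,
        ct_tables=ct_tables,
    )
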