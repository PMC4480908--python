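"""End-to-end orchestration: calls → response classes → enrichment report.

Two entry points.  :func:`analyse_dataset` runs the analysis chain on an
in-memory :class:`~methylshift.simulate.SyntheticDataset` (or anything
shaped like one) and is what the recovery harness and the CLI's
``run-all`` use.  :func:`run_pipeline` is the file-based variant driven by
a :class:`PipelineConfig`: it loads annotation, counts, array scores and
gene sets from disk, runs the same chain, and writes response lists, an
enrichment table, a cross-list overlap report and a reproducibility
manifest.

Every reported P value is accompanied by the universe size N used for the
test; the default universe is all genes the calling stage actually scored.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .diff_methylation import (
    ArrayPeakConfig,
    call_array_peaks,
    call_diffmeth_seq,
    score_presence_absence,
)
from .enrichment import (
    EnrichmentResult,
    cross_list_overlap,
    gene_set_enrichment,
    read_gene_list,
    read_gmt,
)
from .genomic_features import CountMatrix, read_gene_models
from .response import ResponseSets, classify_response
from .simulate import SEQ_CONDITIONS, SimulationConfig, SyntheticDataset, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "RecoveryReport",
    "analyse_dataset",
    "end_to_end_recovery",
    "run_pipeline",
]


@dataclass
class AnalysisResult:
    """Response sets per arm plus the enrichment and overlap reports."""

    seq_response: ResponseSets
    array_response: ResponseSets
    table1: pd.DataFrame
    fig2: pd.DataFrame
    universe_size: int


def _enrichment_row(name: str, arm: str, klass: str, res: EnrichmentResult) -> dict:
    return {
        "target_set": name,
        "arm": arm,
        "response_class": klass,
        "query_size": res.size_query,
        "target_size": res.size_target,
        "observed": res.observed,
        "expected": res.expected,
        "rf": res.rf,
        "chi2": res.chi2,
        "p_chi2": res.p_chi2,
        "p_exact": res.p_exact,
        "universe_n": res.universe_size,
        "warnings": ";".join(res.warnings),
    }


def _seq_direction_sets(
    counts: CountMatrix,
    cond_a: Sequence[str],
    cond_b: Sequence[str],
    alpha: float,
) -> tuple[set[str], set[str]]:
    """(hyper-in-a, hypo-in-a) gene sets from the pooled sequencing caller."""
    calls = call_diffmeth_seq(counts, cond_a, cond_b, alpha=alpha)
    hyper = {c.gene_id for c in calls if c.direction == "hyper"}
    hypo = {c.gene_id for c in calls if c.direction == "hypo"}
    return hyper, hypo


def _array_response(
    ds: SyntheticDataset,
    peak_cfg: ArrayPeakConfig,
    sirna_combine: str,
) -> ResponseSets:
    enriched = {cond: call_array_peaks(ds.array_scores[cond], peak_cfg) for cond in SEQ_CONDITIONS}
    if sirna_combine == "union":
        kd = enriched["kd_siRNA1"] | enriched["kd_siRNA2"]
    elif sirna_combine == "intersection":
        kd = enriched["kd_siRNA1"] & enriched["kd_siRNA2"]
    else:
        raise ValueError(f"unknown sirna_combine {sirna_combine!r}")
    hypo_kd, hyper_kd, _ = score_presence_absence(enriched["kd_control"], kd)
    hypo_oe, hyper_oe, _ = score_presence_absence(enriched["oe_control"], enriched["oe"])
    return classify_response(hypo_kd=hypo_kd, hyper_kd=hyper_kd, hyper_oe=hyper_oe, hypo_oe=hypo_oe)


def analyse_dataset(
    ds: SyntheticDataset,
    alpha: float = 0.05,
    peak_cfg: ArrayPeakConfig | None = None,
    sirna_combine: str = "union",
) -> AnalysisResult:
    """Run calls, classification and enrichment on a simulated experiment.

    The sequencing arm pools the two knockdown siRNA libraries against the
    control; the array arm combines the two siRNA enriched lists by union
    (or intersection).  Enrichment of each response class against every
    PCGT set is tested in the universe of all annotated genes.
    """
    peak_cfg = peak_cfg or ArrayPeakConfig(replicate_count=ds.config.replicate_count)
    universe = ds.universe

    hyper_kd, hypo_kd = _seq_direction_sets(
        ds.seq_counts, ["kd_siRNA1:enriched", "kd_siRNA2:enriched"], ["kd_control:enriched"], alpha
    )
    hyper_oe, hypo_oe = _seq_direction_sets(
        ds.seq_counts, ["oe:enriched"], ["oe_control:enriched"], alpha
    )
    seq_response = classify_response(
        hypo_kd=hypo_kd, hyper_kd=hyper_kd, hyper_oe=hyper_oe, hypo_oe=hypo_oe
    )
    array_response = _array_response(ds, peak_cfg, sirna_combine)

    rows = []
    queries = {
        ("seq", "positive"): seq_response.positive,
        ("seq", "negative"): seq_response.negative,
        ("array", "positive"): array_response.positive,
        ("array", "negative"): array_response.negative,
    }
    for set_name, target in ds.pcgt_sets.items():
        for (arm, klass), query in queries.items():
            if not query:
                logger.warning("empty %s %s response set: enrichment skipped", arm, klass)
                continue
            res = gene_set_enrichment(query, target, universe)
            rows.append(_enrichment_row(set_name, arm, klass, res))
    table1 = pd.DataFrame(rows)

    fig2_rows = []
    for klass in ("positive", "negative"):
        a, b = queries[("seq", klass)], queries[("array", klass)]
        if a and b:
            res = cross_list_overlap(a, b, len(universe))
            fig2_rows.append(
                {
                    "response_class": klass,
                    "size_seq": len(a),
                    "size_array": len(b),
                    "observed": res.observed,
                    "expected": res.expected,
                    "rf": res.rf,
                    "chi2": res.chi2,
                    "p_chi2": res.p_chi2,
                    "p_exact": res.p_exact,
                    "universe_n": res.universe_size,
                }
            )
    fig2 = pd.DataFrame(fig2_rows)
    return AnalysisResult(
        seq_response=seq_response,
        array_response=array_response,
        table1=table1,
        fig2=fig2,
        universe_size=len(universe),
    )


@dataclass
class RecoveryReport:
    """Planted vs recovered quantities for one simulated experiment."""

    analysis: AnalysisResult
    planted_rf: float
    estimated_rf: float
    rf_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    direction_accuracy: float

    def summary(self) -> dict:
        return {
            "planted_rf": self.planted_rf,
            "estimated_rf": self.estimated_rf,
            "rf_ci_low": self.rf_ci[0],
            "rf_ci_high": self.rf_ci[1],
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "direction_accuracy": self.direction_accuracy,
        }


def end_to_end_recovery(cfg: SimulationConfig, alpha: float = 0.05) -> RecoveryReport:
    """simulate → call → classify → enrich, scored against the planted truth.

    Sensitivity/specificity are for sequencing-arm detection of responsive
    genes (either class); direction accuracy is the fraction of detected
    truly-responsive genes put in their planted class.  The planted and
    estimated RFs refer to the PCGT-any set in the full gene universe.
    """
    ds = simulate_experiment(cfg)
    analysis = analyse_dataset(ds, alpha=alpha)
    universe = ds.universe
    pcgt = ds.pcgt_sets["pcgt_any"]

    truth = ds.truth_responsive
    detected = analysis.seq_response.positive | analysis.seq_response.negative
    tp = len(detected & truth)
    sensitivity = tp / len(truth) if truth else float("nan")
    fp = len(detected - truth)
    negatives = len(universe) - len(truth)
    specificity = 1.0 - fp / negatives if negatives else float("nan")
    correct_dir = len(analysis.seq_response.positive & ds.truth_positive) + len(
        analysis.seq_response.negative & ds.truth_negative
    )
    direction_accuracy = correct_dir / tp if tp else float("nan")

    planted = gene_set_enrichment(truth, pcgt, universe) if truth else None
    estimated = gene_set_enrichment(detected, pcgt, universe) if detected else None
    return RecoveryReport(
        analysis=analysis,
        planted_rf=planted.rf if planted else float("nan"),
        estimated_rf=estimated.rf if estimated else float("nan"),
        rf_ci=estimated.rf_ci if estimated else (float("nan"), float("nan")),
        sensitivity=sensitivity,
        specificity=specificity,
        direction_accuracy=direction_accuracy,
    )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (YAML key-value, schema v1).

    ``universe_policy`` is either ``annotation_all`` (background = every
    gene in the annotation) or ``explicit_list`` (background read from
    ``universe_path``).
    """

    annotation_path: str
    counts_path: str
    gene_sets_path: str
    output_dir: str
    universe_policy: str = "annotation_all"
    universe_path: str | None = None
    window_bp: int = 2000
    alpha: float = 0.05
    min_replicates: int = 2
    score_cutoff: float = 2.0
    replicate_count: int = 3
    kd_samples: list[str] = field(default_factory=lambda: ["kd_siRNA1:enriched", "kd_siRNA2:enriched"])
    kd_control_samples: list[str] = field(default_factory=lambda: ["kd_control:enriched"])
    oe_samples: list[str] = field(default_factory=lambda: ["oe:enriched"])
    oe_control_samples: list[str] = field(default_factory=lambda: ["oe_control:enriched"])
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.annotation_path, self.counts_path, self.gene_sets_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"pipeline input missing: {p}")
        if self.universe_policy not in ("annotation_all", "explicit_list"):
            raise ValueError(f"unknown universe_policy {self.universe_policy!r}")
        if self.universe_policy == "explicit_list":
            if not self.universe_path or not Path(self.universe_path).exists():
                raise FileNotFoundError("universe_policy=explicit_list requires universe_path")


def _write_gene_list(genes: set[str], path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the file-based chain and write the report bundle.

    Emits response gene lists, an enrichment table over the supplied gene
    sets, a cross-arm overlap report when both arms are present, and a
    manifest recording versions, seed and parameters.  Any stage failure
    aborts with the stage named.
    """
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "annotation"
    try:
        models = read_gene_models(cfg.annotation_path)
        stage = "counts"
        counts = CountMatrix.from_tsv(cfg.counts_path)
        stage = "universe"
        if cfg.universe_policy == "explicit_list":
            universe = read_gene_list(cfg.universe_path)
        else:
            universe = {m.gene_id for m in models} & set(counts.gene_ids)
        stage = "call-seq"
        hyper_kd, hypo_kd = _seq_direction_sets(
            counts, cfg.kd_samples, cfg.kd_control_samples, cfg.alpha
        )
        have_oe = all(s in counts.counts.columns for s in cfg.oe_samples + cfg.oe_control_samples)
        if have_oe:
            hyper_oe, hypo_oe = _seq_direction_sets(
                counts, cfg.oe_samples, cfg.oe_control_samples, cfg.alpha
            )
        else:
            hyper_oe, hypo_oe = set(), set()
        stage = "classify"
        response = classify_response(
            hypo_kd=hypo_kd & universe,
            hyper_kd=hyper_kd & universe,
            hyper_oe=hyper_oe & universe,
            hypo_oe=hypo_oe & universe,
        )
        stage = "enrich"
        gene_sets = read_gmt(cfg.gene_sets_path)
        rows = []
        for set_name, target in gene_sets.items():
            for klass, query in (("positive", response.positive), ("negative", response.negative)):
                if not query:
                    continue
                res = gene_set_enrichment(query, target, universe)
                rows.append(_enrichment_row(set_name, "seq", klass, res))
        table = pd.DataFrame(rows)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_gene_list(response.positive, outdir / "response_positive.txt")
    _write_gene_list(response.negative, outdir / "response_negative.txt")
    _write_gene_list(response.conflicted, outdir / "response_conflicted.txt")
    table.to_csv(outdir / "enrichment_table.tsv", sep="\t", index=False, float_format="%.6g")
    manifest = {
        "package": "methylshift",
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(cfg),
        "universe_n": len(universe),
        "n_positive": len(response.positive),
        "n_negative": len(response.negative),
        "n_conflicted": len(response.conflicted),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
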