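"""Threshold-cycle (Ct) arithmetic and group comparison for qPCR data.

Covers three tasks: relative mRNA quantification by the ΔΔCt method
(fold = 2^(−ΔΔCt), amplification efficiency fixed at 2), fold-enrichment
of a methylated vs unmethylated species in an immunoprecipitation
(spike-in QC), and the one-way ANOVA + Dunnett many-to-one comparison
used for treated-vs-control expression panels.

Reference correction uses the arithmetic mean of the reference-gene Cts,
which on the linear scale is the geometric mean of the reference
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "FoldChange",
    "DunnettResult",
    "delta_delta_ct",
    "spikein_fold_enrichment",
    "anova_dunnett",
    "read_ct_table",
]

_ROLES = ("target", "reference", "spike_methylated", "spike_unmethylated")
_FRACTIONS = ("input", "enriched")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: sample, amplicon, threshold cycle, role."""

    sample_id: str
    target: str
    ct: float
    role: str = "target"
    fraction: str = "input"

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct):
            raise ValueError(f"{self.sample_id}/{self.target}: non-finite Ct")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.fraction not in _FRACTIONS:
            raise ValueError(f"unknown fraction {self.fraction!r}")


@dataclass(frozen=True)
class FoldChange:
    """Relative quantity of a target in treated vs control samples."""

    target: str
    fold: float
    delta_delta_ct: float

    def __post_init__(self) -> None:
        if not np.isclose(self.fold, 2.0 ** (-self.delta_delta_ct)):
            raise ValueError("fold must equal 2^(-ddCt)")


def _mean_ct(records: Sequence[CtRecord], sample: str, target: str) -> float:
    cts = [r.ct for r in records if r.sample_id == sample and r.target == target]
    if not cts:
        raise ValueError(f"no Ct measurement for sample {sample!r}, target {target!r}")
    return float(np.mean(cts))


def delta_delta_ct(
    records: Sequence[CtRecord],
    reference_targets: Sequence[str],
    treated: str,
    control: str,
) -> dict[str, FoldChange]:
    """ΔΔCt relative quantification for every non-reference target.

    ΔCt(sample) = Ct_target − mean(Ct of reference targets);
    ΔΔCt = ΔCt(treated) − ΔCt(control); fold = 2^(−ΔΔCt).
    Replicate Cts are averaged before differencing.  A missing reference
    measurement raises, naming the sample and target.
    """
    if not reference_targets:
        raise ValueError("need at least one reference target")
    targets = sorted(
        {r.target for r in records if r.target not in set(reference_targets)}
    )
    out: dict[str, FoldChange] = {}
    for sample in (treated, control):
        for ref in reference_targets:
            _mean_ct(records, sample, ref)  # raises early with a clear name
    for target in targets:
        d_ct = {}
        for sample in (treated, control):
            ref_mean = float(np.mean([_mean_ct(records, sample, ref) for ref in reference_targets]))
            d_ct[sample] = _mean_ct(records, sample, target) - ref_mean
        ddct = d_ct[treated] - d_ct[control]
        out[target] = FoldChange(target=target, fold=2.0 ** (-ddct), delta_delta_ct=ddct)
    return out


def spikein_fold_enrichment(
    ct_input_meth: float,
    ct_ip_meth: float,
    ct_input_unmeth: float,
    ct_ip_unmeth: float,
) -> float:
    """Fold preference of the immunoprecipitation for the methylated species.

    fold = 2^(Ct_input,meth − Ct_IP,meth) / 2^(Ct_input,unmeth − Ct_IP,unmeth).
    The same arithmetic serves endogenous hyper- vs hypomethylated locus
    pairs.  Invariant under adding a constant to all four Cts.
    """
    return 2.0 ** ((ct_input_meth - ct_ip_meth) - (ct_input_unmeth - ct_ip_unmeth))


@dataclass
class DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparisons against control."""

    f_stat: float
    p_anova: float
    t_stats: np.ndarray          # one per non-control group, in input order
    p_unadjusted: np.ndarray     # two-sided t, pooled variance
    p_adjusted: np.ndarray       # max-|t| family-wise adjusted
    group_indices: list[int]     # non-control group positions


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    n_mc: int = 20000,
    rng: np.random.Generator | int | None = 0,
) -> DunnettResult:
    """One-way ANOVA then Dunnett's test of each group against the control.

    Adjusted p values come from the null distribution of the maximum
    absolute t statistic across comparisons, estimated by ``n_mc`` Monte
    Carlo draws under equal-variance normality with the observed group
    sizes.  The draw is seeded (``rng``) and therefore reproducible.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    if not (0 <= control_index < len(groups)):
        raise ValueError("control_index out of range")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    sizes = np.array([len(g) for g in groups])
    n_total, k = int(sizes.sum()), len(groups)
    df = n_total - k
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ss_within == 0.0:
        raise ValueError("zero within-group variance everywhere: t statistics undefined")
    s2 = ss_within / df

    f_stat, p_anova = stats.f_oneway(*groups)

    ctrl = groups[control_index]
    others = [i for i in range(k) if i != control_index]
    se = np.sqrt(s2 * (1.0 / sizes[others] + 1.0 / sizes[control_index]))
    t_obs = np.array([groups[i].mean() - ctrl.mean() for i in others]) / se
    p_unadj = 2.0 * stats.t.sf(np.abs(t_obs), df)

    # Monte Carlo null of max |t|: simulate all groups standard normal at the
    # observed sizes, recompute the pooled-variance t statistics each draw
    max_abs_t = _simulate_max_abs_t(sizes, control_index, n_mc, rng)
    p_adj = np.array([(np.sum(max_abs_t >= abs(t)) + 1) / (n_mc + 1) for t in t_obs])
    # family-wise adjustment can never be more liberal than the raw t test
    p_adj = np.maximum(p_adj, p_unadj)

    return DunnettResult(
        f_stat=float(f_stat),
        p_anova=float(p_anova),
        t_stats=t_obs,
        p_unadjusted=p_unadj,
        p_adjusted=p_adj,
        group_indices=others,
    )


def _simulate_max_abs_t(
    sizes: np.ndarray, control_index: int, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Null draws of max |t| over many-to-one comparisons, vectorised."""
    k = len(sizes)
    df = int(sizes.sum()) - k
    others = [i for i in range(k) if i != control_index]

    means = np.empty((n_mc, k))
    ss = np.zeros(n_mc)
    for i, n_i in enumerate(sizes):
        x = rng.standard_normal((n_mc, int(n_i)))
        means[:, i] = x.mean(axis=1)
        ss += ((x - means[:, [i]]) ** 2).sum(axis=1)
    s2 = ss / df
    se = np.sqrt(s2[:, None] * (1.0 / sizes[others] + 1.0 / sizes[control_index]))
    t = (means[:, others] - means[:, [control_index]]) / se
    return np.abs(t).max(axis=1)


def read_ct_table(path) -> list[CtRecord]:
    """Read Ct records from a sample, target, role, fraction, ct TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target", "role", "fraction", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return [
        CtRecord(
            sample_id=str(r.sample_id),
            target=str(r.target),
            ct=float(r.ct),
            role=str(r.role),
            fraction=str(r.fraction),
        )
        for r in df.itertuples()
    ]


def write_ct_table(records: Iterable[CtRecord], path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.target, r.role, r.fraction, r.ct) for r in records],
        columns=["sample_id", "target", "role", "fraction", "ct"],
    ).to_csv(path, sep="\t", index=False)
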