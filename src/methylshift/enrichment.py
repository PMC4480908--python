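"""Gene-list overlap statistics.

The central quantity is the representation factor (RF): the ratio of the
observed size of the intersection of two gene lists to the size expected
by chance, |A|·|B|/N, in a background ("universe") of N genes.
Significance is assessed with the chi-square test on the 2×2 contingency
table with Yates' continuity correction, the convention used for
published RF tables in this domain; a two-sided exact hypergeometric test
is computed alongside as an oracle and is reported automatically whenever
any expected cell drops below 5.

The universe N is a mandatory explicit parameter of every call: published
overlap P values are sensitive to it, and no default could be defended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "yates_chi_square",
    "exact_overlap_p",
    "representation_factor",
    "overlap_enrichment",
    "gene_set_enrichment",
    "combine_gene_sets",
    "cross_list_overlap",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 table of gene counts: a = in both lists, b = query only,
    c = target only, d = in neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], dtype=float) / self.n


@dataclass
class EnrichmentResult:
    """Full over-representation report for one query/target pair.

    ``rf * expected == observed`` exactly; ``rf_ci`` is a 95% interval for
    the RF from a Clopper–Pearson interval on the overlap fraction of the
    query (binomial approximation to the hypergeometric draw).
    """

    observed: int
    expected: float
    rf: float
    chi2: float
    p_chi2: float
    p_exact: float
    universe_size: int
    size_query: int
    size_target: int
    rf_ci: tuple[float, float] = (float("nan"), float("nan"))
    warnings: list[str] = field(default_factory=list)


def yates_chi_square(t: ContingencyTable) -> tuple[float, float]:
    """Chi-square statistic with Yates' continuity correction, df = 1.

    chi2 = n·(max(0, |ad − bc| − n/2))² / ((a+b)(c+d)(a+c)(b+d)); the
    correction is floored so a table at exact independence gives chi2 = 0,
    p = 1.  Zero margins are an error (use the exact test instead).
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: chi-square undefined, use exact_overlap_p")
    num = max(0.0, abs(t.a * t.d - t.b * t.c) - t.n / 2.0)
    chi2 = t.n * num * num / (float(r1) * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def exact_overlap_p(t: ContingencyTable, method: str = "minlike") -> float:
    """Two-sided exact P for the table by hypergeometric summation.

    With margins fixed, the overlap count follows a hypergeometric
    distribution; ``minlike`` (default) sums the probabilities of all
    tables no more likely than the observed one (Fisher's exact
    convention), ``doubling`` doubles the smaller tail.
    """
    n, k_query, k_target = t.n, t.a + t.b, t.a + t.c
    h = stats.hypergeom(n, k_target, k_query)
    support = np.arange(max(0, k_query + k_target - n), min(k_query, k_target) + 1)
    pmf = h.pmf(support)
    p_obs = h.pmf(t.a)
    if method == "minlike":
        # tolerance guards against ties broken by floating-point noise
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif method == "doubling":
        upper = float(h.sf(t.a - 1))
        lower = float(h.cdf(t.a))
        p = 2.0 * min(upper, lower)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(1.0, p)


def representation_factor(
    observed: int, size_a: int, size_b: int, universe_size: int
) -> tuple[float, float]:
    """(expected, rf) for an overlap of ``observed`` genes.

    expected = |A|·|B|/N; rf = observed / expected.
    """
    if observed > min(size_a, size_b):
        raise ValueError("observed overlap exceeds the smaller list")
    if max(size_a, size_b) > universe_size:
        raise ValueError("list larger than the universe")
    if universe_size < size_a + size_b - observed:
        raise ValueError("impossible configuration: lists cannot fit in the universe")
    expected = size_a * size_b / universe_size
    rf = observed / expected if expected > 0 else float("nan")
    return expected, rf


def _rf_confidence_interval(
    observed: int, size_a: int, size_b: int, universe_size: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson interval on observed/|A|, rescaled to the RF axis."""
    if size_a == 0:
        return (float("nan"), float("nan"))
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, observed, size_a - observed + 1) if observed > 0 else 0.0
    hi = (
        stats.beta.ppf(1 - alpha / 2, observed + 1, size_a - observed)
        if observed < size_a
        else 1.0
    )
    scale = size_b / universe_size
    return (float(lo) / scale, float(hi) / scale)


def overlap_enrichment(
    observed: int, size_a: int, size_b: int, universe_size: int
) -> EnrichmentResult:
    """Full enrichment report from overlap counts alone."""
    expected, rf = representation_factor(observed, size_a, size_b, universe_size)
    t = ContingencyTable(
        a=observed,
        b=size_a - observed,
        c=size_b - observed,
        d=universe_size - size_a - size_b + observed,
    )
    warnings: list[str] = []
    p_exact = exact_overlap_p(t)
    try:
        chi2, p_chi2 = yates_chi_square(t)
    except ValueError:
        chi2, p_chi2 = float("nan"), float("nan")
        warnings.append("zero margin: chi-square unavailable, use the exact P")
    if (t.expected() < 5).any():
        warnings.append("expected cell < 5: chi-square approximation unreliable, exact P reported")
    return EnrichmentResult(
        observed=observed,
        expected=expected,
        rf=rf,
        chi2=chi2,
        p_chi2=p_chi2,
        p_exact=p_exact,
        universe_size=universe_size,
        size_query=size_a,
        size_target=size_b,
        rf_ci=_rf_confidence_interval(observed, size_a, size_b, universe_size),
        warnings=warnings,
    )


def gene_set_enrichment(
    query: set[str], target: set[str], universe: set[str]
) -> EnrichmentResult:
    """Over-representation of ``target`` genes within ``query``.

    The query must lie inside the universe; the target is intersected with
    the universe before testing (genes outside the background cannot
    contribute to either cell of the table).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    stray = set(query) - set(universe)
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    target_in = set(target) & set(universe)
    observed = len(set(query) & target_in)
    return overlap_enrichment(observed, len(query), len(target_in), len(universe))


def cross_list_overlap(
    list_a: set[str], list_b: set[str], universe_size: int
) -> EnrichmentResult:
    """Enrichment of the overlap of two gene lists in an explicit universe.

    Used for cross-cell-line intersections where the shared background is
    known only by size.
    """
    return overlap_enrichment(len(set(list_a) & set(list_b)), len(set(list_a)), len(set(list_b)), universe_size)


def combine_gene_sets(sets: Sequence[set[str]], mode: str) -> set[str]:
    """Intersection ('all') or union ('at_least_one') of gene sets."""
    if not sets:
        raise ValueError("need at least one gene set")
    if mode == "all":
        out = set(sets[0])
        for s in sets[1:]:
            out &= set(s)
        return out
    if mode == "at_least_one":
        out = set()
        for s in sets:
            out |= set(s)
        return out
    raise ValueError(f"unknown mode {mode!r}; expected 'all' or 'at_least_one'")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >= 1 member")
            sets[fields[0]] = set(fields[2:]) - {""}
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
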