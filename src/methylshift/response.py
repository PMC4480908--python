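"""Directional response classification.

A gene has a *positive* methylation response to the regulator when it
loses methylation under knockdown and/or gains methylation under
overexpression; the opposite pattern is a *negative* response.  Genes with
evidence in both directions are *conflicted* and excluded from both
classes so that downstream over-representation inputs stay disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

__all__ = ["ResponseSets", "classify_response"]

_EVIDENCE_TAGS = ("hypo_kd", "hyper_oe", "hyper_kd", "hypo_oe")


@dataclass
class ResponseSets:
    """Disjoint positive / negative / conflicted gene sets with provenance."""

    positive: set[str]
    negative: set[str]
    conflicted: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive & self.negative or self.conflicted & (self.positive | self.negative):
            raise ValueError("positive, negative and conflicted sets must be pairwise disjoint")


def classify_response(
    hypo_kd: set[str],
    hyper_kd: set[str],
    hyper_oe: set[str] = frozenset(),
    hypo_oe: set[str] = frozenset(),
) -> ResponseSets:
    """Combine knockdown and overexpression calls into response classes.

    positive = (hypo_kd ∪ hyper_oe) minus conflicts;
    negative = (hyper_kd ∪ hypo_oe) minus conflicts;
    conflicted = genes with evidence in both directions.

    The overexpression sets may be empty (knockdown-only design).  A gene
    called both hypo and hyper within one arm is impossible output from a
    single caller and raises.
    """
    hypo_kd, hyper_kd = set(hypo_kd), set(hyper_kd)
    hyper_oe, hypo_oe = set(hyper_oe), set(hypo_oe)

    bad_kd = hypo_kd & hyper_kd
    if bad_kd:
        raise ValueError(f"corrupt input: genes both hypo and hyper in knockdown arm: {sorted(bad_kd)[:5]}")
    bad_oe = hypo_oe & hyper_oe
    if bad_oe:
        raise ValueError(f"corrupt input: genes both hypo and hyper in overexpression arm: {sorted(bad_oe)[:5]}")

    pos_evidence = hypo_kd | hyper_oe
    neg_evidence = hyper_kd | hypo_oe
    conflicted = pos_evidence & neg_evidence
    positive = pos_evidence - conflicted
    negative = neg_evidence - conflicted

    provenance: dict[str, set[str]] = {}
    for tag, genes in zip(_EVIDENCE_TAGS, (hypo_kd, hyper_oe, hyper_kd, hypo_oe)):
        for g in genes:
            provenance.setdefault(g, set()).add(tag)

    if conflicted:
        logger.info("classify_response: %d conflicted genes excluded from both classes", len(conflicted))
    return ResponseSets(positive=positive, negative=negative, conflicted=conflicted, provenance=provenance)
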