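"""Glue: match-set reduction dispatch and ready-made match-set providers."""

from __future__ import annotations

from functools import lru_cache
from typing import Callable

from .genome_io import Genome
from .matchset import (
    DEFAULT_EVALUE_THRESHOLD,
    DirectedMatchSet,
    filter_by_evalue,
    find_exact_matches,
)
from .trimming import TrimmedMatchSet, coverage_reduce, greedy_trim

__all__ = ["reduce_match_set", "internal_matcher_provider"]


def reduce_match_set(match_set: DirectedMatchSet, spec) -> TrimmedMatchSet:
    """Apply the e-value filter (if requested) and the spec's reduction."""
    ms = match_set
    if spec.evalue_filter:
        ms = filter_by_evalue(ms, DEFAULT_EVALUE_THRESHOLD)
    if spec.reduction == "trim":
        return greedy_trim(ms)
    return coverage_reduce(ms)


def internal_matcher_provider(
    min_length: int = 20,
) -> Callable[[Genome, Genome], DirectedMatchSet]:
    """Provider computing directed match sets with the built-in exact matcher."""

    def provider(query: Genome, subject: Genome) -> DirectedMatchSet:
        return find_exact_matches(query, subject, min_length)

    return provider
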