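"""One-to-one gene → probe-set selection from scored probe sets."""

from __future__ import annotations

from collections import defaultdict

from .core import GeneMapping, MappingRow, ProbeSetScores

__all__ = ["best_probeset_per_gene", "lookup"]


def best_probeset_per_gene(scores: list[ProbeSetScores]) -> GeneMapping:
    """Select, per targeted gene, the probe set with the highest overall score.

    Ties on the overall score fall back to higher robustness (empirically
    the component that drives selection), then higher specificity, then the
    lexicographically smallest probe-set id, and are flagged ``tie_broken``.
    Probe sets without a targeted gene are ignored; genes never targeted are
    absent from the mapping.  Genes whose best overall score is zero are
    still mapped, carrying that zero so users can filter — no absolute score
    cutoff is imposed.
    """
    by_gene: dict[str, list[ProbeSetScores]] = defaultdict(list)
    for s in scores:
        if s.targeted_gene is not None:
            by_gene[s.targeted_gene].append(s)
    rows = []
    for gene in sorted(by_gene):
        candidates = sorted(
            by_gene[gene],
            key=lambda s: (-s.overall, -s.robustness, -s.specificity, s.probeset_id),
        )
        winner = candidates[0]
        tied = sum(1 for s in candidates if s.overall == winner.overall) > 1
        rows.append(
            MappingRow(
                gene_id=gene,
                probeset_id=winner.probeset_id,
                overall_score=winner.overall,
                tie_broken=tied,
            )
        )
    return GeneMapping(rows=tuple(rows))


def lookup(mapping: GeneMapping, gene_id: str) -> str | None:
    """Probe-set id representing ``gene_id``, or None if the gene is unmapped."""
    return mapping.lookup(gene_id)
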