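"""Hub acupoint identification and prescription assembly.

A hub is a node that is jointly central by strength and betweenness.  The
combined score is the equal-weight mean of the min-max-normalized strength
and betweenness columns; a field with zero range contributes 0.5 to every
node.  Hubs are either the best-scoring node of each community (default)
or the global top-k.  The final prescription is the deduplicated sorted
union of the computed hubs with a configured supplementary point list —
the supplementary points come from expert (Delphi) elicitation and are
shipped as configuration, not computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .corpus import is_valid_code, normalize_code
from .errors import ValidationError
from .metrics import CommunityPartition

#: Supplementary acupoints of the published 2021 prescription (expert-elicited).
PAPER2021_SUPPLEMENTARY = ("CV3", "EX-CA1", "KI3", "LR3", "ST36")

HUB_MODES = ("community-center", "top-k")


@dataclass(frozen=True)
class Prescription:
    """Final acupoint prescription: computed hubs plus configured extras."""

    hubs: tuple[str, ...]
    supplementary: tuple[str, ...]
    final_set: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps({"hubs": list(self.hubs),
                           "supplementary": list(self.supplementary),
                           "final_set": list(self.final_set)}, indent=2)

    def to_text(self) -> str:
        return (f"hubs: {', '.join(self.hubs)}\n"
                f"supplementary: {', '.join(self.supplementary)}\n"
                f"prescription ({len(self.final_set)} points): "
                f"{', '.join(self.final_set)}\n")


def _minmax(col: pd.Series) -> pd.Series:
    lo, hi = float(col.min()), float(col.max())
    if hi - lo <= 0:
        return pd.Series(0.5, index=col.index)
    return (col - lo) / (hi - lo)


def hub_scores(centrality: pd.DataFrame) -> pd.Series:
    """Combined centrality score in [0, 1] per node.

    ``centrality`` must carry ``strength`` and one betweenness column
    (``betweenness_norm`` preferred); the score is the mean of the two
    min-max-normalized columns.
    """
    if centrality.empty:
        raise ValidationError("empty centrality table")
    bcol = "betweenness_norm" if "betweenness_norm" in centrality else "betweenness_raw"
    for col in ("strength", bcol):
        if col not in centrality:
            raise ValidationError(f"centrality table lacks column {col!r}")
    score = (_minmax(centrality["strength"]) + _minmax(centrality[bcol])) / 2.0
    return score.rename("hub_score")


def select_hubs(scores: pd.Series, partition: CommunityPartition,
                mode: str = "community-center", k: int = 3) -> list[str]:
    """Pick hub nodes from scores and the community structure.

    ``community-center``: the maximum-score node of each community, ties
    to the lexicographically smaller code.  ``top-k``: the k best-scoring
    nodes overall (same tie rule).  Result sorted by code.
    """
    if set(scores.index) != set(partition.assignment):
        raise ValidationError("scores and partition cover different node sets")
    if mode == "community-center":
        hubs = []
        for comm in partition.communities():
            best = min(comm, key=lambda u: (-scores[u], u))
            hubs.append(best)
        return sorted(hubs)
    if mode == "top-k":
        if k > len(scores):
            raise ValidationError(f"k={k} exceeds node count {len(scores)}")
        ranked = sorted(scores.index, key=lambda u: (-scores[u], u))
        return sorted(ranked[:k])
    raise ValidationError(f"unknown hub mode {mode!r}; expected {HUB_MODES}")


def assemble_prescription(hubs: list[str],
                          supplementary: list[str] = PAPER2021_SUPPLEMENTARY
                          ) -> Prescription:
    """Union the computed hubs with the configured supplementary points."""
    norm_hubs = [normalize_code(h) for h in hubs]
    norm_supp = [normalize_code(s) for s in supplementary]
    for code in norm_hubs + norm_supp:
        if not is_valid_code(code):
            raise ValidationError(f"malformed acupoint code {code!r}")
    final = tuple(sorted(set(norm_hubs) | set(norm_supp)))
    return Prescription(hubs=tuple(sorted(set(norm_hubs))),
                        supplementary=tuple(sorted(set(norm_supp))),
                        final_set=final)
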