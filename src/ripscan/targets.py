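"""Bound-target calling by the boxplot 1.5-IQR outlier rule, and
exclusive / shared (Venn-region) target sets across synthetases.

A gene is called a target when its background-corrected RIP efficiency
lies above the upper whisker of the distribution: ``c > Q3 + k * IQR``
with ``k = 1.5`` and ``IQR = Q3 - Q1`` (boxplot convention).  An
alternative center rule, ``c > mean + k * IQR``, is exposed because the
whisker convention and a mean-anchored reading of "above the average"
are both defensible; quartiles use linear interpolation between order
statistics and the rule parameters are recorded in the output so Venn
counts remain reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "TargetCallParams",
    "TargetSet",
    "call_targets",
    "untagged_outliers",
    "exclusive_targets",
    "shared_targets",
]


@dataclass(frozen=True)
class TargetCallParams:
    """IQR multiplier ``k`` and anchoring rule (``quartile`` or ``mean``)."""

    k: float = 1.5
    center_rule: str = "quartile"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.center_rule not in ("quartile", "mean"):
            raise ValueError(
                f"center_rule must be 'quartile' or 'mean', got {self.center_rule!r}"
            )


@dataclass(frozen=True)
class TargetSet:
    """Genes called bound for one synthetase, with the threshold used."""

    label: str
    members: frozenset[str]
    threshold: float
    params: TargetCallParams


def _threshold(values: np.ndarray, params: TargetCallParams) -> float:
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    anchor = q3 if params.center_rule == "quartile" else float(values.mean())
    return anchor + params.k * iqr


def call_targets(
    c: pd.Series,
    params: TargetCallParams | None = None,
    label: str = "",
) -> TargetSet:
    """Call IQR outliers of the corrected-efficiency distribution.

    Membership requires ``c > threshold`` (strict); at least 4 genes are
    needed for quartiles to be defined.
    """
    params = params or TargetCallParams()
    if len(c) < 4:
        raise ValueError(f"need >= 4 genes to call targets, got {len(c)}")
    thr = _threshold(c.to_numpy(dtype=float), params)
    members = frozenset(c.index[c > thr])
    return TargetSet(label=label, members=members, threshold=thr, params=params)


def untagged_outliers(
    e_untagged: pd.Series, params: TargetCallParams | None = None
) -> frozenset[str]:
    """Genes that are IQR outliers of the untagged (uncorrected) efficiencies.

    Used to exclude bead-sticky transcripts from a called target set:
    a gene that outlies in the untagged control cannot be attributed to
    the tagged protein.
    """
    return call_targets(e_untagged, params, label="untagged").members


def exclusive_targets(sets: dict[str, TargetSet]) -> dict[str, frozenset[str]]:
    """Per-synthetase genes bound by that synthetase and no other."""
    if len(sets) < 2:
        raise ValueError("need >= 2 target sets")
    out = {}
    for label, ts in sets.items():
        others = frozenset().union(
            *(o.members for l, o in sets.items() if l != label)
        )
        out[label] = ts.members - others
    return out


def shared_targets(
    sets: dict[str, TargetSet]
) -> dict[frozenset[str], frozenset[str]]:
    """Venn regions: membership pattern -> genes with exactly that pattern.

    Every gene of the union is assigned to exactly one region (keyed by
    the frozenset of labels whose sets contain it); region sizes sum to
    the union size.  Regions with no genes are included for every
    non-empty combination of labels, so lookups never miss.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 target sets")
    labels = list(sets)
    regions: dict[frozenset[str], set[str]] = {
        frozenset(combo): set()
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    union = set().union(*(ts.members for ts in sets.values()))
    for gene in union:
        pattern = frozenset(l for l in labels if gene in sets[l].members)
        regions[pattern].add(gene)
    return {k: frozenset(v) for k, v in regions.items()}
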