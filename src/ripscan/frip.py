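"""Binding-site localization from tiling-amplicon fRIP signals.

In fragmentation RIP the transcript is mildly RNase-cleaved before
pull-down, so only the fragment carrying the protein-binding site
co-purifies.  The site is then localized by semiquantitative PCR over a
panel of amplicons tiling the coding sequence: per fragment, the ratio
of Bound to Fragmented-Input band intensity (both taken at a common,
unsaturated amplification cycle) peaks at the fragment holding the
site, with a decaying "smear" on the fragments immediately upstream
left by partial cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "design_tiling",
    "select_common_cycle",
    "fragment_enrichment",
    "peak_fragment",
    "PeakReport",
]


def design_tiling(
    cds_length: int, n_fragments: int, product_len: int
) -> pd.DataFrame:
    """Evenly spaced amplicon windows of fixed product length over a CDS.

    Starts are spread over ``[1, cds_length - product_len + 1]`` with
    deterministic half-up rounding.  Coordinates are 1-based from the
    start codon, ends inclusive.  Returns a DataFrame indexed by
    fragment (1..n) with ``start`` and ``end`` columns.
    """
    if n_fragments < 1:
        raise ValueError(f"n_fragments must be >= 1, got {n_fragments}")
    if product_len < 1 or product_len > cds_length:
        raise ValueError(
            f"product_len {product_len} infeasible for CDS of length {cds_length}"
        )
    last_start = cds_length - product_len + 1
    if n_fragments == 1:
        starts = np.array([1])
    else:
        raw = 1 + np.arange(n_fragments) * (last_start - 1) / (n_fragments - 1)
        starts = np.floor(raw + 0.5).astype(int)  # half-up, platform-stable
    panel = pd.DataFrame(
        {"start": starts, "end": starts + product_len - 1},
        index=pd.RangeIndex(1, n_fragments + 1, name="fragment"),
    )
    return panel


def select_common_cycle(
    curves: pd.DataFrame, saturation_level: float
) -> int:
    """Largest PCR cycle at which no fragment's Input intensity saturates.

    ``curves``: DataFrame indexed by cycle number, one column per
    fragment, holding Input intensities.  All downstream ratios should
    be read at the returned cycle.  Raises if every recorded cycle has
    at least one saturated fragment.
    """
    if len(curves) == 0:
        raise ValueError("no cycles recorded")
    ok = (curves < saturation_level).all(axis=1)
    if not ok.any():
        raise ValueError(
            f"all recorded cycles have a fragment at/above saturation "
            f"({saturation_level})"
        )
    return int(curves.index[ok].max())


def fragment_enrichment(
    signal: pd.DataFrame, input_floor: float | None = None
) -> pd.DataFrame:
    """Per-fragment Bound/Input ratio with a low-confidence flag.

    ``signal`` needs ``bound`` and ``input`` columns (common-cycle band
    intensities).  Fragments whose Input intensity falls below
    ``input_floor`` -- default 10% of the median Input -- amplify too
    poorly for their ratio to be trusted; they are flagged and excluded
    from peak calling.
    """
    if not {"bound", "input"}.issubset(signal.columns):
        raise ValueError("signal needs 'bound' and 'input' columns")
    if (signal["bound"] < 0).any() or (signal["input"] < 0).any():
        raise ValueError("intensities must be nonnegative")
    if input_floor is None:
        input_floor = 0.1 * float(signal["input"].median())
    out = signal.copy()
    out["low_confidence"] = out["input"] < input_floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["bound"].to_numpy() / out["input"].to_numpy()
    out["ratio"] = np.where(out["input"] > 0, ratio, np.nan)
    out.loc[out["low_confidence"], "ratio"] = np.nan
    return out


@dataclass(frozen=True)
class PeakReport:
    """Peak fragment plus the upstream partial-cleavage smear."""

    peak: int
    smear: tuple[int, ...]
    ratios: dict[int, float]
    flagged: tuple[int, ...]


def peak_fragment(enrichment: pd.DataFrame) -> PeakReport:
    """Call the binding-site fragment and its upstream smear.

    Peak = argmax of the Bound/Input ratio over unflagged fragments
    (ties go to the smaller index).  The smear lists contiguous
    fragments immediately upstream of the peak whose ratio exceeds the
    median ratio of the non-peak unflagged fragments -- the signature of
    partial RNase cleavage leaving longer fragments that still carry the
    site.  Flagged fragments never win the peak and interrupt the smear.
    """
    ok = enrichment[~enrichment["low_confidence"]]
    if len(ok) == 0:
        raise ValueError("all fragments are flagged low-confidence")
    ratios = ok["ratio"]
    peak = int(ratios.idxmax())
    # idxmax returns the first occurrence on ties; index is ascending.
    nonpeak = ratios.drop(index=peak)
    smear: list[int] = []
    if len(nonpeak):
        cutoff = float(nonpeak.median())
        j = peak - 1
        while j in ratios.index and ratios.loc[j] > cutoff:
            smear.append(j)
            j -= 1
        smear.reverse()
    return PeakReport(
        peak=peak,
        smear=tuple(smear),
        ratios={int(i): float(r) for i, r in ratios.items()},
        flagged=tuple(int(i) for i in enrichment.index[enrichment["low_confidence"]]),
    )
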