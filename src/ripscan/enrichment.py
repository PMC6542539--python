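"""Per-gene RIP-efficiency statistics with background correction.

RIP-seq quantifies, for each transcript, reads in the total extract
(Input) and in the co-purified fraction (Bound).  The per-gene binding
statistic is the RIP efficiency

    e = RPM(Bound) / RPM(Input)

which controls for transcript abundance and length, and its
background-corrected form

    c = e(tagged strain) - e(untagged strain)

computed protocol-matched (TAP against TAP-untagged, GFP against
GFP-untagged), which removes nonspecific bead capture.  Genes are
filtered on Input coverage before the ratio and ranked by descending
``c`` with a fully specified tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "FilterParams",
    "normalize_rpm",
    "filter_transcripts",
    "rip_efficiency",
    "background_correct",
    "rank_genes",
    "enrichment_table",
]

_ROLES = {"Input", "Bound"}


@dataclass
class CountTable:
    """Gene x sample raw read counts with sample metadata.

    ``counts``: DataFrame, index gene_id, one integer column per sample.
    ``samples``: DataFrame indexed by sample label with columns
    ``strain`` (tagged aaRS name or ``"untagged"``), ``protocol``
    (``TAP``/``GFP``) and ``role`` (``Input``/``Bound``).
    ``gene_types``: optional Series mapping gene_id to ``coding`` /
    ``noncoding``; genes absent from it are treated as coding.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_types: pd.Series | None = None

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise ValueError("gene_ids must be unique")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")
        for col in ("strain", "protocol", "role"):
            if col not in self.samples.columns:
                raise ValueError(f"samples metadata lacks column {col!r}")
        bad_role = set(self.samples["role"]) - _ROLES
        if bad_role:
            raise ValueError(f"unknown sample roles: {sorted(bad_role)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")

    def sample_for(self, strain: str, protocol: str, role: str) -> str:
        """Label of the unique sample matching (strain, protocol, role)."""
        mask = (
            (self.samples["strain"] == strain)
            & (self.samples["protocol"] == protocol)
            & (self.samples["role"] == role)
        )
        labels = self.samples.index[mask]
        if len(labels) == 0:
            raise KeyError(
                f"no {role} sample for strain={strain!r} protocol={protocol!r}"
            )
        if len(labels) > 1:
            raise KeyError(
                f"ambiguous {role} sample for strain={strain!r} protocol={protocol!r}: "
                f"{list(labels)}"
            )
        return labels[0]

    def is_coding(self) -> pd.Series:
        if self.gene_types is None:
            return pd.Series(True, index=self.counts.index)
        types = self.gene_types.reindex(self.counts.index).fillna("coding")
        return types.eq("coding")


@dataclass(frozen=True)
class FilterParams:
    """Input-coverage filter: drop genes with Input RPM below the threshold.

    The boundary is exclusive -- "below 15" drops 14.999 and retains
    exactly 15 -- and noncoding transcripts are dropped by default.
    """

    min_input_rpm: float = 15.0
    drop_noncoding: bool = True

    def __post_init__(self):
        if self.min_input_rpm < 0:
            raise ValueError(f"min_input_rpm must be >= 0, got {self.min_input_rpm}")


def normalize_rpm(table: CountTable) -> CountTable:
    """Reads-per-million normalization: count / column_total * 1e6.

    Every returned column sums to 1e6 (up to floating tolerance).
    Raises ``ValueError`` naming the sample if a column has zero total.
    """
    totals = table.counts.sum(axis=0)
    empty = totals.index[totals <= 0]
    if len(empty):
        raise ValueError(f"sample column(s) with zero total reads: {list(empty)}")
    rpm = table.counts / totals * 1e6
    return CountTable(counts=rpm, samples=table.samples, gene_types=table.gene_types)


def filter_transcripts(
    rpm: CountTable,
    params: FilterParams,
    strains: list[str] | None = None,
    protocol: str | None = None,
) -> pd.Index:
    """Genes retained under the Input-coverage filter.

    A gene is retained iff its RPM is >= ``min_input_rpm`` in every
    relevant Input sample (all Input samples by default, or those of
    the given strains/protocol) and, when ``drop_noncoding``, it is
    annotated coding.
    """
    meta = rpm.samples
    mask = meta["role"] == "Input"
    if strains is not None:
        mask &= meta["strain"].isin(strains)
    if protocol is not None:
        mask &= meta["protocol"] == protocol
    input_cols = meta.index[mask]
    if len(input_cols) == 0:
        raise ValueError("no Input samples match the requested strains/protocol")
    keep = (rpm.counts[input_cols] >= params.min_input_rpm).all(axis=1)
    if params.drop_noncoding:
        keep &= rpm.is_coding()
    return rpm.counts.index[keep]


def rip_efficiency(
    rpm: CountTable,
    strain: str,
    protocol: str,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Per-gene RIP efficiency e = RPM(Bound) / RPM(Input) for one strain.

    ``genes`` restricts the computation to pre-filtered gene ids (whose
    Input RPM the filter guarantees positive).
    """
    bound = rpm.counts[rpm.sample_for(strain, protocol, "Bound")]
    input_ = rpm.counts[rpm.sample_for(strain, protocol, "Input")]
    if genes is not None:
        bound, input_ = bound.loc[genes], input_.loc[genes]
    if (input_ <= 0).any():
        offender = input_.index[input_ <= 0][0]
        raise ValueError(
            f"Input RPM is zero for gene {offender!r}; filter transcripts first"
        )
    e = bound / input_
    e.name = f"{strain}_{protocol}_efficiency"
    return e


def background_correct(
    e_tagged: pd.Series,
    e_untagged: pd.Series,
    mode: str = "intersection",
) -> pd.Series:
    """Background-corrected efficiency c = e(tagged) - e(untagged).

    ``mode="intersection"`` (default) keeps only genes present in both
    series -- subtraction is undefined for a gene that failed the
    coverage filter in either experiment.  ``mode="fill_zero"`` keeps
    all tagged genes, treating a missing untagged efficiency as 0.
    Negative values are kept; they simply rank low.
    """
    if mode == "intersection":
        common = e_tagged.index.intersection(e_untagged.index)
        c = e_tagged.loc[common] - e_untagged.loc[common]
    elif mode == "fill_zero":
        c = e_tagged - e_untagged.reindex(e_tagged.index).fillna(0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    c.name = "corrected"
    return c


def rank_genes(c: pd.Series, rpm_bound: pd.Series | None = None) -> pd.Series:
    """1-based ranks, descending by corrected efficiency.

    Ties break toward the gene with the larger Bound RPM, then
    lexicographically by gene_id, giving a deterministic total order.
    """
    if len(c) == 0:
        raise ValueError("cannot rank an empty series")
    df = pd.DataFrame({"c": c.to_numpy()})
    df["rpm_bound"] = (
        rpm_bound.reindex(c.index).to_numpy() if rpm_bound is not None else 0.0
    )
    df["gene"] = list(c.index)
    order = c.index[
        df.sort_values(
            by=["c", "rpm_bound", "gene"], ascending=[False, False, True]
        ).index
    ]
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order, name="rank")
    return ranks.reindex(c.index)


def enrichment_table(
    counts: CountTable,
    strain: str,
    protocol: str,
    untagged_strain: str = "untagged",
    filter_params: FilterParams | None = None,
    mode: str = "intersection",
) -> pd.DataFrame:
    """Full pipeline for one experiment: RPM -> filter -> e -> c -> rank.

    Returns a DataFrame indexed by gene_id with columns ``rpm_input``,
    ``rpm_bound``, ``efficiency``, ``untagged_efficiency``,
    ``corrected`` and ``rank``, sorted by rank.
    """
    filter_params = filter_params or FilterParams()
    rpm = normalize_rpm(counts)
    genes_tag = filter_transcripts(rpm, filter_params, strains=[strain], protocol=protocol)
    genes_untag = filter_transcripts(
        rpm, filter_params, strains=[untagged_strain], protocol=protocol
    )
    e_tag = rip_efficiency(rpm, strain, protocol, genes=genes_tag)
    e_untag = rip_efficiency(rpm, untagged_strain, protocol, genes=genes_untag)
    c = background_correct(e_tag, e_untag, mode=mode)
    rpm_bound = rpm.counts[rpm.sample_for(strain, protocol, "Bound")].loc[c.index]
    rpm_input = rpm.counts[rpm.sample_for(strain, protocol, "Input")].loc[c.index]
    out = pd.DataFrame(
        {
            "rpm_input": rpm_input,
            "rpm_bound": rpm_bound,
            "efficiency": e_tag.loc[c.index],
            "untagged_efficiency": e_untag.reindex(c.index),
            "corrected": c,
            "rank": rank_genes(c, rpm_bound=rpm_bound),
        }
    )
    return out.sort_values("rank")
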