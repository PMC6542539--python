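"""Seeded synthetic inputs with the statistical structure of RIP-seq,
fRIP tiling panels, and mimic-bearing coding sequences.

The generators stand in for the study's raw data so that every analysis
stage runs without external downloads.  Their defaults emulate the study
conditions: ~5,000 yeast genes, 10-18 million reads per library,
negative-binomial (gamma-Poisson) count noise, a bead-background capture
shared between tagged and untagged strains, and planted enriched
transcripts (including a "self" transcript).

All randomness flows through explicit integer seeds; there is no global
random state, and identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import CountTable

__all__ = [
    "RipSimParams",
    "RipSimTruth",
    "FripSimParams",
    "simulate_ripseq",
    "simulate_frip",
    "simulate_cds_with_mimic",
]


@dataclass(frozen=True)
class RipSimParams:
    """Parameters of the RIP-seq count simulator.

    ``dispersion`` is the standard RNA-seq overdispersion alpha of the
    negative binomial, ``var = mu + alpha * mu^2`` (alpha -> 0 recovers
    Poisson).  ``background_capture`` is the mean fraction of a
    transcript's abundance captured nonspecifically by the beads; the
    per-gene bead affinity it scales is drawn once and shared by the
    tagged and untagged strains -- exactly the assumption that justifies
    subtracting the untagged RIP efficiency.  ``planted`` lists
    ``(gene_index, fold)`` enrichments of true targets over background.
    """

    n_genes: int = 5000
    lib_size_input: int = 14_000_000
    lib_size_bound: int = 14_000_000
    dispersion: float = 0.1
    background_capture: float = 0.02
    planted: tuple[tuple[int, float], ...] = ()
    seed: int = 0
    strain: str = "HTS1"
    protocol: str = "TAP"
    abundance_sigma: float = 1.5
    bead_sigma: float = 0.5

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError(f"n_genes must be >= 2, got {self.n_genes}")
        if self.lib_size_input <= 0:
            raise ValueError(f"lib_size_input must be > 0, got {self.lib_size_input}")
        if self.lib_size_bound <= 0:
            raise ValueError(f"lib_size_bound must be > 0, got {self.lib_size_bound}")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if not (0 < self.background_capture <= 1):
            raise ValueError(
                f"background_capture must be in (0, 1], got {self.background_capture}"
            )
        object.__setattr__(self, "planted", tuple(self.planted))
        for idx, fold in self.planted:
            if not (0 <= idx < self.n_genes):
                raise ValueError(f"planted gene index {idx} >= n_genes {self.n_genes}")
            if fold < 1:
                raise ValueError(f"planted enrichment fold must be >= 1, got {fold}")


@dataclass(frozen=True)
class RipSimTruth:
    """Ground truth of a simulated RIP-seq table (never fed to the analysis)."""

    planted: tuple[tuple[int, float], ...]
    abundances: np.ndarray
    bead_affinity: np.ndarray


def simulate_ripseq(params: RipSimParams) -> tuple[CountTable, RipSimTruth]:
    """Simulate Input/Bound counts for a tagged strain and the untagged control.

    Per-gene latent abundances are log-normal (heavy-tailed
    transcriptome); planted genes are clamped to at least the median
    abundance -- true targets, and in particular the "self" transcript
    of a synthetase, are well-expressed housekeeping mRNAs that pass
    the Input-coverage filter.  Input library means are proportional to
    abundance.  Bound library means are proportional to
    ``abundance x (bead_affinity + background_capture x (fold - 1))``:
    the first term is the nonspecific bead background (identical in the
    tagged and untagged strains), the second the protein-mediated
    specific capture, present only for planted genes of the tagged
    strain.

    Counts are negative binomial at the requested dispersion via a
    gamma-Poisson mixture in which the gamma factor -- gene-wise
    biological variation of expression in that culture -- is drawn once
    per strain and shared by its Input and Bound libraries, because both
    are prepared from the same extract; only the Poisson counting noise
    is independent per library.  Marginally each column is NB with
    ``var = mu + dispersion * mu^2``, while the Bound/Input ratio of a
    strain carries counting noise only, mirroring the single-experiment
    design the tables emulate.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    abundance = rng.lognormal(mean=0.0, sigma=params.abundance_sigma, size=n)
    if params.planted:
        floor = float(np.median(abundance))
        for idx, _ in params.planted:
            abundance[idx] = max(abundance[idx], floor)
    p = abundance / abundance.sum()
    bead = params.background_capture * rng.lognormal(
        mean=-params.bead_sigma**2 / 2, sigma=params.bead_sigma, size=n
    )
    fold = np.ones(n)
    for idx, f in params.planted:
        fold[idx] = f

    w_tag = p * (bead + params.background_capture * (fold - 1.0))
    w_untag = p * bead
    columns = {}
    meta = {}
    for strain, w_bound in ((params.strain, w_tag), ("untagged", w_untag)):
        gamma = rng.gamma(1.0 / params.dispersion, params.dispersion, size=n)
        w_in = p * gamma
        w_bd = w_bound * gamma
        mu_in = params.lib_size_input * w_in / w_in.sum()
        mu_bd = params.lib_size_bound * w_bd / w_bd.sum()
        for role, mu in (("Input", mu_in), ("Bound", mu_bd)):
            label = f"{strain}_{params.protocol}_{role}"
            columns[label] = rng.poisson(mu)
            meta[label] = {"strain": strain, "protocol": params.protocol, "role": role}

    gene_ids = [f"gene{i:05d}" for i in range(n)]
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(meta).T
    samples.index.name = "sample"
    table = CountTable(counts=counts, samples=samples)
    truth = RipSimTruth(planted=params.planted, abundances=abundance, bead_affinity=bead)
    return table, truth


@dataclass(frozen=True)
class FripSimParams:
    """Parameters of the tiling-fragment (fRIP) signal simulator.

    The binding site lives on ``site_fragment``; partial RNase cleavage
    leaves longer fragments that still carry the site, so the fragments
    immediately upstream receive a decaying ``carryover`` signal.  The
    leak is bounded at ``carryover_span`` fragments: cleavage products
    average ~200 nt, about two amplicon spacings, so more distal
    fragments see only background.  ``pcr_efficiency`` multiplies both
    Bound and Fragmented-Input signals and cancels in their ratio.
    """

    n_fragments: int = 14
    site_fragment: int = 10
    carryover: float = 0.4
    carryover_span: int = 2
    pcr_efficiency: tuple[float, ...] | None = None
    background: float = 0.05
    noise_sigma: float = 0.1
    cds_length: int = 1644
    product_len: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments < 1:
            raise ValueError(f"n_fragments must be >= 1, got {self.n_fragments}")
        if not (1 <= self.site_fragment <= self.n_fragments):
            raise ValueError(
                f"site_fragment must be in [1, {self.n_fragments}], got {self.site_fragment}"
            )
        if not (0 <= self.carryover < 1):
            raise ValueError(f"carryover must be in [0, 1), got {self.carryover}")
        if self.carryover_span < 0:
            raise ValueError(f"carryover_span must be >= 0, got {self.carryover_span}")
        if self.pcr_efficiency is not None:
            eff = tuple(float(x) for x in self.pcr_efficiency)
            if len(eff) != self.n_fragments:
                raise ValueError(
                    f"pcr_efficiency length {len(eff)} != n_fragments {self.n_fragments}"
                )
            if any(x <= 0 for x in eff):
                raise ValueError("pcr_efficiency entries must be > 0")
            object.__setattr__(self, "pcr_efficiency", eff)
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")


def expected_frip_profile(params: FripSimParams) -> np.ndarray:
    """Noise-free Bound/Input ratio the generator targets, per fragment."""
    n = params.n_fragments
    profile = np.full(n, params.background)
    site = params.site_fragment - 1
    profile[site] += 1.0
    for d in range(1, params.carryover_span + 1):
        if site - d >= 0:
            profile[site - d] += params.carryover**d
    return profile


def simulate_frip(params: FripSimParams) -> pd.DataFrame:
    """Simulate a tiling panel with Bound and Fragmented-Input intensities.

    Returns a DataFrame indexed by fragment (1..n) with columns
    ``start``, ``end``, ``bound``, ``input``.  Bound intensity follows
    the carryover profile times PCR efficiency; Input intensity is
    proportional to PCR efficiency only.  Both carry multiplicative
    log-normal noise.
    """
    from .frip import design_tiling

    rng = np.random.default_rng(params.seed)
    n = params.n_fragments
    eff = (
        np.asarray(params.pcr_efficiency, dtype=float)
        if params.pcr_efficiency is not None
        else np.ones(n)
    )
    profile = expected_frip_profile(params)
    noise = lambda: rng.lognormal(mean=0.0, sigma=params.noise_sigma, size=n)
    bound = profile * eff * noise()
    input_ = eff * noise()
    panel = design_tiling(params.cds_length, n, params.product_len)
    panel = panel.copy()
    panel["bound"] = bound
    panel["input"] = input_
    return panel


def simulate_cds_with_mimic(
    length: int,
    triplet: str = "GUG",
    insert_pos: int | None = None,
    stem_len: int = 5,
    seed: int = 0,
    flank_buffer: int = 15,
) -> tuple[str, int]:
    """Generate a CDS carrying one designed anticodon-mimic stem-loop.

    The element is ``stem_len`` G-C pairs closing a 3-nt loop that holds
    ``triplet`` with its first base at ``insert_pos`` (1-based; default:
    window centered in the sequence).  Flanks are random A/C -- a
    pairing-poor alphabet (no A-A, C-C or A-C pairs) -- with an A-only
    buffer of ``flank_buffer`` nt around the element so the designed
    hairpin is the unique maximum-pairing structure in every scan window
    that contains it.  Returns ``(sequence, insert_pos)``; the sequence
    is RNA-alphabet and of exactly ``length`` nt.
    """
    from .structure import to_rna

    trip = to_rna(triplet)
    if len(trip) != 3:
        raise ValueError(f"triplet must be 3 nt, got {triplet!r}")
    if stem_len < 3:
        raise ValueError(f"stem_len must be >= 3, got {stem_len}")
    if insert_pos is None:
        insert_pos = length // 2
    elem_start = insert_pos - stem_len  # 1-based start of 5' stem
    elem_end = insert_pos + 2 + stem_len  # 1-based end of 3' stem
    if elem_start < 1 or elem_end > length:
        raise ValueError(
            f"mimic element [{elem_start}, {elem_end}] does not fit in a "
            f"CDS of length {length} (insert_pos={insert_pos}, stem_len={stem_len})"
        )
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("AC"), size=length, p=(0.75, 0.25)))
    buf_lo = max(0, elem_start - 1 - flank_buffer)
    buf_hi = min(length, elem_end + flank_buffer)
    for i in range(buf_lo, buf_hi):
        seq[i] = "A"
    stem5 = ["G"] * stem_len
    stem3 = ["C"] * stem_len
    element = stem5 + list(trip) + stem3
    seq[elem_start - 1 : elem_end] = element
    return "".join(seq), insert_pos
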