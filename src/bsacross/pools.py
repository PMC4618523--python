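"""Phenotype-based selection, equimolar pooling, and pooled-seq read counts.

Selected segregants are pooled in exactly equimolar fractions (as in the
wet protocol), so the true pooled 3S frequency at a marker is simply the
fraction of pooled haploids carrying the 3S origin there.  Sequencing is
emulated marker-by-marker: depth is Poisson in the mean coverage and each
read reports the true pooled allele with probability 1 - e, otherwise one
of the three other bases uniformly, so BY<->3S cross-contamination occurs
at e/3 and the remaining 2e/3 of errors land in ``count_other``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross import Haplotype, Segregant
from .markers import ENGINEERED_GENES, MarkerMap


@dataclass(frozen=True)
class PoolSeqParams:
    """Pooled-sequencing emulation parameters.

    ``mean_coverage``: expected per-site depth (the study's pools ran at
    73x and 122x).  ``error_rate``: per-read miscall probability; the real
    data showed a small number of sequencing/read-mapping errors of
    unreported rate, the default here is a nominal 0.5%.
    """

    mean_coverage: float = 100.0
    error_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class PoolFrequencies:
    """True (pre-sequencing) pooled allele frequencies."""

    map: MarkerMap
    freq_3s: np.ndarray                 # per-marker fraction of 3S origins
    mutant_frac: dict[str, float]       # engineered gene -> mutant fraction
    n_segregants: int


@dataclass
class AlleleCountTable:
    """Per-marker pooled sequencing counts (BY / 3S / other).

    ``mutant`` carries, for each engineered gene on the map, the number of
    reads at its marker supporting the engineered lesion, out of that
    marker's depth — the pooled analogue of detecting ira2Δ2933 or sfl1Δ
    directly from the alignments.
    """

    map: MarkerMap
    depth: np.ndarray
    count_by: np.ndarray
    count_3s: np.ndarray
    count_other: np.ndarray
    mutant: dict[str, tuple[int, int]] = field(default_factory=dict)  # gene -> (count, depth)

    def __post_init__(self) -> None:
        n = self.map.n_markers
        for name in ("depth", "count_by", "count_3s", "count_other"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per marker")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)
        if np.any(self.count_by + self.count_3s + self.count_other != self.depth):
            raise ValueError("count conservation violated: by + 3s + other != depth")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": self.map.marker_ids().to_numpy(),
            "chrom": self.map.chrom,
            "pos_bp": self.map.pos_bp,
            "depth": self.depth,
            "count_by": self.count_by,
            "count_3s": self.count_3s,
            "count_other": self.count_other,
        })
        df["mut_gene"] = ""
        df["mut_count"] = -1
        df["mut_depth"] = -1
        for gene, (count, depth) in self.mutant.items():
            i = self.map.causal_index[gene]
            df.loc[i, ["mut_gene", "mut_count", "mut_depth"]] = [gene, count, depth]
        return df


def _haplotypes(pop: Sequence[Segregant | Haplotype]) -> list[Haplotype]:
    return [s.haplotype if isinstance(s, Segregant) else s for s in pop]


def select_segregants(
    pop: Sequence[Segregant],
    phenotype: str = "ROUGH",
    allele_filter: Mapping[str, str] | None = None,
) -> list[Segregant]:
    """Retain segregants matching a phenotype and optional per-gene alleles.

    ``allele_filter`` mirrors the study's restriction-marker genotyping
    step (e.g. keeping only END3^3S rough individuals from the BY
    backcross before pooling).
    """
    kept = [s for s in pop if s.phenotype == phenotype]
    if allele_filter:
        for gene in allele_filter:
            if kept and gene not in kept[0].haplotype.map.causal_index:
                raise KeyError(f"allele_filter gene {gene!r} is not a causal site")
        kept = [s for s in kept
                if all(s.haplotype.origin_at(g) == o for g, o in allele_filter.items())]
    return kept


def pool_true_frequencies(
    subpop: Sequence[Segregant | Haplotype],
    marker_map: MarkerMap | None = None,
    abundance_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PoolFrequencies:
    """Pooled 3S frequency at every marker, plus mutant fractions.

    Pooling is exactly equimolar by default, matching the wet protocol.
    ``abundance_cv`` optionally adds per-strain abundance noise: strain
    weights are drawn from a gamma distribution with the given coefficient
    of variation and the pool becomes a weighted mixture.
    """
    haps = _haplotypes(subpop)
    if not haps:
        raise ValueError("cannot pool an empty set of segregants")
    marker_map = marker_map or haps[0].map
    origins = np.stack([h.origins for h in haps])
    ira2 = np.array([h.ira2_state == "D2933" for h in haps], dtype=float)
    sfl1 = np.array([h.sfl1_state == "DELETED" for h in haps], dtype=float)
    if abundance_cv > 0:
        rng = rng if rng is not None else np.random.default_rng()
        shape = 1.0 / abundance_cv**2
        w = rng.gamma(shape, 1.0 / shape, size=len(haps))
        w /= w.sum()
        freq = np.clip(w @ origins, 0.0, 1.0)
        f_ira2, f_sfl1 = float(np.clip(w @ ira2, 0, 1)), float(np.clip(w @ sfl1, 0, 1))
    else:
        # exact equimolar mean keeps fixed markers at exactly 0 or 1
        freq = origins.mean(axis=0)
        f_ira2, f_sfl1 = float(ira2.mean()), float(sfl1.mean())
    mutant_frac = {}
    if "IRA2" in marker_map.causal_index:
        mutant_frac["IRA2"] = f_ira2
    if "SFL1" in marker_map.causal_index:
        mutant_frac["SFL1"] = f_sfl1
    return PoolFrequencies(marker_map, freq, mutant_frac, len(haps))


def simulate_pool_counts(
    freqs: PoolFrequencies | np.ndarray,
    params: PoolSeqParams,
    marker_map: MarkerMap | None = None,
    rng: np.random.Generator | None = None,
) -> AlleleCountTable:
    """Draw pooled-sequencing allele counts from true pooled frequencies."""
    if isinstance(freqs, PoolFrequencies):
        marker_map = freqs.map
        f = np.asarray(freqs.freq_3s, dtype=float)
        mutant_frac = freqs.mutant_frac
    else:
        if marker_map is None:
            raise ValueError("marker_map is required when freqs is a bare array")
        f = np.asarray(freqs, dtype=float)
        mutant_frac = {}
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    e = params.error_rate
    p_3s = f * (1 - e) + (1 - f) * e / 3.0
    p_by = (1 - f) * (1 - e) + f * e / 3.0
    p_other = np.full_like(f, 2.0 * e / 3.0)

    depth = rng.poisson(params.mean_coverage, size=f.shape[0])
    count_3s = rng.binomial(depth, p_3s)
    rest = depth - count_3s
    denom = p_by + p_other
    with np.errstate(invalid="ignore", divide="ignore"):
        p_by_given_rest = np.where(denom > 0, p_by / np.where(denom > 0, denom, 1.0), 1.0)
    count_by = rng.binomial(rest, p_by_given_rest)
    count_other = rest - count_by

    mutant = {}
    for gene in ENGINEERED_GENES:
        if gene in mutant_frac and gene in marker_map.causal_index:
            idx = marker_map.causal_index[gene]
            d = int(depth[idx])
            mutant[gene] = (int(rng.binomial(d, mutant_frac[gene])), d)
    return AlleleCountTable(marker_map, depth, count_by, count_3s, count_other, mutant)
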