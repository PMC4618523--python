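"""Meiosis and cross/backcross simulation for haploid yeast segregants.

Recombination follows the Haldane (no-interference) model: per chromosome,
the crossover count is Poisson in the genetic length (Morgans), crossover
positions are uniform on the genetic map, and the gamete alternates between
the two parental strands from a fair random start.  Engineered lesions
(ira2Δ2933, sfl1Δ) sit at their gene's marker and are transmitted with
whichever strand the gamete carries there — i.e. they segregate exactly
like alleles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .markers import CAUSAL_GENES, MarkerMap
from .traits import SMOOTH, TraitRuleSet, classify_phenotype

BY, S3 = "BY", "3S"
_BY, _3S = 0, 1
_ORIGIN_LABELS = np.array([BY, S3])

IRA2_STATES = ("WT", "D2933")
SFL1_STATES = ("PRESENT", "DELETED")

SCHEME_NAMES = ("BYx3S_WT", "BYx3S_IRA2MUT", "BYx3S_SFL1DEL",
                "BACKCROSS_BY", "BACKCROSS_3S")


@dataclass
class Haplotype:
    """Per-marker parental origin plus engineered-site states.

    ``origins`` is a uint8 array over the map's markers, 0 = BY, 1 = 3S.
    """

    origins: np.ndarray
    map: MarkerMap
    ira2_state: str = "WT"
    sfl1_state: str = "PRESENT"

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=np.uint8)
        if self.origins.shape != (self.map.n_markers,):
            raise ValueError(
                f"haplotype length {self.origins.shape} does not match map "
                f"({self.map.n_markers} markers)")
        if np.any(self.origins > 1):
            raise ValueError("origins must be 0 (BY) or 1 (3S)")
        if self.ira2_state not in IRA2_STATES:
            raise ValueError(f"unknown ira2_state {self.ira2_state!r}")
        if self.sfl1_state not in SFL1_STATES:
            raise ValueError(f"unknown sfl1_state {self.sfl1_state!r}")

    def origin_at(self, gene_or_marker: str) -> str:
        idx = self.map.causal_index.get(gene_or_marker)
        if idx is None:
            idx = self.map.index_of(gene_or_marker)
        return _ORIGIN_LABELS[self.origins[idx]]

    def causal_origins(self) -> dict[str, str]:
        """Origins at every causal site, keyed by gene name."""
        return {g: _ORIGIN_LABELS[self.origins[i]]
                for g, i in self.map.causal_index.items()}

    def origin_labels(self) -> np.ndarray:
        return _ORIGIN_LABELS[self.origins]


def by_parent(marker_map: MarkerMap, ira2_state: str = "WT",
              sfl1_state: str = "PRESENT") -> Haplotype:
    """The BY founder: BY origin at every marker."""
    return Haplotype(np.zeros(marker_map.n_markers, dtype=np.uint8), marker_map,
                     ira2_state, sfl1_state)


def s3_parent(marker_map: MarkerMap, ira2_state: str = "WT",
              sfl1_state: str = "PRESENT") -> Haplotype:
    """The 3S founder: 3S origin at every marker."""
    return Haplotype(np.ones(marker_map.n_markers, dtype=np.uint8), marker_map,
                     ira2_state, sfl1_state)


@dataclass
class Segregant:
    haplotype: Haplotype
    phenotype: str = SMOOTH
    scheme: str = ""


@dataclass
class CrossScheme:
    """One of the study's mating designs.

    ``BYx3S_WT``      BY x 3S, wild-type at IRA2 and SFL1.
    ``BYx3S_IRA2MUT`` BY x 3S with ira2Δ2933 carried by the 3S founder.
    ``BYx3S_SFL1DEL`` BY sfl1Δ x 3S sfl1Δ (the lesion does not segregate).
    ``BACKCROSS_BY``  founder segregant x wild-type BY.
    ``BACKCROSS_3S``  founder segregant x wild-type 3S.
    """

    name: str
    founder_segregant: Haplotype | None = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.name.startswith("BACKCROSS") and self.founder_segregant is None:
            raise ValueError(f"scheme {self.name} requires a founder_segregant")

    # -- convenience constructors ---------------------------------------
    @classmethod
    def byx3s_wt(cls) -> "CrossScheme":
        return cls("BYx3S_WT")

    @classmethod
    def byx3s_ira2mut(cls) -> "CrossScheme":
        return cls("BYx3S_IRA2MUT")

    @classmethod
    def byx3s_sfl1del(cls) -> "CrossScheme":
        return cls("BYx3S_SFL1DEL")

    @classmethod
    def backcross_by(cls, founder: Haplotype) -> "CrossScheme":
        return cls("BACKCROSS_BY", founder_segregant=founder)

    @classmethod
    def backcross_3s(cls, founder: Haplotype) -> "CrossScheme":
        return cls("BACKCROSS_3S", founder_segregant=founder)

    # -- parents and segregation bookkeeping -----------------------------
    def parents(self, marker_map: MarkerMap) -> tuple[Haplotype, Haplotype]:
        if self.name == "BYx3S_WT":
            return by_parent(marker_map), s3_parent(marker_map)
        if self.name == "BYx3S_IRA2MUT":
            return by_parent(marker_map), s3_parent(marker_map, ira2_state="D2933")
        if self.name == "BYx3S_SFL1DEL":
            return (by_parent(marker_map, sfl1_state="DELETED"),
                    s3_parent(marker_map, sfl1_state="DELETED"))
        founder = self.founder_segregant
        assert founder is not None
        if founder.map is not marker_map and founder.map.n_markers != marker_map.n_markers:
            raise ValueError("founder segregant was simulated on a different map")
        recurrent = by_parent(marker_map) if self.name == "BACKCROSS_BY" else s3_parent(marker_map)
        return founder, recurrent

    def segregating_mask(self, marker_map: MarkerMap) -> np.ndarray:
        """True where the two parents differ, i.e. where the cross is informative."""
        a, b = self.parents(marker_map)
        return a.origins != b.origins

    def engineered_segregating(self, marker_map: MarkerMap) -> dict[str, bool]:
        """Whether each engineered lesion segregates (parents differ in state)."""
        a, b = self.parents(marker_map)
        return {"IRA2": a.ira2_state != b.ira2_state,
                "SFL1": a.sfl1_state != b.sfl1_state}

    def transmission(self) -> "Transmission":
        """Per-locus transmission probabilities for exact enumeration."""
        if self.name in ("BYx3S_WT", "BYx3S_IRA2MUT", "BYx3S_SFL1DEL"):
            p_gene = {g: 0.5 for g in CAUSAL_GENES}
            p_ira2 = 0.5 if self.name == "BYx3S_IRA2MUT" else 0.0
            p_sfl1 = 1.0 if self.name == "BYx3S_SFL1DEL" else 0.0
            return Transmission(p_gene, p_ira2, p_sfl1)
        founder = self.founder_segregant
        assert founder is not None
        recurrent_3s = 1.0 if self.name == "BACKCROSS_3S" else 0.0
        p_gene = {}
        for g, origin in founder.causal_origins().items():
            founder_3s = 1.0 if origin == S3 else 0.0
            p_gene[g] = 0.5 if founder_3s != recurrent_3s else founder_3s
        p_ira2 = 0.5 if founder.ira2_state == "D2933" else 0.0
        p_sfl1 = 0.5 if founder.sfl1_state == "DELETED" else 0.0
        return Transmission(p_gene, p_ira2, p_sfl1)


@dataclass(frozen=True)
class Transmission:
    """P(3S) per causal gene and P(mutant state) for the engineered sites."""

    p_3s: Mapping[str, float]
    p_ira2_mut: float
    p_sfl1_del: float


def simulate_meiosis(
    parent_hap_a: Haplotype,
    parent_hap_b: Haplotype,
    marker_map: MarkerMap | None = None,
    rng: np.random.Generator | None = None,
) -> Haplotype:
    """One gamete from an A/B diploid under the Haldane crossover model."""
    marker_map = marker_map or parent_hap_a.map
    if parent_hap_a.origins.shape != (marker_map.n_markers,) or \
            parent_hap_b.origins.shape != (marker_map.n_markers,):
        raise ValueError("parent haplotypes do not conform to the marker map")
    rng = rng if rng is not None else np.random.default_rng()

    strand = np.empty(marker_map.n_markers, dtype=np.int64)
    for block in marker_map.chrom_slices.values():
        cm = marker_map.pos_cM[block]
        length_m = (cm[-1] - cm[0]) / 100.0
        start = int(rng.integers(2))
        n_xo = int(rng.poisson(length_m)) if length_m > 0 else 0
        if n_xo:
            xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_xo))
            strand[block] = (start + np.searchsorted(xpos, cm, side="left")) % 2
        else:
            strand[block] = start

    origins = np.where(strand == 0, parent_hap_a.origins, parent_hap_b.origins)
    states = {}
    for gene, attr in (("IRA2", "ira2_state"), ("SFL1", "sfl1_state")):
        idx = marker_map.causal_index.get(gene)
        if idx is None:
            states[attr] = getattr(parent_hap_a, attr)
            continue
        donor = parent_hap_a if strand[idx] == 0 else parent_hap_b
        states[attr] = getattr(donor, attr)
    return Haplotype(origins.astype(np.uint8), marker_map, **states)


def simulate_cross(
    scheme: CrossScheme,
    n: int,
    marker_map: MarkerMap,
    rules: TraitRuleSet | None = None,
    rng: np.random.Generator | None = None,
    viability_bias: Mapping[str, Mapping[str, float]] | None = None,
) -> list[Segregant]:
    """``n`` independent haploid segregants from a scheme, phenotyped.

    ``viability_bias`` optionally models allele-dependent survival during
    spore isolation: a mapping ``gene -> {origin: relative survival}``
    (probabilities in [0, 1]; unlisted origins survive at 1).  Non-
    surviving spores are redrawn, so the returned population still has
    ``n`` members but skewed allele frequencies at the biased loci.  The
    strength of such biases is system-specific; no default is applied.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    parent_a, parent_b = scheme.parents(marker_map)
    out = []
    while len(out) < n:
        hap = simulate_meiosis(parent_a, parent_b, marker_map, rng)
        if viability_bias is not None and not _survives(hap, viability_bias, rng):
            continue
        pheno = classify_phenotype(hap, rules, rng) if rules is not None else SMOOTH
        out.append(Segregant(hap, pheno, scheme.name))
    return out


def _survives(hap: Haplotype, viability_bias: Mapping[str, Mapping[str, float]],
              rng: np.random.Generator) -> bool:
    p = 1.0
    for gene, by_origin in viability_bias.items():
        p *= by_origin.get(hap.origin_at(gene), 1.0)
    return p >= 1.0 or rng.random() < p


def simulate_until(
    scheme: CrossScheme,
    marker_map: MarkerMap,
    rules: TraitRuleSet,
    n_wanted: int,
    rng: np.random.Generator,
    phenotype: str = "ROUGH",
    allele_filter: Mapping[str, str] | None = None,
    max_attempts: int | None = None,
) -> list[Segregant]:
    """Screen segregants until ``n_wanted`` match a phenotype (and optional
    allele filter), mimicking plate screening plus marker genotyping.

    Raises ``RuntimeError`` if the quota is not reached within
    ``max_attempts`` simulated segregants (default ``200 * n_wanted``).
    """
    max_attempts = max_attempts or 200 * n_wanted
    parent_a, parent_b = scheme.parents(marker_map)
    kept: list[Segregant] = []
    for _ in range(max_attempts):
        if len(kept) >= n_wanted:
            break
        hap = simulate_meiosis(parent_a, parent_b, marker_map, rng)
        pheno = classify_phenotype(hap, rules, rng)
        if pheno != phenotype:
            continue
        if allele_filter and any(hap.origin_at(g) != o for g, o in allele_filter.items()):
            continue
        kept.append(Segregant(hap, pheno, scheme.name))
    if len(kept) < n_wanted:
        raise RuntimeError(
            f"only {len(kept)}/{n_wanted} {phenotype} segregants found in "
            f"{max_attempts} attempts under scheme {scheme.name}")
    return kept
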