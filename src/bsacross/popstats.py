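"""Interaction-class genetics: classification and exact expectations.

Rough segregants in the ira2Δ2933 background fall into two mutually
exclusive interaction classes distinguished by their END3 allele:

* FIVE_WAY:  END3^BY FLO8^3S MSS11^BY TRR1^3S  (MGA1, SFL1 free)
* SIX_WAY:   END3^3S FLO8^3S MGA1^BY MSS11^BY SFL1^BY  (TRR1 free)

Because the five-way genotype constrains four cryptic genes and the
six-way five, Mendelian transmission at unlinked loci makes the five-way
class exactly twice as frequent: P(five-way)/P(six-way) = (1/2)^4 / (1/2)^5
= 2.  Expectations here are computed by exact enumeration over causal-site
allele combinations weighted by per-locus transmission probabilities — no
Monte Carlo — so they carry no sampling error.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross import CrossScheme, Haplotype, Segregant
from .markers import CRYPTIC_GENES
from .traits import TraitRuleSet

FIVE_WAY, SIX_WAY, OTHER = "FIVE_WAY", "SIX_WAY", "OTHER"
GENOTYPE_CLASSES = (FIVE_WAY, SIX_WAY, OTHER)

FIVE_WAY_ALLELES: dict[str, str] = {"END3": "BY", "FLO8": "3S", "MSS11": "BY", "TRR1": "3S"}
SIX_WAY_ALLELES: dict[str, str] = {"END3": "3S", "FLO8": "3S", "MGA1": "BY",
                                   "MSS11": "BY", "SFL1": "BY"}


def classify_interaction_alleles(alleles: Mapping[str, str], ira2_state: str) -> str:
    """Interaction class from causal-gene origins and IRA2 state."""
    missing = [g for g in CRYPTIC_GENES if g not in alleles]
    if missing:
        raise KeyError(f"genotype does not resolve causal genes: {missing}")
    if ira2_state == "D2933":
        if all(alleles[g] == o for g, o in FIVE_WAY_ALLELES.items()):
            return FIVE_WAY
        if all(alleles[g] == o for g, o in SIX_WAY_ALLELES.items()):
            return SIX_WAY
    return OTHER


def classify_interaction(h: Haplotype) -> str:
    """FIVE_WAY / SIX_WAY / OTHER for one segregant haplotype.

    The two classes are mutually exclusive: they require opposite END3
    alleles.  Both require the ira2Δ2933 lesion.
    """
    return classify_interaction_alleles(h.causal_origins(), h.ira2_state)


@dataclass(frozen=True)
class ClassExpectation:
    """Exact class probabilities among all progeny and among rough progeny."""

    among_all: Mapping[str, float]
    among_rough: Mapping[str, float]
    p_rough: float

    @property
    def five_to_six_ratio(self) -> float:
        p6 = self.among_all[SIX_WAY]
        return np.inf if p6 == 0 else self.among_all[FIVE_WAY] / p6


def expected_class_probabilities(rules: TraitRuleSet,
                                 scheme: CrossScheme) -> ClassExpectation:
    """Exact enumeration over causal-site genotypes under a cross scheme.

    Each cryptic gene transmits its 3S allele with the scheme's per-locus
    probability (0.5 when segregating, 0/1 when fixed); the engineered
    states are enumerated the same way.  Penetrance weights P(rough |
    genotype).  The whole state space is at most 2^8 combinations.
    """
    tr = scheme.transmission()
    p_all = {c: 0.0 for c in GENOTYPE_CLASSES}
    p_class_and_rough = {c: 0.0 for c in GENOTYPE_CLASSES}
    p_rough = 0.0
    for combo in itertools.product(("BY", "3S"), repeat=len(CRYPTIC_GENES)):
        alleles = dict(zip(CRYPTIC_GENES, combo))
        w_genes = 1.0
        for g, origin in alleles.items():
            p3s = tr.p_3s.get(g, 0.5)
            w_genes *= p3s if origin == "3S" else 1.0 - p3s
        if w_genes == 0.0:
            continue
        for ira2, w_i in (("D2933", tr.p_ira2_mut), ("WT", 1.0 - tr.p_ira2_mut)):
            for sfl1, w_s in (("DELETED", tr.p_sfl1_del), ("PRESENT", 1.0 - tr.p_sfl1_del)):
                w = w_genes * w_i * w_s
                if w == 0.0:
                    continue
                cls = classify_interaction_alleles(alleles, ira2)
                p_all[cls] += w
                # P(rough | genotype): penetrance of the first matching rule
                p_pen = 0.0
                for rule in rules:
                    if rule.background_matches(ira2, sfl1) and rule.alleles_match(alleles):
                        if rule.phenotype_if_matched == "ROUGH":
                            p_pen = rule.penetrance
                        break
                if p_pen > 0.0:
                    p_rough += w * p_pen
                    p_class_and_rough[cls] += w * p_pen
    among_rough = {c: (p_class_and_rough[c] / p_rough if p_rough > 0 else 0.0)
                   for c in GENOTYPE_CLASSES}
    return ClassExpectation(p_all, among_rough, p_rough)


@dataclass
class PopulationSummary:
    """Phenotype x interaction-class tabulation of a simulated population."""

    counts: pd.DataFrame      # rows: phenotype, columns: class
    n: int

    @property
    def fractions(self) -> pd.DataFrame:
        if self.n == 0:
            return self.counts.astype(float)
        return self.counts / self.n

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["total"] = df.sum(axis=1)
        return df

    def to_json(self) -> str:
        import json
        return json.dumps({"n": self.n,
                           "counts": {p: dict(row) for p, row in
                                      self.counts.astype(int).iterrows()}},
                          indent=2)


def summarize_population(pop: Sequence[Segregant]) -> PopulationSummary:
    """Counts per phenotype and interaction class (all zeros when empty)."""
    phenotypes = ("SMOOTH", "BUMPY", "ROUGH")
    counts = pd.DataFrame(0, index=list(phenotypes), columns=list(GENOTYPE_CLASSES))
    for s in pop:
        cls = classify_interaction(s.haplotype)
        counts.loc[s.phenotype, cls] += 1
    return PopulationSummary(counts, len(pop))
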