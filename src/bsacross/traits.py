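"""Higher-order genotype -> colony-morphology rules.

Colony morphology in the BY x 3S cross is governed by higher-order genetic
interactions: a segregant is rough only when it carries a specific
combination of parental alleles at several cryptic-variant genes *and* a
capacitating perturbation (the spontaneous ira2Δ2933 lesion, or deletion of
the transcriptional repressor SFL1).  A :class:`TraitRule` encodes one such
combination; :func:`default_rule_set` ships the three interactions
characterised in the study system:

* five-way:  END3^BY FLO8^3S MSS11^BY TRR1^3S, requires ira2Δ2933
* six-way:   END3^3S FLO8^3S MGA1^BY MSS11^BY SFL1^BY, requires ira2Δ2933
* sfl1Δ:     END3^BY FLO8^3S MSS11^BY TRR1^3S, requires sfl1Δ

Everything else is smooth.  A ``BUMPY`` intermediate class exists for
configurable rules but has no default genotype.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import yaml

from .markers import CRYPTIC_GENES

if TYPE_CHECKING:  # pragma: no cover
    from .cross import Haplotype

SMOOTH, BUMPY, ROUGH = "SMOOTH", "BUMPY", "ROUGH"
PHENOTYPES = (SMOOTH, BUMPY, ROUGH)

#: Background requirements a rule may impose.
BACKGROUNDS = ("IRA2_D2933", "SFL1_DELETED", "NONE")


@dataclass(frozen=True)
class TraitRule:
    """One penetrance rule: allele combination + background -> phenotype."""

    name: str
    background: str
    required_alleles: Mapping[str, str]
    phenotype_if_matched: str = ROUGH
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"rule {self.name}: unknown background {self.background!r}")
        if self.phenotype_if_matched not in (BUMPY, ROUGH):
            raise ValueError(f"rule {self.name}: phenotype must be BUMPY or ROUGH")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"rule {self.name}: penetrance must lie in [0, 1]")
        for gene, origin in self.required_alleles.items():
            if origin not in ("BY", "3S"):
                raise ValueError(f"rule {self.name}: required allele for {gene} must be BY or 3S")
        object.__setattr__(self, "required_alleles", dict(self.required_alleles))

    def background_matches(self, ira2_state: str, sfl1_state: str) -> bool:
        if self.background == "IRA2_D2933":
            return ira2_state == "D2933"
        if self.background == "SFL1_DELETED":
            return sfl1_state == "DELETED"
        return True

    def alleles_match(self, alleles: Mapping[str, str]) -> bool:
        try:
            return all(alleles[g] == o for g, o in self.required_alleles.items())
        except KeyError as exc:
            raise KeyError(f"rule {self.name} requires gene {exc.args[0]}, "
                           "absent from the supplied genotype") from None


@dataclass(frozen=True)
class TraitRuleSet:
    """Ordered rules; the first matching rule decides, default is SMOOTH."""

    rules: tuple[TraitRule, ...] = field(default_factory=tuple)
    default_phenotype: str = SMOOTH

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "default_phenotype": self.default_phenotype,
            "rules": [
                {
                    "name": r.name,
                    "background": r.background,
                    "required_alleles": dict(r.required_alleles),
                    "phenotype": r.phenotype_if_matched,
                    "penetrance": r.penetrance,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TraitRuleSet":
        rules = tuple(
            TraitRule(
                name=r["name"],
                background=r.get("background", "NONE"),
                required_alleles=r["required_alleles"],
                phenotype_if_matched=r.get("phenotype", ROUGH),
                penetrance=float(r.get("penetrance", 1.0)),
            )
            for r in d.get("rules", [])
        )
        return cls(rules=rules, default_phenotype=d.get("default_phenotype", SMOOTH))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TraitRuleSet":
        return cls.from_dict(yaml.safe_load(text))


def default_rule_set() -> TraitRuleSet:
    """The three rough-morphology interactions, at full penetrance."""
    return TraitRuleSet(rules=(
        TraitRule(
            name="five_way",
            background="IRA2_D2933",
            required_alleles={"END3": "BY", "FLO8": "3S", "MSS11": "BY", "TRR1": "3S"},
        ),
        TraitRule(
            name="six_way",
            background="IRA2_D2933",
            required_alleles={"END3": "3S", "FLO8": "3S", "MGA1": "BY",
                              "MSS11": "BY", "SFL1": "BY"},
        ),
        TraitRule(
            name="sfl1_delta",
            background="SFL1_DELETED",
            required_alleles={"END3": "BY", "FLO8": "3S", "MSS11": "BY", "TRR1": "3S"},
        ),
    ))


def classify_alleles(
    alleles: Mapping[str, str],
    ira2_state: str,
    sfl1_state: str,
    rules: TraitRuleSet,
    rng: np.random.Generator | None = None,
    force_full_penetrance: bool = False,
) -> str:
    """Classify a genotype given causal-gene origins and engineered states.

    The first rule whose background and required alleles all match fires
    with probability equal to its penetrance; a failed penetrance draw
    falls through to the default phenotype.
    """
    for rule in rules:
        if not rule.background_matches(ira2_state, sfl1_state):
            continue
        if not rule.alleles_match(alleles):
            continue
        p = 1.0 if force_full_penetrance else rule.penetrance
        if p >= 1.0:
            return rule.phenotype_if_matched
        if p <= 0.0:
            return rules.default_phenotype
        if rng is None:
            raise ValueError(
                f"rule {rule.name} has penetrance {p}; an rng is required")
        return rule.phenotype_if_matched if rng.random() < p else rules.default_phenotype
    return rules.default_phenotype


def classify_phenotype(
    h: "Haplotype",
    rules: TraitRuleSet,
    rng: np.random.Generator | None = None,
) -> str:
    """Phenotype of a haploid segregant under a rule set.

    Raises ``KeyError`` if a rule names a gene absent from the map's
    causal sites.  Deterministic whenever all penetrances are 0 or 1.
    """
    return classify_alleles(h.causal_origins(), h.ira2_state, h.sfl1_state, rules, rng)


def enumerate_rough_genotypes(
    rules: TraitRuleSet,
    background: str,
    genes: Iterable[str] = CRYPTIC_GENES,
) -> list[dict[str, str]]:
    """Brute-force the rule set over all 2^6 cryptic-gene allele combinations.

    ``background`` fixes the engineered states (``IRA2_D2933`` or
    ``SFL1_DELETED``); penetrance is forced to 1 so the enumeration reflects
    which genotypes *can* express a non-smooth phenotype.
    """
    if background not in ("IRA2_D2933", "SFL1_DELETED"):
        raise ValueError("background must be IRA2_D2933 or SFL1_DELETED")
    ira2 = "D2933" if background == "IRA2_D2933" else "WT"
    sfl1 = "DELETED" if background == "SFL1_DELETED" else "PRESENT"
    genes = tuple(genes)
    out = []
    for combo in itertools.product(("BY", "3S"), repeat=len(genes)):
        alleles = dict(zip(genes, combo))
        pheno = classify_alleles(alleles, ira2, sfl1, rules, force_full_penetrance=True)
        if pheno != SMOOTH:
            out.append(alleles)
    return out
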