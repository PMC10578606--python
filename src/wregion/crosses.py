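"""Mendelian model of W / W* / Z sex-chromosome transmission.

In *Xenopus laevis*, females are ZW and males ZZ; the W-linked gene *dm-w*
triggers ovary development. ``W*`` denotes a W chromosome whose *dm-w* copy
has been inactivated, so a carrier develops as a phenotypic male unless an
intact W is also present. This module computes exact offspring genotype
distributions for arbitrary crosses among W/W*/Z carriers, maps genotypes to
phenotypic sex under dm-w dominance, pools genotype classes that a sequencing
assay cannot distinguish, and tests observed brood counts against the
Mendelian expectation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy import stats

__all__ = [
    "ALLELES",
    "FUNCTIONAL_DMW",
    "Genotype",
    "OffspringDistribution",
    "GOFResult",
    "parse_genotype",
    "offspring_genotype_distribution",
    "phenotype_of",
    "collapse_classes",
    "chi_square_gof",
]

#: Recognised sex-chromosome allele symbols, in canonical display order.
ALLELES = ("W", "W*", "Z")

#: Whether each allele carries a functional dm-w copy.
FUNCTIONAL_DMW = {"W": True, "W*": False, "Z": False}

_ORDER = {a: i for i, a in enumerate(ALLELES)}


def _tokenize(text: str) -> list[str]:
    """Split a compact genotype string such as ``"ZW*"`` into allele symbols."""
    out: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "W":
            if i + 1 < len(text) and text[i + 1] == "*":
                out.append("W*")
                i += 2
            else:
                out.append("W")
                i += 1
        elif c == "Z":
            out.append("Z")
            i += 1
        else:
            raise ValueError(
                f"invalid sex-chromosome symbol {c!r} at position {i} in {text!r}"
            )
    return out


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of sex-chromosome alleles, stored canonically.

    The canonical display order is W before W* before Z, so the genotype
    {W, W*} prints as ``WW*`` whichever order it was entered in.
    """

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError(f"a genotype carries exactly two alleles, got {self.alleles!r}")
        for a in self.alleles:
            if a not in FUNCTIONAL_DMW:
                raise ValueError(f"invalid allele symbol {a!r}; expected one of {ALLELES}")
        ordered = tuple(sorted(self.alleles, key=_ORDER.__getitem__))
        object.__setattr__(self, "alleles", ordered)

    @property
    def label(self) -> str:
        return "".join(self.alleles)

    @property
    def has_functional_dmw(self) -> bool:
        return any(FUNCTIONAL_DMW[a] for a in self.alleles)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.label


def parse_genotype(spec: "str | Genotype | Sequence[str]") -> Genotype:
    """Coerce a genotype from a string (``"ZW*"``), allele pair, or Genotype."""
    if isinstance(spec, Genotype):
        return spec
    if isinstance(spec, str):
        return Genotype(tuple(_tokenize(spec)))
    return Genotype(tuple(spec))


def phenotype_of(genotype: "str | Genotype | Sequence[str]") -> str:
    """Phenotypic sex under dm-w dominance.

    An individual develops as a female iff at least one allele carries a
    functional dm-w copy (an intact W); W*Z, W*W* and ZZ individuals develop
    as males.
    """
    g = parse_genotype(genotype)
    return "female" if g.has_functional_dmw else "male"


@dataclass(frozen=True)
class OffspringDistribution:
    """Exact genotype-class probabilities for a cross.

    ``probs`` maps class label to a :class:`fractions.Fraction`; probabilities
    are non-negative and sum to exactly 1.
    """

    probs: Mapping[str, Fraction]

    def __post_init__(self) -> None:
        total = sum(self.probs.values(), Fraction(0))
        if total != 1:
            raise ValueError(f"class probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("class probabilities must be non-negative")
        object.__setattr__(self, "probs", dict(self.probs))

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.probs)

    def as_floats(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.probs.items()}

    def __getitem__(self, label: str) -> Fraction:
        return self.probs[label]


def offspring_genotype_distribution(
    mother: "str | Genotype", father: "str | Genotype"
) -> OffspringDistribution:
    """Mendelian offspring genotype distribution of a cross.

    Each parent transmits either of its two alleles with probability 1/2;
    identical unordered offspring genotypes are merged. Probabilities are
    exact rationals (quarters or halves).
    """
    m = parse_genotype(mother)
    f = parse_genotype(father)
    probs: dict[str, Fraction] = {}
    for a_m in m.alleles:
        for a_f in f.alleles:
            label = Genotype((a_m, a_f)).label
            probs[label] = probs.get(label, Fraction(0)) + Fraction(1, 4)
    return OffspringDistribution(probs)


def collapse_classes(
    dist: OffspringDistribution,
    assay: "Mapping[str, Iterable[str]] | Iterable[Iterable[str]]",
) -> OffspringDistribution:
    """Pool genotype classes that an assay cannot distinguish.

    ``assay`` is either a mapping from pooled-class label to the member
    genotype labels, or an iterable of member groups (pooled labels are then
    the members joined with ``/``). Classes not mentioned remain singletons.
    Groups must be disjoint and refer only to classes of ``dist``.
    """
    if isinstance(assay, Mapping):
        groups = {name: tuple(members) for name, members in assay.items()}
    else:
        groups = {"/".join(g): tuple(g) for g in (tuple(g) for g in assay)}

    seen: set[str] = set()
    for name, members in groups.items():
        for m in members:
            if m not in dist.probs:
                raise ValueError(f"assay group {name!r} references unknown class {m!r}")
            if m in seen:
                raise ValueError(f"assay groups overlap on class {m!r}; not a partition")
            seen.add(m)

    pooled: dict[str, Fraction] = {}
    for name, members in groups.items():
        pooled[name] = sum((dist.probs[m] for m in members), Fraction(0))
    for label, p in dist.probs.items():
        if label not in seen:
            pooled[label] = p
    return OffspringDistribution(pooled)


@dataclass(frozen=True)
class GOFResult:
    """Goodness of fit of observed brood counts to a Mendelian expectation."""

    chi2: float
    df: int
    p_chi2: float
    p_exact: "float | None" = None
    n: int = 0
    expected_counts: Mapping[str, float] = field(default_factory=dict)


def _chi2_stat(observed: Sequence[float], expected: Sequence[float]) -> float:
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def chi_square_gof(
    observed: Mapping[str, int],
    expected: OffspringDistribution,
    exact_max_n: int = 40,
    exact_max_classes: int = 4,
) -> GOFResult:
    """Pearson chi-square (and small-n exact multinomial) goodness of fit.

    Observed counts are matched to the expected classes by label (compact
    genotype strings are canonicalised first, so ``"W*W"`` matches ``"WW*"``).
    The exact multinomial p-value is computed by full enumeration of outcome
    vectors, ordered by the chi-square statistic, when ``n <= exact_max_n``
    and the number of classes is at most ``exact_max_classes``.
    """
    canon: dict[str, int] = {}
    for label, count in observed.items():
        if label not in expected.probs:
            try:
                label = parse_genotype(label).label
            except ValueError:
                pass
        if label not in expected.probs:
            raise ValueError(f"observed class {label!r} not among expected classes "
                             f"{expected.classes}")
        if label in canon:
            raise ValueError(f"duplicate observed class {label!r}")
        canon[label] = int(count)

    classes = list(expected.classes)
    obs = [canon.get(c, 0) for c in classes]
    n = sum(obs)
    if n < 1:
        raise ValueError("total observed count must be at least 1")
    probs = [float(expected.probs[c]) for c in classes]
    for c, p, o in zip(classes, probs, obs):
        if p == 0 and o > 0:
            raise ValueError(f"class {c!r} has expected probability 0 but observed count {o}")

    # Drop structurally impossible (probability-0, count-0) classes from the test.
    kept = [(c, p, o) for c, p, o in zip(classes, probs, obs) if p > 0]
    classes = [c for c, _, _ in kept]
    probs = [p for _, p, _ in kept]
    obs = [o for _, _, o in kept]

    exp_counts = [n * p for p in probs]
    chi2 = _chi2_stat(obs, exp_counts)
    df = len(classes) - 1
    if df < 1:
        raise ValueError("goodness of fit needs at least two classes")
    p_chi2 = float(stats.chi2.sf(chi2, df))

    p_exact = None
    if n <= exact_max_n and len(classes) <= exact_max_classes:
        p_exact = _exact_multinomial_p(obs, probs)

    return GOFResult(
        chi2=float(chi2),
        df=df,
        p_chi2=p_chi2,
        p_exact=p_exact,
        n=n,
        expected_counts=dict(zip(classes, exp_counts)),
    )


def _exact_multinomial_p(observed: Sequence[int], probs: Sequence[float]) -> float:
    """Exact multinomial goodness-of-fit p by enumeration.

    Sums the probability of every outcome vector whose chi-square statistic is
    at least as extreme as the observed one (with a small tolerance for
    floating-point ties).
    """
    n = sum(observed)
    k = len(probs)
    expected = [n * p for p in probs]
    chi2_obs = _chi2_stat(observed, expected)
    log_probs = [math.log(p) for p in probs]
    log_nfact = math.lgamma(n + 1)

    total = 0.0
    for counts in _compositions(n, k):
        if _chi2_stat(counts, expected) >= chi2_obs - 1e-9:
            logp = log_nfact + sum(
                c * lp - math.lgamma(c + 1) for c, lp in zip(counts, log_probs)
            )
            total += math.exp(logp)
    return min(total, 1.0)


def _compositions(n: int, k: int):
    """Yield all k-tuples of non-negative integers summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)
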