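"""Single-locus gamete models for autotetraploid meiosis.

An autotetraploid carries four homologs of each chromosome. A locus at which
``d`` of the four homologs carry the allele of interest (the *donor* allele,
here the non-recurrent-parent allele) is called nulliplex (d=0), simplex
(d=1), duplex (d=2), triplex (d=3) or quadruplex (d=4). Gametes receive two
chromatids, so the donor-allele dosage of a gamete is 0, 1 or 2.

How chromatids assort depends on whether the locus recombines with its
centromere:

* **random chromosome segregation** — no locus–centromere crossover; a gamete
  is one chromatid from each of two distinct homologs. Double-reduction
  coefficient alpha = 0.
* **random chromatid segregation** — chromatids assort freely; any of the
  C(8,2)=28 chromatid pairs is a gamete. alpha = 1/7.
* **maximum equational segregation** — a locus–centromere crossover always
  occurs; alpha = 1/6, the ceiling of double reduction.

alpha is the probability that a gamete carries two chromatids derived from
the same original homolog (double reduction). For intermediate alpha the
classical single-locus closed forms are, writing the gamete distribution as
(p2, p1, p0) over donor dosage:

* simplex:  (alpha/4, (1-alpha)/2, 1/2 + alpha/4)
* duplex:   ((1+2*alpha)/6, (4-4*alpha)/6, (1+2*alpha)/6)

Triplex/quadruplex follow by swapping the roles of the two alleles, and
nulliplex is degenerate. In a backcross of an F1 to a parent contributing
only null gametes (donor dosage 0), progeny scored for donor-allele
*presence* segregate het:hom = (1-p0):p0 — hence the textbook ratios 1:1,
13:15, 11:13 for simplex and 5:1, 11:3, 7:2 for duplex under the three
named models.

`gamete_dosage_distribution` implements the closed forms;
`enumerate_chromatid_gametes` derives the same distributions for the three
named models by exhaustive enumeration in exact rational arithmetic, and
serves as the independent check on the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

__all__ = [
    "SegModel",
    "DosageDistribution",
    "MODEL_ALPHAS",
    "ALPHA_MAX",
    "gamete_dosage_distribution",
    "enumerate_chromatid_gametes",
    "expected_bc1_ratio",
]

#: Double-reduction coefficients of the three named segregation models.
MODEL_ALPHAS: dict[str, Fraction] = {
    "random_chromosome": Fraction(0),
    "random_chromatid": Fraction(1, 7),
    "max_equational": Fraction(1, 6),
}

#: Upper bound of the double-reduction coefficient (maximum equational).
ALPHA_MAX = Fraction(1, 6)

# the three ways of partitioning homologs {0,1,2,3} into two bivalents
_PAIRINGS = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


@dataclass(frozen=True)
class SegModel:
    """A single-locus segregation model, identified by name and alpha.

    Named models fix alpha (see :data:`MODEL_ALPHAS`); a ``custom`` model
    requires an explicit alpha in [0, 1/6].
    """

    name: str
    alpha: Fraction | float | None = None

    def __post_init__(self) -> None:
        if self.name in MODEL_ALPHAS:
            fixed = MODEL_ALPHAS[self.name]
            if self.alpha is None:
                object.__setattr__(self, "alpha", fixed)
            elif Fraction(self.alpha) != fixed:
                raise ValueError(
                    f"model {self.name!r} implies alpha={fixed}, got {self.alpha}"
                )
        elif self.name == "custom":
            if self.alpha is None:
                raise ValueError("custom model requires an explicit alpha")
            if not 0 <= self.alpha <= ALPHA_MAX:
                raise ValueError(
                    f"alpha must lie in [0, 1/6], got {self.alpha}"
                )
        else:
            raise ValueError(
                f"unknown model {self.name!r}; choose one of "
                f"{sorted(MODEL_ALPHAS)} or 'custom'"
            )

    @property
    def is_named(self) -> bool:
        return self.name in MODEL_ALPHAS


@dataclass(frozen=True)
class DosageDistribution:
    """Probabilities that a gamete carries 0, 1 or 2 donor-allele copies."""

    p0: Fraction | float
    p1: Fraction | float
    p2: Fraction | float

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1, self.p2):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if abs(self.p0 + self.p1 + self.p2 - 1) > 1e-12:
            raise ValueError("dosage probabilities must sum to 1")

    def as_tuple(self) -> tuple:
        return (self.p0, self.p1, self.p2)

    def reversed(self) -> "DosageDistribution":
        """Swap the roles of the two alleles (dosage d -> 2-d)."""
        return DosageDistribution(self.p2, self.p1, self.p0)


def _check_dosage(f1_dosage: int) -> None:
    if not isinstance(f1_dosage, (int,)) or isinstance(f1_dosage, bool):
        raise ValueError(f"f1_dosage must be an integer, got {f1_dosage!r}")
    if not 0 <= f1_dosage <= 4:
        raise ValueError(f"f1_dosage must lie in 0..4, got {f1_dosage}")


def gamete_dosage_distribution(f1_dosage: int, model: SegModel) -> DosageDistribution:
    """Closed-form gamete dosage distribution for a tetraploid parent.

    Parameters
    ----------
    f1_dosage
        Donor-allele dosage of the parent, 0..4.
    model
        Segregation model supplying the double-reduction coefficient alpha.

    Returns
    -------
    DosageDistribution
        Exact (``Fraction``) when alpha is rational, float otherwise.
    """
    _check_dosage(f1_dosage)
    a = model.alpha
    if isinstance(a, float):
        half, sixth = 0.5, 1.0 / 6.0
    else:
        a = Fraction(a)
        half, sixth = Fraction(1, 2), Fraction(1, 6)

    if f1_dosage == 0:
        zero, one = 0 * a, 1 + 0 * a
        return DosageDistribution(one, zero, zero)
    if f1_dosage == 1:
        p2 = a / 4
        p1 = (1 - a) * half
        return DosageDistribution(1 - p1 - p2, p1, p2)
    if f1_dosage == 2:
        p2 = (1 + 2 * a) * sixth
        p1 = 1 - 2 * p2
        return DosageDistribution(p2, p1, p2)
    # triplex / quadruplex by allele-swap symmetry
    return gamete_dosage_distribution(4 - f1_dosage, model).reversed()


def enumerate_chromatid_gametes(f1_dosage: int, model: SegModel) -> DosageDistribution:
    """Gamete dosage distribution by exhaustive chromatid enumeration.

    Brute-force oracle for the three named models, in exact rational
    arithmetic. Each homolog contributes two sister chromatids carrying the
    same allele; the three models differ in which chromatid pairs can end up
    in a gamete:

    * random_chromosome — one chromatid from each of two distinct homologs;
    * random_chromatid — any of the C(8,2)=28 chromatid pairs;
    * max_equational — one obligate locus–centromere exchange per bivalent,
      so each centromere unit carries one chromatid of each homolog of its
      bivalent; gametes are the 24 chromatid pairs not sharing a centromere
      unit, averaged over the three bivalent pairings.
    """
    _check_dosage(f1_dosage)
    if not model.is_named:
        raise ValueError(
            "enumeration oracle is defined only for the named models, "
            f"not {model.name!r}"
        )
    alleles = [1] * f1_dosage + [0] * (4 - f1_dosage)
    counts = {0: Fraction(0), 1: Fraction(0), 2: Fraction(0)}

    if model.name == "random_chromosome":
        pairs = list(combinations(range(4), 2))
        w = Fraction(1, len(pairs))
        for i, j in pairs:
            counts[alleles[i] + alleles[j]] += w
    elif model.name == "random_chromatid":
        chromatids = [a for a in alleles for _ in range(2)]
        pairs = list(combinations(range(8), 2))
        w = Fraction(1, len(pairs))
        for i, j in pairs:
            counts[chromatids[i] + chromatids[j]] += w
    else:  # max_equational
        for bivalents in _PAIRINGS:
            # centromere unit of homolog k (paired with partner m) carries
            # one chromatid with allele[k] and one with allele[m]
            chromatids = []  # (unit, allele)
            for i, j in bivalents:
                chromatids += [(i, alleles[i]), (i, alleles[j])]
                chromatids += [(j, alleles[j]), (j, alleles[i])]
            legal = [
                (a, b)
                for a, b in combinations(chromatids, 2)
                if a[0] != b[0]
            ]
            w = Fraction(1, len(_PAIRINGS) * len(legal))
            for a, b in legal:
                counts[a[1] + b[1]] += w

    return DosageDistribution(counts[0], counts[1], counts[2])


def expected_bc1_ratio(f1_dosage: int, model: SegModel) -> float:
    """Expected het:hom ratio among BC1 progeny scored for donor presence.

    The recurrent parent contributes a null gamete, so a progeny individual
    is heterozygous (donor present) unless the F1 gamete had dosage 0:
    ratio = (1 - p0) / p0.

    Raises
    ------
    ValueError
        If p0 = 0 (quadruplex parent), where the ratio is undefined.
    """
    dist = gamete_dosage_distribution(f1_dosage, model)
    if dist.p0 == 0:
        raise ValueError(
            f"het:hom ratio undefined for f1_dosage={f1_dosage}: no "
            "homozygous progeny are produced (p0 = 0)"
        )
    return float((1 - dist.p0) / dist.p0)
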