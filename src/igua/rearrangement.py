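"""Generative model of unmutated V(D)J rearrangements.

A rearrangement hypothesis (segments, trim counts, N-region sequences)
deterministically assembles one candidate unmutated ancestor. This module
builds that sequence, evaluates the (improper) prior of a hypothesis, and —
for small toy libraries — computes the exact prior mass of an ancestor by
enumeration, which serves as an independent oracle for the inference engine.

N nucleotides are nontemplated bases inserted by TdT at segment junctions;
their composition prior pi_N defaults to uniform (1/4 per base) and their
length prior is improper-uniform up to an operational cap ``n_max``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .germline import (
    NUCLEOTIDES,
    P_MAX,
    LibrarySet,
    Role,
    trim_range,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RearrangementError(ValueError):
    """Raised for parameter values inconsistent with the library."""


@dataclass(frozen=True)
class RearrangementParams:
    """One rearrangement hypothesis.

    Trim counts follow the joining-end convention of :mod:`igua.germline`;
    ``n1`` is the V-(D or J) junction N region, ``n2`` the D-J junction
    (heavy chains only). Light chains leave all D fields as ``None``.
    """

    v_id: str
    j_id: str
    r_v: int
    r_j: int
    n1: str = ""
    d_id: Optional[str] = None
    r_d1: Optional[int] = None
    r_d2: Optional[int] = None
    n2: Optional[str] = None

    @property
    def chain(self) -> str:
        return "heavy" if self.d_id is not None else "light"

    def __post_init__(self) -> None:
        for n in (self.n1, self.n2 or ""):
            bad = set(n) - set(NUCLEOTIDES)
            if bad:
                raise RearrangementError(f"N region has non-ACGT bases {sorted(bad)!r}")
        if self.d_id is not None and (self.r_d1 is None or self.r_d2 is None):
            raise RearrangementError("heavy-chain params need both D trims")
        if self.d_id is None and any(
            x is not None for x in (self.r_d1, self.r_d2, self.n2)
        ):
            raise RearrangementError("light-chain params must leave D fields unset")


@dataclass
class PriorConfig:
    """Prior hyperparameters for the rearrangement model.

    pi_n: composition prior of N nucleotides (uniform by default).
    n_max: operational cap on the improper-uniform N-length prior, per
        junction. 30 nt comfortably exceeds junction lengths seen in real
        repertoires.
    d_trim_max: operational cap on germline trimming per D end; exonuclease
        processing beyond ~10 nt per end is not biologically plausible, and
        an uncapped uniform makes most of the D unrecoverable by any method.
    """

    pi_n: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in NUCLEOTIDES}
    )
    n_max: int = 30
    d_trim_max: int = 10

    def __post_init__(self) -> None:
        if abs(sum(self.pi_n.values()) - 1.0) > 1e-9:
            raise ValueError("pi_n must sum to 1")
        if self.n_max < 0:
            raise ValueError("n_max must be >= 0")


def segment_fragment(sequence: str, role: Role, *trims: int) -> str:
    """Apply trim counts to one germline segment.

    V trims act on the 3' end, J trims on the 5' end, D takes (5', 3') trims.
    Negative counts append P nucleotides: the reverse complement of the
    terminal germline bases, as produced by asymmetric hairpin opening.
    """
    n = len(sequence)
    if role is Role.V:
        (r,) = trims
        r1, r2 = 0, r
    elif role is Role.J:
        (r,) = trims
        r1, r2 = r, 0
    else:
        r1, r2 = trims
    for r in (r1, r2):
        if r < -P_MAX:
            raise RearrangementError(f"trim {r} below the -{P_MAX} P-nucleotide bound")
    if max(r1, 0) + max(r2, 0) > n:
        raise RearrangementError(
            f"trims ({r1}, {r2}) remove more than the {n} nt segment"
        )
    core = sequence[max(r1, 0) : n - max(r2, 0)]
    prefix = revcomp(sequence[: -r1]) if r1 < 0 else ""
    suffix = revcomp(sequence[n + r2 :]) if r2 < 0 else ""
    return prefix + core + suffix


def build_ancestor_sequence(
    params: RearrangementParams, library: LibrarySet, validate: bool = True
) -> str:
    """Assemble the unmutated ancestor S(V,(D),J,R,n) for one hypothesis."""
    v = library.v.get(params.v_id)
    j = library.j.get(params.j_id)
    if validate:
        _check_trim(v, params.r_v)
        _check_trim(j, params.r_j)
    parts = [segment_fragment(v.sequence, Role.V, params.r_v), params.n1]
    if params.d_id is not None:
        d = library.library(Role.D).get(params.d_id)
        if validate:
            _check_trim(d, params.r_d1)
            _check_trim(d, params.r_d2)
        parts.append(segment_fragment(d.sequence, Role.D, params.r_d1, params.r_d2))
        parts.append(params.n2 or "")
    parts.append(segment_fragment(j.sequence, Role.J, params.r_j))
    return "".join(parts)


def _check_trim(segment, r: int) -> None:
    lo, hi = trim_range(segment)
    if not lo <= r <= hi:
        raise RearrangementError(
            f"{segment.segment_id}: trim {r} outside [{lo}, {hi}]"
        )


def log_prior(
    params: RearrangementParams, library: LibrarySet, config: PriorConfig
) -> float:
    """Improper log prior pi(V,RV) pi(J,RJ) [pi(D,RD1,RD2)] pi(n).

    Segment factors are the locus-uniform allele priors; trims are uniform
    over their segment's allowed range; each N base contributes log pi_N and
    the N length itself carries no factor (improper-uniform up to n_max).
    """
    v = library.v.get(params.v_id)
    j = library.j.get(params.j_id)
    lp = math.log(library.v.allele_prior[params.v_id])
    lp += math.log(library.j.allele_prior[params.j_id])
    lp -= math.log(_range_size(v))
    lp -= math.log(_range_size(j))
    n_regions = [params.n1]
    if params.d_id is not None:
        d = library.library(Role.D).get(params.d_id)
        lp += math.log(library.d.allele_prior[params.d_id])
        lp -= 2.0 * math.log(_range_size(d, config))
        n_regions.append(params.n2 or "")
    for n in n_regions:
        if len(n) > config.n_max:
            return -math.inf
        lp += sum(math.log(config.pi_n[b]) for b in n)
    return lp


def _range_size(segment, config: Optional[PriorConfig] = None) -> int:
    lo, hi = trim_range(segment)
    if segment.role is Role.D and config is not None:
        hi = min(hi, config.d_trim_max)
    return hi - lo + 1


def d_trim_pairs(segment, config: PriorConfig) -> Iterator[tuple[int, int]]:
    """Admissible (5', 3') D trim pairs: each within its capped range and
    leaving at least one germline base."""
    lo, _ = trim_range(segment)
    hi = min(len(segment.sequence), config.d_trim_max)
    for r1 in range(lo, hi + 1):
        for r2 in range(lo, hi + 1):
            if max(r1, 0) + max(r2, 0) <= len(segment.sequence) - 1:
                yield (r1, r2)


def iter_hypotheses(
    library: LibrarySet, config: PriorConfig, n_max: Optional[int] = None
) -> Iterator[RearrangementParams]:
    """Enumerate every parameter tuple (including explicit N sequences).

    Exponential in n_max; intended for the exhaustive-Bayes oracle on toy
    libraries, not for inference.
    """
    n_max = config.n_max if n_max is None else n_max
    n_strings = [
        "".join(bases)
        for k in range(n_max + 1)
        for bases in itertools.product(NUCLEOTIDES, repeat=k)
    ]
    for v in library.v:
        for r_v in range(*_closed(trim_range(v))):
            for j in library.j:
                for r_j in range(*_closed(trim_range(j))):
                    if library.d is None:
                        for n1 in n_strings:
                            yield RearrangementParams(
                                v_id=v.segment_id, j_id=j.segment_id,
                                r_v=r_v, r_j=r_j, n1=n1,
                            )
                    else:
                        for d in library.d:
                            for r_d1, r_d2 in d_trim_pairs(d, config):
                                for n1 in n_strings:
                                    for n2 in n_strings:
                                        yield RearrangementParams(
                                            v_id=v.segment_id, j_id=j.segment_id,
                                            r_v=r_v, r_j=r_j, n1=n1,
                                            d_id=d.segment_id,
                                            r_d1=r_d1, r_d2=r_d2, n2=n2,
                                        )


def _closed(rng: tuple[int, int]) -> tuple[int, int]:
    return (rng[0], rng[1] + 1)


def count_hypotheses(library: LibrarySet, config: PriorConfig, n_max: int) -> int:
    n_strings = sum(4**k for k in range(n_max + 1))
    total = 0
    vj = sum(_range_size(v) for v in library.v) * sum(
        _range_size(j) for j in library.j
    )
    if library.d is None:
        return vj * n_strings
    d_pairs = sum(len(list(d_trim_pairs(d, config))) for d in library.d)
    total = vj * d_pairs * n_strings**2
    return total


def ancestor_prior_mass(
    alpha: str,
    library: LibrarySet,
    config: PriorConfig,
    n_max: Optional[int] = None,
    budget: int = 2_000_000,
) -> float:
    """Exact P0(alpha): summed prior of every tuple generating ``alpha``,
    normalized over all sequences generable in the enumeration.

    Test oracle only — raises if the enumeration exceeds ``budget`` tuples.
    """
    n_max = config.n_max if n_max is None else n_max
    n_tuples = count_hypotheses(library, config, n_max)
    if n_tuples > budget:
        raise RearrangementError(
            f"enumeration of {n_tuples} tuples exceeds budget {budget}; "
            "ancestor_prior_mass is an oracle for toy libraries only"
        )
    mass = 0.0
    total = 0.0
    for params in iter_hypotheses(library, config, n_max=n_max):
        w = math.exp(log_prior(params, library, config))
        total += w
        if build_ancestor_sequence(params, library, validate=False) == alpha:
            mass += w
    return mass / total if total > 0 else 0.0
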