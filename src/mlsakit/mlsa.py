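"""Concatenation, sequence types and MLSA similarity.

The scheme concatenates five housekeeping loci in a fixed order
(gyrB, rpoD, dnaK, trpB, recA), assigns multilocus sequence types from
per-locus allele numbers, and measures pairwise similarity on the
concatenated alignment. The locus order affects column coordinates but not
similarity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import diversity
from .errors import EmptyInputError, MissingLocusError
from .seqio import GeneAlignment, SimilarityMatrix

__all__ = [
    "LOCUS_ORDER",
    "AlleleProfile",
    "concatenate",
    "assign_sts",
    "mlsa_similarity",
]

#: canonical concatenation order of the five housekeeping loci
LOCUS_ORDER: tuple[str, ...] = ("gyrB", "rpoD", "dnaK", "trpB", "recA")


@dataclass(frozen=True)
class AlleleProfile:
    """Per-strain allele tuple over the scheme's loci plus its sequence
    type (ST) number; strains share an ST iff their tuples are identical."""

    strain_id: str
    alleles: tuple[int, ...]
    st: int


def _check_strains(
    alignments: Sequence[GeneAlignment], allow_missing: bool
) -> tuple[str, ...]:
    """Common strain ordering across loci; loud failure on mismatch."""
    ref = alignments[0].strain_ids
    common = set(ref)
    for aln in alignments:
        common &= set(aln.strain_ids)
    for aln in alignments:
        extra_missing = set(ref) - set(aln.strain_ids)
        if extra_missing and not allow_missing:
            strain = sorted(extra_missing)[0]
            raise MissingLocusError(
                f"strain {strain!r} missing from locus {aln.locus!r}"
            )
    if common != set(ref):
        warnings.warn(
            f"restricting to {len(common)} strains present at every locus",
            stacklevel=3,
        )
    return tuple(s for s in ref if s in common)


def concatenate(
    alignments: Sequence[GeneAlignment],
    order: Sequence[str] | None = None,
    allow_missing: bool = False,
) -> GeneAlignment:
    """Join per-locus alignments end-to-end, per strain.

    ``order`` rearranges the inputs by locus name (the CLI passes the
    canonical five-gene order); with ``order=None`` the given order is
    kept. Locus boundary coordinates (0-based, half-open) are recorded in
    the result's ``boundaries``. A strain absent from any locus fails the
    run unless ``allow_missing`` downgrades that to exclusion + warning.
    """
    if not alignments:
        raise EmptyInputError("no alignments to concatenate")
    if order is not None:
        by_name = {a.locus: a for a in alignments}
        missing = [name for name in order if name not in by_name]
        if missing:
            raise MissingLocusError(f"no alignment for locus {missing[0]!r}")
        alignments = [by_name[name] for name in order]
    strains = _check_strains(alignments, allow_missing)

    boundaries: dict[str, tuple[int, int]] = {}
    offset = 0
    for aln in alignments:
        boundaries[aln.locus] = (offset, offset + aln.n_columns)
        offset += aln.n_columns
    sequences = {
        s: "".join(a.sequences[s] for a in alignments) for s in strains
    }
    locus = "+".join(a.locus for a in alignments)
    return GeneAlignment(locus, sequences, boundaries=boundaries)


def assign_sts(
    per_locus_alleles: Sequence[Mapping[str, int]]
) -> list[AlleleProfile]:
    """Assign sequence types from per-locus allele maps.

    ST numbers start at 1 in order of first appearance over the strain
    order of the first map.
    """
    if not per_locus_alleles:
        raise EmptyInputError("no allele maps given")
    strains = list(per_locus_alleles[0])
    ref = set(strains)
    for k, m in enumerate(per_locus_alleles):
        if set(m) != ref:
            diff = sorted(ref.symmetric_difference(m))[0]
            raise MissingLocusError(
                f"strain {diff!r} not shared by allele map {k}"
            )
    st_of: dict[tuple[int, ...], int] = {}
    profiles = []
    for s in strains:
        tup = tuple(m[s] for m in per_locus_alleles)
        if tup not in st_of:
            st_of[tup] = len(st_of) + 1
        profiles.append(AlleleProfile(strain_id=s, alleles=tup, st=st_of[tup]))
    return profiles


def mlsa_similarity(
    alignments: Sequence[GeneAlignment],
    gap_policy: str = "pairwise-deletion",
    order: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Pairwise percent identity on the concatenated alignment."""
    return diversity.pairwise_identity(
        concatenate(alignments, order=order), gap_policy
    )
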