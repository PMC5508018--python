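"""Per-locus nucleotide diversity statistics.

For each housekeeping locus (and 16S) this module computes the battery a
classical MLSA study reports: number of alleles, parsimony-informative
sites, mean G+C content, pairwise identity summaries and the
Nei–Gojobori Ka/Ks estimate of selective pressure.

Conventions shared by every statistic here:

* only the unambiguous states A/C/G/T are counted; gaps and IUPAC
  ambiguity codes are missing data, never a fifth character state;
* reported percentages are rounded half-up, to 2 decimals when the value
  is below 10 and to 1 decimal otherwise (the mixed precision of typical
  diversity tables);
* the denominator of the parsimony-informative percentage is the minimum
  per-sequence ungapped length across the alignment, i.e. the length of
  the shortest trimmed sequence.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from ._genetic_code import (
    CODON_TO_AA,
    UNAMBIGUOUS,
    is_stop,
    is_synonymous,
)
from .errors import (
    FrameError,
    InsufficientDataError,
    UndefinedContentError,
    UndefinedSimilarityError,
)
from .seqio import GeneAlignment, SimilarityMatrix

__all__ = [
    "LocusStats",
    "KaKsResult",
    "round_report",
    "pi_percent",
    "count_alleles",
    "parsimony_informative",
    "mean_gc",
    "pairwise_identity",
    "similarity_summary",
    "nei_gojobori_kaks",
    "locus_stats",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def round_report(value: float) -> float:
    """Round half-up: 2 decimals below 10, 1 decimal from 10 up."""
    q = Decimal("0.01") if value < 10 else Decimal("0.1")
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pi_percent(pi_count: int, denominator: int) -> float:
    """Parsimony-informative percentage under the reporting convention."""
    return round_report(100.0 * pi_count / denominator)


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: float | None  # None when Ks == 0 (undefined, not zero)
    n_pairs: int
    n_dropped: int  # saturated pairs excluded


@dataclass(frozen=True)
class LocusStats:
    """One row of a per-locus diversity table."""

    locus: str
    length_min: int
    length_max: int
    n_alleles: int
    pi_count: int
    pi_pct: float
    mean_gc: float
    sim_min: float
    sim_max: float
    sim_mean: float
    ka: float | None = None
    ks: float | None = None
    kaks_ratio: float | None = None


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of unambiguous A/C/G/T cells."""
    return np.isin(arr, _ACGT)


# ---------------------------------------------------------------------------

def count_alleles(aln: GeneAlignment) -> tuple[int, dict[str, int]]:
    """Group strains by exact (case-insensitive) sequence identity.

    Allele numbers start at 1 in order of first appearance.
    """
    allele_of: dict[str, int] = {}
    seen: dict[str, int] = {}
    for sid, seq in aln.sequences.items():
        if seq not in seen:
            seen[seq] = len(seen) + 1
        allele_of[sid] = seen[seq]
    return len(seen), allele_of


def parsimony_informative(aln: GeneAlignment) -> tuple[int, float]:
    """Count parsimony-informative columns.

    A column is informative iff, among unambiguous A/C/G/T states only, at
    least two distinct states each occur in at least two sequences. The
    percentage uses the minimum ungapped sequence length as denominator.
    """
    if len(aln) < 2:
        raise InsufficientDataError(
            "parsimony-informative sites need >= 2 sequences"
        )
    arr = aln.to_array()
    valid = _valid_mask(arr)
    counts = np.stack(
        [((arr == b) & valid).sum(axis=0) for b in _ACGT]
    )  # (4, n_columns)
    pi_count = int(((counts >= 2).sum(axis=0) >= 2).sum())
    denominator = int(valid.sum(axis=1).min())
    # an all-missing sequence makes the percentage vacuous, not an error
    pct = pi_percent(pi_count, denominator) if denominator > 0 else 0.0
    return pi_count, pct


def mean_gc(aln: GeneAlignment) -> float:
    """Unweighted mean of per-sequence G+C fractions (mol%), counting only
    unambiguous bases."""
    arr = aln.to_array()
    valid = _valid_mask(arr)
    totals = valid.sum(axis=1)
    if np.any(totals == 0):
        sid = aln.strain_ids[int(np.argmax(totals == 0))]
        raise UndefinedContentError(
            f"sequence {sid!r} has no unambiguous bases"
        )
    gc = ((arr == ord("G")) | (arr == ord("C"))).sum(axis=1)
    return round_report(float(np.mean(gc / totals)) * 100.0)


def pairwise_identity(
    aln: GeneAlignment, gap_policy: str = "pairwise-deletion"
) -> SimilarityMatrix:
    """Percent identity for every strain pair.

    ``pairwise-deletion`` drops, per pair, any column with a gap or
    ambiguity in either member; ``complete-deletion`` drops columns with a
    gap or ambiguity in any sequence before comparing.
    """
    if gap_policy not in ("pairwise-deletion", "complete-deletion"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    if len(aln) < 2:
        raise InsufficientDataError("pairwise identity needs >= 2 sequences")
    arr = aln.to_array()
    valid = _valid_mask(arr)
    if gap_policy == "complete-deletion":
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    n = arr.shape[0]
    out = np.full((n, n), 100.0)
    ids = aln.strain_ids
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise UndefinedSimilarityError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
                )
            matches = int(((arr[i] == arr[j]) & both).sum())
            out[i, j] = out[j, i] = 100.0 * matches / comparable
    return SimilarityMatrix(ids, out, "identity")


def similarity_summary(m: SimilarityMatrix) -> tuple[float, float, float]:
    """(min, max, mean) over the strict upper triangle, reporting-rounded."""
    n = len(m.strain_ids)
    if n < 2:
        raise InsufficientDataError("similarity summary needs >= 2 strains")
    iu = np.triu_indices(n, k=1)
    vals = m.values[iu]
    return (
        round_report(float(vals.min())),
        round_report(float(vals.max())),
        round_report(float(vals.mean())),
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three possible single-base
    changes that are synonymous; changes to stop codons count as
    nonsynonymous.
    """
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if not is_stop(mutant) and is_synonymous(codon, mutant):
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) observed differences between two sense
    codons, averaged with equal weight over all minimal mutation pathways
    that avoid stop codons (all pathways if every one is blocked)."""
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_positions):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt):
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if not is_stop(a) and not is_stop(b) and is_synonymous(a, b):
                syn += 1.0
            else:
                nonsyn += 1.0
    k = len(usable)
    return syn / k, nonsyn / k


def _jukes_cantor(p: float) -> float:
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def nei_gojobori_kaks(aln: GeneAlignment) -> KaKsResult:
    """Nei–Gojobori (1986-style) Ka/Ks for a coding alignment.

    Pairwise dN and dS (Jukes–Cantor corrected proportions) are averaged
    over all strain pairs; the reported ratio is the ratio of those means.
    Codons with a gap or ambiguity in either member of a pair are skipped
    for that pair. Pairs with pS or pN >= 0.75 are saturated and dropped
    with a warning; a zero mean dS leaves the ratio undefined (None).
    """
    if aln.n_columns % 3 != 0:
        raise FrameError(
            f"alignment length {aln.n_columns} is not a multiple of 3"
        )
    if len(aln) < 2:
        raise InsufficientDataError("Ka/Ks needs >= 2 sequences")

    seqs = aln.sequences
    n_codons = aln.n_columns // 3
    codon_lists: dict[str, list[str | None]] = {}
    for sid, seq in seqs.items():
        codons: list[str | None] = []
        for k in range(n_codons):
            cod = seq[3 * k : 3 * k + 3]
            if set(cod) <= UNAMBIGUOUS:
                if is_stop(cod):
                    if k < n_codons - 1:
                        raise FrameError(
                            f"internal stop codon {cod} at codon {k + 1} "
                            f"in {sid!r}"
                        )
                    codons.append(None)  # terminal stop: not informative
                else:
                    codons.append(cod)
            else:
                codons.append(None)
        codon_lists[sid] = codons

    site_cache: dict[str, tuple[float, float]] = {}
    diff_cache: dict[tuple[str, str], tuple[float, float]] = {}

    def sites(c: str) -> tuple[float, float]:
        if c not in site_cache:
            site_cache[c] = _codon_sites(c)
        return site_cache[c]

    def diffs(a: str, b: str) -> tuple[float, float]:
        key = (a, b) if a <= b else (b, a)
        if key not in diff_cache:
            diff_cache[key] = _codon_differences(*key)
        return diff_cache[key]

    ids = list(seqs)
    dn_vals: list[float] = []
    ds_vals: list[float] = []
    n_dropped = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ci, cj = codon_lists[ids[i]], codon_lists[ids[j]]
            S = N = Sd = Nd = 0.0
            for a, b in zip(ci, cj):
                if a is None or b is None:
                    continue
                sa, na = sites(a)
                sb, nb = sites(b)
                S += 0.5 * (sa + sb)
                N += 0.5 * (na + nb)
                sd, nd = diffs(a, b)
                Sd += sd
                Nd += nd
            if S == 0 or N == 0:
                continue
            pS, pN = Sd / S, Nd / N
            if pS >= 0.75 or pN >= 0.75:
                n_dropped += 1
                warnings.warn(
                    f"pair ({ids[i]}, {ids[j]}) saturated "
                    f"(pS={pS:.3f}, pN={pN:.3f}); dropped",
                    stacklevel=2,
                )
                continue
            ds_vals.append(float(_jukes_cantor(pS)))
            dn_vals.append(float(_jukes_cantor(pN)))

    if not dn_vals:
        raise InsufficientDataError("no usable pairs for Ka/Ks")
    ka = float(np.mean(dn_vals))
    ks = float(np.mean(ds_vals))
    ratio = ka / ks if ks > 0 else None
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, n_pairs=len(dn_vals),
                      n_dropped=n_dropped)


# ---------------------------------------------------------------------------

def locus_stats(aln: GeneAlignment, coding: bool) -> LocusStats:
    """Compose the full diversity row for one locus.

    Ka/Ks fields are omitted (None) for non-coding loci such as 16S.
    """
    arr = aln.to_array()
    ungapped = (arr != ord("-")).sum(axis=1)
    n_alleles, _ = count_alleles(aln)
    pi_count, pi_pct = parsimony_informative(aln)
    sim = pairwise_identity(aln)
    smin, smax, smean = similarity_summary(sim)
    stats = LocusStats(
        locus=aln.locus,
        length_min=int(ungapped.min()),
        length_max=int(ungapped.max()),
        n_alleles=n_alleles,
        pi_count=pi_count,
        pi_pct=pi_pct,
        mean_gc=mean_gc(aln),
        sim_min=smin,
        sim_max=smax,
        sim_mean=smean,
    )
    if coding:
        kk = nei_gojobori_kaks(aln)
        stats = LocusStats(
            **{
                **stats.__dict__,
                "ka": kk.ka,
                "ks": kk.ks,
                "kaks_ratio": kk.ratio,
            }
        )
    return stats
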