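"""Multi-evidence species demarcation.

Combines the soft MLSA boundary with genome-level evidence (dDDH, ANI)
and the 16S screen into a species partition:

1. a strain pair with MLSA similarity at or above the upper zone bound is
   the same species; below the lower bound, different species; in the
   ambiguous zone in between the call is deferred;
2. ambiguous pairs are resolved by dDDH against the 70% boundary, or —
   when dDDH is unavailable — by ANI (same >= 96%, different < 95%, the
   95-96% band stays ambiguous per the published narrowed boundary);
3. clusters are the single-linkage closure over resolved same-species
   pairs; a pair whose non-ambiguous MLSA verdict contradicts dDDH or ANI
   is flagged as a conflict (for MLSA-vs-dDDH contradictions, dDDH wins
   the final label);
4. clusters containing no user-designated reference (type) strain are
   putative novel species.

The 16S screen reports pairs the 16S rRNA gene cannot split (similarity
at or above 98.65% by default), which is what motivates MLSA in the
first place.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .calibration import ThresholdZones
from .errors import InvalidParameterError, MatrixRangeError
from .seqio import SimilarityMatrix

__all__ = [
    "SpeciesPartition",
    "classify_pair",
    "resolve_ambiguous",
    "demarcate",
    "screen_16s",
]

SAME = "same"
AMBIGUOUS = "ambiguous"
DIFFERENT = "different"

DDDH_THRESHOLD = 70.0
ANI_SAME = 96.0
ANI_DIFFERENT = 95.0
SIXTEEN_S_THRESHOLD = 98.65


@dataclass(frozen=True)
class SpeciesPartition:
    """Demarcation result: clusters, per-pair labels/evidence, conflicts
    and putative novel clusters (those without a reference type strain)."""

    clusters: tuple[frozenset[str], ...]
    pair_labels: dict[tuple[str, str], str]
    evidence: dict[tuple[str, str], list[tuple[str, float, str]]]
    conflicts: frozenset[tuple[str, str]]
    putative_novel: tuple[frozenset[str], ...]

    @property
    def n_species(self) -> int:
        return len(self.clusters)

    def cluster_of(self, strain_id: str) -> frozenset[str]:
        for c in self.clusters:
            if strain_id in c:
                return c
        raise KeyError(strain_id)


def classify_pair(mlsa_sim: float, zones: ThresholdZones) -> str:
    """Three-situation soft-boundary rule on MLSA similarity."""
    if mlsa_sim >= zones.upper:
        return SAME
    if mlsa_sim >= zones.lower:
        return AMBIGUOUS
    return DIFFERENT


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise MatrixRangeError(f"{name} value {value} outside [0, 100]")


def resolve_ambiguous(
    dddh: float | None = None,
    ani: float | None = None,
    dddh_threshold: float = DDDH_THRESHOLD,
    ani_same: float = ANI_SAME,
    ani_different: float = ANI_DIFFERENT,
) -> str:
    """Resolve an MLSA-ambiguous pair with genome evidence.

    dDDH is decisive when present; otherwise ANI decides outside its
    borderline 95-96% band; with neither, the pair stays ambiguous.
    """
    if dddh is not None:
        _check_pct("dDDH", dddh)
        return SAME if dddh >= dddh_threshold else DIFFERENT
    if ani is not None:
        _check_pct("ANI", ani)
        if ani >= ani_same:
            return SAME
        if ani < ani_different:
            return DIFFERENT
        return AMBIGUOUS
    return AMBIGUOUS


def _verdict_dddh(v: float, thr: float = DDDH_THRESHOLD) -> str:
    return SAME if v >= thr else DIFFERENT


def _verdict_ani(v: float) -> str:
    if v >= ANI_SAME:
        return SAME
    if v < ANI_DIFFERENT:
        return DIFFERENT
    return AMBIGUOUS


def demarcate(
    mlsa: SimilarityMatrix,
    zones: ThresholdZones,
    dddh: SimilarityMatrix | None = None,
    ani: SimilarityMatrix | None = None,
    references: Iterable[str] = (),
) -> SpeciesPartition:
    """Full species partition from MLSA zones plus optional dDDH/ANI.

    Non-transitive same-species relations are surfaced as conflicts but
    closure is still taken so the output is a partition.
    """
    ids = mlsa.strain_ids
    refs = set(references)

    def opt(m: SimilarityMatrix | None, a: str, b: str) -> float | None:
        if m is None:
            return None
        if a not in m.strain_ids or b not in m.strain_ids:
            return None
        return m[a, b]

    pair_labels: dict[tuple[str, str], str] = {}
    evidence: dict[tuple[str, str], list[tuple[str, float, str]]] = {}
    conflicts: set[tuple[str, str]] = set()

    for a, b, sim in mlsa.pairs():
        key = (a, b)
        mlsa_label = classify_pair(sim, zones)
        ev: list[tuple[str, float, str]] = [("MLSA", sim, mlsa_label)]
        dv, av = opt(dddh, a, b), opt(ani, a, b)
        if dv is not None:
            _check_pct("dDDH", dv)
            ev.append(("dDDH", dv, _verdict_dddh(dv, zones.dddh_anchor)))
        if av is not None:
            _check_pct("ANI", av)
            ev.append(("ANI", av, _verdict_ani(av)))

        if mlsa_label == AMBIGUOUS:
            final = resolve_ambiguous(dddh=dv, ani=av,
                                      dddh_threshold=zones.dddh_anchor)
        else:
            final = mlsa_label
            # genome evidence contradicting a firm MLSA verdict
            if dv is not None and _verdict_dddh(dv, zones.dddh_anchor) != mlsa_label:
                conflicts.add(key)
                final = _verdict_dddh(dv, zones.dddh_anchor)  # dDDH wins
            if av is not None:
                av_label = _verdict_ani(av)
                if av_label != AMBIGUOUS and av_label != mlsa_label:
                    conflicts.add(key)
        pair_labels[key] = final
        evidence[key] = ev

    # single-linkage closure over resolved same pairs
    n = len(ids)
    index = {s: i for i, s in enumerate(ids)}
    adj = np.eye(n, dtype=np.int8)
    for (a, b), lab in pair_labels.items():
        if lab == SAME:
            adj[index[a], index[b]] = adj[index[b], index[a]] = 1
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters = tuple(
        sorted(
            (frozenset(s for s in ids if labels[index[s]] == k)
             for k in range(n_comp)),
            key=lambda c: min(c),
        )
    )

    # non-transitivity: a different-labeled pair forced into one cluster
    for (a, b), lab in pair_labels.items():
        if lab == DIFFERENT and labels[index[a]] == labels[index[b]]:
            conflicts.add((a, b))

    novel = tuple(c for c in clusters if not (c & refs))
    return SpeciesPartition(
        clusters=clusters,
        pair_labels=pair_labels,
        evidence=evidence,
        conflicts=frozenset(conflicts),
        putative_novel=novel,
    )


def screen_16s(
    sixteen_s: SimilarityMatrix, threshold: float = SIXTEEN_S_THRESHOLD
) -> list[tuple[str, str, float]]:
    """Pairs the 16S rRNA gene cannot separate (similarity >= threshold)."""
    if sixteen_s.metric != "identity":
        raise InvalidParameterError("16S screen expects an identity matrix")
    return [
        (a, b, v) for a, b, v in sixteen_s.pairs() if v >= threshold
    ]
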