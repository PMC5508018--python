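"""Input/output for the MLSA pipeline.

Handles the external formats the workflow touches: aligned FASTA (one file
per housekeeping locus), a strain metadata TSV, square similarity matrices
(percent identity, dDDH, ANI) as TSV, Newick trees and JSON reports.

Core in-memory containers live here as well: :class:`StrainRecord`,
:class:`GeneAlignment` and :class:`SimilarityMatrix`. Everything downstream
(diversity statistics, concatenation, trees, demarcation) consumes these.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyInputError,
    MatrixAsymmetryError,
    MatrixRangeError,
    MatrixShapeError,
)

__all__ = [
    "StrainRecord",
    "GeneAlignment",
    "SimilarityMatrix",
    "read_alignment",
    "write_alignment",
    "read_metadata",
    "write_metadata",
    "read_matrix",
    "write_matrix",
    "read_newick",
    "write_newick",
    "write_json_report",
]

#: mirrored cells further apart than this are treated as a data error
MATRIX_ASYMMETRY_TOL = 0.05


@dataclass(frozen=True)
class StrainRecord:
    """One row of the strain metadata table.

    ``true_species`` is only ever populated for synthetic fixtures, where
    the generating process knows the answer; real metadata leaves it None.
    """

    strain_id: str
    collection_no: str | None = None
    origin: str | None = None
    source: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    true_species: str | None = None

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")


@dataclass
class GeneAlignment:
    """An aligned set of nucleotide sequences for one locus, keyed by strain.

    Sequences are stored uppercase over {A,C,G,T,-,IUPAC ambiguity codes};
    insertion order of ``sequences`` is the record order. ``boundaries``
    is populated on concatenated alignments and maps locus name to a
    0-based half-open column interval.
    """

    locus: str
    sequences: dict[str, str]
    boundaries: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError(f"alignment {self.locus!r} has no sequences")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}
        lengths = {sid: len(s) for sid, s in self.sequences.items()}
        if min(lengths.values()) == 0:
            empty = next(s for s, n in lengths.items() if n == 0)
            raise AlignmentShapeError(
                f"alignment {self.locus!r}: sequence for {empty!r} is empty"
            )
        if len(set(lengths.values())) > 1:
            ref_id, ref_len = next(iter(lengths.items()))
            bad = next((s, n) for s, n in lengths.items() if n != ref_len)
            raise AlignmentShapeError(
                f"alignment {self.locus!r}: record {bad[0]!r} has length "
                f"{bad[1]}, expected {ref_len} (as in {ref_id!r})"
            )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def to_array(self) -> np.ndarray:
        """(n_strains, n_columns) uint8 byte matrix of the alignment."""
        return np.frombuffer(
            "".join(self.sequences.values()).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.sequences), self.n_columns)

    def subset(self, strain_ids: Sequence[str]) -> "GeneAlignment":
        return GeneAlignment(
            self.locus,
            {s: self.sequences[s] for s in strain_ids},
            boundaries=self.boundaries,
        )


@dataclass
class SimilarityMatrix:
    """Symmetric percentage matrix over strains (identity, dDDH or ANI)."""

    strain_ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "identity"

    def __post_init__(self) -> None:
        self.strain_ids = tuple(self.strain_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise MatrixShapeError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} strain ids"
            )
        if self.metric not in ("identity", "dDDH", "ANI"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise MatrixRangeError("matrix values must lie in [0, 100]")
        if not np.allclose(self.values, self.values.T, atol=1e-9, rtol=0):
            raise MatrixAsymmetryError("matrix is not symmetric within 1e-9")
        if self.metric == "identity" and not np.allclose(
            np.diag(self.values), 100.0, atol=1e-9
        ):
            raise MatrixRangeError("identity matrix diagonal must be 100")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.strain_ids.index(pair[0])
        j = self.strain_ids.index(pair[1])
        return float(self.values[i, j])

    def pairs(self) -> Iterator[tuple[str, str, float]]:
        """Yield (strain_i, strain_j, value) over the strict upper triangle."""
        ids = self.strain_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                yield ids[i], ids[j], float(self.values[i, j])

    def reorder(self, strain_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.strain_ids.index(s) for s in strain_ids]
        return SimilarityMatrix(
            tuple(strain_ids), self.values[np.ix_(idx, idx)], self.metric
        )


# ---------------------------------------------------------------------------
# FASTA

def read_alignment(path: str | Path, locus: str) -> GeneAlignment:
    """Read one aligned FASTA file into a :class:`GeneAlignment`.

    Record ids are the token before the first whitespace in the header;
    the remainder of the header line is ignored. Record order is preserved
    and sequences are uppercased.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise DuplicateIdError(
                f"{path}: duplicate record id {rec.id!r}"
            )
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return GeneAlignment(locus, sequences)


def write_alignment(aln: GeneAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Strain metadata TSV

_META_COLUMNS = ["strain_id", "collection_no", "origin", "source", "lat", "lon"]


def read_metadata(path: str | Path) -> list[StrainRecord]:
    """Read the strain metadata TSV (columns strain_id, collection_no,
    origin, source, lat, lon, optionally true_species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "strain_id" not in df.columns:
        raise MatrixShapeError(f"{path}: missing required column 'strain_id'")
    ids = list(df["strain_id"])
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"{path}: duplicate strain_id values")

    def _f(v: str | float | None) -> float | None:
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    def _s(v: object) -> str | None:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return str(v)

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            StrainRecord(
                strain_id=str(d["strain_id"]),
                collection_no=_s(d.get("collection_no")),
                origin=_s(d.get("origin")),
                source=_s(d.get("source")),
                latitude=_f(d.get("lat")),
                longitude=_f(d.get("lon")),
                true_species=_s(d.get("true_species")),
            )
        )
    if not records:
        raise EmptyInputError(f"{path}: metadata table is empty")
    return records


def write_metadata(records: Sequence[StrainRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "strain_id": r.strain_id,
                "collection_no": r.collection_no or "",
                "origin": r.origin or "",
                "source": r.source or "",
                "lat": "" if r.latitude is None else f"{r.latitude:.4f}",
                "lon": "" if r.longitude is None else f"{r.longitude:.4f}",
                "true_species": r.true_species or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Square matrix TSV

def read_matrix(path: str | Path, metric: str = "identity") -> SimilarityMatrix:
    """Read a square similarity matrix TSV.

    Layout: header row of strain ids, first column of strain ids, values in
    percent with '.' decimals. A half-filled matrix (only the upper or lower
    triangle present) is mirrored; for identity/ANI an absent diagonal is
    filled with 100. Mirrored cells disagreeing by more than
    ``MATRIX_ASYMMETRY_TOL`` raise an asymmetry error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise MatrixShapeError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise MatrixShapeError(f"{path}: row and column strain ids disagree")
    vals = df.to_numpy(dtype=float)
    n = len(rows)
    # mirror whichever triangle is present
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vals[i, j], vals[j, i]
            if np.isnan(a) and not np.isnan(b):
                vals[i, j] = b
            elif np.isnan(b) and not np.isnan(a):
                vals[j, i] = a
            elif not np.isnan(a) and not np.isnan(b):
                if abs(a - b) > MATRIX_ASYMMETRY_TOL:
                    raise MatrixAsymmetryError(
                        f"{path}: cells ({rows[i]},{rows[j]}) differ: "
                        f"{a} vs {b}"
                    )
                m = 0.5 * (a + b)
                vals[i, j] = vals[j, i] = m
    diag = np.diag(vals)
    if np.any(np.isnan(diag)):
        if metric in ("identity", "ANI"):
            np.fill_diagonal(vals, np.where(np.isnan(diag), 100.0, diag))
        else:
            np.fill_diagonal(vals, np.where(np.isnan(diag), 100.0, diag))
    if np.any(np.isnan(vals)):
        raise MatrixShapeError(f"{path}: matrix has unfilled cells")
    if np.any(vals < 0) or np.any(vals > 100):
        bad = vals[(vals < 0) | (vals > 100)][0]
        raise MatrixRangeError(f"{path}: value {bad} outside [0, 100]")
    return SimilarityMatrix(tuple(rows), vals, metric)


def write_matrix(m: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.values, index=m.strain_ids, columns=m.strain_ids)
    df.to_csv(path, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# Newick (the tree type lives in mlsakit.phylo; imported lazily to keep the
# module import graph acyclic)

def read_newick(path: str | Path):
    """Read a Newick file into a :class:`mlsakit.phylo.PhyloTree`."""
    from . import phylo

    return phylo.tree_from_newick(Path(path).read_text())


def write_newick(tree, path: str | Path) -> None:
    """Write a :class:`mlsakit.phylo.PhyloTree` with branch lengths and
    integer bootstrap supports as internal-node labels."""
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# JSON report

def write_json_report(obj: Mapping, path: str | Path) -> None:
    """Write a run report as deterministic JSON (sorted keys, fixed float
    formatting handled upstream)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
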