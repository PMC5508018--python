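"""Synthetic strain sets with known ground truth.

Generates desk-scale datasets carrying the statistical structure the MLSA
workflow assumes: a species-structured strain tree, per-gene codon
alignments evolved under purifying selection (so Ka/Ks estimation is
testable against a known omega), a conserved non-coding 16S-like locus,
and dDDH/ANI matrices tied to MLSA similarity through the reference
calibration curve.

The dDDH surrogate is deliberate and minimal: pairwise dDDH is obtained by
numerically inverting the calibration curve at each pair's realized MLSA
similarity and adding Gaussian noise, rather than from an independent
genome model. That is exactly the structure needed to test calibration
recovery and multi-evidence demarcation; it does not emulate genome
evolution. ANI is an affine map of dDDH anchored so that 70% dDDH
corresponds to about 95.5% ANI (the middle of the published 95-96%
boundary).

The default configuration mimics a small marine genus: 23 strains in 9
species (cluster sizes 6, 6, 4, 2, 1, 1, 1, 1, 1), five coding loci of
933/885/918/927/852 bp with per-locus omega in the 0.02-0.07 range, and a
1430-bp conserved non-coding locus.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eigh

from . import calibration as _cal
from . import demarcation, diversity, mlsa, seqio
from ._genetic_code import SENSE_CODONS, is_synonymous, is_transition
from .errors import InvalidParameterError
from .phylo import Node, PhyloTree
from .seqio import GeneAlignment, SimilarityMatrix, StrainRecord

__all__ = [
    "LocusParams",
    "SimulationConfig",
    "FixtureBundle",
    "DEFAULT_LOCI",
    "sample_species_tree",
    "evolve_locus",
    "simulate_calibration_pairs",
    "make_fixture",
]


@dataclass(frozen=True)
class LocusParams:
    """Simulation parameters for one locus.

    ``rate_multiplier`` scales the shared tree's branch lengths for this
    locus; ``omega`` (dN/dS) and ``kappa`` (transition/transversion rate
    ratio) parameterize the codon model; non-coding loci evolve under a
    Kimura 2-parameter nucleotide model and ignore ``omega``.
    """

    name: str
    length_bp: int
    rate_multiplier: float = 1.0
    omega: float = 0.05
    kappa: float = 2.0
    coding: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise InvalidParameterError("locus length must be positive")
        if self.coding and self.length_bp % 3 != 0:
            raise InvalidParameterError(
                f"coding locus {self.name!r}: length {self.length_bp} "
                f"not divisible by 3"
            )
        if not (0.0 < self.omega <= 1.0):
            raise InvalidParameterError("omega must be in (0, 1]")
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be positive")
        if self.rate_multiplier <= 0:
            raise InvalidParameterError("rate_multiplier must be positive")


#: housekeeping loci at their typical aligned lengths, with per-locus
#: omega spanning the strong-purifying range such genes show, plus a
#: conserved non-coding 16S-like locus
DEFAULT_LOCI: tuple[LocusParams, ...] = (
    LocusParams("gyrB", 933, 1.0, 0.07, 2.0),
    LocusParams("rpoD", 885, 1.0, 0.04, 2.0),
    LocusParams("dnaK", 918, 1.0, 0.04, 2.0),
    LocusParams("trpB", 927, 1.0, 0.04, 2.0),
    LocusParams("recA", 852, 1.0, 0.02, 2.0),
    LocusParams("16S", 1430, 0.25, 1.0, 2.0, coding=False),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int = 9
    strains_per_species: tuple[int, ...] = (6, 6, 4, 2, 1, 1, 1, 1, 1)
    loci: tuple[LocusParams, ...] = DEFAULT_LOCI
    within_species_divergence: float = 0.010
    between_species_divergence: float = 0.105
    dddh_noise_sd: float = 1.0
    seed: int = 0
    #: species (by name) whose first strain acts as the reference type
    #: strain; None selects a default set of up to five species chosen to
    #: leave a mix of known and novel clusters
    reference_species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InvalidParameterError("n_species must be >= 1")
        if len(self.strains_per_species) != self.n_species:
            raise InvalidParameterError(
                "strains_per_species must list one count per species"
            )
        if any(k < 1 for k in self.strains_per_species):
            raise InvalidParameterError("each species needs >= 1 strain")
        if self.within_species_divergence <= 0 or \
                self.between_species_divergence <= 0:
            raise InvalidParameterError("divergences must be positive")
        if self.within_species_divergence >= self.between_species_divergence:
            raise InvalidParameterError(
                "within-species divergence must be smaller than "
                "between-species divergence"
            )
        if self.dddh_noise_sd < 0:
            raise InvalidParameterError("dddh_noise_sd must be >= 0")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"sp{k + 1}" for k in range(self.n_species))

    def default_references(self) -> tuple[str, ...]:
        """Up to five reference species: skip the second and third (which
        stay 'novel') and then fill from the remaining, mirroring a genus
        where several clusters lack described type strains."""
        names = list(self.species_names)
        if self.n_species <= 5:
            return tuple(names)
        picked = [names[0], names[3], names[4], names[5], names[6]]
        return tuple(picked[: min(5, self.n_species)])


# ---------------------------------------------------------------------------
# Species tree

def _species_subtree(
    species: str, n_strains: int, tip_len: float, rng: np.random.Generator
) -> tuple[Node, float]:
    """Star subtree of one species; returns (root, nominal height)."""
    names = [f"{species}_{i + 1}" for i in range(n_strains)]
    if n_strains == 1:
        return Node(name=names[0]), 0.0
    children = [
        Node(name=nm, length=float(tip_len * rng.uniform(0.7, 1.3)))
        for nm in names
    ]
    return Node(children=children), tip_len


def sample_species_tree(
    config: SimulationConfig,
) -> tuple[PhyloTree, dict[str, str]]:
    """Random species topology with strains attached.

    Species subtrees are stars at height within/2 (strain tip lengths
    jittered); species join at heights spread around between/2, so
    between-species path lengths spread around the configured
    between-species divergence. Deterministic given ``config.seed``.
    """
    if config.n_species < 2:
        raise InvalidParameterError(
            "sample_species_tree needs n_species >= 2"
        )
    rng = np.random.default_rng(config.seed)
    tip_len = config.within_species_divergence / 2.0
    subtrees: list[tuple[Node, float]] = []
    species_of: dict[str, str] = {}
    for sp, k in zip(config.species_names, config.strains_per_species):
        node, h = _species_subtree(sp, k, tip_len, rng)
        subtrees.append((node, h))
        for leaf in node.leaf_names():
            species_of[leaf] = sp

    n_joins = config.n_species - 1
    base = config.between_species_divergence / 2.0
    if n_joins == 1:
        heights = np.array([base])
    else:
        heights = base * np.linspace(0.75, 1.25, n_joins)
        heights = np.sort(heights * rng.uniform(0.97, 1.03, size=n_joins))
    for h_join in heights:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        (node_j, h_j) = subtrees.pop(j)
        (node_i, h_i) = subtrees.pop(i)
        node_i.length = float(max(h_join - h_i, 1e-9))
        node_j.length = float(max(h_join - h_j, 1e-9))
        subtrees.append((Node(children=[node_i, node_j]), float(h_join)))
    root, _ = subtrees[0]
    return PhyloTree(root), species_of


# ---------------------------------------------------------------------------
# Sequence evolution

_codon_model_cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
_nuc_model_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _codon_model(omega: float, kappa: float):
    """Eigendecomposition of the normalized 61-state codon rate matrix.

    Uniform codon frequencies make the matrix symmetric, so branch
    transition matrices come from a single symmetric eigendecomposition.
    Rates: kappa for transitions, omega for nonsynonymous changes, zero
    into stop codons; normalized to one expected substitution per
    *nucleotide* site per unit branch length.
    """
    key = (omega, kappa)
    if key in _codon_model_cache:
        return _codon_model_cache[key]
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rate = kappa if is_transition(ci[p], cj[p]) else 1.0
            if not is_synonymous(ci, cj):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # one substitution per nucleotide site = three per codon... no: per
    # codon the expected number of substitutions over branch t is
    # mean(-diag)*t; dividing by 3 expresses t in per-site units.
    Q /= np.mean(-np.diag(Q)) / 3.0
    w, V = eigh(Q)
    _codon_model_cache[key] = (w, V)
    return w, V


def _nuc_model(kappa: float):
    """Kimura 2-parameter nucleotide model, one substitution/site/unit."""
    if kappa in _nuc_model_cache:
        return _nuc_model_cache[kappa]
    bases = "ACGT"
    Q = np.zeros((4, 4))
    for i, bi in enumerate(bases):
        for j, bj in enumerate(bases):
            if i != j:
                Q[i, j] = kappa if is_transition(bi, bj) else 1.0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= np.mean(-np.diag(Q))
    w, V = eigh(Q)
    _nuc_model_cache[kappa] = (w, V)
    return w, V


def _transition_matrix(w: np.ndarray, V: np.ndarray, t: float) -> np.ndarray:
    P = (V * np.exp(w * t)) @ V.T
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _propagate(
    states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    child = np.empty_like(states)
    for s in np.unique(states):
        idx = np.flatnonzero(states == s)
        cum = np.cumsum(P[s])
        cum[-1] = 1.0
        child[idx] = np.searchsorted(cum, rng.random(idx.size), side="right")
    return child


def evolve_locus(
    tree: PhyloTree, params: LocusParams, seed: int
) -> GeneAlignment:
    """Evolve one locus along the strain tree.

    Coding loci use the codon model (root drawn uniformly from sense
    codons, stop codons unreachable); non-coding loci use K2P. Branch
    lengths are the tree's lengths times ``rate_multiplier``. The output
    alignment is gapless and deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if params.coding:
        w, V = _codon_model(params.omega, params.kappa)
        n_units = params.length_bp // 3
        alphabet = SENSE_CODONS
    else:
        w, V = _nuc_model(params.kappa)
        n_units = params.length_bp
        alphabet = tuple("ACGT")

    root_states = rng.integers(0, len(alphabet), size=n_units)
    leaf_states: dict[str, np.ndarray] = {}

    def walk(node: Node, states: np.ndarray) -> None:
        for child in node.children:
            t = (child.length or 0.0) * params.rate_multiplier
            if t > 0:
                P = _transition_matrix(w, V, t)
                child_states = _propagate(states, P, rng)
            else:
                child_states = states.copy()
            if child.is_leaf:
                leaf_states[child.name] = child_states
            else:
                walk(child, child_states)

    if tree.root.is_leaf:
        leaf_states[tree.root.name] = root_states
    else:
        walk(tree.root, root_states)

    sequences = {
        leaf: "".join(alphabet[s] for s in leaf_states[leaf])
        for leaf in tree.leaves
    }
    return GeneAlignment(params.name, sequences)


# ---------------------------------------------------------------------------
# Calibration pairs

def simulate_calibration_pairs(
    model: _cal.CalibrationModel,
    n: int,
    noise_sd: float,
    x_range: tuple[float, float] = (20.0, 100.0),
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Draw (dDDH, MLSA) pairs from the curve plus Gaussian noise.

    x is uniform on ``x_range``; deterministic given ``seed``. The model
    must be monotone over the range.
    """
    if not model.is_monotone(x_range):
        raise _cal.InvalidModelError(
            "calibration model is not monotone on the requested range"
        )
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = np.asarray(_cal.evaluate(model, x), dtype=float)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return [(float(a), float(b)) for a, b in zip(x, y)]


# ---------------------------------------------------------------------------
# Full fixture

@dataclass
class FixtureBundle:
    """A complete synthetic dataset plus its ground truth."""

    config: SimulationConfig
    tree: PhyloTree
    metadata: list[StrainRecord]
    alignments: dict[str, GeneAlignment]
    mlsa_sim: SimilarityMatrix
    dddh: SimilarityMatrix
    ani: SimilarityMatrix
    references: tuple[str, ...]
    truth: dict = field(default_factory=dict)

    @property
    def coding_loci(self) -> list[GeneAlignment]:
        return [
            self.alignments[p.name]
            for p in self.config.loci
            if p.coding
        ]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in self.alignments.items():
            seqio.write_alignment(aln, out / f"{name}.fasta")
        seqio.write_metadata(self.metadata, out / "metadata.tsv")
        seqio.write_matrix(self.dddh, out / "dddh.tsv")
        seqio.write_matrix(self.ani, out / "ani.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _star_tree(config: SimulationConfig) -> tuple[PhyloTree, dict[str, str]]:
    """Degenerate single-species tree (all strains in one star)."""
    rng = np.random.default_rng(config.seed)
    node, _ = _species_subtree(
        config.species_names[0],
        config.strains_per_species[0],
        config.within_species_divergence / 2.0,
        rng,
    )
    species_of = {leaf: config.species_names[0] for leaf in node.leaf_names()}
    if node.is_leaf:
        node = Node(children=[node])
        node.children[0].length = 0.0
    return PhyloTree(node), species_of


def make_fixture(config: SimulationConfig) -> FixtureBundle:
    """Generate the full bundle: loci evolved on one shared strain tree,
    MLSA similarity, dDDH derived through the reference calibration plus
    noise, ANI as an affine map of dDDH, and ground truth."""
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(config.loci) + 2, dtype=np.uint32
    )
    if config.n_species == 1:
        tree, species_of = _star_tree(config)
    else:
        tree, species_of = sample_species_tree(config)

    alignments = {
        p.name: evolve_locus(tree, p, int(seeds[k]))
        for k, p in enumerate(config.loci)
    }
    coding = [alignments[p.name] for p in config.loci if p.coding]
    mlsa_sim = mlsa.mlsa_similarity(coding)

    model = _cal.THIOCLAVA_CALIBRATION
    ids = mlsa_sim.strain_ids
    n = len(ids)
    rng = np.random.default_rng(int(seeds[-2]))
    dvals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            x = _cal.invert(model, float(mlsa_sim.values[i, j]))
            x += rng.normal(0.0, config.dddh_noise_sd)
            dvals[i, j] = dvals[j, i] = float(np.clip(x, 0.0, 100.0))
    dddh = SimilarityMatrix(ids, dvals, "dDDH")
    # affine dDDH -> ANI map anchored at (70, 95.5) and (100, 100)
    avals = np.clip(95.5 + 0.15 * (dvals - 70.0), 0.0, 100.0)
    np.fill_diagonal(avals, 100.0)
    ani = SimilarityMatrix(ids, avals, "ANI")

    refs_species = config.reference_species or config.default_references()
    references = tuple(f"{sp}_1" for sp in refs_species)

    threshold = _cal.derive_threshold(model, 70.0)
    pair_sims = [v for _, _, v in mlsa_sim.pairs()]
    pair_dddh = [dddh[a, b] for a, b, _ in mlsa_sim.pairs()]
    zones = _cal.detect_gap(pair_sims, pair_dddh, threshold)
    labels = {
        f"{a}|{b}": demarcation.classify_pair(v, zones)
        for a, b, v in mlsa_sim.pairs()
    }

    metadata = [
        StrainRecord(
            strain_id=s,
            origin="synthetic",
            source="simulation",
            true_species=species_of[s],
        )
        for s in ids
    ]
    truth = {
        "true_species": {s: species_of[s] for s in ids},
        "tree": tree.to_newick(),
        "references": list(references),
        "zones": {"upper": zones.upper, "lower": zones.lower},
        "expected_pair_labels": labels,
        "seed": config.seed,
    }
    return FixtureBundle(
        config=config,
        tree=tree,
        metadata=metadata,
        alignments=alignments,
        mlsa_sim=mlsa_sim,
        dddh=dddh,
        ani=ani,
        references=references,
        truth=truth,
    )
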