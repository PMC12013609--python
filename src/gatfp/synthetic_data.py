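"""Seeded synthetic corpora with planted fragment-to-bit associations.

The generator emulates the shape of real spectra-derived training data:
each sample owns a binary fingerprint target; every active bit emits its
associated fragments (with probability ``p_emit``), noise fragments are
inserted (each unassociated pool fragment with probability ``p_noise``),
and the resulting fragment set is wired into a random rooted tree ordered
by decreasing fragment mass.  Because fragment presence carries the bit
signal, a graph model that reads node identity can recover the mapping -
this is the learnability test bed, not a simulation of fragmentation
chemistry.

A paired candidate library holds, per sample, the true compound (its
fingerprint equals the target) plus formula-matched decoys with corrupted
fingerprints and mass-shifted decoys outside the widest ppm window, so
both retrieval modes have positive and negative cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formulas import format_formula
from .msio import CandidateRecord, FragmentNode, FragmentationTree

# monoisotopic masses for the synthetic CHNO fragment alphabet
_ATOM_MASS = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}


class SyntheticConfigError(ValueError):
    pass


def _formula_mass(formula: dict[str, int]) -> float:
    return sum(_ATOM_MASS[el] * n for el, n in formula.items())


@dataclass(frozen=True)
class PlantedModel:
    """Stated world for the synthetic corpus.

    Defaults: 32 fingerprint bits at prevalence 0.2, an 80-fragment CHNO
    pool with 2 associated fragments per bit, emission probability 0.9
    and noise probability 0.1.  When the pool is large enough the per-bit
    association sets are disjoint, so the planted mapping is identifiable
    and a failure to learn indicts the model, not the world; leftover
    pool fragments appear only as noise.
    """

    n_bits: int = 32
    pool_size: int = 80
    assoc_size: int = 2
    p_emit: float = 0.9
    p_noise: float = 0.1
    bit_prevalence: float = 0.2
    n_decoys: int = 9
    decoy_flip_prob: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_emit <= 1 and 0 <= self.p_noise <= 1):
            raise SyntheticConfigError("p_emit/p_noise must be in [0, 1]")
        if self.pool_size < 1:
            raise SyntheticConfigError("empty fragment pool")


@dataclass
class SyntheticCorpus:
    trees: list[FragmentationTree]
    targets: dict[str, np.ndarray]
    library: list[CandidateRecord]
    truth: dict[str, str]                      # sample_id -> candidate_id
    candidate_fps: dict[str, np.ndarray]       # candidate_id -> bits
    fragment_pool: list[dict[str, int]] = field(default_factory=list)
    assoc: dict[int, list[int]] = field(default_factory=dict)


def _make_pool(rng: np.random.Generator, size: int) -> list[dict[str, int]]:
    """Random small distinct CHNO compositions."""
    pool: list[dict[str, int]] = []
    seen: set[str] = set()
    while len(pool) < size:
        comp = {
            "C": int(rng.integers(1, 9)),
            "H": int(rng.integers(1, 9)),
            "N": int(rng.integers(0, 3)),
            "O": int(rng.integers(0, 4)),
        }
        comp = {k: v for k, v in comp.items() if v > 0}
        key = format_formula(comp)
        if key not in seen:
            seen.add(key)
            pool.append(comp)
    return pool


def _build_tree(sample_id: str, frag_ids: list[int],
                pool: list[dict[str, int]],
                rng: np.random.Generator) -> FragmentationTree:
    """Wire fragments into a rooted tree, heaviest fragment as root."""
    frag_ids = sorted(frag_ids, key=lambda i: -_formula_mass(pool[i]))
    intensities = rng.uniform(0.0, 1.0, size=len(frag_ids)) + 1e-6
    intensities /= intensities.max()
    nodes = [
        FragmentNode(node_id=k, formula=dict(pool[i]),
                     mz=_formula_mass(pool[i]) + _ATOM_MASS["H"],  # [M+H]+ like
                     rel_intensity=float(v))
        for k, (i, v) in enumerate(zip(frag_ids, intensities))
    ]
    edges = [(int(rng.integers(0, k)), k) for k in range(1, len(nodes))]
    return FragmentationTree(
        sample_id=sample_id, nodes=nodes, edges=edges,
        precursor_mass=nodes[0].mz, precursor_formula=dict(nodes[0].formula),
        adduct="[M+H]+",
    )


def generate_corpus(model: PlantedModel, n_samples: int) -> SyntheticCorpus:
    """Draw a full corpus: trees, targets, candidate library and truth map."""
    if n_samples < 1:
        raise SyntheticConfigError("n_samples must be >= 1")
    rng = np.random.default_rng(model.seed)
    pool = _make_pool(rng, model.pool_size)
    need = model.n_bits * model.assoc_size
    if model.pool_size >= need:
        # disjoint association sets: the planted mapping is identifiable
        perm = rng.permutation(model.pool_size)[:need]
        assoc = {b: sorted(perm[b * model.assoc_size:(b + 1) * model.assoc_size].tolist())
                 for b in range(model.n_bits)}
    else:
        assoc = {b: sorted(rng.choice(model.pool_size, size=model.assoc_size,
                                      replace=False).tolist())
                 for b in range(model.n_bits)}

    trees, targets = [], {}
    library: list[CandidateRecord] = []
    truth: dict[str, str] = {}
    candidate_fps: dict[str, np.ndarray] = {}

    for s in range(n_samples):
        sid = f"S{s:04d}"
        bits = (rng.random(model.n_bits) < model.bit_prevalence).astype(np.int8)
        emitted: set[int] = set()
        associated: set[int] = set()
        for b in np.flatnonzero(bits):
            for fi in assoc[b]:
                associated.add(fi)
                if rng.random() < model.p_emit:
                    emitted.add(fi)
        for fi in range(model.pool_size):
            if fi not in associated and rng.random() < model.p_noise:
                emitted.add(fi)
        if not emitted:
            emitted.add(int(rng.integers(0, model.pool_size)))

        tree = _build_tree(sid, sorted(emitted), pool, rng)
        trees.append(tree)
        targets[sid] = bits

        # --- candidate library for this sample -------------------------
        comp = tree.precursor_formula
        mass = _formula_mass(comp)
        tid = f"T{s:04d}"
        library.append(CandidateRecord(candidate_id=tid, formula=dict(comp),
                                       monoisotopic_mass=mass, smiles=""))
        candidate_fps[tid] = bits.copy()
        truth[sid] = tid
        for d in range(model.n_decoys):
            did = f"D{s:04d}_{d}"
            flips = rng.random(model.n_bits) < model.decoy_flip_prob
            fp = np.where(flips, 1 - bits, bits).astype(np.int8)
            library.append(CandidateRecord(candidate_id=did, formula=dict(comp),
                                           monoisotopic_mass=mass, smiles=""))
            candidate_fps[did] = fp
        # mass-shifted decoys outside the widest (100 ppm) window
        for d in range(2):
            did = f"X{s:04d}_{d}"
            shifted = mass * (1 + (d + 2) * 500e-6)       # 1000 / 1500 ppm away
            library.append(CandidateRecord(candidate_id=did, formula=dict(comp),
                                           monoisotopic_mass=shifted, smiles=""))
            candidate_fps[did] = (rng.random(model.n_bits) < 0.5).astype(np.int8)

    return SyntheticCorpus(trees=trees, targets=targets, library=library,
                           truth=truth, candidate_fps=candidate_fps,
                           fragment_pool=pool, assoc=assoc)


def make_toy_fixture() -> SyntheticCorpus:
    """A fixed 3-tree, 4-fragment corpus whose statistics are hand-checkable.

    Fragments: CH2O, C2H4O2, C3H6O3, H2O.  Tree edges (parent -> child):

    * t1: C3H6O3 -> C2H4O2 -> CH2O        (intensities 1.0, 0.5, 0.25)
    * t2: C3H6O3 -> CH2O, C3H6O3 -> H2O   (intensities 1.0, 0.8, 0.4)
    * t3: C2H4O2 -> CH2O                  (intensities 1.0, 0.5)

    Totals: 5 edges; CH2O appears in all three trees (its IDF is 0).
    """
    A = {"C": 1, "H": 2, "O": 1}
    B = {"C": 2, "H": 4, "O": 2}
    C = {"C": 3, "H": 6, "O": 3}
    D = {"H": 2, "O": 1}

    def node(nid, comp, inten):
        return FragmentNode(node_id=nid, formula=dict(comp),
                            mz=_formula_mass(comp) + _ATOM_MASS["H"],
                            rel_intensity=inten)

    t1 = FragmentationTree("t1", [node(0, C, 1.0), node(1, B, 0.5), node(2, A, 0.25)],
                           [(0, 1), (1, 2)], _formula_mass(C), dict(C))
    t2 = FragmentationTree("t2", [node(0, C, 1.0), node(1, A, 0.8), node(2, D, 0.4)],
                           [(0, 1), (0, 2)], _formula_mass(C), dict(C))
    t3 = FragmentationTree("t3", [node(0, B, 1.0), node(1, A, 0.5)],
                           [(0, 1)], _formula_mass(B), dict(B))
    trees = [t1, t2, t3]

    targets = {t.sample_id: np.array([1, 0, 1, 0], dtype=np.int8) for t in trees}
    library = [CandidateRecord(candidate_id=f"T_{t.sample_id}",
                               formula=dict(t.precursor_formula),
                               monoisotopic_mass=_formula_mass(t.precursor_formula),
                               smiles="") for t in trees]
    truth = {t.sample_id: f"T_{t.sample_id}" for t in trees}
    candidate_fps = {f"T_{t.sample_id}": targets[t.sample_id].copy() for t in trees}
    return SyntheticCorpus(trees=trees, targets=targets, library=library,
                           truth=truth, candidate_fps=candidate_fps)
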