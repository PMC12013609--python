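"""Corpus statistics and graph assembly.

Fragmentation trees become attributed graphs: node features are a
per-element one-hot encoding of the fragment formula plus (scaled) m/z and
relative abundance; each structural edge carries a 2-vector
``[PMI(i, j), TF-IDF of the child fragment in this tree]``.

PMI is computed over the corpus of tree edges,

    PMI(i, j) = log( p(i, j) / (p(i) p(j)) ),
    p(i, j) = #W(i, j) / #W,   p(i) = #W(i) / #W,

where ``#W`` is the total number of edges in the corpus, ``#W(i)`` the
number of edges incident to a node with formula ``i`` and ``#W(i, j)`` the
number of edges whose endpoints carry formulas ``i`` and ``j`` (unordered).
TF-IDF uses relative intensity as the term frequency:

    TF-IDF_sj = rel_intensity(j in sample s) * log(S / F_j),

with ``S`` the number of samples and ``F_j`` the number of samples in
which fragment ``j`` appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formulas import canonical_formula
from .msio import FragmentationTree, FragmentNode

UNK = "<UNK>"


class CorpusError(ValueError):
    pass


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentVocabulary:
    """Bijection between canonical fragment-formula strings and indices.

    When built with ``reserve_unk=True`` the last index is a reserved
    out-of-vocabulary bucket so statistics fitted on training folds can be
    applied to unseen test fragments.
    """

    key_of: dict[str, int]
    unk_index: int | None = None

    @property
    def size(self) -> int:
        return len(self.key_of) + (1 if self.unk_index is not None else 0)

    def index(self, formula: dict[str, int] | str) -> int:
        key = canonical_formula(formula) if not isinstance(formula, str) else formula
        if key in self.key_of:
            return self.key_of[key]
        if self.unk_index is not None:
            return self.unk_index
        raise CorpusError(f"fragment formula {key!r} not in vocabulary")


@dataclass
class CorpusStats:
    """Edge co-occurrence and document-frequency counts over a tree corpus."""

    co_count: dict[tuple[int, int], int]
    frag_edge_count: dict[int, int]
    total_edges: int
    doc_freq: dict[int, int]
    n_samples: int

    def validate(self) -> None:
        for (i, j), cij in self.co_count.items():
            if cij > min(self.frag_edge_count.get(i, 0), self.frag_edge_count.get(j, 0)):
                raise CorpusError(f"co_count({i},{j})={cij} exceeds marginal counts")
        for i, ci in self.frag_edge_count.items():
            if ci > 2 * self.total_edges:
                raise CorpusError(f"frag_edge_count({i}) exceeds 2*total_edges")
        for j, fj in self.doc_freq.items():
            if fj > self.n_samples:
                raise CorpusError(f"doc_freq({j}) exceeds n_samples")


@dataclass(frozen=True)
class NodeFeatureSpec:
    """Layout of the node-feature vector.

    ``include_elements``/``include_mz`` off reproduces the FFv ablation,
    which keeps only the relative abundance.  m/z is divided by
    ``mz_scale`` (default 1000 Da) so it stays O(1) next to one-hot blocks.
    """

    element_alphabet: tuple[str, ...] = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")
    max_count: int = 8
    include_elements: bool = True
    include_mz: bool = True
    include_intensity: bool = True
    mz_scale: float = 1000.0

    @property
    def width(self) -> int:
        w = len(self.element_alphabet) * (self.max_count + 1) if self.include_elements else 0
        return w + int(self.include_mz) + int(self.include_intensity)

    @classmethod
    def ffv(cls, **kw) -> "NodeFeatureSpec":
        """The node-feature ablation: relative abundance only."""
        return cls(include_elements=False, include_mz=False, **kw)


@dataclass
class GraphSample:
    """One spectrum as model input: features, edges and fingerprint target."""

    sample_id: str
    node_features: np.ndarray          # (n_nodes, width)
    edge_index: np.ndarray             # (n_edges, 2) int, rows (src, dst)
    edge_features: np.ndarray          # (n_edges, 2) [PMI, TF-IDF]
    target: np.ndarray                 # (n_bits,) binary

    def __post_init__(self):
        if self.edge_features.shape[0] != self.edge_index.shape[0]:
            raise EncodingError("edge_features rows must match edge count")
        if self.node_features.ndim != 2:
            raise EncodingError("node_features must be 2-D")
        if self.target.size and not np.isin(self.target, (0, 1)).all():
            raise EncodingError("target entries must be binary")


def build_vocabulary(trees: list[FragmentationTree],
                     reserve_unk: bool = False) -> FragmentVocabulary:
    """Index every distinct canonical fragment formula, sorted lexicographically."""
    if not trees:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    keys = sorted({n.formula_str for t in trees for n in t.nodes})
    key_of = {k: i for i, k in enumerate(keys)}
    return FragmentVocabulary(key_of=key_of,
                              unk_index=len(keys) if reserve_unk else None)


def accumulate_corpus_stats(trees: list[FragmentationTree],
                            vocab: FragmentVocabulary) -> CorpusStats:
    """Count edge co-occurrences and per-sample document frequencies.

    Each structural edge counts once toward ``#W``; an edge increments
    ``#W(i)`` for each endpoint formula (twice if both endpoints share a
    formula) and the unordered pair count ``#W(i, j)`` once.
    """
    co: dict[tuple[int, int], int] = {}
    marg: dict[int, int] = {}
    df: dict[int, int] = {}
    total = 0
    for tree in trees:
        idx = {n.node_id: vocab.index(n.formula_str) for n in tree.nodes}
        for j in set(idx.values()):
            df[j] = df.get(j, 0) + 1
        for p, c in tree.edges:
            i, j = idx[p], idx[c]
            total += 1
            marg[i] = marg.get(i, 0) + 1
            marg[j] = marg.get(j, 0) + 1
            key = (i, j) if i <= j else (j, i)
            co[key] = co.get(key, 0) + 1
    if vocab.unk_index is not None:
        df.setdefault(vocab.unk_index, 1)
    stats = CorpusStats(co_count=co, frag_edge_count=marg, total_edges=total,
                        doc_freq=df, n_samples=len(trees))
    stats.validate()
    return stats


def compute_pmi(i: int, j: int, stats: CorpusStats, base: float = math.e) -> float:
    """Pointwise mutual information of an unordered fragment pair."""
    key = (i, j) if i <= j else (j, i)
    cij = stats.co_count.get(key, 0)
    ci = stats.frag_edge_count.get(i, 0)
    cj = stats.frag_edge_count.get(j, 0)
    if stats.total_edges == 0 or cij == 0 or ci == 0 or cj == 0:
        raise CorpusError(
            f"PMI undefined for pair ({i},{j}): counts #W={stats.total_edges}, "
            f"#W(i)={ci}, #W(j)={cj}, #W(i,j)={cij}"
        )
    w = stats.total_edges
    return math.log((cij / w) / ((ci / w) * (cj / w)), base)


def compute_tfidf(sample: FragmentationTree, j: int, stats: CorpusStats,
                  vocab: FragmentVocabulary, base: float = math.e) -> float:
    """Relative-intensity TF times inverse document frequency of fragment ``j``."""
    if stats.n_samples <= 0:
        raise CorpusError("TF-IDF undefined for an empty corpus")
    tf = 0.0
    for n in sample.nodes:
        if vocab.index(n.formula_str) == j:
            tf = max(tf, n.rel_intensity)
    if tf == 0.0:
        return 0.0
    fj = stats.doc_freq.get(j, 0)
    if fj == 0:
        raise CorpusError(f"fragment {j} present in sample but doc_freq is 0")
    return tf * math.log(stats.n_samples / fj, base)


def encode_node_features(node: FragmentNode, spec: NodeFeatureSpec) -> np.ndarray:
    """Encode one fragment per the spec layout (one-hot blocks, m/z, intensity)."""
    parts: list[np.ndarray] = []
    if spec.include_elements:
        block = np.zeros((len(spec.element_alphabet), spec.max_count + 1))
        for el, cnt in node.formula.items():
            if el not in spec.element_alphabet:
                raise EncodingError(f"element {el!r} outside alphabet")
            block[spec.element_alphabet.index(el), min(cnt, spec.max_count)] = 1.0
        for k in range(len(spec.element_alphabet)):
            if block[k].sum() == 0:
                block[k, 0] = 1.0  # absent element -> count 0
        parts.append(block.ravel())
    if spec.include_mz:
        parts.append(np.array([node.mz / spec.mz_scale]))
    if spec.include_intensity:
        parts.append(np.array([node.rel_intensity]))
    return np.concatenate(parts)


def build_graph(tree: FragmentationTree, vocab: FragmentVocabulary,
                stats: CorpusStats, spec: NodeFeatureSpec,
                target: np.ndarray, *, edge_mode: str = "full",
                add_reverse_edges: bool = True,
                clamp_negative_pmi: bool = False,
                missing_pair: str = "error",
                log_base: float = math.e) -> GraphSample:
    """Assemble one :class:`GraphSample` from a tree and fitted corpus stats.

    ``edge_mode='full'`` attaches ``[PMI, TF-IDF(child)]`` per structural
    edge; ``edge_mode='ones'`` is the FFe ablation (connectivity only).
    Reverse edges (child → parent) are appended by default so attention
    can propagate information toward the root; they copy the forward
    edge's features.

    When stats were fitted on training folds only, a test tree may hold an
    edge whose formula pair was never counted; ``missing_pair='error'``
    raises (the within-corpus contract), ``missing_pair='zero'`` assigns
    PMI 0 (independence) so fold transfer degrades gracefully.
    """
    order = {n.node_id: k for k, n in enumerate(tree.nodes)}
    feats = np.stack([encode_node_features(n, spec) for n in tree.nodes]) \
        if tree.nodes else np.zeros((0, spec.width))

    src, dst, efeat = [], [], []
    for p, c in tree.edges:
        src.append(order[p])
        dst.append(order[c])
        if edge_mode == "ones":
            efeat.append((1.0, 1.0))
        elif edge_mode == "full":
            i = vocab.index(tree.node(p).formula_str)
            j = vocab.index(tree.node(c).formula_str)
            key = (i, j) if i <= j else (j, i)
            seen = (stats.co_count.get(key, 0) > 0
                    and stats.frag_edge_count.get(i, 0) > 0
                    and stats.frag_edge_count.get(j, 0) > 0)
            if seen:
                pmi = compute_pmi(i, j, stats, base=log_base)
            elif missing_pair == "zero":
                pmi = 0.0
            else:
                raise CorpusError(
                    f"tree {tree.sample_id}: edge pair ({i},{j}) absent from "
                    "corpus stats")
            if clamp_negative_pmi:
                pmi = max(pmi, 0.0)
            tfidf = compute_tfidf(tree, j, stats, vocab, base=log_base)
            efeat.append((pmi, tfidf))
        else:
            raise ValueError(f"unknown edge_mode {edge_mode!r}")

    edge_index = np.array(list(zip(src, dst)), dtype=np.int64).reshape(-1, 2)
    edge_features = np.array(efeat, dtype=np.float64).reshape(-1, 2)
    if add_reverse_edges and len(src):
        edge_index = np.vstack([edge_index, edge_index[:, ::-1]])
        edge_features = np.vstack([edge_features, edge_features])

    return GraphSample(sample_id=tree.sample_id, node_features=feats,
                       edge_index=edge_index, edge_features=edge_features,
                       target=np.asarray(target, dtype=np.float64))
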