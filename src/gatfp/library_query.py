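"""Candidate retrieval and fingerprint-similarity ranking.

A query retrieves library candidates either by precursor mass within a
ppm window (|m_cand - m_query| / m_query * 1e6 <= ppm) or by exact
molecular-formula match after Hill-notation canonicalization.  The
predicted fingerprint is binarized and each candidate scored with the
bit-count cosine

    score = c / sqrt(a * b),

where *a* and *b* are the numbers of set bits in the prediction and the
candidate and *c* the number of bits set in both.  Ties are broken by
candidate id so rankings are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fingerprints import FingerprintConfig, compute_concatenated_fingerprint
from .formulas import canonical_formula
from .msio import CandidateRecord

logger = logging.getLogger(__name__)

PPM_WINDOWS = (5.0, 20.0, 50.0, 100.0)


@dataclass(frozen=True)
class QuerySpec:
    mode: str                                  # "precursor_mass" | "formula"
    precursor_mass: float | None = None
    ppm: float | None = None
    formula: dict[str, int] | str | None = None

    def __post_init__(self):
        if self.mode == "precursor_mass":
            if self.precursor_mass is None or self.ppm is None or self.ppm < 0:
                raise ValueError("precursor-mass mode needs a mass and ppm >= 0")
        elif self.mode == "formula":
            if self.formula is None:
                raise ValueError("formula mode needs a formula")
        else:
            raise ValueError(f"unknown query mode {self.mode!r}")


@dataclass
class RankedCandidates:
    ranking: list[tuple[str, float]]           # (candidate_id, score), best first
    rank_of_truth: int | None = None

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.ranking[:k]


def query_by_precursor_mass(mass: float, ppm: float,
                            library: list[CandidateRecord]) -> list[CandidateRecord]:
    if mass <= 0:
        raise ValueError(f"non-positive query mass {mass}")
    tol = mass * ppm * 1e-6
    return [c for c in library if abs(c.monoisotopic_mass - mass) <= tol]


def query_by_formula(formula: dict[str, int] | str,
                     library: list[CandidateRecord]) -> list[CandidateRecord]:
    key = canonical_formula(formula)
    return [c for c in library if canonical_formula(c.formula) == key]


def cosine_score(pred_bits: np.ndarray, cand_bits: np.ndarray) -> float:
    p = np.asarray(pred_bits).astype(bool)
    q = np.asarray(cand_bits).astype(bool)
    if p.shape != q.shape:
        raise ValueError(f"fingerprint length mismatch: {p.shape} vs {q.shape}")
    a, b = int(p.sum()), int(q.sum())
    if a == 0 or b == 0:
        return 0.0
    c = int((p & q).sum())
    return c / np.sqrt(a * b)


def rank_candidates(pred: np.ndarray, candidates: list[CandidateRecord],
                    fp_config: FingerprintConfig | None = None,
                    threshold: float = 0.5,
                    truth_id: str | None = None,
                    candidate_fps: dict[str, np.ndarray] | None = None) -> RankedCandidates:
    """Score retrieved candidates against a predicted fingerprint.

    Candidate fingerprints come from *candidate_fps* when given (the
    synthetic path), else are computed from each candidate's SMILES with
    *fp_config*.
    """
    pred_bits = (np.asarray(pred) >= threshold).astype(np.int8)
    if pred_bits.sum() == 0:
        logger.warning("predicted fingerprint has no set bits; all scores are 0")
    scored = []
    for cand in candidates:
        if candidate_fps is not None:
            bits = candidate_fps[cand.candidate_id]
        elif fp_config is not None:
            bits = compute_concatenated_fingerprint(cand.smiles, fp_config).bits
        else:
            raise ValueError("need fp_config or candidate_fps to score candidates")
        scored.append((cand.candidate_id, cosine_score(pred_bits, bits)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    rank = None
    if truth_id is not None:
        for r, (cid, _) in enumerate(scored, start=1):
            if cid == truth_id:
                rank = r
                break
    return RankedCandidates(ranking=scored, rank_of_truth=rank)


def topk_rates(rankings: list[RankedCandidates], ks: list[int]) -> dict[int, float]:
    """Fraction of all queries whose truth ranks within the top k.

    Queries whose truth was never retrieved stay in the denominator.
    """
    if not rankings:
        return {k: 0.0 for k in ks}
    return {
        k: sum(1 for r in rankings
               if r.rank_of_truth is not None and r.rank_of_truth <= k) / len(rankings)
        for k in ks
    }
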