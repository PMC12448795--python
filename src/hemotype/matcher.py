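r"""Cosine-similarity diplotype matching.

Each haplotype — a catalog allele or an observed strand — is encoded over
2·V dimensions for the V catalog variants of a system: one REF dimension and
one ALT dimension per variant, each in {0, 1}.  An allele sets exactly one of
the two dimensions at every variant, so its norm is always √V and the
reference allele (no variants) is still a nonzero vector.  An observed strand
sets one dimension per *observed* variant and leaves both at 0 where the site
dropped out, so dropout strictly lowers similarity to every allele.

A diplotype candidate (a1, a2) is scored as the arithmetic mean of the two
strand cosines,

    score = ½ · [cos(s1, a1) + cos(s2, a2)],

maximized over the per-block strand orientations and over the (a1, a2) order.
Because both observed strands share the norm √O (O = observed sites), the
score is additive over phase blocks, so choosing each block's orientation
independently is *exactly* optimal — equivalent to the 2^B exhaustive search
for any number of blocks B (the test suite asserts this against brute force).

Unphased heterozygous calls are singleton blocks, which makes UNPHASED mode
the special case where every het's cis/trans configuration is free — exactly
the ambiguity that phasing resolves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import Allele, Catalog, Variant
from .errors import UsageError
from .variant_io import MISSING, SampleObservation

#: two best scores within this distance tie (floating-point argmax set)
TIE_TOLERANCE = 1e-12

#: calls whose best score falls below this default are reported NO_CALL
DEFAULT_MIN_SCORE = 0.5

PHASED, UNPHASED = "phased", "unphased"


@dataclass(frozen=True)
class HaplotypeVector:
    """A haplotype in the dual REF/ALT encoding.

    ``values`` has layout [REF dims (V), ALT dims (V)] in catalog variant
    order; ``mask`` flags the observed variants (all-True for alleles).
    """

    system: str
    values: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class DiplotypeCandidate:
    """An unordered allele pair with its similarity score.

    ``orientation`` maps phase-block id -> 0 (keep VCF strand order) or
    1 (swap), for the orientation attaining the score; None when not derived.
    """

    pair: tuple[Allele, Allele]
    score: float
    orientation: dict | None = None

    @property
    def name_pair(self) -> tuple[str, str]:
        return tuple(sorted(a.allele_name for a in self.pair))


@dataclass
class CallResult:
    """Ranked diplotype call for one sample in one system."""

    system: str
    best_score: float
    best_pairs: list[DiplotypeCandidate]
    ambiguous: bool
    no_call: bool
    grouped_name_pairs: list[tuple[str, str]]
    all_scores: list[tuple[tuple[str, str], float]] | None = None


class SystemEncoding:
    """Precomputed allele matrices for one system (scoring hot path).

    Alleles are ordered lexicographically by name; ``alt_matrix[i, v]`` is 1
    iff allele i carries variant v.
    """

    def __init__(self, system: str, variants: list[Variant], alleles: list[Allele]):
        self.system = system
        self.variant_ids = [v.variant_id for v in variants]
        self.index = {vid: i for i, vid in enumerate(self.variant_ids)}
        self.alleles = sorted(alleles, key=lambda a: a.allele_name)
        self.n_variants = len(variants)
        self.n_alleles = len(self.alleles)
        V, n = self.n_variants, self.n_alleles
        self.alt_matrix = np.zeros((n, V), dtype=np.float64)
        for i, allele in enumerate(self.alleles):
            for vid in allele.variant_ids:
                self.alt_matrix[i, self.index[vid]] = 1.0
        self.ref_matrix = 1.0 - self.alt_matrix
        # unordered pairs (i <= j), row-major == lexicographic by allele name
        self._triu = np.triu_indices(n)

    @classmethod
    def from_catalog(cls, catalog: Catalog, system: str) -> "SystemEncoding":
        return cls(system, catalog.variants(system), catalog.alleles(system))

    def pair_index(self) -> list[tuple[int, int]]:
        """All unordered pairs with repetition, lexicographic by allele name."""
        return [(i, j) for i in range(self.n_alleles) for j in range(i, self.n_alleles)]


def encode_allele(allele: Allele, variants: list[Variant]) -> HaplotypeVector:
    """Encode a fully-known allele: ALT dim 1 at its variants, REF dim 1 elsewhere."""
    if any(v.system != allele.system for v in variants):
        raise UsageError("encode_allele: variant list is not from the allele's system")
    V = len(variants)
    values = np.zeros(2 * V, dtype=np.float64)
    for i, v in enumerate(variants):
        if v.variant_id in allele.variant_ids:
            values[V + i] = 1.0
        else:
            values[i] = 1.0
    return HaplotypeVector(allele.system, values, np.ones(V, dtype=bool))


def _singleton_key(variant_id: str) -> str:
    return f"v:{variant_id}"


def observation_blocks(obs: SampleObservation, mode: str = PHASED) -> list[tuple[np.ndarray, object]]:
    """Het-call blocks as (member index array, block key) in position order.

    Unphased hets are singleton blocks keyed by their variant id; in UNPHASED
    mode every het is a singleton regardless of recorded blocks.
    """
    het = np.flatnonzero(obs.dosage == 1)
    blocks: dict[object, list[int]] = {}
    order: list[object] = []
    for i in het:
        if mode == UNPHASED or obs.block[i] == MISSING:
            key = _singleton_key(obs.variant_ids[i])
        else:
            key = int(obs.block[i])
        if key not in blocks:
            blocks[key] = []
            order.append(key)
        blocks[key].append(int(i))
    return [(np.asarray(blocks[k], dtype=np.intp), k) for k in order]


def encode_observed_strand(obs: SampleObservation, orientation: dict, strand: int,
                           mode: str = PHASED) -> HaplotypeVector:
    """Encode one observed strand under a full per-block orientation.

    ``orientation`` maps every block key (int phase-set id, or ``"v:<id>"``
    for singleton unphased hets) to 0/1; 1 swaps the block's two strands.
    Homozygous calls contribute to both strands; missing sites to neither.
    """
    if strand not in (1, 2):
        raise UsageError("strand must be 1 or 2")
    V = len(obs.variant_ids)
    values = np.zeros(2 * V, dtype=np.float64)
    mask = np.zeros(V, dtype=bool)
    for i in range(V):
        d = int(obs.dosage[i])
        if d == MISSING:
            continue
        mask[i] = True
        if d == 0:
            values[i] = 1.0
        elif d == 2:
            values[V + i] = 1.0
    for idx, key in observation_blocks(obs, mode):
        if key not in orientation:
            raise UsageError(f"orientation missing for block {key!r}")
        flip = int(orientation[key])
        for i in idx:
            # phase==0: strand 1 carries ALT (before any flip)
            alt_on_first = obs.phase[i] == 0
            if flip:
                alt_on_first = not alt_on_first
            carries_alt = alt_on_first if strand == 1 else not alt_on_first
            values[V + i if carries_alt else i] = 1.0
    return HaplotypeVector(obs.system, values, mask)


def cosine_similarity(u, v) -> float:
    """cos(u, v) = u·v / (‖u‖‖v‖); 0 when either norm is 0 (all-dropout guard)."""
    uv = u.values if isinstance(u, HaplotypeVector) else np.asarray(u, dtype=float)
    vv = v.values if isinstance(v, HaplotypeVector) else np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(uv))
    nv = float(np.linalg.norm(vv))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(uv, vv) / (nu * nv))


def enumerate_diplotypes(alleles: list[Allele]) -> list[tuple[Allele, Allele]]:
    """All n(n+1)/2 unordered pairs (homozygous included), lexicographic order."""
    if not alleles:
        raise UsageError("enumerate_diplotypes: need at least one allele")
    ordered = sorted(alleles, key=lambda a: a.allele_name)
    return [(ordered[i], ordered[j])
            for i in range(len(ordered)) for j in range(i, len(ordered))]


def score_all_pairs(enc: SystemEncoding, obs: SampleObservation, mode: str = PHASED) -> np.ndarray:
    """Score matrix S[i, j] over all ordered allele index pairs (symmetric).

    The per-block orientation maximization is folded in; S[i, j] is the best
    achievable mean-of-cosines for the diplotype (allele i, allele j).
    Returns the zero matrix when no site is observed.
    """
    V, n = enc.n_variants, enc.n_alleles
    observed = obs.dosage >= 0
    O = int(observed.sum())
    if O == 0:
        return np.zeros((n, n))
    w0 = (obs.dosage == 0).astype(np.float64)
    w2 = (obs.dosage == 2).astype(np.float64)
    fixed = enc.ref_matrix @ w0 + enc.alt_matrix @ w2
    S = fixed[:, None] + fixed[None, :]
    for idx, _key in observation_blocks(obs, mode):
        x = (obs.phase[idx] == 0).astype(np.float64)  # 1 where strand1 carries ALT
        alt_cols = enc.alt_matrix[:, idx]
        ref_cols = enc.ref_matrix[:, idx]
        c1 = alt_cols @ x + ref_cols @ (1.0 - x)       # strand-1 dot per allele
        c2 = alt_cols @ (1.0 - x) + ref_cols @ x       # strand-2 dot per allele
        S = S + np.maximum(c1[:, None] + c2[None, :], c2[:, None] + c1[None, :])
    S /= 2.0 * math.sqrt(V * O)
    return S


def score_diplotype(obs: SampleObservation, pair: tuple[Allele, Allele],
                    mode: str = PHASED, enc: SystemEncoding | None = None) -> DiplotypeCandidate:
    """Score one candidate pair, returning the optimal per-block orientation."""
    a1, a2 = pair
    if a1.system != obs.system or a2.system != obs.system:
        raise UsageError(
            f"score_diplotype: pair system mismatch ({a1.system!r}/{a2.system!r} "
            f"vs observation {obs.system!r})"
        )
    if enc is None:
        sub = [a1] if a1.allele_name == a2.allele_name else sorted(
            (a1, a2), key=lambda a: a.allele_name)
        enc = SystemEncoding(obs.system, _variants_placeholder(obs), sub)
    i = next(k for k, a in enumerate(enc.alleles) if a.allele_name == a1.allele_name)
    j = next(k for k, a in enumerate(enc.alleles) if a.allele_name == a2.allele_name)
    V = enc.n_variants
    observed = obs.dosage >= 0
    O = int(observed.sum())
    blocks = observation_blocks(obs, mode)
    orientation: dict = {}
    if O == 0:
        return DiplotypeCandidate(pair=_sorted_pair(pair), score=0.0,
                                  orientation={key: 0 for _, key in blocks})
    w0 = (obs.dosage == 0).astype(np.float64)
    w2 = (obs.dosage == 2).astype(np.float64)
    total = float(enc.ref_matrix[i] @ w0 + enc.alt_matrix[i] @ w2
                  + enc.ref_matrix[j] @ w0 + enc.alt_matrix[j] @ w2)
    for idx, key in blocks:
        x = (obs.phase[idx] == 0).astype(np.float64)
        c1 = enc.alt_matrix[:, idx] @ x + enc.ref_matrix[:, idx] @ (1.0 - x)
        c2 = enc.alt_matrix[:, idx] @ (1.0 - x) + enc.ref_matrix[:, idx] @ x
        keep = c1[i] + c2[j]
        swap = c2[i] + c1[j]
        orientation[key] = 0 if keep >= swap else 1
        total += max(keep, swap)
    score = total / (2.0 * math.sqrt(V * O))
    return DiplotypeCandidate(pair=_sorted_pair(pair), score=score, orientation=orientation)


def _sorted_pair(pair: tuple[Allele, Allele]) -> tuple[Allele, Allele]:
    a, b = pair
    return (a, b) if a.allele_name <= b.allele_name else (b, a)


def _variants_placeholder(obs: SampleObservation) -> list[Variant]:
    # minimal Variant stubs carrying ids in observation order; positions are
    # irrelevant to scoring, only the id->column mapping matters
    return [Variant(vid, "na", i + 1, "A", "C", obs.system)
            for i, vid in enumerate(obs.variant_ids)]


def call_system(obs: SampleObservation, catalog: Catalog, system: str,
                mode: str = PHASED, min_score: float = DEFAULT_MIN_SCORE,
                include_all_scores: bool = False,
                enc: SystemEncoding | None = None) -> CallResult:
    """Score every candidate diplotype and collect the argmax set.

    The ambiguity flag counts *grouped* name pairs: alleles collapsed to one
    reporting label by the catalog's grouping do not make a call ambiguous.
    Results whose best score falls below ``min_score`` (or with no observed
    site at all) are flagged NO_CALL rather than forced to a best guess.
    """
    if obs.system != system:
        raise UsageError(f"observation system {obs.system!r} != requested {system!r}")
    if enc is None:
        enc = SystemEncoding.from_catalog(catalog, system)
    S = score_all_pairs(enc, obs, mode)
    I, J = enc._triu
    scores = S[I, J]
    best_score = float(scores.max())
    hits = np.flatnonzero(scores >= best_score - TIE_TOLERANCE)
    best_pairs = [
        DiplotypeCandidate(pair=(enc.alleles[int(I[h])], enc.alleles[int(J[h])]),
                           score=float(scores[h]))
        for h in hits
    ]
    grouped = sorted({
        tuple(sorted((catalog.display_name(c.pair[0].allele_name),
                      catalog.display_name(c.pair[1].allele_name))))
        for c in best_pairs
    })
    no_call = best_score < min_score
    all_scores = None
    if include_all_scores:
        all_scores = sorted(
            ((tuple(sorted((enc.alleles[i].allele_name, enc.alleles[j].allele_name))),
              float(S[i, j])) for i, j in enc.pair_index()),
            key=lambda t: (-t[1], t[0]),
        )
    return CallResult(
        system=system,
        best_score=best_score,
        best_pairs=best_pairs,
        ambiguous=len(grouped) > 1,
        no_call=no_call,
        grouped_name_pairs=grouped,
        all_scores=all_scores,
    )
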