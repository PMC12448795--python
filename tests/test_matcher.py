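"""Encoding, cosine scoring, orientation search and call semantics.

The orientation-search oracle here is deliberately independent of the
matcher: it materializes every one of the 2^B per-block orientations as
explicit strand vectors and takes the max of plain cosine means.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemotype.errors import UsageError
from hemotype.fixtures import cis_trans_catalog, cis_trans_observation
from hemotype.matcher import (
    SystemEncoding,
    TIE_TOLERANCE,
    call_system,
    cosine_similarity,
    encode_allele,
    encode_observed_strand,
    enumerate_diplotypes,
    observation_blocks,
    score_all_pairs,
    score_diplotype,
)
from hemotype.simulate import (
    apply_dropout,
    apply_phase_breaks,
    generate_synthetic_catalog,
    observe_truth,
)
from hemotype.variant_io import MISSING, SampleObservation


# ---------------------------------------------------------------- encoding

class TestEncoding:
    def test_reference_allele_vector(self, cis_trans_cat):
        ref = next(a for a in cis_trans_cat.alleles("TOY") if a.is_reference)
        hv = encode_allele(ref, cis_trans_cat.variants("TOY"))
        assert list(hv.values) == [1, 1, 0, 0]  # REF dims then ALT dims

    def test_allele_vector_norm_is_sqrt_V(self, synthetic_cat):
        for system in synthetic_cat.system_names():
            variants = synthetic_cat.variants(system)
            for allele in synthetic_cat.alleles(system):
                hv = encode_allele(allele, variants)
                assert np.linalg.norm(hv.values) == pytest.approx(math.sqrt(len(variants)))
                # exactly one of the two dims per variant
                V = len(variants)
                assert np.array_equal(hv.values[:V] + hv.values[V:], np.ones(V))

    def test_all_missing_encodes_to_zero_vector(self):
        obs = SampleObservation("s", "TOY", ["m1", "m2"],
                                np.full(2, MISSING), np.full(2, MISSING), np.full(2, MISSING))
        hv = encode_observed_strand(obs, {}, strand=1)
        assert not hv.values.any() and not hv.mask.any()

    def test_hom_ref_equals_reference_allele_vector(self, cis_trans_cat):
        obs = SampleObservation("s", "TOY", ["m1", "m2"],
                                np.zeros(2), np.full(2, MISSING), np.full(2, MISSING))
        hv1 = encode_observed_strand(obs, {}, strand=1)
        hv2 = encode_observed_strand(obs, {}, strand=2)
        ref = next(a for a in cis_trans_cat.alleles("TOY") if a.is_reference)
        expected = encode_allele(ref, cis_trans_cat.variants("TOY")).values
        assert np.array_equal(hv1.values, expected)
        assert np.array_equal(hv2.values, expected)

    def test_orientation_flip_swaps_strands_at_block_only(self):
        obs = SampleObservation("s", "TOY", ["m1", "m2"],
                                np.array([1, 2]), np.array([0, MISSING]),
                                np.array([7, MISSING]))
        keep1 = encode_observed_strand(obs, {7: 0}, strand=1)
        keep2 = encode_observed_strand(obs, {7: 0}, strand=2)
        flip1 = encode_observed_strand(obs, {7: 1}, strand=1)
        flip2 = encode_observed_strand(obs, {7: 1}, strand=2)
        # strands swap at the het variant m1 ...
        assert np.array_equal(keep1.values[[0, 2]], flip2.values[[0, 2]])
        assert np.array_equal(keep2.values[[0, 2]], flip1.values[[0, 2]])
        # ... and agree at the hom variant m2
        assert np.array_equal(keep1.values[[1, 3]], flip1.values[[1, 3]])


# ---------------------------------------------------------------- cosine

class TestCosine:
    def test_worked_examples(self):
        assert cosine_similarity(np.ones(4), np.ones(4)) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1, 0, 0, 1]), np.array([0, 1, 1, 0])) == 0.0
        # allele over 3 variants vs strand observed at 2 matching sites
        allele = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        strand = np.array([1, 1, 0, 0, 0, 0], dtype=float)
        assert cosine_similarity(allele, strand) == pytest.approx(2 / math.sqrt(6))

    def test_zero_norm_guard(self):
        assert cosine_similarity(np.zeros(4), np.ones(4)) == 0.0

    @given(st.lists(st.integers(0, 1), min_size=2, max_size=16),
           st.lists(st.integers(0, 1), min_size=2, max_size=16))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_symmetry(self, u, v):
        n = min(len(u), len(v))
        a, b = np.array(u[:n], float), np.array(v[:n], float)
        s = cosine_similarity(a, b)
        assert 0.0 <= s <= 1.0 + 1e-15
        assert s == pytest.approx(cosine_similarity(b, a))
        if a.any():
            assert cosine_similarity(a, a) == pytest.approx(1.0)


# ---------------------------------------------------------------- candidates

@pytest.mark.parametrize("n,expected", [(1, 1), (3, 6), (10, 55)])
def test_enumerate_diplotypes_counts(n, expected):
    cat = generate_synthetic_catalog(n_systems=1, alleles_per_system=(n, n),
                                     variants_per_system=(5, 5), seed=9)
    alleles = cat.alleles(cat.system_names()[0])
    pairs = enumerate_diplotypes(alleles)
    assert len(pairs) == expected
    # brute-force double loop agrees
    names = sorted(a.allele_name for a in alleles)
    brute = {(a, b) for k, a in enumerate(names) for b in names[k:]}
    assert {(p[0].allele_name, p[1].allele_name) for p in pairs} == brute


# ---------------------------------------------------------------- scoring

class TestScoreDiplotype:
    def test_noiseless_self_match_is_one(self, synthetic_cat, rng):
        for system in synthetic_cat.system_names():
            enc = SystemEncoding.from_catalog(synthetic_cat, system)
            i, j = sorted(rng.integers(0, enc.n_alleles, size=2))
            obs = observe_truth(enc, int(i), int(j))
            cand = score_diplotype(obs, (enc.alleles[int(i)], enc.alleles[int(j)]), enc=enc)
            assert cand.score == pytest.approx(1.0)

    def test_system_mismatch_rejected(self, cis_trans_cat, toy_cat):
        obs = cis_trans_observation("cis")
        abo = toy_cat.alleles("ABO")
        with pytest.raises(UsageError, match="mismatch"):
            score_diplotype(obs, (abo[0], abo[1]))

    def test_orientation_reported_per_block(self, cis_trans_cat):
        obs = cis_trans_observation("trans")
        alleles = {a.allele_name: a for a in cis_trans_cat.alleles("TOY")}
        cand = score_diplotype(obs, (alleles["TOY*X"], alleles["TOY*Z"]))
        assert cand.score == pytest.approx(1.0)
        assert set(cand.orientation) == {7}
        assert cand.orientation[7] in (0, 1)


class TestCallSystem:
    def test_hom_reference_unique_call(self, cis_trans_cat):
        obs = SampleObservation("s", "TOY", ["m1", "m2"],
                                np.zeros(2), np.full(2, MISSING), np.full(2, MISSING))
        r = call_system(obs, cis_trans_cat, "TOY")
        assert r.best_score == pytest.approx(1.0)
        assert not r.ambiguous and not r.no_call
        assert r.grouped_name_pairs == [("TOY*Y", "TOY*Y")]

    def test_cis_trans_toy(self, cis_trans_cat):
        unphased = call_system(cis_trans_observation("unphased"), cis_trans_cat, "TOY",
                               mode="unphased")
        assert unphased.ambiguous
        assert unphased.grouped_name_pairs == [("TOY*W", "TOY*Y"), ("TOY*X", "TOY*Z")]
        cis = call_system(cis_trans_observation("cis"), cis_trans_cat, "TOY")
        assert cis.grouped_name_pairs == [("TOY*W", "TOY*Y")] and not cis.ambiguous
        trans = call_system(cis_trans_observation("trans"), cis_trans_cat, "TOY")
        assert trans.grouped_name_pairs == [("TOY*X", "TOY*Z")] and not trans.ambiguous

    def test_all_missing_is_no_call(self, cis_trans_cat):
        obs = SampleObservation("s", "TOY", ["m1", "m2"],
                                np.full(2, MISSING), np.full(2, MISSING), np.full(2, MISSING))
        r = call_system(obs, cis_trans_cat, "TOY")
        assert r.no_call and r.best_score == 0.0

    def test_unknown_system_rejected(self, cis_trans_cat):
        obs = cis_trans_observation("cis")
        with pytest.raises(UsageError):
            call_system(obs, cis_trans_cat, "KEL")

    def test_all_scores_ranking(self, cis_trans_cat):
        r = call_system(cis_trans_observation("cis"), cis_trans_cat, "TOY",
                        include_all_scores=True)
        assert len(r.all_scores) == 10  # 4 alleles -> 10 unordered pairs
        scores = [s for _, s in r.all_scores]
        assert scores == sorted(scores, reverse=True)
        assert r.all_scores[0][0] == ("TOY*W", "TOY*Y")


# ------------------------------------------------- orientation-search oracle

def brute_force_tie_set(enc, obs):
    """Independent oracle: enumerate all 2^B orientations explicitly.

    Builds strand vectors from scratch (no matcher encoding helpers) and
    returns (best_score, tie set of name pairs).
    """
    V = enc.n_variants
    observed = np.asarray(obs.dosage) >= 0
    O = int(observed.sum())
    A = np.hstack([enc.ref_matrix, enc.alt_matrix])  # (n, 2V) REF dims first
    names = [a.allele_name for a in enc.alleles]
    blocks = {}
    for k, vid in enumerate(obs.variant_ids):
        if obs.dosage[k] == 1:
            key = obs.block[k] if obs.block[k] != MISSING else f"solo:{vid}"
            blocks.setdefault(key, []).append(k)
    keys = list(blocks)
    best, ties = -1.0, set()
    if O == 0:
        return 0.0, {tuple(sorted((a, b))) for k, a in enumerate(names) for b in names[k:]}
    for bits in itertools.product((0, 1), repeat=len(keys)):
        s1 = np.zeros(2 * V)
        s2 = np.zeros(2 * V)
        for k in range(V):
            d = int(obs.dosage[k])
            if d == MISSING:
                continue
            if d == 0:
                s1[k] = s2[k] = 1.0
            elif d == 2:
                s1[V + k] = s2[V + k] = 1.0
        for key, flip in zip(keys, bits):
            for k in blocks[key]:
                alt_first = (obs.phase[k] == 0) != bool(flip)
                if alt_first:
                    s1[V + k] = 1.0
                    s2[k] = 1.0
                else:
                    s1[k] = 1.0
                    s2[V + k] = 1.0
        d1 = A @ s1 / (math.sqrt(V) * math.sqrt(O))
        d2 = A @ s2 / (math.sqrt(V) * math.sqrt(O))
        for i in range(len(names)):
            for j in range(i, len(names)):
                s = max(0.5 * (d1[i] + d2[j]), 0.5 * (d1[j] + d2[i]))
                if s > best + TIE_TOLERANCE:
                    best, ties = s, {tuple(sorted((names[i], names[j])))}
                elif s >= best - TIE_TOLERANCE:
                    ties.add(tuple(sorted((names[i], names[j]))))
    return best, ties


def _random_observation(enc, rng, n_blocks_max=12, het_p=0.3):
    """Random dosages with hets partitioned contiguously into random blocks."""
    V = enc.n_variants
    rest = 1.0 - het_p
    dosage = rng.choice([MISSING, 0, 1, 2], size=V,
                        p=[0.2 * rest, 0.5 * rest, het_p, 0.3 * rest]).astype(np.int8)
    phase = np.full(V, MISSING, dtype=np.int8)
    block = np.full(V, MISSING, dtype=np.int32)
    het = np.flatnonzero(dosage == 1)
    if het.size:
        n_blocks = int(rng.integers(1, min(n_blocks_max, het.size) + 1))
        cuts = np.sort(rng.choice(np.arange(1, het.size), size=n_blocks - 1, replace=False)) \
            if n_blocks > 1 else np.array([], dtype=int)
        labels = np.zeros(het.size, dtype=int)
        for c in cuts:
            labels[c:] += 1
        phase[het] = rng.integers(0, 2, size=het.size)
        block[het] = labels
    return SampleObservation("rand", enc.system, enc.variant_ids, dosage, phase, block)


def test_per_block_search_equals_exhaustive_oracle():
    """Per-block orientation optimization == brute force over 2^B assignments."""
    cat = generate_synthetic_catalog(n_systems=2, alleles_per_system=(5, 7),
                                     variants_per_system=(8, 12), seed=77)
    rng = np.random.default_rng(2024)
    for _ in range(60):
        system = cat.system_names()[int(rng.integers(0, 2))]
        enc = SystemEncoding.from_catalog(cat, system)
        obs = _random_observation(enc, rng)
        r = call_system(obs, cat, system, min_score=0.0)
        best, ties = brute_force_tie_set(enc, obs)
        assert r.best_score == pytest.approx(best, abs=1e-12)
        assert {c.name_pair for c in r.best_pairs} == ties


# ---------------------------------------------------------------- properties

def test_self_consistency_every_pair(cis_trans_cat, toy_cat):
    """Noiseless observation of any pair scores 1.0 with the truth in the tie set."""
    for cat in (cis_trans_cat, toy_cat):
        for system in cat.system_names():
            enc = SystemEncoding.from_catalog(cat, system)
            for i in range(enc.n_alleles):
                for j in range(i, enc.n_alleles):
                    obs = observe_truth(enc, i, j)
                    r = call_system(obs, cat, system)
                    truth = tuple(sorted((enc.alleles[i].allele_name,
                                          enc.alleles[j].allele_name)))
                    assert r.best_score == pytest.approx(1.0)
                    assert truth in {c.name_pair for c in r.best_pairs}


def test_phasing_never_hurts(synthetic_cat, rng):
    """|best_pairs| in phased mode <= |best_pairs| unphased, same data."""
    for _ in range(40):
        system = synthetic_cat.system_names()[int(rng.integers(0, 6))]
        enc = SystemEncoding.from_catalog(synthetic_cat, system)
        i, j = sorted(rng.integers(0, enc.n_alleles, size=2))
        obs = observe_truth(enc, int(i), int(j))
        obs = apply_phase_breaks(obs, float(rng.random() * 0.5), rng)
        obs = apply_dropout(obs, float(rng.random() * 0.4), rng)
        phased = call_system(obs, synthetic_cat, system, min_score=0.0)
        unphased = call_system(obs, synthetic_cat, system, mode="unphased", min_score=0.0)
        assert len(phased.best_pairs) <= len(unphased.best_pairs)


def test_observation_blocks_unphased_mode_is_all_singletons(synthetic_cat, rng):
    system = synthetic_cat.system_names()[0]
    enc = SystemEncoding.from_catalog(synthetic_cat, system)
    obs = observe_truth(enc, 0, enc.n_alleles - 1)
    n_het = int((obs.dosage == 1).sum())
    assert len(observation_blocks(obs, "unphased")) == n_het
    assert len(observation_blocks(obs, "phased")) <= 1
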