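"""Synthetic catalogs, synthetic diploid samples, and the robustness grid.

The generator stands in for real ISBT tables: per system it emits a
reference allele plus alleles defined by random *distinct* variant subsets,
so a noiseless observation always identifies its true diplotype uniquely.

Two noise operators mirror how real inputs degrade:

- **dropout** — each catalog site independently loses its call with
  probability d (the whole site: a missing VCF record loses both strands);
- **phase breaks** — scanning heterozygous calls in order within a block,
  each adjacent pair is split with probability b; the relative strand
  orientation *between* the resulting blocks is randomized (that is exactly
  the information a phasing break destroys), orientation within each block
  is preserved.  At b=1 every het is a singleton block, which is the
  unphased limit.

``run_grid`` sweeps (d, b) conditions, calling every simulated sample and
tabulating concordance (true pair recovered as the *unique* top-scoring
diplotype), ambiguity and no-call rates.  Truth diplotypes are drawn
uniformly over each system's alleles; allele-frequency weighting is possible
via ``weights`` but uniform is the tested default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import Allele, Catalog, ValidationReport, Variant, build_catalog
from .errors import UsageError
from .matcher import DEFAULT_MIN_SCORE, PHASED, SystemEncoding, call_system
from .variant_io import MISSING, SampleObservation

_BASES = np.array(list("ACGT"))


def generate_synthetic_catalog(n_systems: int = 10,
                               alleles_per_system: tuple[int, int] = (4, 12),
                               variants_per_system: tuple[int, int] = (4, 12),
                               seed: int = 0,
                               null_allele_fraction: float = 0.2) -> Catalog:
    """Deterministic random catalog: reference + distinct-variant-set alleles.

    Each system gets ``variants_per_system`` SNVs at increasing positions on
    its own contig and ``alleles_per_system`` alleles: allele *01 is the
    reference (empty variant set) and the rest are distinct random nonempty
    subsets.  About ``null_allele_fraction`` of non-reference alleles are
    null (no antigens); the others express one antigen each.
    """
    a_lo, a_hi = alleles_per_system
    v_lo, v_hi = variants_per_system
    if a_lo < 1 or v_lo < 1 or a_hi < a_lo or v_hi < v_lo:
        raise UsageError("allele/variant ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    variants: list[Variant] = []
    alleles: list[Allele] = []
    for s in range(n_systems):
        system = f"SYN{s + 1:02d}"
        chrom = f"chr{s + 1}"
        n_var = int(rng.integers(v_lo, v_hi + 1))
        n_all = int(rng.integers(a_lo, a_hi + 1))
        if n_all - 1 > 2 ** n_var - 1:
            raise UsageError(
                f"system {system}: cannot draw {n_all - 1} distinct nonempty "
                f"subsets of {n_var} variants"
            )
        vids = []
        for k in range(n_var):
            ref, alt = rng.choice(4, size=2, replace=False)
            vid = f"{system}.v{k + 1}"
            vids.append(vid)
            variants.append(Variant(
                variant_id=vid, chrom=chrom, pos=10_000 + 100 * k,
                ref=str(_BASES[ref]), alt=str(_BASES[alt]), system=system,
            ))
        subsets: set[frozenset[str]] = {frozenset()}
        ordered_subsets: list[frozenset[str]] = [frozenset()]
        attempts = 0
        while len(ordered_subsets) < n_all:
            attempts += 1
            if attempts > 100_000:
                raise UsageError(f"system {system}: subset sampling failed to converge")
            size = int(rng.integers(1, n_var + 1))
            members = frozenset(np.take(vids, rng.choice(n_var, size=size, replace=False)))
            if members not in subsets:
                subsets.add(members)
                ordered_subsets.append(members)
        for k, subset in enumerate(ordered_subsets):
            name = f"{system}*{k + 1:02d}"
            if k > 0 and rng.random() < null_allele_fraction:
                antigens: frozenset[str] = frozenset()
            else:
                antigens = frozenset({f"{system}.AG{k + 1}"})
            alleles.append(Allele(
                allele_name=name, system=system,
                variant_ids=subset, antigens=antigens,
            ))
    return build_catalog(variants, alleles, ValidationReport())


def sample_truth(catalog: Catalog, rng: np.random.Generator) -> dict[str, tuple[Allele, Allele]]:
    """Draw a true diplotype per system: two independent uniform alleles."""
    truth = {}
    for system in catalog.system_names():
        alleles = sorted(catalog.alleles(system), key=lambda a: a.allele_name)
        i, j = rng.integers(0, len(alleles), size=2)
        pair = (alleles[int(i)], alleles[int(j)])
        truth[system] = pair if pair[0].allele_name <= pair[1].allele_name else (pair[1], pair[0])
    return truth


def observe_truth(enc: SystemEncoding, i: int, j: int, sample_id: str = "sim") -> SampleObservation:
    """Noiseless, perfectly phased observation of diplotype (allele i, allele j).

    All heterozygous sites share one phase block (id 0); strand 1 carries
    allele i.  Homozygous and reference sites need no block.
    """
    ai = enc.alt_matrix[i]
    aj = enc.alt_matrix[j]
    dosage = (ai + aj).astype(np.int8)
    V = enc.n_variants
    phase = np.full(V, MISSING, dtype=np.int8)
    block = np.full(V, MISSING, dtype=np.int32)
    het = dosage == 1
    phase[het] = np.where(ai[het] == 1, 0, 1)
    block[het] = 0
    return SampleObservation(sample_id, enc.system, enc.variant_ids, dosage, phase, block)


def simulate_observation(catalog: Catalog, system: str, pair: tuple[Allele, Allele],
                         sample_id: str = "sim") -> SampleObservation:
    """Public wrapper over :func:`observe_truth` resolving alleles by name."""
    enc = SystemEncoding.from_catalog(catalog, system)
    names = [a.allele_name for a in enc.alleles]
    try:
        i, j = names.index(pair[0].allele_name), names.index(pair[1].allele_name)
    except ValueError as exc:
        raise UsageError(f"pair not in system {system!r}: {exc}") from None
    return observe_truth(enc, i, j, sample_id)


def apply_phase_breaks(obs: SampleObservation, b: float,
                       rng: np.random.Generator) -> SampleObservation:
    """Split phase blocks between adjacent hets with probability b (in place on a copy).

    Members keep their within-block orientation; every block created by a
    split is flipped as a whole with probability 1/2 relative to its
    predecessor, erasing the inter-block linkage.  b=0 is the identity,
    b=1 the unphased limit (all singletons).
    """
    if not 0.0 <= b <= 1.0:
        raise UsageError(f"phase-break rate must be in [0,1], got {b}")
    dosage = obs.dosage.copy()
    phase = obs.phase.copy()
    block = obs.block.copy()
    het_idx = np.flatnonzero((dosage == 1) & (block != MISSING))
    if het_idx.size:
        next_id = int(block.max()) + 1
        # walk hets in catalog (position) order, grouped by original block
        current: dict[int, int] = {}      # original id -> current new id
        flip: dict[int, int] = {}         # original id -> current segment flip
        for i in het_idx:
            orig = int(block[i])
            if orig not in current:
                current[orig] = next_id
                flip[orig] = 0
                next_id += 1
            elif rng.random() < b:
                current[orig] = next_id
                next_id += 1
                flip[orig] = int(rng.integers(0, 2))
            block[i] = current[orig]
            if flip[orig]:
                phase[i] = 1 - phase[i]
    out = SampleObservation(obs.sample_id, obs.system, obs.variant_ids, dosage, phase, block)
    return out


def apply_dropout(obs: SampleObservation, d: float,
                  rng: np.random.Generator) -> SampleObservation:
    """Set each variant call to MISSING independently with probability d.

    Whole-site dropout: dosage, both strands, and block membership are lost
    together, matching what an absent VCF record costs.
    """
    if not 0.0 <= d <= 1.0:
        raise UsageError(f"dropout rate must be in [0,1], got {d}")
    dosage = obs.dosage.copy()
    phase = obs.phase.copy()
    block = obs.block.copy()
    drop = rng.random(dosage.shape[0]) < d
    dosage[drop] = MISSING
    phase[drop] = MISSING
    block[drop] = MISSING
    return SampleObservation(obs.sample_id, obs.system, obs.variant_ids, dosage, phase, block)


@dataclass
class GridResult:
    """Concordance/ambiguity/no-call rates per (dropout, phase-break) condition."""

    table: pd.DataFrame

    COLUMNS = ("dropout", "phase_break", "n_units", "concordance",
               "ambiguity_rate", "no_call_rate", "discordance")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2, double_precision=6)

    def rate(self, d: float, b: float, column: str) -> float:
        row = self.table[(self.table.dropout == d) & (self.table.phase_break == b)]
        if row.empty:
            raise UsageError(f"no grid condition ({d}, {b})")
        return float(row.iloc[0][column])


def run_grid(catalog: Catalog, d_values, b_values, n_samples: int, seed: int,
             mode: str = PHASED, min_score: float = DEFAULT_MIN_SCORE) -> GridResult:
    """Simulate and call ``n_samples`` per (d, b) condition; tabulate rates.

    Units are (sample, system) calls.  A unit is *concordant* when the true
    diplotype is the unique top-scoring pair (ambiguous-but-contains-truth is
    not concordant); *ambiguous* when several grouped pairs tie at the top;
    *no-call* when the best score falls below ``min_score``.  Discordance is
    the complement of concordance and no-call, so ambiguous units count as
    discordant and concordance + discordance + no_call = 1.

    Deterministic for a fixed seed: every condition runs on its own spawned
    substream, so single conditions can be reproduced independently.
    """
    systems = catalog.system_names()
    encodings = {s: SystemEncoding.from_catalog(catalog, s) for s in systems}
    n_alleles = {s: encodings[s].n_alleles for s in systems}
    conditions = [(float(d), float(b)) for d in d_values for b in b_values]
    streams = np.random.SeedSequence(seed).spawn(len(conditions))
    rows = []
    for (d, b), ss in zip(conditions, streams):
        rng = np.random.default_rng(ss)
        concordant = ambiguous = no_call = 0
        n_units = 0
        for k in range(n_samples):
            for system in systems:
                enc = encodings[system]
                i, j = rng.integers(0, n_alleles[system], size=2)
                i, j = (int(i), int(j)) if i <= j else (int(j), int(i))
                obs = observe_truth(enc, i, j, sample_id=f"sim{k}")
                if b > 0:
                    obs = apply_phase_breaks(obs, b, rng)
                if d > 0:
                    obs = apply_dropout(obs, d, rng)
                result = call_system(obs, catalog, system, mode=mode,
                                     min_score=min_score, enc=enc)
                n_units += 1
                if result.no_call:
                    no_call += 1
                    continue
                if result.ambiguous:
                    ambiguous += 1
                    continue
                truth_names = tuple(sorted((enc.alleles[i].allele_name,
                                            enc.alleles[j].allele_name)))
                if any(c.name_pair == truth_names for c in result.best_pairs):
                    concordant += 1
        rows.append({
            "dropout": d, "phase_break": b, "n_units": n_units,
            "concordance": concordant / n_units,
            "ambiguity_rate": ambiguous / n_units,
            "no_call_rate": no_call / n_units,
            "discordance": 1.0 - concordant / n_units - no_call / n_units,
        })
    return GridResult(pd.DataFrame(rows, columns=list(GridResult.COLUMNS)))
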