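"""Bundled toy catalog and worked-example fixtures.

The toy catalog is a miniature stand-in for real ISBT tables: an ABO-like
system wired to reproduce the classic cis/trans ambiguity, an RH-like system,
and eight synthetic systems from the catalog generator.  It ships as two
TSV files under ``hemotype/data/toy_catalog``.

``cis_trans_catalog`` is the minimal four-allele system exercising the
mechanism behind ambiguous pairs like ABO*B.01/O.01.01 vs A1.01/O.01.41:
two heterozygous sites whose cis configuration means one compound allele
plus the reference, and whose trans configuration means the two single-site
alleles.  Unphased, both diplotypes explain the dosages equally well.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .catalog import Allele, Catalog, ValidationReport, Variant, build_catalog, load_catalog
from .variant_io import MISSING, SampleObservation


def toy_catalog() -> Catalog:
    """Load the bundled toy catalog (ABO-like + RH-like + 8 synthetic systems)."""
    data = resources.files("hemotype.data") / "toy_catalog"
    return load_catalog(str(data / "variants.tsv"), str(data / "haplotypes.tsv"))


def cis_trans_catalog() -> Catalog:
    """Four alleles over two variants: W={m1,m2}, X={m1}, Z={m2}, Y={} (ref)."""
    system = "TOY"
    variants = [
        Variant("m1", "chrT", 100, "A", "G", system),
        Variant("m2", "chrT", 200, "C", "T", system),
    ]
    alleles = [
        Allele("TOY*W", system, frozenset({"m1", "m2"}), frozenset({"W"})),
        Allele("TOY*X", system, frozenset({"m1"}), frozenset({"X"})),
        Allele("TOY*Y", system, frozenset(), frozenset({"Y"})),
        Allele("TOY*Z", system, frozenset({"m2"}), frozenset({"Z"})),
    ]
    return build_catalog(variants, alleles, ValidationReport())


def _het_obs(phase: tuple[int, int], block: tuple[int, int],
             sample_id: str = "toy") -> SampleObservation:
    return SampleObservation(
        sample_id, "TOY", ["m1", "m2"],
        dosage=np.array([1, 1], dtype=np.int8),
        phase=np.array(phase, dtype=np.int8),
        block=np.array(block, dtype=np.int32),
    )


def cis_trans_observation(phasing: str) -> SampleObservation:
    """Double-het observation of the cis/trans toy.

    ``phasing`` is "cis" (both ALTs on strand 1 in one block: truth W/Y),
    "trans" (ALTs on opposite strands: truth X/Z) or "unphased" (no blocks:
    both diplotypes tie).
    """
    if phasing == "cis":
        return _het_obs(phase=(0, 0), block=(7, 7))
    if phasing == "trans":
        return _het_obs(phase=(0, 1), block=(7, 7))
    if phasing == "unphased":
        return _het_obs(phase=(0, 0), block=(MISSING, MISSING))
    raise ValueError(f"unknown phasing {phasing!r}")
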