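"""Blood-group allele catalogs.

A catalog describes, per blood-group system, the panel of catalog-defining
variants and the named alleles (haplotypes) built from them, in the style of
ISBT allele tables.  Two tab-delimited tables define a catalog:

``variants.tsv`` — columns ``system``, ``variant_id``, ``chrom``, ``pos``,
``ref``, ``alt``.  One row per catalog-defining SNV/indel; coordinates are
1-based and indels are VCF-style anchored so rows compare directly to VCF
records.

``haplotypes.tsv`` — columns ``system``, ``allele_name``, ``variant_ids``
(semicolon-separated, empty for the reference allele), ``antigens``
(semicolon-separated, empty for null alleles).

Lines starting with ``#`` are comments in both files.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

from .errors import CatalogFormatError, CatalogValidationError, UsageError

_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ("system", "variant_id", "chrom", "pos", "ref", "alt")
HAPLOTYPE_COLUMNS = ("system", "allele_name", "variant_ids", "antigens")


@dataclass(frozen=True)
class Variant:
    """One catalog-defining genomic change (SNV or anchored indel)."""

    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    system: str

    def validate(self) -> None:
        if self.pos < 1:
            raise CatalogValidationError(
                f"variant {self.variant_id!r}: pos must be >= 1, got {self.pos}"
            )
        if not self.ref or not self.alt:
            raise CatalogValidationError(
                f"variant {self.variant_id!r}: ref and alt must be non-empty"
            )
        if self.ref == self.alt:
            raise CatalogValidationError(
                f"variant {self.variant_id!r}: ref equals alt ({self.ref!r})"
            )
        bad = (set(self.ref) | set(self.alt)) - _BASES
        if bad:
            raise CatalogValidationError(
                f"variant {self.variant_id!r}: non-ACGT characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Allele:
    """A named haplotype: a set of variants plus the antigens it expresses.

    The empty variant set identifies the system's reference allele; an empty
    antigen set is a null allele (expresses nothing serologically).
    """

    allele_name: str
    system: str
    variant_ids: frozenset[str]
    antigens: frozenset[str]

    @property
    def is_reference(self) -> bool:
        return not self.variant_ids


@dataclass
class ValidationReport:
    """Warnings collected while building a catalog (never fatal)."""

    warnings: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_dict(self) -> dict:
        return {"warnings": list(self.warnings)}


@dataclass
class Catalog:
    """Per-system variant panels and allele definitions.

    ``groupings`` optionally maps allele names to a reporting label; grouping
    collapses names at reporting time only and never changes scores.
    """

    systems: dict[str, tuple[list[Variant], list[Allele]]]
    groupings: dict[str, str] = field(default_factory=dict)
    report: ValidationReport = field(default_factory=ValidationReport)

    def system_names(self) -> list[str]:
        return list(self.systems)

    def variants(self, system: str) -> list[Variant]:
        self._check_system(system)
        return self.systems[system][0]

    def alleles(self, system: str) -> list[Allele]:
        self._check_system(system)
        return self.systems[system][1]

    def display_name(self, allele_name: str) -> str:
        """Reporting label for an allele after grouping (identity if ungrouped)."""
        return self.groupings.get(allele_name, allele_name)

    def _check_system(self, system: str) -> None:
        if system not in self.systems:
            raise UsageError(f"unknown system {system!r}")


def _data_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Read a TSV, skipping comments; returns (header, [(line_no, fields)])."""
    with open(path, "rt", encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        rows: list[tuple[int, list[str]]] = []
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = next(csv.reader(io.StringIO(line), delimiter="\t"))
            fields = [f.strip() for f in fields]
            if header is None:
                header = fields
            else:
                rows.append((line_no, fields))
    if header is None:
        raise CatalogFormatError(f"{path}: empty table (no header line)")
    return header, rows


def _column_index(header: list[str], required: tuple[str, ...], path) -> dict[str, int]:
    index = {}
    for col in required:
        if col not in header:
            raise CatalogFormatError(f"{path}: missing required column {col!r}")
        index[col] = header.index(col)
    return index


def parse_variant_table(path) -> list[Variant]:
    """Parse the variant-mapping table into validated :class:`Variant` rows.

    Order is preserved; duplicate ``variant_id`` values are rejected.
    """
    header, rows = _data_rows(path)
    idx = _column_index(header, VARIANT_COLUMNS, path)
    variants: list[Variant] = []
    seen: dict[str, int] = {}
    for line_no, fields in rows:
        if len(fields) < len(header):
            raise CatalogFormatError(f"{path}:{line_no}: expected {len(header)} fields")
        raw_pos = fields[idx["pos"]]
        try:
            pos = int(raw_pos)
        except ValueError:
            raise CatalogFormatError(
                f"{path}:{line_no}: pos must be an integer, got {raw_pos!r}"
            ) from None
        variant = Variant(
            variant_id=fields[idx["variant_id"]],
            chrom=fields[idx["chrom"]],
            pos=pos,
            ref=fields[idx["ref"]].upper(),
            alt=fields[idx["alt"]].upper(),
            system=fields[idx["system"]],
        )
        variant.validate()
        if variant.variant_id in seen:
            raise CatalogValidationError(
                f"{path}:{line_no}: duplicate variant_id {variant.variant_id!r} "
                f"(first defined at line {seen[variant.variant_id]})"
            )
        seen[variant.variant_id] = line_no
        variants.append(variant)
    return variants


def _split_list(raw: str) -> list[str]:
    return [tok.strip() for tok in raw.split(";") if tok.strip()]


def parse_haplotype_table(path, variants: list[Variant]) -> tuple[list[Allele], ValidationReport]:
    """Parse the haplotype-definition table, resolving variant references.

    Two alleles of one system with identical variant sets are intrinsically
    indistinguishable at the panel's resolution; both are kept and a warning
    is recorded (they surface downstream as call ambiguity).
    """
    header, rows = _data_rows(path)
    idx = _column_index(header, HAPLOTYPE_COLUMNS, path)
    by_system_ids = {}
    for v in variants:
        by_system_ids.setdefault(v.system, set()).add(v.variant_id)

    report = ValidationReport()
    alleles: list[Allele] = []
    names_seen: set[tuple[str, str]] = set()
    sets_seen: dict[tuple[str, frozenset[str]], str] = {}
    for line_no, fields in rows:
        if len(fields) < len(header):
            raise CatalogFormatError(f"{path}:{line_no}: expected {len(header)} fields")
        system = fields[idx["system"]]
        name = fields[idx["allele_name"]]
        variant_ids = frozenset(_split_list(fields[idx["variant_ids"]]))
        antigens = frozenset(_split_list(fields[idx["antigens"]]))
        unknown = variant_ids - by_system_ids.get(system, set())
        if unknown:
            raise CatalogValidationError(
                f"{path}:{line_no}: allele {name!r} references unknown variant id(s) "
                f"{sorted(unknown)} in system {system!r}"
            )
        if (system, name) in names_seen:
            raise CatalogValidationError(
                f"{path}:{line_no}: duplicate allele_name {name!r} in system {system!r}"
            )
        names_seen.add((system, name))
        key = (system, variant_ids)
        if key in sets_seen:
            report.warn(
                f"system {system}: alleles {sets_seen[key]!r} and {name!r} share an "
                "identical variant set and are indistinguishable at this panel"
            )
        else:
            sets_seen[key] = name
        alleles.append(
            Allele(allele_name=name, system=system, variant_ids=variant_ids, antigens=antigens)
        )
    return alleles, report


def build_catalog(variants: list[Variant], alleles: list[Allele],
                  report: ValidationReport | None = None) -> Catalog:
    """Assemble and cross-validate a :class:`Catalog` from parsed rows."""
    systems: dict[str, tuple[list[Variant], list[Allele]]] = {}
    for v in variants:
        systems.setdefault(v.system, ([], []))[0].append(v)
    for a in alleles:
        systems.setdefault(a.system, ([], []))[1].append(a)
    for system, (svars, salleles) in systems.items():
        if not salleles:
            raise CatalogValidationError(f"system {system!r} defines variants but no alleles")
        refs = [a.allele_name for a in salleles if a.is_reference]
        if len(refs) > 1:
            raise CatalogValidationError(
                f"system {system!r} has more than one reference allele: {refs}"
            )
    return Catalog(systems=systems, report=report or ValidationReport())


def load_catalog(variant_path, haplotype_path) -> Catalog:
    """Load a catalog from its two TSV files."""
    variants = parse_variant_table(variant_path)
    alleles, report = parse_haplotype_table(haplotype_path, variants)
    return build_catalog(variants, alleles, report)


def write_variant_table(variants: list[Variant], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(f"{v.system}\t{v.variant_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


def write_haplotype_table(alleles: list[Allele], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(HAPLOTYPE_COLUMNS) + "\n")
        for a in alleles:
            fh.write(
                f"{a.system}\t{a.allele_name}\t"
                f"{';'.join(sorted(a.variant_ids))}\t{';'.join(sorted(a.antigens))}\n"
            )


def apply_allele_grouping(catalog: Catalog, groups: dict[str, str]) -> Catalog:
    """Return a catalog whose *reports* collapse grouped alleles to their label.

    Scoring always uses the full allele definitions; only the names emitted in
    call results are rewritten, so grouping can merge alleles a downstream
    reference method cannot distinguish (e.g. GYPB*03N.xx null alleles under a
    single GYPB*03 label) without touching similarity scores.
    """
    known = {a.allele_name for _, salleles in catalog.systems.values() for a in salleles}
    unknown = set(groups) - known
    if unknown:
        raise CatalogValidationError(
            f"grouping references unknown allele name(s): {sorted(unknown)}"
        )
    merged = dict(catalog.groupings)
    merged.update(groups)
    return replace(catalog, groupings=merged)


def antigen_phenotype(pair: tuple[Allele, Allele]) -> frozenset[str]:
    """Predicted serological phenotype of a diplotype: codominant union.

    Null alleles contribute nothing; (null, null) yields the empty set (an
    O-like phenotype).  Dominance/suppressor epistasis is out of scope.
    """
    a, b = pair
    if a.system != b.system:
        raise UsageError(
            f"antigen_phenotype: mixed-system pair ({a.system!r}, {b.system!r})"
        )
    return a.antigens | b.antigens
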