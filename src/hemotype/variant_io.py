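"""Sample observations: VCF genotypes and coverage, projected onto a catalog.

The projection is total: a :class:`SampleObservation` always carries exactly
one call per catalog variant of its system, whatever the VCF contains.
Catalog sites absent from the VCF resolve according to ``missing_policy`` —
``ASSUME_REF`` (sensible for whole-genome single-sample VCFs, where an
unlisted site usually means hom-ref) or ``ASSUME_MISSING`` (recommended for
targeted panels, and the semantics of the dropout simulations).

Coverage summaries are read from bedGraph tracks (``chrom  start  end  value``,
0-based half-open intervals); bases without data count as depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .catalog import Catalog
from .errors import UsageError

#: sentinel for a missing dosage / absent phase block in the packed arrays
MISSING = -1

REF, ALT = "REF", "ALT"


@dataclass(frozen=True)
class ObservedCall:
    """One catalog variant as observed in a sample.

    ``dosage`` is the alt-allele count in {0, 1, 2} or ``None`` when missing.
    ``strand_alleles`` is the ordered (strand1, strand2) pair over
    {"REF", "ALT", "MISSING"}; the order is meaningful only within a phase
    block.  ``phase_block`` is set only for *phased heterozygous* calls.
    """

    variant_id: str
    dosage: int | None
    strand_alleles: tuple[str, str]
    phase_block: int | None


@dataclass
class SampleObservation:
    """All observed calls for one sample in one blood-group system.

    Internally packed as parallel numpy arrays over the system's catalog
    variants (in catalog order):

    - ``dosage``: int8, alt count or -1 for missing;
    - ``phase``: int8, for heterozygous calls 0 if strand 1 carries the ALT
      allele and 1 if strand 2 does (block-local convention), -1 otherwise;
    - ``block``: int32, phase-block id for phased hets, -1 otherwise
      (unphased hets are their own implicit singleton blocks).
    """

    sample_id: str
    system: str
    variant_ids: list[str]
    dosage: np.ndarray
    phase: np.ndarray
    block: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phase = np.asarray(self.phase, dtype=np.int8)
        self.block = np.asarray(self.block, dtype=np.int32)
        if not (self.dosage.shape == self.phase.shape == self.block.shape == (n,)):
            raise ValueError("observation arrays must match the variant list length")

    @property
    def calls(self) -> list[ObservedCall]:
        out = []
        for i, vid in enumerate(self.variant_ids):
            d = int(self.dosage[i])
            if d == MISSING:
                out.append(ObservedCall(vid, None, ("MISSING", "MISSING"), None))
            elif d == 0:
                out.append(ObservedCall(vid, 0, (REF, REF), None))
            elif d == 2:
                out.append(ObservedCall(vid, 2, (ALT, ALT), None))
            else:
                strands = (ALT, REF) if self.phase[i] == 0 else (REF, ALT)
                blk = int(self.block[i])
                out.append(ObservedCall(vid, 1, strands, None if blk == MISSING else blk))
        return out

    @property
    def blocks(self) -> dict[int, list[str]]:
        """Phase-block id -> member variant ids (phased hets only)."""
        out: dict[int, list[str]] = {}
        for i, vid in enumerate(self.variant_ids):
            if self.dosage[i] == 1 and self.block[i] != MISSING:
                out.setdefault(int(self.block[i]), []).append(vid)
        return out

    @classmethod
    def from_calls(cls, sample_id: str, system: str, variant_ids: list[str],
                   calls: dict[str, ObservedCall]) -> "SampleObservation":
        n = len(variant_ids)
        dosage = np.full(n, MISSING, dtype=np.int8)
        phase = np.full(n, MISSING, dtype=np.int8)
        block = np.full(n, MISSING, dtype=np.int32)
        for i, vid in enumerate(variant_ids):
            call = calls.get(vid)
            if call is None or call.dosage is None:
                continue
            dosage[i] = call.dosage
            if call.dosage == 1:
                phase[i] = 0 if call.strand_alleles[0] == ALT else 1
                if call.phase_block is not None:
                    block[i] = call.phase_block
        return cls(sample_id, system, list(variant_ids), dosage, phase, block)


def _parse_genotype(sample_field, alt_index: int):
    """Return (dosage, first_strand_is_alt, phased, ps) for one alt allele.

    ``sample_field`` is a pysam VariantRecordSample.  Any allele index other
    than 0 or the requested alt counts as REF for this projection (a site is
    matched per (chrom, pos, ref, alt) after multi-allelic splitting).
    """
    gt = sample_field.get("GT")
    if gt is None or len(gt) != 2 or any(a is None for a in gt):
        return None
    a1, a2 = (1 if a == alt_index else 0 for a in gt)
    phased = bool(sample_field.phased)
    ps = sample_field.get("PS") if phased else None
    return a1 + a2, a1 == 1, phased, ps


def read_sample_observation(vcf_path, sample_id: str, catalog: Catalog, system: str,
                            missing_policy: str = "ASSUME_REF") -> SampleObservation:
    """Project a sample's VCF genotypes onto one system's catalog variants.

    Catalog variants are matched by (chrom, pos, ref, alt) after splitting
    multi-allelic records.  Phased heterozygous genotypes ("|" separator)
    carry their PS tag as the phase block, defaulting to one block per contig
    when GT is phased but PS is absent.  Symbolic alleles are skipped with a
    warning.  VCF records not in the catalog are ignored.
    """
    if missing_policy not in ("ASSUME_REF", "ASSUME_MISSING"):
        raise UsageError(f"unknown missing_policy {missing_policy!r}")
    variants = catalog.variants(system)
    variant_ids = [v.variant_id for v in variants]
    lookup = {(v.chrom, v.pos, v.ref, v.alt): i for i, v in enumerate(variants)}

    n = len(variants)
    default = 0 if missing_policy == "ASSUME_REF" else MISSING
    dosage = np.full(n, default, dtype=np.int8)
    phase = np.full(n, MISSING, dtype=np.int8)
    block = np.full(n, MISSING, dtype=np.int32)
    notes: list[str] = []

    # stable synthetic block ids for phased-without-PS records, one per contig
    contig_block: dict[str, int] = {}
    next_auto_block = 1_000_000

    with pysam.VariantFile(str(vcf_path)) as vcf:
        if sample_id not in vcf.header.samples:
            raise UsageError(f"sample {sample_id!r} not present in {vcf_path}")
        wanted_contigs = {v.chrom for v in variants}
        for rec in vcf:
            if rec.chrom not in wanted_contigs or rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt.startswith("<"):
                    notes.append(f"{rec.chrom}:{rec.pos}: symbolic allele {alt} skipped")
                    continue
                i = lookup.get((rec.chrom, rec.pos, rec.ref, alt))
                if i is None:
                    continue
                parsed = _parse_genotype(rec.samples[sample_id], alt_index)
                if parsed is None:
                    notes.append(f"{rec.chrom}:{rec.pos}: malformed GT, call set MISSING")
                    dosage[i] = MISSING
                    continue
                dos, first_is_alt, phased, ps = parsed
                dosage[i] = dos
                if dos == 1:
                    phase[i] = 0 if first_is_alt else 1
                    if phased:
                        if ps is None:
                            if rec.chrom not in contig_block:
                                contig_block[rec.chrom] = next_auto_block
                                next_auto_block += 1
                            block[i] = contig_block[rec.chrom]
                        else:
                            block[i] = int(ps)
    obs = SampleObservation(sample_id, system, variant_ids, dosage, phase, block)
    obs.warnings.extend(notes)
    return obs


def write_vcf(observations: list[SampleObservation], catalog: Catalog, path,
              sample_id: str | None = None) -> None:
    """Write a minimal single-sample VCF 4.2 covering the given observations.

    Intended for fixtures and simulation dumps: round-trips dosage, strand
    order, and block structure through :func:`read_sample_observation` when
    read back with ``missing_policy="ASSUME_MISSING"``.
    """
    if not observations:
        raise UsageError("write_vcf: no observations given")
    sample = sample_id or observations[0].sample_id
    rows = []
    contigs: list[str] = []
    for obs in observations:
        variants = {v.variant_id: v for v in catalog.variants(obs.system)}
        for i, vid in enumerate(obs.variant_ids):
            d = int(obs.dosage[i])
            if d == MISSING:
                continue
            v = variants[vid]
            if v.chrom not in contigs:
                contigs.append(v.chrom)
            if d == 0:
                gt, ps = "0/0", None
            elif d == 2:
                gt, ps = "1/1", None
            else:
                ordered = ("1", "0") if obs.phase[i] == 0 else ("0", "1")
                blk = int(obs.block[i])
                if blk != MISSING:
                    gt, ps = "|".join(ordered), blk
                else:
                    gt, ps = "/".join(ordered), None
            fmt = "GT:PS" if ps is not None else "GT"
            val = f"{gt}:{ps}" if ps is not None else gt
            rows.append((v.chrom, v.pos, vid, v.ref, v.alt, fmt, val))
    rows.sort(key=lambda r: (contigs.index(r[0]), r[1]))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, vid, ref, alt, fmt, val in rows:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t{val}\n")


class BedGraphCoverage:
    """Per-base coverage from a bedGraph track, absent bases counting as 0."""

    def __init__(self, path):
        self.path = str(path)
        self._intervals: dict[str, list[tuple[int, int, float]]] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                chrom, start, end, value = line.split()[:4]
                self._intervals.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        for ivs in self._intervals.values():
            ivs.sort()

    @property
    def contigs(self) -> set[str]:
        return set(self._intervals)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean depth over the 1-based closed interval [start, end]."""
        if chrom not in self._intervals:
            raise UsageError(f"contig {chrom!r} not present in {self.path}")
        if start < 1 or end < start:
            raise UsageError(f"bad interval {chrom}:{start}-{end}")
        lo, hi = start - 1, end  # 0-based half-open
        total = 0.0
        for istart, iend, value in self._intervals[chrom]:
            overlap = min(hi, iend) - max(lo, istart)
            if overlap > 0:
                total += overlap * value
        return total / (hi - lo)


def read_mean_coverage(coverage_path, chrom: str, start: int, end: int) -> float:
    """Arithmetic mean depth over a 1-based closed region of a bedGraph track."""
    return BedGraphCoverage(coverage_path).mean(chrom, start, end)


def write_bedgraph(path, tracks: dict[str, np.ndarray], offsets: dict[str, int] | None = None) -> None:
    """Write per-base depth arrays as a bedGraph (run-length encoded).

    ``tracks`` maps contig -> per-base values starting at the contig's offset
    (0-based; default 0).  Zero runs are emitted too, so the contig is always
    present in the file.
    """
    offsets = offsets or {}
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom, values in tracks.items():
            values = np.asarray(values, dtype=float)
            off = offsets.get(chrom, 0)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{off + s}\t{off + e}\t{values[s]:g}\n")
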