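"""Structured JSON report: the tool's machine-readable output contract.

The schema is versioned and normative for this artifact; a JSON Schema
rendering (generated from the pydantic models) ships under
``hemotype/data/report.schema.json`` for external consumers.  Field order is
deterministic (model definition order) so reports diff cleanly.
"""

from __future__ import annotations

import hashlib
import json

from pydantic import BaseModel, Field

from .catalog import Catalog, antigen_phenotype
from .matcher import CallResult

SCHEMA_VERSION = "1.0"


class SystemCall(BaseModel):
    """One system's diplotype call, with grouped (reporting) allele names."""

    best_pairs: list[tuple[str, str]]
    best_score: float
    ambiguous: bool
    no_call: bool
    antigen_phenotype: list[str]
    all_scores: list[tuple[tuple[str, str], float]] | None = None


class CoverageCall(BaseModel):
    rule_id: str
    status: str
    target_mean: float | None = None
    control_mean: float | None = None
    ratio: float | None = None
    copy_number: int | None = None
    label: str | None = None
    reason: str | None = None


class Provenance(BaseModel):
    catalog_checksum: str | None = None
    inputs: dict[str, str] = Field(default_factory=dict)
    parameters: dict[str, str] = Field(default_factory=dict)
    seed: int | None = None


class Report(BaseModel):
    schema_version: str = SCHEMA_VERSION
    sample_id: str
    systems: dict[str, SystemCall]
    coverage_calls: list[CoverageCall] = Field(default_factory=list)
    provenance: Provenance = Field(default_factory=Provenance)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=indent)


def validate_report(data: dict) -> Report:
    """Parse-or-raise validation of a report dict against the schema."""
    return Report.model_validate(data)


def report_json_schema() -> dict:
    return Report.model_json_schema()


def catalog_checksum(*paths) -> str:
    """sha256 over the catalog files, for provenance."""
    h = hashlib.sha256()
    for path in paths:
        with open(path, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()


def _call_phenotype(result: CallResult) -> list[str]:
    """Antigens implied by the call: intersection over tied best pairs.

    With a unique best pair this is the codominant union of its two alleles'
    antigens; under ambiguity only antigens common to every tied candidate
    are reported (antigens certain to be present).
    """
    if result.no_call or not result.best_pairs:
        return []
    sets = [antigen_phenotype(c.pair) for c in result.best_pairs]
    common = frozenset.intersection(*sets)
    return sorted(common)


def build_report(sample_id: str, results: dict[str, CallResult], catalog: Catalog,
                 coverage_calls: list[dict] | None = None,
                 provenance: Provenance | None = None) -> Report:
    systems = {}
    for system, result in results.items():
        systems[system] = SystemCall(
            best_pairs=result.grouped_name_pairs,
            best_score=result.best_score,
            ambiguous=result.ambiguous,
            no_call=result.no_call,
            antigen_phenotype=_call_phenotype(result),
            all_scores=result.all_scores,
        )
    return Report(
        sample_id=sample_id,
        systems=systems,
        coverage_calls=[CoverageCall.model_validate(c) for c in (coverage_calls or [])],
        provenance=provenance or Provenance(),
    )
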