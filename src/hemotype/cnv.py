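"""Coverage-ratio copy-number heuristics.

Structural events that short-read variant callers routinely miss — the RHD
gene deletion (RHD*01N.01) and the hybrid-defining RHCE interval behind the
C antigen — leave a clean footprint in read depth.  Each rule compares the
mean depth of a target region against a control region known to sit at two
copies, and maps the ratio onto a copy number through ordered breakpoints:

    expected ratio ~ 0.0 (0 copies), 0.5 (1 copy), 1.0 (2 copies)

with default midpoint breakpoints at 0.25 and 0.75.  Ratios are invariant
under joint depth scaling, so the heuristic is robust to overall coverage
level (though not to GC or capture bias — no GC normalization is applied).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import LowControlDepthError, UsageError
from .variant_io import BedGraphCoverage

#: control regions shallower than this (reads) make a sample untypeable
DEFAULT_MIN_CONTROL_DEPTH = 10.0

DEFAULT_BREAKPOINTS = (0.25, 0.75)


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based closed
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise UsageError(f"bad region {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class CoverageRule:
    """One target/control depth-ratio rule.

    ``breakpoints`` are the strictly increasing ratio thresholds between copy
    numbers 0|1 and 1|2; ``label_map`` maps copy number -> reported label
    (e.g. {0: "D-", 1: "D+", 2: "D+"} for RHD presence/absence).
    """

    rule_id: str
    target_region: Region
    control_region: Region
    breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS
    label_map: dict = field(default_factory=dict)
    min_control_depth: float = DEFAULT_MIN_CONTROL_DEPTH

    def __post_init__(self):
        lo, hi = self.breakpoints
        if not (0.0 < lo < hi):
            raise UsageError(f"rule {self.rule_id}: breakpoints must be strictly increasing and positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CoverageRule":
        return cls(
            rule_id=d["rule_id"],
            target_region=Region(**d["target_region"]),
            control_region=Region(**d["control_region"]),
            breakpoints=tuple(d.get("breakpoints", DEFAULT_BREAKPOINTS)),
            label_map={int(k): v for k, v in d.get("label_map", {}).items()},
            min_control_depth=float(d.get("min_control_depth", DEFAULT_MIN_CONTROL_DEPTH)),
        )


def load_rules(path) -> list[CoverageRule]:
    """Load coverage rules from a JSON config (list of rule objects)."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [CoverageRule.from_dict(d) for d in raw]


def coverage_ratio(target_mean: float, control_mean: float,
                   min_control_depth: float = DEFAULT_MIN_CONTROL_DEPTH) -> float:
    """target/control depth ratio; errors when the control is too shallow."""
    if control_mean <= min_control_depth:
        raise LowControlDepthError(
            f"control depth {control_mean:.2f} <= minimum {min_control_depth:.2f}"
        )
    return target_mean / control_mean


def infer_copy_number(ratio: float, rule: CoverageRule) -> tuple[int, str]:
    """Map a depth ratio to (copy number, label) via the rule's breakpoints."""
    if ratio < 0:
        raise UsageError(f"negative coverage ratio {ratio}")
    lo, hi = rule.breakpoints
    cn = 0 if ratio < lo else (1 if ratio < hi else 2)
    return cn, rule.label_map.get(cn, str(cn))


def apply_coverage_rules(coverage_path, rules: list[CoverageRule]) -> list[dict]:
    """Evaluate every rule against a coverage track; failures stay per-rule.

    Each result dict carries rule_id, status ("OK" or "NO_CALL"), and on
    success the ratio, copy number and label; a failing rule (missing contig,
    shallow control) never affects its siblings.
    """
    coverage = BedGraphCoverage(coverage_path)
    results = []
    for rule in rules:
        try:
            t, c = rule.target_region, rule.control_region
            target_mean = coverage.mean(t.chrom, t.start, t.end)
            control_mean = coverage.mean(c.chrom, c.start, c.end)
            ratio = coverage_ratio(target_mean, control_mean, rule.min_control_depth)
            cn, label = infer_copy_number(ratio, rule)
            results.append({
                "rule_id": rule.rule_id,
                "status": "OK",
                "target_mean": target_mean,
                "control_mean": control_mean,
                "ratio": ratio,
                "copy_number": cn,
                "label": label,
            })
        except (LowControlDepthError, UsageError) as exc:
            results.append({
                "rule_id": rule.rule_id,
                "status": "NO_CALL",
                "reason": str(exc),
            })
    return results
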